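"""Two-stage optimisation schedule.

Stage 1 pretrains the encoder + ViT with the contrastive latent objective
while the decoder is frozen; stage 2 freezes the encoder + ViT and fine-tunes
the decoder with the composite Dice + CE + LRP loss.  Both stages use SGD
with Nesterov momentum 0.99 and a polynomial learning-rate schedule decaying
from 0.001 to zero.

At full clinical scale this schedule runs for 4000 + 4000 epochs of 201 batch
iterations; the desk-scale defaults here (tens of epochs, whole-volume
batches over a small phantom cohort) keep the same structure at a size a
single CPU handles in minutes.  Because the encoder is frozen during stage 2,
its features for each cohort volume are computed once and cached, and only
the decoder is evaluated per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .losses import LossConfig, composite_loss
from .network import Network, normalize_volume

__all__ = ["TrainConfig", "SGD", "poly_lr", "finetune", "run_two_stage",
           "load_cohort"]


@dataclass
class TrainConfig:
    """Optimisation hyperparameters.

    Clinical-scale values: epochs_pretrain = epochs_finetune = 4000 with 201
    batch iterations per epoch.  Desk-scale defaults are far smaller; one
    "iteration" is one whole-volume batch.
    """

    epochs_pretrain: int = 30
    epochs_finetune: int = 30
    iters_per_epoch: int | None = None   # None: one pass over the cohort
    lr0: float = 1e-3
    momentum: float = 0.99               # Nesterov
    poly_power: float = 0.9
    batch_size: int = 2
    clip_norm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs_pretrain < 1 or self.epochs_finetune < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")


def poly_lr(epoch: int, total_epochs: int, lr0: float = 1e-3,
            power: float = 0.9) -> float:
    """Polynomial decay: lr0 * (1 - epoch/total)^power; zero at the end."""
    if total_epochs == 0:
        raise ValueError("total_epochs must be positive")
    if not 0 <= epoch <= total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs}]")
    return float(lr0 * (1.0 - epoch / total_epochs) ** power)


class SGD:
    """SGD with (Nesterov) momentum and global-norm gradient clipping."""

    def __init__(self, params: list[Tensor], momentum: float = 0.99,
                 nesterov: bool = True, clip_norm: float | None = 10.0):
        self.params = params
        self.momentum = momentum
        self.nesterov = nesterov
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float) -> None:
        grads = [np.zeros_like(p.data) if p.grad is None else p.grad
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
            if total > self.clip_norm:
                grads = [g * (self.clip_norm / total) for g in grads]
        for p, v, g in zip(self.params, self.velocity, grads):
            v *= self.momentum
            v += g
            step = g + self.momentum * v if self.nesterov else v
            p.data -= lr * step


def load_cohort(manifest: dict, cohort_dir: str | Path | None = None):
    """Load all (image, mask) pairs referenced by a cohort manifest."""
    from . import io as msio
    base = Path(cohort_dir) if cohort_dir is not None else Path(
        manifest.get("dir", "."))
    volumes, masks = [], []
    for rec in manifest["patients"]:
        vol, _ = msio.read_volume(base / rec["image"])
        mask, _ = msio.read_mask(base / rec["mask"])
        volumes.append(vol)
        masks.append(mask)
    return volumes, masks


def _encode_cached(net: Network, volumes) -> list[tuple[list[Tensor], Tensor]]:
    """Encoder + ViT features for each volume, detached (frozen in stage 2)."""
    cached = []
    for vol in volumes:
        x = Tensor(normalize_volume(vol)[None, None])
        skips, tokens = net.encode(x)
        cached.append(([s.detach() for s in skips], tokens.detach()))
    return cached


def finetune(net: Network, manifest: dict,
             train_config: TrainConfig | None = None,
             loss_config: LossConfig | None = None,
             cohort_dir=None) -> list[float]:
    """Stage 2: decoder fine-tuning with the composite loss.

    Encoder + ViT are frozen, so their per-volume outputs are cached once.
    Returns the per-epoch mean composite loss.
    """
    tc = train_config or TrainConfig()
    lc = loss_config or LossConfig()
    volumes, masks = load_cohort(manifest, cohort_dir)
    net.set_stage("finetune")
    cached = _encode_cached(net, volumes)
    opt = SGD(net.trainable_params(), momentum=tc.momentum, nesterov=True,
              clip_norm=tc.clip_norm)
    rng = np.random.default_rng(tc.seed)
    trace: list[float] = []
    n = len(volumes)
    for epoch in range(tc.epochs_finetune):
        lr = poly_lr(epoch, tc.epochs_finetune, tc.lr0, tc.poly_power)
        if tc.iters_per_epoch is None:
            order = rng.permutation(n)
        else:   # fixed iteration budget per epoch, sampled with replacement
            order = rng.integers(0, n,
                                 size=tc.iters_per_epoch * tc.batch_size)
        losses = []
        for start in range(0, n, tc.batch_size):
            batch = order[start:start + tc.batch_size]
            batch_loss = None
            for idx in batch:
                skips, tokens = cached[idx]
                probs = net.decode(skips, tokens)
                loss = composite_loss(probs[0, 1], np.asarray(
                    masks[idx], dtype=np.float64), lc)
                batch_loss = loss if batch_loss is None else batch_loss + loss
            batch_loss = batch_loss * (1.0 / len(batch))
            opt.zero_grad()
            batch_loss.backward()
            opt.step(lr)
            losses.append(float(batch_loss))
        trace.append(float(np.mean(losses)))
    net.set_stage("inference")
    return trace


def run_two_stage(net: Network, manifest: dict,
                  train_config: TrainConfig | None = None,
                  loss_config: LossConfig | None = None,
                  clp_config=None, cohort_dir=None,
                  out_dir: str | Path | None = None) -> dict:
    """Full schedule: contrastive pretraining then decoder fine-tuning.

    Returns the loss traces for both stages; optionally writes stage
    checkpoints under ``out_dir``.
    """
    from .clp import CLPConfig, pretrain
    tc = train_config or TrainConfig()
    cc = clp_config or CLPConfig()
    pre_trace = pretrain(net, manifest, cc, train_config=tc,
                         cohort_dir=cohort_dir)
    if out_dir is not None:
        net.save(Path(out_dir) / "stage1_pretrained")
    fine_trace = finetune(net, manifest, tc, loss_config, cohort_dir)
    if out_dir is not None:
        net.save(Path(out_dir) / "stage2_finetuned")
    return {"pretrain_loss": pre_trace, "finetune_loss": fine_trace}
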
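"""Supervised contrastive latent pretraining (CLP).

The encoder + ViT map a volume to L = 512 bottleneck tokens z in R^{d x L}.
The lesion mask is subsampled onto the same 8x8x8 grid (a cell is positive
iff it contains any lesion voxel), giving a binary vector m of length L in
the same raster order.  Tokens from lesion cells form positive pairs with
each other and negative pairs with lesion-free cells, and an InfoNCE-style
objective pulls positives together while contrasting anchors against
negatives:

    L_CLP = sum over anchors i (m_i = 1) of
        sum_{j pos, j != i} -log( exp(s_ij) / sum_{j' pos, j' != i} exp(s_ij') )
      + sum_{k neg}          log( exp(s_ik) / sum_{k' neg}        exp(s_ik') )

with similarity s_ab = z~_a . z~_b / temperature.  The attraction denominator
runs over the *positive* set only (the literal pseudo-code convention);
``denominator="supcon"`` switches to the standard supervised-contrastive
denominator over positives and negatives.  Tokens are unit-normalised before
the dot product by default — the raw exp(z.z) similarity is available via
``normalize_tokens=False`` (with clamping to survive the exponential).

This is *not* an augmentation-based scheme: pairs are formed in latent space
from the supervision mask, never from transformed copies of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, astensor
from .network import Network, normalize_volume

__all__ = ["CLPConfig", "subsample_mask", "clp_loss", "pretrain",
           "separation_score", "tsne_embed"]

SIM_CLAMP = 50.0     # cap on raw similarities when tokens are not normalised


@dataclass
class CLPConfig:
    max_anchors: int = 64        # per-volume anchor cap
    max_negatives: int = 128     # per-volume negative cap
    normalize_tokens: bool = True
    temperature: float = 1.0
    denominator: str = "literal"  # "literal" (positives only) | "supcon"
    epochs: int = 30
    lr: float = 1e-3

    def __post_init__(self):
        if self.max_anchors < 1 or self.max_negatives < 1:
            raise ValueError("sampling caps must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.denominator not in ("literal", "supcon"):
            raise ValueError(f"unknown denominator {self.denominator!r}")


def subsample_mask(gt: np.ndarray,
                   grid_shape: tuple[int, int, int] = (8, 8, 8)) -> np.ndarray:
    """Max-pool the lesion mask onto the bottleneck grid.

    Cell l is positive iff it contains at least one lesion voxel; returns a
    {0,1} vector of length prod(grid_shape) in C-order raster — the same
    order as the token axis of the latent field.
    """
    gt = np.asarray(gt)
    for s, g in zip(gt.shape, grid_shape):
        if s % g:
            raise ValueError(
                f"mask shape {gt.shape} not divisible by grid {grid_shape}")
    cd, ch, cw = (s // g for s, g in zip(gt.shape, grid_shape))
    v = gt.reshape(grid_shape[0], cd, grid_shape[1], ch, grid_shape[2], cw)
    pooled = v.transpose(0, 2, 4, 1, 3, 5).reshape(np.prod(grid_shape), -1)
    return (pooled.max(axis=1) > 0).astype(np.float64)


def _select_indices(m: np.ndarray, config: CLPConfig,
                    rng: np.random.Generator | None):
    pos = np.flatnonzero(m > 0.5)
    neg = np.flatnonzero(m <= 0.5)
    if rng is not None:
        if len(pos) > config.max_anchors:
            pos = np.sort(rng.choice(pos, config.max_anchors, replace=False))
        if len(neg) > config.max_negatives:
            neg = np.sort(rng.choice(neg, config.max_negatives, replace=False))
    return pos, neg


def clp_loss(z, m: np.ndarray, config: CLPConfig | None = None,
             rng: np.random.Generator | None = None) -> Tensor | None:
    """InfoNCE-style contrastive loss on one latent field.

    ``z`` has shape (d, L); ``m`` is the subsampled mask of length L.
    Returns ``None`` when the volume has no positive token (no lesion reaches
    the bottleneck grid) — such volumes contribute no CLP loss.  Raises on
    non-finite latents.  When ``rng`` is given, anchors/negatives beyond the
    configured caps are subsampled (seeded); tests use the uncapped loss.
    """
    config = config or CLPConfig()
    z = astensor(z)
    if not np.isfinite(z.data).all():
        raise ValueError("latent field contains non-finite values")
    m = np.asarray(m, dtype=np.float64).ravel()
    if z.shape[1] != m.size:
        raise ValueError(f"latent has {z.shape[1]} tokens but mask has {m.size}")
    pos, neg = _select_indices(m, config, rng)
    if len(pos) == 0:
        return None

    zt = z.transpose(1, 0)                                   # L x d
    if config.normalize_tokens:
        norms = ((zt ** 2).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
        zt = zt / norms
    zp = zt[pos]                                             # P x d
    sim_pp = (zp @ zp.transpose(1, 0)) * (1.0 / config.temperature)
    if not config.normalize_tokens:
        sim_pp = sim_pp.clip(-SIM_CLAMP, SIM_CLAMP)

    loss = Tensor(0.0)
    P = len(pos)
    if P >= 2:
        off_diag = ~np.eye(P, dtype=bool)
        if config.denominator == "literal":
            masked = sim_pp + Tensor(np.where(off_diag, 0.0, -1e30))
            lse = masked.logsumexp(axis=1, keepdims=True)    # P x 1
        else:                                                # supcon: pos+neg
            zn_ = zt[neg] if len(neg) else None
            parts = [sim_pp + Tensor(np.where(off_diag, 0.0, -1e30))]
            if zn_ is not None:
                sim_pn_full = (zp @ zn_.transpose(1, 0)) * (1.0 / config.temperature)
                if not config.normalize_tokens:
                    sim_pn_full = sim_pn_full.clip(-SIM_CLAMP, SIM_CLAMP)
                from .autodiff import concatenate
                parts.append(sim_pn_full)
            lse = concatenate(parts, axis=1).logsumexp(axis=1, keepdims=True)
        # attraction: sum over anchors i, positives j != i of (lse_i - s_ij)
        attraction = ((lse - sim_pp) * Tensor(off_diag.astype(float))).sum()
        loss = loss + attraction
    if len(neg) > 0:
        zn = zt[neg]
        sim_pn = (zp @ zn.transpose(1, 0)) * (1.0 / config.temperature)
        if not config.normalize_tokens:
            sim_pn = sim_pn.clip(-SIM_CLAMP, SIM_CLAMP)
        lse_n = sim_pn.logsumexp(axis=1, keepdims=True)      # P x 1
        repulsion = (sim_pn - lse_n).sum()
        loss = loss + repulsion
    return loss


def pretrain(net: Network, manifest: dict, config: CLPConfig | None = None,
             train_config=None, cohort_dir=None) -> list[float]:
    """Contrastive pretraining of encoder + ViT on a phantom cohort.

    Optimises ``clp_loss`` with SGD + Nesterov momentum under the polynomial
    learning-rate schedule; the decoder stays frozen (bitwise unchanged).
    Returns the per-epoch mean loss trace.  Raises if the cohort contributes
    no positive tokens at all.
    """
    from .trainer import TrainConfig, SGD, poly_lr, load_cohort
    config = config or CLPConfig()
    tc = train_config or TrainConfig(epochs_pretrain=config.epochs, lr0=config.lr)
    volumes, masks = load_cohort(manifest, cohort_dir)
    subs = [subsample_mask(m, (8, 8, 8)) for m in masks]
    if not any(s.sum() > 0 for s in subs):
        raise ValueError("cohort has no lesioned volume on the bottleneck grid")

    net.set_stage("pretrain")
    opt = SGD(net.trainable_params(), momentum=tc.momentum, nesterov=True,
              clip_norm=tc.clip_norm)
    rng = np.random.default_rng(tc.seed)
    trace: list[float] = []
    n_skipped = 0
    for epoch in range(tc.epochs_pretrain):
        lr = poly_lr(epoch, tc.epochs_pretrain, tc.lr0, tc.poly_power)
        if tc.iters_per_epoch is None:
            indices = range(len(volumes))
        else:
            indices = rng.integers(0, len(volumes), size=tc.iters_per_epoch)
        epoch_losses = []
        for idx in indices:
            vol, sub = volumes[idx], subs[idx]
            x = Tensor(normalize_volume(vol)[None, None])
            _, tokens = net.encode(x)
            z = tokens[0].transpose(1, 0)               # d x L
            loss = clp_loss(z, sub, config, rng)
            if loss is None:
                n_skipped += 1
                continue
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            epoch_losses.append(float(loss))
        trace.append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)
    net.set_stage("inference")
    return trace


def separation_score(z: np.ndarray, m: np.ndarray,
                     normalize_by_negatives: bool = True) -> float:
    """Class-separation proxy for latent tokens.

    After per-dimension normalisation by the mean/SD of the lesion-free
    (negative) tokens, returns the distance between the two class centroids
    divided by the mean within-class SD.  Two identical clouds score 0;
    isotropic unit clouds shifted by k SDs score ~k.  Invariant to a common
    affine rescaling of all tokens when normalisation is on.
    """
    z = np.asarray(z, dtype=np.float64)
    m = np.asarray(m).ravel() > 0.5
    if m.all() or not m.any():
        raise ValueError("separation_score needs both classes present")
    tokens = z.T                                       # L x d
    if normalize_by_negatives:
        mu = tokens[~m].mean(axis=0)
        sd = tokens[~m].std(axis=0)
        sd = np.where(sd > 1e-12, sd, 1.0)
        tokens = (tokens - mu) / sd
    c_pos = tokens[m].mean(axis=0)
    c_neg = tokens[~m].mean(axis=0)

    def cloud_sd(x):
        return float(np.sqrt(x.var(axis=0).mean()))

    within = 0.5 * (cloud_sd(tokens[m]) + cloud_sd(tokens[~m]))
    if within < 1e-12:
        return float(np.inf) if np.linalg.norm(c_pos - c_neg) > 0 else 0.0
    return float(np.linalg.norm(c_pos - c_neg) / within)


def tsne_embed(z: np.ndarray, m: np.ndarray, seed: int = 0) -> np.ndarray:
    """2D t-SNE embedding of latent tokens, for class-separation figures.

    Returns an (L, 3) array: x, y coordinates and the class label.
    """
    from sklearn.manifold import TSNE
    z = np.asarray(z, dtype=np.float64)
    tokens = z.T
    if tokens.shape[0] < 10:
        raise ValueError("need at least 10 tokens for a t-SNE embedding")
    if np.allclose(tokens, tokens[0]):
        raise ValueError("degenerate input: all tokens identical")
    perplexity = min(30.0, (tokens.shape[0] - 1) / 3.0)
    emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
               init="pca").fit_transform(tokens)
    labels = (np.asarray(m).ravel() > 0.5).astype(float)
    return np.column_stack([emb, labels])
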
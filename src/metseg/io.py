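"""NIfTI I/O, experiment configuration and run manifests.

Volumes and masks travel as NIfTI (.nii / .nii.gz) with per-axis voxel
spacing read from the header; images are RAS-canonicalised on load.  Masks
must be strictly binary — any other value is rejected with the offending
values listed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .clp import CLPConfig
from .losses import LossConfig
from .network import NetConfig
from .phantom import PhantomConfig
from .trainer import TrainConfig

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask",
           "ExperimentConfig", "write_run_manifest"]


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Load a NIfTI volume; returns (data, per-axis spacing in mm)."""
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_volume(path: str | Path, data: np.ndarray,
                 spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Load a binary lesion mask; rejects non-binary values."""
    data, spacing = read_volume(path)
    values = np.unique(data)
    bad = [v for v in values if v not in (0.0, 1.0)]
    if bad:
        raise ValueError(
            f"mask {path} is not binary; offending values: "
            f"{[float(v) for v in bad[:10]]}")
    return data.astype(np.uint8), spacing


def write_mask(path: str | Path, mask: np.ndarray,
               spacing=(1.0, 1.0, 1.0)) -> None:
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(mask.astype(np.uint8), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


# ------------------------------------------------------------- configuration
@dataclass
class ExperimentConfig:
    """One file describing a full simulate -> train -> evaluate experiment."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    net: NetConfig = field(default_factory=NetConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    clp: CLPConfig = field(default_factory=CLPConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_patients: int = 5
    seed: int = 0
    out_root: str = "runs"

    def __post_init__(self):
        # the global seed drives every block unless overridden per block
        if self.phantom.seed == 0:
            self.phantom.seed = self.seed
        if self.train.seed == 0:
            self.train.seed = self.seed
        if tuple(self.phantom.shape) != tuple(self.net.input_shape):
            raise ValueError(
                f"phantom shape {self.phantom.shape} != network input "
                f"{self.net.input_shape}")

    def to_dict(self) -> dict:
        d = asdict(self)
        return json.loads(json.dumps(d))       # tuples -> lists, plain types

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kwargs = dict(d)
        for key, klass in (("phantom", PhantomConfig), ("net", NetConfig),
                           ("loss", LossConfig), ("clp", CLPConfig),
                           ("train", TrainConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                block = dict(kwargs[key])
                for k, v in block.items():
                    if isinstance(v, list):
                        block[k] = tuple(v)
                kwargs[key] = klass(**block)
        return cls(**kwargs)

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def write_run_manifest(out_dir: str | Path, config: ExperimentConfig,
                       extra: dict | None = None) -> Path:
    """Write a reproducibility manifest (config hash, seed, versions)."""
    import scipy
    import sklearn
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    manifest = {
        "config": cfg,
        "config_hash": digest,
        "seed": config.seed,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "nibabel": nib.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
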
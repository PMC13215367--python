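"""Synthetic T1c-like lesion phantoms.

No clinical volumes ship with this package, so evaluation and training are
exercised on seeded synthetic "patients": a homogeneous background volume
containing randomly oriented ellipsoidal contrast-enhancing lesions, plus the
matching noise-free binary ground-truth mask.  Lesion sizes follow the
three-stratum longest-axis mixture observed in multi-institutional metastasis
cohorts — small (<3 mm), medium ([3, 6] mm), large (>6 mm) with default
proportions 25.73 / 40.92 / 33.35 % — and per-patient lesion counts follow a
decreasing (truncated geometric) law capped at 50.

``perturb_prediction`` degrades a ground-truth mask in controlled ways
(partial coverage, dropped lesions, spurious components) to produce
evaluation fixtures with known true-positive/false-positive structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = ["LesionSpec", "PhantomConfig", "sample_lesions", "render_phantom",
           "perturb_prediction", "generate_cohort", "PlacementError",
           "STRATUM_BOUNDS"]

# longest-axis stratum bounds in mm: small [0,3), medium [3,6], large (6, inf)
STRATUM_BOUNDS = (3.0, 6.0)
DEFAULT_MIXTURE = (0.2573, 0.4092, 0.3335)   # small, medium, large


class PlacementError(RuntimeError):
    """Raised when lesions cannot be placed without overlap — volume too small."""


@dataclass
class LesionSpec:
    """One ellipsoidal lesion in physical (mm) coordinates."""

    center: tuple[float, float, float]      # mm
    semi_axes: tuple[float, float, float]   # mm, descending
    orientation: tuple[float, float, float]  # Euler angles (xyz), radians
    contrast: float                          # intensity multiplier vs background
    target_diameter: float                   # 2 * max(semi_axes), mm

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")

    @property
    def stratum(self) -> str:
        d = self.target_diameter
        if d < STRATUM_BOUNDS[0]:
            return "small"
        if d <= STRATUM_BOUNDS[1]:
            return "medium"
        return "large"


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lesions: int | str = "geometric"     # int, or "geometric" sampling law
    geometric_p: float = 0.18              # decreasing count law, mean ~5.6
    max_lesions: int = 50
    size_mixture: tuple[float, float, float] = DEFAULT_MIXTURE
    d_min: float = 1.0                     # smallest lesion diameter, mm
    d_max: float = 12.0                    # largest lesion diameter, mm
    background: float = 100.0
    contrast_range: tuple[float, float] = (1.4, 2.0)
    aspect_range: tuple[float, float] = (0.6, 1.0)
    noise_sd: float = 5.0
    bias_field: bool = False
    bias_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.size_mixture) - 1.0) > 1e-8:
            raise ValueError("size_mixture must sum to 1")
        extent = min(s * sp for s, sp in zip(self.shape, self.spacing))
        if extent < self.d_max + 2 * max(self.spacing):
            raise ValueError(
                f"volume extent {extent} mm cannot contain a {self.d_max} mm lesion")


def _sample_count(config: PhantomConfig, rng: np.random.Generator) -> int:
    if isinstance(config.n_lesions, (int, np.integer)):
        return int(config.n_lesions)
    if config.n_lesions == "geometric":
        n = int(rng.geometric(config.geometric_p))
        return min(n, config.max_lesions)
    raise ValueError(f"unknown lesion count law {config.n_lesions!r}")


def _sample_diameter(config: PhantomConfig, rng: np.random.Generator) -> float:
    stratum = rng.choice(3, p=config.size_mixture)
    lo_s, hi_s = STRATUM_BOUNDS
    if stratum == 0:
        return float(rng.uniform(config.d_min, lo_s))
    if stratum == 1:
        return float(rng.uniform(lo_s, hi_s))
    return float(rng.uniform(hi_s, config.d_max))


def sample_lesions(config: PhantomConfig,
                   rng: np.random.Generator) -> list[LesionSpec]:
    """Draw non-overlapping lesion specs from the configured size mixture.

    Deterministic given the generator state.  Raises :class:`PlacementError`
    if a lesion cannot be placed after bounded retries (volume too small /
    too crowded).
    """
    n = _sample_count(config, rng)
    extent = np.array(config.shape) * np.array(config.spacing)
    specs: list[LesionSpec] = []
    for _ in range(n):
        d = _sample_diameter(config, rng)
        a = d / 2.0
        ratios = rng.uniform(*config.aspect_range, size=2)
        semi = (a, a * float(ratios[0]), a * float(ratios[1]))
        euler = tuple(rng.uniform(0, 2 * np.pi, size=3))
        contrast = float(rng.uniform(*config.contrast_range))
        margin = a + max(config.spacing)
        placed = False
        for _attempt in range(200):
            center = tuple(rng.uniform(margin, e - margin) for e in extent)
            ok = all(
                np.linalg.norm(np.array(center) - np.array(s.center))
                > a + max(s.semi_axes) + 1.0
                for s in specs)
            if ok:
                specs.append(LesionSpec(center, semi, euler, contrast, d))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place lesion {len(specs) + 1}/{n} of {d:.1f} mm; "
                "volume too small for the requested lesion load")
    return specs


def _voxel_centers_mm(shape, spacing):
    axes = [(np.arange(s) + 0.5) * sp for s, sp in zip(shape, spacing)]
    return axes


def _rasterize(spec: LesionSpec, shape, spacing) -> tuple[tuple, np.ndarray]:
    """Voxelize one ellipsoid: voxel is inside iff its center is inside.

    Returns (bounding-box slices, boolean block).
    """
    spacing = np.asarray(spacing, dtype=float)
    c = np.asarray(spec.center)
    r = max(spec.semi_axes)
    lo = np.maximum(np.floor((c - r) / spacing - 1), 0).astype(int)
    hi = np.minimum(np.ceil((c + r) / spacing + 1),
                    np.asarray(shape)).astype(int)
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    axes = [(np.arange(l, h) + 0.5) * sp for l, h, sp in zip(lo, hi, spacing)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1) - c
    rot = Rotation.from_euler("xyz", spec.orientation).as_matrix()
    local = grid @ rot                       # rotate into lesion frame
    q = (local / np.asarray(spec.semi_axes)) ** 2
    return sl, q.sum(axis=-1) <= 1.0


def render_phantom(specs: list[LesionSpec],
                   config: PhantomConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Render (image, mask) for a list of lesion specs.

    The mask is noise-free; the image is background + per-lesion enhancement
    + optional smooth multiplicative bias field + Gaussian noise.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    shape = tuple(config.shape)
    mask = np.zeros(shape, dtype=np.uint8)
    image = np.full(shape, config.background, dtype=np.float64)
    for spec in specs:
        sl, inside = _rasterize(spec, shape, config.spacing)
        mask[sl][inside] = 1
        image[sl][inside] = config.background * spec.contrast
    if config.bias_field:
        field_ = rng.normal(size=shape)
        field_ = ndimage.gaussian_filter(field_, sigma=min(shape) / 4)
        field_ = field_ / (np.abs(field_).max() + 1e-12)
        image = image * (1.0 + config.bias_amplitude * field_)
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=shape)
    return image, mask


# --------------------------------------------------------------- perturbation
@dataclass
class PerturbationPlan:
    """Per-lesion actions plus spurious components to add.

    ``actions`` maps GT component label -> "keep" | "drop" | coverage fraction
    in (0, 1].  Labels missing from the map are kept.  ``spurious`` is a list
    of (center voxel, radius in voxels) balls added away from the GT.
    """

    actions: dict[int, object] = field(default_factory=dict)
    spurious: list[tuple[tuple[int, int, int], float]] = field(
        default_factory=list)


def perturb_prediction(gt: np.ndarray, plan: PerturbationPlan,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Build a synthetic 'prediction' mask realising a perturbation plan.

    Kept lesions eroded to a coverage fraction f retain exactly
    ``round(f * |lesion|)`` voxels (within the one-voxel rounding), removed
    from the boundary inward so the remnant stays connected around the
    centroid.  Spurious components must not touch the GT.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    structure = np.ones((3, 3, 3), dtype=bool)       # 26-connectivity
    labels, n = ndimage.label(gt > 0, structure=structure)
    pred = np.zeros_like(gt, dtype=np.uint8)
    for lab in range(1, n + 1):
        action = plan.actions.get(lab, "keep")
        voxels = np.argwhere(labels == lab)
        if action == "drop":
            continue
        if action == "keep":
            pred[tuple(voxels.T)] = 1
            continue
        frac = float(action)
        target = int(round(frac * len(voxels)))
        if target < 1:
            raise ValueError(
                f"lesion {lab} has {len(voxels)} voxels; coverage {frac} "
                "is unreachable")
        centroid = voxels.mean(axis=0)
        dist = np.linalg.norm(voxels - centroid, axis=1)
        keep = voxels[np.argsort(dist, kind="stable")[:target]]
        pred[tuple(keep.T)] = 1
    for center, radius in plan.spurious:
        ball = _ball_at(gt.shape, center, radius)
        if (ball & (gt > 0)).any():
            raise ValueError(f"spurious component at {center} touches the GT")
        pred[ball] = 1
    return pred


def _ball_at(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius ** 2


# -------------------------------------------------------------------- cohort
def generate_cohort(config: PhantomConfig, n_patients: int,
                    out_dir: str | Path) -> dict:
    """Write a cohort of paired image/mask NIfTI files plus a JSON manifest.

    Per-patient seeds are spawned deterministically from ``config.seed``, so
    re-running with the same config reproduces the same cohort.
    """
    from . import io as msio
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    patients = []
    for i, child in enumerate(root.spawn(n_patients)):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(seed)
        specs = sample_lesions(config, rng)
        image, mask = render_phantom(specs, config, rng)
        pid = f"phantom_{i:03d}"
        img_path = out_dir / f"{pid}_img.nii.gz"
        msk_path = out_dir / f"{pid}_mask.nii.gz"
        msio.write_volume(img_path, image, config.spacing)
        msio.write_mask(msk_path, mask, config.spacing)
        patients.append({
            "id": pid, "seed": seed, "n_lesions": len(specs),
            "diameters_mm": [round(s.target_diameter, 3) for s in specs],
            "image": img_path.name, "mask": msk_path.name,
        })
    manifest = {
        "seed": config.seed,
        "shape": list(config.shape),
        "spacing": list(config.spacing),
        "n_patients": n_patients,
        "patients": patients,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
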
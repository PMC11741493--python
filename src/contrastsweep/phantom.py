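"""Digital head phantom: quantitative maps, structure labels, simulated raters.

The phantom is a head-sized ellipsoid of muscle-like tissue containing four
ellipsoidal salivary-gland-like structures — a bilateral parotid-like pair
and a bilateral submandibular-like pair, mirror-symmetric about the
mid-sagittal plane — plus a fat-like anterior region for intensity
diversity.  Tissue T1/T2/PD values are literature-plausible 3 T defaults;
only the contrast *ordering* between tissues matters for exercising the
sweep, and the values are phantom defaults, not measurements.

Geometry is specified in millimetres relative to the volume center, so one
spec renders consistently at any shape/spacing.  Rater masks emulate
contouring disagreement with a signed boundary offset plus smooth Gaussian
boundary jitter applied to the true mask's signed distance map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .relaxometry import QuantitativeMaps
from .staple import RaterMaskStack

__all__ = ["Tissue", "Structure", "PhantomSpec", "build_phantom",
           "simulate_raters", "apply_b1_bias", "DEFAULT_STRUCTURES"]


@dataclass(frozen=True)
class Tissue:
    """Relaxometry parameters of one tissue class (T1/T2 in ms, PD in a.u.)."""

    name: str
    t1: float
    t2: float
    pd: float

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0 or self.pd <= 0:
            raise ValueError(f"tissue {self.name}: parameters must be positive")


@dataclass(frozen=True)
class Structure:
    """One ellipsoidal structure: center offset and radii in mm."""

    name: str
    label: int
    center_mm: Tuple[float, float, float]  # offset from volume center
    radii_mm: Tuple[float, float, float]
    tissue: Tissue


# Literature-plausible 3 T defaults (phantom values, not subject measurements).
PAROTID_TISSUE = Tissue("parotid-like", t1=1100.0, t2=120.0, pd=0.90)
SUBMANDIBULAR_TISSUE = Tissue("submandibular-like", t1=1300.0, t2=100.0, pd=0.85)
MUSCLE_TISSUE = Tissue("muscle-like", t1=1400.0, t2=40.0, pd=0.70)
FAT_TISSUE = Tissue("fat-like", t1=400.0, t2=130.0, pd=1.00)

DEFAULT_STRUCTURES: List[Structure] = [
    Structure("parotid_l", 1, (-30.0, 8.0, 0.0), (9.0, 13.0, 16.0), PAROTID_TISSUE),
    Structure("parotid_r", 2, (30.0, 8.0, 0.0), (9.0, 13.0, 16.0), PAROTID_TISSUE),
    Structure("submandibular_l", 3, (-15.0, -24.0, -12.0), (7.0, 8.0, 10.0),
              SUBMANDIBULAR_TISSUE),
    Structure("submandibular_r", 4, (15.0, -24.0, -12.0), (7.0, 8.0, 10.0),
              SUBMANDIBULAR_TISSUE),
]


@dataclass
class PhantomSpec:
    """Configuration of the digital phantom.

    ``spacing`` defaults to 0.5 x 0.5 mm in-plane with a 5 mm slice axis
    (4 mm slices + 1 mm gap: center-to-center distance is what surface
    metrics need).  ``noise_sigma`` holds the Gaussian noise s.d. added to
    each quantitative map inside the head, in map units (ms, ms, a.u.).
    """

    shape: Tuple[int, int, int] = (192, 192, 16)
    spacing: Tuple[float, float, float] = (0.5, 0.5, 5.0)
    head_radii_mm: Tuple[float, float, float] = (46.0, 42.0, 60.0)
    structures: List[Structure] = field(
        default_factory=lambda: list(DEFAULT_STRUCTURES))
    background_tissue: Tissue = MUSCLE_TISSUE
    fat_center_mm: Tuple[float, float, float] = (0.0, 30.0, 5.0)
    fat_radii_mm: Tuple[float, float, float] = (14.0, 7.0, 20.0)
    fat_tissue: Tissue = FAT_TISSUE
    noise_sigma: Tuple[float, float, float] = (20.0, 4.0, 0.02)  # (T1, T2, PD)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(s < 0 for s in self.noise_sigma):
            raise ValueError("noise_sigma entries must be non-negative")
        labels = [s.label for s in self.structures]
        if len(set(labels)) != len(labels):
            raise ValueError("structure labels must be unique")

    @property
    def structure_names(self) -> List[str]:
        return [s.name for s in self.structures]

    def label_of(self, name: str) -> int:
        for s in self.structures:
            if s.name == name:
                return s.label
        raise KeyError(f"unknown structure {name!r}")


def _mm_grid(shape: Sequence[int], spacing: Sequence[float]) -> list[np.ndarray]:
    """Voxel-center coordinates in mm, origin at the volume center."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(grid: list[np.ndarray], center: Sequence[float],
                    radii: Sequence[float]) -> np.ndarray:
    acc = np.zeros_like(grid[0])
    for g, c, r in zip(grid, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def build_phantom(spec: PhantomSpec, seed: int = 0
                  ) -> tuple[QuantitativeMaps, np.ndarray]:
    """Render the phantom: quantitative maps plus an integer label volume.

    Maps carry the tissue-table values inside each region (background 0)
    with optional Gaussian noise added inside the head; the label volume is
    noise-free and deterministic given the spec.  Overlapping structures are
    an error naming the colliding pair.
    """
    grid = _mm_grid(spec.shape, spec.spacing)
    head = _ellipsoid_mask(grid, (0.0, 0.0, 0.0), spec.head_radii_mm)

    t1 = np.where(head, spec.background_tissue.t1, 0.0)
    t2 = np.where(head, spec.background_tissue.t2, 0.0)
    pd_ = np.where(head, spec.background_tissue.pd, 0.0)

    fat = _ellipsoid_mask(grid, spec.fat_center_mm, spec.fat_radii_mm) & head
    t1[fat] = spec.fat_tissue.t1
    t2[fat] = spec.fat_tissue.t2
    pd_[fat] = spec.fat_tissue.pd

    labels = np.zeros(spec.shape, dtype=np.int32)
    masks: Dict[str, np.ndarray] = {}
    for s in spec.structures:
        mask = _ellipsoid_mask(grid, s.center_mm, s.radii_mm)
        if not mask.any():
            raise ValueError(f"structure {s.name!r} renders empty at this "
                             f"shape/spacing")
        if not (mask <= head).all():
            raise ValueError(f"structure {s.name!r} extends outside the head")
        for other, omask in masks.items():
            if (mask & omask).any():
                raise ValueError(
                    f"structures {other!r} and {s.name!r} overlap")
        if (mask & fat).any():
            fat &= ~mask  # glands take precedence over the fat region
        masks[s.name] = mask
        labels[mask] = s.label
        t1[mask] = s.tissue.t1
        t2[mask] = s.tissue.t2
        pd_[mask] = s.tissue.pd

    if any(sig > 0 for sig in spec.noise_sigma):
        rng = np.random.default_rng(seed)
        for vol, sig in zip((t1, t2, pd_), spec.noise_sigma):
            if sig > 0:
                noise = rng.normal(0.0, sig, size=spec.shape)
                vol[head] = np.maximum(vol[head] + noise[head], 1e-3)

    maps = QuantitativeMaps(t1_map=t1, t2_map=t2, pd_map=pd_,
                            spacing=spec.spacing)
    return maps, labels


def simulate_raters(
    labels: np.ndarray,
    structure_label: int,
    n_raters: int,
    perturbation_mm: float,
    seed: int,
    spacing: Sequence[float] = (0.5, 0.5, 5.0),
    rater_ids: Sequence[str] | None = None,
) -> RaterMaskStack:
    """Simulate rater contours of one structure by boundary perturbation.

    Each rater's mask is the true mask grown or shrunk by an independently
    drawn signed offset ~ N(0, perturbation) mm plus a smooth zero-mean
    jitter field of the same scale, applied through the signed distance
    transform; the largest connected component is kept so a connected truth
    stays connected.  Perturbation 0 reproduces the truth exactly.
    """
    if n_raters < 1:
        raise ValueError("need at least one rater")
    if perturbation_mm < 0:
        raise ValueError("perturbation must be non-negative")
    truth = np.asarray(labels) == structure_label
    if not truth.any():
        raise ValueError(f"structure label {structure_label} not present")

    if perturbation_mm == 0:
        masks = np.repeat(truth[None], n_raters, axis=0)
    else:
        spacing = tuple(float(s) for s in spacing)
        # signed distance: negative inside the truth, positive outside (mm)
        d_out = ndimage.distance_transform_edt(~truth, sampling=spacing)
        d_in = ndimage.distance_transform_edt(truth, sampling=spacing)
        sdist = np.where(truth, -d_in, d_out)
        rng = np.random.default_rng(seed)
        out = []
        smooth_vox = [max(3.0 / s, 0.5) for s in spacing]  # ~3 mm correlation
        for _ in range(n_raters):
            offset = rng.normal(0.0, perturbation_mm)
            jitter = rng.normal(0.0, 1.0, size=truth.shape)
            jitter = ndimage.gaussian_filter(jitter, sigma=smooth_vox)
            sd = jitter.std()
            if sd > 0:
                jitter *= perturbation_mm / sd
            # bounded boundary error: raters disagree locally by at most 2 s.d.
            np.clip(jitter, -2.0 * perturbation_mm, 2.0 * perturbation_mm,
                    out=jitter)
            mask = sdist <= offset + jitter
            lab, n_comp = ndimage.label(mask)
            if n_comp > 1:
                sizes = ndimage.sum_labels(mask, lab, index=range(1, n_comp + 1))
                mask = lab == (1 + int(np.argmax(sizes)))
            if not mask.any():
                raise ValueError(
                    f"perturbation {perturbation_mm} mm emptied a rater mask "
                    f"for label {structure_label}")
            out.append(mask)
        masks = np.stack(out)

    if rater_ids is None:
        rater_ids = [f"rater_{i + 1}" for i in range(n_raters)]
    return RaterMaskStack(masks=masks, rater_ids=rater_ids, spacing=spacing)


def apply_b1_bias(maps: QuantitativeMaps, amplitude: float,
                  seed: int = 0) -> QuantitativeMaps:
    """Attach a smooth, left-right asymmetric transmit-bias field.

    The field is a low-order random polynomial in normalized coordinates,
    rescaled to exactly span [1 - amplitude, 1 + amplitude].  A guaranteed
    linear term along the first (left-right) axis makes mirrored voxels
    differ, emulating coil-placement inhomogeneity.
    """
    if not 0.0 <= amplitude < 1.0:
        raise ValueError(f"amplitude must be in [0, 1), got {amplitude}")
    if amplitude == 0:
        return QuantitativeMaps(
            t1_map=maps.t1_map, t2_map=maps.t2_map, pd_map=maps.pd_map,
            spacing=maps.spacing, b1_field=np.ones(maps.shape))
    rng = np.random.default_rng(seed)
    axes = [np.linspace(-1.0, 1.0, n) for n in maps.shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    coeffs = rng.normal(0.0, 1.0, size=6)
    coeffs[0] = np.sign(coeffs[0]) * max(abs(coeffs[0]), 0.5)  # force asymmetry
    poly = (coeffs[0] * x + coeffs[1] * y + coeffs[2] * z
            + coeffs[3] * x * y + coeffs[4] * x * z + coeffs[5] * y * z)
    poly /= np.abs(poly).max()
    b1 = 1.0 + amplitude * poly
    return QuantitativeMaps(t1_map=maps.t1_map, t2_map=maps.t2_map,
                            pd_map=maps.pd_map, spacing=maps.spacing,
                            b1_field=b1)
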
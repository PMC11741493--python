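"""Segmenter plug-in contract, preprocessing chain, and a toy reference segmenter.

A segmenter is any callable ``(image, spacing) -> label volume`` that is
deterministic for fixed inputs, returns the input shape, and uses the label
ids it was configured with.  The sweep engine treats the segmenter as a
black box, so trained models drop in through the same contract.

The built-in :class:`IntensityWindowSegmenter` is deliberately simple: for
each structure it keeps voxels whose *preprocessed* intensity falls in a
window calibrated at one anchor acquisition, intersects with a spatial
prior ball around the calibrated centroid, and keeps the largest connected
component.  Because the window is tied to the anchor's absolute contrast,
segmentation quality degrades as (TR, TE) moves away from the calibration
contrast — the sensitivity the sweep is designed to expose.  This is a
feature of the test harness, not a model of any trained network.

Preprocessing follows the common deep-learning normalization chain: clip to
the [0.25, 99.75] intensity percentiles, z-score (population s.d.), then
linearly map the observed min/max to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = ["preprocess", "calibrate", "Calibration", "StructureCalibration",
           "IntensityWindowSegmenter", "register_segmenter", "get_segmenter",
           "check_contract"]

Segmenter = Callable[[np.ndarray, Sequence[float]], np.ndarray]


def preprocess(image: np.ndarray, lo_pct: float = 0.25,
               hi_pct: float = 99.75) -> np.ndarray:
    """Clip to percentiles, z-score, and rescale to [-1, 1].

    A constant image maps to all zeros (the z-score and the min/max map are
    both degenerate there).  The rescale uses the post-clip min/max, so the
    output of any non-constant image spans exactly [-1, 1].
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = np.percentile(image, [lo_pct, hi_pct])
    clipped = np.clip(image, lo, hi)
    sd = clipped.std()
    if sd == 0:
        return np.zeros_like(clipped)
    z = (clipped - clipped.mean()) / sd
    zmin, zmax = z.min(), z.max()
    if zmax == zmin:
        return np.zeros_like(z)
    return (z - zmin) / (zmax - zmin) * 2.0 - 1.0


@dataclass(frozen=True)
class StructureCalibration:
    """Per-structure intensity window and spatial prior (from the anchor image)."""

    label: int
    window: Tuple[float, float]  # preprocessed-intensity [P5, P95] inside truth
    centroid_mm: Tuple[float, ...]
    radius_mm: float


@dataclass(frozen=True)
class Calibration:
    structures: Tuple[StructureCalibration, ...]

    def labels(self) -> tuple:
        return tuple(s.label for s in self.structures)


def _centroid_mm(mask: np.ndarray, spacing: Sequence[float]) -> tuple:
    idx = np.nonzero(mask)
    return tuple(float(np.mean(c) * s) for c, s in zip(idx, spacing))


def calibrate(image: np.ndarray, truth_labels: np.ndarray,
              spacing: Sequence[float],
              structure_labels: Sequence[int]) -> Calibration:
    """Calibrate the reference segmenter on one anchor image + truth labels.

    Per structure: the intensity window is [P5, P95] of the preprocessed
    intensities inside the true mask; the spatial prior is a ball at the
    true centroid with radius = the mask's maximal centroid distance
    dilated by 20 %.  Deterministic; empty truth is an error.
    """
    pre = preprocess(image)
    out = []
    for label in structure_labels:
        mask = np.asarray(truth_labels) == label
        if not mask.any():
            raise ValueError(f"truth for label {label} is empty")
        vals = pre[mask]
        lo, hi = np.percentile(vals, [5, 95])
        # widen by half a window width per side: tolerates moderate contrast
        # drift so performance decays smoothly away from the anchor instead
        # of collapsing at the first off-anchor grid point
        margin = 0.5 * (hi - lo)
        window = (float(lo - margin), float(hi + margin))
        centroid = _centroid_mm(mask, spacing)
        idx = np.nonzero(mask)
        coords_mm = np.stack(
            [c * s for c, s in zip(idx, spacing)], axis=1)
        radius = float(np.max(np.linalg.norm(coords_mm - np.array(centroid),
                                             axis=1))) * 1.2
        out.append(StructureCalibration(label=label, window=window,
                                        centroid_mm=centroid,
                                        radius_mm=radius))
    return Calibration(structures=tuple(out))


class IntensityWindowSegmenter:
    """Anchor-calibrated intensity-window segmenter (toy reference model).

    ``segment(image, spacing)`` preprocesses the image, then per structure
    thresholds to the calibrated window, intersects a prior ball around the
    calibrated centroid, and keeps the largest connected component.  An
    empty result for a structure is allowed (the sweep records a failure).
    """

    def __init__(self, calibration: Calibration):
        self.calibration = calibration

    def __call__(self, image: np.ndarray,
                 spacing: Sequence[float]) -> np.ndarray:
        return self.segment(image, spacing)

    def segment(self, image: np.ndarray,
                spacing: Sequence[float]) -> np.ndarray:
        pre = preprocess(image)
        labels = np.zeros(pre.shape, dtype=np.int32)
        grids = np.meshgrid(
            *[np.arange(n) * s for n, s in zip(pre.shape, spacing)],
            indexing="ij")
        for sc in self.calibration.structures:
            lo, hi = sc.window
            cand = (pre >= lo) & (pre <= hi)
            dist2 = sum((g - c) ** 2 for g, c in zip(grids, sc.centroid_mm))
            cand &= dist2 <= sc.radius_mm ** 2
            if cand.any():
                lab, n_comp = ndimage.label(cand)
                if n_comp > 1:
                    sizes = ndimage.sum_labels(
                        cand, lab, index=range(1, n_comp + 1))
                    cand = lab == (1 + int(np.argmax(sizes)))
                labels[cand] = sc.label
        return labels


def check_contract(segmenter: Segmenter,
                   spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> None:
    """Smoke-check a plug-in on an 8x8x4 volume before registration.

    Verifies the output is an integer label volume of the input shape and
    that two identical calls agree (determinism).
    """
    rng = np.random.default_rng(0)
    vol = rng.random((8, 8, 4))
    out1 = segmenter(vol, spacing)
    out2 = segmenter(vol, spacing)
    out1 = np.asarray(out1)
    if out1.shape != vol.shape:
        raise ValueError(
            f"segmenter returned shape {out1.shape}, expected {vol.shape}")
    if not np.issubdtype(out1.dtype, np.integer):
        raise ValueError(f"segmenter must return integer labels, "
                         f"got dtype {out1.dtype}")
    if not np.array_equal(out1, np.asarray(out2)):
        raise ValueError("segmenter is not deterministic")


_REGISTRY: Dict[str, Callable[..., Segmenter]] = {}


def register_segmenter(name: str,
                       factory: Callable[..., Segmenter]) -> None:
    """Register a segmenter factory under a config-addressable name."""
    _REGISTRY[name] = factory


def get_segmenter(name: str, **kwargs) -> Segmenter:
    """Build a registered segmenter; contract-checks it before returning."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown segmenter {name!r}; registered: {sorted(_REGISTRY)}")
    seg = _REGISTRY[name](**kwargs)
    check_contract(seg)
    return seg


register_segmenter(
    "intensity_window",
    lambda calibration: IntensityWindowSegmenter(calibration),
)
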
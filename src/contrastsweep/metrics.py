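"""Contour agreement metrics: Dice similarity coefficient and HD95.

Both metrics are computed in 3D over whole volumes with physical voxel
spacing.  HD95 uses the pooled symmetric convention: the 95th percentile
(linear interpolation) of the union of both directed surface-distance
multisets, measured between surface-voxel centers.  This is the most common
convention in contouring-QA toolkits and is exactly symmetric; a
directed-max variant (max of the two directed 95th percentiles) is available
via ``directed=True``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = ["UndefinedMetricError", "dice", "surface_voxels", "hd95",
           "surface_distances"]


class UndefinedMetricError(ValueError):
    """A surface metric is undefined (e.g. one mask is empty).

    The sweep layer catches this and records a failure sentinel instead of
    aborting, since degenerate predictions are an expected outcome of a
    contrast sweep.
    """


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} is not binary (values {vals[:5]}...)")
    return arr.astype(bool)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|).

    Both masks empty -> 1.0 (perfect agreement on absence); exactly one
    empty -> 0.0.
    """
    a = _as_binary(a, "a")
    b = _as_binary(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na = int(a.sum())
    nb = int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (na + nb)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one face-adjacent background neighbor.

    6-connectivity in 3D; the volume boundary counts as background, so a
    mask touching the array edge contributes its edge voxels to the surface.
    """
    mask = _as_binary(mask, "mask")
    if not mask.any():
        return np.zeros_like(mask)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def surface_distances(
    a: np.ndarray, b: np.ndarray, spacing: Sequence[float]
) -> np.ndarray:
    """Pooled symmetric multiset of surface-to-surface distances (mm).

    Distances run from each surface-voxel center of one mask to the nearest
    surface-voxel center of the other, in both directions, under anisotropic
    spacing.
    """
    a = _as_binary(a, "a")
    b = _as_binary(b, "b")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise UndefinedMetricError(
            "surface distance undefined: "
            + ("first" if not a.any() else "second")
            + " mask is empty"
        )
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != a.ndim or any(s <= 0 for s in spacing):
        raise ValueError(f"invalid spacing {spacing} for {a.ndim}-D masks")
    sa = surface_voxels(a)
    sb = surface_voxels(b)
    # Distance from every voxel to the nearest surface voxel of the other
    # mask: Euclidean distance transform of the surface complement.
    dt_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    return np.concatenate([dt_b[sa], dt_a[sb]])


def hd95(
    a: np.ndarray,
    b: np.ndarray,
    spacing: Sequence[float],
    percentile: float = 95.0,
    directed: bool = False,
) -> float:
    """95th-percentile Hausdorff distance in millimetres.

    Pooled symmetric convention by default; ``directed=True`` returns the
    maximum of the two directed percentiles instead.  Raises
    :class:`UndefinedMetricError` when either mask is empty.
    """
    dists = surface_distances(a, b, spacing)
    if directed:
        sa_count = int(surface_voxels(_as_binary(a, "a")).sum())
        d_ab = dists[:sa_count]
        d_ba = dists[sa_count:]
        return float(
            max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile))
        )
    return float(np.percentile(dists, percentile))
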
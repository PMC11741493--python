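"""NIfTI-1 reading and writing for maps, masks and synthesized volumes.

All volumes travel as NIfTI-1 through :mod:`nibabel`.  Voxel spacing is taken
from the header zooms; a sidecar consistency check rejects sets of volumes
whose affines disagree beyond a small tolerance, since every downstream step
assumes voxelwise alignment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

from .relaxometry import QuantitativeMaps

AFFINE_ATOL = 1e-4


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple, np.ndarray]:
    """Read a NIfTI volume; return (data, spacing_mm, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
    return data, spacing, np.asarray(img.affine, dtype=float)


def write_volume(
    path: str | Path,
    data: np.ndarray,
    spacing: Sequence[float],
    affine: np.ndarray | None = None,
    dtype=None,
) -> None:
    """Write a volume as NIfTI-1 with a diagonal affine built from spacing."""
    if affine is None:
        affine = np.diag(list(spacing) + [1.0])
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def check_affines(affines: Iterable[np.ndarray], names: Iterable[str]) -> None:
    """Reject volume sets whose affines disagree beyond ``AFFINE_ATOL``."""
    affines = list(affines)
    names = list(names)
    if not affines:
        return
    ref = affines[0]
    for aff, name in zip(affines[1:], names[1:]):
        if not np.allclose(aff, ref, atol=AFFINE_ATOL):
            raise ValueError(
                f"affine of {name!r} disagrees with {names[0]!r} beyond "
                f"{AFFINE_ATOL}; volumes are not co-registered"
            )


def read_maps(t1_path: str | Path, t2_path: str | Path, pd_path: str | Path,
              b1_path: str | Path | None = None) -> QuantitativeMaps:
    """Load T1/T2/PD (and optional B1) maps, checking co-registration."""
    t1, spacing, a1 = read_volume(t1_path)
    t2, _, a2 = read_volume(t2_path)
    pd_, _, a3 = read_volume(pd_path)
    affines = [a1, a2, a3]
    names = [str(t1_path), str(t2_path), str(pd_path)]
    b1 = None
    if b1_path is not None:
        b1, _, a4 = read_volume(b1_path)
        affines.append(a4)
        names.append(str(b1_path))
    check_affines(affines, names)
    return QuantitativeMaps(t1_map=t1, t2_map=t2, pd_map=pd_, spacing=spacing,
                            b1_field=b1)


def write_maps(maps: QuantitativeMaps, directory: str | Path,
               prefix: str = "phantom") -> dict[str, Path]:
    """Write the three maps (and B1 if present) next to each other."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for key, vol in (("t1", maps.t1_map), ("t2", maps.t2_map), ("pd", maps.pd_map)):
        path = directory / f"{prefix}_{key}.nii"
        write_volume(path, vol, maps.spacing)
        out[key] = path
    if maps.b1_field is not None:
        path = directory / f"{prefix}_b1.nii"
        write_volume(path, maps.b1_field, maps.spacing)
        out["b1"] = path
    return out


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple]:
    """Read a binary mask; values are binarized at 0.5."""
    data, spacing, _ = read_volume(path)
    return (data > 0.5), spacing


def write_mask(path: str | Path, mask: np.ndarray,
               spacing: Sequence[float]) -> None:
    write_volume(path, np.asarray(mask, dtype=np.uint8), spacing, dtype=np.uint8)
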
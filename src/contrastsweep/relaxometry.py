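"""Quantitative-map data model and spin-echo contrast synthesis.

Contrast-weighted images are generated from voxelwise T1, T2 and proton
density (PD) maps with the standard saturation-recovery spin-echo signal
model

    S = gain * B1 * PD * (1 - exp(-TR/T1)) * exp(-TE/T2)

which is the canonical approximation used by synthetic-MR packages.  An
inversion-recovery variant (magnitude signal) is available when an
inversion time TI is supplied.  Commercial synthesis engines apply further
sequence-specific corrections (slice profile, echo-train effects) that are
not modelled here; for TR/TE contrast behaviour the model above is the
accepted stand-in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "QuantitativeMaps",
    "AcquisitionParams",
    "synthesize_image",
    "synthesize_ir_image",
    "quantize_12bit",
]


@dataclass
class QuantitativeMaps:
    """Co-registered quantitative relaxometry volumes.

    Parameters
    ----------
    t1_map, t2_map : ndarray
        Longitudinal / transverse relaxation times in milliseconds.
        Zero marks background (air).
    pd_map : ndarray
        Proton density in arbitrary units; zero marks background.
    spacing : sequence of float
        Voxel spacing in millimetres, one entry per axis.
    b1_field : ndarray, optional
        Multiplicative transmit-field bias; defaults to 1 everywhere.
    """

    t1_map: np.ndarray
    t2_map: np.ndarray
    pd_map: np.ndarray
    spacing: Sequence[float]
    b1_field: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.t1_map = np.asarray(self.t1_map, dtype=float)
        self.t2_map = np.asarray(self.t2_map, dtype=float)
        self.pd_map = np.asarray(self.pd_map, dtype=float)
        shape = self.t1_map.shape
        for name in ("t2_map", "pd_map"):
            vol = getattr(self, name)
            if vol.shape != shape:
                raise ValueError(
                    f"shape mismatch: {name} has shape {vol.shape}, "
                    f"expected {shape} (from t1_map)"
                )
        if self.b1_field is not None:
            self.b1_field = np.asarray(self.b1_field, dtype=float)
            if self.b1_field.shape != shape:
                raise ValueError(
                    f"shape mismatch: b1_field has shape {self.b1_field.shape}, "
                    f"expected {shape} (from t1_map)"
                )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.t1_map.ndim:
            raise ValueError(
                f"spacing has {len(self.spacing)} entries for a "
                f"{self.t1_map.ndim}-dimensional volume"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        # Fitted maps can be noisy: T2 > T1 is unphysical but tolerated.
        tissue = (self.t1_map > 0) & (self.t2_map > 0)
        n_bad = int(np.count_nonzero(self.t2_map[tissue] > self.t1_map[tissue]))
        if n_bad:
            warnings.warn(
                f"{n_bad} voxel(s) have T2 > T1; physically implausible but "
                "kept as-is (noisy fits can violate this)",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple:
        return self.t1_map.shape

    def b1(self) -> np.ndarray:
        """The transmit-bias field, materialized (ones when absent)."""
        if self.b1_field is None:
            return np.ones(self.shape, dtype=float)
        return self.b1_field


@dataclass(frozen=True)
class AcquisitionParams:
    """One acquisition point: repetition time TR, echo time TE, optional TI (ms)."""

    tr: float
    te: float
    ti: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if self.te < 0:
            raise ValueError(f"TE must be non-negative, got {self.te}")
        if self.ti is not None and self.ti <= 0:
            raise ValueError(f"TI must be positive, got {self.ti}")

    def validate(self) -> None:
        """Check the timing constraints required before synthesis."""
        if self.te >= self.tr:
            raise ValueError(
                f"TE ({self.te} ms) must be smaller than TR ({self.tr} ms)"
            )
        if self.ti is not None and self.ti >= self.tr:
            raise ValueError(
                f"TI ({self.ti} ms) must be smaller than TR ({self.tr} ms)"
            )


def _signal_factors(
    maps: QuantitativeMaps, params: AcquisitionParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel recovery and decay factors, with background zeroed."""
    t1 = maps.t1_map
    t2 = maps.t2_map
    foreground = (maps.pd_map > 0) & (t1 > 0)

    tr_over_t1 = np.divide(params.tr, t1, out=np.zeros_like(t1), where=t1 > 0)
    recovery = np.where(t1 > 0, -np.expm1(-tr_over_t1), 0.0)
    if params.te == 0:
        decay = np.ones_like(t2)
    else:
        te_over_t2 = np.divide(params.te, t2, out=np.full_like(t2, np.inf), where=t2 > 0)
        decay = np.exp(-te_over_t2)
    return recovery, decay, foreground


def synthesize_image(
    maps: QuantitativeMaps, params: AcquisitionParams, gain: float = 1.0
) -> np.ndarray:
    """Synthesize a spin-echo contrast-weighted image at (TR, TE).

    S = gain * B1 * PD * (1 - exp(-TR/T1)) * exp(-TE/T2); background voxels
    (PD = 0 or T1 = 0) map to zero.  The output shares the maps' shape;
    spacing travels with the maps.
    """
    if gain <= 0:
        raise ValueError(f"gain must be positive, got {gain}")
    params.validate()
    recovery, decay, foreground = _signal_factors(maps, params)
    signal = gain * maps.b1() * maps.pd_map * recovery * decay
    return np.where(foreground, signal, 0.0)


def synthesize_ir_image(
    maps: QuantitativeMaps, params: AcquisitionParams, gain: float = 1.0
) -> np.ndarray:
    """Synthesize an inversion-recovery spin-echo image (magnitude signal).

    S = |gain * B1 * PD * (1 - 2 exp(-TI/T1) + exp(-TR/T1)) * exp(-TE/T2)|.
    Requires ``params.ti``; the signal nulls where TI = T1 ln 2 (for long TR).
    """
    if params.ti is None:
        raise ValueError("inversion-recovery synthesis requires TI")
    if gain <= 0:
        raise ValueError(f"gain must be positive, got {gain}")
    params.validate()
    t1 = maps.t1_map
    _, decay, foreground = _signal_factors(maps, params)
    ti_over_t1 = np.divide(params.ti, t1, out=np.full_like(t1, np.inf), where=t1 > 0)
    tr_over_t1 = np.divide(params.tr, t1, out=np.full_like(t1, np.inf), where=t1 > 0)
    ir = np.where(t1 > 0, 1.0 - 2.0 * np.exp(-ti_over_t1) + np.exp(-tr_over_t1), 0.0)
    signal = gain * maps.b1() * maps.pd_map * ir * decay
    return np.abs(np.where(foreground, signal, 0.0))


def quantize_12bit(volume: np.ndarray) -> np.ndarray:
    """Linearly rescale a float volume to the unsigned 12-bit range [0, 4095].

    Off by default in the pipeline (segmenter preprocessing re-normalizes);
    provided for realism when exporting scanner-like intensities.
    """
    volume = np.asarray(volume, dtype=float)
    lo, hi = float(volume.min()), float(volume.max())
    if hi == lo:
        return np.zeros(volume.shape, dtype=np.uint16)
    scaled = (volume - lo) / (hi - lo) * 4095.0
    return np.round(scaled).astype(np.uint16)
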
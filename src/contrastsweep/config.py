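"""Run configuration: YAML schema, validation, defaults.

An empty config file (or ``RunConfig()``) describes the full default run:
the standard 18 x 16 TR/TE grid with the mixed region excluded, the
published salivary-gland IOV cutoffs, the default digital phantom with
three simulated raters, STAPLE consensus, and the anchor-calibrated
intensity-window segmenter.  Unknown keys anywhere in the file are
rejected by name so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .phantom import PhantomSpec
from .relaxometry import AcquisitionParams
from .sweep import IOVThresholds, SweepGrid

__all__ = ["RunConfig", "load_config"]

_SCHEMA: Dict[str, Any] = {
    "seed": None,
    "output_dir": None,
    "gain": None,
    "phantom": {"shape", "spacing", "noise_sigma", "b1_amplitude"},
    "paths": {"t1_map", "t2_map", "pd_map", "b1_map", "truth", "raters"},
    "grid": {"tr_ms", "te_ms", "include_mixed", "anchor_tr_ms",
             "anchor_te_ms"},
    "iov": {"dsc", "hd95_mm"},
    "staple": {"max_iter", "tol", "threshold", "prior"},
    "raters": {"n", "perturbation_mm"},
    "segmenter": {"name"},
}


@dataclass
class StapleSettings:
    max_iter: int = 100
    tol: float = 1e-7
    threshold: float = 0.5
    prior: Optional[float] = None


@dataclass
class RaterSettings:
    n: int = 3
    perturbation_mm: float = 1.0


@dataclass
class RunConfig:
    """Fully-resolved run configuration (defaults = the standard analysis)."""

    seed: int = 0
    output_dir: str = "contrastsweep_run"
    gain: float = 1.0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    b1_amplitude: float = 0.0
    paths: Optional[Dict[str, Any]] = None
    grid: SweepGrid = field(default_factory=SweepGrid)
    iov: IOVThresholds = field(default_factory=IOVThresholds)
    staple: StapleSettings = field(default_factory=StapleSettings)
    raters: RaterSettings = field(default_factory=RaterSettings)
    segmenter_name: str = "intensity_window"

    def to_dict(self) -> Dict[str, Any]:
        """Round-trippable echo of the configuration (for provenance)."""
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "gain": self.gain,
            "phantom": {
                "shape": list(self.phantom.shape),
                "spacing": list(self.phantom.spacing),
                "noise_sigma": list(self.phantom.noise_sigma),
                "b1_amplitude": self.b1_amplitude,
            },
            "grid": {
                "tr_ms": list(self.grid.tr_values),
                "te_ms": list(self.grid.te_values),
                "include_mixed": self.grid.include_mixed,
                "anchor_tr_ms": self.grid.anchor.tr,
                "anchor_te_ms": self.grid.anchor.te,
            },
            "iov": {"dsc": dict(self.iov.dsc),
                    "hd95_mm": dict(self.iov.hd95_mm)},
            "staple": {"max_iter": self.staple.max_iter,
                       "tol": self.staple.tol,
                       "threshold": self.staple.threshold,
                       "prior": self.staple.prior},
            "raters": {"n": self.raters.n,
                       "perturbation_mm": self.raters.perturbation_mm},
            "segmenter": {"name": self.segmenter_name},
        }


def _check_keys(data: Dict[str, Any]) -> None:
    for key, val in data.items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown key: {key}")
        allowed = _SCHEMA[key]
        if isinstance(allowed, set):
            if not isinstance(val, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            for sub in val:
                if sub not in allowed:
                    raise ValueError(f"unknown key: {key}.{sub}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing sections take the documented defaults; unknown keys raise a
    ``ValueError`` naming the key; structurally invalid values raise with
    the key and constraint.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    _check_keys(data)

    cfg = RunConfig()
    if "seed" in data:
        cfg.seed = int(data["seed"])
    if "output_dir" in data:
        cfg.output_dir = str(data["output_dir"])
    if "gain" in data:
        cfg.gain = float(data["gain"])
        if cfg.gain <= 0:
            raise ValueError("gain: must be positive")

    ph = data.get("phantom", {})
    kwargs = {}
    if "shape" in ph:
        kwargs["shape"] = tuple(int(v) for v in ph["shape"])
    if "spacing" in ph:
        kwargs["spacing"] = tuple(float(v) for v in ph["spacing"])
    if "noise_sigma" in ph:
        kwargs["noise_sigma"] = tuple(float(v) for v in ph["noise_sigma"])
    cfg.phantom = PhantomSpec(**kwargs)
    cfg.b1_amplitude = float(ph.get("b1_amplitude", 0.0))
    if not 0.0 <= cfg.b1_amplitude < 1.0:
        raise ValueError("phantom.b1_amplitude: must be in [0, 1)")

    if "paths" in data:
        cfg.paths = dict(data["paths"])

    gr = data.get("grid", {})
    anchor = AcquisitionParams(
        tr=float(gr.get("anchor_tr_ms", 1535.0)),
        te=float(gr.get("anchor_te_ms", 212.0)))
    grid_kwargs: Dict[str, Any] = {"anchor": anchor}
    if "tr_ms" in gr:
        grid_kwargs["tr_values"] = [float(v) for v in gr["tr_ms"]]
    if "te_ms" in gr:
        grid_kwargs["te_values"] = [float(v) for v in gr["te_ms"]]
    if "include_mixed" in gr:
        grid_kwargs["include_mixed"] = bool(gr["include_mixed"])
    cfg.grid = SweepGrid(**grid_kwargs)

    iov = data.get("iov", {})
    iov_kwargs = {}
    if "dsc" in iov:
        iov_kwargs["dsc"] = {str(k): float(v) for k, v in iov["dsc"].items()}
    if "hd95_mm" in iov:
        iov_kwargs["hd95_mm"] = {str(k): float(v)
                                 for k, v in iov["hd95_mm"].items()}
    cfg.iov = IOVThresholds(**iov_kwargs)

    st = data.get("staple", {})
    cfg.staple = StapleSettings(
        max_iter=int(st.get("max_iter", 100)),
        tol=float(st.get("tol", 1e-7)),
        threshold=float(st.get("threshold", 0.5)),
        prior=None if st.get("prior") is None else float(st["prior"]),
    )
    if cfg.staple.max_iter < 1:
        raise ValueError("staple.max_iter: must be >= 1")
    if not 0.0 < cfg.staple.threshold <= 1.0:
        raise ValueError("staple.threshold: must be in (0, 1]")

    ra = data.get("raters", {})
    cfg.raters = RaterSettings(
        n=int(ra.get("n", 3)),
        perturbation_mm=float(ra.get("perturbation_mm", 1.0)))
    if cfg.raters.n < 1:
        raise ValueError("raters.n: must be >= 1")
    if cfg.raters.perturbation_mm < 0:
        raise ValueError("raters.perturbation_mm: must be >= 0")

    seg = data.get("segmenter", {})
    cfg.segmenter_name = str(seg.get("name", "intensity_window"))
    return cfg
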
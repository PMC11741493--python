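"""STAPLE label fusion: EM estimation of a consensus mask and rater performance.

Given R aligned binary rater masks, the algorithm alternates between

* E-step: the posterior foreground probability per voxel,
  W_i = a_i / (a_i + b_i), with
  a_i = pi * prod_j [ p_j if rater j voted 1 else (1 - p_j) ] and
  b_i = (1 - pi) * prod_j [ (1 - q_j) if rater j voted 1 else q_j ],
* M-step: per-rater sensitivity p_j = sum_{i: D_ij=1} W_i / sum_i W_i and
  specificity q_j = sum_{i: D_ij=0} (1 - W_i) / sum_i (1 - W_i),

until the change in mean(p) + mean(q) falls below a tolerance.  The
computation is restricted to a bounding box dilated a fixed margin around
the union of the rater masks; the specificity estimate is sensitive to the
amount of background included, so the crop rule is fixed and part of the
method definition.  Voxels outside the crop are background with W = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = ["RaterMaskStack", "RaterPerformance", "ConsensusResult", "staple"]

CROP_MARGIN_VOXELS = 5


@dataclass
class RaterMaskStack:
    """Aligned binary masks from R raters for one structure."""

    masks: np.ndarray  # (R, *shape) boolean
    rater_ids: Sequence[str]
    spacing: Sequence[float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.masks)
        if arr.ndim < 2:
            raise ValueError("masks must be a stack of >= 1 volume")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("rater masks must be binary (0/1)")
            arr = arr.astype(bool)
        self.masks = arr
        self.rater_ids = list(self.rater_ids)
        if len(self.rater_ids) != arr.shape[0]:
            raise ValueError(
                f"{len(self.rater_ids)} rater ids for {arr.shape[0]} masks"
            )
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_raters(self) -> int:
        return self.masks.shape[0]

    @property
    def shape(self) -> tuple:
        return self.masks.shape[1:]


@dataclass
class RaterPerformance:
    """Estimated per-rater sensitivity p and specificity q."""

    sensitivity: np.ndarray
    specificity: np.ndarray
    rater_ids: Sequence[str] = field(default_factory=list)


@dataclass
class ConsensusResult:
    """STAPLE output: posterior probability map, binary consensus, performance."""

    probability: np.ndarray
    consensus: np.ndarray
    performance: RaterPerformance
    iterations: int
    converged: bool
    log_likelihood_trace: np.ndarray


def _crop_slices(union: np.ndarray, margin: int) -> tuple[slice, ...]:
    idx = np.nonzero(union)
    slices = []
    for ax, coords in enumerate(idx):
        lo = max(int(coords.min()) - margin, 0)
        hi = min(int(coords.max()) + margin + 1, union.shape[ax])
        slices.append(slice(lo, hi))
    return tuple(slices)


def staple(
    stack: RaterMaskStack,
    prior: Optional[Union[float, np.ndarray]] = None,
    max_iter: int = 100,
    tol: float = 1e-7,
    threshold: float = 0.5,
) -> ConsensusResult:
    """Run STAPLE on a stack of rater masks.

    Parameters
    ----------
    stack : RaterMaskStack
        R >= 1 aligned binary masks; all-empty stacks are rejected.
    prior : float or ndarray, optional
        Prior foreground probability pi; default is the mean rater
        foreground fraction inside the crop (scalar).  A volume prior must
        match the mask shape and is cropped alongside the masks.
    max_iter, tol :
        EM stops when |Δ(mean p + mean q)| < tol or after max_iter rounds.
    threshold :
        Binary consensus = (W >= threshold); the W == threshold tie goes to
        foreground.
    """
    masks = stack.masks
    R = stack.n_raters
    union = masks.any(axis=0)
    if not union.any():
        raise ValueError("all rater masks are empty; STAPLE is undefined")

    slices = _crop_slices(union, CROP_MARGIN_VOXELS)
    votes = masks[(slice(None),) + slices].reshape(R, -1).astype(float)
    n_vox = votes.shape[1]

    if prior is None:
        pi = float(votes.mean())
    elif np.isscalar(prior):
        pi = float(prior)
        if not 0.0 < pi < 1.0:
            raise ValueError(f"scalar prior must lie in (0, 1), got {pi}")
    else:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != stack.shape:
            raise ValueError(
                f"prior volume shape {prior.shape} does not match masks {stack.shape}"
            )
        pi = np.clip(prior[slices].ravel(), 1e-12, 1.0 - 1e-12)

    p = np.full(R, 0.99999)
    q = np.full(R, 0.99999)
    eps = 1e-12
    ll_trace = []
    converged = False
    it = 0
    prev_stat = p.mean() + q.mean()

    for it in range(1, max_iter + 1):
        # E-step in log space for numerical safety with many raters
        lp = np.log(np.clip(p, eps, 1.0))
        l1p = np.log(np.clip(1.0 - p, eps, 1.0))
        lq = np.log(np.clip(q, eps, 1.0))
        l1q = np.log(np.clip(1.0 - q, eps, 1.0))
        log_a = np.log(pi) + votes.T @ lp + (1.0 - votes.T) @ l1p
        log_b = np.log1p(-pi) + votes.T @ l1q + (1.0 - votes.T) @ lq
        m = np.maximum(log_a, log_b)
        ea = np.exp(log_a - m)
        eb = np.exp(log_b - m)
        ll_trace.append(float(np.sum(m + np.log(ea + eb))))
        W = ea / (ea + eb)

        # M-step
        sum_w = W.sum()
        sum_1w = n_vox - sum_w
        p = (votes @ W) / max(sum_w, eps)
        q = ((1.0 - votes) @ (1.0 - W)) / max(sum_1w, eps)
        p = np.clip(p, eps, 1.0)
        q = np.clip(q, eps, 1.0)

        stat = p.mean() + q.mean()
        if abs(stat - prev_stat) < tol:
            converged = True
            break
        prev_stat = stat

    probability = np.zeros(stack.shape, dtype=float)
    probability[slices] = W.reshape(masks[0][slices].shape)
    consensus = probability >= threshold

    perf = RaterPerformance(
        sensitivity=np.asarray(p), specificity=np.asarray(q),
        rater_ids=list(stack.rater_ids),
    )
    return ConsensusResult(
        probability=probability,
        consensus=consensus,
        performance=perf,
        iterations=it,
        converged=converged,
        log_likelihood_trace=np.asarray(ll_trace),
    )
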
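"""Weber-fraction estimation by non-linear least squares on block accuracies.

The fit mirrors the classical procedure for child numerosity data: the
proportion correct observed at each available ratio is matched against the
cumulative-Gaussian psychometric prediction

    p(r; w) = Phi((1 - r) / (w * sqrt(1 + r**2))),   r = n_small / n_large,

and w minimizes the unweighted sum of squared residuals over ratios.  The two
same-ratio stimulus pairs share this prediction exactly (scale invariance), so
blocks are pooled by ratio before fitting.  Minimization is a coarse grid
(w = 0.05, 0.10, ..., 2.00) followed by bounded local refinement; the search
is restricted to w in (1e-3, 5].  Estimates above 1 are flagged for exclusion
from downstream correlational analyses (acuity coarser than that of
6-month-olds is treated as an unusable fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

from .errors import InsufficientDataError
from .stimuli import ratio_fraction
from .task import BlockResult, StaircaseOutcome

__all__ = ["WeberEstimate", "fit_weber", "fit_cohort", "estimates_frame", "W_BOUNDS"]

W_BOUNDS = (1e-3, 5.0)
_GRID = np.arange(0.05, 2.0 + 1e-9, 0.05)


@dataclass(frozen=True)
class WeberEstimate:
    """Fitted Weber fraction with convergence and exclusion metadata."""

    w_hat: float
    sse: float
    n_ratios_used: int
    converged: bool
    excluded_above_one: bool


def _sensitivity(ratios: np.ndarray) -> np.ndarray:
    """Scaled-difference coefficient c(r) with p(r; w) = Phi(c(r) / w)."""
    return (1.0 - ratios) / np.sqrt(1.0 + ratios**2)


def _sse(w: float, coef: np.ndarray, observed: np.ndarray) -> float:
    return float(np.sum((observed - ndtr(coef / w)) ** 2))


def fit_weber(blocks: list[BlockResult]) -> WeberEstimate:
    """Estimate w from block-level counts (blocks pooled by ratio).

    Raises
    ------
    InsufficientDataError
        With fewer than two distinct ratios carrying trials.
    """
    counts: dict[str, list[int]] = {}
    for b in blocks:
        if b.n_trials > 0:
            t, k = counts.setdefault(b.ratio_label, [0, 0])
            counts[b.ratio_label] = [t + b.n_trials, k + b.n_correct]
    if len(counts) < 2:
        raise InsufficientDataError("need blocks at >= 2 ratios to fit w")
    ratios = np.array([ratio_fraction(r) for r in counts])
    observed = np.array([k / t for t, k in counts.values()])
    coef = _sensitivity(ratios)

    # Coarse grid, vectorized over w.
    pred = ndtr(coef[:, None] / _GRID[None, :])
    sse_grid = ((observed[:, None] - pred) ** 2).sum(axis=0)
    i = int(np.argmin(sse_grid))
    step = float(_GRID[1] - _GRID[0])
    lo = max(W_BOUNDS[0], float(_GRID[i]) - step)
    hi = min(W_BOUNDS[1], float(_GRID[i]) + step)
    # The upper grid end can hide a minimum beyond 2; widen once if it is hit.
    if i == len(_GRID) - 1:
        hi = W_BOUNDS[1]
    res = minimize_scalar(
        _sse,
        bounds=(lo, hi),
        args=(coef, observed),
        method="bounded",
        options={"xatol": 1e-7},
    )
    converged = bool(res.success)
    w_hat = float(res.x) if converged else float(_GRID[i])
    sse = _sse(w_hat, coef, observed)
    # Guard: never return worse than the best grid point.
    if sse > sse_grid[i]:
        w_hat, sse = float(_GRID[i]), float(sse_grid[i])
    # Perfect data leave SSE flat near zero; prefer the boundary when it is
    # not worse, so ceiling performance pins the lower search bound.
    sse_lo = _sse(W_BOUNDS[0], coef, observed)
    if sse_lo <= sse + 1e-12:
        w_hat, sse = W_BOUNDS[0], sse_lo
    return WeberEstimate(
        w_hat=w_hat,
        sse=sse,
        n_ratios_used=len(counts),
        converged=converged,
        excluded_above_one=w_hat > 1.0,
    )


def fit_cohort(outcomes: list[StaircaseOutcome]) -> list[WeberEstimate]:
    """Fit every child; estimates with w > 1 stay in the table but are flagged."""
    return [fit_weber(o.blocks) for o in outcomes]


def estimates_frame(child_ids, estimates: list[WeberEstimate]) -> pd.DataFrame:
    """Estimates as a tidy table (child_id, w_hat, sse, converged, excluded_above_one)."""
    return pd.DataFrame(
        {
            "child_id": list(child_ids),
            "w_hat": [e.w_hat for e in estimates],
            "sse": [e.sse for e in estimates],
            "converged": [e.converged for e in estimates],
            "excluded_above_one": [e.excluded_above_one for e in estimates],
        }
    )
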
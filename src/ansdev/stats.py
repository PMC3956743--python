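"""Correlation machinery and cross-lagged inference.

The scientific core is the comparison of two dependent lagged correlations in
a two-wave design: r_SA (symbolic knowledge at wave 1 with ANS acuity at wave
2) against r_AS (acuity at wave 1 with symbolic knowledge at wave 2), with
r_Pred the wave-1 correlation of the two predictors.  Williams' t for
dependent correlations sharing a sample,

    t = (r_SA - r_AS) * sqrt( (n-1)(1 + r_Pred) /
        ( 2 (n-1)/(n-3) |R| + rbar^2 (1 - r_Pred)^3 ) ),   df = n - 3,

with |R| = 1 - r_SA^2 - r_AS^2 - r_Pred^2 + 2 r_SA r_AS r_Pred and
rbar = (r_SA + r_AS)/2, tests whether one predictive direction is stronger.
Correlations may first be partialled for covariates (age, general cognitive
factors) and for the autoregressor — the wave-1 value of each predicted
variable — so that a lagged correlation reflects change rather than
stability; each partialled covariate costs one degree of freedom.

Because the two lagged correlations share no variable once each is
residualized against its own autoregressor, Williams' test (which formally
assumes a common third variable) is an approximation here; Steiger's
no-shared-variable Z (the pooled Pearson-Filon statistic) is exposed as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    CollinearCovariatesError,
    DegenerateInputError,
    InsufficientDataError,
)

__all__ = [
    "PartialSpec",
    "CrossLagResult",
    "pearson_r",
    "partial_corr",
    "williams_t",
    "steiger_z",
    "chi_square_vs_chance",
    "contingency_chi_square",
    "paired_t",
    "crosslag_analysis",
    "correlation_table",
    "performance_table",
    "crosslag_table",
]


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation with explicit degeneracy checks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-d vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance input to pearson_r")
    return float(sps.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class PartialSpec:
    """Which correlation to compute and what to partial out of it."""

    x: str
    y: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.x in self.covariates or self.y in self.covariates:
            raise ValueError("target columns must not appear among covariates")


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise CollinearCovariatesError("covariate design matrix is rank deficient")
    return y - design @ coef

def partial_corr(data: pd.DataFrame, spec: PartialSpec) -> tuple[float, int]:
    """Correlation of x and y after removing covariates by least squares.

    Rows with a missing value in any used column are dropped (listwise).
    Returns (r, df) with df = n - 2 - k for k covariates.
    """
    cols = [spec.x, spec.y, *spec.covariates]
    sub = data[cols].dropna()
    k = len(spec.covariates)
    n = len(sub)
    if n < k + 4:
        raise InsufficientDataError(f"need >= {k + 4} complete rows, have {n}")
    design = np.column_stack([np.ones(n), sub[list(spec.covariates)].to_numpy(float)])
    rx = _residualize(sub[spec.x].to_numpy(float), design)
    ry = _residualize(sub[spec.y].to_numpy(float), design)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise DegenerateInputError("a target variable is fully explained by covariates")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    return r, n - 2 - k


def chi_square_vs_chance(k: int, n: int) -> float:
    """Pearson chi-square (df = 1) of k successes in n trials against 50%."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    e = n / 2.0
    return (k - e) ** 2 / e + ((n - k) - e) ** 2 / e


def contingency_chi_square(table) -> tuple[float, int]:
    """Standard Pearson chi-square of an r x c count table, df = (r-1)(c-1)."""
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateInputError("table has an all-zero margin")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof)


def paired_t(x1: Sequence[float], x2: Sequence[float]) -> tuple[float, int]:
    """Paired t on the differences x1 - x2 (negative t when x2 exceeds x1)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or len(x1) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x1 - x2) == 0:
        raise DegenerateInputError("differences have zero variance")
    res = sps.ttest_rel(x1, x2)
    return float(res.statistic), len(x1) - 1


# ---------------------------------------------------------------------------
# dependent-correlation tests
# ---------------------------------------------------------------------------


def williams_t(
    r_sa: float,
    r_as: float,
    r_pred: float,
    n: int,
    two_sided: bool = False,
    det_tol: float = 1e-10,
) -> tuple[float, int, float]:
    """Williams' test for two dependent correlations sharing a sample.

    Returns (t, df, p) with df = n - 3.  ``p`` is one-sided for the
    alternative r_SA > r_AS unless ``two_sided``.  Raises if the correlation
    triple is numerically inconsistent (negative determinant of the implied
    3 x 3 correlation matrix beyond ``det_tol``).
    """
    for r in (r_sa, r_as, r_pred):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n < 5:
        raise ValueError("Williams' test needs n >= 5")
    det = 1.0 - r_sa**2 - r_as**2 - r_pred**2 + 2.0 * r_sa * r_as * r_pred
    if det < -det_tol:
        raise ValueError("inconsistent correlation triple (negative determinant)")
    det = max(det, 0.0)
    rbar = 0.5 * (r_sa + r_as)
    df = n - 3
    denom = 2.0 * ((n - 1) / (n - 3)) * det + rbar**2 * (1.0 - r_pred) ** 3
    t = (r_sa - r_as) * np.sqrt((n - 1) * (1.0 + r_pred) / denom)
    if two_sided:
        p = float(2.0 * sps.t.sf(abs(t), df))
    else:
        p = float(sps.t.sf(t, df))
    return float(t), df, p


def steiger_z(
    r_jk: float,
    r_hm: float,
    r_jh: float,
    r_jm: float,
    r_kh: float,
    r_km: float,
    n: int,
    two_sided: bool = False,
) -> tuple[float, float]:
    """Steiger's pooled Pearson-Filon Z for correlations with no shared variable.

    Compares r_jk against r_hm given the cross-correlations among the four
    variables j, k, h, m.  Returns (z, p); ``p`` is one-sided for
    r_jk > r_hm unless ``two_sided``.
    """
    if n < 5:
        raise ValueError("need n >= 5")
    rbar = 0.5 * (r_jk + r_hm)
    cov = (
        0.5 * rbar * rbar * (r_jh**2 + r_jm**2 + r_kh**2 + r_km**2)
        + r_jh * r_km
        + r_jm * r_kh
        - rbar * (r_jh * r_jm + r_kh * r_km)
        - rbar * (r_jh * r_kh + r_jm * r_km)
    )
    c = cov / (1.0 - rbar**2) ** 2
    z_jk = np.arctanh(r_jk)
    z_hm = np.arctanh(r_hm)
    z = (z_jk - z_hm) * np.sqrt((n - 3) / (2.0 - 2.0 * c))
    if two_sided:
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        p = float(sps.norm.sf(z))
    return float(z), p


# ---------------------------------------------------------------------------
# cross-lagged analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossLagResult:
    """The pair of lagged partial correlations and their Williams comparison."""

    r_SA: float
    r_AS: float
    r_Pred: float
    n: int
    df: int
    t: float
    p_one_sided: float
    direction: int  # sign of r_SA - r_AS
    symbolic_measure: str
    acuity_measure: str
    covariates: tuple[str, ...] = ()
    use_autoregressor: bool = True
    method: str = "williams"


def _columns(measure: str) -> tuple[str, str]:
    return f"{measure}_t1", f"{measure}_t2"


def crosslag_analysis(
    cohort: pd.DataFrame,
    symbolic_measure: str,
    acuity_measure: str,
    covariates: Sequence[str] = ("age_months",),
    use_autoregressor: bool = True,
    group: str | None = None,
    method: str = "williams",
    two_sided: bool = False,
) -> CrossLagResult:
    """Run the full cross-lagged comparison on a wide cohort table.

    ``cohort`` has one row per child with ``<measure>_t1``/``<measure>_t2``
    columns.  Children flagged ``below_chance_t1``/``below_chance_t2`` are
    dropped; when the acuity measure is the fitted Weber fraction (column
    prefix ``w_hat``), children flagged ``w_excluded_t1``/``w_excluded_t2``
    are dropped as well.  Remaining missing values are handled listwise.

    r_SA and r_AS are partial correlations given ``covariates`` (plus, when
    ``use_autoregressor``, the wave-1 value of each correlation's predicted
    variable); r_Pred relates the two wave-1 predictors under the base
    covariates.  The Williams comparison uses effective n' = n - k (k =
    number of partialled covariates including the autoregressor), so
    df = n - 3 - k.
    """
    s1, s2 = _columns(symbolic_measure)
    a1, a2 = _columns(acuity_measure)
    df_in = cohort
    if group is not None:
        df_in = df_in[df_in["age_group"] == group]
    for flag in ("below_chance_t1", "below_chance_t2"):
        if flag in df_in.columns:
            df_in = df_in[~df_in[flag].astype(bool)]
    if acuity_measure.startswith("w"):
        for flag in ("w_excluded_t1", "w_excluded_t2"):
            if flag in df_in.columns:
                df_in = df_in[~df_in[flag].astype(bool)]

    base = tuple(covariates)
    used = list(dict.fromkeys([s1, s2, a1, a2, *base]))
    sub = df_in[used].dropna()
    n = len(sub)
    k = len(base) + (1 if use_autoregressor else 0)
    if n < k + 5:
        raise InsufficientDataError(f"need >= {k + 5} complete rows, have {n}")

    cov_sa = base + ((a1,) if use_autoregressor else ())
    cov_as = base + ((s1,) if use_autoregressor else ())
    r_sa, _ = partial_corr(sub, PartialSpec(s1, a2, cov_sa))
    r_as, _ = partial_corr(sub, PartialSpec(a1, s2, cov_as))
    r_pred, _ = partial_corr(sub, PartialSpec(s1, a1, base))

    n_eff = n - k
    if method == "williams":
        t, dof, p = williams_t(r_sa, r_as, r_pred, n_eff, two_sided=two_sided)
    elif method == "steiger":
        # Residualize all four variables against the base covariates, then
        # compare the two no-shared-variable correlations.
        design = np.column_stack(
            [np.ones(n), sub[list(base)].to_numpy(float)] if base else [np.ones(n)]
        )
        res = {c: _residualize(sub[c].to_numpy(float), design) for c in (s1, a2, a1, s2)}
        rmat = np.corrcoef(np.column_stack([res[s1], res[a2], res[a1], res[s2]]).T)
        z, p = steiger_z(
            rmat[0, 1], rmat[2, 3], rmat[0, 2], rmat[0, 3], rmat[1, 2], rmat[1, 3],
            n_eff, two_sided=two_sided,
        )
        t, dof = z, n_eff - 3
    else:
        raise ValueError(f"unknown method {method!r}")

    return CrossLagResult(
        r_SA=r_sa,
        r_AS=r_as,
        r_Pred=r_pred,
        n=n,
        df=dof,
        t=t,
        p_one_sided=p,
        direction=int(np.sign(r_sa - r_as)),
        symbolic_measure=symbolic_measure,
        acuity_measure=acuity_measure,
        covariates=base,
        use_autoregressor=use_autoregressor,
        method=method,
    )


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------


def correlation_table(
    cohort: pd.DataFrame, columns: Sequence[str], age_column: str = "age_months"
) -> pd.DataFrame:
    """Dual-triangle correlation matrix.

    Simple Pearson correlations below the diagonal, age-partialled ones above
    it, blank (NaN) diagonal.  Pairwise-complete rows are used per cell.
    """
    cols = list(columns)
    out = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            if i == j:
                continue
            if i > j:  # below diagonal: simple r
                sub = cohort[[ci, cj]].dropna()
                out.loc[ci, cj] = pearson_r(sub[ci], sub[cj])
            else:  # above diagonal: age-partialled r
                r, _ = partial_corr(cohort, PartialSpec(ci, cj, (age_column,)))
                out.loc[ci, cj] = r
    return out


def performance_table(
    cohort: pd.DataFrame, measures: Sequence[str]
) -> pd.DataFrame:
    """Per-measure wave means/SDs with the paired t for the change over time."""
    rows = []
    for m in measures:
        c1, c2 = _columns(m)
        sub = cohort[[c1, c2]].dropna()
        t, dof = paired_t(sub[c1], sub[c2])
        rows.append(
            {
                "measure": m,
                "mean_t1": sub[c1].mean(),
                "sd_t1": sub[c1].std(ddof=1),
                "mean_t2": sub[c2].mean(),
                "sd_t2": sub[c2].std(ddof=1),
                "df": dof,
                "t": t,
            }
        )
    return pd.DataFrame(rows).set_index("measure")


def crosslag_table(
    cohort: pd.DataFrame,
    symbolic_measures: Sequence[str],
    acuity_measures: Sequence[str],
    covariates: Sequence[str] = ("age_months",),
    groups: Sequence[str | None] = (None,),
) -> pd.DataFrame:
    """Per-age-group rows of lagged correlations and Williams statistics."""
    rows = []
    for g in groups:
        for s in symbolic_measures:
            for a in acuity_measures:
                res = crosslag_analysis(
                    cohort, s, a, covariates=covariates, group=g
                )
                rows.append(
                    {
                        "age_group": "all" if g is None else g,
                        "symbolic": s,
                        "acuity": a,
                        "n": res.n,
                        "df": res.df,
                        "r_SA": res.r_SA,
                        "r_AS": res.r_AS,
                        "r_Pred": res.r_Pred,
                        "t": res.t,
                        "p_one_sided": res.p_one_sided,
                    }
                )
    return pd.DataFrame(rows)
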
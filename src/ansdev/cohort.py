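"""Generative model for longitudinal cohorts of 3- and 4-year-olds.

Each child carries standardized latent abilities at two waves seven months
apart: symbolic number knowledge S and ANS acuity A.  Age (in months,
standardized over the sampled mixture) loads on both wave-1 latents, acuity
additionally couples to concurrent symbolic knowledge (rho_T1), and the
wave-2 latents follow a cross-lagged linear system

    S2* = lambda_S * S1 + beta_AS * A1 + noise_sd_S * eps
    A2* = lambda_A * A1 + beta_SA * S1 + noise_sd_A * eps

(rescaled to unit variance analytically, so every latent is standard normal
by construction).  The directional claim "symbolic knowledge predicts later
ANS acuity" is the single coefficient beta_SA.

Observables are produced by running the task and scoring machinery, not by
adding noise to the latents directly: the true Weber fraction is a lognormal
link w = exp(mu - sigma * A) with (mu, sigma) solved so the population
matches the published mean/SD targets at each wave; accuracy and fitted w
come from simulated staircase sessions; give-a-number responses come from an
ordered-threshold knower-level model on S calibrated to the published
knower-level frequencies; counting-list and battery scores are linear in S,
rounded and truncated to instrument bounds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .errors import CalibrationError
from .symbolic import (
    BATTERY_MAX,
    COUNTING_LIST_CAP,
    GiveANumberResponse,
    KnowerLevel,
    classify_knower_level,
    score_give_a_number,
)
from .task import PsychometricModel, StaircaseOutcome, run_staircase
from .weber import WeberEstimate, fit_weber

__all__ = [
    "CohortConfig",
    "ChildRecord",
    "generate_cohort",
    "generate_give_a_number",
    "apply_exclusions",
    "cohort_frame",
    "cohort_long",
    "simulate_crosslag_replicates",
    "KNOWER_LEVEL_FREQS",
]

#: Knower-level frequency targets per (age_group, time point), calibrated to
#: the published level counts: 3-year-olds n = 16, 4-year-olds n = 41.
#: 3-year-olds are tested up to 5, 4-year-olds up to 7.
KNOWER_LEVEL_FREQS: dict[tuple[str, int], dict[KnowerLevel, float]] = {
    ("3yo", 1): {
        KnowerLevel.PRE: 1 / 16,
        KnowerLevel.ONE: 5 / 16,
        KnowerLevel.TWO: 5 / 16,
        KnowerLevel.THREE: 1 / 16,
        KnowerLevel.FOUR: 2 / 16,
        KnowerLevel.FIVE: 2 / 16,
    },
    ("3yo", 2): {
        KnowerLevel.ONE: 2 / 16,
        KnowerLevel.TWO: 7 / 16,
        KnowerLevel.THREE: 1 / 16,
        KnowerLevel.FOUR: 2 / 16,
        KnowerLevel.FIVE: 4 / 16,
    },
    ("4yo", 1): {
        KnowerLevel.PRE: 1 / 41,
        KnowerLevel.TWO: 8 / 41,
        KnowerLevel.THREE: 2 / 41,
        KnowerLevel.FOUR: 7 / 41,
        KnowerLevel.FIVE: 9 / 41,
        KnowerLevel.SEVEN: 14 / 41,
    },
    ("4yo", 2): {
        KnowerLevel.TWO: 2 / 41,
        KnowerLevel.THREE: 1 / 41,
        KnowerLevel.FOUR: 4 / 41,
        KnowerLevel.FIVE: 16 / 41,
        KnowerLevel.SEVEN: 18 / 41,
    },
}


@dataclass
class CohortConfig:
    """Generator parameters; defaults encode the emulated study conditions.

    Calibration targets (w, counting, battery, covariate moments, knower-level
    frequencies) come from the published wave summaries; structural
    coefficients (couplings, stabilities, loadings) are free choices that
    reproduce the qualitative correlational pattern of the study design.
    """

    n_children: int = 57
    age_range_months: tuple[float, float] = (36.0, 57.0)
    #: Age mixture: younger (3-year-old) vs older (4-year-old) components.
    younger_range: tuple[float, float] = (36.0, 46.0)
    older_range: tuple[float, float] = (44.0, 57.0)
    prop_younger: float = 16 / 57
    #: Cross-lag couplings: symbolic -> later acuity, acuity -> later symbolic.
    beta_SA: float = 0.35
    beta_AS: float = 0.0
    #: Wave-1 to wave-2 stabilities of the latents.
    lambda_S: float = 0.70
    lambda_A: float = 0.55
    #: Concurrent wave-1 coupling of acuity on symbolic knowledge.
    rho_T1: float = 0.45
    age_loading_S: float = 0.45
    age_loading_A: float = 0.25
    #: Wave-2 innovation scales (before analytic re-standardization).
    noise_sd_S: float = 0.55
    noise_sd_A: float = 0.65
    #: (mean_T1, sd_T1, mean_T2, sd_T2) of the true Weber fraction.
    w_calibration: tuple[float, float, float, float] = (0.42, 0.21, 0.26, 0.17)
    #: Per-measure (mean_T1, sd_T1, mean_T2, sd_T2) targets for scores linear
    #: in the symbolic latent.
    score_calibrations: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "counting": (13.0, 6.0, 21.0, 12.0),
            "battery": (30.0, 18.4, 38.8, 17.4),
        }
    )
    #: Covariates measured once: mean, sd, loading on standardized age, and
    #: loading on a child-level general cognitive factor.
    covariate_structure: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "iq": {"mean": 13.0, "sd": 3.6, "age_loading": 0.40, "g_loading": 0.45},
            "verbal_span": {"mean": 3.45, "sd": 0.7, "age_loading": 0.35, "g_loading": 0.45},
            "visuospatial_span": {"mean": 2.4, "sd": 0.8, "age_loading": 0.35, "g_loading": 0.45},
            "naming": {"mean": 38.6, "sd": 12.9, "age_loading": 0.45, "g_loading": 0.45},
        }
    )
    #: Per-trial success probability on give-a-number requests within the
    #: child's knower level.
    p_know: float = 0.9
    seed: int | None = None

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """The no-coupling null: S and A unrelated at and across both waves.

        Zeroes beta_SA, beta_AS and the concurrent coupling rho_T1, leaving
        age loadings (age is observed exactly and partialled out in the
        analyses) and everything else at their defaults.
        """
        overrides = {"beta_SA": 0.0, "beta_AS": 0.0, "rho_T1": 0.0, **overrides}
        return cls(**overrides)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("age_range_months", "younger_range", "older_range", "w_calibration"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "score_calibrations" in d:
            d["score_calibrations"] = {
                k: tuple(v) for k, v in d["score_calibrations"].items()
            }
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ChildRecord:
    """One simulated child across both waves."""

    id: int
    age_months: float
    age_group: str  # "3yo" or "4yo"
    S1: float
    A1: float
    S2: float
    A2: float
    true_w_t1: float
    true_w_t2: float
    drawn_level_t1: KnowerLevel
    drawn_level_t2: KnowerLevel
    staircase_t1: StaircaseOutcome | None = None
    staircase_t2: StaircaseOutcome | None = None
    accuracy_t1: float | None = None
    accuracy_t2: float | None = None
    below_chance_t1: bool = False
    below_chance_t2: bool = False
    weber_t1: WeberEstimate | None = None
    weber_t2: WeberEstimate | None = None
    gan_responses_t1: list[GiveANumberResponse] | None = None
    gan_responses_t2: list[GiveANumberResponse] | None = None
    give_a_number_t1: int | None = None
    give_a_number_t2: int | None = None
    knower_level_t1: KnowerLevel | None = None
    knower_level_t2: KnowerLevel | None = None
    counting_t1: int | None = None
    counting_t2: int | None = None
    battery_t1: float | None = None
    battery_t2: float | None = None
    covariates: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# latent structure
# ---------------------------------------------------------------------------


def _age_mixture_moments(cfg: CohortConfig) -> tuple[float, float]:
    """Analytic mean and SD of the two-component uniform age mixture."""
    p = cfg.prop_younger
    m_y = 0.5 * sum(cfg.younger_range)
    m_o = 0.5 * sum(cfg.older_range)
    v_y = (cfg.younger_range[1] - cfg.younger_range[0]) ** 2 / 12.0
    v_o = (cfg.older_range[1] - cfg.older_range[0]) ** 2 / 12.0
    mean = p * m_y + (1 - p) * m_o
    var = p * v_y + (1 - p) * v_o + p * (m_y - mean) ** 2 + (1 - p) * (m_o - mean) ** 2
    return mean, float(np.sqrt(var))


def _latent_coefficients(cfg: CohortConfig) -> dict[str, float]:
    """Residual scales that make every latent unit-variance, plus covariances."""
    aS, aA, rho = cfg.age_loading_S, cfg.age_loading_A, cfg.rho_T1
    v_eS1 = 1.0 - aS**2
    if v_eS1 <= 0:
        raise CalibrationError("age_loading_S too large for unit-variance S1")
    # Var(A1*) = aA^2 + rho^2 + 2 aA rho aS + v; Cov(z, S1) = aS.
    v_eA1 = 1.0 - (aA**2 + rho**2 + 2 * aA * rho * aS)
    if v_eA1 <= 0:
        raise CalibrationError("wave-1 loadings leave no residual variance for A1")
    c_SA1 = aS * aA + rho  # Cov(S1, A1)
    sd_S2 = np.sqrt(
        cfg.lambda_S**2 + cfg.beta_AS**2 + 2 * cfg.lambda_S * cfg.beta_AS * c_SA1
        + cfg.noise_sd_S**2
    )
    sd_A2 = np.sqrt(
        cfg.lambda_A**2 + cfg.beta_SA**2 + 2 * cfg.lambda_A * cfg.beta_SA * c_SA1
        + cfg.noise_sd_A**2
    )
    return {
        "sd_eS1": float(np.sqrt(v_eS1)),
        "sd_eA1": float(np.sqrt(v_eA1)),
        "c_SA1": float(c_SA1),
        "sd_S2": float(sd_S2),
        "sd_A2": float(sd_A2),
    }


def _lognormal_link(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of w = exp(mu - sigma * A) matching mean/SD for A ~ N(0,1)."""
    if mean <= 0 or sd <= 0:
        raise CalibrationError("w calibration targets must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - 0.5 * sigma2), float(np.sqrt(sigma2))


def _group_latent_moments(
    cfg: CohortConfig, loading: float, which: str
) -> dict[str, tuple[float, float]]:
    """Approximate conditional mean/SD of a wave-1-style latent per age group.

    Used only to centre the knower-level thresholds within each age group; the
    within-group age distribution is treated as the corresponding uniform
    component.
    """
    mean, sd = _age_mixture_moments(cfg)
    out = {}
    for grp, rng_ in (("3yo", cfg.younger_range), ("4yo", cfg.older_range)):
        mz = (0.5 * sum(rng_) - mean) / sd
        vz = ((rng_[1] - rng_[0]) ** 2 / 12.0) / sd**2
        m = loading * mz
        v = loading**2 * vz + (1.0 - loading**2)
        out[grp] = (float(m), float(np.sqrt(v)))
    return out


def _knower_thresholds() -> dict[tuple[str, int], tuple[list[float], list[KnowerLevel]]]:
    """Standard-normal cut points realizing the target level frequencies."""
    tables = {}
    for key, freqs in KNOWER_LEVEL_FREQS.items():
        levels = sorted(freqs, key=int)
        cum = np.cumsum([freqs[l] for l in levels])
        cuts = [float(norm.ppf(min(c, 1.0 - 1e-12))) for c in cum[:-1]]
        tables[key] = (cuts, levels)
    return tables


_THRESHOLDS = _knower_thresholds()


def _draw_knower_level(s_cond: float, age_group: str, time_point: int) -> KnowerLevel:
    cuts, levels = _THRESHOLDS[(age_group, time_point)]
    return levels[int(np.searchsorted(cuts, s_cond))]


# ---------------------------------------------------------------------------
# observable generators
# ---------------------------------------------------------------------------


def generate_give_a_number(
    child: ChildRecord,
    time_point: int,
    rng: np.random.Generator,
    p_know: float = 0.9,
) -> list[GiveANumberResponse]:
    """Simulate the give-a-number trials from the child's drawn knower level.

    Requests at or below the level are produced correctly with probability
    ``p_know``; other requests (and lapses) yield a draw from 1-10.  Three
    animal sets give three trials per requested numerosity: 15 trials for
    3-year-olds (requests 1-5), 18 for 4-year-olds (requests 1-5 and 7).
    """
    level = child.drawn_level_t1 if time_point == 1 else child.drawn_level_t2
    requests = (1, 2, 3, 4, 5) if child.age_group == "3yo" else (1, 2, 3, 4, 5, 7)
    responses = []
    for set_index in (1, 2, 3):
        for req in requests:
            if req <= int(level) and rng.random() < p_know:
                produced = req
            else:
                produced = int(rng.integers(1, 11))
            responses.append(
                GiveANumberResponse(requested=req, produced=produced, set_index=set_index)
            )
    return responses


def _truncated_linear_score(
    latent: np.ndarray, mean: float, sd: float, lower: float, upper: float
) -> np.ndarray:
    return np.clip(np.rint(mean + sd * latent), lower, upper)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    simulate_tasks: bool = True,
    fit_w: bool = True,
    simulate_gan: bool = True,
) -> list[ChildRecord]:
    """Draw a full cohort; deterministic for a fixed config seed (or rng).

    The switches skip expensive observables for replicate-heavy simulations:
    ``simulate_tasks`` controls staircase sessions (and therefore accuracy,
    below-chance flags and, with ``fit_w``, the fitted Weber fractions);
    ``simulate_gan`` controls give-a-number responses and knower-level
    classification.  Counting, battery and covariates are always produced.
    """
    if config.n_children < 4:
        raise CalibrationError("n_children must be at least 4")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_children
    coeffs = _latent_coefficients(config)
    age_mean, age_sd = _age_mixture_moments(config)

    younger = rng.random(n) < config.prop_younger
    ages = np.where(
        younger,
        rng.uniform(*config.younger_range, size=n),
        rng.uniform(*config.older_range, size=n),
    )
    z_age = (ages - age_mean) / age_sd

    S1 = config.age_loading_S * z_age + coeffs["sd_eS1"] * rng.standard_normal(n)
    A1 = (
        config.age_loading_A * z_age
        + config.rho_T1 * S1
        + coeffs["sd_eA1"] * rng.standard_normal(n)
    )
    S2 = (
        config.lambda_S * S1
        + config.beta_AS * A1
        + config.noise_sd_S * rng.standard_normal(n)
    ) / coeffs["sd_S2"]
    A2 = (
        config.lambda_A * A1
        + config.beta_SA * S1
        + config.noise_sd_A * rng.standard_normal(n)
    ) / coeffs["sd_A2"]

    m1, s1_, m2, s2_ = config.w_calibration
    mu1, sig1 = _lognormal_link(m1, s1_)
    mu2, sig2 = _lognormal_link(m2, s2_)
    w_t1 = np.exp(mu1 - sig1 * A1)
    w_t2 = np.exp(mu2 - sig2 * A2)

    # Covariates: shared general factor g plus age, residual to unit variance.
    g = rng.standard_normal(n)
    covariate_values: dict[str, np.ndarray] = {}
    for name, spec in config.covariate_structure.items():
        al, gl = spec["age_loading"], spec["g_loading"]
        resid_var = 1.0 - al**2 - gl**2
        if resid_var <= 0:
            raise CalibrationError(f"covariate {name!r} loadings exceed unit variance")
        latent = al * z_age + gl * g + np.sqrt(resid_var) * rng.standard_normal(n)
        covariate_values[name] = spec["mean"] + spec["sd"] * latent

    # Knower levels: threshold model on the group-centred symbolic latent.
    moments_t1 = _group_latent_moments(config, config.age_loading_S, "S1")
    # Wave-2 age loading on S2 is lambda_S * age_loading_S (plus beta_AS path).
    eff_loading_t2 = (
        config.lambda_S * config.age_loading_S + config.beta_AS * config.age_loading_A
    ) / coeffs["sd_S2"]
    moments_t2 = _group_latent_moments(config, eff_loading_t2, "S2")

    children: list[ChildRecord] = []
    for i in range(n):
        grp = "3yo" if younger[i] else "4yo"
        m_g1, s_g1 = moments_t1[grp]
        m_g2, s_g2 = moments_t2[grp]
        child = ChildRecord(
            id=i,
            age_months=float(ages[i]),
            age_group=grp,
            S1=float(S1[i]),
            A1=float(A1[i]),
            S2=float(S2[i]),
            A2=float(A2[i]),
            true_w_t1=float(w_t1[i]),
            true_w_t2=float(w_t2[i]),
            drawn_level_t1=_draw_knower_level((S1[i] - m_g1) / s_g1, grp, 1),
            drawn_level_t2=_draw_knower_level((S2[i] - m_g2) / s_g2, grp, 2),
            covariates={k: float(v[i]) for k, v in covariate_values.items()},
        )

        if simulate_tasks:
            for tp, w_true in ((1, child.true_w_t1), (2, child.true_w_t2)):
                outcome = run_staircase(PsychometricModel(w=w_true), rng)
                setattr(child, f"staircase_t{tp}", outcome)
                setattr(child, f"accuracy_t{tp}", outcome.overall_accuracy)
                setattr(child, f"below_chance_t{tp}", outcome.below_chance_flag)
                if fit_w:
                    setattr(child, f"weber_t{tp}", fit_weber(outcome.blocks))

        if simulate_gan:
            for tp in (1, 2):
                responses = generate_give_a_number(child, tp, rng, config.p_know)
                setattr(child, f"gan_responses_t{tp}", responses)
                setattr(child, f"give_a_number_t{tp}", score_give_a_number(responses))
                setattr(child, f"knower_level_t{tp}", classify_knower_level(responses))

        children.append(child)

    for name, (cm1, cs1, cm2, cs2) in config.score_calibrations.items():
        upper = COUNTING_LIST_CAP if name == "counting" else BATTERY_MAX
        v1 = _truncated_linear_score(S1, cm1, cs1, 0, upper)
        v2 = _truncated_linear_score(S2, cm2, cs2, 0, upper)
        for i, child in enumerate(children):
            setattr(child, f"{name}_t1", float(v1[i]) if name == "battery" else int(v1[i]))
            setattr(child, f"{name}_t2", float(v2[i]) if name == "battery" else int(v2[i]))

    return children


# ---------------------------------------------------------------------------
# exclusions and tabulation
# ---------------------------------------------------------------------------


def apply_exclusions(
    children: Sequence[ChildRecord],
) -> tuple[list[ChildRecord], dict[str, int]]:
    """Remove below-chance children; flag (but keep) unusable Weber fits.

    Below-chance performance at either wave removes the child from all
    analyses.  Fitted Weber fractions above 1 only flag the child for
    exclusion from w-based correlations (the flags travel in the cohort
    table as ``w_excluded_t1``/``w_excluded_t2``).
    """
    retained = [
        c for c in children if not (c.below_chance_t1 or c.below_chance_t2)
    ]
    report = {
        "n_input": len(children),
        "below_chance": len(children) - len(retained),
        "weber_above_one_t1": sum(
            1 for c in retained if c.weber_t1 is not None and c.weber_t1.excluded_above_one
        ),
        "weber_above_one_t2": sum(
            1 for c in retained if c.weber_t2 is not None and c.weber_t2.excluded_above_one
        ),
        "n_retained": len(retained),
    }
    return retained, report


def cohort_frame(children: Sequence[ChildRecord]) -> pd.DataFrame:
    """Wide analysis table: one row per child."""
    rows = []
    for c in children:
        row = {
            "id": c.id,
            "age_months": c.age_months,
            "age_group": c.age_group,
            "S1": c.S1,
            "A1": c.A1,
            "S2": c.S2,
            "A2": c.A2,
            "true_w_t1": c.true_w_t1,
            "true_w_t2": c.true_w_t2,
            "accuracy_t1": c.accuracy_t1,
            "accuracy_t2": c.accuracy_t2,
            "below_chance_t1": c.below_chance_t1,
            "below_chance_t2": c.below_chance_t2,
            "w_hat_t1": c.weber_t1.w_hat if c.weber_t1 else None,
            "w_hat_t2": c.weber_t2.w_hat if c.weber_t2 else None,
            "w_excluded_t1": c.weber_t1.excluded_above_one if c.weber_t1 else False,
            "w_excluded_t2": c.weber_t2.excluded_above_one if c.weber_t2 else False,
            "give_a_number_t1": c.give_a_number_t1,
            "give_a_number_t2": c.give_a_number_t2,
            "knower_level_t1": int(c.knower_level_t1) if c.knower_level_t1 is not None else None,
            "knower_level_t2": int(c.knower_level_t2) if c.knower_level_t2 is not None else None,
            "counting_t1": c.counting_t1,
            "counting_t2": c.counting_t2,
            "battery_t1": c.battery_t1,
            "battery_t2": c.battery_t2,
        }
        row.update(c.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_long(children: Sequence[ChildRecord]) -> pd.DataFrame:
    """Tidy table: one row per child per time point."""
    wide = cohort_frame(children)
    static = [
        c for c in wide.columns if not (c.endswith("_t1") or c.endswith("_t2"))
    ]
    frames = []
    for tp in (1, 2):
        cols = {f"{b}_t{tp}": b for b in
                {c[:-3] for c in wide.columns if c.endswith(f"_t{tp}")}}
        sub = wide[static + list(cols)].rename(columns=cols)
        sub.insert(1, "time_point", tp)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True).sort_values(["id", "time_point"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# replicated experiments
# ---------------------------------------------------------------------------


def simulate_crosslag_replicates(
    config: CohortConfig,
    n_reps: int,
    seed: int,
    symbolic_measure: str = "battery",
    acuity_measure: str = "accuracy",
    covariates: Sequence[str] = ("age_months",),
    use_autoregressor: bool = True,
    fit_w: bool | None = None,
    simulate_gan: bool | None = None,
) -> pd.DataFrame:
    """Repeatedly generate, exclude and analyze cohorts under one config.

    Only the observables the chosen measures require are simulated unless
    overridden.  Returns one row per replicate with the lagged correlations,
    Williams t, df and one-sided p.
    """
    from .stats import crosslag_analysis

    if fit_w is None:
        fit_w = acuity_measure.startswith("w")
    if simulate_gan is None:
        simulate_gan = "give_a_number" in (symbolic_measure, acuity_measure)
    ss = np.random.SeedSequence(seed)
    rows = []
    for child_ss in ss.spawn(n_reps):
        rng = np.random.default_rng(child_ss)
        children = generate_cohort(
            config, rng=rng, fit_w=fit_w, simulate_gan=simulate_gan
        )
        retained, _ = apply_exclusions(children)
        res = crosslag_analysis(
            cohort_frame(retained),
            symbolic_measure,
            acuity_measure,
            covariates=covariates,
            use_autoregressor=use_autoregressor,
        )
        rows.append(
            {
                "r_SA": res.r_SA,
                "r_AS": res.r_AS,
                "r_Pred": res.r_Pred,
                "n": res.n,
                "df": res.df,
                "t": res.t,
                "p_one_sided": res.p_one_sided,
            }
        )
    return pd.DataFrame(rows)
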
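"""Synthetic respondents and validation cohorts.

Two generators make the full pipeline testable without participant data:

* :func:`simulate_respondent` produces trial-level forced-choice logs and
  VAS ratings from a latent-utility model of a single child.  Each
  activity carries a utility; the latent sedentary preference ``theta``
  is the mean sedentary utility minus the mean physical utility.  Choices
  follow a logistic rule on the utility difference and reaction times
  shrink with the absolute utility gap (easy decisions are fast), so both
  the win counts and the RT ratios of the bias formula are informative.

* :func:`simulate_cohort` draws a cohort table (one row per child) whose
  bias scores co-vary with the validation measures — free-play sedentary
  time, accelerometry, fitness, adiposity — at configurable target
  correlations, via a single-factor Gaussian model: the standardized bias
  score is the factor and each measure loads on it with its target
  correlation.  The implied correlation matrix (rank-1 plus diagonal) is
  positive semidefinite by construction.  A full correlation matrix can
  be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from apa.scoring import TrialResponse, VASResponse
from apa.task_schedule import (
    ActivityCatalog,
    Category,
    TrialSchedule,
    build_default_catalog,
)


@dataclass(frozen=True)
class RespondentProfile:
    """Latent preference model of one simulated child.

    Parameters
    ----------
    catalog : ActivityCatalog
        Activities the utilities refer to.
    utilities : mapping of activity id to float
        Latent utility of each activity; higher = more wanted.
    beta : float
        Choice sensitivity (>= 0); ``inf`` gives deterministic choices
        (exact utility ties are resolved by a fair coin).
    rt_base : float
        Baseline reaction time in seconds (> 0).
    rt_slope : float
        Speed-up per unit absolute utility gap (>= 0).
    rt_sigma : float
        SD of multiplicative lognormal RT noise (>= 0).
    vas_intercept, vas_gain, vas_noise : float
        Affine map from utility to the 0-100 VAS scale, plus rating noise.
    p_nonresponse : float
        Per-trial probability of no response.
    """

    catalog: ActivityCatalog
    utilities: Mapping[str, float]
    beta: float = 4.0
    rt_base: float = 1.5
    rt_slope: float = 0.3
    rt_sigma: float = 0.25
    vas_intercept: float = 50.0
    vas_gain: float = 30.0
    vas_noise: float = 8.0
    p_nonresponse: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0 or self.rt_base <= 0 or self.rt_slope < 0 or self.rt_sigma < 0:
            raise ValueError("parameter outside its domain")
        if not 0.0 <= self.p_nonresponse < 1.0:
            raise ValueError("p_nonresponse must be in [0, 1)")
        missing = [a.id for a in self.catalog if a.id not in self.utilities]
        if missing:
            raise ValueError(f"missing utilities for activities: {missing}")

    @property
    def theta(self) -> float:
        """Latent sedentary preference: mean SED minus mean PA utility."""
        sed = [self.utilities[i] for i in self.catalog.ids(Category.SEDENTARY)]
        pa = [self.utilities[i] for i in self.catalog.ids(Category.PHYSICAL)]
        return float(np.mean(sed) - np.mean(pa))


def make_profile(
    theta: float,
    catalog: ActivityCatalog | None = None,
    seed: int = 0,
    u_sigma: float = 0.3,
    **kwargs,
) -> RespondentProfile:
    """Build a profile whose realized theta equals the requested value.

    Per-activity utilities are ``+/- theta/2`` plus Gaussian scatter of SD
    ``u_sigma``, then each category is recentred so the category means are
    exactly ``+theta/2`` (sedentary) and ``-theta/2`` (physical).
    """
    if catalog is None:
        catalog = build_default_catalog()
    rng = np.random.default_rng(seed)
    utilities: dict[str, float] = {}
    for cat, center in ((Category.SEDENTARY, theta / 2), (Category.PHYSICAL, -theta / 2)):
        ids = catalog.ids(cat)
        u = center + rng.normal(0.0, u_sigma, size=len(ids))
        u = u - u.mean() + center
        utilities.update(zip(ids, u.tolist()))
    return RespondentProfile(catalog=catalog, utilities=utilities, **kwargs)


def _p_left(beta: float, du: float) -> float:
    if math.isinf(beta):
        return 0.5 if du == 0 else (1.0 if du > 0 else 0.0)
    return 1.0 / (1.0 + math.exp(-beta * du))


def simulate_respondent(
    profile: RespondentProfile,
    schedule: TrialSchedule,
    seed: int = 0,
) -> tuple[list[TrialResponse], list[VASResponse]]:
    """Simulate one run of the task: trial log plus VAS ratings.

    Per trial, the left option is chosen with probability
    ``logistic(beta * (u_left - u_right))`` and the reaction time is
    ``rt_base * exp(-rt_slope * |u_left - u_right|)`` times lognormal
    noise.  VAS liking and wanting are clipped affine maps of utility
    with independent rating noise.  Same profile, schedule and seed give
    identical output.
    """
    rng = np.random.default_rng(seed)
    u = profile.utilities
    trials: list[TrialResponse] = []
    for pair in schedule.trials:
        if pair.left not in u or pair.right not in u:
            raise ValueError(f"no utility for a member of pair {pair.pair_id}")
        if profile.p_nonresponse and rng.random() < profile.p_nonresponse:
            trials.append(TrialResponse(pair.pair_id, None, None, responded=False))
            continue
        du = u[pair.left] - u[pair.right]
        chosen = pair.left if rng.random() < _p_left(profile.beta, du) else pair.right
        rt = profile.rt_base * math.exp(-profile.rt_slope * abs(du))
        if profile.rt_sigma > 0:
            rt *= math.exp(rng.normal(0.0, profile.rt_sigma))
        trials.append(TrialResponse(pair.pair_id, chosen, rt))

    vas: list[VASResponse] = []
    for act in profile.catalog:
        base = profile.vas_intercept + profile.vas_gain * u[act.id]
        liking = float(np.clip(base + rng.normal(0, profile.vas_noise), 0, 100))
        wanting = float(np.clip(base + rng.normal(0, profile.vas_noise), 0, 100))
        vas.append(VASResponse(act.id, liking, wanting))
    return trials, vas


@dataclass(frozen=True)
class VariableSpec:
    """Marginal mean/SD and factor loading of one cohort variable.

    ``loading`` is the target Pearson correlation with the bias score;
    ``loading_girls`` overrides it for girls when the association is
    sex-specific.  ``observed_fraction`` < 1 marks a random subset of the
    cohort as missing, mimicking measurement-inclusion criteria.
    """

    mean: float
    sd: float
    loading: float
    loading_girls: float | None = None
    observed_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        for l in (self.loading, self.loading_girls):
            if l is not None and not -1.0 <= l <= 1.0:
                raise ValueError(f"loading {l} outside [-1, 1]")
        if not 0.0 < self.observed_fraction <= 1.0:
            raise ValueError("observed_fraction must be in (0, 1]")


def default_variables() -> dict[str, VariableSpec]:
    """Study-condition defaults for the synthetic cohort.

    Marginals and bias-score correlations follow the validation study's
    descriptives: bias 18.8 (46.2); free-play sedentary 57% (36), r=0.38;
    daily sedentary 151 (49) min and MVPA 45 (17) min from accelerometry
    (MVPA r=-0.41 in girls only, measured in 52/60 children); VO2peak
    40.5 (8.1) mL/kg FFM/min, r=-0.52, attained by 30/60; BMI z 0.69
    (1.24), r=0.35; %body fat 31.5 (9.0), r=0.43; FMI r=0.44 with an
    assumed marginal of 7.0 (3.5) kg/m^2.  The retest bias score shares
    the Time-1 marginal with a test-retest correlation of 0.59.
    """
    return {
        "bias": VariableSpec(18.8, 46.2, 1.0),
        "bias_retest": VariableSpec(18.8, 46.2, 0.59),
        "freeplay_sed_pct": VariableSpec(57.0, 36.0, 0.38),
        "daily_sed_min": VariableSpec(151.0, 49.0, 0.0, observed_fraction=52 / 60),
        "daily_mvpa_min": VariableSpec(
            45.0, 17.0, 0.0, loading_girls=-0.41, observed_fraction=52 / 60
        ),
        "vo2peak_ffm": VariableSpec(40.5, 8.1, -0.52, observed_fraction=30 / 60),
        "bmi_z": VariableSpec(0.69, 1.24, 0.35),
        "pct_body_fat": VariableSpec(31.5, 9.0, 0.43),
        "fmi": VariableSpec(7.0, 3.5, 0.44),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic validation cohort.

    By default variables are generated from the single-factor model with
    the loadings in :func:`default_variables`.  Supplying
    ``correlation_matrix`` (over ``variables`` order, symmetric, unit
    diagonal, positive semidefinite) switches to a direct multivariate
    normal draw; sex-specific loadings are a factor-model feature only.
    """

    n: int = 60
    variables: Mapping[str, VariableSpec] = field(default_factory=default_variables)
    correlation_matrix: np.ndarray | None = None
    female_fraction: float = 0.5
    white_fraction: float = 25 / 60
    age_range: tuple[int, int] = (8, 17)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        if self.correlation_matrix is not None:
            m = np.asarray(self.correlation_matrix, dtype=float)
            k = len(self.variables)
            if m.shape != (k, k):
                raise ValueError(f"correlation matrix must be {k}x{k}")
            if not np.allclose(m, m.T):
                raise ValueError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")
            w = np.linalg.eigvalsh(m)
            if w.min() < -1e-10:
                raise ValueError(
                    f"correlation matrix is not positive semidefinite "
                    f"(smallest eigenvalue {w.min():.6g})"
                )
            object.__setattr__(self, "correlation_matrix", m)


def _psd_factor(m: np.ndarray) -> np.ndarray:
    # Cholesky-like factor tolerant of semidefinite matrices
    w, v = np.linalg.eigh(m)
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort table.

    Returns a DataFrame with ``participant_id``, ``age``, ``sex``
    ('F'/'M'), ``race_group`` ('white'/'minority') and one column per
    variable in the spec, with NaN where a measure is unobserved.  The
    empirical correlation matrix converges to the spec's target as the
    cohort grows.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n
    n_girls = round(n * spec.female_fraction)
    sex = np.array(["F"] * n_girls + ["M"] * (n - n_girls))
    rng.shuffle(sex)
    girls = sex == "F"
    age = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n)
    race = np.where(rng.random(n) < spec.white_fraction, "white", "minority")

    data: dict[str, np.ndarray] = {}
    names = list(spec.variables)
    if spec.correlation_matrix is not None:
        z = rng.standard_normal((n, len(names))) @ _psd_factor(
            spec.correlation_matrix
        ).T
        for j, name in enumerate(names):
            v = spec.variables[name]
            data[name] = v.mean + v.sd * z[:, j]
    else:
        factor = rng.standard_normal(n)  # standardized bias score
        for name in names:
            v = spec.variables[name]
            load = np.full(n, v.loading)
            if v.loading_girls is not None:
                load[girls] = v.loading_girls
            noise = rng.standard_normal(n)
            latent = load * factor + np.sqrt(1.0 - load**2) * noise
            data[name] = v.mean + v.sd * latent

    for name in names:
        frac = spec.variables[name].observed_fraction
        if frac < 1.0:
            n_miss = n - round(n * frac)
            idx = rng.choice(n, size=n_miss, replace=False)
            data[name][idx] = np.nan

    table = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "race_group": race,
            **data,
        }
    )
    return table
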
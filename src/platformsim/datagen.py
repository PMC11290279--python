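"""Synthetic outcome data for the two-stage platform trial.

Mechanism
---------
Stage-one outcomes are multivariate normal with mean
``(mu_01, mu_A1, mu_B1)`` replicated over subjects and covariance
``sigma^2 I + sigma_c^2 11'``; stage-two outcomes have mean
``(mu_02, mu_A2, mu_B2, mu_C2) + tau`` and covariance
``(sigma^2 + sigma_e^2) I + sigma_c^2 11'``.  The rank-one term is a
random cohort effect shared by every subject of a stage; ``tau`` is a
fixed cohort effect (a step time trend) added to all stage-two arms,
including the control and the added arm; ``sigma_e^2`` is extra
stage-two residual variance (heteroscedasticity).

The default sampler draws one shared normal deviate per stage plus
independent residuals, which is distributionally identical to the full
multivariate normal above; ``method="mvn"`` draws from the literal joint
normal instead and exists for equivalence checks.  A variant that shares
the random effect per randomization cohort rather than per stage is
available as ``cohort_effect="cohort"`` but is not the default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import CONTROL, DesignError, TrialDesign, build_design

#: columns of the tidy subject-level dataset
DATASET_COLUMNS = ("subject_id", "stage", "cohort", "arm", "y")

#: stage-wise mean vectors of the effect scenarios (arm -> mean); entries
#: not listed are zero
MEAN_SCENARIOS: dict[str, dict[str, dict[str, float]]] = {
    "S0": {"stage1": {}, "stage2": {}},
    "SC.m": {"stage1": {}, "stage2": {"0": 0.2}},
    "SC.b": {"stage1": {}, "stage2": {"0": 0.7}},
    "SA.m": {"stage1": {}, "stage2": {"A": 0.2}},
    "SA.b": {"stage1": {}, "stage2": {"A": 0.7}},
}

#: variance scenarios 1-4 as (sigma_c, sigma_e)
VARIANCE_SCENARIOS: dict[int, tuple[float, float]] = {
    1: (0.0, 0.0),
    2: (0.38, 0.0),
    3: (0.0, 0.38),
    4: (0.38, 0.38),
}

TAUS: tuple[float, float] = (0.0, -0.5)


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """Data-generating parameters for one simulation cell.

    ``mu_stage1`` holds the stage-one means of arms 0, A, B and
    ``mu_stage2`` the stage-two means of arms 0, A, B, C, before the
    fixed cohort effect ``tau`` is added to stage two.  ``sigma2`` is the
    residual variance (1 throughout the study), ``sigma_c`` the SD of the
    shared random cohort effect and ``sigma_e`` the SD of the extra
    stage-two residual component (variances add).
    """

    label: str
    mu_stage1: dict[str, float] = field(default_factory=dict)
    mu_stage2: dict[str, float] = field(default_factory=dict)
    tau: float = 0.0
    sigma2: float = 1.0
    sigma_c: float = 0.0
    sigma_e: float = 0.0

    def __post_init__(self):
        if self.sigma2 <= 0 or self.sigma_c < 0 or self.sigma_e < 0:
            raise ScenarioError("variance components must be non-negative, sigma2 > 0")

    def mean(self, arm: str, stage: int) -> float:
        """Marginal mean of arm ``arm`` in stage ``stage`` (tau included)."""
        if stage == 1:
            return self.mu_stage1.get(arm, 0.0)
        return self.mu_stage2.get(arm, 0.0) + self.tau

    def stage_variance(self, stage: int) -> float:
        """Marginal outcome variance in stage ``stage`` (cohort effect included)."""
        extra = self.sigma_e**2 if stage == 2 else 0.0
        return self.sigma2 + extra + self.sigma_c**2


def make_scenario(
    label: str,
    variance_scenario: int = 1,
    tau: float = 0.0,
    sigma2: float = 1.0,
) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from the catalogue labels.

    ``label`` is one of S0, SC.m, SC.b, SA.m, SA.b; ``variance_scenario``
    indexes {sigma_c, sigma_e} = (0,0), (0.38,0), (0,0.38), (0.38,0.38).
    """
    if label not in MEAN_SCENARIOS:
        raise ScenarioError(
            f"unknown effect scenario {label!r}; expected one of {sorted(MEAN_SCENARIOS)}"
        )
    if variance_scenario not in VARIANCE_SCENARIOS:
        raise ScenarioError(f"unknown variance scenario {variance_scenario!r}")
    sigma_c, sigma_e = VARIANCE_SCENARIOS[variance_scenario]
    means = MEAN_SCENARIOS[label]
    return ScenarioSpec(
        label=label,
        mu_stage1=dict(means["stage1"]),
        mu_stage2=dict(means["stage2"]),
        tau=tau,
        sigma2=sigma2,
        sigma_c=sigma_c,
        sigma_e=sigma_e,
    )


def scenario_catalog() -> list[tuple[str, ScenarioSpec, int]]:
    """The full study grid as ``(setting_id, scenario, variance_scenario)``.

    All five effect scenarios are crossed with the four variance
    scenarios and tau in {0, -0.5} under setting one (arm C added at the
    midpoint); scenario SA.b is additionally run under settings two and
    three.
    """
    cells: list[tuple[str, ScenarioSpec, int]] = []
    for label, vs, tau in itertools.product(MEAN_SCENARIOS, VARIANCE_SCENARIOS, TAUS):
        cells.append(("50pct", make_scenario(label, vs, tau), vs))
    for setting, vs, tau in itertools.product(
        ("25pct", "75pct"), VARIANCE_SCENARIOS, TAUS
    ):
        cells.append((setting, make_scenario("SA.b", vs, tau), vs))
    return cells


def two_step_randomize(
    design: TrialDesign, stage: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Randomize one stage's subjects to (cohort, arm) by simple randomization.

    Subjects are first assigned a cohort with probabilities proportional
    to the stage's step-one weights, then the intervention or control
    arm within the cohort with probabilities proportional to the
    step-two weights.  Stage totals are fixed at the sum of the step-one
    weights; realized arm counts are random with expectations equal to
    the planned stage-wise sizes.
    """
    if stage not in design.step1_ratios:
        raise DesignError(f"stage must be 1 or 2, got {stage}")
    weights = design.step1_ratios[stage]
    if stage == 1 and weights.get("C", 0) > 0:
        raise DesignError("cohort C cannot recruit in stage 1")
    cohorts = np.array([c for c, w in weights.items() if w > 0])
    w1 = np.array([weights[str(c)] for c in cohorts], dtype=float)
    n_total = int(w1.sum())
    idx = rng.choice(len(cohorts), size=n_total, p=w1 / w1.sum())
    cohort = cohorts[idx]
    arm = np.empty(n_total, dtype=object)
    u = rng.random(n_total)
    for ci, c in enumerate(cohorts):
        wi, wc = design.step2_ratios[(stage, c)]
        mask = idx == ci
        arm[mask] = np.where(u[mask] < wi / (wi + wc), c, CONTROL)
    return cohort, arm


def simulate_trial(
    design: TrialDesign,
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    method: str = "additive",
    cohort_effect: str = "stage",
) -> pd.DataFrame:
    """Simulate one platform-trial dataset.

    Returns a tidy frame with columns ``subject_id`` (1-based enrolment
    index), ``stage``, ``cohort``, ``arm`` and outcome ``y``.

    ``method="additive"`` (default) draws the shared cohort effect and
    independent residuals separately; ``method="mvn"`` samples the
    literal joint multivariate normal of each stage.  The two are
    distributionally identical.  ``cohort_effect="cohort"`` shares the
    random effect per randomization cohort within a stage instead of per
    stage (a non-default variant interpretation).
    """
    if method not in ("additive", "mvn"):
        raise ValueError(f"unknown sampling method {method!r}")
    if cohort_effect not in ("stage", "cohort"):
        raise ValueError(f"unknown cohort_effect mode {cohort_effect!r}")
    parts: dict[str, list[np.ndarray]] = {c: [] for c in DATASET_COLUMNS}
    next_id = 1
    for stage in (1, 2):
        cohort, arm = two_step_randomize(design, stage, rng)
        n = len(arm)
        mu = np.zeros(n)
        for a in dict.fromkeys(arm):
            mu[arm == a] = scenario.mean(a, stage)
        resid_var = scenario.sigma2 + (scenario.sigma_e**2 if stage == 2 else 0.0)
        if method == "mvn":
            cov = resid_var * np.eye(n) + scenario.sigma_c**2 * np.ones((n, n))
            y = rng.multivariate_normal(mu, cov, method="cholesky")
        else:
            eps = rng.normal(0.0, resid_var**0.5, size=n)
            if cohort_effect == "stage":
                shared = rng.normal(0.0, scenario.sigma_c)
                y = mu + shared + eps
            else:
                y = mu + eps
                for c in np.unique(cohort):
                    y[cohort == c] += rng.normal(0.0, scenario.sigma_c)
        parts["subject_id"].append(np.arange(next_id, next_id + n))
        parts["stage"].append(np.full(n, stage))
        parts["cohort"].append(cohort.astype(str))
        parts["arm"].append(arm.astype(str))
        parts["y"].append(y)
        next_id += n
    return pd.DataFrame(
        {col: np.concatenate(chunks) for col, chunks in parts.items()}
    )


def write_dataset(dataset: pd.DataFrame, path) -> None:
    dataset.to_csv(path, index=False, columns=list(DATASET_COLUMNS))


def read_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"arm": str, "cohort": str})
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dataset file is missing columns {sorted(missing)}")
    return df


def with_tau(scenario: ScenarioSpec, tau: float) -> ScenarioSpec:
    """Copy of ``scenario`` with a different fixed cohort effect."""
    return replace(scenario, tau=tau)
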
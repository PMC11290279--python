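"""Structural designs for a two-stage platform trial that adds one arm.

The trial starts with a control arm (``"0"``) and two intervention arms
(``"A"``, ``"B"``).  A third intervention arm ``"C"`` opens at the start of
stage two, after 25%, 50% or 75% of the per-arm recruitment target of the
initial arms has been reached.  Every arm recruits 120 subjects in total;
arm C recruits all of them in stage two.

Randomization is a two-step procedure: subjects are first randomized to a
cohort (one intervention arm plus the control arm), then within the cohort
to the intervention or the control treatment.  The step ratios are stored
as the printed integers; probabilities are obtained by normalization at
use time.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

from scipy import stats

ARMS: tuple[str, ...] = ("0", "A", "B", "C")
CONTROL = "0"
COMPARISONS: tuple[str, ...] = ("A", "B", "C")


class DesignError(ValueError):
    """Raised for unknown settings or structurally invalid designs."""


#: canonical setting ids keyed by the aliases accepted in configuration
SETTING_ALIASES: Mapping[str, str] = MappingProxyType(
    {
        "one": "50pct",
        "two": "25pct",
        "three": "75pct",
        "50pct": "50pct",
        "25pct": "25pct",
        "75pct": "75pct",
        "0.5": "50pct",
        "0.25": "25pct",
        "0.75": "75pct",
    }
)


@dataclass(frozen=True)
class TrialDesign:
    """Stage-wise sample sizes and two-step randomization ratios.

    Attributes
    ----------
    setting_id:
        Canonical id: ``"25pct"``, ``"50pct"`` or ``"75pct"`` -- the
        fraction of initial-arm recruitment completed when arm C opens.
    stage_sizes:
        Planned subject counts ``n_jk`` keyed by ``(arm, stage)``.
    step1_ratios:
        Per stage, cohort label -> integer weight for the first
        randomization step (cohorts A, B in stage 1; A, B, C in stage 2).
    step2_ratios:
        Per ``(stage, cohort)``, the ``(intervention, control)`` integer
        weight pair for the second step.
    """

    setting_id: str
    stage_sizes: Mapping[tuple[str, int], int]
    step1_ratios: Mapping[int, Mapping[str, int]]
    step2_ratios: Mapping[tuple[int, str], tuple[int, int]]

    @property
    def stage_totals(self) -> dict[int, int]:
        """Total number of subjects recruited in each stage, N_k."""
        return {k: sum(w.values()) for k, w in self.step1_ratios.items()}

    @property
    def per_arm_totals(self) -> dict[str, int]:
        """Planned total sample size per arm, n_j = n_j1 + n_j2."""
        return {
            j: sum(n for (arm, _), n in self.stage_sizes.items() if arm == j)
            for j in ARMS
        }

    def planned_weights(self, arm: str) -> dict[int, float]:
        """Planned stage weights w_jk = n_jk / n_j for one arm."""
        n_j = self.per_arm_totals[arm]
        return {k: self.stage_sizes.get((arm, k), 0) / n_j for k in (1, 2)}

    def validate(self) -> None:
        for (stage, cohort), (wi, wc) in self.step2_ratios.items():
            if wi + wc != self.step1_ratios[stage][cohort]:
                raise DesignError(
                    f"step-2 weights {wi}+{wc} for stage {stage} cohort "
                    f"{cohort} do not sum to the step-1 weight"
                )
        if self.stage_sizes.get(("C", 1), 0) != 0:
            raise DesignError("arm C must not recruit in stage 1")


def _sizes(n1: int, n2: int) -> dict[tuple[str, int], int]:
    return {
        ("0", 1): n1, ("A", 1): n1, ("B", 1): n1, ("C", 1): 0,
        ("0", 2): n2, ("A", 2): n2, ("B", 2): n2, ("C", 2): 120,
    }


_SETTINGS: dict[str, TrialDesign] = {
    "50pct": TrialDesign(
        setting_id="50pct",
        stage_sizes=_sizes(60, 60),
        step1_ratios={1: {"A": 90, "B": 90}, 2: {"A": 80, "B": 80, "C": 140}},
        step2_ratios={
            (1, "A"): (60, 30), (1, "B"): (60, 30),
            (2, "A"): (60, 20), (2, "B"): (60, 20), (2, "C"): (120, 20),
        },
    ),
    "25pct": TrialDesign(
        setting_id="25pct",
        stage_sizes=_sizes(30, 90),
        step1_ratios={1: {"A": 45, "B": 45}, 2: {"A": 120, "B": 120, "C": 150}},
        step2_ratios={
            (1, "A"): (30, 15), (1, "B"): (30, 15),
            (2, "A"): (90, 30), (2, "B"): (90, 30), (2, "C"): (120, 30),
        },
    ),
    "75pct": TrialDesign(
        setting_id="75pct",
        stage_sizes=_sizes(90, 30),
        step1_ratios={1: {"A": 135, "B": 135}, 2: {"A": 40, "B": 40, "C": 130}},
        step2_ratios={
            (1, "A"): (90, 45), (1, "B"): (90, 45),
            (2, "A"): (30, 10), (2, "B"): (30, 10), (2, "C"): (120, 10),
        },
    ),
}


def build_design(setting_id: str) -> TrialDesign:
    """Return the trial design for one of the three timing settings.

    Parameters
    ----------
    setting_id:
        ``"25pct"``, ``"50pct"``, ``"75pct"`` or one of the aliases
        ``"one"``/``"two"``/``"three"`` (setting one adds arm C at the
        midpoint) or the timing fractions ``"0.25"``/``"0.5"``/``"0.75"``.
    """
    key = SETTING_ALIASES.get(str(setting_id).lower())
    if key is None:
        raise DesignError(
            f"unknown design setting {setting_id!r}; "
            f"expected one of {sorted(set(SETTING_ALIASES))}"
        )
    design = _SETTINGS[key]
    design.validate()
    return design


def analytic_power(
    n_per_arm: int,
    effect_size: float,
    alpha: float = 0.05,
    one_sided: bool = True,
) -> float:
    """Power of a two-sample t-test with equal per-arm n and unit SD.

    Uses the exact noncentral-t formulation: with per-arm sample size n
    and standardized effect delta, the t statistic has a noncentral t
    distribution with 2n - 2 degrees of freedom and noncentrality
    delta * sqrt(n / 2).

    The design's headline calculation: 120 subjects per arm give 90%
    power to detect an effect of 0.38 at one-sided alpha = 5%.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_per_arm < 2:
        raise ValueError(f"need at least 2 subjects per arm, got {n_per_arm}")
    df = 2 * n_per_arm - 2
    ncp = effect_size * (n_per_arm / 2.0) ** 0.5
    crit = stats.t.ppf(1 - (alpha if one_sided else alpha / 2), df)
    power = stats.nct.sf(crit, df, ncp)
    if not one_sided:
        power += stats.nct.cdf(-crit, df, ncp)
    return float(power)
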
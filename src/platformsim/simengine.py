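"""Replication loop, performance measures, configuration and CSV reporting.

Each simulation cell (design setting x effect scenario x variance
scenario x fixed cohort effect) is replicated independently:
re-randomize, re-simulate, run the configured testing strategies and
estimation models.  Replication r of a run with master seed s uses the
generator spawned from ``SeedSequence(s, spawn_key=(r,))``, so any
single replication can be re-materialized from (seed, index) alone and
results do not depend on execution order.

Summaries are the study's performance measures: per-hypothesis rejection
probabilities (type-I error under null scenarios) and the
reject-at-least-one rate (FWER) for the multiplicity-controlling
strategies, with binomial Monte-Carlo standard errors; and per
(model, comparison) estimate distributions (mean, median, quartiles)
plus the root mean squared error against a configured truth.

The default truth is the stage-weighted treatment effect
``sum_k w_jk (mu_jk - mu_0k)`` with the intervention arm's planned stage
weights, under which the fixed cohort effect cancels within each stage;
for the added arm C this reduces to the stage-two contrast
``mu_C2 - mu_02``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .datagen import (
    ScenarioSpec,
    make_scenario,
    simulate_trial,
)
from .design import COMPARISONS, TrialDesign, build_design
from .estimation import MODELS, EstimationError, fit_model
from .testing import (
    ALL_STRATEGIES,
    CellStats,
    DegenerateDataError,
    EmptyCellError,
    run_all_strategies,
)

#: strategies that report the FWER (reject at least one hypothesis)
FWER_STRATEGIES = frozenset(
    {
        "Bonferroni",
        "Bonferroni-nc",
        "Dunnett.closed",
        "Dunnett.closed-nc",
        "Combination.closed",
    }
)


@dataclass
class SimulationConfig:
    """Configuration of a simulation run (mirrors the YAML config keys)."""

    setting: str = "one"
    scenarios: list[str] = field(default_factory=lambda: ["S0"])
    variance_scenarios: list[int] = field(default_factory=lambda: [1, 2, 3, 4])
    taus: list[float] = field(default_factory=lambda: [0.0, -0.5])
    n_reps: int = 5000
    alpha: float = 0.05
    seed: int = 20240730
    strategies: list[str] = field(default_factory=lambda: list(ALL_STRATEGIES))
    models: list[str] = field(default_factory=lambda: list(MODELS))
    out: str = "results"

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "strategies" in raw and raw["strategies"] in ("all", None):
        raw["strategies"] = list(ALL_STRATEGIES)
    if "models" in raw and raw["models"] in ("all", None):
        raw["models"] = list(MODELS)
    return SimulationConfig(**raw)


def replication_rng(master_seed: int, rep: int) -> np.random.Generator:
    """Independent, order-insensitive substream for one replication."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(rep,)))


def stage_weighted_truth(design: TrialDesign, scenario: ScenarioSpec) -> dict[str, float]:
    """True treatment effects weighted by the intervention arm's planned stage weights.

    truth_j = sum_k w_jk (mu_jk - mu_0k); the fixed cohort effect cancels
    within each stage, and w_C = (0, 1) gives mu_C2 - mu_02 for arm C.
    """
    truth = {}
    for j in COMPARISONS:
        w = design.planned_weights(j)
        truth[j] = sum(
            w[k] * (scenario.mean(j, k) - scenario.mean("0", k))
            for k in (1, 2)
            if w[k] > 0
        )
    return truth


def mc_band(nominal: float, n_reps: int, level: float = 0.95) -> tuple[float, float]:
    """Binomial Monte-Carlo band around a nominal rejection rate."""
    if not 0 < nominal < 1:
        raise ValueError("nominal rate must be in (0, 1)")
    z = stats.norm.ppf((1 + level) / 2)
    half = z * np.sqrt(nominal * (1 - nominal) / n_reps)
    return nominal - half, nominal + half


def run_replications(
    design: TrialDesign,
    scenario: ScenarioSpec,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    strategies: Iterable[str] | None = None,
    models: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate ``n_reps`` trials and analyse each.

    Returns ``(decisions, estimates, failures)``: tidy per-replication
    frames plus a count of replications excluded per analysis because of
    degenerate data (empty cells); failed replications are recorded, not
    silently regenerated.
    """
    strategies = list(ALL_STRATEGIES if strategies is None else strategies)
    models = list(MODELS if models is None else models)
    dec_rows, est_rows = [], []
    failures: dict[str, int] = {}
    for rep in range(n_reps):
        rng = replication_rng(seed, rep)
        data = simulate_trial(design, scenario, rng)
        cells = CellStats.from_dataset(data)
        if strategies:
            try:
                results = run_all_strategies(cells, alpha, strategies)
            except (EmptyCellError, DegenerateDataError):
                failures["testing"] = failures.get("testing", 0) + 1
            else:
                for name, ds in results.items():
                    for hyp, rej in ds.reject.items():
                        dec_rows.append(
                            (rep, name, hyp, ds.p_values.get(hyp, np.nan), rej)
                        )
        for model_id in models:
            try:
                est = fit_model(data, model_id)
            except EstimationError:
                failures[model_id] = failures.get(model_id, 0) + 1
                continue
            for j in COMPARISONS:
                est_rows.append((rep, model_id, j, est.theta[j], est.se[j]))
    decisions = pd.DataFrame(
        dec_rows, columns=["rep", "strategy", "hypothesis", "p", "reject"]
    )
    estimates = pd.DataFrame(
        est_rows, columns=["rep", "model", "comparison", "theta_hat", "se"]
    )
    return decisions, estimates, failures


def summarize_rejections(decisions: pd.DataFrame) -> pd.DataFrame:
    """Rejection rates with binomial MC standard errors.

    Per-hypothesis rows for every strategy, plus an ``"any"`` row (the
    FWER) for the multiplicity-controlling strategies.
    """
    if decisions.empty:
        raise ValueError("no successful replications to summarize")
    rows = []

    def add(strategy, hypothesis, flags):
        rate = float(np.mean(flags))
        n = len(flags)
        rows.append(
            {
                "strategy": strategy,
                "hypothesis": hypothesis,
                "rate": rate,
                "mc_se": float(np.sqrt(rate * (1 - rate) / n)),
                "n_effective": n,
            }
        )

    for strategy, grp in decisions.groupby("strategy", sort=False):
        for hyp, sub in grp.groupby("hypothesis", sort=True):
            add(strategy, hyp, sub["reject"].to_numpy())
        if strategy in FWER_STRATEGIES:
            any_flags = grp.groupby("rep")["reject"].any().to_numpy()
            add(strategy, "any", any_flags)
    return pd.DataFrame(rows)


def summarize_estimates(
    estimates: pd.DataFrame, truth: Mapping[str, float]
) -> pd.DataFrame:
    """Mean/median/quartiles and rMSE of the estimates per (model, comparison)."""
    if estimates.empty:
        raise ValueError("no successful replications to summarize")
    rows = []
    for (model, comp), grp in estimates.groupby(["model", "comparison"], sort=False):
        th = grp["theta_hat"].to_numpy(dtype=float)
        t0 = float(truth[comp])
        rows.append(
            {
                "model": model,
                "comparison": comp,
                "truth": t0,
                "mean": float(th.mean()),
                "median": float(np.median(th)),
                "q1": float(np.quantile(th, 0.25)),
                "q3": float(np.quantile(th, 0.75)),
                "rmse": float(np.sqrt(np.mean((th - t0) ** 2))),
                "n_effective": len(th),
            }
        )
    return pd.DataFrame(rows)


def run_grid(config: SimulationConfig) -> dict[str, Path]:
    """Run every cell of the configured grid and write tidy CSV outputs.

    Writes ``rejections.csv``, ``estimates.csv`` (per replication),
    ``estimate_summary.csv`` and a ``manifest.json`` recording the
    configuration and software version.
    """
    design = build_design(config.setting)
    out_dir = Path(config.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    rej_parts, est_parts, summ_parts = [], [], []
    all_failures = {}
    for label in config.scenarios:
        for vs in config.variance_scenarios:
            for tau in config.taus:
                scenario = make_scenario(label, vs, tau)
                decisions, estimates, failures = run_replications(
                    design,
                    scenario,
                    config.n_reps,
                    config.seed,
                    config.alpha,
                    config.strategies,
                    config.models,
                )
                meta = {
                    "setting": design.setting_id,
                    "effect_scenario": label,
                    "variance_scenario": vs,
                    "tau": tau,
                }
                if failures:
                    all_failures[str(meta)] = failures
                if not decisions.empty:
                    rej = summarize_rejections(decisions)
                    rej_parts.append(rej.assign(**meta))
                if not estimates.empty:
                    est_parts.append(estimates.assign(**meta))
                    truth = stage_weighted_truth(design, scenario)
                    summ_parts.append(
                        summarize_estimates(estimates, truth).assign(**meta)
                    )
    paths = {}
    meta_cols = ["setting", "effect_scenario", "variance_scenario", "tau"]
    if rej_parts:
        rej = pd.concat(rej_parts, ignore_index=True)
        paths["rejections"] = out_dir / "rejections.csv"
        rej[meta_cols + ["strategy", "hypothesis", "rate", "mc_se", "n_effective"]].to_csv(
            paths["rejections"], index=False
        )
    if est_parts:
        est = pd.concat(est_parts, ignore_index=True)
        paths["estimates"] = out_dir / "estimates.csv"
        est[meta_cols + ["model", "comparison", "rep", "theta_hat", "se"]].to_csv(
            paths["estimates"], index=False
        )
        summ = pd.concat(summ_parts, ignore_index=True)
        paths["estimate_summary"] = out_dir / "estimate_summary.csv"
        summ.to_csv(paths["estimate_summary"], index=False)
    manifest = {
        "config": asdict(config),
        "version": __version__,
        "failures": all_failures,
    }
    paths["manifest"] = out_dir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
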
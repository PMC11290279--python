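"""Estimation strategies: four OLS regressions and the pairwise trials analysis.

The regression models share the arm-indicator parametrization
``E(y) = b0 + theta_A I(j=A) + theta_B I(j=B) + theta_C I(j=C)`` and add,
in turn, a stage effect (``M.stage``), a stage-by-A interaction
(``M.stageXA``) and a stage-by-B interaction (``M.stageXAXB``).  The
coefficient theta_j is the quantity of interest for research comparison
j throughout.

The pairwise trials analysis (``M.new``) duplicates the shared control
data once per research comparison (two copies of stage-one controls,
three of stage-two controls), labels every record with its comparison
block Z in {A0, B0, C0}, fits one OLS model with comparison fixed
effects, and computes standard errors with a cluster-robust sandwich
estimator clustered on the original subject id to account for the
duplication.  Its theta_A and theta_B equal the stage-weighted mean
difference ``sum_k w_jk Xbar_jk - sum_k w_0k Xbar_0k`` with realized
weights ``w_jk = n_jk / n_j``, and its theta_C equals the concurrent
contrast ``Xbar_C2 - Xbar_02`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import COMPARISONS, CONTROL

MODELS: tuple[str, ...] = ("M0", "M.stage", "M.stageXA", "M.stageXAXB", "M.new")


class EstimationError(ValueError):
    """Raised when a model cannot be fitted (e.g. an empty design cell)."""


@dataclass
class EstimateResult:
    model_id: str
    theta: dict[str, float]
    se: dict[str, float]
    aux: dict[str, float] = field(default_factory=dict)
    df_resid: float = float("nan")
    vcov_theta: np.ndarray | None = None  # covariance of (theta_A, theta_B, theta_C)


def arm_stage_summary(dataset: pd.DataFrame) -> pd.DataFrame:
    """Realized per (arm, stage) counts, means and stage weights w_jk = n_jk/n_j."""
    g = dataset.groupby(["arm", "stage"])["y"].agg(n="size", mean="mean").reset_index()
    totals = g.groupby("arm")["n"].transform("sum")
    g["w"] = g["n"] / totals
    return g


def weighted_mean_diff_oracle(dataset: pd.DataFrame, comparison: str) -> float:
    """Stage-weighted mean difference, the closed form for M0 / M.new estimates.

    ``sum_k w_jk Xbar_jk - sum_k w_0k Xbar_0k`` with realized counts.
    """
    summ = arm_stage_summary(dataset).set_index(["arm", "stage"])
    for needed in (comparison, CONTROL):
        if needed not in summ.index.get_level_values("arm"):
            raise EstimationError(f"arm {needed!r} has no observations")

    def wmean(arm: str) -> float:
        rows = summ.loc[arm]
        return float((rows["w"] * rows["mean"]).sum())

    return wmean(comparison) - wmean(CONTROL)


def _indicator_matrix(dataset: pd.DataFrame, model_id: str) -> tuple[np.ndarray, list[str]]:
    arm = dataset["arm"].to_numpy()
    stage2 = (dataset["stage"].to_numpy() == 2).astype(float)
    cols = [np.ones(len(dataset))]
    names = ["beta0"]
    for j in COMPARISONS:
        cols.append((arm == j).astype(float))
        names.append(f"theta_{j}")
    if model_id in ("M.stage", "M.stageXA", "M.stageXAXB"):
        cols.append(stage2)
        names.append("tau")
    if model_id in ("M.stageXA", "M.stageXAXB"):
        cols.append((arm == "A").astype(float) * stage2)
        names.append("eta_A")
    if model_id == "M.stageXAXB":
        cols.append((arm == "B").astype(float) * stage2)
        names.append("eta_B")
    return np.column_stack(cols), names


def _check_cells(dataset: pd.DataFrame, model_id: str) -> None:
    counts = dataset.groupby(["arm", "stage"]).size()
    required = [(j, None) for j in ("0", "A", "B", "C")]
    missing = [j for j, _ in required if counts.get(j, pd.Series(dtype=int)).sum() == 0]
    if model_id != "M0":
        for cell in [("0", 1), ("0", 2), ("C", 2)]:
            if counts.get(cell, 0) == 0:
                missing.append(cell)
    if model_id in ("M.stageXA", "M.stageXAXB"):
        for cell in [("A", 1), ("A", 2)]:
            if counts.get(cell, 0) == 0:
                missing.append(cell)
    if model_id == "M.stageXAXB":
        for cell in [("B", 1), ("B", 2)]:
            if counts.get(cell, 0) == 0:
                missing.append(cell)
    if missing:
        raise EstimationError(f"empty design cells for {model_id}: {missing}")


def fit_regression(dataset: pd.DataFrame, model_id: str) -> EstimateResult:
    """OLS fit of M0, M.stage, M.stageXA or M.stageXAXB with conventional SEs."""
    if model_id not in ("M0", "M.stage", "M.stageXA", "M.stageXAXB"):
        raise ValueError(f"unknown regression model {model_id!r}")
    _check_cells(dataset, model_id)
    X, names = _indicator_matrix(dataset, model_id)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError(f"rank-deficient design matrix for {model_id}")
    res = sm.OLS(dataset["y"].to_numpy(dtype=float), X).fit()
    return _pack_result(model_id, res, names)


def _pack_result(model_id, res, names, vcov=None, df_resid=None) -> EstimateResult:
    params = dict(zip(names, res.params))
    if vcov is None:
        vcov = res.cov_params()
    vcov = np.asarray(vcov)
    # sandwich variances of deterministic contrasts (e.g. gamma_B0, which is
    # identically zero under full duplication) can round to tiny negatives
    bse = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    ses = dict(zip(names, bse))
    theta_ix = [names.index(f"theta_{j}") for j in COMPARISONS]
    return EstimateResult(
        model_id=model_id,
        theta={j: float(params[f"theta_{j}"]) for j in COMPARISONS},
        se={j: float(ses[f"theta_{j}"]) for j in COMPARISONS},
        aux={k: float(v) for k, v in params.items() if not k.startswith("theta_")},
        df_resid=float(res.df_resid if df_resid is None else df_resid),
        vcov_theta=vcov[np.ix_(theta_ix, theta_ix)],
    )


def build_pairwise_dataset(dataset: pd.DataFrame) -> pd.DataFrame:
    """Duplicate control data per research comparison and label the blocks.

    Stage-one control records appear twice (blocks A0 and B0), stage-two
    control records three times (A0, B0, C0); intervention records
    appear once in their own block.  ``subject_id`` is retained and
    serves as the clustering variable of the sandwich variance.
    """
    arm = dataset["arm"].to_numpy()
    stage = dataset["stage"].to_numpy()
    is_control = arm == CONTROL
    idx_parts, z_parts = [], []
    for j in COMPARISONS:
        ctrl = is_control if j != "C" else is_control & (stage == 2)
        block = np.flatnonzero((arm == j) | ctrl)
        idx_parts.append(block)
        z_parts.append(np.full(block.size, f"{j}0"))
    out = dataset.iloc[np.concatenate(idx_parts)].reset_index(drop=True)
    out["z"] = np.concatenate(z_parts)
    return out


def fit_pairwise(
    duplicated: pd.DataFrame,
    cov: str = "CR0",
    df_mode: str = "residual",
) -> EstimateResult:
    """Fit the pairwise trials analysis model to a duplicated dataset.

    OLS of y on arm indicators plus the comparison-block indicators
    I(Z=B0), I(Z=C0); cluster-robust sandwich covariance clustered on
    ``subject_id``.  ``cov`` selects the plain sandwich (``"CR0"``) or
    the small-sample-corrected flavour (``"CR1"``); ``df_mode`` selects
    residual degrees of freedom (default) or ``"cluster"`` for
    cluster-count-based df.
    """
    if cov not in ("CR0", "CR1"):
        raise ValueError(f"unknown sandwich flavour {cov!r}")
    arm = duplicated["arm"].to_numpy()
    z = duplicated["z"].to_numpy()
    for j in COMPARISONS:
        block = z == f"{j}0"
        if not np.any(block & (arm == j)) or not np.any(block & (arm == CONTROL)):
            raise EstimationError(f"comparison block {j}0 has an empty cell")
    X = np.column_stack(
        [
            np.ones(len(duplicated)),
            (arm == "A").astype(float),
            (arm == "B").astype(float),
            (arm == "C").astype(float),
            (z == "B0").astype(float),
            (z == "C0").astype(float),
        ]
    )
    names = ["beta0", "theta_A", "theta_B", "theta_C", "gamma_B0", "gamma_C0"]
    groups = pd.factorize(duplicated["subject_id"])[0]
    res = sm.OLS(duplicated["y"].to_numpy(dtype=float), X).fit(
        cov_type="cluster",
        cov_kwds={"groups": groups, "use_correction": cov == "CR1"},
    )
    df_resid = groups.max() if df_mode == "cluster" else len(duplicated) - X.shape[1]
    return _pack_result("M.new", res, names, vcov=res.cov_params(), df_resid=df_resid)


def fit_model(dataset: pd.DataFrame, model_id: str, **kwargs) -> EstimateResult:
    """Fit any of the five estimation strategies to an (unduplicated) dataset."""
    if model_id == "M.new":
        return fit_pairwise(build_pairwise_dataset(dataset), **kwargs)
    return fit_regression(dataset, model_id)
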
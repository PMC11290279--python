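"""Hypothesis-testing strategies for the two-stage platform trial.

All tests are one-sided with benefit equal to a positive intervention
minus control difference, and use pooled-variance t statistics under a
homoscedastic working model.  That working model is deliberately wrong
under the heteroscedastic and random-cohort-effect scenarios -- probing
that mis-specification is the point of the simulation study.

Strategies
----------
* per-comparison t-tests (``T-test A/B/C``) with concurrent control data
  and ``T-test C-nc`` pooling non-concurrent (stage-one) control data;
* Bonferroni: each elementary t-test at alpha/3 (``Bonferroni`` /
  ``Bonferroni-nc``);
* closed Dunnett testing over the intersection hypotheses of the three
  many-to-one comparisons (``Dunnett.closed`` / ``Dunnett.closed-nc``);
* a two-stage Fisher combination test with closed testing
  (``Combination.closed``), combining stage-wise Dunnett p-values.

Dunnett p-values are computed exactly (to quadrature accuracy) from the
joint multivariate-t distribution of the contrast statistics.  The
correlation matrix is derived from the contrast covariances; when
different comparisons use different (nested) control pools, the
covariance between two control means is ``sigma^2 / n`` with ``n`` the
larger pool (the pools share the smaller one entirely).  The resulting
correlation matrix has the product form ``R = ll' + diag(1 - l^2)``,
which admits a fast two-dimensional Gauss quadrature over the shared
normal factor and the chi-distributed variance estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import chain, combinations
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .design import COMPARISONS, CONTROL

ALL_STRATEGIES: tuple[str, ...] = (
    "T-test A",
    "T-test B",
    "T-test C",
    "T-test C-nc",
    "Bonferroni",
    "Bonferroni-nc",
    "Dunnett.closed",
    "Dunnett.closed-nc",
    "Combination.closed",
)


class EmptyCellError(ValueError):
    """A test needed data from an arm-stage cell that has no subjects."""


class DegenerateDataError(ValueError):
    """Zero pooled variance (all relevant outcomes identical)."""


@dataclass(frozen=True)
class TTestResult:
    estimate: float
    se: float
    t: float
    p: float
    df: int


@dataclass
class TestDecisionSet:
    """Per-strategy rejection flags (and p-values where the strategy yields one)."""

    strategy: str
    p_values: dict[str, float] = field(default_factory=dict)
    reject: dict[str, bool] = field(default_factory=dict)

    @property
    def any_rejection(self) -> bool:
        return any(self.reject.values())


# ---------------------------------------------------------------------------
# sufficient statistics
# ---------------------------------------------------------------------------


class CellStats:
    """Per (arm, stage) counts, sums and sums of squares.

    Every strategy in this module is a function of these sufficient
    statistics, which makes replication loops cheap.
    """

    __slots__ = ("n", "s", "ss")

    def __init__(self, n: dict, s: dict, ss: dict):
        self.n, self.s, self.ss = n, s, ss

    @classmethod
    def from_dataset(cls, dataset: pd.DataFrame) -> "CellStats":
        arm = dataset["arm"].to_numpy()
        stage = dataset["stage"].to_numpy()
        y = dataset["y"].to_numpy(dtype=float)
        n, s, ss = {}, {}, {}
        for a in ("0", "A", "B", "C"):
            for k in (1, 2):
                mask = (arm == a) & (stage == k)
                cnt = int(mask.sum())
                if cnt:
                    yv = y[mask]
                    n[(a, k)] = cnt
                    s[(a, k)] = float(yv.sum())
                    ss[(a, k)] = float((yv * yv).sum())
        return cls(n, s, ss)

    def group(self, cells: Iterable[tuple[str, int]]) -> tuple[int, float, float]:
        """(count, mean, within-group SS) of a set of cells sharing one mean."""
        cells = [c for c in cells if c in self.n]
        n = sum(self.n[c] for c in cells)
        if n == 0:
            raise EmptyCellError(f"no observations in cells {list(cells)}")
        s = sum(self.s[c] for c in cells)
        ss = sum(self.ss[c] for c in cells)
        mean = s / n
        return n, mean, ss - s * s / n


def _as_cells(dataset) -> CellStats:
    return dataset if isinstance(dataset, CellStats) else CellStats.from_dataset(dataset)


def _control_cells(
    comparison: str, control_policy: str, stages: tuple[int, ...]
) -> list[tuple[str, int]]:
    """Control pool of one comparison: stage-2 only for concurrent C."""
    if comparison == "C" and control_policy == "concurrent":
        stages = tuple(k for k in stages if k == 2)
        if not stages:
            raise EmptyCellError("comparison C has no concurrent control in stage 1")
    return [(CONTROL, k) for k in stages]


def _stages(stage_filter) -> tuple[int, ...]:
    if stage_filter in (None, "all"):
        return (1, 2)
    if stage_filter in (1, 2):
        return (stage_filter,)
    raise ValueError(f"stage_filter must be None, 'all', 1 or 2; got {stage_filter!r}")


# ---------------------------------------------------------------------------
# elementary t-test
# ---------------------------------------------------------------------------


def mean_diff_t_test(
    dataset,
    comparison: str,
    control_policy: str = "concurrent",
    stage_filter=None,
) -> TTestResult:
    """One-sided pooled-variance two-sample t-test of one research comparison.

    ``control_policy`` is ``"concurrent"`` (comparison C uses stage-two
    control data only) or ``"all"`` (pool the non-concurrent stage-one
    controls as well); comparisons A and B use both stages' controls
    under either policy.  ``stage_filter`` restricts both groups to one
    stage, as needed by the stage-wise combination test.
    """
    cells = _as_cells(dataset)
    stages = _stages(stage_filter)
    n1, m1, ss1 = cells.group([(comparison, k) for k in stages])
    n0, m0, ss0 = cells.group(_control_cells(comparison, control_policy, stages))
    if n1 < 2 or n0 < 2:
        raise EmptyCellError(f"comparison {comparison}: need >=2 subjects per group")
    df = n1 + n0 - 2
    s2 = (ss1 + ss0) / df
    if s2 <= 0:
        raise DegenerateDataError(f"zero pooled variance for comparison {comparison}")
    se = math.sqrt(s2 * (1 / n1 + 1 / n0))
    t = (m1 - m0) / se
    return TTestResult(m1 - m0, se, t, float(stats.t.sf(t, df)), df)


# ---------------------------------------------------------------------------
# Dunnett max-t distribution
# ---------------------------------------------------------------------------


@lru_cache(maxsize=256)
def _chi_nodes(df: int, n_u: int = 32) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights for u = s/sigma, with chi density weight."""
    lo = math.sqrt(stats.chi2.ppf(1e-11, df) / df)
    hi = math.sqrt(stats.chi2.ppf(1 - 1e-11, df) / df)
    x, w = np.polynomial.legendre.leggauss(n_u)
    u = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    pdf = stats.chi2.pdf(df * u**2, df) * 2 * df * u
    wu = w * 0.5 * (hi - lo) * pdf
    return u, wu / wu.sum()


@lru_cache(maxsize=8)
def _hermite_nodes(n_z: int = 48) -> tuple[np.ndarray, np.ndarray]:
    z, w = np.polynomial.hermite_e.hermegauss(n_z)
    return z, w / math.sqrt(2 * math.pi)


def max_t_sf(t_obs: float, lambdas: np.ndarray, df: int) -> float:
    """P(max_j T_j >= t_obs) for product-correlated multivariate t.

    The T_j share one chi-distributed variance estimate with ``df``
    degrees of freedom and have correlation ``lambda_i * lambda_j``.
    Integrates the conditional normal product over the shared factor
    (Gauss-Hermite) and the variance estimate (Gauss-Legendre against
    the chi density).
    """
    lam = np.asarray(lambdas, dtype=float)
    if np.any((lam < 0) | (lam >= 1)):
        raise ValueError("lambda loadings must lie in [0, 1)")
    u, wu = _chi_nodes(int(df))
    z, wz = _hermite_nodes()
    # args shape (n_u, n_z) per comparison
    tu = t_obs * u[:, None]
    prod = np.ones((u.size, z.size))
    for l_j in lam:
        prod *= ndtr((tu - l_j * z[None, :]) / math.sqrt(1 - l_j * l_j))
    cdf = float(wu @ prod @ wz)
    return min(max(1.0 - cdf, 0.0), 1.0)


def _lambdas_from_correlation(corr: np.ndarray) -> np.ndarray | None:
    """Product-form loadings reproducing ``corr``, or None if not decomposable."""
    m = corr.shape[0]
    if m == 1:
        return np.zeros(1)
    if np.any(corr[~np.eye(m, dtype=bool)] <= 0):
        return None
    if m == 2:
        lam = np.full(2, math.sqrt(corr[0, 1]))
    else:
        lam = np.empty(m)
        idx = range(m)
        for i in idx:
            j, k = [x for x in idx if x != i][:2]
            lam[i] = math.sqrt(corr[i, j] * corr[i, k] / corr[j, k])
    if np.any(lam >= 1):
        return None
    recon = np.outer(lam, lam)
    np.fill_diagonal(recon, 1.0)
    if not np.allclose(recon, corr, atol=1e-8):
        return None
    return lam


def _mvt_max_sf(t_obs: float, corr: np.ndarray, df: int) -> float:
    """General-correlation fallback via scipy's multivariate t CDF (QMC, seeded)."""
    dist = stats.multivariate_t(shape=corr, df=df, seed=12345)
    cdf = float(dist.cdf(np.full(corr.shape[0], t_obs)))
    return min(max(1.0 - cdf, 0.0), 1.0)


def dunnett_p(
    dataset,
    comparisons: Iterable[str],
    control_policy: str = "concurrent",
    stage_filter=None,
) -> float:
    """Intersection p-value of the Dunnett max-t test over a comparison subset.

    The p-value is P(max_j T_j >= observed max) under the joint
    multivariate-t null.  The pooled variance is estimated from all arms
    contributing to the involved statistics, with the union of the
    control pools treated as a single group; degrees of freedom are
    N - (number of groups).  Reduces to the plain one-sided t-test for a
    singleton subset.
    """
    comps = sorted(set(comparisons))
    if not comps:
        raise ValueError("comparison subset must be non-empty")
    cells = _as_cells(dataset)
    stages = _stages(stage_filter)

    pools = {j: _control_cells(j, control_policy, stages) for j in comps}
    union_pool = sorted(set(chain.from_iterable(pools.values())))
    n_u, _, ss_u = cells.group(union_pool)

    n_arm, m_arm, ss_arm = {}, {}, {}
    for j in comps:
        n_arm[j], m_arm[j], ss_arm[j] = cells.group([(j, k) for k in stages])
    pool_n, pool_m = {}, {}
    for j in comps:
        pool_n[j], pool_m[j], _ = cells.group(pools[j])

    df = n_u + sum(n_arm.values()) - (len(comps) + 1)
    s2 = (ss_u + sum(ss_arm.values())) / df
    if s2 <= 0:
        raise DegenerateDataError("zero pooled variance in Dunnett statistic")

    t_obs = np.array(
        [
            (m_arm[j] - pool_m[j])
            / math.sqrt(s2 * (1 / n_arm[j] + 1 / pool_n[j]))
            for j in comps
        ]
    )
    m = len(comps)
    if m == 1:
        return float(stats.t.sf(t_obs[0], df))

    # correlation of the contrast statistics: control pools are nested, so
    # Cov(mean_pool_i, mean_pool_j) = sigma^2 / max(n_i, n_j)
    corr = np.eye(m)
    denom = [math.sqrt(1 / n_arm[j] + 1 / pool_n[j]) for j in comps]
    for a in range(m):
        for b in range(a + 1, m):
            cov = 1.0 / max(pool_n[comps[a]], pool_n[comps[b]])
            corr[a, b] = corr[b, a] = cov / (denom[a] * denom[b])

    tmax = float(t_obs.max())
    lam = _lambdas_from_correlation(corr)
    if lam is None:  # pragma: no cover - pools are always nested here
        return _mvt_max_sf(tmax, corr, df)
    return max_t_sf(tmax, lam, df)


# ---------------------------------------------------------------------------
# closed testing and the combination test
# ---------------------------------------------------------------------------


def _subsets(comparisons: Iterable[str]) -> list[frozenset]:
    comps = sorted(set(comparisons))
    return [
        frozenset(c)
        for r in range(1, len(comps) + 1)
        for c in combinations(comps, r)
    ]


def closed_test(
    intersection_p: Mapping[frozenset, float] | Callable[[frozenset], float],
    alpha: float,
    comparisons: Iterable[str] = COMPARISONS,
) -> TestDecisionSet:
    """Apply the closed testing principle to intersection p-values.

    An elementary hypothesis is rejected iff every subset containing it
    has intersection p-value <= alpha, which controls the familywise
    error rate in the strong sense.
    """
    subsets = _subsets(comparisons)
    get_p = intersection_p if callable(intersection_p) else intersection_p.__getitem__
    p = {s: float(get_p(s)) for s in subsets}
    decisions = TestDecisionSet(strategy="closed")
    for j in sorted(set(comparisons)):
        decisions.p_values[j] = p[frozenset({j})]
        decisions.reject[j] = all(pv <= alpha for s, pv in p.items() if j in s)
    return decisions


def fisher_threshold(alpha: float) -> float:
    """Critical value for the product of two stage-wise p-values."""
    return math.exp(-0.5 * stats.chi2.ppf(1 - alpha, 4))


def fisher_combination_reject(p1: float, p2: float, alpha: float) -> bool:
    """Fisher's combination rule: reject iff p1 * p2 <= exp(-chi2_4(1-alpha)/2)."""
    return p1 * p2 <= fisher_threshold(alpha)


def combination_closed(dataset, alpha: float = 0.05) -> TestDecisionSet:
    """Fisher combination test with closed testing over stage-wise Dunnett p-values.

    For each subset of {A, B, C}, the stage-one p-value is the Dunnett
    p of the subset with comparison C removed, computed from stage-one
    data only (subsets that reduce to the empty set carry p1 = 1: there
    is no stage-one information about the added arm); the stage-two
    p-value is the Dunnett p of the full subset from stage-two data.
    The subset is rejected when the product passes Fisher's rule, and
    elementary decisions follow from the closed principle.
    """
    cells = _as_cells(dataset)
    p1_cache: dict[frozenset, float] = {}

    def stage1_p(reduced: frozenset) -> float:
        if not reduced:
            return 1.0
        if reduced not in p1_cache:
            p1_cache[reduced] = dunnett_p(cells, reduced, stage_filter=1)
        return p1_cache[reduced]

    decisions = TestDecisionSet(strategy="Combination.closed")
    subset_reject: dict[frozenset, bool] = {}
    for s in _subsets(COMPARISONS):
        p1 = stage1_p(s - {"C"})
        p2 = dunnett_p(cells, s, stage_filter=2)
        subset_reject[s] = fisher_combination_reject(p1, p2, alpha)
    for j in COMPARISONS:
        decisions.reject[j] = all(
            rej for s, rej in subset_reject.items() if j in s
        )
    return decisions


# ---------------------------------------------------------------------------
# strategy batteries
# ---------------------------------------------------------------------------


def run_all_strategies(
    dataset,
    alpha: float = 0.05,
    strategies: Iterable[str] | None = None,
) -> dict[str, TestDecisionSet]:
    """Run the named testing strategies on one dataset.

    ``strategies`` defaults to all nine; pass a subset to skip the more
    expensive closed procedures in narrow simulation runs.
    """
    wanted = tuple(strategies) if strategies is not None else ALL_STRATEGIES
    unknown = set(wanted) - set(ALL_STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies {sorted(unknown)}")
    cells = _as_cells(dataset)
    out: dict[str, TestDecisionSet] = {}

    t_cache: dict[tuple[str, str], TTestResult] = {}

    def t_res(j: str, policy: str) -> TTestResult:
        key = (j, policy)
        if key not in t_cache:
            t_cache[key] = mean_diff_t_test(cells, j, control_policy=policy)
        return t_cache[key]

    for name, j, policy in (
        ("T-test A", "A", "concurrent"),
        ("T-test B", "B", "concurrent"),
        ("T-test C", "C", "concurrent"),
        ("T-test C-nc", "C", "all"),
    ):
        if name in wanted:
            r = t_res(j, policy)
            out[name] = TestDecisionSet(name, {j: r.p}, {j: r.p <= alpha})

    for name, policy in (("Bonferroni", "concurrent"), ("Bonferroni-nc", "all")):
        if name in wanted:
            ds = TestDecisionSet(name)
            for j in COMPARISONS:
                r = t_res(j, policy)
                ds.p_values[j] = r.p
                ds.reject[j] = r.p <= alpha / 3
            out[name] = ds

    for name, policy in (
        ("Dunnett.closed", "concurrent"),
        ("Dunnett.closed-nc", "all"),
    ):
        if name in wanted:
            ds = closed_test(
                lambda s, pol=policy: dunnett_p(cells, s, control_policy=pol),
                alpha,
            )
            ds.strategy = name
            out[name] = ds

    if "Combination.closed" in wanted:
        out["Combination.closed"] = combination_closed(cells, alpha)

    return {name: out[name] for name in wanted}


def model_based_tests(estimate_result, alpha: float = 0.05) -> dict[str, TestDecisionSet]:
    """Testing strategies applied to the statistics of a fitted model.

    Uses theta_hat_j / SE_j with the model's residual degrees of freedom
    per hypothesis at level alpha (``T-test j``), at alpha/3
    (``Bonferroni``), and with a closed Dunnett procedure whose joint
    distribution takes the correlation matrix of the three estimators
    from the model's estimated covariance (``Dunnett.closed``).
    """
    theta, se = estimate_result.theta, estimate_result.se
    df = estimate_result.df_resid
    vcov = np.asarray(estimate_result.vcov_theta, dtype=float)
    sd = np.sqrt(np.diag(vcov))
    if np.any(sd <= 0) or not np.all(np.isfinite(vcov)):
        raise ValueError("singular or non-finite estimator covariance")
    corr = vcov / np.outer(sd, sd)

    t_stats = {j: theta[j] / se[j] for j in COMPARISONS}
    p_one = {j: float(stats.t.sf(t_stats[j], df)) for j in COMPARISONS}

    out: dict[str, TestDecisionSet] = {}
    for j in COMPARISONS:
        out[f"T-test {j}"] = TestDecisionSet(
            f"T-test {j}", {j: p_one[j]}, {j: p_one[j] <= alpha}
        )
    out["Bonferroni"] = TestDecisionSet(
        "Bonferroni", dict(p_one), {j: p_one[j] <= alpha / 3 for j in COMPARISONS}
    )

    index = {j: i for i, j in enumerate(COMPARISONS)}

    def subset_p(s: frozenset) -> float:
        js = sorted(s)
        tmax = max(t_stats[j] for j in js)
        if len(js) == 1:
            return p_one[js[0]]
        ix = [index[j] for j in js]
        sub = corr[np.ix_(ix, ix)]
        lam = _lambdas_from_correlation(sub)
        if lam is None:
            return _mvt_max_sf(tmax, sub, int(round(df)))
        return max_t_sf(tmax, lam, int(round(df)))

    ds = closed_test(subset_p, alpha)
    ds.strategy = "Dunnett.closed"
    out["Dunnett.closed"] = ds
    return out
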
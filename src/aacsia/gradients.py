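"""Univariate gradient and group-comparison statistics.

Two analysis motifs recur across isotope metrics:

* **ln-distance regressions** — ordinary least squares of a per-sample
  response (centered d13C, d15N of a source amino acid, or a trophic
  position) on natural-log-transformed distance from shore, with
  two-tailed t-tests on the slope and Benjamini-Hochberg correction
  across the family of responses.

* **assumption-gated group comparisons** — Shapiro-Wilk normality per
  group and Levene's homogeneity (median-centered) decide the path:
  all gates pass at alpha = 0.05 -> parametric (one-way ANOVA + Tukey
  for three groups, Welch's t for two); any gate fails -> nonparametric
  (Kruskal-Wallis + BH-corrected Dunn, or Mann-Whitney U). Post hoc
  tests run only when the omnibus p < 0.05, strictly.

The gate is deterministic: identical input always selects the identical
path.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateDataError, DomainError, InsufficientDataError

ALPHA = 0.05


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of a response on ln(distance from shore)."""

    response: str
    slope: float          # response units per ln(km)
    intercept: float
    adj_r2: float
    p_raw: float
    p_adj: float | None
    n: int


@dataclass
class GroupComparisonResult:
    """Outcome of an assumption-gated group comparison.

    ``path`` records the branch taken; ``gate_report`` holds the
    Shapiro-Wilk p per group and the Levene p behind that decision.
    ``pairwise`` is non-empty only when the omnibus p < 0.05 (and, for
    two-group paths, stays empty — the omnibus is the comparison).
    """

    response: str
    path: str                      # anova_tukey | kruskal_dunn | welch_t | mann_whitney
    omnibus_stat: float
    omnibus_p: float
    pairwise: list[tuple[tuple[str, str], float]] = field(default_factory=list)
    gate_report: dict = field(default_factory=dict)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone non-decreasing after sorting, capped at 1; input order
    preserved in the output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DomainError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ln_distance_regression(values, distances_km, response: str = "response",
                           p_adj: float | None = None) -> RegressionResult:
    """OLS of ``values`` on ln(``distances_km``).

    Slope significance is a two-tailed t-test; fit quality is the
    adjusted R-squared. A zero-variance (constant) response is reported
    with slope 0 and p = 1 rather than an error, since a flat gradient
    is a legitimate result.
    """
    y = np.asarray(values, dtype=float)
    d = np.asarray(distances_km, dtype=float)
    if y.shape != d.shape or y.ndim != 1:
        raise DomainError("values and distances_km must be equal-length 1-D")
    if np.any(d <= 0):
        raise DomainError("distances must be > 0 km")
    mask = np.isfinite(y) & np.isfinite(d)
    y, d = y[mask], d[mask]
    if y.size < 3:
        raise InsufficientDataError(f"regression needs >= 3 points, got {y.size}")
    x = np.log(d)
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance in ln(distance)")
    if np.ptp(y) == 0:
        return RegressionResult(response, 0.0, float(y[0]), 0.0, 1.0, p_adj, y.size)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        response=response,
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        adj_r2=float(model.rsquared_adj),
        p_raw=float(model.pvalues[1]),
        p_adj=p_adj,
        n=int(y.size),
    )


def regression_family(named_series, distances_by_name) -> list[RegressionResult]:
    """Run a family of ln-distance regressions with one BH correction.

    ``named_series`` maps response name -> values; ``distances_by_name``
    maps response name -> matching distances (families may have
    different complete-case sample sets per response).
    """
    fits = [ln_distance_regression(named_series[name], distances_by_name[name],
                                   response=name)
            for name in named_series]
    adj = bh_adjust([f.p_raw for f in fits])
    return [RegressionResult(f.response, f.slope, f.intercept, f.adj_r2,
                             f.p_raw, float(a), f.n)
            for f, a in zip(fits, adj)]


def _gate(groups: dict[str, np.ndarray]) -> tuple[bool, dict]:
    """Shapiro-Wilk per group + median-centered Levene at alpha = 0.05."""
    report: dict = {"shapiro_p": {}, "alpha": ALPHA}
    parametric = True
    for name, vals in groups.items():
        if np.ptp(vals) == 0:
            # Shapiro is undefined for constant data; a constant group
            # is maximally non-normal for our purposes.
            p = 0.0
        else:
            p = float(stats.shapiro(vals).pvalue)
        report["shapiro_p"][name] = p
        if p < ALPHA:
            parametric = False
    lev = stats.levene(*groups.values(), center="median")
    lev_p = float(lev.pvalue) if np.isfinite(lev.pvalue) else 0.0
    report["levene_p"] = lev_p
    if lev_p < ALPHA:
        parametric = False
    report["parametric"] = parametric
    return parametric, report


def _split(values, labels) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise DomainError("values and labels must have equal length")
    groups = {}
    for name in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        vals = values[labels == name]
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise InsufficientDataError(
                f"group {name!r} has {vals.size} observation(s); need >= 2"
            )
        groups[name] = vals
    return groups


def compare_groups(values, labels, response: str = "response") -> GroupComparisonResult:
    """Three-group comparison with the assumption gate and post hoc tests.

    Parametric path: one-way ANOVA, Tukey HSD pairwise. Nonparametric
    path: Kruskal-Wallis (tie-corrected), Dunn's pairwise z-tests with
    BH correction. Pairwise tests run only when the omnibus p < 0.05.
    """
    groups = _split(values, labels)
    if len(groups) != 3:
        raise DomainError(f"compare_groups expects exactly 3 groups, got {len(groups)}")
    parametric, report = _gate(groups)
    names = list(groups)
    arrays = [groups[n] for n in names]
    if parametric:
        stat, p = stats.f_oneway(*arrays)
        result = GroupComparisonResult(response, "anova_tukey", float(stat),
                                       float(p), gate_report=report)
        if p < ALPHA:
            tukey = stats.tukey_hsd(*arrays)
            for i, j in itertools.combinations(range(3), 2):
                result.pairwise.append(
                    ((names[i], names[j]), float(tukey.pvalue[i, j]))
                )
    else:
        stat, p = stats.kruskal(*arrays)
        result = GroupComparisonResult(response, "kruskal_dunn", float(stat),
                                       float(p), gate_report=report)
        if p < ALPHA:
            result.pairwise = dunn_posthoc(groups)
    return result


def compare_two_groups(values, labels, response: str = "response") -> GroupComparisonResult:
    """Two-group comparison: Welch's t when the gate passes, else
    Mann-Whitney U.

    Mann-Whitney uses exact enumeration when total n <= 12 and the data
    are tie-free, otherwise the normal approximation with tie and
    continuity corrections. The returned p is raw; collect a family of
    responses and apply :func:`bh_adjust` across them.
    """
    groups = _split(values, labels)
    if len(groups) != 2:
        raise DomainError(f"compare_two_groups expects exactly 2 groups, got {len(groups)}")
    parametric, report = _gate(groups)
    a, b = groups.values()
    if parametric:
        res = stats.ttest_ind(a, b, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        path = "welch_t"
    else:
        pooled = np.concatenate([a, b])
        exact = (pooled.size <= 12) and (np.unique(pooled).size == pooled.size)
        method = "exact" if exact else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=True)
        stat, p = float(res.statistic), float(res.pvalue)
        path = "mann_whitney"
    if not math.isfinite(p):  # identical constant groups
        stat, p = 0.0, 1.0
    return GroupComparisonResult(response, path, stat, p, gate_report=report)


def dunn_posthoc(groups: dict[str, np.ndarray]) -> list[tuple[tuple[str, str], float]]:
    """Dunn's rank-based pairwise z-tests with BH-adjusted p-values.

    Uses joint mid-ranks with the standard tie correction
    T = sum(t^3 - t) / (12 (N - 1)) subtracted from N(N+1)/12 in the
    variance term.
    """
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # mean rank per group
    mean_rank, sizes = {}, {}
    offset = 0
    for name in names:
        k = groups[name].size
        mean_rank[name] = float(ranks[offset:offset + k].mean())
        sizes[name] = k
        offset += k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs, p_raw = [], []
    for na, nb in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[na] + 1.0 / sizes[nb]))
        if se == 0:
            p = 1.0
        else:
            z = (mean_rank[na] - mean_rank[nb]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        pairs.append((na, nb))
        p_raw.append(p)
    p_adj = bh_adjust(p_raw)
    return [(pair, float(p)) for pair, p in zip(pairs, p_adj)]
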
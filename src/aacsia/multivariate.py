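"""Multivariate habitat discrimination: Euclidean PERMANOVA and LDA.

PERMANOVA partitions the total sum of squared Euclidean inter-point
distances into among- and within-group components and forms a pseudo-F
(among-group mean square over within-group mean square). Significance
comes from permuting group labels while preserving group sizes: all
distinct assignments are enumerated exhaustively when their number is
at most 10,000, otherwise seeded Monte-Carlo sampling is used with the
(count + 1)/(n_perm + 1) convention. On univariate data the pseudo-F
equals the classical one-way ANOVA F exactly.

A betadisper-style dispersion test accompanies every PERMANOVA:
per-sample Euclidean distances to the own-group centroid are computed
once under the observed grouping, and a one-way F on those distances is
compared against label permutations.

LDA follows the classical Fisher construction: discriminant axes are
generalized eigenvectors of the between-class scatter against the
pooled within-class scatter (axes normalized to unit within-class
variance, a' W a = 1), variance proportions come from the eigenvalues,
and posteriors use the shared-covariance Gaussian model with
configurable priors. A small ridge (lambda * trace(W)/p, lambda = 1e-8)
is added to the within-class covariance only if it is singular.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .exceptions import (ConfigError, DegenerateDataError, DomainError,
                         InsufficientDataError, SchemaError)
from .gradients import bh_adjust

log = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 10_000
DEFAULT_N_PERM = 9_999
RIDGE_LAMBDA = 1e-8

_ridge_seen: set[tuple[str, ...]] = set()


@dataclass
class FeatureMatrix:
    """Samples x features with group labels; no missing cells allowed."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise SchemaError("sample_ids/labels length must match value rows")
        if len(self.feature_names) != p:
            raise SchemaError("feature_names length must match value columns")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("feature matrix contains non-finite cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def groups(self) -> dict[str, np.ndarray]:
        """Group name -> row indices, in first-seen order."""
        labels = np.asarray(self.labels)
        return {g: np.flatnonzero(labels == g)
                for g in dict.fromkeys(self.labels)}

    def require_groups(self, min_groups: int = 2, min_per_group: int = 2) -> None:
        grp = self.groups()
        if len(grp) < min_groups:
            raise InsufficientDataError(
                f"need >= {min_groups} groups, got {len(grp)}")
        for g, idx in grp.items():
            if idx.size < min_per_group:
                raise InsufficientDataError(
                    f"group {g!r} has {idx.size} sample(s); need >= {min_per_group}")

    def subset_groups(self, names) -> "FeatureMatrix":
        keep = [i for i, lab in enumerate(self.labels) if lab in set(names)]
        return FeatureMatrix(
            [self.sample_ids[i] for i in keep],
            list(self.feature_names),
            self.values[keep],
            [self.labels[i] for i in keep],
        )


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int          # effective permutation count (exhaustive: total assignments)
    seed: int | None
    exhaustive: bool
    dispersion_p: float | None = None


@dataclass(frozen=True)
class PairwiseContrast:
    pair: tuple[str, str]
    pseudo_f: float
    p_raw: float
    p_adj: float


@dataclass
class LdaModel:
    """Fitted linear discriminant model (shared-covariance Gaussian)."""

    classes: list[str]
    feature_names: list[str]
    class_means: np.ndarray          # k x p
    pooled_cov: np.ndarray           # p x p (within-class, ridge-adjusted if needed)
    priors: np.ndarray               # k, sums to 1
    grand_mean: np.ndarray           # p (prior-weighted overall mean)
    axes: np.ndarray                 # p x r, a' W a = 1, sign-normalized
    eigenvalues: np.ndarray          # r
    variance_proportions: np.ndarray  # r, sums to 1

    @property
    def loadings(self) -> np.ndarray:
        """Feature weights per discriminant axis (alias of ``axes``)."""
        return self.axes

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project rows of ``x`` onto the discriminant axes."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.grand_mean) @ self.axes


# ---------------------------------------------------------------------------
# PERMANOVA machinery


def _squared_distance_matrix(x: np.ndarray) -> np.ndarray:
    sq = np.sum(x * x, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def _pseudo_f(d2: np.ndarray, group_indices: list[np.ndarray],
              sst: float) -> tuple[float, float]:
    """(pseudo-F, R^2) from squared distances for one label assignment."""
    n = d2.shape[0]
    k = len(group_indices)
    ssw = 0.0
    for idx in group_indices:
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ssa = sst - ssw
    r2 = ssa / sst if sst > 0 else 0.0
    denom = ssw / (n - k)
    if denom == 0.0:
        return math.inf, r2
    return (ssa / (k - 1)) / denom, r2


def _assignment_count(sizes: list[int]) -> int:
    total = math.factorial(sum(sizes))
    for s in sizes:
        total //= math.factorial(s)
    return total


def _enumerate_assignments(n: int, sizes: list[int]):
    """Yield all distinct group-size-preserving index assignments."""
    def rec(remaining: tuple[int, ...], sizes_left: list[int], acc: list):
        if not sizes_left:
            yield list(acc)
            return
        if len(sizes_left) == 1:
            yield acc + [np.asarray(remaining)]
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            chosen = set(combo)
            rest = tuple(i for i in remaining if i not in chosen)
            yield from rec(rest, sizes_left[1:], acc + [np.asarray(combo)])
    yield from rec(tuple(range(n)), sizes, [])


def permanova(features: FeatureMatrix, n_perm: int = DEFAULT_N_PERM,
              seed: int | None = None, with_dispersion: bool = True,
              method: str = "auto") -> PermanovaResult:
    """One-factor PERMANOVA on Euclidean distances.

    Exhaustive enumeration of group-size-preserving label assignments
    when there are <= 10,000 of them (p = count of F_perm >= F_obs over
    the total, the observed assignment included); otherwise seeded
    Monte-Carlo with p = (count + 1)/(n_perm + 1). ``method`` may force
    ``"exhaustive"`` or ``"sampled"`` instead of the ``"auto"`` rule.
    """
    features.require_groups(min_groups=2, min_per_group=2)
    if n_perm < 99:
        raise DomainError(f"n_perm must be >= 99, got {n_perm}")
    if method not in ("auto", "exhaustive", "sampled"):
        raise DomainError(f"unknown method {method!r}")
    d2 = _squared_distance_matrix(features.values)
    n = features.n
    sst = d2.sum() / (2.0 * n)
    if sst <= 0:
        raise DegenerateDataError("all points identical: zero total variance")
    groups = features.groups()
    obs_indices = list(groups.values())
    sizes = [idx.size for idx in obs_indices]
    f_obs, r2 = _pseudo_f(d2, obs_indices, sst)
    tol = 1e-12 * max(1.0, abs(f_obs) if math.isfinite(f_obs) else 1.0)

    total = _assignment_count(sizes)
    use_exhaustive = (total <= EXHAUSTIVE_LIMIT) if method == "auto" else (
        method == "exhaustive")
    if use_exhaustive and total > EXHAUSTIVE_LIMIT:
        raise DomainError(
            f"{total} assignments exceed the exhaustive limit {EXHAUSTIVE_LIMIT}")
    if use_exhaustive:
        count = 0
        for assignment in _enumerate_assignments(n, sizes):
            f_perm, _ = _pseudo_f(d2, assignment, sst)
            if f_perm >= f_obs - tol:
                count += 1
        p = count / total
        result_n_perm, exhaustive = total, True
    else:
        rng = np.random.default_rng(seed)
        count = 0
        order = np.arange(n)
        bounds = np.cumsum(sizes)[:-1]
        for _ in range(n_perm):
            perm = rng.permutation(order)
            assignment = np.split(perm, bounds)
            f_perm, _ = _pseudo_f(d2, assignment, sst)
            if f_perm >= f_obs - tol:
                count += 1
        p = (count + 1) / (n_perm + 1)
        result_n_perm, exhaustive = n_perm, False

    disp_p = None
    if with_dispersion:
        try:
            disp_p = dispersion_homogeneity(features, n_perm=n_perm, seed=seed)
        except DegenerateDataError:
            disp_p = None
    return PermanovaResult(float(f_obs), float(r2), float(p), result_n_perm,
                           seed, exhaustive, disp_p)


def dispersion_homogeneity(features: FeatureMatrix, n_perm: int = DEFAULT_N_PERM,
                           seed: int | None = None) -> float:
    """Permutation test for homogeneity of multivariate dispersion.

    Per-sample Euclidean distances to the own-group centroid are fixed;
    group labels are permuted and the one-way F on the distances
    recomputed ((count + 1)/(n_perm + 1) convention).
    """
    features.require_groups(min_groups=2, min_per_group=2)
    groups = features.groups()
    x = features.values
    z = np.empty(features.n)
    for idx in groups.values():
        centroid = x[idx].mean(axis=0)
        z[idx] = np.linalg.norm(x[idx] - centroid, axis=1)
    if np.ptp(z) == 0:
        raise DegenerateDataError(
            "all centroid distances identical; dispersion test undefined")

    sizes = [idx.size for idx in groups.values()]
    obs = list(groups.values())

    def f_of(assignment) -> float:
        grand = z.mean()
        ssb = sum(idx.size * (z[idx].mean() - grand) ** 2 for idx in assignment)
        ssw = sum(((z[idx] - z[idx].mean()) ** 2).sum() for idx in assignment)
        k, n = len(assignment), z.size
        if ssw == 0:
            return math.inf
        return (ssb / (k - 1)) / (ssw / (n - k))

    f_obs = f_of(obs)
    tol = 1e-12 * max(1.0, abs(f_obs) if math.isfinite(f_obs) else 1.0)
    rng = np.random.default_rng(seed)
    bounds = np.cumsum(sizes)[:-1]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(features.n)
        if f_of(np.split(perm, bounds)) >= f_obs - tol:
            count += 1
    return (count + 1) / (n_perm + 1)


def pairwise_permanova(features: FeatureMatrix, n_perm: int = DEFAULT_N_PERM,
                       seed: int | None = None) -> list[PairwiseContrast]:
    """PERMANOVA on every group pair with BH adjustment across pairs.

    Requires >= 3 groups (with 2 groups the omnibus test already is the
    pairwise contrast). Both raw and BH-adjusted p-values are reported.
    """
    groups = list(features.groups())
    if len(groups) < 3:
        raise DomainError(
            "pairwise_permanova needs >= 3 groups; use permanova for 2")
    pairs = list(itertools.combinations(groups, 2))
    results = []
    for i, pair in enumerate(pairs):
        sub = features.subset_groups(pair)
        sub_seed = None if seed is None else (seed + 1009 * (i + 1)) % (2**31 - 1)
        res = permanova(sub, n_perm=n_perm, seed=sub_seed, with_dispersion=False)
        results.append((pair, res))
    p_adj = bh_adjust([r.p for _, r in results])
    return [PairwiseContrast(pair, r.pseudo_f, r.p, float(a))
            for (pair, r), a in zip(results, p_adj)]


# ---------------------------------------------------------------------------
# Linear discriminant analysis


def _resolve_priors(priors, classes: list[str], counts: np.ndarray) -> np.ndarray:
    if priors is None:
        pri = counts / counts.sum()
    elif isinstance(priors, str) and priors == "uniform":
        pri = np.full(len(classes), 1.0 / len(classes))
    elif isinstance(priors, dict):
        pri = np.array([float(priors[c]) for c in classes])
    else:
        pri = np.asarray(priors, dtype=float)
    if pri.shape != (len(classes),) or np.any(pri <= 0):
        raise ConfigError("priors must be positive, one per class")
    return pri / pri.sum()


def lda_fit(features: FeatureMatrix, priors=None) -> LdaModel:
    """Fit Fisher LDA with a pooled within-class covariance.

    Axes solve the generalized eigenproblem B a = lambda W a (B the
    between-class scatter, W the pooled within-class covariance), kept
    in descending-eigenvalue order up to min(k - 1, p) axes.
    ``variance_proportions`` are the eigenvalue shares; each axis is
    oriented so its largest-magnitude loading is positive.
    """
    features.require_groups(min_groups=2, min_per_group=2)
    x = features.values
    groups = features.groups()
    classes = list(groups)
    k, p = len(classes), x.shape[1]
    counts = np.array([groups[c].size for c in classes], dtype=float)
    priors_arr = _resolve_priors(priors, classes, counts)

    means = np.vstack([x[groups[c]].mean(axis=0) for c in classes])
    within = np.zeros((p, p))
    for ci, c in enumerate(classes):
        dev = x[groups[c]] - means[ci]
        within += dev.T @ dev
    n = x.shape[0]
    pooled = within / (n - k)

    grand = priors_arr @ means
    between = np.zeros((p, p))
    for ci in range(k):
        d = means[ci] - grand
        between += counts[ci] * np.outer(d, d)

    ridged = False
    cov = pooled
    for attempt in range(2):
        try:
            evals, evecs = linalg.eigh(between, cov)
            break
        except linalg.LinAlgError:
            if attempt == 1:
                raise DegenerateDataError(
                    f"within-class covariance singular even after ridge; "
                    f"feature space {features.feature_names} is rank-deficient"
                ) from None
            cov = pooled + RIDGE_LAMBDA * (np.trace(pooled) / p) * np.eye(p)
            ridged = True
            key = tuple(features.feature_names)
            # a fully mean-centered EAA block is rank-deficient by
            # construction; announce the ridge once per feature space
            emit = log.warning if key not in _ridge_seen else log.debug
            _ridge_seen.add(key)
            emit("singular within-class covariance for features %s; "
                 "added ridge lambda*trace(W)/p with lambda=%g",
                 list(key), RIDGE_LAMBDA)
    order = np.argsort(evals)[::-1]
    r = min(k - 1, p)
    evals = np.clip(evals[order][:r], 0.0, None)
    axes = evecs[:, order][:, :r]
    total = evals.sum()
    if total <= 0:
        raise DegenerateDataError("no between-class variance; groups coincide")
    proportions = evals / total
    # orient each axis so its largest-|loading| is positive
    for j in range(axes.shape[1]):
        lead = np.argmax(np.abs(axes[:, j]))
        if axes[lead, j] < 0:
            axes[:, j] = -axes[:, j]

    return LdaModel(
        classes=classes,
        feature_names=list(features.feature_names),
        class_means=means,
        pooled_cov=cov if ridged else pooled,
        priors=priors_arr,
        grand_mean=grand,
        axes=axes,
        eigenvalues=evals,
        variance_proportions=proportions,
    )


def lda_classify(model: LdaModel, features) -> tuple[list[str], np.ndarray]:
    """Classify samples under the shared-covariance Gaussian model.

    ``features`` may be a :class:`FeatureMatrix` (feature names are
    checked against the model) or a bare array in model feature order.
    Returns (argmax labels, posterior matrix with per-sample rows
    summing to 1 over ``model.classes``).
    """
    if isinstance(features, FeatureMatrix):
        if list(features.feature_names) != list(model.feature_names):
            raise SchemaError(
                f"feature mismatch: model expects {model.feature_names}, "
                f"got {features.feature_names}")
        x = features.values
    else:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != len(model.feature_names):
            raise SchemaError(
                f"expected {len(model.feature_names)} features, got {x.shape[1]}")
    # mean-centered feature sets make the pooled covariance structurally
    # rank-deficient (profiles sum to zero); the pseudo-inverse restricts
    # the Gaussian model to the effective-rank subspace
    prec = linalg.pinvh(model.pooled_cov, rtol=1e-7)
    # log discriminant: x' P m - m' P m / 2 + log prior
    lin = x @ prec @ model.class_means.T
    quad = 0.5 * np.einsum("ij,jk,ik->i", model.class_means, prec,
                           model.class_means)
    scores = lin - quad[None, :] + np.log(model.priors)[None, :]
    scores -= scores.max(axis=1, keepdims=True)
    post = np.exp(scores)
    post /= post.sum(axis=1, keepdims=True)
    labels = [model.classes[i] for i in np.argmax(post, axis=1)]
    return labels, post


def loocv_accuracy(features: FeatureMatrix, priors=None) -> float:
    """Leave-one-out cross-validated classification accuracy.

    The model (means, pooled covariance, frequency priors) is refit on
    every fold without the held-out sample, so no information leaks.
    Requires >= 3 samples per group so each fold keeps >= 2.
    """
    features.require_groups(min_groups=2, min_per_group=3)
    n = features.n
    correct = 0
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        train = FeatureMatrix(
            [features.sample_ids[j] for j in keep],
            list(features.feature_names),
            features.values[keep],
            [features.labels[j] for j in keep],
        )
        model = lda_fit(train, priors=priors)
        label, _ = lda_classify(model, features.values[i:i + 1])
        if label[0] == features.labels[i]:
            correct += 1
    return correct / n


@dataclass
class FingerprintResult:
    """Consumer classification against producer training endmembers."""

    model: LdaModel
    sample_ids: list[str]
    labels: list[str]
    posteriors: np.ndarray        # n_consumers x n_producer_groups
    coordinates: np.ndarray       # n_consumers x n_axes


def fingerprint_classify(training: FeatureMatrix,
                         consumers: FeatureMatrix,
                         priors=None) -> FingerprintResult:
    """Supervised producer-source classification of consumers.

    Fits LDA on the producer endmember library and projects consumers
    into the same discriminant space. Both matrices must use the
    identical mean-centered EAA feature set.
    """
    if list(training.feature_names) != list(consumers.feature_names):
        raise SchemaError(
            f"EAA set mismatch: training {training.feature_names} vs "
            f"consumers {consumers.feature_names}")
    model = lda_fit(training, priors=priors)
    labels, post = lda_classify(model, consumers)
    coords = model.transform(consumers.values)
    return FingerprintResult(model, list(consumers.sample_ids), labels,
                             post, coords)
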
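"""Internal quality measures for modules.

Two families of measures that need no gold standard:

* **cluster validity indices** (average silhouette width, Davies–Bouldin,
  Kim–Ramakrishna) on a correlation-derived distance matrix — used to pick
  detector parameters automatically. They assume an exhaustive partition, so
  non-exhaustive module sets are first completed (every unassigned gene joins
  its best-correlated module) and overlaps resolved the same way.
* **co-expression metrics** per module: average pairwise correlation
  (global co-expression), the mean of each gene's top-5% z-scores (extreme,
  condition-specific expression), and the root-mean-squared deviation of
  standardized profiles around the module's per-sample mean (profile
  coherence). A permutation test compares real modules with gene-relabelled
  ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, NamedTuple

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.metrics import silhouette_score

from .io import ExpressionMatrix, Module, ModuleSet

__all__ = [
    "DistanceMatrix",
    "CoexpressionTriple",
    "ValidityResult",
    "correlation_distance",
    "complete_assignment",
    "resolve_overlaps",
    "cluster_validity",
    "coexpression_metrics",
    "permuted_metric_test",
]


@dataclass(frozen=True)
class DistanceMatrix:
    items: tuple
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.items), len(self.items)):
            raise ValueError("distance matrix shape does not match items")
        if not np.isfinite(v).all():
            raise ValueError("distances must be finite")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")


class CoexpressionTriple(NamedTuple):
    avg_correlation: float
    extreme_z: float
    rmsd: float


class ValidityResult(NamedTuple):
    value: float
    higher_is_better: bool


def _correlations(expr: ExpressionMatrix) -> np.ndarray:
    values = expr.values
    sds = values.std(axis=1)
    if (sds == 0).any():
        bad = [g for g, sd in zip(expr.genes, sds) if sd == 0]
        raise ValueError(f"zero-variance gene(s): {bad[:5]}")
    return np.corrcoef(values)


def correlation_distance(expr: ExpressionMatrix, absolute: bool = True) -> DistanceMatrix:
    """Distance matrix d = 1 - |r| (Pearson), or (1 - r)/2 when signed
    correlation should keep anti-correlated genes apart."""
    if len(expr.samples) < 3:
        raise ValueError("need at least 3 samples for correlation distances")
    corr = _correlations(expr)
    dist = 1.0 - np.abs(corr) if absolute else (1.0 - corr) / 2.0
    dist = np.clip(dist, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    return DistanceMatrix(tuple(expr.genes), dist)


def _mean_corr_to_modules(gene: str, ms: ModuleSet, expr: ExpressionMatrix, corr: np.ndarray, index: dict) -> np.ndarray:
    gi = index[gene]
    out = np.empty(len(ms))
    for j, m in enumerate(ms):
        members = [index[g] for g in m.genes if g in index and g != gene]
        out[j] = corr[gi, members].mean() if members else -np.inf
    return out


def complete_assignment(ms: ModuleSet, expr: ExpressionMatrix) -> ModuleSet:
    """Assign every unassigned expression gene to the module with the highest
    mean correlation to its members (ties: lowest-index module)."""
    if len(ms) == 0:
        raise ValueError("module set is empty")
    assigned = ms.genes
    unassigned = [g for g in expr.genes if g not in assigned]
    if not unassigned:
        return ms
    corr = _correlations(expr)
    index = {g: i for i, g in enumerate(expr.genes)}
    new_members: dict = {j: set(m.genes) for j, m in enumerate(ms)}
    for g in unassigned:
        means = _mean_corr_to_modules(g, ms, expr, corr, index)
        best = int(np.argmax(means))  # argmax returns the first (lowest) index on ties
        new_members[best].add(g)
    return ModuleSet(
        (ms[j].name, frozenset(new_members[j])) for j in range(len(ms))
    )


def resolve_overlaps(ms: ModuleSet, expr: ExpressionMatrix) -> ModuleSet:
    """Give every multi-module gene a single home: the member module with the
    highest mean correlation to the gene (ties: lowest-index module)."""
    counts: dict = {}
    for m in ms:
        for g in m.genes:
            counts[g] = counts.get(g, 0) + 1
    shared = [g for g, c in counts.items() if c > 1]
    if not shared:
        return ms
    corr = _correlations(expr)
    index = {g: i for i, g in enumerate(expr.genes)}
    membership = {j: set(m.genes) for j, m in enumerate(ms)}
    for g in sorted(shared):
        homes = [j for j, m in enumerate(ms) if g in m.genes]
        means = []
        for j in homes:
            members = [index[x] for x in ms[j].genes if x != g and x in index]
            means.append(corr[index[g], members].mean() if members else -np.inf)
        keep = homes[int(np.argmax(means))]
        for j in homes:
            if j != keep:
                membership[j].discard(g)
    return ModuleSet(
        (ms[j].name, frozenset(membership[j]))
        for j in range(len(ms))
        if membership[j]
    )


def _labels(ms: ModuleSet, items: tuple) -> np.ndarray:
    label: dict = {}
    for j, m in enumerate(ms):
        for g in m.genes:
            if g in label:
                raise ValueError(f"overlapping module set: gene {g!r} in several modules")
            label[g] = j
    missing = [g for g in items if g not in label]
    if missing:
        raise ValueError(
            f"module set is not exhaustive over the distance items (e.g. {missing[:3]}); "
            "run complete_assignment first"
        )
    return np.array([label[g] for g in items])


def _medoids(dist: np.ndarray, labels: np.ndarray) -> dict:
    medoid = {}
    for k in np.unique(labels):
        idx = np.nonzero(labels == k)[0]
        sums = dist[np.ix_(idx, idx)].sum(axis=1)
        medoid[k] = idx[int(np.argmin(sums))]
    return medoid


def cluster_validity(ms: ModuleSet, dist: DistanceMatrix, index: str) -> ValidityResult:
    """Cluster validity index of an exhaustive, non-overlapping module set.

    ``index`` is one of ``silhouette`` (higher better), ``davies_bouldin``
    (lower better; medoid formulation on the distance matrix) or
    ``kim_ramakrishna`` (lower better; under-partition term = mean
    within-cluster mean distance to the medoid, over-partition term =
    K / minimal inter-medoid distance).
    """
    labels = _labels(ms, dist.items)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 modules for a validity index")
    d = dist.values
    if index == "silhouette":
        return ValidityResult(float(silhouette_score(d, labels, metric="precomputed")), True)

    medoid = _medoids(d, labels)
    ks = sorted(medoid)
    scatter = {}
    for k in ks:
        idx = np.nonzero(labels == k)[0]
        scatter[k] = float(d[idx, medoid[k]].mean())
    if index == "davies_bouldin":
        ratios = []
        for i in ks:
            worst = 0.0
            for j in ks:
                if i == j:
                    continue
                sep = d[medoid[i], medoid[j]]
                worst = max(worst, (scatter[i] + scatter[j]) / sep if sep > 0 else np.inf)
            ratios.append(worst)
        return ValidityResult(float(np.mean(ratios)), False)
    if index == "kim_ramakrishna":
        under = float(np.mean([scatter[k] for k in ks]))
        min_sep = min(
            d[medoid[i], medoid[j]] for i in ks for j in ks if i < j
        )
        over = len(ks) / min_sep if min_sep > 0 else np.inf
        return ValidityResult(under + over, False)
    raise ValueError(f"unknown validity index {index!r}")


def coexpression_metrics(module: Iterable, expr: ExpressionMatrix) -> CoexpressionTriple:
    """Average correlation, mean top-5% z-score and profile RMSD of a module."""
    module = sorted(set(module))
    if len(module) < 2:
        raise ValueError("module needs at least 2 genes")
    missing = [g for g in module if g not in set(expr.genes)]
    if missing:
        raise ValueError(f"module gene(s) missing from expression matrix: {missing[:5]}")
    sub = expr.subset_genes(module)
    corr = _correlations(sub)
    iu = np.triu_indices(len(module), k=1)
    avg_corr = float(corr[iu].mean())

    values = sub.values
    z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, ddof=1, keepdims=True)
    k = max(1, math.ceil(0.05 * values.shape[1]))
    top = np.sort(z, axis=1)[:, -k:]
    extreme = float(top.mean())

    sample_mean = z.mean(axis=0, keepdims=True)
    rmsd = float(np.sqrt(np.mean((z - sample_mean) ** 2)))
    return CoexpressionTriple(avg_correlation=avg_corr, extreme_z=extreme, rmsd=rmsd)


_METRICS: dict = {
    "avg_correlation": lambda genes, expr: coexpression_metrics(genes, expr).avg_correlation,
    "extreme_z": lambda genes, expr: coexpression_metrics(genes, expr).extreme_z,
    "rmsd": lambda genes, expr: -coexpression_metrics(genes, expr).rmsd,  # lower rmsd = better
}


def permuted_metric_test(
    ms: ModuleSet,
    expr: ExpressionMatrix,
    metric="avg_correlation",
    n_perm: int = 100,
    seed: int = 0,
) -> tuple:
    """Compare a per-module co-expression metric against permuted modules.

    Permuted modules replace genes through random bijections of the
    expression genes (structure preserved, assignment destroyed). Returns
    (median difference real - permuted, two-sided rank-sum p). ``metric`` is
    a name from {avg_correlation, extreme_z, rmsd} (rmsd is sign-flipped so
    larger is always better) or a callable (genes, expr) -> float.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    fn: Callable = _METRICS[metric] if isinstance(metric, str) else metric
    real = [fn(m.genes, expr) for m in ms]
    rng = np.random.default_rng(seed)
    genes = np.asarray(expr.genes, dtype=object)
    permuted = []
    for _ in range(n_perm):
        image = rng.permutation(genes)
        mapping = dict(zip(genes, image))
        for m in ms:
            permuted.append(fn([mapping[g] for g in m.genes], expr))
    median_diff = float(np.median(real) - np.median(permuted))
    stat = mannwhitneyu(real, permuted, alternative="two-sided")
    return median_diff, float(stat.pvalue)
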
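"""Reference module detectors.

The framework evaluates *external* detectors through the callable contract
``detector(expr, params) -> ModuleSet``. The two detectors here are small,
deterministic reference implementations used by the examples, the test
harness and sensitivity analyses — a correlation-graph + Markov-clustering
detector and a k-means detector. They are not meant to compete with
dedicated module detection software.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans

from .gold_standard import interconnected_modules
from .io import ExpressionMatrix, ModuleSet, RegulatoryNetwork

__all__ = ["correlation_mcl_detector", "kmeans_detector"]


def correlation_mcl_detector(expr: ExpressionMatrix, params: dict) -> ModuleSet:
    """Threshold the absolute-correlation graph at ``r_cutoff`` and cluster
    it with MCL at ``inflation``. Genes with no strong partner end up in
    singleton modules (dropped by the usual size filters)."""
    r_cutoff = float(params.get("r_cutoff", 0.9))
    inflation = float(params.get("inflation", 2.0))
    values = expr.values
    sds = values.std(axis=1)
    keep = sds > 0
    corr = np.corrcoef(values[keep])
    genes = [g for g, k in zip(expr.genes, keep) if k]
    iu, ju = np.nonzero(np.triu(np.abs(corr) >= r_cutoff, k=1))
    edges = {(genes[i], genes[j]): None for i, j in zip(iu, ju)}
    if not edges:
        return ModuleSet([])
    return interconnected_modules(RegulatoryNetwork(edges), inflation)


def kmeans_detector(expr: ExpressionMatrix, params: dict) -> ModuleSet:
    """K-means on gene-standardized profiles; ``k`` clusters, seeded via
    ``seed`` (default 0). Deliberately parameter-sensitive: the score depends
    strongly on whether ``k`` matches the planted module count."""
    k = int(params.get("k", 8))
    seed = int(params.get("seed", 0))
    values = expr.values
    sds = values.std(axis=1, keepdims=True)
    sds[sds == 0] = 1.0
    z = (values - values.mean(axis=1, keepdims=True)) / sds
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(z)
    genes = np.asarray(expr.genes, dtype=object)
    return ModuleSet(
        (f"k{lab}", frozenset(genes[labels == lab]))
        for lab in range(k)
        if (labels == lab).any()
    )
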
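"""Overlap-aware comparison scores between known and observed module sets.

Classical clustering-comparison scores (Rand index, NMI, F1 between
partitions) assume disjoint, exhaustive clusterings and break down on module
sets that overlap or leave genes unassigned. This module implements four
scores that do handle both:

* **precision / recall** (CICE-BCubed) — gene-pair-centric: for every gene
  pair sharing a module, compares how many modules of each set the pair
  shares, weighted by a module-matching term Phi; reaches 1 only when the two
  overlapping clusterings are identical.
* **relevance / recovery** — module-centric best-match Jaccard, averaged over
  observed modules (relevance) or known modules (recovery).

With ``G`` the genes, ``M`` known and ``M'`` observed modules, ``M(g)`` the
modules containing ``g`` and ``E(g, M)`` the genes sharing at least one
module of ``M`` with ``g`` (including ``g`` itself)::

    Precision = 1/|G_P| sum_{g in G_P} 1/|E(g,M')| sum_{g' in E(g,M')}
                min(|M'(g) n M'(g')|, |M(g) n M(g')|) * Phi(g,g')
                / |M'(g) n M'(g')|

    Phi(g,g') = mean_{m' in M'(g,g')} max_{m in M(g,g')} Jaccard(m', m)

where ``M(g,g')`` are the modules containing both genes, and ``G_P`` the
genes covered by at least one observed module (the outer average cannot be
taken over genes with ``M'(g)`` empty). Recall swaps ``M`` and ``M'``.
Subset variants (precision*/recall*) restrict the outer average to a chosen
gene subset, e.g. genes in exactly one vs several known modules, to probe
how well a method handles overlap.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np

from .io import Module, ModuleSet

__all__ = [
    "ScorePair",
    "MatchPair",
    "jaccard",
    "restrict_observed",
    "cice_pair_scores",
    "match_scores",
    "subset_pair_scores",
    "harmonic_composite",
    "raw_scores",
]


class ScorePair(NamedTuple):
    precision: float
    recall: float


class MatchPair(NamedTuple):
    recovery: float
    relevance: float


def jaccard(a: Iterable, b: Iterable) -> float:
    """|a n b| / |a u b|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def restrict_observed(observed: ModuleSet, universe: Iterable, min_size: int = 5) -> ModuleSet:
    """Prepare observed modules for scoring against a gold standard.

    Genes absent from the gold-standard universe are removed from every
    observed module (they cannot be judged: most belong to modules the gold
    standard simply does not know), then modules smaller than ``min_size``
    are dropped.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    kept = []
    for m in observed:
        genes = m.genes & universe
        if len(genes) >= min_size:
            kept.append(Module(m.name, genes))
    return ModuleSet(kept)


def _module_jaccard_matrix(a: ModuleSet, b: ModuleSet) -> np.ndarray:
    """len(a) x len(b) matrix of pairwise module Jaccard indices."""
    genes = sorted(a.genes | b.genes)
    ia = a.indicator(genes).astype(np.float64)
    ib = b.indicator(genes).astype(np.float64)
    inter = ia.T @ ib
    sizes_a = ia.sum(axis=0)[:, None]
    sizes_b = ib.sum(axis=0)[None, :]
    union = sizes_a + sizes_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def _bcubed_one_sided(known: ModuleSet, observed: ModuleSet, subset=None) -> float:
    """The precision side of the CICE-BCubed score; recall = swapped call.

    ``subset`` restricts (and renormalizes) the outer average to the given
    genes; inner sums still run over the full neighbourhood E(g, M').
    """
    if len(known) == 0 or len(observed) == 0:
        raise ValueError("both module sets must be non-empty")
    genes = sorted(known.genes | observed.genes)
    index = {g: i for i, g in enumerate(genes)}
    bk = known.indicator(genes)
    bo = observed.indicator(genes)
    co_known = (bk.astype(np.int64)) @ bk.T.astype(np.int64)
    co_obs = (bo.astype(np.int64)) @ bo.T.astype(np.int64)
    jac = _module_jaccard_matrix(observed, known)  # rows: observed, cols: known

    if subset is not None:
        subset = frozenset(subset)
        if not subset:
            raise ValueError("subset must be non-empty")
        population = [index[g] for g in genes if g in subset]
    else:
        population = [i for i in range(len(genes)) if bo[i].any()]
    if not population:
        raise ValueError("no gene to average over")

    total = 0.0
    for gi in population:
        if not bo[gi].any():
            continue  # no observed module: contributes 0 to a subset average
        neighbours = np.nonzero(co_obs[gi])[0]
        denom = co_obs[gi, neighbours].astype(float)
        minv = np.minimum(denom, co_known[gi, neighbours].astype(float))
        acc = 0.0
        rows_g = bo[gi]
        cols_g = bk[gi]
        for gj, mn, dn in zip(neighbours, minv, denom):
            if mn == 0:
                continue
            rows = rows_g & bo[gj]
            cols = cols_g & bk[gj]
            sub = jac[np.ix_(rows, cols)]
            phi = float(sub.max(axis=1).mean()) if sub.size else 0.0
            acc += mn * phi / dn
        total += acc / len(neighbours)
    return float(total / len(population))


def cice_pair_scores(known: ModuleSet, observed: ModuleSet) -> ScorePair:
    """CICE-BCubed precision and recall between known and observed modules."""
    return ScorePair(
        precision=_bcubed_one_sided(known, observed),
        recall=_bcubed_one_sided(observed, known),
    )


def subset_pair_scores(known: ModuleSet, observed: ModuleSet, subset: Iterable) -> ScorePair:
    """Precision*/recall*: the pair scores with the outer average restricted
    to ``subset`` (e.g. genes belonging to exactly one known module)."""
    subset = frozenset(subset)
    return ScorePair(
        precision=_bcubed_one_sided(known, observed, subset=subset),
        recall=_bcubed_one_sided(observed, known, subset=subset),
    )


def match_scores(known: ModuleSet, observed: ModuleSet) -> MatchPair:
    """Recovery and relevance: best-match Jaccard averaged over known
    (recovery) or observed (relevance) modules."""
    if len(known) == 0 or len(observed) == 0:
        raise ValueError("both module sets must be non-empty")
    jac = _module_jaccard_matrix(observed, known)
    return MatchPair(
        recovery=float(jac.max(axis=0).mean()),
        relevance=float(jac.max(axis=1).mean()),
    )


def raw_scores(known: ModuleSet, observed: ModuleSet) -> dict:
    """All four raw scores as a dict: recovery, relevance, recall, precision."""
    pair = cice_pair_scores(known, observed)
    match = match_scores(known, observed)
    return {
        "recovery": match.recovery,
        "relevance": match.relevance,
        "recall": pair.recall,
        "precision": pair.precision,
    }


def harmonic_composite(values: Iterable) -> float:
    """Harmonic mean; 0 if any value is 0 (its limit)."""
    values = [float(v) for v in values]
    if not values:
        raise ValueError("harmonic_composite needs at least one value")
    if any(v < 0 for v in values):
        raise ValueError("values must be non-negative")
    if any(v == 0 for v in values):
        return 0.0
    return len(values) / sum(1.0 / v for v in values)
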
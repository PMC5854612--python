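"""Enrichment-based scoring of observed modules.

Where a regulatory gold standard is too noisy for direct module comparison
(typically human data), modules are scored by how well they cover the
targets of known regulators: every (regulator, module) pair gets a
right-tailed Fisher's exact test and an odds ratio; per regulator the best
enrichment across modules is kept and summarized over all regulators with
the **aucodds** curve — the area under the fraction-of-regulators-with-OR-
above-cutoff curve, integrated over log10 cutoffs between 1 and 1000-fold
enrichment.

The same machinery drives two annotation-based quality measures used for
automatic parameter estimation: **F-aucodds** (harmonic mean of aucodds in
the gene-set and in the module dimension) and the **biological homogeneity
index** (fraction of intra-module gene pairs sharing a functional class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import ModuleSet

__all__ = [
    "EnrichmentResult",
    "GeneSetCollection",
    "WeightedRegulonCollection",
    "fisher_enrichment",
    "holm_sidak",
    "aucodds",
    "regulator_coverage_score",
    "filter_redundant_genesets",
    "faucodds",
    "bhi",
    "read_regulons",
]


class EnrichmentResult(NamedTuple):
    p_value: float
    odds_ratio: float
    table: tuple  # ((a, b), (c, d))


@dataclass
class GeneSetCollection:
    """Ordered (name, gene set) pairs — functional classes (GO/KEGG-like)."""

    sets: list  # list of (name, frozenset)

    def __post_init__(self):
        names = [n for n, _ in self.sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene-set names")
        self.sets = [(n, frozenset(s)) for n, s in self.sets]
        if any(not s for _, s in self.sets):
            raise ValueError("empty gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    @classmethod
    def from_moduleset(cls, ms: ModuleSet) -> "GeneSetCollection":
        return cls([(m.name, m.genes) for m in ms])


@dataclass
class WeightedRegulonCollection:
    """Per-context, per-regulator weighted target lists.

    ``entries`` maps (context, regulator) to a list of (target, weight>0)
    pairs, e.g. regulator->target confidence weights estimated separately in
    many tissue or cell-type contexts.
    """

    entries: dict = field(default_factory=dict)

    def __post_init__(self):
        for (ctx, reg), targets in self.entries.items():
            for t, w in targets:
                if not (np.isfinite(w) and w > 0):
                    raise ValueError(f"weight for {ctx}/{reg}->{t} must be finite and > 0")

    @property
    def contexts(self) -> list:
        return sorted({ctx for ctx, _ in self.entries})

    @property
    def regulators(self) -> list:
        return sorted({reg for _, reg in self.entries})

    def all_weights(self) -> np.ndarray:
        return np.array([w for targets in self.entries.values() for _, w in targets])

    @classmethod
    def single_context(cls, regulons: dict, context: str = "all") -> "WeightedRegulonCollection":
        """Wrap unweighted {regulator: targets} regulons as one context with
        unit weights."""
        entries = {
            (context, reg): [(t, 1.0) for t in sorted(targets)]
            for reg, targets in regulons.items()
        }
        return cls(entries)


def read_regulons(path) -> WeightedRegulonCollection:
    """Read a TSV with columns context, regulator, target, weight ('#' comments)."""
    entries: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            ctx, reg, tgt, w = fields
            entries.setdefault((ctx, reg), []).append((tgt, float(w)))
    return WeightedRegulonCollection(entries)


def fisher_enrichment(module: Iterable, geneset: Iterable, universe: Iterable) -> EnrichmentResult:
    """Right-tailed Fisher's exact test of module x gene-set overlap.

    p = P(X >= overlap) under the hypergeometric null; the odds ratio is
    (a*d)/(b*c) from the 2x2 table, with a Haldane +0.5 added to every cell
    when any cell is zero (OR only, never the p-value).
    """
    module, geneset, universe = frozenset(module), frozenset(geneset), frozenset(universe)
    if len(universe) < 2:
        raise ValueError("universe must have at least 2 genes")
    if not module <= universe or not geneset <= universe:
        raise ValueError("module and geneset must be subsets of the universe")
    a = len(module & geneset)
    b = len(module - geneset)
    c = len(geneset - module)
    d = len(universe) - a - b - c
    p = float(hypergeom.sf(a - 1, len(universe), len(geneset), len(module)))
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(p_value=min(p, 1.0), odds_ratio=float(odds), table=((a, b), (c, d)))


def holm_sidak(pvalues: Sequence) -> list:
    """Holm–Šídák step-down multiple-testing correction, input order kept."""
    pvalues = list(pvalues)
    if not pvalues:
        return []
    arr = np.asarray(pvalues, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # p == 1 hits log1p(-1) internally
        _, adjusted, _, _ = multipletests(arr, method="holm-sidak")
    return [float(p) for p in adjusted]


def aucodds(odds_ratios: Sequence, lo: float = 1.0, hi: float = 1000.0) -> float:
    """Area under the fraction-of-items-with-OR >= cutoff curve over log10
    cutoffs in [lo, hi], normalized to [0, 1].

    Closed form: the step curve integrates to the mean of
    log10(clip(OR, lo, hi)) - log10(lo), divided by the interval width.
    """
    odds_ratios = np.asarray(list(odds_ratios), dtype=float)
    if odds_ratios.size == 0:
        raise ValueError("aucodds needs at least one odds ratio")
    if not lo < hi:
        raise ValueError("lo must be < hi")
    if (odds_ratios < 0).any():
        raise ValueError("odds ratios must be non-negative")
    clipped = np.clip(odds_ratios, lo, hi)
    width = np.log10(hi) - np.log10(lo)
    return float(np.mean(np.log10(clipped) - np.log10(lo)) / width)


def regulator_coverage_score(
    observed: ModuleSet,
    regulons: WeightedRegulonCollection,
    universe: Iterable,
    p_cutoff: float = 0.1,
    weight_cutoffs: Sequence | None = None,
    lo: float = 1.0,
    hi: float = 1000.0,
) -> float:
    """How well observed modules cover regulator targets (aucodds score).

    Per weight cutoff: threshold every regulon's weighted targets; for each
    (regulator, context) test every module (Fisher), Holm–Šídák-correct
    within that family; per (regulator, module) keep the context with the
    minimal corrected p and its odds ratio; per regulator take the maximal
    odds ratio among modules with corrected p < ``p_cutoff`` (1 if none);
    aucodds over regulators. The final score averages over the weight
    cutoffs (default: deciles of the positive weight distribution).
    """
    if len(observed) == 0:
        raise ValueError("observed module set is empty")
    universe = frozenset(universe)
    if weight_cutoffs is None:
        weights = regulons.all_weights()
        if weights.size == 0:
            raise ValueError("regulon collection is empty")
        weight_cutoffs = np.unique(np.quantile(weights, np.arange(0.0, 1.0, 0.1)))

    module_sets = [(m.genes & universe) for m in observed]
    scores = []
    for cutoff in weight_cutoffs:
        # regulator -> list over (context, module) of (corrected p, OR)
        per_pair: dict = {}
        for (ctx, reg), targets in regulons.entries.items():
            tset = frozenset(t for t, w in targets if w >= cutoff) & universe
            if not tset:
                continue
            results = [
                fisher_enrichment(mod, tset, universe) if mod else EnrichmentResult(1.0, 1.0, ((0, 0), (0, 0)))
                for mod in module_sets
            ]
            corrected = holm_sidak([r.p_value for r in results])
            for j, (r, p_adj) in enumerate(zip(results, corrected)):
                key = (reg, j)
                prev = per_pair.get(key)
                if prev is None or p_adj < prev[0]:
                    per_pair[key] = (p_adj, r.odds_ratio)
        regulators = sorted({reg for reg, _ in per_pair})
        if not regulators:
            continue
        best_or = []
        for reg in regulators:
            ors = [
                orv
                for (r, _), (p_adj, orv) in per_pair.items()
                if r == reg and p_adj < p_cutoff
            ]
            best_or.append(max(ors) if ors else lo)
        scores.append(aucodds(best_or, lo=lo, hi=hi))
    if not scores:
        raise ValueError("no regulator has any target inside the universe")
    return float(np.mean(scores))


def filter_redundant_genesets(gs: GeneSetCollection, max_jaccard: float = 0.7) -> GeneSetCollection:
    """Drop gene sets overlapping too strongly (Jaccard > ``max_jaccard``)
    with a larger, already-retained set; iterates in decreasing size order."""
    if not (0 < max_jaccard <= 1):
        raise ValueError("max_jaccard must be in (0, 1]")
    order = sorted(range(len(gs.sets)), key=lambda i: (-len(gs.sets[i][1]), i))
    kept_idx: list = []
    for i in order:
        _, genes = gs.sets[i]
        redundant = False
        for j in kept_idx:
            other = gs.sets[j][1]
            if len(genes & other) / len(genes | other) > max_jaccard:
                redundant = True
                break
        if not redundant:
            kept_idx.append(i)
    kept_idx.sort()
    return GeneSetCollection([gs.sets[i] for i in kept_idx])


def _best_or_matrix(
    observed: ModuleSet, gs: GeneSetCollection, universe: frozenset
) -> tuple:
    """Per-(module, geneset) odds ratios and corrected p-values.

    Correction families follow the comparison direction: across modules for
    each gene set, and across gene sets for each module.
    """
    module_sets = [m.genes & universe for m in observed]
    set_sets = [s & universe for _, s in gs]
    n_mod, n_set = len(module_sets), len(set_sets)
    pvals = np.ones((n_mod, n_set))
    ors = np.ones((n_mod, n_set))
    for i, mod in enumerate(module_sets):
        for j, s in enumerate(set_sets):
            if mod and s:
                res = fisher_enrichment(mod, s, universe)
                pvals[i, j] = res.p_value
                ors[i, j] = res.odds_ratio
    p_by_set = np.column_stack([holm_sidak(pvals[:, j]) for j in range(n_set)])
    p_by_mod = np.vstack([holm_sidak(pvals[i, :]) for i in range(n_mod)])
    return ors, p_by_set, p_by_mod


def faucodds(
    observed: ModuleSet,
    gs: GeneSetCollection,
    universe: Iterable,
    p_cutoff: float = 0.1,
    lo: float = 1.0,
    hi: float = 1000.0,
) -> float:
    """Harmonic mean of aucodds in the gene-set dimension (are all functional
    sets covered by some module?) and the module dimension (is every module
    enriched in some set?). Used to pick detector parameters from functional
    annotations alone."""
    if len(gs) == 0:
        raise ValueError("gene-set collection is empty")
    universe = frozenset(universe)
    ors, p_by_set, p_by_mod = _best_or_matrix(observed, gs, universe)
    set_best = [
        max((ors[i, j] for i in range(ors.shape[0]) if p_by_set[i, j] < p_cutoff), default=lo)
        for j in range(ors.shape[1])
    ]
    mod_best = [
        max((ors[i, j] for j in range(ors.shape[1]) if p_by_mod[i, j] < p_cutoff), default=lo)
        for i in range(ors.shape[0])
    ]
    a_sets = aucodds(set_best, lo=lo, hi=hi)
    a_mods = aucodds(mod_best, lo=lo, hi=hi)
    if a_sets == 0 or a_mods == 0:
        return 0.0
    return 2.0 * a_sets * a_mods / (a_sets + a_mods)


def bhi(observed: ModuleSet, gs: GeneSetCollection) -> float:
    """Biological homogeneity index: fraction of annotated intra-module gene
    pairs sharing at least one functional class, averaged per module and
    then over modules (modules without an annotated pair are skipped)."""
    if len(observed) == 0:
        raise ValueError("observed module set is empty")
    annotation: dict = {}
    for k, (_, genes) in enumerate(gs):
        for g in genes:
            annotation.setdefault(g, set()).add(k)
    per_module = []
    for m in observed:
        genes = [g for g in sorted(m.genes) if g in annotation]
        n_pairs = 0
        n_shared = 0
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                n_pairs += 1
                if annotation[genes[i]] & annotation[genes[j]]:
                    n_shared += 1
        if n_pairs:
            per_module.append(n_shared / n_pairs)
    if not per_module:
        raise ValueError("no module contains an annotated gene pair")
    return float(np.mean(per_module))
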
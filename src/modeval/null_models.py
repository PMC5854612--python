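"""Permutation null models and score normalization.

Raw agreement scores depend strongly on the structure of the known modules
(their number, sizes and overlap): a trivial module structure is easy to hit
by chance. Every raw score is therefore divided by its mean over permuted
versions of the known modules — the genes of the dataset are mapped through
a random bijection, which preserves module number, sizes and the full
overlap structure while destroying the assignment. The normalized score is
a *fold improvement over permuted known modules*; the four normalized scores
are combined with a harmonic mean into one composite.

A degree-preserving random rewiring of directed networks (the "sticky"
model, with separate stickiness indices for incoming and outgoing edges) is
provided as an alternative null for network-derived gold standards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable

import numpy as np

from .io import Module, ModuleSet, RegulatoryNetwork
from .scores import harmonic_composite, raw_scores

__all__ = [
    "ScoreReport",
    "NullDistribution",
    "permute_moduleset",
    "normalized_scores",
    "sticky_rewire",
]

SCORE_NAMES = ("recovery", "relevance", "recall", "precision")


@dataclass(frozen=True)
class NullDistribution:
    score: str
    values: tuple

    @property
    def mean(self) -> float:
        return fmean(self.values)

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


@dataclass(frozen=True)
class ScoreReport:
    """Raw, null-mean and normalized versions of the four scores, plus the
    harmonic-mean composite."""

    raw: dict
    null_means: dict
    normalized: dict
    composite: float
    n_permutations: int
    seed: int
    nulls: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "raw": dict(self.raw),
            "null_means": dict(self.null_means),
            "normalized": dict(self.normalized),
            "composite": self.composite,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def permute_moduleset(ms: ModuleSet, universe: Iterable, seed: int) -> ModuleSet:
    """Relabel every gene through one uniform random bijection of the universe.

    Module count, sizes and all pairwise intersection sizes are preserved
    exactly; only the gene assignment changes.
    """
    universe = sorted(set(universe))
    missing = ms.genes - set(universe)
    if missing:
        raise ValueError(f"universe is missing {len(missing)} module genes, e.g. {sorted(missing)[:3]}")
    rng = np.random.default_rng(seed)
    image = list(rng.permutation(universe))
    mapping = dict(zip(universe, image))
    return ModuleSet(
        (Module(m.name, frozenset(mapping[g] for g in m.genes)) for m in ms),
        universe=universe,
    )


def normalized_scores(
    known: ModuleSet,
    observed: ModuleSet,
    universe: Iterable,
    n_perm: int = 500,
    seed: int = 0,
) -> ScoreReport:
    """Raw scores divided by their mean over ``n_perm`` permutations of the
    known modules (observed fixed); composite = harmonic mean of the four
    normalized scores."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = sorted(set(universe))
    raw = raw_scores(known, observed)

    rng = np.random.default_rng(seed)
    perm_seeds = rng.integers(0, 2**31 - 1, size=n_perm)
    nulls: dict = {name: [] for name in SCORE_NAMES}
    for ps in perm_seeds:
        permuted = permute_moduleset(known, universe, int(ps))
        for name, value in raw_scores(permuted, observed).items():
            nulls[name].append(value)

    null_means = {name: fmean(vals) for name, vals in nulls.items()}
    for name, mean in null_means.items():
        if mean == 0:
            raise ValueError(
                f"null mean of {name} is 0; enlarge the universe or use more permutations"
            )
    normalized = {name: raw[name] / null_means[name] for name in SCORE_NAMES}
    return ScoreReport(
        raw=raw,
        null_means=null_means,
        normalized=normalized,
        composite=harmonic_composite(normalized.values()),
        n_permutations=n_perm,
        seed=seed,
        nulls={name: NullDistribution(name, tuple(vals)) for name, vals in nulls.items()},
    )


def sticky_rewire(net: RegulatoryNetwork, seed: int) -> RegulatoryNetwork:
    """Degree-sequence-preserving random directed network.

    Each potential edge (r, t) is drawn independently with probability
    min(1, s_out(r) * s_in(t)), where s_out(r) = outdeg(r)/sqrt(|E|) and
    s_in(t) = indeg(t)/sqrt(|E|); in- and out-degree sequences are preserved
    in expectation.
    """
    if len(net) == 0:
        return RegulatoryNetwork({})
    nodes = sorted(net.nodes)
    outdeg = {n: 0 for n in nodes}
    indeg = {n: 0 for n in nodes}
    for r, t in net.edges:
        outdeg[r] += 1
        indeg[t] += 1
    sqrt_e = np.sqrt(len(net))
    s_out = np.array([outdeg[n] for n in nodes]) / sqrt_e
    s_in = np.array([indeg[n] for n in nodes]) / sqrt_e
    probs = np.minimum(1.0, np.outer(s_out, s_in))
    rng = np.random.default_rng(seed)
    draws = rng.random(probs.shape) < probs
    edges = {
        (nodes[i], nodes[j]): None
        for i, j in np.argwhere(draws)
    }
    return RegulatoryNetwork(edges)
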
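"""Known-module ("gold standard") derivation from regulatory networks.

Three module definitions turn a trusted regulator->target network into sets
of known co-regulated modules:

* **minimal co-regulation** — genes sharing at least one regulator; one
  (possibly overlapping) module per regulator, i.e. its regulon.
* **strict co-regulation** — genes regulated by exactly the same regulator
  set; a partition of the regulated genes.
* **interconnected modules** — strongly interconnected genes found by Markov
  clustering (MCL) of the network graph; the inflation parameter controls
  cluster granularity (typical settings: 2, 10, 50).

Derived module sets are then cleaned with :func:`filter_modules`: strongly
overlapping modules (Jaccard above 0.8) are merged and small modules
(fewer than 5 genes) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Module, ModuleSet, RegulatoryNetwork

__all__ = [
    "ModuleDefinition",
    "minimal_coregulation",
    "strict_coregulation",
    "interconnected_modules",
    "threshold_weighted_network",
    "filter_modules",
    "derive_modules",
]

_KINDS = ("minimal_coregulation", "strict_coregulation", "interconnected")


@dataclass(frozen=True)
class ModuleDefinition:
    """Which definition to apply, plus its parameters (e.g. MCL inflation)."""

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown module definition {self.kind!r}; choose from {_KINDS}")
        inflation = self.params.get("inflation")
        if inflation is not None and inflation <= 1:
            raise ValueError("MCL inflation must be > 1")


def minimal_coregulation(net: RegulatoryNetwork) -> ModuleSet:
    """One module per regulator: its full target set. Modules may overlap."""
    if len(net) == 0:
        raise ValueError("network has no edges")
    modules = []
    seen = set()
    for r, t in net.edges:  # preserve first-appearance order of regulators
        if r not in seen:
            seen.add(r)
            modules.append((r, frozenset(net.regulons()[r])))
    return ModuleSet(modules)


def strict_coregulation(net: RegulatoryNetwork) -> ModuleSet:
    """Group genes by identical incoming-regulator sets; a disjoint partition
    of all regulated genes. Genes with no regulator are excluded."""
    if len(net) == 0:
        raise ValueError("network has no edges")
    incoming: dict = {}
    for r, t in net.edges:
        incoming.setdefault(t, set()).add(r)
    groups: dict = {}
    for t, regs in incoming.items():
        groups.setdefault(frozenset(regs), set()).add(t)
    modules = []
    for i, key in enumerate(sorted(groups, key=lambda k: tuple(sorted(k)))):
        name = "+".join(sorted(key))
        modules.append((name, frozenset(groups[key])))
    return ModuleSet(modules)


def interconnected_modules(
    net: RegulatoryNetwork,
    inflation: float = 2.0,
    *,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune: float = 1e-8,
) -> ModuleSet:
    """Markov clustering of the (symmetrized, self-looped) network graph.

    The adjacency matrix is symmetrized with max(A, A^T), unit self-loops are
    added, and columns are normalized to a stochastic matrix. Expansion
    (matrix square) and inflation (elementwise power followed by column
    renormalization) alternate until the matrix is stable; clusters are read
    from the attractor rows. Attractors appearing in several rows can yield
    overlapping clusters; those are kept.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if len(net) == 0:
        raise ValueError("network has no edges")
    nodes = sorted(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for (r, t), w in net.edges.items():
        val = 1.0 if w is None else float(w)
        a[index[r], index[t]] = max(a[index[r], index[t]], val)
    a = np.maximum(a, a.T)
    np.fill_diagonal(a, np.maximum(a.diagonal(), 1.0))
    m = a / a.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        residual = np.abs(inflated - m).max()
        m = inflated
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"MCL did not converge after {max_iter} iterations (residual {residual:.3g})"
        )

    # attractors: nodes with mass on their own diagonal
    clusters = []
    for i in range(n):
        if m[i, i] > prune:
            members = frozenset(nodes[j] for j in np.nonzero(m[i] > prune)[0])
            if members not in clusters:
                clusters.append(members)
    # nodes attracted by no attractor row (numerical corner): own singleton
    covered = set().union(*clusters) if clusters else set()
    for node in nodes:
        if node not in covered:
            clusters.append(frozenset([node]))
    clusters.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return ModuleSet((f"mcl_{i + 1}", c) for i, c in enumerate(clusters))


def threshold_weighted_network(net: RegulatoryNetwork, cutoff: float) -> RegulatoryNetwork:
    """Convert a weighted network (e.g. a network-inference ranking) to an
    unweighted one by keeping edges with weight >= cutoff."""
    if not net.is_weighted:
        raise ValueError("threshold_weighted_network requires a fully weighted network")
    return RegulatoryNetwork({(r, t): None for (r, t), w in net.edges.items() if w >= cutoff})


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def filter_modules(
    ms: ModuleSet,
    merge_jaccard: float = 0.8,
    min_size: int = 5,
    universe=None,
) -> ModuleSet:
    """Clean a module set: restrict to a universe, merge strongly overlapping
    modules, drop small ones.

    Merging is iterative: while some pair has Jaccard > ``merge_jaccard``, the
    highest-Jaccard pair (ties by module-name pair) is replaced by its union.
    Output is ordered by descending size, ties by name.
    """
    if not (0 < merge_jaccard <= 1):
        raise ValueError("merge_jaccard must be in (0, 1]")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")

    mods: list = []
    for m in ms:
        genes = m.genes & frozenset(universe) if universe is not None else m.genes
        if genes:
            mods.append(Module(m.name, genes))

    while True:
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                jac = _jaccard(mods[i].genes, mods[j].genes)
                if jac > merge_jaccard:
                    key = (-jac, tuple(sorted((mods[i].name, mods[j].name))))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        a, b = mods[i], mods[j]
        merged = Module("+".join(sorted((a.name, b.name))), a.genes | b.genes)
        mods = [m for k, m in enumerate(mods) if k not in (i, j)] + [merged]

    mods = [m for m in mods if len(m) >= min_size]
    mods.sort(key=lambda m: (-len(m), m.name))
    return ModuleSet(mods)


def derive_modules(
    net: RegulatoryNetwork,
    definition: ModuleDefinition,
    *,
    merge_jaccard: float = 0.8,
    min_size: int = 5,
    universe=None,
) -> ModuleSet:
    """Apply a module definition and the standard filtering in one call."""
    if definition.kind == "minimal_coregulation":
        ms = minimal_coregulation(net)
    elif definition.kind == "strict_coregulation":
        ms = strict_coregulation(net)
    else:
        ms = interconnected_modules(net, float(definition.params.get("inflation", 2.0)))
    return filter_modules(ms, merge_jaccard=merge_jaccard, min_size=min_size, universe=universe)
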
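"""Synthetic gold standards and expression data with planted modules.

A lightweight linear-activity generator stands in for full kinetic network
simulation: each regulator gets a regulon (with a controllable fraction of
genes shared between regulons, creating genuinely overlapping modules), each
module an activity profile across samples, and each gene the sum of the
activities of the modules containing it plus Gaussian noise. Modules can be
*global* (active in every sample) or *local* (activity restricted to a
random subset of samples — local co-expression present in only part of the
compendium). Background genes carry pure noise so scoring paths that
restrict to the gold-standard universe are exercised.

Everything is bit-reproducible from ``SyntheticConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .gold_standard import minimal_coregulation
from .io import ExpressionMatrix, Module, ModuleSet, RegulatoryNetwork

__all__ = ["SyntheticConfig", "generate_gold_standard", "simulate_expression", "degrade_modules"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults plant 10 regulons of 20 genes with 20% of each regulon shared
    with others, half as many background genes as module genes, 100 samples,
    a fifth of the modules only locally co-expressed (active in 30% of
    samples), and noise at half the unit activity scale.
    """

    n_regulators: int = 10
    targets_per_regulator: int = 20
    overlap_fraction: float = 0.2
    n_background_genes: int = 100
    n_samples: int = 100
    local_fraction: float = 0.2
    active_sample_fraction: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_regulators < 1 or self.targets_per_regulator < 1 or self.n_samples < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0 <= self.local_fraction <= 1:
            raise ValueError("local_fraction must be in [0, 1]")
        if not 0 < self.active_sample_fraction <= 1:
            raise ValueError("active_sample_fraction must be in (0, 1]")
        if self.noise_sd < 0 or self.n_background_genes < 0:
            raise ValueError("noise_sd and n_background_genes must be non-negative")


def generate_gold_standard(cfg: SyntheticConfig):
    """Build a regulator->target network with planted, possibly overlapping
    regulons; known modules are its minimal-coregulation modules.

    Returns (RegulatoryNetwork, ModuleSet). Each regulon consists of its own
    genes plus ``round(overlap_fraction * size)`` genes borrowed from other
    regulons' own pools.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n_shared = round(cfg.overlap_fraction * cfg.targets_per_regulator)
    n_own = cfg.targets_per_regulator - n_shared
    if n_own < 1:
        raise ValueError("overlap_fraction too high: every regulon needs >=1 own gene")
    if n_shared > 0 and cfg.n_regulators < 2:
        raise ValueError("overlap needs at least 2 regulators")

    own: dict = {}
    gene_counter = 0
    for i in range(cfg.n_regulators):
        own[i] = [f"g{gene_counter + k:04d}" for k in range(n_own)]
        gene_counter += n_own

    edges: dict = {}
    for i in range(cfg.n_regulators):
        reg = f"R{i + 1:02d}"
        targets = list(own[i])
        if n_shared:
            pool = sorted(g for j, genes in own.items() if j != i for g in genes)
            if len(pool) < n_shared:
                raise ValueError("not enough genes in other regulons to share")
            targets += list(rng.choice(pool, size=n_shared, replace=False))
        for t in targets:
            edges[(reg, t)] = None
    net = RegulatoryNetwork(edges)
    return net, minimal_coregulation(net)


def simulate_expression(modules: ModuleSet, cfg: SyntheticConfig) -> ExpressionMatrix:
    """Linear module-activity expression: gene value = sum of activities of
    the modules containing it (+ noise); background genes are pure noise.

    Per module and sample the activity is standard normal; a
    ``local_fraction`` of the modules is active only in a random
    ``active_sample_fraction`` subset of samples (zero activity elsewhere).
    """
    if len(modules) == 0:
        raise ValueError("module set is empty")
    if cfg.n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng([cfg.seed, 1])
    module_genes = sorted(modules.genes)
    background = [f"bg{k:04d}" for k in range(cfg.n_background_genes)]
    genes = module_genes + background
    samples = [f"s{k:03d}" for k in range(cfg.n_samples)]

    n_mod = len(modules)
    activity = rng.standard_normal((n_mod, cfg.n_samples))
    n_local = round(cfg.local_fraction * n_mod)
    local_idx = rng.choice(n_mod, size=n_local, replace=False) if n_local else np.array([], dtype=int)
    n_active = max(1, round(cfg.active_sample_fraction * cfg.n_samples))
    for j in local_idx:
        active = rng.choice(cfg.n_samples, size=n_active, replace=False)
        mask = np.ones(cfg.n_samples, dtype=bool)
        mask[active] = False
        activity[j, mask] = 0.0

    indicator = modules.indicator(genes).astype(float)  # genes x modules
    values = indicator @ activity
    values += rng.normal(0.0, cfg.noise_sd, size=values.shape) if cfg.noise_sd > 0 else 0.0
    return ExpressionMatrix.from_arrays(genes, samples, values)


def degrade_modules(ms: ModuleSet, universe: Iterable, swap_fraction: float, seed: int) -> ModuleSet:
    """Corrupt each module by swapping ``round(swap_fraction * size)`` of its
    members for uniformly drawn non-member genes; sizes are preserved.

    A controlled degradation instrument: agreement scores against the
    original modules should fall monotonically with ``swap_fraction``.
    """
    if not 0 <= swap_fraction <= 1:
        raise ValueError("swap_fraction must be in [0, 1]")
    universe = sorted(set(universe))
    if not set(universe) >= ms.genes:
        raise ValueError("universe must contain all module genes")
    rng = np.random.default_rng(seed)
    out = []
    for m in ms:
        k = round(swap_fraction * len(m))
        if k == 0:
            out.append(m)
            continue
        members = sorted(m.genes)
        outside = [g for g in universe if g not in m.genes]
        if len(outside) < k:
            raise ValueError(f"universe too small to swap {k} genes out of module {m.name!r}")
        dropped = set(rng.choice(members, size=k, replace=False))
        added = rng.choice(outside, size=k, replace=False)
        out.append(Module(m.name, (m.genes - dropped) | set(added)))
    return ModuleSet(out, universe=universe)


def variant(cfg: SyntheticConfig, **changes) -> SyntheticConfig:
    """A copy of the config with some fields changed (e.g. a new seed)."""
    return replace(cfg, **changes)
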
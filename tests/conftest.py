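import numpy as np
import pytest

from modeval.io import ModuleSet
from modeval.synthetic import SyntheticConfig, generate_gold_standard, simulate_expression


@pytest.fixture
def overlapping_known():
    """Three mutually overlapping modules over a 10-gene universe."""
    return ModuleSet(
        [
            ("m1", {"g1", "g2", "g3", "g4", "g5"}),
            ("m2", {"g4", "g5", "g6", "g7", "g8"}),
            ("m3", {"g1", "g5", "g8", "g9", "g10", "g2"}),
        ]
    )


@pytest.fixture(scope="session")
def planted():
    """Clean planted benchmark: 5 disjoint modules x 20 genes, noiseless."""
    cfg = SyntheticConfig(
        n_regulators=5,
        targets_per_regulator=20,
        overlap_fraction=0.0,
        n_background_genes=0,
        n_samples=60,
        local_fraction=0.0,
        noise_sd=0.0,
        seed=0,
    )
    net, known = generate_gold_standard(cfg)
    expr = simulate_expression(known, cfg)
    return cfg, net, known, expr


@pytest.fixture(scope="session")
def noisy_overlapping():
    """Overlapping planted benchmark with noise and background genes."""
    cfg = SyntheticConfig(
        n_regulators=8,
        targets_per_regulator=15,
        overlap_fraction=0.2,
        n_background_genes=40,
        n_samples=80,
        local_fraction=0.25,
        noise_sd=0.5,
        seed=0,
    )
    net, known = generate_gold_standard(cfg)
    expr = simulate_expression(known, cfg)
    return cfg, net, known, expr


def random_moduleset(rng: np.random.Generator, max_genes=12, max_modules=5, prefix="m"):
    """Small random (possibly overlapping, non-exhaustive) module set."""
    n_genes = int(rng.integers(4, max_genes + 1))
    genes = [f"g{i}" for i in range(n_genes)]
    n_modules = int(rng.integers(1, max_modules + 1))
    modules = []
    for j in range(n_modules):
        size = int(rng.integers(2, max(3, n_genes // 2) + 1))
        members = rng.choice(genes, size=min(size, n_genes), replace=False)
        modules.append((f"{prefix}{j}", frozenset(members)))
    return ModuleSet(modules)
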
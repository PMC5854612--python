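"""Enrichment-based (aucodds) scoring of modules against weighted regulons.

When the gold standard is a weighted regulator->target resource estimated in
many contexts (rather than a trusted module list), modules are scored by how
strongly each regulator's targets are enriched in at least one module:
Fisher's exact test per (regulator, context, module), Holm-Sidak correction,
best odds ratio per regulator, and the aucodds area over log10 odds-ratio
cutoffs between 1 and 1000.
"""

import numpy as np

from modeval.enrichment import WeightedRegulonCollection, regulator_coverage_score
from modeval.io import ModuleSet
from modeval.synthetic import SyntheticConfig, degrade_modules, generate_gold_standard

cfg = SyntheticConfig(n_regulators=10, targets_per_regulator=20, overlap_fraction=0.0, seed=2)
net, known = generate_gold_standard(cfg)
universe = sorted(known.genes) + [f"extra{i}" for i in range(100)]

rng = np.random.default_rng(0)
regulons = WeightedRegulonCollection(
    {
        ("tissueA", reg): [(t, float(w)) for t, w in zip(sorted(ts), rng.uniform(0.2, 1.0, len(ts)))]
        for reg, ts in net.regulons().items()
    }
)

perfect = ModuleSet([(m.name, m.genes) for m in known])
sloppy = degrade_modules(known, universe, swap_fraction=0.5, seed=0)

for label, observed in (("perfect modules", perfect), ("half-corrupted", sloppy)):
    score = regulator_coverage_score(observed, regulons, universe, p_cutoff=0.1)
    print(f"{label:16s} regulator-coverage aucodds = {score:.3f}")
print("1.0 would mean every regulator has a >=1000-fold enriched module; 0 means none beats 1-fold")
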
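"""Grid-search training and cross-dataset test transfer.

Tunes the k of a k-means detector on each of two synthetic datasets with
different planted module counts, then swaps the tuned parameters between
datasets. The training score (own optimum) bounds the test score
(transferred parameters); the gap measures parameter overfitting.
"""

from modeval.detect import kmeans_detector
from modeval.harness import ParamGrid, aggregate_scores, grid_search, transfer_test
from modeval.synthetic import SyntheticConfig, generate_gold_standard, simulate_expression

datasets = []
for i, n_reg in enumerate((4, 8)):
    cfg = SyntheticConfig(
        n_regulators=n_reg, targets_per_regulator=15, overlap_fraction=0.0,
        n_background_genes=20, n_samples=60, noise_sd=0.5, seed=10 + i,
    )
    _, known = generate_gold_standard(cfg)
    datasets.append((f"ds{i}", known, simulate_expression(known, cfg)))

grid = ParamGrid({"k": [4, 6, 8]})
tuned = {
    name: grid_search(kmeans_detector, grid, expr, known, known.genes,
                      n_perm=20, seed=0, dataset_id=name)
    for name, known, expr in datasets
}
rows = []
for name, result in tuned.items():
    print(f"{name}: best {result.best_params}, training score {result.training_score:.2f}")
for src_name, _, _ in datasets:
    for tgt_name, known, expr in datasets:
        if src_name == tgt_name:
            continue
        test = transfer_test(tuned[src_name], kmeans_detector, grid, expr, known,
                             known.genes, n_perm=20, seed=0)
        print(f"params from {src_name} applied to {tgt_name}: test score {test:.2f}")
        rows.append(dict(dataset=tgt_name, organism="synthetic", definition="minimal", score=test))
print(f"aggregate test score (equal weight per organism and definition): "
      f"{aggregate_scores(rows):.2f}")
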
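import numpy as np
import pytest

from modeval.io import ExpressionMatrix, ModuleSet
from modeval.quality import (
    DistanceMatrix,
    cluster_validity,
    coexpression_metrics,
    complete_assignment,
    correlation_distance,
    permuted_metric_test,
    resolve_overlaps,
)


def expr_from(genes, values):
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix.from_arrays(genes, samples, values)


@pytest.fixture
def two_tight_clusters():
    """Two groups of duplicated profiles, uncorrelated between groups."""
    a = np.array([1.0, 2.0, 3.0, 4.0, 2.0, 0.0])
    b = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])  # r(a, b) = 0 by design
    assert abs(np.corrcoef(a, b)[0, 1]) < 1e-12
    genes = ["a1", "a2", "a3", "b1", "b2", "b3"]
    expr = expr_from(genes, [a, a, a, b, b, b])
    ms = ModuleSet([("A", {"a1", "a2", "a3"}), ("B", {"b1", "b2", "b3"})])
    return expr, ms


class TestCorrelationDistance:
    def test_duplicated_profiles_distance_zero(self, two_tight_clusters):
        expr, _ = two_tight_clusters
        dist = correlation_distance(expr)
        assert dist.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_zero_with_absolute(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        expr = expr_from(["up", "down"], [a, -a])
        dist = correlation_distance(expr, absolute=True)
        assert dist.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_profiles_distance_one(self, two_tight_clusters):
        expr, _ = two_tight_clusters
        dist = correlation_distance(expr)
        assert dist.values[0, 3] == pytest.approx(1.0, abs=1e-12)

    def test_invariants_on_random_input(self):
        rng = np.random.default_rng(0)
        expr = expr_from([f"g{i}" for i in range(15)], rng.standard_normal((15, 30)))
        dist = correlation_distance(expr)
        assert isinstance(dist, DistanceMatrix)  # validates symmetry/diag/range

    def test_zero_variance_gene_named(self):
        expr = expr_from(["flat", "ok"], [[1, 1, 1], [1, 2, 3]])
        with pytest.raises(ValueError, match="flat"):
            correlation_distance(expr)


class TestCompleteAssignment:
    def test_exhaustive_input_unchanged(self, two_tight_clusters):
        expr, ms = two_tight_clusters
        assert complete_assignment(ms, expr) == ms

    def test_duplicate_profile_joins_its_module(self, two_tight_clusters):
        expr, _ = two_tight_clusters
        partial = ModuleSet([("A", {"a1", "a2"}), ("B", {"b1", "b2"})])
        out = complete_assignment(partial, expr)
        assert "a3" in out["A"].genes and "b3" in out["B"].genes

    def test_never_moves_assigned_and_covers_all(self, noisy_overlapping):
        _, _, known, expr = noisy_overlapping
        partial = ModuleSet(list(known)[:4])
        out = complete_assignment(partial, expr)
        for before, after in zip(partial, out):
            assert before.genes <= after.genes
        assert out.genes >= set(expr.genes)

    def test_tie_goes_to_lowest_index_module(self):
        a = np.array([1.0, 2.0, 3.0, 5.0])
        expr = expr_from(["x1", "x2", "new"], [a, a, a])
        ms = ModuleSet([("first", {"x1"}), ("second", {"x2"})])
        out = complete_assignment(ms, expr)
        assert "new" in out["first"].genes and "new" not in out["second"].genes


class TestResolveOverlaps:
    def test_disjoint_unchanged(self, two_tight_clusters):
        expr, ms = two_tight_clusters
        assert resolve_overlaps(ms, expr) == ms

    def test_shared_gene_keeps_best_home(self, two_tight_clusters):
        expr, _ = two_tight_clusters
        ms = ModuleSet([("A", {"a1", "a2", "b3"}), ("B", {"b1", "b2", "b3"})])
        out = resolve_overlaps(ms, expr)
        assert "b3" not in out["A"].genes and "b3" in out["B"].genes


class TestClusterValidity:
    def test_silhouette_perfect_separation(self, two_tight_clusters):
        expr, ms = two_tight_clusters
        dist = correlation_distance(expr)
        result = cluster_validity(ms, dist, "silhouette")
        assert result.value == pytest.approx(1.0) and result.higher_is_better

    def test_davies_bouldin_zero_scatter(self, two_tight_clusters):
        expr, ms = two_tight_clusters
        dist = correlation_distance(expr)
        result = cluster_validity(ms, dist, "davies_bouldin")
        assert result.value == pytest.approx(0.0) and not result.higher_is_better

    def test_kim_ramakrishna_prefers_true_partition(self, planted):
        _, _, known, expr = planted
        dist = correlation_distance(expr)
        good = cluster_validity(known, dist, "kim_ramakrishna")
        # split the first module in half: over-partitioned alternative
        first = sorted(known[0].genes)
        worse_ms = ModuleSet(
            [("h1", set(first[:10])), ("h2", set(first[10:]))] + [
                (m.name, m.genes) for m in list(known)[1:]
            ]
        )
        worse = cluster_validity(worse_ms, dist, "kim_ramakrishna")
        assert good.value < worse.value

    def test_single_cluster_rejected(self, two_tight_clusters):
        expr, _ = two_tight_clusters
        dist = correlation_distance(expr)
        ms = ModuleSet([("all", set(expr.genes))])
        with pytest.raises(ValueError, match="at least 2"):
            cluster_validity(ms, dist, "silhouette")

    def test_overlapping_input_rejected(self, two_tight_clusters):
        expr, _ = two_tight_clusters
        dist = correlation_distance(expr)
        ms = ModuleSet([("A", {"a1", "a2", "a3", "b1"}), ("B", {"b1", "b2", "b3"})])
        with pytest.raises(ValueError, match="overlap"):
            cluster_validity(ms, dist, "silhouette")

    def test_silhouette_bounds_davies_bouldin_sign(self, noisy_overlapping):
        _, _, known, expr = noisy_overlapping
        ms = resolve_overlaps(complete_assignment(known, expr), expr)
        dist = correlation_distance(expr)
        sil = cluster_validity(ms, dist, "silhouette").value
        db = cluster_validity(ms, dist, "davies_bouldin").value
        assert -1.0 <= sil <= 1.0 and db >= 0.0


class TestCoexpressionMetrics:
    def test_duplicated_profiles(self):
        a = np.array([1.0, 4.0, 2.0, 5.0, 3.0])
        expr = expr_from(["g1", "g2", "g3"], [a, a, a])
        triple = coexpression_metrics({"g1", "g2", "g3"}, expr)
        assert triple.avg_correlation == pytest.approx(1.0)
        assert triple.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_correlation_near_zero(self):
        rng = np.random.default_rng(0)
        n = 1000
        expr = expr_from([f"g{i}" for i in range(6)], rng.standard_normal((6, n)))
        triple = coexpression_metrics(set(expr.genes), expr)
        assert abs(triple.avg_correlation) < 3 / np.sqrt(n)

    def test_spiked_samples_raise_extreme_z(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((5, 100))
        spiked = base.copy()
        spiked[:, :5] += 4.0  # shared extreme activity in 5% of samples
        expr_base = expr_from([f"g{i}" for i in range(5)], base)
        expr_spiked = expr_from([f"g{i}" for i in range(5)], spiked)
        genes = set(expr_base.genes)
        assert (
            coexpression_metrics(genes, expr_spiked).extreme_z
            > coexpression_metrics(genes, expr_base).extreme_z
        )

    def test_missing_gene_rejected(self, two_tight_clusters):
        expr, _ = two_tight_clusters
        with pytest.raises(ValueError, match="missing"):
            coexpression_metrics({"a1", "nope"}, expr)


class TestPermutedMetricTest:
    def test_planted_modules_beat_null(self, noisy_overlapping):
        _, _, known, expr = noisy_overlapping
        diff, p = permuted_metric_test(known, expr, "avg_correlation", n_perm=30, seed=0)
        assert diff > 0 and p < 0.05

    def test_null_modules_match_null(self, noisy_overlapping):
        from modeval.null_models import permute_moduleset

        _, _, known, expr = noisy_overlapping
        shuffled = permute_moduleset(known, expr.genes, seed=42)
        diff, p = permuted_metric_test(shuffled, expr, "avg_correlation", n_perm=30, seed=1)
        assert abs(diff) < 0.05 and p > 0.001

    def test_too_few_permutations_rejected(self, noisy_overlapping):
        _, _, known, expr = noisy_overlapping
        with pytest.raises(ValueError):
            permuted_metric_test(known, expr, n_perm=5)
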
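import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modeval.enrichment import (
    GeneSetCollection,
    WeightedRegulonCollection,
    aucodds,
    bhi,
    faucodds,
    filter_redundant_genesets,
    fisher_enrichment,
    holm_sidak,
    read_regulons,
    regulator_coverage_score,
)
from modeval.io import ModuleSet
from oracles import aucodds_step_oracle, holm_sidak_oracle, hypergeom_upper_tail


def _sets(n_universe, n_geneset, n_module, overlap):
    universe = [f"u{i}" for i in range(n_universe)]
    geneset = universe[:n_geneset]
    module = universe[n_geneset - overlap : n_geneset - overlap + n_module]
    assert len(set(module) & set(geneset)) == overlap
    return set(module), set(geneset), set(universe)


class TestFisherEnrichment:
    def test_frozen_example(self):
        module, geneset, universe = _sets(20, 5, 5, 4)
        res = fisher_enrichment(module, geneset, universe)
        assert res.p_value == pytest.approx(76 / 15504, rel=1e-12)
        assert res.odds_ratio == pytest.approx(56.0)

    def test_zero_overlap_p_is_one(self):
        module, geneset, universe = _sets(20, 5, 5, 0)
        assert fisher_enrichment(module, geneset, universe).p_value == pytest.approx(1.0)

    def test_identical_small_sets(self):
        universe = {"a", "b", "c", "d"}
        res = fisher_enrichment({"a", "b"}, {"a", "b"}, universe)
        assert res.p_value == pytest.approx(1 / 6, rel=1e-12)

    def test_matches_enumeration_small_universes(self):
        """Exhaustive check against integer-arithmetic hypergeometric
        enumeration for every feasible table with universe <= 12."""
        for n in range(2, 13):
            for k, m in itertools.product(range(n + 1), range(n + 1)):
                for a in range(max(0, k + m - n), min(k, m) + 1):
                    if m == 0 or k == 0:
                        continue
                    module, geneset, universe = _sets(n, k, m, a)
                    res = fisher_enrichment(module, geneset, universe)
                    assert res.p_value == pytest.approx(
                        hypergeom_upper_tail(n, k, m, a), rel=1e-10
                    ), (n, k, m, a)

    def test_subset_requirement(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_enrichment({"x"}, {"a"}, {"a", "b"})

    def test_haldane_only_on_zero_cells(self):
        # all cells positive: plain cross-product ratio
        module, geneset, universe = _sets(20, 10, 10, 6)
        res = fisher_enrichment(module, geneset, universe)
        (a, b), (c, d) = res.table
        assert min(a, b, c, d) > 0 and res.odds_ratio == pytest.approx(a * d / (b * c))


class TestHolmSidak:
    def test_single_p_unchanged(self):
        assert holm_sidak([0.03]) == [pytest.approx(0.03)]

    def test_hand_computed_pair(self):
        assert holm_sidak([0.01, 0.04]) == [pytest.approx(0.0199), pytest.approx(0.04)]

    def test_all_ones(self):
        assert holm_sidak([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            ps = rng.random(int(rng.integers(1, 12))).tolist()
            np.testing.assert_allclose(holm_sidak(ps), holm_sidak_oracle(ps), atol=1e-12)

    def test_output_dominates_input(self):
        rng = np.random.default_rng(3)
        ps = rng.random(10).tolist()
        assert all(adj >= p for adj, p in zip(holm_sidak(ps), ps))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.5])


class TestAucodds:
    def test_all_above_interval(self):
        assert aucodds([1000, 5000, 1e9]) == pytest.approx(1.0)

    def test_all_below_interval(self):
        assert aucodds([1.0, 0.5, 0.0]) == pytest.approx(0.0)

    def test_frozen_midpoint(self):
        assert aucodds([10, 1000]) == pytest.approx(2 / 3, rel=1e-12)

    def test_matches_step_integration(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            ors = (10 ** (rng.random(8) * 4 - 0.5)).tolist()
            assert aucodds(ors) == pytest.approx(aucodds_step_oracle(ors), abs=1e-4)

    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=10),
        st.integers(min_value=0, max_value=9),
        st.floats(min_value=1.001, max_value=100.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_and_bounded(self, ors, idx, factor):
        base = aucodds(ors)
        raised = list(ors)
        raised[idx % len(ors)] *= factor
        assert 0.0 <= base <= 1.0
        assert aucodds(raised) >= base - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aucodds([])


@pytest.fixture(scope="module")
def regulon_world():
    """10 regulons of 20 genes inside a 500-gene universe; observed modules
    exactly equal to the regulons."""
    universe = [f"g{i:03d}" for i in range(500)]
    regulons = {f"R{j}": set(universe[20 * j : 20 * j + 20]) for j in range(10)}
    observed = ModuleSet([(f"mod{j}", regulons[f"R{j}"]) for j in range(10)])
    collection = WeightedRegulonCollection.single_context(regulons)
    return observed, collection, universe


class TestRegulatorCoverage:
    def test_perfect_modules_score_high(self, regulon_world):
        observed, collection, universe = regulon_world
        score = regulator_coverage_score(observed, collection, universe)
        assert score >= 0.8

    def test_disjoint_modules_score_zero(self, regulon_world):
        _, collection, universe = regulon_world
        observed = ModuleSet([("far", frozenset(universe[400:450]))])
        score = regulator_coverage_score(observed, collection, universe)
        assert score == pytest.approx(0.0)

    def test_context_duplication_invariant(self, regulon_world):
        observed, collection, universe = regulon_world
        doubled = WeightedRegulonCollection(
            {
                **{("ctx1", r): ts for (_, r), ts in collection.entries.items()},
                **{("ctx2", r): ts for (_, r), ts in collection.entries.items()},
            }
        )
        assert regulator_coverage_score(observed, doubled, universe) == pytest.approx(
            regulator_coverage_score(observed, collection, universe)
        )

    def test_module_order_invariant(self, regulon_world):
        observed, collection, universe = regulon_world
        reordered = ModuleSet(list(observed)[::-1])
        assert regulator_coverage_score(reordered, collection, universe) == pytest.approx(
            regulator_coverage_score(observed, collection, universe)
        )

    def test_regulons_tsv_round_trip(self, tmp_path, regulon_world):
        _, collection, _ = regulon_world
        path = tmp_path / "regulons.tsv"
        lines = ["#context\tregulator\ttarget\tweight"]
        for (ctx, reg), targets in collection.entries.items():
            lines += [f"{ctx}\t{reg}\t{t}\t{w}" for t, w in targets]
        path.write_text("\n".join(lines) + "\n")
        again = read_regulons(path)
        assert again.entries == collection.entries


class TestFilterRedundantGenesets:
    def test_identical_pair_keeps_first(self):
        gs = GeneSetCollection([("a", set("xyzvw")), ("b", set("xyzvw"))])
        out = filter_redundant_genesets(gs)
        assert [n for n, _ in out] == ["a"]

    def test_moderate_overlap_kept(self):
        gs = GeneSetCollection([("a", set("abcd")), ("b", set("cdef"))])  # Jaccard 1/3
        assert len(filter_redundant_genesets(gs)) == 2

    def test_nested_above_threshold_removed(self):
        gs = GeneSetCollection([("big", set("abcdefgh")), ("sub", set("abcdef"))])  # 0.75
        out = filter_redundant_genesets(gs, max_jaccard=0.7)
        assert [n for n, _ in out] == ["big"]


class TestFaucodds:
    def test_gene_sets_equal_modules(self, regulon_world):
        observed, _, universe = regulon_world
        gs = GeneSetCollection.from_moduleset(observed)
        value = faucodds(observed, gs, universe)
        assert value > 0.8

    def test_no_enrichment_is_zero(self, regulon_world):
        _, _, universe = regulon_world
        observed = ModuleSet([("m", frozenset(universe[:30]))])
        rng = np.random.default_rng(0)
        gs = GeneSetCollection(
            [("s", frozenset(universe[250:280]))]
        )
        assert faucodds(observed, gs, universe) == pytest.approx(0.0)


class TestBhi:
    def test_all_pairs_shared(self):
        observed = ModuleSet([("m", {"a", "b", "c"})])
        gs = GeneSetCollection([("s", {"a", "b", "c"})])
        assert bhi(observed, gs) == pytest.approx(1.0)

    def test_no_pair_shared(self):
        observed = ModuleSet([("m", {"a", "b"})])
        gs = GeneSetCollection([("s1", {"a"}), ("s2", {"b"})])
        assert bhi(observed, gs) == pytest.approx(0.0)

    def test_half_shared_pairs(self):
        # 4 genes, 6 pairs; sets {a,b,c} and {d}: shared pairs ab, ac, bc = 3/6
        observed = ModuleSet([("m", {"a", "b", "c", "d"})])
        gs = GeneSetCollection([("s1", {"a", "b", "c"}), ("s2", {"d"})])
        assert bhi(observed, gs) == pytest.approx(0.5)

    def test_unannotated_error(self):
        observed = ModuleSet([("m", {"a", "b"})])
        gs = GeneSetCollection([("s", {"x"})])
        with pytest.raises(ValueError, match="annotated"):
            bhi(observed, gs)
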
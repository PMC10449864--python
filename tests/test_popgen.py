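"""Bruvo distances, UPGMA trees, bootstrap support and diversity."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ystrkit.popgen import (
    HaplotypeMatrix,
    allele_summary,
    bootstrap_support,
    bruvo_distance,
    bruvo_matrix,
    gene_diversity,
    upgma,
)

NA = float("nan")


class TestBruvo:
    @pytest.mark.parametrize(
        "h1,h2,periods,expected",
        [
            ([45, 30], [45, 30], [3, 3], 0.0),
            ([45], [48], [3], 0.5),  # one unit: 1 - 2^-1
            ([40], [48], [4], 0.75),  # two units: 1 - 2^-2
            ([40, 40], [40, 48], [4, 4], 0.375),  # (0 + 0.75) / 2
        ],
    )
    def test_closed_forms(self, h1, h2, periods, expected):
        assert bruvo_distance(h1, h2, periods) == pytest.approx(expected, abs=1e-12)

    def test_disjoint_loci_na(self):
        assert np.isnan(bruvo_distance([45, NA], [NA, 30], [3, 3]))

    def test_pairwise_deletion(self):
        # missing loci are dropped pairwise, not imputed
        d = bruvo_distance([45, NA, 40], [48, 30, 40], [3, 3, 4])
        assert d == pytest.approx(0.25)

    def test_semimetric_properties(self):
        rng = np.random.default_rng(7)
        periods = [3, 4, 5, 6]
        for _ in range(50):
            h1 = 30 + np.array(periods) * rng.integers(0, 5, 4)
            h2 = 30 + np.array(periods) * rng.integers(0, 5, 4)
            d12 = bruvo_distance(h1, h2, periods)
            assert bruvo_distance(h2, h1, periods) == d12  # symmetry
            assert 0.0 <= d12 < 1.0
            assert (d12 == 0.0) == bool((h1 == h2).all())

    def test_real_valued_unit_differences(self):
        # a 2-bp shift at a period-3 locus contributes 1 - 2^(-2/3)
        assert bruvo_distance([30], [32], [3]) == pytest.approx(1 - 2 ** (-2 / 3))


def brute_force_upgma_heights(d: np.ndarray, names):
    """Independent average-linkage oracle keeping explicit member lists."""
    clusters = [[i] for i in range(len(names))]
    merges = []
    d0 = d.copy()
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            val = np.mean([d0[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or val < best[0] - 1e-15:
                best = (val, a, b)
        val, a, b = best
        merges.append((frozenset(names[i] for i in clusters[a] + clusters[b]), val / 2))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return dict(merges)


class TestUpgma:
    def test_three_leaf_example(self):
        d = pd.DataFrame(
            [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]],
            index=list("ABC"), columns=list("ABC"),
        )
        tree = upgma(d)
        assert tree.to_newick() == "((A:0.1,B:0.1):0.2,C:0.3);"

    def test_two_leaf_cherry(self):
        d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=list("AB"), columns=list("AB"))
        tree = upgma(d)
        assert tree.height == pytest.approx(0.2)
        assert tree.to_newick() == "(A:0.2,B:0.2);"

    def test_ultrametric_input_recovered_exactly(self):
        # cophenetic distances of an ultrametric matrix are reproduced
        d = pd.DataFrame(
            [
                [0.0, 0.2, 0.8, 0.8],
                [0.2, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.4],
                [0.8, 0.8, 0.4, 0.0],
            ],
            index=list("ABCD"), columns=list("ABCD"),
        )
        tree = upgma(d)
        pd.testing.assert_frame_equal(tree.cophenetic(), d.loc[list("ABCD"), list("ABCD")])

    def test_rejects_na(self):
        d = pd.DataFrame([[0, NA], [NA, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError, match="co-genotyped"):
            upgma(d)

    def test_output_ultrametric_and_newick_roundtrip(self):
        import dendropy

        rng = np.random.default_rng(1)
        m = rng.random((6, 6))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        names = list("ABCDEF")
        tree = upgma(pd.DataFrame(d, index=names, columns=names))
        # ultrametric: all leaves equidistant from root
        coph = tree.cophenetic()
        dt = dendropy.Tree.get(
            data=tree.to_newick(), schema="newick", rooting="force-rooted"
        )
        depths = {
            leaf.taxon.label: leaf.distance_from_root() for leaf in dt.leaf_node_iter()
        }
        assert max(depths.values()) - min(depths.values()) < 1e-9
        # branch lengths round-trip through newick to 1e-9
        for a in names:
            for b in names:
                if a != b:
                    mrca = dt.mrca(taxon_labels=[a, b])
                    got = depths[a] + depths[b] - 2 * mrca.distance_from_root()
                    assert got == pytest.approx(coph.loc[a, b], abs=1e-9)

    def test_matches_bruteforce_oracle_random_matrices(self):
        names = list("ABCDE")
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = rng.random((5, 5))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            tree = upgma(pd.DataFrame(d, index=names, columns=names))
            expected = brute_force_upgma_heights(d, names)
            got = {
                frozenset(node.leaves()): node.height
                for node in tree.walk()
                if not node.is_leaf
            }
            assert set(got) == set(expected), f"seed {seed}: topology differs"
            for clade, h in expected.items():
                assert got[clade] == pytest.approx(h, abs=1e-12), f"seed {seed}"


def two_clade_matrix(n_per_clade=4, n_loci=20, offset_units=6, seed=0):
    rng = np.random.default_rng(seed)
    periods = [4] * n_loci
    base = 40 + 4 * rng.integers(0, 2, n_loci)
    rows = []
    samples = []
    for c, clade in enumerate(("X", "Y")):
        for i in range(n_per_clade):
            jitter = 4 * rng.integers(0, 2, n_loci)
            rows.append(base + c * 4 * offset_units + jitter)
            samples.append(f"{clade}{i}")
    return HaplotypeMatrix(samples, [f"L{j}" for j in range(n_loci)], periods, np.array(rows, dtype=float))


class TestBootstrap:
    def test_well_separated_clades_full_support(self):
        m = two_clade_matrix()
        tree = bootstrap_support(m, n_resamples=50, n_loci_per_resample=10, seed=3)
        clades = {frozenset(n.leaves()): n.support for n in tree.walk() if not n.is_leaf}
        both = frozenset(m.samples)
        cx = frozenset(s for s in m.samples if s.startswith("X"))
        cy = frozenset(s for s in m.samples if s.startswith("Y"))
        assert clades[both] == 1.0
        assert clades.get(cx, clades.get(cy)) == 1.0

    def test_seed_reproducibility(self):
        m = two_clade_matrix(seed=5)
        t1 = bootstrap_support(m, 25, 8, seed=9)
        t2 = bootstrap_support(m, 25, 8, seed=9)
        s1 = {frozenset(n.leaves()): n.support for n in t1.walk()}
        s2 = {frozenset(n.leaves()): n.support for n in t2.walk()}
        assert s1 == s2

    def test_full_resample_without_replacement_gives_unit_support(self):
        m = two_clade_matrix(seed=2)
        tree = bootstrap_support(m, 10, len(m.loci), seed=1)
        assert all(n.support == 1.0 for n in tree.walk())

    def test_leaves_always_full_support_and_bounds(self):
        m = two_clade_matrix(seed=4)
        tree = bootstrap_support(m, 20, 5, seed=2)
        for n in tree.walk():
            assert 0.0 <= n.support <= 1.0
            if n.is_leaf:
                assert n.support == 1.0

    def test_rejects_bad_args(self):
        m = two_clade_matrix()
        with pytest.raises(ValueError):
            bootstrap_support(m, 0)
        with pytest.raises(ValueError):
            bootstrap_support(m, 10, len(m.loci) + 1)


class TestGeneDiversity:
    def matrix(self, columns):
        n = len(columns[0])
        return HaplotypeMatrix(
            [f"s{i}" for i in range(n)],
            [f"L{j}" for j in range(len(columns))],
            [4] * len(columns),
            np.array(columns, dtype=float).T,
        )

    def test_monomorphic_zero(self):
        _, means = gene_diversity(self.matrix([[40, 40, 40, 40]]))
        assert means["all"] == 0.0

    def test_two_equifrequent_alleles(self):
        per_locus, _ = gene_diversity(self.matrix([[40, 40, 44, 44]]))
        assert per_locus["all"].iloc[0] == pytest.approx(0.5)

    def test_four_equifrequent_alleles(self):
        per_locus, _ = gene_diversity(self.matrix([[40, 44, 48, 52]]))
        assert per_locus["all"].iloc[0] == pytest.approx(0.75)

    def test_small_sample_correction(self):
        m = self.matrix([[40, 40, 44, 44]])
        per_locus, _ = gene_diversity(m, corrected=True)
        assert per_locus["all"].iloc[0] == pytest.approx(0.5 * 4 / 3)

    def test_bound_and_missing_locus_excluded(self):
        m = self.matrix([[40, 44, 48, 52], [NA, NA, NA, NA]])
        per_locus, means = gene_diversity(m)
        # h <= 1 - 1/m for m observed alleles
        assert per_locus["all"].iloc[0] <= 1 - 1 / 4 + 1e-12
        assert np.isnan(per_locus["all"].iloc[1])
        assert means["all"] == pytest.approx(0.75)  # all-missing locus excluded

    def test_polymorphic_only_flag(self):
        m = self.matrix([[40, 40, 44, 44], [40, 40, 40, 40]])
        _, with_mono = gene_diversity(m)
        _, poly_only = gene_diversity(m, polymorphic_only=True)
        assert with_mono["all"] == pytest.approx(0.25)
        assert poly_only["all"] == pytest.approx(0.5)

    def test_grouping(self):
        m = self.matrix([[40, 44, 40, 40]])
        groups = {"s0": "a", "s1": "a", "s2": "b", "s3": "b"}
        per_locus, means = gene_diversity(m, groups)
        assert means["a"] == pytest.approx(0.5)
        assert means["b"] == 0.0


class TestAlleleSummary:
    def test_constructed_table(self):
        m = HaplotypeMatrix(
            ["a", "b", "c"],
            ["L1", "L2"],
            [3, 3],
            np.array([[45, 30], [45, 30], [48, 30.0]]),
        )
        out = allele_summary(m)
        assert list(out["allele_counts"]["all"]) == [2, 1]
        assert out["invariant_per_group"]["all"] == 1
        assert out["monomorphic_all"] == 1 and out["polymorphic_all"] == 1

    def test_identical_samples_all_invariant(self):
        m = HaplotypeMatrix(
            ["a", "b"], ["L1", "L2"], [4, 4], np.array([[40, 44], [40, 44.0]])
        )
        out = allele_summary(m)
        assert out["monomorphic_all"] == 2

    def test_group_stats(self):
        m = HaplotypeMatrix(
            ["a", "b", "c", "d"],
            ["L1", "L2", "L3"],
            [4] * 3,
            np.array([[40, 40, 40], [44, 40, 44], [48, 40, 44], [52, 40, 40.0]]),
        )
        out = allele_summary(m, {s: "g" for s in m.samples})
        st = out["group_stats"]["g"]
        assert st["mean_alleles"] == pytest.approx((4 + 1 + 2) / 3)
        assert st["median_alleles"] == 2.0
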
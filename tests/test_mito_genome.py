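import itertools
import math

import numpy as np
import pytest

from mitoconcord.mito_genome import (CodingRegion, HaplotypeAlignment,
                                     assign_clades, build_msn,
                                     fixed_differences, ne_from_diversity,
                                     pairwise_differences,
                                     translate_and_compare,
                                     wf_absorption_time, wf_forward_simulate)


def aln(seqs, labels=None, groups=None):
    labels = labels or [f"h{i}" for i in range(len(seqs))]
    return HaplotypeAlignment(sequences=list(seqs), labels=labels, groups=groups)


class TestPairwiseDifferences:
    @pytest.mark.parametrize("s1,s2,expected", [
        ("ACGT", "ACGT", 0),
        ("ACGT", "ACGA", 1),
        ("ACNT", "AGTT", 1),    # N position ignored
        ("AC-T", "ACGT", 0),    # gap position ignored
    ])
    def test_hamming_with_ambiguity(self, s1, s2, expected):
        d = pairwise_differences(aln([s1, s2]))
        assert d[0, 1] == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="unequal lengths"):
            aln(["ACGT", "ACG"])


class TestMsn:
    def test_identical_sequences_collapse(self):
        net = build_msn(aln(["AAAA"] * 5))
        assert len(net.haplotypes) == 1
        assert net.node_sizes == [5]
        assert net.edges == []

    def test_chain_topology(self):
        # d(A,B)=1, d(B,C)=1, d(A,C)=2 -> chain A-B-C with total weight 2
        net = build_msn(aln(["AAAA", "AAAT", "AATT"]))
        assert len(net.edges) == 2
        assert sum(w for _, _, w in net.edges) == 2

    def test_two_clusters_bridge_is_maximum_edge(self):
        base0 = "A" * 20
        base1 = "G" * 8 + "A" * 12   # 8 mutations away
        # within-cluster variants at non-overlapping positions so every
        # cross-cluster distance is >= 8
        cluster0 = [base0, base0[:19] + "T", base0[:18] + "C" + base0[19:],
                    base0[:17] + "T" + base0[18:], base0]
        cluster1 = [base1, base1[:11] + "T" + base1[12:],
                    base1[:12] + "C" + base1[13:], base1[:13] + "T" + base1[14:],
                    base1]
        net = build_msn(aln(cluster0 + cluster1))
        weights = sorted(w for _, _, w in net.edges)
        assert weights[-1] >= 8
        assert weights[-2] < weights[-1]

    def test_mst_minimality_against_brute_force(self, rng):
        # every spanning tree over <= 6 haplotypes weighs at least the MST
        seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(6)]
        a = aln(seqs)
        net = build_msn(a)
        d = pairwise_differences(a)
        mst_weight = sum(w for _, _, w in net.edges)
        n = len(seqs)
        best = math.inf
        for edges in itertools.combinations(
                [(i, j) for i in range(n) for j in range(i + 1, n)], n - 1):
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            ok = True
            for u, v in edges:
                ru, rv = find(u), find(v)
                if ru == rv:
                    ok = False
                    break
                parent[ru] = rv
            if ok:
                best = min(best, sum(d[u, v] for u, v in edges))
        assert mst_weight == best

    def test_node_sizes_sum_to_sample_count(self):
        net = build_msn(aln(["AAAA", "AAAA", "AATT", "GGGG", "AATT"]))
        assert sum(net.node_sizes) == 5
        assert len(net.edges) == len(net.haplotypes) - 1


class TestCladeAssignment:
    def _two_cluster_aln(self):
        base0 = "A" * 20
        base1 = "G" * 8 + "A" * 12
        seqs = [base0, base0[:19] + "T", base1, "C" + base1[1:]]
        return aln(seqs, labels=["a1", "a2", "b1", "b2"])

    def test_bipartition_recovers_clusters(self):
        net = build_msn(self._two_cluster_aln())
        scores = assign_clades(net, reference_label="a1")
        assert scores["a1"] == scores["a2"] == 0
        assert scores["b1"] == scores["b2"] == 1

    def test_reference_sets_polarity(self):
        net = build_msn(self._two_cluster_aln())
        scores = assign_clades(net, reference_label="b1")
        assert scores["b1"] == 0 and scores["a1"] == 1

    def test_all_identical_single_clade(self):
        net = build_msn(aln(["AAAA"] * 3))
        scores = assign_clades(net)
        assert set(scores.values()) == {0}

    def test_tied_maximum_edge_raises(self):
        # three haplotypes pairwise 2 apart: both tree edges weigh 2
        net = build_msn(aln(["AACC", "AAGG", "AATT"]))
        with pytest.raises(ValueError, match="tie"):
            assign_clades(net)


class TestFixedDifferences:
    def test_fixed_and_polymorphic_sites(self):
        a = aln(["AAAA", "AAAA", "GAAA", "GAGA"],
                groups=["x", "x", "y", "y"])
        fixed, _ = fixed_differences(a, "x", "y")
        assert fixed == [1]   # site 3 polymorphic in y only -> not fixed

    def test_shared_allele_not_fixed(self):
        a = aln(["AAAA", "GAAA", "GAAA", "GAAA"], groups=["x", "x", "y", "y"])
        fixed, _ = fixed_differences(a, "x", "y")
        assert fixed == []

    def test_engineered_alignment_dxy_enumeration(self, rng):
        L = 100
        base = "".join(rng.choice(list("ACGT"), L))
        other = list(base)
        for p in (5, 40, 77):    # three engineered fixed differences
            other[p] = {"A": "G", "C": "T", "G": "A", "T": "C"}[other[p]]
        other = "".join(other)
        seqs = [base, base, other, other]
        a = aln(seqs, groups=["x", "x", "y", "y"])
        fixed, dxy = fixed_differences(a, "x", "y")
        assert fixed == [6, 41, 78]
        # oracle: average over the 4 between-group pairs
        pairs = [(0, 2), (0, 3), (1, 2), (1, 3)]
        oracle = np.mean([
            sum(c1 != c2 for c1, c2 in zip(seqs[i], seqs[j])) / L
            for i, j in pairs])
        assert dxy == pytest.approx(oracle)

    def test_empty_group_raises(self):
        a = aln(["AAAA", "GAAA"], groups=["x", "x"])
        with pytest.raises(ValueError, match="empty group"):
            fixed_differences(a, "x", "y")


class TestTranslation:
    def _coding_aln(self, codons_x, codons_y):
        sx = "".join(codons_x)
        sy = "".join(codons_y)
        return aln([sx, sx, sy, sy], groups=["x", "x", "y", "y"])

    def test_missense_reported_in_standard_notation(self):
        # residue 150 needs 149 leading codons; keep it small with a
        # synthetic 3-codon gene instead and check label arithmetic
        a = self._coding_aln(["ATG", "AAT", "TAA"], ["ATG", "GAT", "TAA"])
        subs = translate_and_compare(a, [CodingRegion("nd2", 1, 9)], "x", "y")
        assert len(subs) == 1
        assert subs[0]["label"] == "N2D"

    def test_residue_index_scales_with_position(self):
        codons_x = ["ATG"] + ["CCA"] * 148 + ["AAT"] + ["TAA"]
        codons_y = ["ATG"] + ["CCA"] * 148 + ["GAT"] + ["TAA"]
        a = self._coding_aln(codons_x, codons_y)
        subs = translate_and_compare(a, [CodingRegion("nd2", 1, 453)], "x", "y")
        assert [s["label"] for s in subs] == ["N150D"]

    def test_synonymous_change_not_reported(self):
        a = self._coding_aln(["ATG", "CTA", "TAA"], ["ATG", "CTG", "TAA"])
        assert translate_and_compare(a, [CodingRegion("g", 1, 9)], "x", "y") == []

    def test_vertebrate_mito_code_tga_is_tryptophan(self):
        a = self._coding_aln(["ATG", "TGA", "TAA"], ["ATG", "TGG", "TAA"])
        # TGA and TGG both encode W under the vertebrate mito code
        assert translate_and_compare(a, [CodingRegion("g", 1, 9)], "x", "y") == []

    def test_internal_stop_raises(self):
        a = self._coding_aln(["ATG", "TAA", "AAT"], ["ATG", "AAA", "AAT"])
        with pytest.raises(ValueError, match="internal stop"):
            translate_and_compare(a, [CodingRegion("g", 1, 9)], "x", "y")

    def test_partial_codon_raises(self):
        a = self._coding_aln(["ATG", "AA"], ["ATG", "GA"])
        with pytest.raises(ValueError, match="codon"):
            translate_and_compare(a, [CodingRegion("g", 1, 5)], "x", "y")


class TestDriftArithmetic:
    def test_ne_modes(self):
        assert ne_from_diversity(0.0015, 4.42e-9) == pytest.approx(339366.5, rel=1e-4)
        assert ne_from_diversity(0.0015, 4.42e-9, mode="pi_over_4mu") == (
            pytest.approx(84841.6, rel=1e-4))

    def test_ne_limits(self):
        assert ne_from_diversity(1e-3, 1e3) < 1e-5
        with pytest.raises(ValueError):
            ne_from_diversity(0.0, 1e-9)

    def test_absorption_time_headline_value(self):
        ne = ne_from_diversity(0.0015, 4.42e-9)
        t = wf_absorption_time(ne, 0.5)["t_absorption"]
        assert t == pytest.approx(9.4e5, rel=0.01)

    def test_symmetry_at_half(self):
        out = wf_absorption_time(1000.0, 0.5)
        assert out["t_absorption"] == pytest.approx(4000 * math.log(2))
        assert out["t_loss"] == pytest.approx(out["t_absorption"])

    def test_boundary_start_returns_zero(self):
        assert wf_absorption_time(100.0, 1.0)["t_absorption"] == 0.0

    def test_maximal_at_half(self):
        grid = np.linspace(0.01, 0.99, 49)
        times = [wf_absorption_time(500.0, p)["t_absorption"] for p in grid]
        assert np.argmax(times) == len(grid) // 2

    def test_small_p_limit(self):
        assert wf_absorption_time(1000.0, 1e-9)["t_absorption"] < 1.0


class TestForwardSimulator:
    def test_mean_matches_diffusion_theory(self):
        times = wf_forward_simulate(100, 0.5, n_reps=2000, seed=5)
        expected = 4 * 100 * math.log(2)
        se = times.std() / math.sqrt(len(times))
        assert abs(times.mean() - expected) < 3 * se

    @pytest.mark.parametrize("n", [50, 500])
    def test_diffusion_agreement_across_sizes(self, n):
        times = wf_forward_simulate(n, 0.5, n_reps=600, seed=11)
        expected = 4 * n * math.log(2)
        se = times.std() / math.sqrt(len(times))
        assert abs(times.mean() - expected) < 4 * se

    def test_boundary_start_absorbs_immediately(self):
        times = wf_forward_simulate(50, 1.0, n_reps=10, seed=0)
        assert np.all(times == 0)

    def test_seed_reproducibility(self):
        t1 = wf_forward_simulate(60, 0.3, n_reps=50, seed=9)
        t2 = wf_forward_simulate(60, 0.3, n_reps=50, seed=9)
        np.testing.assert_array_equal(t1, t2)
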
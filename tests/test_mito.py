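"""Mitochondrial barcode statistics against brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventpop import mito
from ventpop.mito import HaplotypeAlignment


def brute_pi(seqs):
    """Mean pairwise difference proportion, pairwise-deleting N/-."""
    vals = []
    for a, b in itertools.combinations(seqs, 2):
        ok = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
        vals.append(sum(x != y for x, y in ok) / len(ok))
    return sum(vals) / len(vals)


def brute_dxy(seqs_a, seqs_b):
    vals = []
    for a in seqs_a:
        for b in seqs_b:
            ok = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
            vals.append(sum(x != y for x, y in ok) / len(ok))
    return sum(vals) / len(vals)


def random_seqs(rng, n, L, miss=0.0):
    out = []
    for _ in range(n):
        s = rng.choice(list("ACGT"), size=L)
        if miss:
            s[rng.uniform(size=L) < miss] = "N"
        out.append("".join(s))
    return out


class TestCollapse:
    def test_identical_and_mixed(self):
        aln = HaplotypeAlignment(
            ["AAA"] * 4, [f"i{k}" for k in range(4)], ["x"] * 4
        )
        rows = mito.collapse_haplotypes(aln)
        assert len(rows) == 1 and rows[0]["count"] == 4

        aln = HaplotypeAlignment(["AAA", "AAT", "AAT"], ["a", "b", "c"], ["x"] * 3)
        rows = mito.collapse_haplotypes(aln)
        assert [r["count"] for r in rows] == [2, 1]

    def test_matches_set_oracle(self, rng):
        seqs = ["".join(rng.choice(list("AT"), size=5)) for _ in range(20)]
        aln = HaplotypeAlignment(seqs, [f"i{k}" for k in range(20)], ["x"] * 20)
        rows = mito.collapse_haplotypes(aln)
        assert len(rows) == len(set(seqs))
        assert sum(r["count"] for r in rows) == 20

    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            HaplotypeAlignment(["AA", "AAA"], ["a", "b"], ["x", "x"])


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [((5,), 0.0), ((1, 1), 1.0), ((2, 2), 2.0 / 3.0)],
    )
    def test_known_values(self, counts, expected):
        assert mito.haplotype_diversity(counts) == pytest.approx(expected)

    def test_needs_two(self):
        with pytest.raises(ValueError):
            mito.haplotype_diversity([1])

    @given(st.lists(st.integers(1, 30), min_size=2, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_matches_pair_enumeration(self, counts):
        # Hd is the probability two haplotypes drawn without replacement differ
        n = sum(counts)
        diff_pairs = sum(
            ci * cj for ci, cj in itertools.combinations(counts, 2)
        )
        expected = 2 * diff_pairs / (n * (n - 1))
        assert mito.haplotype_diversity(counts) == pytest.approx(expected)


class TestPi:
    def test_known_values(self):
        two = HaplotypeAlignment(
            ["AAAAAAAAAA", "TTAAAAAAAA"], ["a", "b"], ["x", "x"]
        )
        assert mito.nucleotide_diversity(two) == pytest.approx(0.2)
        tri = HaplotypeAlignment(["AAA", "AAT", "ATT"], ["a", "b", "c"], ["x"] * 3)
        assert mito.nucleotide_diversity(tri) == pytest.approx(4.0 / 9.0)
        mono = HaplotypeAlignment(["ACGT"] * 3, ["a", "b", "c"], ["x"] * 3)
        assert mito.nucleotide_diversity(mono) == 0.0

    def test_brute_force_with_missing(self, rng):
        seqs = random_seqs(rng, 8, 30, miss=0.1)
        aln = HaplotypeAlignment(seqs, [f"i{k}" for k in range(8)], ["x"] * 8)
        assert mito.nucleotide_diversity(aln) == pytest.approx(
            brute_pi(seqs), abs=1e-12
        )

    def test_reorder_invariance(self, rng):
        seqs = random_seqs(rng, 6, 20)
        perm = rng.permutation(6)
        a1 = HaplotypeAlignment(seqs, [f"i{k}" for k in range(6)], ["x"] * 6)
        a2 = HaplotypeAlignment(
            [seqs[i] for i in perm], [f"i{k}" for k in range(6)], ["x"] * 6
        )
        assert mito.nucleotide_diversity(a1) == pytest.approx(
            mito.nucleotide_diversity(a2)
        )


class TestDxy:
    def test_single_pair(self):
        a = HaplotypeAlignment(["AAAA"], ["a"], ["x"])
        b = HaplotypeAlignment(["TAAA"], ["b"], ["y"])
        assert mito.dxy(a, b) == pytest.approx(0.25)

    def test_brute_force_and_symmetry(self, rng):
        sa = random_seqs(rng, 5, 25, miss=0.05)
        sb = random_seqs(rng, 4, 25, miss=0.05)
        a = HaplotypeAlignment(sa, [f"a{k}" for k in range(5)], ["x"] * 5)
        b = HaplotypeAlignment(sb, [f"b{k}" for k in range(4)], ["y"] * 4)
        assert mito.dxy(a, b) == pytest.approx(brute_dxy(sa, sb), abs=1e-12)
        assert mito.dxy(a, b) == pytest.approx(mito.dxy(b, a))

    def test_self_copy_equals_cross_pair_mean(self, rng):
        seqs = random_seqs(rng, 5, 20)
        a = HaplotypeAlignment(seqs, [f"a{k}" for k in range(5)], ["x"] * 5)
        b = HaplotypeAlignment(seqs, [f"b{k}" for k in range(5)], ["x"] * 5)
        assert mito.dxy(a, b) == pytest.approx(brute_dxy(seqs, seqs), abs=1e-12)

    def test_length_mismatch(self):
        a = HaplotypeAlignment(["AAAA"], ["a"], ["x"])
        b = HaplotypeAlignment(["AAA"], ["b"], ["y"])
        with pytest.raises(ValueError, match="length mismatch"):
            mito.dxy(a, b)


class TestNetDivergence:
    def test_identity_and_bounds(self):
        assert mito.net_divergence(0.5, 0.0, 0.0) == 0.5
        da = mito.net_divergence(0.126, 0.003, 0.004)
        assert da == pytest.approx(0.1225)
        assert da <= 0.126

    def test_negative_flagged(self):
        with pytest.warns(UserWarning, match="negative net divergence"):
            assert mito.net_divergence(0.001, 0.01, 0.01) < 0

    def test_rounding_half_away(self):
        assert mito.round_half_away(0.0275, 3) == 0.028
        assert mito.round_half_away(0.0855, 3) == 0.086
        assert mito.round_half_away(-0.0275, 3) == -0.028


class TestFstHaplotype:
    def test_fixed_difference(self):
        a = HaplotypeAlignment(["AAA"] * 4, [f"a{k}" for k in range(4)], ["x"] * 4)
        b = HaplotypeAlignment(["TTT"] * 4, [f"b{k}" for k in range(4)], ["y"] * 4)
        assert mito.fst_haplotype(a, b) == pytest.approx(1.0)

    def test_identical_distributions_near_zero(self):
        seqs = ["AAA"] * 50 + ["AAT"] * 30 + ["ATT"] * 20
        a = HaplotypeAlignment(seqs, [f"a{k}" for k in range(100)], ["x"] * 100)
        b = HaplotypeAlignment(seqs, [f"b{k}" for k in range(100)], ["y"] * 100)
        assert abs(mito.fst_haplotype(a, b)) < 0.02

    def test_permutation_of_pooled_sample_near_zero(self, rng):
        pool = list(rng.choice(["AAA", "AAT", "ATT", "TTT"], size=200,
                               p=[0.4, 0.3, 0.2, 0.1]))
        rng.shuffle(pool)
        a = HaplotypeAlignment(pool[:100], [f"a{k}" for k in range(100)], ["x"] * 100)
        b = HaplotypeAlignment(pool[100:], [f"b{k}" for k in range(100)], ["y"] * 100)
        assert abs(mito.fst_haplotype(a, b)) < 0.02

    def test_strong_divergence(self, isolated_study):
        # with complete lineage sorting the distance-weighted estimator
        # approaches 1; the frequency-only estimator is bounded by the
        # within-group haplotype homozygosity and stays lower but positive
        aln = isolated_study.mito_alignment
        a = aln.by_species("kojimai")
        b = aln.by_species("boucheti")
        assert mito.phist_haplotype(a, b) > 0.9
        freq_fst = mito.fst_haplotype(a, b)
        assert 0.0 < freq_fst <= 1.0
        assert freq_fst < mito.phist_haplotype(a, b)

    def test_monomorphic_warns(self):
        a = HaplotypeAlignment(["AAA"] * 2, ["a0", "a1"], ["x"] * 2)
        b = HaplotypeAlignment(["AAA"] * 2, ["b0", "b1"], ["y"] * 2)
        with pytest.warns(UserWarning):
            assert mito.fst_haplotype(a, b) == 0.0


class TestAssignSpecies:
    def test_exact_match_and_tie(self):
        refs = HaplotypeAlignment(["AAAA", "TTTT"], ["r1", "r2"], ["sp1", "sp2"])
        sp, d, amb = mito.assign_species("AAAA", refs)
        assert (sp, d, amb) == ("sp1", 0.0, False)
        # equidistant query
        _, d, amb = mito.assign_species("AATT", refs)
        assert amb and d == pytest.approx(0.5)

    def test_simulated_queries_all_correct(self, isolated_study):
        aln = isolated_study.mito_alignment
        # precondition of the claim: between-species divergence >= 10x pi
        pis = [
            mito.nucleotide_diversity(aln.by_species(s))
            for s in aln.species_names()
        ]
        d = mito.dxy(
            aln.by_species("kojimai"), aln.by_species("boucheti")
        )
        assert d >= 10 * max(pis)
        correct = 0
        n_query = min(50, aln.n)
        for i in range(n_query):
            refs = aln.subset([j for j in range(aln.n) if j != i])
            sp, _, amb = mito.assign_species(aln.sequence(i), refs)
            correct += (sp == aln.species[i]) and not amb
        assert correct == n_query


class TestMedianJoiningNetwork:
    def test_two_haplotypes(self):
        net = mito.median_joining_network(["AAA", "TTA"])
        g = net.graph
        assert g.number_of_edges() == 1
        assert g.edges["AAA", "TTA"]["weight"] == 2

    def test_triplet_cost_bound(self):
        net = mito.median_joining_network(["AA", "AT", "TA"])
        total = sum(d["weight"] for _, _, d in net.graph.edges(data=True))
        # exhaustive: spanning trees on the three observed nodes cost 2, 3 or 3
        assert total <= 2
        assert all(
            h in net.graph for h in ["AA", "AT", "TA"]
        )

    def test_star_center_max_degree(self):
        center = "AAAAAA"
        leaves = ["TAAAAA", "ATAAAA", "AATAAA", "AAATAA", "AAAATA"]
        net = mito.median_joining_network([center] + leaves)
        degs = dict(net.graph.degree())
        assert degs[center] == max(degs.values()) == 5

    def test_connected(self, rng):
        seqs = list({
            "".join(rng.choice(list("ACGT"), size=8)) for _ in range(10)
        })
        net = mito.median_joining_network(seqs)
        import networkx as nx

        assert nx.is_connected(net.graph)
        assert all(d["weight"] >= 1 for _, _, d in net.graph.edges(data=True))


class TestDiversitySummary:
    def test_counts(self):
        aln = HaplotypeAlignment(
            ["AAAA", "AATA", "AATA", "AATT"], list("abcd"), ["x"] * 4
        )
        s = mito.diversity_summary(aln)
        assert (s.N, s.K, s.H) == (4, 2, 3)
        assert 0 <= s.Hd <= 1 and s.pi > 0
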
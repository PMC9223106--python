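"""SNP-matrix filtering, partitioning, FST and divergence statistics."""

import numpy as np
import pandas as pd
import pytest

from ventpop import mito, radseq, synthdata
from ventpop.radseq import MISSING, FilterConfig, GenotypeMatrix


def make_matrix(geno, species=None, basin=None, locus=None, locus_len=100):
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    species = species or ["sp1"] * n
    basin = basin or ["b1"] * n
    locus = locus if locus is not None else [f"L{j}" for j in range(m)]
    return GenotypeMatrix(
        genotypes=geno,
        snp_meta=pd.DataFrame({"locus": locus, "pos": [0] * m})
        if len(set(locus)) == m
        else pd.DataFrame({"locus": locus, "pos": list(range(m))}),
        ind_meta=pd.DataFrame({"species": species, "basin": basin},
                              index=[f"i{k}" for k in range(n)]),
        locus_len=locus_len,
    )


class TestFilterMatrix:
    def test_clean_matrix_unchanged(self):
        g = make_matrix([[0, 1, 2]] * 8 + [[2, 1, 0]] * 8)
        out, report = radseq.filter_matrix(g, FilterConfig())
        assert out.n_snp == 3 and out.n_ind == 16
        assert list(report["step"]) == [
            "input", "locus_sharing", "mac", "snp_call_rate", "ind_call_rate"
        ]

    def test_mac_removes_singleton(self):
        # 6 individuals x 5 SNPs; SNP 0 has MAC 1, others MAC >= 4
        geno = np.array([
            [1, 1, 2, 1, 1],
            [0, 1, 2, 1, 1],
            [0, 1, 2, 1, 1],
            [0, 1, 0, 1, 1],
            [0, 0, 0, 0, 1],
            [0, 0, 0, 0, 0],
        ])
        g = make_matrix(geno)
        out, _ = radseq.filter_matrix(g, FilterConfig(r=0, snp_call_rate=0,
                                                      ind_call_rate=0))
        # hand enumeration: MAC per SNP = [1, 4, 6, 4, 5] -> SNP0 dropped
        assert out.n_snp == 4

    def test_low_callrate_individual_dropped(self):
        geno = np.zeros((6, 10), dtype=np.int8)
        geno[:, 0] = [1, 1, 1, 1, 0, 0]  # keep a polymorphic SNP
        geno[5, :5] = MISSING  # individual 5 genotyped at 50%
        g = make_matrix(geno)
        out, _ = radseq.filter_matrix(
            g, FilterConfig(r=0, mac=0, snp_call_rate=0, ind_call_rate=0.85)
        )
        assert out.n_ind == 5

    def test_idempotent(self, small_study):
        f = FilterConfig(r=0.8, mac=2, snp_call_rate=0.9, ind_call_rate=0.85)
        once, _ = radseq.filter_matrix(small_study.genotypes, f)
        twice, _ = radseq.filter_matrix(once, f)
        assert np.array_equal(once.genotypes, twice.genotypes)

    def test_all_filtered_raises(self):
        g = make_matrix([[0, 0], [0, 0], [1, 0], [0, 1]])
        with pytest.raises(ValueError, match="all filtered|removed"):
            radseq.filter_matrix(g, FilterConfig(r=0, mac=4))


class TestMafFloor:
    @pytest.mark.parametrize("n,expected", [(36, 0.0139), (1, 0.5), (250, 0.002)])
    def test_values(self, n, expected):
        assert round(radseq.maf_floor(n), 4) == pytest.approx(expected)

    def test_zero_raises(self):
        with pytest.raises(ValueError):
            radseq.maf_floor(0)


class TestPartition:
    def make_three_species(self):
        # 2 diploids per species, 6 SNPs, classification hand-enumerated
        geno = np.array([
            [0, 0, 0, 0, 0, 0],   # sp1 ind1
            [1, 1, 0, 0, 0, 0],   # sp1 ind2
            [0, 0, 1, 1, 0, 0],   # sp2 ind1
            [2, 0, 1, 0, 0, 0],   # sp2 ind2
            [0, 0, 0, 0, 1, 0],   # sp3 ind1
            [2, 0, 0, 0, 1, 0],   # sp3 ind2
        ])
        return make_matrix(
            geno, species=["sp1", "sp1", "sp2", "sp2", "sp3", "sp3"]
        )

    def test_hand_enumeration(self):
        g = self.make_three_species()
        part = radseq.partition_polymorphism(g)
        # SNP0: poly in sp1 (0/1), sp2 (0/2), sp3 (0/2) -> all three
        # SNP1: poly in sp1 only; SNP2: sp2 only fixed 1? alleles 1,1 ->
        #   freq 0.5,0.5... genotypes 1,1 -> both het: poly sp2 only
        # SNP3: sp2 only; SNP4: sp3 only; SNP5: nowhere
        assert part.count("sp1", "sp2", "sp3") == 1
        assert part.count("sp1") == 1
        assert part.count("sp2") == 2
        assert part.count("sp3") == 1
        assert part.total == 5

    def test_floor_monotonicity(self, small_study):
        # raising the floor can only demote SNPs from "polymorphic in s",
        # so the total and every shared-polymorphism count are non-increasing
        g = small_study.genotypes
        p0 = radseq.partition_polymorphism(g, floor=0.0)
        p1 = radseq.partition_polymorphism(g, floor=radseq.maf_floor(6))
        assert p1.total <= p0.total
        for size in (3, 2):
            n0 = sum(n for r, n in p0.regions.items() if len(r) >= size)
            n1 = sum(n for r, n in p1.regions.items() if len(r) >= size)
            assert n1 <= n0

    def test_fixed_everywhere_not_counted(self):
        geno = np.zeros((6, 3), dtype=np.int8)
        g = make_matrix(geno, species=["a", "a", "b", "b", "c", "c"])
        part = radseq.partition_polymorphism(g)
        assert part.total == 0


class TestPCA:
    def test_two_clusters(self):
        geno = np.vstack([np.zeros((5, 20)), np.full((5, 20), 2)]).astype(np.int8)
        g = make_matrix(geno)
        coords, pct = radseq.pca_genotypes(g)
        assert pct[0] > 99.0
        assert np.allclose(coords[:5, 0], coords[0, 0])
        assert np.all(np.diff(pct) <= 1e-9)

    def test_three_species_separate(self, small_study):
        from sklearn.metrics import silhouette_score

        coords, pct = radseq.pca_genotypes(small_study.genotypes, n_components=2)
        labels = small_study.genotypes.species
        assert silhouette_score(coords[:, :2], labels) > 0.8

    def test_constant_matrix_raises(self):
        g = make_matrix(np.ones((4, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            radseq.pca_genotypes(g)


class TestFstWC:
    def test_fixed_demes(self):
        geno = np.vstack([np.zeros((6, 10)), np.full((6, 10), 2)]).astype(np.int8)
        g = make_matrix(geno, species=["a"] * 6 + ["b"] * 6)
        fst, per = radseq.fst_wc(g, "species")
        assert fst == pytest.approx(1.0)
        assert np.allclose(per[np.isfinite(per)], 1.0)

    def test_panmictic_split_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, size=300)
        geno = rng.binomial(2, p, size=(40, 300)).astype(np.int8)
        g = make_matrix(geno, species=["a"] * 20 + ["b"] * 20)
        fst, _ = radseq.fst_wc(g, "species")
        # permutation-style null: 3 SE of 0 for 300 SNPs is well under 0.02
        assert abs(fst) < 0.02

    def test_island_model_analytic(self, rng):
        # 2 demes, Hudson-style FST expectation 1/(1 + 8Nm)
        from ventpop._engine import Epoch, drop_infinite_sites, simulate_genealogy

        N, m = 5000.0, 1e-4  # 8Nm = 4 -> FST = 0.2
        epochs = [Epoch(0.0, [2 * N, 2 * N], mig=[[0.0, m], [m, 0.0]])]
        piw, pib = [], []
        for _ in range(250):
            gen = simulate_genealogy([20, 20], epochs, rng)
            masks = drop_infinite_sites(gen, 1e-8, 2000, rng)
            for mask in masks:
                ca = bin(mask & ((1 << 20) - 1)).count("1")
                cb = bin(mask >> 20).count("1")
                pa, pb = ca / 20, cb / 20
                piw.append(pa * (1 - pa) * 20 / 19 + pb * (1 - pb) * 20 / 19)
                pib.append(pa * (1 - pb) + pb * (1 - pa))
        fst = 1.0 - np.sum(piw) / np.sum(pib)
        assert fst == pytest.approx(0.2, abs=0.05)


class TestPiDxy:
    def test_monomorphic(self):
        g = make_matrix(np.zeros((4, 3), dtype=np.int8),
                        species=["a", "a", "b", "b"])
        pis, pairs = radseq.pi_dxy_rad(g)
        assert all(v == 0 for v in pis.values())
        assert (pairs["dxy"] == 0).all()

    def test_single_fixed_snp(self):
        g = make_matrix(
            np.array([[2], [2], [0], [0]], dtype=np.int8),
            species=["a", "a", "b", "b"],
            locus_len=100,
        )
        _, pairs = radseq.pi_dxy_rad(g)
        assert pairs.loc[0, "dxy"] == pytest.approx(0.01)

    def test_matches_sequence_computation(self, rng):
        # explicit haplotypes -> genotypes; frequency-based statistics must
        # equal the sequence-based ones exactly
        n_ind, n_snp = 8, 40
        haps = rng.integers(0, 2, size=(2 * n_ind, n_snp))
        geno = haps[0::2] + haps[1::2]
        species = ["a"] * 4 + ["b"] * 4
        g = make_matrix(geno.astype(np.int8), species=species)
        pis, pairs = radseq.pi_dxy_rad(g, per_variant=True)

        seqs = ["".join("AT"[v] for v in row) for row in haps]
        hap_species = np.repeat(species, 2)
        aln_a = mito.HaplotypeAlignment(
            [s for s, sp in zip(seqs, hap_species) if sp == "a"],
            [f"a{k}" for k in range(8)], ["a"] * 8)
        aln_b = mito.HaplotypeAlignment(
            [s for s, sp in zip(seqs, hap_species) if sp == "b"],
            [f"b{k}" for k in range(8)], ["b"] * 8)
        assert pis["a"] == pytest.approx(
            mito.nucleotide_diversity(aln_a), abs=1e-10)
        assert pis["b"] == pytest.approx(
            mito.nucleotide_diversity(aln_b), abs=1e-10)
        assert pairs.loc[0, "dxy"] == pytest.approx(
            mito.dxy(aln_a, aln_b), abs=1e-10)

    def test_species_fst_exceeds_basin_fst(self, small_study):
        g = small_study.genotypes
        sp_fst, _ = radseq.fst_wc(g, "species")
        for sp in g.species_names():
            sub = g.take_ind(g.species == sp)
            if sub.ind_meta["basin"].value_counts().ge(2).sum() < 2:
                continue
            basin_fst, _ = radseq.fst_wc(sub, "basin")
            assert basin_fst < sp_fst


class TestErrorRate:
    def test_identical_and_empty(self, clean_study):
        reps = synthdata.make_replicate_triplets(clean_study, 4, error=0.0)
        assert radseq.genotyping_error_rate(reps) == 0.0
        empty = synthdata.make_replicate_triplets(clean_study, 0, error=0.0)
        assert empty.n_ind == 0

    def test_error_within_three_se(self, clean_study):
        err = 0.01
        reps = synthdata.make_replicate_triplets(clean_study, 8, error=err, seed=3)
        rate = radseq.genotyping_error_rate(reps)
        # enumerated mismatch probability for two independently perturbed
        # copies of genotype g (symmetric one-allele flip with prob e)
        e = err
        true = clean_study.truth["true_genotypes"][:8]

        def dist(gv):
            if gv == 1:
                return {1: 1 - e, 0: e / 2, 2: e / 2}
            return {gv: 1 - e, 1: e}

        pm = np.mean([
            1.0 - sum(p * p for p in dist(int(gv)).values())
            for gv in true.ravel()
        ])
        n_pairs = 3 * true.size  # 3 pairs per triplet
        se = np.sqrt(pm * (1 - pm) / n_pairs)
        assert abs(rate - pm) < 3 * se

    def test_all_missing_replicate_skipped(self):
        geno = np.array([[0, 1], [0, 1], [MISSING, MISSING]], dtype=np.int8)
        g = make_matrix(geno)
        g.ind_meta["triplet"] = ["t", "t", "t"]
        with pytest.warns(UserWarning, match="skipped"):
            assert radseq.genotyping_error_rate(g) == 0.0
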
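"""RAD SNP matrix: filtering, polymorphism partition, PCA, FST, divergence.

Mirrors a genotype-matrix analysis for three species: sequential
filtering, the Venn partition of shared polymorphism with and without a
minimum-allele-frequency floor, genotype PCA, Weir-Cockerham FST
between species and between basins, and per-site pi / dXY / dA.
"""

from ventpop import radseq, synthdata

study = synthdata.make_study(synthdata.StudyConfig(
    sample_sizes=(25, 25, 12), n_rad_loci=400, n_codon_genes=1,
    codon_gene_len=30, seed=3,
))
g = study.genotypes

filtered, report = radseq.filter_matrix(g, radseq.FilterConfig(
    r=0.8, mac=4, snp_call_rate=0.90, ind_call_rate=0.85,
))
print("filter cascade:")
print(report.to_string(index=False))

floor = radseq.maf_floor(12)
part0 = radseq.partition_polymorphism(filtered, floor=0.0)
part1 = radseq.partition_polymorphism(filtered, floor=floor)
print(f"\npolymorphic in all three species: {part0.count(*part0.species)} "
      f"(floor 0) vs {part1.count(*part1.species)} (floor {floor:.4f})")

coords, pct = radseq.pca_genotypes(filtered, n_components=2)
print(f"PCA: PC1 {pct[0]:.1f}%  PC2 {pct[1]:.1f}% of variance")

sp_fst, _ = radseq.fst_wc(filtered, "species")
print(f"between-species FST: {sp_fst:.3f}")
for sp in filtered.species_names():
    sub = filtered.take_ind(filtered.species == sp)
    if sub.ind_meta["basin"].value_counts().ge(2).sum() >= 2:
        f, _ = radseq.fst_wc(sub, "basin")
        print(f"  within {sp}: between-basin FST {f: .4f}")

pis, pairs = radseq.pi_dxy_rad(filtered)
print("\nper-site diversity:", {k: round(v, 4) for k, v in pis.items()})
print(pairs.round(4).to_string(index=False))
# The species/basin FST contrast (~0.9 vs ~0.01) is the signature of
# three well-sorted species with negligible within-species structure.
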
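# Methods

This note documents the models, estimators, numerical choices and
limitations of `ventpop`, in the order data flows through the package.

## Sequence-level statistics (`mito`)

Diversity and divergence are per-site pairwise statistics: π is the
mean proportion of differing sites over all unordered within-sample
pairs, dXY the mean over all between-sample pairs, and
dA = dXY − (πX + πY)/2. Sites containing `N` or `-` are
pairwise-deleted: each pair is compared over its own valid-site set,
matching the default behaviour of the standard desktop tools for
barcode data; complete deletion is available via a flag. dA may be
negative for very recent splits and is flagged, not clamped.

Haplotype diversity uses the small-sample-corrected form
Hd = n(1 − Σp²)/(n − 1). Two haplotype-level differentiation
estimators are provided: a frequency-only FST
(Hb − Hw)/Hb with Hw the mean within-group haplotype heterozygosity
and Hb the between-group mismatch probability, and a distance-weighted
ΦST that replaces haplotype identity with per-site distance
(ΦST = (dXY − π̄)/dXY). The frequency-only form is the default, but it
is bounded above by 1 − Hw: with haplotype-rich mitochondrial data
(Hd ≈ 0.8–0.96) it cannot approach 1 even under complete lineage
sorting, whereas ΦST can. Published barcode FST values near 0.97 are
only reproducible with the distance-weighted form, which is why both
are exposed.

The median-joining network is built greedily: a minimum spanning
network (union of all minimum spanning trees, with an `epsilon` slack
on edge-weight ties) over observed haplotypes, plus median (Steiner)
vectors proposed as per-site majority consensus of observed triplets
and accepted only when they reduce the total spanning cost. This
reproduces the canonical behaviour at epsilon = 0 on small instances;
it does not implement the full quasi-median closure.

Species assignment is nearest-reference by uncorrected p-distance;
ties across species are reported as ambiguous, never broken silently.

Report tables round half away from zero (0.0275 → 0.028 at three
decimals), with a 1e-9 epsilon so binary float representation cannot
flip a true half downward.

## SNP-matrix analysis (`radseq`)

Genotypes are 0/1/2 alternate-allele copies with −1 for missing
(VCF `./.`). The filtering cascade applies, in a fixed order,
per-species locus sharing (fraction r of individuals with data on the
locus, default 0.8), pooled minor allele count (default 4; exact 50%
ties pass), SNP call rate (0.90) and individual call rate (0.85), and
reports counts after each step so the cascade is auditable. Filtering
is idempotent by construction of each criterion.

π uses the unbiased per-SNP heterozygosity 2p̂q̂·n/(n−1) with n the
non-missing allele count; dXY uses the between-species mismatch
probability p₁(1−p₂) + p₂(1−p₁). Both divide by the total sequenced
length (loci × locus length) by default — the whole-locus denominator —
with a per-variant option, because the published per-site values are
length-normalised. These frequency-based forms are algebraically
identical to the sequence-based statistics on the underlying
haplotypes, which the tests assert to 1e-10.

FST is the Weir–Cockerham variance-components estimator; the global
value is the ratio of summed components (not the mean of ratios), and
per-SNP values may be negative. Groups with fewer than two genotyped
individuals at a SNP are excluded from that SNP. PCA mean-imputes
missing genotypes per SNP and is unscaled by default (a
√(p(1−p)) scaling flag exists).

The minimum observable allele frequency in n diploids is 1/(2n); the
polymorphism partition classifies each SNP by the set of species whose
within-species minor allele frequency exceeds a floor (0 by default,
or 1/(2n_min) to equalise detectability across unequal sample sizes).

The genotyping error rate from replicated individuals is the
discordance fraction over all within-triplet pairs at mutually called
SNPs. Note the statistic estimates pairwise discordance: for a
per-call error e applied independently to each copy it equals
≈ 2e(1 − e), not e.

## Ancestry (`ancestry`)

The genotype-frequency matrix X (entries g/2, missing masked) is
factorized as X ≈ QF with Q on the row simplex and F in [0,1],
minimising the masked squared loss. Updates are projected-gradient
steps with step size 1/L per subproblem (L the spectral Lipschitz
constant), so the objective is provably non-increasing — asserted per
iteration in tests. Regularization is zero. Each random restart masks
a fresh 5% of called genotypes; the best run minimises held-out
binomial cross-entropy. Cluster-to-species mapping is by majority
label of argmax-assigned individuals; ties raise errors. K is a user
input — no automatic selection beyond the cross-entropy values.

## Codon evolution (`codonevol`)

NG86 counting from first principles: per-codon synonymous site counts
are the fraction of the nine single-base changes that preserve the
amino acid, averaged over the two sequences; changes that create a
stop codon count as nonsynonymous sites (the original convention, also
used by the Biopython implementation against which tests cross-check).
Observed differences in multiply-substituted codons average over all
minimal mutational pathways that avoid stop codons; if every pathway
passes through a stop the codon still contributes, with stop-involving
steps counted as nonsynonymous. Jukes–Cantor correction
d = −(3/4)ln(1 − 4p/3) is applied to both proportions; p ≥ 3/4 is
reported as saturation. Codons containing gaps or ambiguity codes in
either sequence are skipped. The genetic code is an explicit NCBI
table id — never guessed — because synonymous site counts differ
between the standard and invertebrate-mitochondrial codes.

The generator's codon sequences evolve under a simple
acceptance-ratio model (nonsynonymous changes kept with probability
ω): the realised pooled dN/dS tracks ω with a small (~4%) downward
bias because mutations into stops are rejected while NG86 still counts
those sites as nonsynonymous.

The MK test walks codons using the within-species major-allele codon
as mutational context: within-species variable positions are
synonymous/nonsynonymous polymorphisms, positions monomorphic within
but disjoint from all outgroup alleles are fixed differences; sites
both polymorphic and divergent count once in each margin. P-values are
two-sided Fisher exact; the neutrality index (Pn/Ps)/(Dn/Ds) is
undefined (not zero) on empty margins. Per-branch ML dN/dS (CodeML
free-ratio style) is deliberately out of scope; only pairwise counting
quantities are produced.

## Coalescent simulation and ABC (`demography`, `_engine`)

The engine simulates structured-coalescent genealogies backward in
time by Gillespie sampling within epochs of piecewise-constant
gene-copy counts, backward migration rates and population merges.
Sizes are in gene copies (2N for nuclear loci, 2N/4 for the maternal
haploid mitochondrial locus — the standard fourfold reduction under an
even sex ratio). Mutations are dropped afterwards: infinite-sites
carrier sets for SNP data (each mutation lands on a branch with
probability proportional to its length), finite-sites Jukes–Cantor
for mtDNA (multiple hits possible, so realistic alignments exist), and
the codon acceptance-ratio model above for coding genes.

The four scenarios share one parameterisation (Na; post-split Nf1/Nf2;
current N1/N2 reached at per-population times Tdem1/Tdem2; Tsplit;
directional M12/M21 = 4Nm): migration is active on [0, Tsplit) for IM,
[0, Tsc) for SC, [Tam, Tsplit) for AM and never for SI. Genome
heterogeneity follows a two-part design: per-locus Ne multipliers
drawn from a Beta(a,b) rescaled to (0, 2] (linked-selection proxy) and
a barrier fraction of loci with me = 0 (semipermeable-barrier proxy).
µ defaults to 1e-8 per site per generation; the plausible range
5e-10–3e-8 is recorded in the prior configuration, and all absolute
times trade off against µ.

Summary statistics are across-locus means and standard deviations of
π, Watterson's θ, dXY, net divergence, a per-locus Hudson-style FST
(1 − π̄w/dXY), private/fixed/shared site counts, plus a folded 5×5
relative-frequency-binned joint SFS normalised to proportions (folding
uses the pooled minor allele, since no outgroup polarization is
simulated). Statistics with zero variance across the reference table
are dropped with a warning.

ABC is rejection-based: all simulations are pooled, standardized by
the pooled mean/sd, and the closest fraction (default 5%) by Euclidean
distance retained; model probabilities are acceptance shares.
Parameter posteriors come from the accepted particles of a
single-scenario table, optionally adjusted by local-linear regression
toward the observed vector (clipped to the accepted range). The
goodness-of-fit statistic is the standardized distance of the observed
vector to the predictive cloud center, reported with the fraction of
predictive simulations at least as central — uniform under the fitted
model, near 1 under gross misfit. The ten-run replication protocol
draws ten independent pseudo-observed datasets and scores each against
one fixed per-scenario reference table; building one table per run
would multiply cost tenfold without changing what the majority vote
measures, since run-to-run variability is dominated by the observed
subsample.

Problem sizes used by the tests and the acceptance script — 1000
simulations per scenario of 50 loci × 1 kb with 10+10 sampled
haploid genomes, 1000-locus pseudo-observed datasets, 20 coverage
replicates — are the package's reduced-scale defaults; they give
decisive model choice on strongly separated truths while keeping a
full acceptance run to minutes. Posterior intervals at this scale are
prior-dominated and wide; the coverage check exercises calibration,
not precision.

## Synthetic studies (`synthdata`)

A study is three species from two nested splits: a sister pair and an
older outgroup branch, each split described by a two-population model.
The merged sister ancestor keeps the sister model's Na until the older
split; the older model's second population branch (N2/Nf2/Tdem2) is
unused in the nested composition. Older-model migration connects the
outgroup with both sister populations while they are separate and with
their ancestor afterwards, within the older model's migration window.

The default configuration mirrors the emulated study design: 250/212/36
diploids, five basins with the observed species occupancy (basin labels
are assigned randomly within species — no within-species structure is
simulated by default), 4380 RAD loci of 144 bp, a 599 bp mitochondrial
fragment with a 5× mitochondrial/nuclear rate ratio, and
secondary-contact demography with post-split bottlenecks. Effective
sizes, bottlenecks, expansion times and the Tsc/Tsplit ≈ 5% ratio
follow the inferred demographic history; the split depths default to
950,000/600,000 generations because, at µ = 1e-8, the generation-scaled
inferred times would produce almost no lineage sorting, while the
observed data the generator must emulate show complete mitochondrial
sorting, between-species FST ≈ 0.84–0.92 and nuclear dXY of 2–3%. The
split-time/µ trade-off is a recognised ambiguity of this system; the
generator resolves it in favour of reproducing the observed data, and
migration defaults (M ≈ 0.05–0.4) are set so a few percent of
heterospecific ancestry appears in occasional individuals rather than
inflating within-species diversity.

Genotyping error is a symmetric single-allele flip per genotype call
(hom→het, het→either hom), the simplest model supporting the
triplicate discordance statistic; missingness is i.i.d. per call.
Both are applied after simulation, and the pre-error genotypes are
kept in the truth block so error-rate estimates can be checked against
enumerated expectations. Replicate triplets re-apply independent
errors to the true genotypes of the first n individuals.

What the generator does **not** emulate: read-level noise and allele
dropout (no FASTQ or RAD-digestion model), linkage within loci,
within-species geographic structure (unless migration between basins
is added by the caller), selection on the nuclear SNPs, and symbiont
sequences. Passing tests therefore demonstrate correctness of the
estimators and the internal consistency of the pipeline on data with
the study's statistical shape — not robustness to library-preparation
artefacts of real ddRAD data.

## Known limitations

- The coalescent engine is event-by-event Python: ~0.2 ms per
  moderate-size genealogy, ample for ABC at the scales above but not
  for chromosome-scale simulation (no recombination is modelled).
- Rejection ABC with ~50 statistics is a deliberately simple,
  fully-specifiable stand-in for learned model-choice methods; its
  posterior probabilities are acceptance shares, valid for ranking and
  majority votes rather than as calibrated Bayes factors.
- The median-joining implementation targets barcode-scale haplotype
  sets (tens of haplotypes); its triplet search is quadratic-cubic and
  not suitable for thousands of haplotypes.
- The MK implementation uses the major allele to polarise context and
  the first outgroup allele for fixed-difference classification;
  multi-allelic codon positions with complex histories are counted
  conservatively rather than enumerated.
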
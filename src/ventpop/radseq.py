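"""Nuclear SNP-matrix analysis for short unlinked RAD-style loci.

Implements the filtering cascade (per-population locus sharing, minor
allele count, SNP and individual call rates), partitioning of shared
polymorphism among three species, genotype PCA, the Weir–Cockerham FST
estimator, per-site diversity/divergence (pi, dXY, dA) averaged over
loci, and the triplicate-based genotyping error rate.

Genotypes are coded 0/1/2 copies of the alternate allele with -1 for
missing; VCF ``./.`` maps to missing on input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mito import net_divergence

__all__ = [
    "GenotypeMatrix",
    "FilterConfig",
    "PolymorphismPartition",
    "filter_matrix",
    "maf_floor",
    "partition_polymorphism",
    "pca_genotypes",
    "fst_wc",
    "pi_dxy_rad",
    "genotyping_error_rate",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs with RAD-locus grouping and metadata.

    ``genotypes`` is an ``(n_ind, n_snp)`` int8 array; ``snp_meta`` has
    columns ``locus`` and ``pos`` (0-based position within the locus);
    ``ind_meta`` is indexed by individual id with columns ``species``
    and ``basin``.  ``locus_len`` is the sequenced length of each RAD
    locus in bp (used as the per-site denominator for pi/dXY).
    """

    genotypes: np.ndarray = field(repr=False)
    snp_meta: pd.DataFrame = field(repr=False)
    ind_meta: pd.DataFrame = field(repr=False)
    locus_len: int = 100

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x SNPs)")
        if len(self.snp_meta) != self.genotypes.shape[1]:
            raise ValueError("snp_meta length != number of SNP columns")
        if len(self.ind_meta) != self.genotypes.shape[0]:
            raise ValueError("ind_meta length != number of individuals")
        dup = self.snp_meta.duplicated(subset=["locus", "pos"])
        if dup.any():
            raise ValueError("duplicate (locus, pos) pairs in snp_meta")

    @property
    def n_ind(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.genotypes.shape[1]

    @property
    def species(self) -> np.ndarray:
        return self.ind_meta["species"].to_numpy()

    def species_names(self) -> list[str]:
        return list(pd.unique(self.ind_meta["species"]))

    def take_ind(self, mask) -> "GenotypeMatrix":
        return replace(
            self,
            genotypes=self.genotypes[mask],
            ind_meta=self.ind_meta.iloc[np.flatnonzero(np.asarray(mask))]
            if np.asarray(mask).dtype == bool
            else self.ind_meta.iloc[list(mask)],
        )

    def take_snp(self, mask) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask) if np.asarray(mask).dtype == bool else list(mask)
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            snp_meta=self.snp_meta.iloc[idx].reset_index(drop=True),
        )


@dataclass
class FilterConfig:
    """Thresholds of the sequential SNP-filtering cascade."""

    r: float = 0.8            # min fraction of individuals sharing a locus, per species
    mac: int = 4              # min pooled minor allele count
    snp_call_rate: float = 0.90
    ind_call_rate: float = 0.85

    def __post_init__(self):
        for name in ("r", "snp_call_rate", "ind_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mac < 0 or int(self.mac) != self.mac:
            raise ValueError("mac must be a non-negative integer")


@dataclass
class PolymorphismPartition:
    """Counts of SNPs polymorphic in each subset of three species.

    ``regions`` maps a frozenset of species names (the species in which
    the SNP is polymorphic) to a count; the seven non-empty subsets are
    the Venn regions.  ``total`` is the number of SNPs polymorphic in at
    least one species.
    """

    species: list[str]
    regions: dict[frozenset, int]
    total: int

    def count(self, *species_subset) -> int:
        return self.regions.get(frozenset(species_subset), 0)


def _allele_counts(g: np.ndarray):
    """Alt-allele count and called-allele count per SNP column."""
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=0)
    n_alleles = 2 * called.sum(axis=0)
    return alt, n_alleles


def filter_matrix(g: GenotypeMatrix, f: FilterConfig | None = None):
    """Apply the filtering cascade; returns (filtered matrix, report).

    Order is fixed: per-species locus sharing r -> pooled MAC -> SNP
    call rate -> individual call rate.  The report is a DataFrame with
    one row per step giving SNPs/individuals remaining, so the cascade
    is auditable.
    """
    f = f or FilterConfig()
    if g.n_snp == 0 or g.n_ind == 0:
        raise ValueError("empty genotype matrix")
    report = []

    def log(step, gg):
        report.append({"step": step, "n_snp": gg.n_snp, "n_ind": gg.n_ind})

    log("input", g)

    # 1. locus sharing: a locus is kept only if, within every species,
    #    >= r of that species' individuals have >= 1 called genotype on it
    loci = g.snp_meta["locus"].to_numpy()
    keep_locus: dict = {}
    called = g.genotypes != MISSING
    for locus in pd.unique(loci):
        cols = loci == locus
        ok = True
        for sp in g.species_names():
            rows = g.species == sp
            if rows.sum() == 0:
                continue
            share = (called[np.ix_(rows, cols)].any(axis=1)).mean()
            if share < f.r:
                ok = False
                break
        keep_locus[locus] = ok
    g = g.take_snp(np.array([keep_locus[l] for l in loci]))
    log("locus_sharing", g)

    # 2. MAC on the pooled sample (ties at 50% pass by convention)
    alt, n_alleles = _allele_counts(g.genotypes)
    mac = np.minimum(alt, n_alleles - alt)
    g = g.take_snp(mac >= f.mac)
    log("mac", g)

    # 3. SNP call rate
    call = (g.genotypes != MISSING).mean(axis=0)
    g = g.take_snp(call >= f.snp_call_rate)
    log("snp_call_rate", g)

    # 4. individual call rate
    if g.n_snp > 0:
        ind_call = (g.genotypes != MISSING).mean(axis=1)
        g = g.take_ind(ind_call >= f.ind_call_rate)
    log("ind_call_rate", g)

    if g.n_snp == 0 or g.n_ind == 0:
        raise ValueError("all SNPs or individuals removed by filtering")
    return g, pd.DataFrame(report)


def maf_floor(n_individuals: int) -> float:
    """Smallest observable allele frequency in n diploids: 1/(2n)."""
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    return 1.0 / (2 * n_individuals)


def partition_polymorphism(g: GenotypeMatrix, floor: float | None = None):
    """Partition SNPs by the subset of species in which they segregate.

    A SNP is polymorphic within species s iff its within-s minor allele
    frequency exceeds ``floor`` (0 or None means any segregation
    counts).  Missing genotypes are excluded from the frequency
    denominator; an all-missing species column leaves that SNP
    unclassified for that species (logged via a warning counter).
    """
    names = g.species_names()
    if len(names) != 3:
        raise ValueError(f"partition expects 3 species, found {len(names)}")
    floor = floor or 0.0
    poly = np.zeros((3, g.n_snp), dtype=bool)
    n_unclassifiable = 0
    for k, sp in enumerate(names):
        sub = g.genotypes[g.species == sp]
        alt, n_alleles = _allele_counts(sub)
        empty = n_alleles == 0
        n_unclassifiable += int(empty.sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(empty, 0.0, alt / np.maximum(n_alleles, 1))
        maf = np.minimum(p, 1.0 - p)
        poly[k] = maf > floor
    if n_unclassifiable:
        warnings.warn(
            f"{n_unclassifiable} species x SNP cells had no called genotypes"
        )
    regions: dict[frozenset, int] = {}
    for j in range(g.n_snp):
        subset = frozenset(names[k] for k in range(3) if poly[k, j])
        if subset:
            regions[subset] = regions.get(subset, 0) + 1
    return PolymorphismPartition(
        species=names, regions=regions, total=sum(regions.values())
    )


def pca_genotypes(g: GenotypeMatrix, n_components: int = 10, scale: bool = False):
    """Centered genotype PCA with per-SNP mean imputation of missing calls.

    Returns ``(coords, pct_variance)``.  ``scale=True`` divides each
    SNP column by sqrt(p(1-p)) (allele-frequency scaling).
    """
    from sklearn.decomposition import PCA

    if g.n_ind < 2 or g.n_snp < 2:
        raise ValueError("PCA needs >= 2 individuals and >= 2 SNPs")
    x = g.genotypes.astype(float)
    miss = x == MISSING
    x[miss] = np.nan
    col_mean = np.nanmean(x, axis=0)
    if np.isnan(col_mean).any():
        raise ValueError("SNP column with no called genotypes")
    x = np.where(np.isnan(x), col_mean, x)
    x -= col_mean
    if scale:
        p = col_mean / 2.0
        sd = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
        x /= sd
    if not np.any(x):
        raise ValueError("constant genotype matrix: PCA undefined")
    n_components = min(n_components, g.n_ind - 1, g.n_snp)
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=0)
    coords = pca.fit_transform(x)
    pct = 100.0 * pca.explained_variance_ratio_
    return coords, pct


def fst_wc(g: GenotypeMatrix, grouping: str = "species"):
    """Weir–Cockerham FST over groups defined by a metadata column.

    Returns ``(global_fst, per_snp)``: the global estimate is the ratio
    of summed variance components (a / (a+b+c)); per-SNP values may be
    negative and are NaN where undefined.  Groups with < 2 genotyped
    individuals at a SNP are excluded from that SNP.
    """
    labels = g.ind_meta[grouping].to_numpy()
    names = [n for n in pd.unique(labels) if (labels == n).sum() >= 2]
    if len(names) < 2:
        raise ValueError("need >= 2 groups with >= 2 individuals")
    dropped = set(pd.unique(labels)) - set(names)
    if dropped:
        warnings.warn(f"groups with < 2 individuals excluded: {sorted(dropped)}")

    geno = g.genotypes
    n_snp = g.n_snp
    r = len(names)
    # per-group per-SNP sample sizes, allele freqs, het freqs
    n_i = np.zeros((r, n_snp))
    p_i = np.zeros((r, n_snp))
    h_i = np.zeros((r, n_snp))
    for k, name in enumerate(names):
        sub = geno[labels == name]
        called = sub != MISSING
        n_i[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(
                n_i[k] > 0, np.where(called, sub, 0).sum(axis=0) / (2 * n_i[k]), np.nan
            )
            h_i[k] = np.where(
                n_i[k] > 0, np.where(called, sub == 1, False).sum(axis=0) / n_i[k], np.nan
            )

    ok = (n_i >= 2).all(axis=0)
    n_i, p_i, h_i = n_i[:, ok], p_i[:, ok], h_i[:, ok]
    n_bar = n_i.mean(axis=0)
    n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0

    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp_ok = np.where(denom != 0, a / denom, np.nan)
    per_snp = np.full(n_snp, np.nan)
    per_snp[ok] = per_snp_ok
    global_fst = float(a.sum() / denom.sum())
    return global_fst, per_snp


def pi_dxy_rad(g: GenotypeMatrix, locus_len: int | None = None, per_variant: bool = False):
    """Per-site pi per species, and dXY / dA per species pair.

    pi uses the unbiased per-SNP heterozygosity 2*p*q*n/(n-1) summed
    over SNPs; dXY sums the between-species mismatch probability
    p1(1-p2) + p2(1-p1).  The denominator is the total sequenced length
    (n_loci x locus_len) by default, or the SNP count if
    ``per_variant``.  Returns ``(pi: dict, pairs: DataFrame)``.
    """
    locus_len = locus_len or g.locus_len
    n_loci = g.snp_meta["locus"].nunique()
    total_sites = g.n_snp if per_variant else n_loci * locus_len
    if total_sites == 0:
        raise ValueError("zero total sequence length")
    names = g.species_names()
    freqs: dict[str, np.ndarray] = {}
    pis: dict[str, float] = {}
    for sp in names:
        sub = g.genotypes[g.species == sp]
        alt, n_alleles = _allele_counts(sub)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        freqs[sp] = p
        n = n_alleles.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            het = np.where(
                n >= 2, 2 * p * (1 - p) * n / np.maximum(n - 1, 1), np.nan
            )
        pis[sp] = float(np.nansum(het) / total_sites)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            pa, pb = freqs[a], freqs[b]
            mism = pa * (1 - pb) + pb * (1 - pa)
            d_xy = float(np.nansum(mism) / total_sites)
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "dxy": d_xy,
                    "da": net_divergence(d_xy, pis[a], pis[b]),
                }
            )
    return pis, pd.DataFrame(rows)


def genotyping_error_rate(replicates: GenotypeMatrix, triplet_col: str = "triplet") -> float:
    """Discordance rate across replicate genotype calls of the same sample.

    ``replicates.ind_meta[triplet_col]`` groups rows that are copies of
    one individual.  The rate is the fraction of discordant calls over
    all within-group pairs at SNPs where both copies are called.
    """
    groups = replicates.ind_meta[triplet_col].to_numpy()
    mism = 0
    comp = 0
    for t in pd.unique(groups):
        rows = np.flatnonzero(groups == t)
        if len(rows) < 2:
            continue
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a = replicates.genotypes[rows[i]]
                b = replicates.genotypes[rows[j]]
                both = (a != MISSING) & (b != MISSING)
                if not both.any():
                    warnings.warn(
                        f"replicate pair in group {t!r} shares no called SNPs; skipped"
                    )
                    continue
                mism += int((a[both] != b[both]).sum())
                comp += int(both.sum())
    if comp == 0:
        raise ValueError("no comparable replicate genotype calls")
    return mism / comp
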
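"""Coding-sequence divergence: NG86 dN/dS counting and the MK test.

The pairwise counting estimator of Nei & Gojobori (1986) is implemented
from first principles: synonymous/nonsynonymous site counts by
enumerating the three possible changes at each codon position, observed
differences by averaging over all minimal mutational pathways between
two codons (pathways through stop codons excluded), and the
Jukes–Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

Genetic codes are NCBI translation tables via Biopython (1 = standard,
5 = invertebrate mitochondrial).  Mutations that create a stop codon
count as nonsynonymous in the site totals, the original NG86
convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from Bio.Data import CodonTable
from scipy.stats import fisher_exact

from .mito import HaplotypeAlignment, dxy as _dxy, net_divergence, nucleotide_diversity

__all__ = [
    "CodonAlignment",
    "DnDsResult",
    "MKTable",
    "ng86_pair",
    "omega_ratio",
    "concat_divergence",
    "mk_test",
]

_BASES = "ACGT"


def _table(code: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code]


def _is_clean(codon: str) -> bool:
    return len(codon) == 3 and all(b in _BASES for b in codon)


@dataclass
class CodonAlignment:
    """In-frame aligned coding sequences with species labels.

    Validates frame (length divisible by 3) and the absence of internal
    stop codons (terminal stops are allowed and trimmed on request by
    the caller).  ``code`` is the NCBI translation table id.
    """

    sequences: list[str]
    ids: list[str]
    species: list[str]
    code: int = 1

    def __post_init__(self):
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("ragged codon alignment")
        (L,) = lengths
        if L % 3 != 0:
            raise ValueError(f"alignment length {L} not divisible by 3")
        stops = set(_table(self.code).stop_codons)
        for sid, s in zip(self.ids, self.sequences):
            for k in range(0, L - 3, 3):  # internal codons only
                if s[k : k + 3] in stops:
                    raise ValueError(f"internal stop codon in {sid} at codon {k // 3}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codons(self, i: int) -> list[str]:
        s = self.sequences[i]
        return [s[k : k + 3] for k in range(0, len(s), 3)]


@dataclass
class DnDsResult:
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    omega: float | None          # None when dS == 0
    saturated: bool = False      # True when a JC correction was undefined


@dataclass
class MKTable:
    Dn: int
    Ds: int
    Pn: int
    Ps: int
    neutrality_index: float | None
    p_value: float | None


def _site_counts(codon: str, code: int):
    """(N, S) mutational-fate site counts for one codon."""
    tbl = _table(code)
    aa = tbl.forward_table[codon]
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in tbl.stop_codons and tbl.forward_table[alt] == aa:
                syn += 1
    s = syn / 3.0
    return 3.0 - s, s


def _path_diffs(c1: str, c2: str, code: int):
    """(Nd, Sd) averaged over minimal mutational pathways c1 -> c2.

    Pathways passing through a stop codon are excluded; if every
    pathway hits a stop, stop-passing pathways are reluctantly allowed
    (their stop-involving steps counted as nonsynonymous) so the codon
    still contributes its differences.
    """
    tbl = _table(code)
    stops = set(tbl.stop_codons)
    diff_pos = [k for k in range(3) if c1[k] != c2[k]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = c1
        nd = sd = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops:
                if not allow_stops:
                    return None
                nd += 1.0
            elif cur in stops:
                nd += 1.0
            elif tbl.forward_table[cur] == tbl.forward_table[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return nd, sd

    results = [r for r in (walk(o, False) for o in permutations(diff_pos)) if r]
    if not results:
        results = [walk(o, True) for o in permutations(diff_pos)]
    nd = sum(r[0] for r in results) / len(results)
    sd = sum(r[1] for r in results) / len(results)
    return nd, sd


def _jc(p: float):
    """Jukes–Cantor correction; returns (d, saturated)."""
    if p == 0.0:
        return 0.0, False
    if p >= 0.75:
        return math.inf, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def ng86_pair(seq_a: str, seq_b: str, code: int = 1) -> DnDsResult:
    """NG86 pairwise dN/dS between two in-frame coding sequences.

    Codons containing gaps, ambiguity codes, or a stop in either
    sequence are skipped.  Site counts are averaged over the two
    sequences; the JC correction maps proportions to rates.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    if len(seq_a) % 3:
        raise ValueError("sequence length not divisible by 3")
    stops = set(_table(code).stop_codons)
    N = S = Nd = Sd = 0.0
    for k in range(0, len(seq_a), 3):
        ca, cb = seq_a[k : k + 3], seq_b[k : k + 3]
        if not (_is_clean(ca) and _is_clean(cb)) or ca in stops or cb in stops:
            continue
        na, sa = _site_counts(ca, code)
        nb, sb = _site_counts(cb, code)
        N += (na + nb) / 2.0
        S += (sa + sb) / 2.0
        nd, sd = _path_diffs(ca, cb, code)
        Nd += nd
        Sd += sd
    if N + S == 0:
        raise ValueError("no comparable codons")
    pN = Nd / N if N else 0.0
    pS = Sd / S if S else 0.0
    dN, satN = _jc(pN)
    dS, satS = _jc(pS)
    saturated = satN or satS
    if saturated:
        warnings.warn("difference proportion >= 3/4: JC correction saturated")
    omega = None if (dS == 0.0 or not math.isfinite(dS)) else dN / dS
    return DnDsResult(N, S, Nd, Sd, pN, pS, dN, dS, omega, saturated)


def omega_ratio(dN: float, dS: float) -> float | None:
    """dN/dS; None (undefined) when dS = 0."""
    if dS == 0.0:
        warnings.warn("dS = 0: omega undefined")
        return None
    return dN / dS


def concat_divergence(alns: list[CodonAlignment], species_a: str, species_b: str):
    """pi / dXY / dA over a site-weighted concatenation of gene alignments.

    Each gene must carry at least one sequence per species.  The genes
    are concatenated (per-species sequence sets are combined gene by
    gene over all within-species combinations implicitly through the
    per-gene pair averages, weighted by gene length), and the
    per-site statistics delegate to the haplotype-alignment machinery.
    Returns a dict with keys ``pi_a, pi_b, dxy, da, sites``.
    """
    if not alns:
        raise ValueError("no gene alignments")
    tot = 0
    acc = {"pi_a": 0.0, "pi_b": 0.0, "dxy": 0.0}
    for aln in alns:
        idx_a = [i for i, s in enumerate(aln.species) if s == species_a]
        idx_b = [i for i, s in enumerate(aln.species) if s == species_b]
        if not idx_a or not idx_b:
            raise ValueError(
                f"gene without sequences for {species_a!r} or {species_b!r}"
            )
        ha = HaplotypeAlignment(
            [aln.sequences[i] for i in idx_a],
            [aln.ids[i] for i in idx_a],
            [species_a] * len(idx_a),
        )
        hb = HaplotypeAlignment(
            [aln.sequences[i] for i in idx_b],
            [aln.ids[i] for i in idx_b],
            [species_b] * len(idx_b),
        )
        L = aln.length
        tot += L
        acc["pi_a"] += L * (nucleotide_diversity(ha) if len(idx_a) > 1 else 0.0)
        acc["pi_b"] += L * (nucleotide_diversity(hb) if len(idx_b) > 1 else 0.0)
        acc["dxy"] += L * _dxy(ha, hb)
    pi_a, pi_b, d_xy = acc["pi_a"] / tot, acc["pi_b"] / tot, acc["dxy"] / tot
    return {
        "pi_a": pi_a,
        "pi_b": pi_b,
        "dxy": d_xy,
        "da": net_divergence(d_xy, pi_a, pi_b),
        "sites": tot,
    }


def mk_test(within: CodonAlignment, outgroup: CodonAlignment | list[str]) -> MKTable:
    """McDonald–Kreitman 2x2 contrast for one species against an outgroup.

    Walks codon by codon.  At each nucleotide position, within-species
    variation is classified as a synonymous or nonsynonymous
    polymorphism by mutating the major-allele codon; positions
    monomorphic within the species but different from all outgroup
    alleles are fixed differences, classified the same way.  Sites that
    are both polymorphic and divergent contribute to both margins once
    each (the original MK accounting).  Codons with non-ACGT states in
    any sequence are skipped.
    """
    if len(within.sequences) < 2:
        raise ValueError("MK test needs >= 2 within-species sequences")
    if isinstance(outgroup, CodonAlignment):
        out_seqs = outgroup.sequences
        if outgroup.length != within.length:
            raise ValueError("outgroup alignment length mismatch")
    else:
        out_seqs = [s.upper() for s in outgroup]
        if any(len(s) != within.length for s in out_seqs):
            raise ValueError("outgroup sequence length mismatch")
    if not out_seqs:
        raise ValueError("MK test needs >= 1 outgroup sequence")

    code = within.code
    tbl = _table(code)
    Dn = Ds = Pn = Ps = 0

    def is_syn(codon, pos, b_from, b_to):
        c1 = codon[:pos] + b_from + codon[pos + 1 :]
        c2 = codon[:pos] + b_to + codon[pos + 1 :]
        if c1 in tbl.stop_codons or c2 in tbl.stop_codons:
            return False
        return tbl.forward_table[c1] == tbl.forward_table[c2]

    for k in range(0, within.length, 3):
        in_codons = [s[k : k + 3] for s in within.sequences]
        out_codons = [s[k : k + 3] for s in out_seqs]
        if not all(_is_clean(c) for c in in_codons + out_codons):
            continue
        if any(c in tbl.stop_codons for c in in_codons + out_codons):
            continue
        # major-allele codon gives the mutational context
        counts: dict[str, int] = {}
        for c in in_codons:
            counts[c] = counts.get(c, 0) + 1
        major = max(counts, key=lambda c: (counts[c], c))
        for pos in range(3):
            in_alleles = {c[pos] for c in in_codons}
            out_alleles = {c[pos] for c in out_codons}
            if len(in_alleles) > 1:
                ref = major[pos]
                for b in in_alleles - {ref}:
                    if is_syn(major, pos, ref, b):
                        Ps += 1
                    else:
                        Pn += 1
            if not (in_alleles & out_alleles):
                b_in = major[pos]
                b_out = sorted(out_alleles)[0]
                if is_syn(major, pos, b_in, b_out):
                    Ds += 1
                else:
                    Dn += 1

    if Dn + Ds + Pn + Ps == 0:
        return MKTable(0, 0, 0, 0, None, None)
    _, p = fisher_exact([[Dn, Ds], [Pn, Ps]], alternative="two-sided")
    ni = None
    if Ds > 0 and Dn > 0 and Ps > 0:
        ni = (Pn / Ps) / (Dn / Ds)
    return MKTable(Dn, Ds, Pn, Ps, ni, float(p))
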
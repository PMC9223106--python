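"""Mitochondrial barcode analysis.

Haplotype-level statistics for a single aligned marker (e.g. a Cox1
fragment): haplotype collapsing, haplotype and nucleotide diversity,
absolute (dXY) and net (dA) divergence between species, a
haplotype-frequency FST, nearest-reference species assignment, and a
median-joining haplotype network.

All sequence-based statistics treat ``N`` and ``-`` as missing and use
pairwise deletion by default: each pair of sequences is compared only at
sites where both carry an unambiguous base, and the per-pair difference
proportion is taken over that pair's own valid-site count.  Complete
deletion (drop any site with a missing state in any sequence) is
available through a flag.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

__all__ = [
    "HaplotypeAlignment",
    "DiversitySummary",
    "HaploNetwork",
    "collapse_haplotypes",
    "haplotype_diversity",
    "nucleotide_diversity",
    "dxy",
    "net_divergence",
    "fst_haplotype",
    "assign_species",
    "median_joining_network",
    "round_half_away",
]

_VALID = frozenset(b"ACGT")


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round with ties going away from zero (report-table convention).

    Python's built-in ``round`` uses banker's rounding; diversity tables
    in the population-genetics literature round half away from zero
    (0.0275 -> 0.028 at 3 decimals), so report code must use this.
    """
    factor = 10.0**ndigits
    scaled = x * factor
    # small epsilon so binary representation error (0.0855 -> 85.4999...)
    # does not flip a true half downward
    return float(np.copysign(np.floor(np.abs(scaled) + 0.5 + 1e-9), scaled) / factor)


@dataclass
class HaplotypeAlignment:
    """Equal-length haploid sequences with individual and species labels.

    Sequences are stored as an ``(n, L)`` uint8 matrix of ASCII codes so
    pairwise comparisons vectorise; the constructor accepts plain
    strings.
    """

    ids: list[str]
    species: list[str]
    matrix: np.ndarray = field(repr=False)

    def __init__(self, sequences, ids, species):
        sequences = [s.upper() if isinstance(s, str) else s for s in sequences]
        if len(sequences) == 0:
            raise ValueError("alignment must contain at least one sequence")
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids must be unique")
        if not (len(ids) == len(species) == len(sequences)):
            raise ValueError("ids, species and sequences must have equal length")
        self.ids = list(ids)
        self.species = list(species)
        self.matrix = np.frombuffer(
            "".join(sequences).encode("ascii"), dtype=np.uint8
        ).reshape(len(sequences), -1).copy()

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, i: int) -> str:
        return self.matrix[i].tobytes().decode("ascii")

    def subset(self, idx) -> "HaplotypeAlignment":
        idx = list(idx)
        return HaplotypeAlignment(
            [self.sequence(i) for i in idx],
            [self.ids[i] for i in idx],
            [self.species[i] for i in idx],
        )

    def by_species(self, name: str) -> "HaplotypeAlignment":
        idx = [i for i, s in enumerate(self.species) if s == name]
        if not idx:
            raise ValueError(f"no sequences labelled {name!r}")
        return self.subset(idx)

    def species_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(s)
        return list(seen)


@dataclass
class DiversitySummary:
    """Single-population diversity summary (table-row currency)."""

    N: int
    K: int
    H: int
    Hd: float
    pi: float


@dataclass
class HaploNetwork:
    graph: nx.Graph
    median_vectors: list[str]


def _valid_mask(matrix: np.ndarray) -> np.ndarray:
    return (
        (matrix == ord("A"))
        | (matrix == ord("C"))
        | (matrix == ord("G"))
        | (matrix == ord("T"))
    )


def _pair_stats(matrix_a, matrix_b, complete_deletion=False, cross_only=True):
    """Mean per-site difference proportion over sequence pairs.

    If ``matrix_b is None`` all unordered pairs within ``matrix_a`` are
    used; otherwise all between-matrix pairs.  Pairs with zero mutually
    valid sites are skipped with a warning.
    """
    va = _valid_mask(matrix_a)
    if matrix_b is None:
        matrix_b, vb = matrix_a, va
        pairs = combinations(range(matrix_a.shape[0]), 2)
    else:
        vb = _valid_mask(matrix_b)
        pairs = (
            (i, j)
            for i in range(matrix_a.shape[0])
            for j in range(matrix_b.shape[0])
        )
    if complete_deletion:
        keep = va.all(axis=0) & vb.all(axis=0)
        va = vb = None
    total, count = 0.0, 0
    for i, j in pairs:
        if complete_deletion:
            ok = keep
        else:
            ok = va[i] & vb[j]
        denom = int(ok.sum())
        if denom == 0:
            warnings.warn("sequence pair with no mutually valid sites skipped")
            continue
        diff = int((matrix_a[i][ok] != matrix_b[j][ok]).sum())
        total += diff / denom
        count += 1
    if count == 0:
        raise ValueError("no comparable sequence pairs")
    return total / count


def collapse_haplotypes(aln: HaplotypeAlignment):
    """Collapse identical sequences into a haplotype table.

    Sequences are compared as literal strings: ``N``/``-`` states make a
    sequence its own haplotype unless another sequence matches exactly.
    Returns a list of dicts ``{sequence, count, species_counts}`` in
    decreasing count order; counts sum to the sample size.
    """
    table: dict[str, Counter] = {}
    for i in range(aln.n):
        table.setdefault(aln.sequence(i), Counter())[aln.species[i]] += 1
    rows = [
        {
            "sequence": seq,
            "count": sum(cnt.values()),
            "species_counts": dict(cnt),
        }
        for seq, cnt in table.items()
    ]
    rows.sort(key=lambda r: (-r["count"], r["sequence"]))
    return rows


def haplotype_diversity(counts) -> float:
    """Nei's haplotype diversity Hd = n(1 - sum p_i^2)/(n - 1)."""
    counts = np.asarray(list(counts), dtype=float)
    if (counts < 1).any():
        raise ValueError("haplotype counts must be >= 1")
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs a sample of at least 2")
    p = counts / n
    return float(n / (n - 1) * (1.0 - (p**2).sum()))


def nucleotide_diversity(aln: HaplotypeAlignment, complete_deletion=False) -> float:
    """Per-site nucleotide diversity: mean pairwise difference proportion."""
    if aln.n < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    return _pair_stats(aln.matrix, None, complete_deletion)


def dxy(alnA: HaplotypeAlignment, alnB: HaplotypeAlignment, complete_deletion=False) -> float:
    """Absolute divergence dXY: mean difference proportion over all A x B pairs."""
    if alnA.length != alnB.length:
        raise ValueError(
            f"alignment length mismatch: {alnA.length} vs {alnB.length}"
        )
    return _pair_stats(alnA.matrix, alnB.matrix, complete_deletion)


def net_divergence(dxy_value: float, piA: float, piB: float) -> float:
    """Net divergence dA = dXY - (piA + piB)/2.

    dA removes the expected contribution of ancestral polymorphism from
    dXY; it can be negative for very recent splits, which is allowed.
    """
    if min(dxy_value, piA, piB) < 0:
        raise ValueError("dXY and pi must be non-negative")
    da = dxy_value - (piA + piB) / 2.0
    if da < 0:
        warnings.warn(f"negative net divergence ({da:.4g}): very recent split?")
    return da


def diversity_summary(aln: HaplotypeAlignment) -> DiversitySummary:
    """N, segregating sites K, haplotype count H, Hd and pi for one sample."""
    rows = collapse_haplotypes(aln)
    valid = _valid_mask(aln.matrix)
    K = 0
    for s in range(aln.length):
        col = aln.matrix[valid[:, s], s]
        if col.size and (col != col[0]).any():
            K += 1
    hd = haplotype_diversity([r["count"] for r in rows]) if aln.n >= 2 else 0.0
    return DiversitySummary(
        N=aln.n,
        K=K,
        H=len(rows),
        Hd=hd,
        pi=nucleotide_diversity(aln) if aln.n >= 2 else 0.0,
    )


def fst_haplotype(alnA: HaplotypeAlignment, alnB: HaplotypeAlignment) -> float:
    """Haplotype-frequency FST (no molecular distance, i.e. not PhiST).

    FST = (Hb - Hw)/Hb with Hw the mean within-group haplotype
    heterozygosity (1 - sum p_i^2) and Hb the probability that one
    haplotype from each group differ (1 - sum p_i q_i).  Clipped to
    [-1, 1]; a pooled-monomorphic sample returns 0 with a warning.
    """
    if alnA.n < 2 or alnB.n < 2:
        raise ValueError("each sample needs >= 2 sequences")

    def freqs(aln):
        c = Counter(aln.sequence(i) for i in range(aln.n))
        return {h: k / aln.n for h, k in c.items()}

    pa, pb = freqs(alnA), freqs(alnB)
    if len(pa) == 1 and pa == pb:
        warnings.warn("pooled sample is monomorphic; FST undefined, returning 0")
        return 0.0
    hw = 0.5 * (
        (1.0 - sum(v**2 for v in pa.values()))
        + (1.0 - sum(v**2 for v in pb.values()))
    )
    hb = 1.0 - sum(pa.get(h, 0.0) * pb.get(h, 0.0) for h in set(pa) | set(pb))
    if hb == 0.0:
        warnings.warn("zero between-group mismatch probability; returning 0")
        return 0.0
    return float(np.clip((hb - hw) / hb, -1.0, 1.0))


def phist_haplotype(alnA: HaplotypeAlignment, alnB: HaplotypeAlignment) -> float:
    """Distance-weighted analogue of :func:`fst_haplotype` (PhiST-like).

    Uses mean pairwise nucleotide differences within and between groups:
    PhiST = (db - dw)/db, with dw the average of the two within-group
    mean pairwise distances.  Provided for comparison; the
    frequency-only estimator is the default elsewhere.
    """
    dw = 0.5 * (nucleotide_diversity(alnA) + nucleotide_diversity(alnB))
    db = dxy(alnA, alnB)
    if db == 0.0:
        warnings.warn("zero between-group distance; PhiST undefined, returning 0")
        return 0.0
    return float(np.clip((db - dw) / db, -1.0, 1.0))


def assign_species(query: str, references: HaplotypeAlignment):
    """Assign a query sequence to the species of its nearest reference.

    Distance is the uncorrected p-distance over mutually valid sites.
    Returns ``(species, distance, ambiguous)``; ``ambiguous`` is True if
    two references from different species tie for the minimum.
    """
    query = query.upper()
    if len(query) != references.length:
        raise ValueError(
            f"query length {len(query)} != reference length {references.length}"
        )
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    qv = _valid_mask(q[None, :])[0]
    rv = _valid_mask(references.matrix)
    best: list[tuple[float, str]] = []
    for i in range(references.n):
        ok = qv & rv[i]
        if not ok.any():
            continue
        d = float((q[ok] != references.matrix[i][ok]).sum() / ok.sum())
        best.append((d, references.species[i]))
    if not best:
        raise ValueError("query shares no valid sites with any reference")
    best.sort(key=lambda t: t[0])
    dmin = best[0][0]
    tied = {sp for d, sp in best if d == dmin}
    return best[0][1], dmin, len(tied) > 1


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _msn_graph(haps: list[str], epsilon: int) -> nx.Graph:
    """Minimum spanning network: union of MST edges plus ties within epsilon.

    Kruskal-style: process candidate edges by increasing Hamming weight;
    an edge is kept if its endpoints are in different components at the
    start of its weight class (plus ``epsilon`` slack), which yields the
    union of all minimum spanning trees when epsilon = 0.
    """
    g = nx.Graph()
    g.add_nodes_from(haps)
    if len(haps) < 2:
        return g
    edges = sorted(
        (( _hamming(a, b), a, b) for a, b in combinations(haps, 2)),
        key=lambda t: t[0],
    )
    comp = nx.utils.UnionFind(haps)
    i = 0
    while i < len(edges) and not nx.is_connected(g):
        w = edges[i][0]
        block = [e for e in edges if w <= e[0] <= w + epsilon]
        snapshot = {h: comp[h] for h in haps}
        for bw, a, b in block:
            if snapshot[a] != snapshot[b]:
                g.add_edge(a, b, weight=bw)
                comp.union(a, b)
        i = next(
            (k for k, e in enumerate(edges) if e[0] > w + epsilon), len(edges)
        )
    return g


def median_joining_network(haplotypes, epsilon: int = 0) -> HaploNetwork:
    """Median-joining haplotype network.

    ``haplotypes`` is the table from :func:`collapse_haplotypes` (or a
    plain list of sequences).  Builds a minimum spanning network and
    greedily adds median (Steiner) vectors — per-site majority
    consensus of connected observed triplets — whenever they reduce the
    total spanning cost.  With epsilon = 0 and no profitable median the
    result is the minimum spanning network.
    """
    if haplotypes and isinstance(haplotypes[0], dict):
        meta = {r["sequence"]: r for r in haplotypes}
        haps = [r["sequence"] for r in haplotypes]
    else:
        haps = list(haplotypes)
        meta = {h: {"sequence": h, "count": 1, "species_counts": {}} for h in haps}
    if len(haps) < 2:
        raise ValueError("network needs >= 2 haplotypes")

    def spanning_cost(nodes):
        full = nx.Graph()
        for a, b in combinations(nodes, 2):
            full.add_edge(a, b, weight=_hamming(a, b))
        return sum(
            d["weight"] for _, _, d in nx.minimum_spanning_edges(full, data=True)
        )

    def median(a, b, c):
        out = []
        for x, y, z in zip(a, b, c):
            if y == z:
                out.append(y)
            else:
                out.append(x)  # majority if exists, else first sequence's state
        return "".join(out)

    nodes = list(haps)
    medians: list[str] = []
    improved = True
    while improved:
        improved = False
        cost = spanning_cost(nodes)
        for trip in combinations(haps, 3):
            m = median(*trip)
            if m in nodes:
                continue
            if spanning_cost(nodes + [m]) < cost:
                nodes.append(m)
                medians.append(m)
                improved = True
                break

    g = _msn_graph(nodes, epsilon)
    for h in nodes:
        info = meta.get(h, {"sequence": h, "count": 0, "species_counts": {}})
        g.nodes[h]["count"] = info["count"]
        g.nodes[h]["species_counts"] = dict(info["species_counts"])
        g.nodes[h]["median_vector"] = h in medians
    return HaploNetwork(graph=g, median_vectors=medians)
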
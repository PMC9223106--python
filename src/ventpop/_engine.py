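"""Structured-coalescent genealogy engine.

Simulates the genealogy of samples from an arbitrary number of
populations backward in time under piecewise-constant population sizes,
piecewise-constant backward migration rates, and population merges,
using Gillespie sampling of exponential waiting times within each
epoch.  Mutations are dropped afterwards, either as infinite-sites
bi-allelic variants (each mutation defines a carrier set) or as
finite-sites Jukes–Cantor sequence evolution from a root sequence
(needed for realistic mtDNA and codon alignments with multiple hits).

Sizes are expressed in *gene copies* (2N for a diploid autosomal locus,
2N/4 for a maternally inherited haploid locus), so the coalescence rate
for k lineages in a population with ``copies`` gene copies is
k(k-1)/2 / copies per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Epoch", "Genealogy", "simulate_genealogy"]


@dataclass
class Epoch:
    """Demographic regime starting at backward time ``start``.

    ``copies[p]`` is the gene-copy count of population p during the
    epoch; ``mig[p][q]`` is the per-lineage per-generation backward
    migration rate from p to q; ``merge`` is a list of (src, dst) pairs
    applied when the epoch begins (all lineages of src move to dst and
    src becomes inactive).
    """

    start: float
    copies: list[float]
    mig: list[list[float]] | None = None
    merge: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class Genealogy:
    n_samples: int
    sample_pops: list[int]
    parent: np.ndarray
    blen: np.ndarray
    time: np.ndarray
    children: list[list[int]]
    root: int

    @property
    def total_length(self) -> float:
        return float(self.blen.sum())

    def leaf_masks(self) -> list[int]:
        """Descendant-leaf bitmask for every node (leaves are bits 0..n-1)."""
        n_nodes = len(self.parent)
        masks = [0] * n_nodes
        for i in range(self.n_samples):
            masks[i] = 1 << i
        # nodes are created in increasing time order, so a forward pass works
        for i in range(n_nodes):
            for c in self.children[i]:
                masks[i] |= masks[c]
        return masks

    def num_lineage_checks(self) -> tuple[int, int]:
        """(number of coalescences, leaves) — conservation diagnostics."""
        n_coal = sum(1 for c in self.children if len(c) == 2)
        return n_coal, self.n_samples


def simulate_genealogy(sample_sizes, epochs, rng) -> Genealogy:
    """Simulate one genealogy.

    ``sample_sizes[p]`` leaves start in population p at time 0;
    ``epochs`` must start with an epoch at time 0 and be sorted by
    start time.  Raises if lineages cannot fully coalesce (no merge
    path to a common population).
    """
    n_pops = len(sample_sizes)
    if epochs[0].start != 0.0:
        raise ValueError("first epoch must start at time 0")
    n = int(sum(sample_sizes))
    if n < 2:
        raise ValueError("need at least 2 sampled lineages")

    time = [0.0] * n
    parent = [-1] * n
    children: list[list[int]] = [[] for _ in range(n)]
    pops: list[list[int]] = [[] for _ in range(n_pops)]
    sample_pops: list[int] = []
    nid = 0
    for p, k in enumerate(sample_sizes):
        for _ in range(int(k)):
            pops[p].append(nid)
            sample_pops.append(p)
            nid += 1

    t = 0.0
    ei = 0
    copies = list(epochs[0].copies)
    mig = [row[:] for row in epochs[0].mig] if epochs[0].mig else [
        [0.0] * n_pops for _ in range(n_pops)
    ]
    n_alive = n

    def enter_epoch(e: Epoch):
        nonlocal copies, mig
        for src, dst in e.merge:
            pops[dst].extend(pops[src])
            pops[src] = []
        copies = list(e.copies)
        mig = [row[:] for row in e.mig] if e.mig else [
            [0.0] * n_pops for _ in range(n_pops)
        ]

    while n_alive > 1:
        next_boundary = epochs[ei + 1].start if ei + 1 < len(epochs) else np.inf
        # per-population event rates under the current regime
        coal_rates = [
            (len(pops[p]) * (len(pops[p]) - 1) / 2.0) / copies[p]
            if len(pops[p]) > 1
            else 0.0
            for p in range(n_pops)
        ]
        mig_rates = [
            [len(pops[p]) * mig[p][q] if p != q else 0.0 for q in range(n_pops)]
            for p in range(n_pops)
        ]
        total = sum(coal_rates) + sum(map(sum, mig_rates))
        if total <= 0.0:
            if not np.isfinite(next_boundary):
                raise RuntimeError(
                    "lineages cannot coalesce: no events possible and no further epoch"
                )
            t = next_boundary
            ei += 1
            enter_epoch(epochs[ei])
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt >= next_boundary:
            t = next_boundary
            ei += 1
            enter_epoch(epochs[ei])
            continue
        t += dt
        u = rng.uniform(0.0, total)
        acc = 0.0
        done = False
        for p in range(n_pops):
            acc += coal_rates[p]
            if u < acc:
                k = len(pops[p])
                i = int(rng.integers(k))
                j = int(rng.integers(k - 1))
                if j >= i:
                    j += 1
                a, b = pops[p][i], pops[p][j]
                time.append(t)
                parent.append(-1)
                children.append([a, b])
                parent[a] = nid
                parent[b] = nid
                for idx in sorted((i, j), reverse=True):
                    pops[p].pop(idx)
                pops[p].append(nid)
                nid += 1
                n_alive -= 1
                done = True
                break
        if not done:
            for p in range(n_pops):
                for q in range(n_pops):
                    acc += mig_rates[p][q]
                    if u < acc:
                        k = int(rng.integers(len(pops[p])))
                        pops[q].append(pops[p].pop(k))
                        done = True
                        break
                if done:
                    break

    parent_arr = np.array(parent)
    time_arr = np.array(time)
    blen = np.where(parent_arr >= 0, time_arr[parent_arr] - time_arr, 0.0)
    return Genealogy(
        n_samples=n,
        sample_pops=sample_pops,
        parent=parent_arr,
        blen=blen,
        time=time_arr,
        children=children,
        root=nid - 1,
    )


def drop_infinite_sites(gen: Genealogy, mu_per_site: float, length: int, rng):
    """Infinite-sites mutations: one carrier bitmask per segregating site.

    The number of mutations is Poisson(mu * L * total tree length); each
    lands on a branch with probability proportional to its length and
    marks that branch's descendant leaves as derived.  Returns a list of
    integer bitmasks (possibly empty).
    """
    total = gen.total_length
    n_mut = rng.poisson(mu_per_site * length * total)
    if n_mut == 0:
        return []
    masks = gen.leaf_masks()
    p = gen.blen / total
    branch_idx = rng.choice(len(p), size=n_mut, p=p)
    full = (1 << gen.n_samples) - 1
    out = []
    for b in branch_idx:
        m = masks[int(b)]
        if m != 0 and m != full:
            out.append(m)
    return out


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def drop_jc_sequences(gen: Genealogy, mu_per_site: float, length: int, rng,
                      root_seq: np.ndarray | None = None):
    """Finite-sites Jukes–Cantor sequence evolution down the genealogy.

    Each branch receives Poisson(mu * L * blen) mutations, each at a
    uniform position to a uniformly chosen different base (multiple
    hits possible).  Returns an (n_samples, L) uint8 array of ASCII
    codes.
    """
    if root_seq is None:
        root_seq = _BASES[rng.integers(4, size=length)]
    seqs: dict[int, np.ndarray] = {gen.root: root_seq.copy()}
    out = np.empty((gen.n_samples, length), dtype=np.uint8)
    stack = [gen.root]
    while stack:
        node = stack.pop()
        seq = seqs.pop(node)
        if node < gen.n_samples:
            out[node] = seq
        for c in gen.children[node]:
            child_seq = seq.copy()
            n_mut = rng.poisson(mu_per_site * length * gen.blen[c])
            for _ in range(n_mut):
                pos = int(rng.integers(length))
                cur = child_seq[pos]
                new = _BASES[int(rng.integers(3))]
                if new == cur:
                    new = _BASES[3]
                child_seq[pos] = new
            seqs[c] = child_seq
            stack.append(c)
    return out


def drop_codon_sequences(gen: Genealogy, n_codons: int, mu_per_site: float,
                         omega: float, code_forward: dict, stop_codons: set,
                         rng, root_seq: np.ndarray | None = None):
    """Codon sequence evolution with a nonsynonymous acceptance ratio.

    Neutral mutation attempts arise as in :func:`drop_jc_sequences`;
    an attempt creating a stop codon is discarded, a synonymous change
    is always kept, and a nonsynonymous change is kept with probability
    ``omega`` (so the expected dN/dS of the output is ~omega).
    """
    length = 3 * n_codons

    def codon_at(seq, ci):
        return seq[3 * ci : 3 * ci + 3].tobytes().decode()

    if root_seq is None:
        sense = sorted(set(code_forward) - stop_codons)
        picks = rng.integers(len(sense), size=n_codons)
        root_seq = np.frombuffer(
            "".join(sense[int(i)] for i in picks).encode("ascii"), dtype=np.uint8
        ).copy()
    seqs: dict[int, np.ndarray] = {gen.root: root_seq.copy()}
    out = np.empty((gen.n_samples, length), dtype=np.uint8)
    stack = [gen.root]
    while stack:
        node = stack.pop()
        seq = seqs.pop(node)
        if node < gen.n_samples:
            out[node] = seq
        for c in gen.children[node]:
            child_seq = seq.copy()
            n_mut = rng.poisson(mu_per_site * length * gen.blen[c])
            for _ in range(n_mut):
                pos = int(rng.integers(length))
                ci = pos // 3
                old_codon = codon_at(child_seq, ci)
                cur = child_seq[pos]
                new = _BASES[int(rng.integers(3))]
                if new == cur:
                    new = _BASES[3]
                trial = bytearray(old_codon.encode())
                trial[pos % 3] = int(new)
                new_codon = trial.decode()
                if new_codon in stop_codons:
                    continue
                if code_forward[old_codon] != code_forward[new_codon]:
                    if rng.uniform() >= omega:
                        continue
                child_seq[pos] = new
            seqs[c] = child_seq
            stack.append(c)
    return out
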
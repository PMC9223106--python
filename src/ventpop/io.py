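"""Readers and writers for the formats the pipeline exchanges.

FASTA via Biopython, VCF v4.2 (diploid GT, ``./.`` for missing; read
through cyvcf2, written as plain text since the matrices are generated
in-memory), tab-separated metadata, and JSON truth blocks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mito import HaplotypeAlignment
from .radseq import MISSING, GenotypeMatrix

__all__ = [
    "write_fasta", "read_fasta_alignment", "write_vcf", "read_vcf",
    "write_metadata", "read_metadata", "write_truth", "read_truth",
]


def write_fasta(path, ids, sequences):
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(ids, sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_alignment(path, metadata: pd.DataFrame | None = None,
                         species_col: str = "species") -> HaplotypeAlignment:
    """Read an aligned FASTA; species labels come from metadata (by id)
    or default to 'unknown'."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if metadata is not None:
        species = [str(metadata.loc[i, species_col]) for i in ids]
    else:
        species = ["unknown"] * len(ids)
    return HaplotypeAlignment(seqs, ids, species)


def write_vcf(g: GenotypeMatrix, path):
    """Write a minimal VCF v4.2: one contig per RAD locus, 1-based POS."""
    path = Path(path)
    loci = list(pd.unique(g.snp_meta["locus"]))
    ref = g.snp_meta["ref"] if "ref" in g.snp_meta else pd.Series(["A"] * g.n_snp)
    alt = g.snp_meta["alt"] if "alt" in g.snp_meta else pd.Series(["T"] * g.n_snp)
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for locus in loci:
            fh.write(f"##contig=<ID={locus},length={g.locus_len}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, g.ind_meta.index))
            + "\n"
        )
        for j in range(g.n_snp):
            row = g.snp_meta.iloc[j]
            calls = "\t".join(code[int(v)] for v in g.genotypes[:, j])
            fh.write(
                f"{row['locus']}\t{int(row['pos']) + 1}\t"
                f"{row['locus']}_{int(row['pos'])}\t{ref.iloc[j]}\t{alt.iloc[j]}"
                f"\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path, metadata: pd.DataFrame, locus_len: int = 100) -> GenotypeMatrix:
    """Read a biallelic VCF into a GenotypeMatrix; metadata indexed by
    individual id must cover every sample column."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = var.genotype.array()
        a, b = gts[:, 0], gts[:, 1]
        g = np.where((a < 0) | (b < 0), MISSING, a + b).astype(np.int8)
        rows.append(g)
        meta.append(
            {"locus": var.CHROM, "pos": var.POS - 1, "ref": var.REF,
             "alt": var.ALT[0]}
        )
    genotypes = np.array(rows, dtype=np.int8).T
    ind_meta = metadata.loc[samples]
    return GenotypeMatrix(
        genotypes=genotypes,
        snp_meta=pd.DataFrame(meta),
        ind_meta=ind_meta,
        locus_len=locus_len,
    )


def write_metadata(meta: pd.DataFrame, path):
    meta.to_csv(path, sep="\t", index_label="individual")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual")


def write_truth(truth: dict, path):
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(f"not serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=default, sort_keys=True)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
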
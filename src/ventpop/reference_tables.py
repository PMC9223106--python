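"""Published diversity/divergence estimates for the three vent snail species.

These are the reported values for *Alviniconcha kojimai*, *A. boucheti*
and *A. strummeri* across the three genomic compartments (a 599 bp
mitochondrial Cox1 fragment, a 60,084-SNP ddRAD dataset, and a
1,186,131 bp concatenated transcriptome alignment).  They serve as
inputs for identity-style recomputations (e.g. dA from printed dXY and
pi, omega from printed dN and dS) and as qualitative calibration
targets for the synthetic-data generator.  Nothing in the analysis
code depends on them.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["diversity_table", "divergence_table", "REPORT_DECIMALS"]

# decimals used in the published report tables
REPORT_DECIMALS = {"da": 3, "dxy": 3, "fst": 3, "pi": 4, "omega": 3}

_DIVERSITY = [
    # compartment, species, N, K, H, Hd, pi
    ("cox1", "kojimai", 454, 89, 102, 0.80, 0.003),
    ("cox1", "boucheti", 243, 67, 62, 0.91, 0.004),
    ("cox1", "strummeri", 25, 31, 19, 0.96, 0.008),
    ("transcriptome", "kojimai", 2, 10672, 2, 1.0, 0.004),
    ("transcriptome", "boucheti", 3, 10851, 3, 1.0, 0.003),
    ("transcriptome", "strummeri", 2, 12010, 2, 1.0, 0.005),
    ("radseq", "kojimai", 250, 21397, None, None, 0.0013),
    ("radseq", "boucheti", 212, 40879, None, None, 0.0014),
    ("radseq", "strummeri", 36, 25801, None, None, 0.0014),
]

_DIVERGENCE = [
    # compartment, pair, dA, dXY, FST, dN, dS  (dN/dS where 4-digit
    # values were reported, those are used: kojimai/boucheti
    # transcriptome dN=0.0129, dS=0.0972)
    ("cox1", ("kojimai", "boucheti"), 0.123, 0.126, 0.974, 0.005, 0.784),
    ("cox1", ("kojimai", "strummeri"), 0.086, 0.091, 0.961, 0.007, 0.468),
    ("cox1", ("boucheti", "strummeri"), 0.118, 0.124, 0.967, 0.002, 0.793),
    ("transcriptome", ("kojimai", "boucheti"), 0.028, 0.031, None, 0.0129, 0.0972),
    ("transcriptome", ("kojimai", "strummeri"), 0.016, 0.020, None, 0.008, 0.062),
    ("transcriptome", ("boucheti", "strummeri"), 0.027, 0.031, None, 0.0128, 0.0960),
    ("radseq", ("kojimai", "boucheti"), 0.031, 0.031, 0.922, None, None),
    ("radseq", ("kojimai", "strummeri"), 0.018, 0.018, 0.842, None, None),
    ("radseq", ("boucheti", "strummeri"), 0.031, 0.031, 0.917, None, None),
]


def diversity_table() -> pd.DataFrame:
    return pd.DataFrame(
        _DIVERSITY,
        columns=["compartment", "species", "N", "K", "H", "Hd", "pi"],
    )


def divergence_table() -> pd.DataFrame:
    rows = [
        {
            "compartment": c, "species_a": p[0], "species_b": p[1],
            "da": da, "dxy": dxy, "fst": fst, "dn": dn, "ds": ds,
        }
        for c, p, da, dxy, fst, dn, ds in _DIVERGENCE
    ]
    return pd.DataFrame(rows)
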
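"""Bundled published data for *Corynebacterium glutamicum*.

Two small tables from the published codon-usage study of the
*C. glutamicum* ATCC 13032 genome are shipped with the package so the
core statistics can be exercised on real numbers without the genome:

* pooled codon counts (with their published RSCU values) for the
  putatively highly and lowly expressed gene groups taken from the two
  extremes of the first correspondence-analysis axis, and
* leading/lagging strand gene counts binned by CAI, plus the ribosomal
  proteins as a named set.

The 22 codons significantly over-used in the highly expressed group —
C-ending codons predominate — double as the default "optimal codon" set
for Fop and for synthetic-genome fixtures.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .expression import load_group_counts
from .genetics import as_dna
from .metrics import CodonCountTable

#: Translationally optimal codons of C. glutamicum (DNA alphabet): the 22
#: codons with significantly higher relative usage in highly expressed genes
#: (14 C-ending, 3 G-ending).
CGLUTAMICUM_OPTIMAL_CODONS = frozenset(
    as_dna(c)
    for c in (
        "UUC", "CUC", "CUG", "AUC", "GUU", "GUC", "UAC", "CAC", "CAG",
        "AAC", "AAG", "GAC", "GAA", "UCC", "CCA", "ACC", "GCU", "GCC",
        "GCA", "UGC", "CGC", "GGC",
    )
)


def _data_path(name: str):
    return resources.files("codonuse.data").joinpath(name)


def extreme_group_counts() -> tuple[CodonCountTable, CodonCountTable]:
    """Pooled codon counts of the highly / lowly expressed extreme groups."""
    with resources.as_file(_data_path("cglutamicum_extreme_group_counts.tsv")) as p:
        return load_group_counts(p)


def extreme_group_table() -> pd.DataFrame:
    """The full published usage table (counts and printed RSCU, both groups)."""
    with resources.as_file(_data_path("cglutamicum_extreme_group_counts.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def leading_strand_bins() -> pd.DataFrame:
    """Published leading/lagging gene counts per CAI bin (plus ribosomal set)."""
    with resources.as_file(_data_path("cglutamicum_leading_strand_bins.tsv")) as p:
        return pd.read_csv(p, sep="\t")
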
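"""Reading CDS sets and applying the gene-inclusion filters.

A :class:`GeneRecord` is one protein-coding sequence broken into codons on
its coding strand, with 1-based inclusive genomic coordinates (GenBank
convention). CDS sets come either from a multi-FASTA of nucleotide coding
sequences or from a GenBank flat file with CDS features; FASTA records
carry no coordinates, so they are laid out head-to-tail on a synthetic
"+" strand.

The inclusion filter retains genes of at least 100 codons (terminal stop
included in the count) that start with an accepted initiation codon, end
with a stop, and contain no internal stop — short or malformed CDS mostly
reflect annotation noise and would add sampling error to per-gene indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .genetics import GeneticCode, as_dna, standard_code

logger = logging.getLogger(__name__)

RIBOSOMAL_TAG = "ribosomal protein"


@dataclass
class GeneRecord:
    """One CDS, codon-split on the coding strand."""

    gene_id: str
    codons: tuple[str, ...]
    strand: str = "+"
    start: int = 1  # 1-based inclusive
    end: int = 0
    product: str = ""
    is_ribosomal: bool = field(default=False)

    def __post_init__(self):
        self.codons = tuple(as_dna(c) for c in self.codons)
        if not self.codons:
            raise ValueError(f"{self.gene_id}: empty codon list")
        if any(len(c) != 3 for c in self.codons):
            raise ValueError(f"{self.gene_id}: non-triplet codon")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.end == 0:
            self.end = self.start + 3 * len(self.codons) - 1
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if not self.product:
            pass
        if not self.is_ribosomal and RIBOSOMAL_TAG in self.product.lower():
            self.is_ribosomal = True

    @property
    def length_codons(self) -> int:
        return len(self.codons)

    @property
    def sequence(self) -> str:
        """Coding-strand nucleotide sequence."""
        return "".join(self.codons)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def _codon_split(gene_id: str, seq: str) -> tuple[str, ...] | None:
    seq = as_dna(seq)
    if len(seq) % 3 != 0:
        logger.warning("%s: length %d not divisible by 3; record excluded", gene_id, len(seq))
        return None
    return tuple(seq[i : i + 3] for i in range(0, len(seq), 3))


def _fasta_records(path) -> Iterable[GeneRecord]:
    offset = 0
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        codons = _codon_split(rec.id, str(rec.seq))
        if codons is None:
            continue
        length = 3 * len(codons)
        yield GeneRecord(
            gene_id=rec.id,
            codons=codons,
            strand="+",
            start=offset + 1,
            end=offset + length,
            product=rec.description.partition(" ")[2].strip(),
        )
        offset += length
    if n == 0:
        raise ValueError(f"{path}: no FASTA records found")


def _genbank_records(path) -> Iterable[GeneRecord]:
    any_cds = False
    for rec in SeqIO.parse(str(path), "genbank"):
        for i, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            any_cds = True
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", quals.get("protein_id", quals.get("gene", [None])))[0]
                or f"{rec.id}_cds{i}"
            )
            seq = str(feat.extract(rec.seq))  # handles joins and minus strand
            codons = _codon_split(gene_id, seq)
            if codons is None:
                continue
            yield GeneRecord(
                gene_id=gene_id,
                codons=codons,
                strand="-" if feat.location.strand == -1 else "+",
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                product=quals.get("product", [""])[0],
            )
    if not any_cds:
        raise ValueError(f"{path}: no CDS features found in GenBank input")


def read_cds(path, format: str = "fasta") -> list[GeneRecord]:
    """Read a CDS set from `path` in the given format ('fasta' or 'genbank').

    Returns one :class:`GeneRecord` per CDS, codons on the coding strand.
    Records whose length is not a multiple of 3 are excluded with a logged
    warning. FASTA records get synthetic head-to-tail "+"-strand coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fasta":
        return list(_fasta_records(path))
    if format == "genbank":
        return list(_genbank_records(path))
    raise ValueError(f"unknown format {format!r} (expected 'fasta' or 'genbank')")


def filter_genes(
    genes: Sequence[GeneRecord],
    code: GeneticCode | None = None,
    min_codons: int = 100,
) -> list[GeneRecord]:
    """Apply the inclusion filter: length, correct start/stop, no internal stop.

    A gene is retained iff it has at least `min_codons` codons (terminal stop
    included), its first codon is in the code's start set, its last codon is a
    stop, and no other codon is a stop. Filtering never raises on content and
    is idempotent.
    """
    code = code or standard_code()
    kept = []
    for g in genes:
        if g.length_codons < min_codons:
            logger.warning("%s: only %d codons (< %d); excluded", g.gene_id, g.length_codons, min_codons)
            continue
        if not code.is_start(g.codons[0]):
            logger.warning("%s: non-standard initiation codon %s; excluded", g.gene_id, g.codons[0])
            continue
        if not code.is_stop(g.codons[-1]):
            logger.warning("%s: missing termination codon; excluded", g.gene_id)
            continue
        if any(code.is_stop(c) for c in g.codons[:-1]):
            logger.warning("%s: internal stop codon; excluded", g.gene_id)
            continue
        kept.append(g)
    return kept


def translate(gene: GeneRecord, code: GeneticCode | None = None) -> str:
    """Translate a gene's codons, dropping the terminal stop.

    Raises ``ValueError`` naming the gene if an internal stop is found.
    """
    code = code or standard_code()
    codons = gene.codons
    if code.is_stop(codons[-1]):
        codons = codons[:-1]
    residues = []
    for i, c in enumerate(codons):
        if code.is_stop(c):
            raise ValueError(f"{gene.gene_id}: internal stop codon {c} at codon {i + 1}")
        residues.append(code.forward[c])
    return "".join(residues)


def write_gene_table(genes: Sequence[GeneRecord], path) -> None:
    """Write a TSV gene table: gene_id, length_codons, strand, start, end, is_ribosomal."""
    with open(path, "w") as fh:
        fh.write("gene_id\tlength_codons\tstrand\tstart\tend\tis_ribosomal\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.length_codons}\t{g.strand}\t{g.start}\t{g.end}\t"
                f"{int(g.is_ribosomal)}\n"
            )


def write_cds_fasta(genes: Sequence[GeneRecord], path) -> None:
    """Write coding sequences as a multi-FASTA (one record per gene)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id} {g.product}\n".rstrip() + "\n")
            seq = g.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
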
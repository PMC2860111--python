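"""Genetic code tables and codon bookkeeping.

Everything downstream (usage indices, ordination, optimal-codon tests,
Ka/Ks counting) is parameterised by a :class:`GeneticCode`, which wraps a
standard NCBI translation table. The default is the bacterial/archaeal
table 11, with the start-codon set restricted to {ATG, GTG, TTG} — the
starts actually used by most actinobacteria — rather than table 11's full
permissive set.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

BASES = ("T", "C", "A", "G")

#: Start codons accepted by default (configurable per GeneticCode instance).
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})

STOP_SYMBOL = "*"
GAP_CODON = "---"


def as_dna(codon: str) -> str:
    """Normalise a codon string to upper-case DNA (U -> T)."""
    return codon.upper().replace("U", "T")


def as_rna(codon: str) -> str:
    """Render a DNA codon in RNA alphabet (T -> U), as usage tables print it."""
    return codon.upper().replace("T", "U")


class GeneticCode:
    """An NCBI translation table plus the derived synonymous-family structure.

    Parameters
    ----------
    table_id :
        NCBI genetic-code table number (default 11, bacterial).
    start_codons :
        Codons accepted as initiation codons. Defaults to
        :data:`DEFAULT_START_CODONS`; pass ``None`` to take the table's own
        (more permissive) start set.
    """

    def __init__(self, table_id: int = 11, start_codons=DEFAULT_START_CODONS):
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.forward: dict[str, str] = dict(table.forward_table)
        self.stop_codons = frozenset(table.stop_codons)
        if start_codons is None:
            start_codons = frozenset(table.start_codons)
        self.start_codons = frozenset(as_dna(c) for c in start_codons)
        if not self.start_codons:
            raise ValueError("start-codon set must be non-empty")

        self.sense_codons: tuple[str, ...] = tuple(sorted(self.forward))
        families: dict[str, list[str]] = {}
        for codon, aa in self.forward.items():
            families.setdefault(aa, []).append(codon)
        #: amino acid -> sorted tuple of its codons; '*' maps to the stops.
        self.families: dict[str, tuple[str, ...]] = {
            aa: tuple(sorted(cs)) for aa, cs in families.items()
        }
        self.families[STOP_SYMBOL] = tuple(sorted(self.stop_codons))
        #: sense codons belonging to families of degeneracy >= 2 (59 in table 11)
        self.synonymous_codons: tuple[str, ...] = tuple(
            c for c in self.sense_codons if len(self.families[self.forward[c]]) > 1
        )

    # -- basic queries -------------------------------------------------

    def amino_acid(self, codon: str) -> str:
        """One-letter amino acid for a codon, '*' for stops."""
        codon = as_dna(codon)
        if codon in self.stop_codons:
            return STOP_SYMBOL
        return self.forward[codon]

    def is_stop(self, codon: str) -> bool:
        return as_dna(codon) in self.stop_codons

    def is_start(self, codon: str) -> bool:
        return as_dna(codon) in self.start_codons

    def family(self, codon: str) -> tuple[str, ...]:
        """All codons synonymous with `codon` (including itself)."""
        return self.families[self.amino_acid(codon)]

    def degeneracy(self, codon: str) -> int:
        return len(self.family(codon))

    def synonymous(self, a: str, b: str) -> bool:
        return self.amino_acid(a) == self.amino_acid(b)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneticCode(table_id={self.table_id})"


@lru_cache(maxsize=None)
def standard_code(table_id: int = 11) -> GeneticCode:
    """Shared default :class:`GeneticCode` instance."""
    return GeneticCode(table_id=table_id)
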
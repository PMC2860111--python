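"""Per-gene codon-usage indices.

Implements the classical battery of synonymous codon usage statistics:

* **RSCU** — relative synonymous codon usage, ``count * k / family_total``
  for a codon in a degeneracy-``k`` family; 1.0 means usage exactly at the
  uniform expectation.
* **ENC (Nc)** — Wright's effective number of codons, from degeneracy-class
  mean homozygosities: ``Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``.
* **GC3s / A3s / T3s / G3s / C3s** — base composition at the third position
  of synonymously variable codons (Met, Trp and stops excluded).
* **CAI** — codon adaptation index of Sharp & Li: the geometric mean of
  relative-adaptiveness weights derived from a highly expressed reference
  set (here ribosomal proteins).
* **Fop** — frequency of optimal codons, restricted to synonymous families
  that contain at least one optimal codon.
* **GRAVY** — mean Kyte–Doolittle hydropathy of the encoded protein.

All indices exclude the terminal stop codon; RSCU/CAI/Fop and the
third-position compositions additionally exclude Met, Trp and stop codons,
which admit no synonymous choice.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .genetics import GeneticCode, STOP_SYMBOL, as_dna, standard_code
from .genome_io import GeneRecord, translate

#: Wright's degeneracy classes and their family multiplicities in table 11.
ENC_CLASS_WEIGHTS = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass
class CodonCountTable:
    """Codon counts for one gene or a pooled set of genes."""

    counts: dict[str, int]
    source: str = ""

    def __post_init__(self):
        self.counts = {as_dna(c): int(n) for c, n in self.counts.items() if n}
        if any(n < 0 for n in self.counts.values()):
            raise ValueError(f"{self.source}: negative codon count")

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(as_dna(codon), 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonCountTable(dict(merged), source=f"{self.source}+{other.source}")


def count_codons(gene: GeneRecord, code: GeneticCode | None = None) -> CodonCountTable:
    """Codon counts over a gene, excluding its terminal stop codon."""
    code = code or standard_code()
    codons = gene.codons
    if codons and code.is_stop(codons[-1]):
        codons = codons[:-1]
    return CodonCountTable(dict(Counter(codons)), source=gene.gene_id)


def pool_counts(tables: Sequence[CodonCountTable], source: str = "pool") -> CodonCountTable:
    """Elementwise sum of codon count tables."""
    if not tables:
        raise ValueError("cannot pool an empty collection of count tables")
    merged: Counter = Counter()
    for t in tables:
        merged.update(t.counts)
    return CodonCountTable(dict(merged), source=source)


def rscu(counts: CodonCountTable, code: GeneticCode | None = None) -> dict[str, float]:
    """Relative synonymous codon usage for every codon family with observations.

    ``RSCU(c) = count(c) * k / N_aa`` where ``k`` is family degeneracy and
    ``N_aa`` the family total. Families with zero total get ``nan`` (undefined),
    never 0. Single-codon families (Met, Trp) trivially score 1, and the stop
    family is treated as a family of its own so pooled tables that include
    stop counts evaluate cleanly.
    """
    code = code or standard_code()
    if counts.total <= 0:
        raise ValueError("RSCU needs a non-empty count table")
    out: dict[str, float] = {}
    for aa, family in code.families.items():
        k = len(family)
        n_aa = sum(counts[c] for c in family)
        for c in family:
            out[c] = counts[c] * k / n_aa if n_aa > 0 else math.nan
    return out


def _family_homozygosity(n: int, codon_counts: Sequence[int]) -> float | None:
    """Wright's F-hat = (n * sum(p_i^2) - 1) / (n - 1); None when n < 2."""
    if n < 2:
        return None
    s = sum((c / n) ** 2 for c in codon_counts)
    return (n * s - 1.0) / (n - 1.0)


def enc(counts: CodonCountTable, code: GeneticCode | None = None) -> float:
    """Wright's effective number of codons, clamped to [20, 61].

    Class means are taken over families with at least two observations;
    families with F-hat = 0 are excluded from their class mean (no bias
    information). A missing 3-fold class is interpolated as
    ``F3 = (F2 + F4) / 2``; if the 2-, 4- or 6-fold class mean is
    unavailable the statistic is undefined (``nan``).
    """
    code = code or standard_code()
    if counts.total <= 0:
        raise ValueError("ENC needs a non-empty count table")
    per_class: dict[int, list[float]] = {k: [] for k in ENC_CLASS_WEIGHTS}
    for aa, family in code.families.items():
        k = len(family)
        if aa == STOP_SYMBOL or k not in ENC_CLASS_WEIGHTS:
            continue
        n = sum(counts[c] for c in family)
        f_hat = _family_homozygosity(n, [counts[c] for c in family])
        if f_hat is not None and f_hat > 0:
            per_class[k].append(f_hat)
    mean_f = {k: (np.mean(v) if v else None) for k, v in per_class.items()}
    if mean_f[3] is None and mean_f[2] is not None and mean_f[4] is not None:
        mean_f[3] = (mean_f[2] + mean_f[4]) / 2.0
    if any(mean_f[k] is None for k in ENC_CLASS_WEIGHTS):
        return math.nan
    nc = 2.0 + sum(w / mean_f[k] for k, w in ENC_CLASS_WEIGHTS.items())
    return min(61.0, max(20.0, nc))


def enc_expected(s: float) -> float:
    """Expected Nc under pure compositional bias at third-position GC content ``s``.

    ``Nc(s) = 2 + s + 29 / (s^2 + (1 - s)^2)`` — the null curve for the
    Nc-vs-GC3s plot: genes whose usage is set only by mutational bias fall
    on it, genes under translational selection fall below it.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must lie in [0, 1]")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


@dataclass(frozen=True)
class ThirdPositionComposition:
    gc3s: float
    a3s: float
    t3s: float
    g3s: float
    c3s: float


def third_position_composition(
    counts: CodonCountTable, code: GeneticCode | None = None
) -> ThirdPositionComposition:
    """Base composition at third positions of synonymously variable codons.

    Met, Trp and stop codons are excluded. Each value is the fraction of
    eligible codon occurrences ending in the given base, so the four base
    fractions sum to 1 and GC3s = G3s + C3s. Returns ``nan`` fields when no
    eligible codons are present.
    """
    code = code or standard_code()
    tallies = {b: 0 for b in "ACGT"}
    for codon in code.synonymous_codons:
        tallies[codon[2]] += counts[codon]
    total = sum(tallies.values())
    if total == 0:
        nan = math.nan
        return ThirdPositionComposition(nan, nan, nan, nan, nan)
    frac = {b: tallies[b] / total for b in tallies}
    return ThirdPositionComposition(
        gc3s=frac["G"] + frac["C"], a3s=frac["A"], t3s=frac["T"], g3s=frac["G"], c3s=frac["C"]
    )


@dataclass
class CaiReference:
    """Relative-adaptiveness weights w(c) built from a reference gene pool."""

    weights: dict[str, float]

    def __getitem__(self, codon: str) -> float:
        return self.weights[as_dna(codon)]


def build_cai_reference(
    reference_tables: Sequence[CodonCountTable],
    code: GeneticCode | None = None,
    pseudo_count: float = 0.5,
) -> CaiReference:
    """CAI weights from a pool of (typically ribosomal-protein) gene counts.

    ``w(c) = count_pool(c) / max_count_in_family``; zero pooled counts are
    replaced by `pseudo_count` before weighting so rare codons keep a
    finite log-weight. The per-family maximum is exactly 1. Met, Trp and
    stop codons carry no information and are excluded.
    """
    code = code or standard_code()
    if not reference_tables:
        raise ValueError("CAI reference set is empty")
    pool = pool_counts(reference_tables, source="cai_reference")
    weights: dict[str, float] = {}
    for aa, family in code.families.items():
        if aa == STOP_SYMBOL or len(family) < 2:
            continue
        raw = {c: pool[c] for c in family}
        top = max(raw.values())
        if top == 0:
            raise ValueError(f"CAI reference pool has no observations for family {aa}")
        for c in family:
            weights[c] = max(raw[c], pseudo_count) / top
    return CaiReference(weights)


def cai(counts: CodonCountTable, ref: CaiReference) -> float:
    """Codon adaptation index: geometric mean of weights over codon occurrences."""
    log_sum = 0.0
    n = 0
    for codon, weight in ref.weights.items():
        k = counts[codon]
        if k:
            log_sum += k * math.log(weight)
            n += k
    if n == 0:
        raise ValueError("no CAI-eligible codons in count table")
    return math.exp(log_sum / n)


def fop(counts: CodonCountTable, optimal: Iterable[str], code: GeneticCode | None = None) -> float:
    """Frequency of optimal codons.

    Numerator: occurrences of optimal codons. Denominator: occurrences of
    any codon in a synonymous family containing at least one optimal codon.
    ``nan`` when the optimal set is empty or the denominator is zero.
    """
    code = code or standard_code()
    optimal = {as_dna(c) for c in optimal}
    if not optimal:
        return math.nan
    eligible_families = {code.amino_acid(c) for c in optimal}
    num = sum(counts[c] for c in optimal)
    den = sum(
        counts[c]
        for aa in eligible_families
        for c in code.families[aa]
    )
    return num / den if den else math.nan


def gravy(protein: str) -> float:
    """Mean Kyte–Doolittle hydropathy over residues of a protein string."""
    if not protein:
        raise ValueError("empty protein")
    try:
        return sum(KYTE_DOOLITTLE[a] for a in protein) / len(protein)
    except KeyError as exc:
        raise ValueError(f"unknown residue symbol {exc.args[0]!r}") from None


@dataclass
class UsageProfile:
    """All per-gene indices, as one row of the gene index table."""

    gene_id: str
    length_codons: int
    enc: float
    gc3s: float
    a3s: float
    t3s: float
    g3s: float
    c3s: float
    cai: float
    fop: float
    gravy: float
    is_ribosomal: bool = False


PROFILE_COLUMNS = [
    "gene_id", "length_codons", "enc", "gc3s", "a3s", "t3s", "g3s", "c3s",
    "cai", "fop", "gravy", "is_ribosomal",
]


def usage_profiles(
    genes: Sequence[GeneRecord],
    code: GeneticCode | None = None,
    cai_ref: CaiReference | None = None,
    optimal: Iterable[str] = (),
) -> pd.DataFrame:
    """Compute the full index table for a filtered gene set.

    When no CAI reference is given, one is built from the genes flagged
    ribosomal (there must be at least one).
    """
    code = code or standard_code()
    tables = {g.gene_id: count_codons(g, code) for g in genes}
    if cai_ref is None:
        ribo = [tables[g.gene_id] for g in genes if g.is_ribosomal]
        cai_ref = build_cai_reference(ribo, code)
    optimal = set(optimal)
    rows = []
    for g in genes:
        t = tables[g.gene_id]
        comp = third_position_composition(t, code)
        rows.append(
            UsageProfile(
                gene_id=g.gene_id,
                length_codons=g.length_codons,
                enc=enc(t, code),
                gc3s=comp.gc3s,
                a3s=comp.a3s,
                t3s=comp.t3s,
                g3s=comp.g3s,
                c3s=comp.c3s,
                cai=cai(t, cai_ref),
                fop=fop(t, optimal, code) if optimal else math.nan,
                gravy=gravy(translate(g, code)),
                is_ribosomal=g.is_ribosomal,
            )
        )
    df = pd.DataFrame([vars(r) for r in rows], columns=PROFILE_COLUMNS)
    return df.set_index("gene_id")


def write_profiles(profiles: pd.DataFrame, path) -> None:
    """Write the gene index table as TSV (full precision)."""
    profiles.to_csv(path, sep="\t", float_format="%.6f")
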
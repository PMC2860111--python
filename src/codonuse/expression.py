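"""Optimal-codon detection from extreme-axis gene groups.

Given pooled codon counts for a putatively highly expressed group and a
putatively lowly expressed group (typically the two extremes of the first
ordination axis), each synonymous codon is tested with a Pearson 2x2
chi-square — this codon versus the rest of its synonymous family, high
group versus low group — with no continuity correction by default. A codon
is called translationally optimal when the test is significant (default
alpha = 0.01) *and* its within-family proportion is higher in the highly
expressed group; proportions rather than raw counts are compared because
the two pools differ in size. No multiple-testing correction is applied:
the per-codon calls mirror the classical star-the-table presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .genetics import GeneticCode, STOP_SYMBOL, as_dna, as_rna, standard_code
from .metrics import CodonCountTable, pool_counts, rscu

__all__ = [
    "CodonTestResult",
    "pool_counts",
    "codon_chi_square",
    "call_optimal_codons",
    "optimal_codon_table",
    "load_group_counts",
]


@dataclass
class CodonTestResult:
    """Per-codon 2x2 chi-square outcome between expression groups."""

    codon: str
    amino_acid: str
    n_high: int
    n_low: int
    rscu_high: float
    rscu_low: float
    chi2: float
    p: float
    is_optimal: bool


def codon_chi_square(
    high: CodonCountTable,
    low: CodonCountTable,
    codon: str,
    code: GeneticCode | None = None,
    alpha: float = 0.01,
    yates: bool = False,
) -> CodonTestResult:
    """Test one synonymous codon for elevated usage in the high group.

    The 2x2 table is [codon, other family codons] x [high, low]. When either
    group has an empty family the test is undefined: chi2 and p are ``nan``
    and the codon is not called optimal.
    """
    code = code or standard_code()
    codon = as_dna(codon)
    aa = code.amino_acid(codon)
    if aa == STOP_SYMBOL or len(code.families[aa]) < 2:
        raise ValueError(f"{codon}: not a synonymously variable codon")
    family = code.families[aa]
    fam_high = sum(high[c] for c in family)
    fam_low = sum(low[c] for c in family)
    a, c_ = high[codon], low[codon]
    rscu_h = a * len(family) / fam_high if fam_high else math.nan
    rscu_l = c_ * len(family) / fam_low if fam_low else math.nan
    if fam_high == 0 or fam_low == 0:
        return CodonTestResult(codon, aa, a, c_, rscu_h, rscu_l, math.nan, math.nan, False)
    table = [[a, fam_high - a], [c_, fam_low - c_]]
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    higher_in_high = a / fam_high > c_ / fam_low
    return CodonTestResult(
        codon, aa, a, c_, rscu_h, rscu_l, float(chi2), float(p),
        bool(p < alpha and higher_in_high),
    )


def call_optimal_codons(
    high: CodonCountTable,
    low: CodonCountTable,
    code: GeneticCode | None = None,
    alpha: float = 0.01,
    yates: bool = False,
) -> tuple[set[str], list[CodonTestResult]]:
    """Apply the per-codon chi-square to all synonymous codons.

    Returns the optimal-codon set and the full list of test results
    (including undefined tests for families absent from either pool).
    """
    code = code or standard_code()
    if high.total == 0 or low.total == 0:
        raise ValueError("both pooled count tables must be non-empty")
    results = [
        codon_chi_square(high, low, c, code, alpha=alpha, yates=yates)
        for c in code.synonymous_codons
    ]
    optimal = {r.codon for r in results if r.is_optimal}
    return optimal, results


def ending_base_tally(codons: set[str]) -> dict[str, int]:
    """How many codons of a set end in each base (DNA alphabet)."""
    tally = {b: 0 for b in "ACGT"}
    for c in codons:
        tally[as_dna(c)[2]] += 1
    return tally


def optimal_codon_table(results: list[CodonTestResult], rna: bool = True) -> pd.DataFrame:
    """Tabulate the per-codon tests in the usage-table layout.

    Columns: amino acid, codon, N and RSCU per group (RSCU at 2 d.p. for
    presentation, full precision retained separately), chi2, p, optimal flag.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "aa": r.amino_acid,
                "codon": as_rna(r.codon) if rna else r.codon,
                "n_high": r.n_high,
                "rscu_high": round(r.rscu_high, 2),
                "n_low": r.n_low,
                "rscu_low": round(r.rscu_low, 2),
                "rscu_high_full": r.rscu_high,
                "rscu_low_full": r.rscu_low,
                "chi2": r.chi2,
                "p": r.p,
                "optimal": r.is_optimal,
            }
        )
    return pd.DataFrame(rows)


def load_group_counts(path) -> tuple[CodonCountTable, CodonCountTable]:
    """Read pooled high/low codon counts from a TSV.

    Expected columns: ``codon`` (DNA or RNA alphabet), ``n_high``, ``n_low``;
    extra columns are ignored. This lets the optimal-codon test run directly
    on published pooled count tables without the underlying sequences.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"codon", "n_high", "n_low"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    high = CodonCountTable(
        {as_dna(r.codon): int(r.n_high) for r in df.itertuples()}, source="high"
    )
    low = CodonCountTable(
        {as_dna(r.codon): int(r.n_low) for r in df.itertuples()}, source="low"
    )
    return high, low
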
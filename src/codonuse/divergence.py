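"""Ortholog pairing and synonymous/nonsynonymous divergence.

Orthologs between two genomes are called by reciprocal best hits over a
12-column tabular protein-hit file (or hits computed internally from
pairwise alignments), filtered on identity, coverage of the longer
protein, E-value and minimum length. Each pair is globally aligned at the
protein level (BLOSUM62, affine gaps), the alignment is back-translated
to codons, and divergence is estimated with the Nei–Gojobori counting
method: synonymous and nonsynonymous sites are apportioned per codon with
equal mutation weights, observed differences are averaged over all
mutational pathways that avoid stop codons, and the proportions are
corrected for multiple hits with the Jukes–Cantor formula
``d = -3/4 * ln(1 - 4p/3)``. Ka is the nonsynonymous and Ks the
synonymous rate; pairs with Ks >= 1 are conventionally dropped as
saturated before correlating divergence with expression proxies.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .genetics import GAP_CODON, GeneticCode, standard_code

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class HitRecord:
    """One row of a 12-column tabular protein search result."""

    query: str
    subject: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float


def import_hits(path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit file; malformed lines are skipped."""
    hits = []
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) != 12:
                logger.warning("skipping malformed hit line: %r", line[:80])
                continue
            try:
                hits.append(
                    HitRecord(
                        parts[0], parts[1], float(parts[2]), int(parts[3]),
                        int(parts[4]), int(parts[5]), int(parts[6]), int(parts[7]),
                        int(parts[8]), int(parts[9]), float(parts[10]), float(parts[11]),
                    )
                )
            except ValueError:
                logger.warning("skipping unparseable hit line: %r", line[:80])
    if not hits:
        raise ValueError(f"{path}: no parseable hit records")
    return hits


def write_hits(hits: Sequence[HitRecord], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(getattr(h, col)) for col in HIT_COLUMNS
                )
                + "\n"
            )


def _best_hits(hits: Sequence[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query: highest bit score, then lowest E-value, then subject id."""
    def key(h: HitRecord):
        # higher bit score wins, then lower E-value, then lexicographic subject
        ev = math.inf if math.isnan(h.evalue) else h.evalue
        return (-h.bitscore, ev, h.subject)

    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query)
        if cur is None or key(h) < key(cur):
            best[h.query] = h
    return best


def reciprocal_best_hits(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    lengths_a: Mapping[str, int],
    lengths_b: Mapping[str, int],
    min_identity: float = 60.0,
    max_evalue: float = 1e-5,
    min_coverage: float = 0.6,
    min_length: int = 100,
) -> list[tuple[str, str]]:
    """Ortholog pairs by reciprocal best hit under the classical thresholds.

    A hit survives when identity >= `min_identity` %, E-value <=
    `max_evalue`, alignment length covers >= `min_coverage` of the longer
    protein, and both proteins have >= `min_length` residues. A pair (a, b)
    is kept iff b is a's best surviving hit and a is b's. E-values of
    ``nan`` (hits produced internally rather than by a database search)
    pass the E-value criterion unexamined.
    """

    def passes(h: HitRecord, la: Mapping[str, int], lb: Mapping[str, int]) -> bool:
        if h.query not in la or h.subject not in lb:
            return False
        longer = max(la[h.query], lb[h.subject])
        if min(la[h.query], lb[h.subject]) < min_length:
            return False
        if h.pident < min_identity:
            return False
        if not math.isnan(h.evalue) and h.evalue > max_evalue:
            return False
        return h.length / longer >= min_coverage

    fwd = _best_hits([h for h in hits_ab if passes(h, lengths_a, lengths_b)])
    rev = _best_hits([h for h in hits_ba if passes(h, lengths_b, lengths_a)])
    pairs = []
    for a, h in sorted(fwd.items()):
        b = h.subject
        back = rev.get(b)
        if back is not None and back.subject == a:
            pairs.append((a, b))
    return pairs


# -- pairwise protein alignment ---------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_proteins(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global protein alignment (BLOSUM62, gap open 11 / extend 1).

    Deterministic: of the co-optimal alignments the aligner's canonical
    first traceback is returned.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    alignment = _aligner().align(seq_a, seq_b)[0]
    a, b = str(alignment[0]), str(alignment[1])
    return a, b


def alignment_identity(aln_a: str, aln_b: str) -> float:
    """Percent identical residues over aligned (non-double-gap) columns."""
    cols = [(x, y) for x, y in zip(aln_a, aln_b) if not (x == "-" and y == "-")]
    if not cols:
        return 0.0
    ident = sum(1 for x, y in cols if x == y and x != "-")
    return 100.0 * ident / len(cols)


def backtranslate_alignment(
    aln_a: str,
    aln_b: str,
    codons_a: Sequence[str],
    codons_b: Sequence[str],
    code: GeneticCode | None = None,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Replace each aligned residue by its source codon, gaps by '---'.

    The ungapped protein strings must translate exactly from the supplied
    codon lists (terminal stops having been removed); any mismatch raises
    with the offending position.
    """
    code = code or standard_code()

    def one(aln: str, codons: Sequence[str], label: str) -> tuple[str, ...]:
        out = []
        i = 0
        for col, residue in enumerate(aln):
            if residue == "-":
                out.append(GAP_CODON)
                continue
            if i >= len(codons):
                raise ValueError(f"{label}: alignment longer than codon sequence at column {col + 1}")
            codon = codons[i]
            if code.amino_acid(codon) != residue:
                raise ValueError(
                    f"{label}: codon {codon} at position {i + 1} translates to "
                    f"{code.amino_acid(codon)}, alignment has {residue}"
                )
            out.append(codon)
            i += 1
        if i != len(codons):
            raise ValueError(f"{label}: {len(codons) - i} codons left over after alignment")
        return tuple(out)

    return one(aln_a, codons_a, "sequence A"), one(aln_b, codons_b, "sequence B")


# -- Nei-Gojobori counting --------------------------------------------


def synonymous_site_count(codon: str, code: GeneticCode) -> float:
    """Synonymous sites of one codon: per position, the fraction of the three
    possible changes that are synonymous. Changes to stop codons count as
    nonsynonymous, so sites per codon always sum to 3."""
    aa = code.amino_acid(codon)
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if not code.is_stop(alt) and code.amino_acid(alt) == aa:
                s += 1.0 / 3.0
    return s


def pathway_differences(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Codons differing at two or three positions are resolved by averaging
    over all orderings of the single-base steps; pathways passing through
    a stop codon are excluded (if every pathway is blocked, all are used).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt) and nxt != c2:
                blocked = True
                break
            if code.amino_acid(cur) == code.amino_acid(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:  # every intermediate is a stop: fall back to all pathways
        for order in itertools.permutations(diff_pos):
            cur = c1
            sd = nd = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if code.amino_acid(cur) == code.amino_acid(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


@dataclass
class Ng86Counts:
    """Site and difference counts underlying a Ka/Ks estimate."""

    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int


def ng86_counts(
    codons_a: Sequence[str], codons_b: Sequence[str], code: GeneticCode | None = None
) -> Ng86Counts:
    """Count sites and differences over the comparable codon columns.

    Columns containing a gap or a stop codon in either sequence are
    skipped. Site counts are averaged between the two sequences.
    """
    code = code or standard_code()
    if len(codons_a) != len(codons_b):
        raise ValueError("codon alignments differ in length")
    S_a = S_b = sd = nd = 0.0
    n = 0
    for ca, cb in zip(codons_a, codons_b):
        if GAP_CODON in (ca, cb) or "-" in ca or "-" in cb:
            continue
        if code.is_stop(ca) or code.is_stop(cb):
            continue
        n += 1
        S_a += synonymous_site_count(ca, code)
        S_b += synonymous_site_count(cb, code)
        d_s, d_n = pathway_differences(ca, cb, code)
        sd += d_s
        nd += d_n
    S = (S_a + S_b) / 2.0
    return Ng86Counts(S, 3.0 * n - S, sd, nd, n)


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -3/4 ln(1 - 4p/3); nan at saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_ng86(
    codons_a: Sequence[str], codons_b: Sequence[str], code: GeneticCode | None = None
) -> tuple[float, float]:
    """(Ka, Ks): Jukes–Cantor-corrected nonsynonymous and synonymous rates.

    ``nan`` marks an undefined estimate (no comparable sites, or a
    difference proportion at or beyond the correction's p = 3/4 saturation
    bound).
    """
    counts = ng86_counts(codons_a, codons_b, code)
    if counts.n_codons == 0:
        return math.nan, math.nan
    ka = jukes_cantor(counts.nonsyn_diffs / counts.nonsyn_sites) if counts.nonsyn_sites else math.nan
    ks = jukes_cantor(counts.syn_diffs / counts.syn_sites) if counts.syn_sites else math.nan
    return ka, ks


@dataclass
class OrthologPair:
    """A called ortholog pair with its alignments and divergence estimates."""

    gene_id_a: str
    gene_id_b: str
    identity: float
    coverage: float
    aln_a: str
    aln_b: str
    codon_aln_a: tuple[str, ...]
    codon_aln_b: tuple[str, ...]
    ka: float
    ks: float

    @property
    def pass_ks_filter(self) -> bool:
        return not math.isnan(self.ks) and self.ks < 1.0


def build_ortholog_pair(
    gene_id_a: str,
    gene_id_b: str,
    protein_a: str,
    protein_b: str,
    codons_a: Sequence[str],
    codons_b: Sequence[str],
    code: GeneticCode | None = None,
) -> OrthologPair:
    """Align, back-translate and estimate Ka/Ks for one gene pair.

    `codons_a`/`codons_b` must exclude the terminal stop codon.
    """
    code = code or standard_code()
    aln_a, aln_b = align_proteins(protein_a, protein_b)
    cod_a, cod_b = backtranslate_alignment(aln_a, aln_b, codons_a, codons_b, code)
    ka, ks = kaks_ng86(cod_a, cod_b, code)
    longer = max(len(protein_a), len(protein_b))
    overlap = sum(1 for x, y in zip(aln_a, aln_b) if x != "-" and y != "-")
    return OrthologPair(
        gene_id_a, gene_id_b,
        identity=alignment_identity(aln_a, aln_b),
        coverage=overlap / longer,
        aln_a=aln_a, aln_b=aln_b,
        codon_aln_a=cod_a, codon_aln_b=cod_b,
        ka=ka, ks=ks,
    )


def filter_and_correlate(
    pairs: Sequence[OrthologPair],
    profiles: pd.DataFrame,
    ks_max: float = 1.0,
    indices: Sequence[tuple[str, str]] = (("ka", "cai"), ("ks", "cai"), ("ka", "ks"), ("ks", "fop")),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop saturated pairs (Ks >= ks_max) and correlate divergence with usage.

    `profiles` is the genome-A usage table indexed by gene id. Returns the
    surviving pair table and a tidy correlation report (Pearson r, p);
    correlations are ``nan`` when fewer than 3 pairs survive.
    """
    rows = []
    for p in pairs:
        if math.isnan(p.ka) or math.isnan(p.ks):
            continue
        if p.ks >= ks_max:
            continue
        row = {"gene_id_a": p.gene_id_a, "gene_id_b": p.gene_id_b,
               "identity": p.identity, "coverage": p.coverage, "ka": p.ka, "ks": p.ks}
        if p.gene_id_a in profiles.index:
            row["cai"] = float(profiles.loc[p.gene_id_a, "cai"])
            row["fop"] = float(profiles.loc[p.gene_id_a, "fop"])
        rows.append(row)
    kept = pd.DataFrame(rows)
    report = []
    for x, y in indices:
        if len(kept) >= 3 and x in kept.columns and y in kept.columns:
            xv, yv = kept[x].to_numpy(), kept[y].to_numpy()
            ok = ~(np.isnan(xv) | np.isnan(yv))
            if ok.sum() >= 3 and np.std(xv[ok]) > 0 and np.std(yv[ok]) > 0:
                r, pval = stats.pearsonr(xv[ok], yv[ok])
            else:
                r, pval = math.nan, math.nan
        else:
            r, pval = math.nan, math.nan
        report.append({"x": x, "y": y, "r": r, "p": pval, "n": len(kept)})
    return kept, pd.DataFrame(report)
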
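"""Synthetic bacterial genomes with planted codon-usage structure.

The generator emulates the causal structure the analysis is meant to
detect in a GC-rich bacterium:

* a per-gene **expression level** drawn log-normal, so a small tail of
  highly expressed genes (the ribosomal-protein analogue) exists;
* **translational selection**: within each synonymous family codons are
  drawn from a softmax whose optimal-codon log-odds grow with
  ``s_expr * e``, where ``e`` is the gene's expression scaled to [0, 1] by
  the maximum — selection is therefore concentrated in the expression
  tail, as in real genomes;
* a **mutational background** tuned so third positions hit a target GC3
  in the absence of selection;
* **replication-strand bias**: genes are laid head-to-tail on a circular
  chromosome with a planted origin and terminus, and genes in the top
  expression quartile land on the leading strand with probability
  ``leading_bias`` (others 50/50);
* **ortholog divergence**: a partner sequence is produced by a point
  substitution process that accepts synonymous changes at full rate and
  nonsynonymous ones at rate ``omega``, never introduces internal stops,
  and records the realised substitution counts as ground truth.

Intergenic spacers are plain A/T filler; the generator makes no attempt at
promoter or RNA-level realism. Given the same spec and seed the output is
byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import CGLUTAMICUM_OPTIMAL_CODONS
from .genetics import GeneticCode, STOP_SYMBOL, standard_code
from .genome_io import GeneRecord, write_cds_fasta, write_gene_table
from .divergence import synonymous_site_count

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticGenomeSpec:
    """Parameters of one synthetic genome draw."""

    n_genes: int = 600
    min_codons: int = 100          # total codons incl. start and stop
    max_codons: int = 400
    target_gc3: float = 0.55
    optimal_codons: frozenset[str] = CGLUTAMICUM_OPTIMAL_CODONS
    s_expr: float = 6.0            # selection strength at the expression maximum
    leading_bias: float = 0.85     # P(leading) for the top expression quartile
    expression_sigma: float = 1.0  # log-normal sd of expression levels
    fraction_ribosomal: float = 0.05
    spacer_bp: int = 150
    table_id: int = 11
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        for name in ("target_gc3", "leading_bias", "fraction_ribosomal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.s_expr < 0:
            raise ValueError("s_expr must be >= 0")
        if self.min_codons < 4 or self.max_codons < self.min_codons:
            raise ValueError("invalid codon-length range")


@dataclass
class GroundTruth:
    """Planted per-gene labels emitted alongside a synthetic genome."""

    expression: dict[str, float]
    strand_class: dict[str, str]            # 'leading' / 'lagging'
    optimal_fraction: dict[str, float]      # realised Fop-style fraction
    ori: int
    ter: int
    optimal_codons: frozenset[str]


def _family_sampler(code: GeneticCode, spec: SyntheticGenomeSpec):
    """Per-family codon lists and their base (mutational) log-weights."""
    gamma = math.log(spec.target_gc3 / (1.0 - spec.target_gc3))
    families = {}
    for aa, codons in code.families.items():
        if aa == STOP_SYMBOL:
            continue
        base = np.array([gamma if c[2] in "GC" else 0.0 for c in codons])
        is_opt = np.array([c in spec.optimal_codons for c in codons], dtype=float)
        families[aa] = (list(codons), base, is_opt)
    return families


def simulate_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[str, list[GeneRecord], GroundTruth]:
    """Draw a genome, its gene annotation, and the planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    code = standard_code(spec.table_id)
    families = _family_sampler(code, spec)
    variable_aas = sorted(aa for aa in families if len(families[aa][0]) > 1)

    expression = rng.lognormal(mean=0.0, sigma=spec.expression_sigma, size=spec.n_genes)
    e_scaled = expression / expression.max()
    top_quartile = expression >= np.quantile(expression, 0.75)
    order = np.argsort(-expression)
    n_ribo = max(1, int(round(spec.fraction_ribosomal * spec.n_genes)))
    ribosomal = np.zeros(spec.n_genes, dtype=bool)
    ribosomal[order[:n_ribo]] = True

    lengths = rng.integers(spec.min_codons, spec.max_codons + 1, size=spec.n_genes)

    # draw the coding sequences
    gene_codons: list[list[str]] = []
    opt_fraction: list[float] = []
    for i in range(spec.n_genes):
        n_internal = lengths[i] - 2  # minus start and stop
        aas = rng.choice(variable_aas, size=n_internal)
        codons = ["ATG"]
        n_opt = n_elig = 0
        for aa in aas:
            cods, base, is_opt = families[aa]
            logits = base + spec.s_expr * e_scaled[i] * is_opt
            w = np.exp(logits - logits.max())
            w /= w.sum()
            c = cods[rng.choice(len(cods), p=w)]
            codons.append(c)
            if is_opt.any():
                n_elig += 1
                n_opt += c in spec.optimal_codons
        codons.append("TAA")
        gene_codons.append(codons)
        opt_fraction.append(n_opt / n_elig if n_elig else math.nan)

    # chromosome layout: genes head-to-tail with A/T spacers, planted ori/ter
    genome_length = int(3 * lengths.sum() + spec.spacer_bp * (spec.n_genes + 1))
    ori, ter = 1, genome_length // 2
    pieces: list[str] = []
    genes: list[GeneRecord] = []
    truth_class: dict[str, str] = {}
    pos = 0

    def spacer() -> str:
        return "".join(rng.choice(["A", "T"], size=spec.spacer_bp))

    pieces.append(spacer())
    pos += spec.spacer_bp
    for i in range(spec.n_genes):
        gene_id = f"synth{i:05d}"
        seq = "".join(gene_codons[i])
        start = pos + 1
        end = pos + len(seq)
        mid = (start + end) / 2.0
        forward_replichore = (mid - ori) % genome_length < (ter - ori) % genome_length
        p_leading = spec.leading_bias if top_quartile[i] else 0.5
        leading = rng.random() < p_leading
        if forward_replichore:
            strand = "+" if leading else "-"
        else:
            strand = "-" if leading else "+"
        pieces.append(seq if strand == "+" else reverse_complement(seq))
        pos = end
        pieces.append(spacer())
        pos += spec.spacer_bp
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                codons=tuple(gene_codons[i]),
                strand=strand,
                start=start,
                end=end,
                product="50S ribosomal protein" if ribosomal[i] else "hypothetical protein",
                is_ribosomal=bool(ribosomal[i]),
            )
        )
        truth_class[gene_id] = "leading" if leading else "lagging"

    genome = "".join(pieces)
    assert len(genome) == genome_length
    truth = GroundTruth(
        expression={g.gene_id: float(expression[i]) for i, g in enumerate(genes)},
        strand_class=truth_class,
        optimal_fraction={g.gene_id: opt_fraction[i] for i, g in enumerate(genes)},
        ori=ori,
        ter=ter,
        optimal_codons=frozenset(spec.optimal_codons),
    )
    return genome, genes, truth


@dataclass
class OrthologTruth:
    """Realised substitution history of one simulated ortholog pair."""

    syn_substitutions: int
    nonsyn_substitutions: int
    syn_sites: float      # NG86 synonymous sites of the ancestral sequence
    nonsyn_sites: float

    @property
    def realised_ks(self) -> float:
        return self.syn_substitutions / self.syn_sites

    @property
    def realised_ka(self) -> float:
        return self.nonsyn_substitutions / self.nonsyn_sites


def simulate_ortholog_pair(
    gene: GeneRecord,
    target_ks: float,
    omega: float,
    code: GeneticCode | None = None,
    seed: int = 0,
) -> tuple[GeneRecord, OrthologTruth]:
    """Diverge a copy of `gene` to roughly `target_ks` synonymous divergence.

    Point substitutions are proposed uniformly over coding positions
    (excluding the start and stop codons); synonymous changes are accepted
    with probability 1, nonsynonymous with probability `omega`, and changes
    creating a stop codon are always rejected. Proposals continue until the
    accepted synonymous substitutions reach ``target_ks x`` the ancestral
    synonymous site count, so the realised counts in the returned
    :class:`OrthologTruth` are exact.
    """
    if target_ks < 0 or omega < 0:
        raise ValueError("target_ks and omega must be non-negative")
    code = code or standard_code()
    rng = np.random.default_rng(seed)
    codons = list(gene.codons)
    has_stop = code.is_stop(codons[-1])
    lo, hi = 1, len(codons) - (1 if has_stop else 0)  # mutable codon range
    if hi <= lo:
        raise ValueError("gene too short to diverge")

    syn_sites = sum(synonymous_site_count(c, code) for c in codons[lo:hi])
    nonsyn_sites = 3.0 * (hi - lo) - syn_sites
    target_syn = int(round(target_ks * syn_sites))
    syn_acc = nonsyn_acc = 0
    max_proposals = max(1, 500 * 3 * (hi - lo))
    proposals = 0
    bases = "ACGT"
    while syn_acc < target_syn and proposals < max_proposals:
        proposals += 1
        idx = int(rng.integers(lo, hi))
        pos = int(rng.integers(0, 3))
        cur = codons[idx]
        alt_base = bases[int(rng.integers(0, 4))]
        if alt_base == cur[pos]:
            continue
        alt = cur[:pos] + alt_base + cur[pos + 1 :]
        if code.is_stop(alt):
            continue
        if code.amino_acid(alt) == code.amino_acid(cur):
            codons[idx] = alt
            syn_acc += 1
        elif rng.random() < omega:
            codons[idx] = alt
            nonsyn_acc += 1
    diverged = GeneRecord(
        gene_id=f"{gene.gene_id}_ortholog",
        codons=tuple(codons),
        strand=gene.strand,
        start=gene.start,
        end=gene.end,
        product=gene.product,
        is_ribosomal=gene.is_ribosomal,
    )
    return diverged, OrthologTruth(syn_acc, nonsyn_acc, syn_sites, nonsyn_sites)


def write_simulation(
    outdir,
    spec: SyntheticGenomeSpec,
    genome: str,
    genes: Sequence[GeneRecord],
    truth: GroundTruth,
) -> None:
    """Write genome FASTA, CDS FASTA, gene table, ground-truth TSV and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fasta", "w") as fh:
        fh.write(">synthetic_chromosome\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")
    write_cds_fasta(genes, outdir / "cds.fasta")
    write_gene_table(genes, outdir / "genes.tsv")
    with open(outdir / "ground_truth.tsv", "w") as fh:
        fh.write("gene_id\texpression\tstrand_class\toptimal_fraction\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{truth.expression[g.gene_id]:.6f}\t"
                f"{truth.strand_class[g.gene_id]}\t{truth.optimal_fraction[g.gene_id]:.6f}\n"
            )
    config = asdict(spec)
    config["optimal_codons"] = sorted(spec.optimal_codons)
    config["ori"], config["ter"] = truth.ori, truth.ter
    with open(outdir / "config.json", "w") as fh:
        json.dump(config, fh, indent=2, default=int)
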
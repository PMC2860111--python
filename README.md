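# codonuse

Synonymous codon usage analysis for bacterial genomes.

Synonymous codons are not used at random: mutational bias, translational
selection and replication-strand asymmetry each leave a distinct
statistical footprint on a genome's coding sequences. `codonuse` is a
toolkit for molecular evolution work on bacteria — originally built
around the codon-usage biology of the GC-rich amino-acid producer
*Corynebacterium glutamicum* — that computes the classical per-gene
indices, ordains genes by their usage profiles, detects translationally
optimal codons, classifies genes by replication strand, and estimates
synonymous/nonsynonymous divergence between orthologs.

## What it computes

For each gene (CDS of ≥ 100 codons with proper start/stop):

- **RSCU** — relative synonymous codon usage, `count·k / N_aa`
- **ENC** — Wright's effective number of codons,
  `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, with the null curve
  `Nc(s) = 2 + s + 29/(s² + (1−s)²)` for the Nc-vs-GC3s plot
- **GC3s, A3s/T3s/G3s/C3s** — third-position composition at
  synonymously variable codons
- **CAI** — codon adaptation index against a ribosomal-protein reference
- **Fop** — frequency of optimal codons; **GRAVY** — mean hydropathy

On gene sets:

- **Correspondence analysis** of the gene × 59-codon matrix (chi-square
  metric, SVD), axis inertia, and axis–index correlations
- **Optimal-codon calling**: per-codon 2×2 chi-square (codon vs rest of
  family, high- vs low-expression pool, P < .01)
- **Replication strand**: windowed GC skew, origin/terminus from
  cumulative-skew extrema, leading/lagging gene classes, and
  leading-strand fractions by CAI bin
- **Divergence**: reciprocal-best-hit orthologs, global protein
  alignment back-translated to codons, Nei–Gojobori Ka/Ks with
  Jukes–Cantor correction, Ks < 1 saturation filter, and
  divergence–expression correlations
- **Synthetic genomes** with planted selection strength, GC3 target, and
  leading-strand bias, plus ground-truth labels for validation

## Worked example

The package ships the published pooled codon counts of the highly and
lowly expressed gene groups of *C. glutamicum* (the two extremes of the
first correspondence-analysis axis), so the core statistics can be run
on real numbers directly:

```python
from codonuse import rscu, call_optimal_codons, ending_base_tally, standard_code
from codonuse.datasets import extreme_group_counts

code = standard_code()
high, low = extreme_group_counts()

w = rscu(high, code)
print("RSCU (high group): UUC=%.2f  UCC=%.2f  CGC=%.2f  GGC=%.2f"
      % (w["TTC"], w["TCC"], w["CGC"], w["GGC"]))

optimal, results = call_optimal_codons(high, low, code, alpha=0.01)
aas = {r.amino_acid for r in results if r.is_optimal}
tally = ending_base_tally(optimal)
print("optimal codons: %d over %d amino acids (C-ending: %d, G-ending: %d)"
      % (len(optimal), len(aas), tally["C"], tally["G"]))
```

prints

```
RSCU (high group): UUC=1.83  UCC=4.11  CGC=4.11  GGC=2.55
optimal codons: 22 over 18 amino acids (C-ending: 14, G-ending: 3)
```

i.e. phenylalanine UUC is used 1.83× its uniform expectation in highly
expressed genes, serine UCC 4.11×, and 22 codons — overwhelmingly
C-ending — are significantly over-used in the highly expressed group:
the signature of translational selection in this organism.

The same stage runs from the shell on any pooled-count TSV:

```bash
codonuse optimal --counts-tsv counts.tsv --outdir out/
```

and the full pipeline on a synthetic genome:

```bash
codonuse report --outdir out/ --seed 1
```

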
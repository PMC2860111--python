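# Methods

`codonuse` analyses synonymous codon usage in bacterial genomes. This note
records the statistical definitions, the numerical conventions, and the
design choices that were genuinely open, along with what the synthetic
validation genomes do and do not establish.

## Gene inclusion

A CDS enters the analysis only if it has at least 100 codons (the
terminal stop is included in the count), begins with an accepted
initiation codon, ends with a stop, and contains no internal stop. The
default start set is {ATG, GTG, TTG} — table 11 formally admits more
starts, but these are the ones actinobacteria actually use; the set is
configurable. Whether the 100-codon threshold counts the stop codon is a
convention; we count it. Short or malformed CDS are excluded with a
logged warning, never an exception: annotation noise is data, not an
error. The terminal stop is kept in the gene record but excluded from
every index.

Coordinates are 1-based inclusive (GenBank convention) throughout.
FASTA input carries no coordinates, so records are laid head-to-tail on
a synthetic "+" strand; GenBank CDS features (including joins and
minus-strand locations) are extracted with Biopython. Genes are flagged
ribosomal by the case-insensitive substring "ribosomal protein" in the
product annotation.

## Usage indices

* **RSCU**: `count(c) · k / N_aa` for a codon in a degeneracy-`k` family.
  Families without observations are *undefined* (NaN), not zero; the
  ordination matrix maps them to 0 explicitly and logs it.
* **ENC (Wright's Nc)**: per-family homozygosity
  `F̂ = (n·Σp² − 1)/(n − 1)`, averaged within degeneracy classes
  {2: 9 families, 3: Ile, 4: 5 families, 6: Leu/Ser/Arg},
  `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, clamped to [20, 61]. Families
  with n < 2 or F̂ = 0 carry no information and are skipped; a missing
  3-fold class is interpolated as (F̄₂ + F̄₄)/2, the CodonW-compatible
  fallback. The 6-fold families are kept whole rather than split 2+4 —
  Wright's original classing.
* **Null Nc curve**: `Nc(s) = 2 + s + 29/(s² + (1−s)²)` at third-position
  GC content `s`. Note the curve is *not* exactly symmetric about
  s = 0.5: the linear term makes Nc(0) = 31 but Nc(1) = 32 and puts the
  true maximum (≈60.501) at s ≈ 0.508. This is a property of the
  published closed form, not a bug.
* **GC3s and A3s/T3s/G3s/C3s**: base fractions at third positions of
  synonymously variable codons only (Met, Trp, stops excluded), so the
  four base fractions sum to 1 and GC3s = G3s + C3s. (CodonW normalises
  each base against slightly different denominators; we use the plain
  tally, which keeps the accounting identity exact.)
* **CAI**: Sharp & Li relative-adaptiveness weights
  `w(c) = count(c)/max_family_count` from a pooled reference of
  ribosomal-protein genes; zero counts get a pseudo-count of 0.5 before
  weighting to avoid log 0. CAI is the geometric mean of `w` over a
  gene's codon occurrences, Met/Trp/stops excluded.
* **Fop**: occurrences of optimal codons over occurrences of all codons
  in families containing at least one optimal codon (Ikemura's
  definition).
* **GRAVY**: mean Kyte–Doolittle hydropathy of the encoded protein
  (table from Biopython).

## Correspondence analysis

Classical CA of the gene × 59-codon matrix (RSCU by default, raw counts
available; which input the classical analyses used is rarely reported,
so both are exposed): relative frequencies are double-centred and
standardised by row/column masses, decomposed by SVD, and genes placed
in principal coordinates `D_r^{-1/2} U Σ`. Per-axis inertia is σ²/Σσ²;
the total equals the table's Pearson chi-square over its grand total
(asserted to 1e-8 in tests). Axis polarity is arbitrary, so axis 1 is
oriented to put the ribosomal reference set on the positive side.
Extreme groups default to 5% of genes per axis end (configurable; the
recovery experiments below use 10%), ties broken by gene id.

## Optimal-codon test

For each of the 59 synonymous codons, a Pearson 2×2 chi-square (no
continuity correction; Yates optional) on
[codon vs rest of family] × [high vs low pool], α = 0.01, no
multiple-testing correction. A codon is optimal when significant *and*
its within-family proportion is higher in the high pool — proportions,
not raw counts, because the pools differ in size. Per-codon 2×2 tests
(rather than one k×2 family test) match the way such tables are starred
codon-by-codon. On the bundled *C. glutamicum* extreme-group counts this
calls exactly 22 codons over 18 amino acids, 14 C-ending and 3 G-ending.

## Replication strand

Windowed GC skew (G−C)/(G+C), default 24 kb window / 3 kb step, circular
wrap-around. Origin and terminus come from the cumulative per-base skew
walk: global minimum = origin, maximum = terminus (ties to the smaller
coordinate) — a deliberate simplification of frame-aware DNA-walk
methods (oriloc); adequate for strand classification and dependency-free.
A gene is *leading* when its midpoint lies on the replichore whose fork
moves co-directionally with its coding strand; midpoints (not starts)
decide boundary genes. CAI bins default to {≤0.35, 0.35–0.65, >0.65}
with boundary values in the lower bin, plus named special sets
(e.g. ribosomal) as extra rows. Reverse-complementing a chromosome
renames strands but leaves every gene co-directional with the same fork,
so leading/lagging classes are invariant under re-orientation — a
property the tests assert.

## Ortholog divergence

Reciprocal best hits over 12-column tabular protein hits with the
classical thresholds (identity ≥ 60% over aligned columns, E ≤ 1e-5,
coverage ≥ 60% of the longer protein, length ≥ 100 aa); best hits by bit
score, then E-value, then subject id. Internally generated hits carry
E = NaN and skip the E-value criterion. Pairs are aligned globally at
the protein level (BLOSUM62, gap open 11 / extend 1, deterministic first
traceback) and back-translated to codons with strict validation.

Ka/Ks uses Nei–Gojobori counting with equal mutation weights:
synonymous sites per codon are the per-position fractions of synonymous
single-base changes, with changes *to* stop codons counted as
nonsynonymous so sites always sum to 3 per codon; multi-position codon
differences average over all mutational orderings, excluding pathways
through stops (falling back to all pathways if every one is blocked);
Jukes–Cantor correction `d = −¾·ln(1 − 4p/3)`, with p ≥ ¾ flagged as
saturated (NaN). Columns with gaps or stop codons are skipped. This is a
counting estimator, not a maximum-likelihood codon model: it ignores
transition/transversion and codon-frequency biases, so its values are
not numerically interchangeable with ML estimates on real data, though
rankings and the Ks < 1 saturation filter behave the same way. A subtle
counting property worth knowing: under purely synonymous evolution,
pathway averaging over codons hit twice leaks a small nonsynonymous
difference count, so Ka is near — not exactly — zero.

## Synthetic genomes

The generator plants exactly the structure the pipeline is meant to
detect. Expression levels are log-normal (σ = 1), giving a realistic
high-expression tail; the top 5% by expression are labelled ribosomal.
Within each synonymous family, codons are drawn from a softmax combining
a mutational term (tuned so third positions hit the target GC3, default
0.55, matching a mildly GC-rich actinobacterium) and a selection term
`s_expr · e` on optimal codons, where `e` is expression scaled by its
maximum — so selection concentrates in the expression tail. The default
optimal set is the 22 published *C. glutamicum* codons; `s_expr`
defaults to 6, which produces CAI spreads (~0.1–0.95) and extreme-group
contrasts comparable to real selection-shaped genomes. Genes are laid
head-to-tail with A/T spacers on a circular chromosome with origin at
position 1 and terminus at the midpoint; top-quartile genes land leading
with probability 0.85 (the ribosomal-row fraction observed in
*C. glutamicum*), others 50/50. The default 600 genes keep a full
pipeline run in seconds while giving pooled family counts large enough
for the per-codon test — the binding case is the Ala family, where three
of four codons are optimal and each codon's proportion shift is small.

Ortholog partners evolve by uniformly proposed point substitutions:
synonymous accepted at rate 1, nonsynonymous at rate ω, stop-creating
proposals rejected, start codon held fixed; the process stops when
accepted synonymous changes reach `target_Ks ×` the ancestral synonymous
site count, and the realised substitution counts are recorded as ground
truth. Estimator validation therefore compares NG86 output against the
*realised* rates, the standard way to test a counting estimator.

What the synthetic genomes do **not** emulate: amino-acid composition
variation between genes, length–expression correlation, intergenic
realism, indels, strand-specific mutational skew inside genes, and
operon structure. Passing the recovery tests shows the statistics detect
the planted effects at realistic magnitudes; it does not certify
behaviour under confounders real genomes add (e.g. amino-acid usage
trends loading on CA axes).

## Numerical conventions

Undefined statistics are NaN markers, never silent zeros. Report tables
round to 2 decimals but full-precision columns are retained. All
randomness flows through explicitly seeded `numpy` generators; a given
spec + seed reproduces byte-identical FASTA output. Presentation TSVs
are tab-separated, UTF-8, "." decimal.
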
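# Methods

## Scope and data model

`mitopanel` treats mitochondrial genotypes as haploid sequences on the
rCRS coordinate system (positions 1–16,569). The central objects are:

- `ReferenceAlignment` — a rectangular character matrix with a
  designated rCRS row; after projection every column maps to one rCRS
  position.
- `VariantPanel` — variable sites as an allele-index matrix
  (0 = reference allele = the rCRS base, 1.. = alternates by
  descending count, −1 = missing), the imputation reference.
- `TypedGenotypes` — observed bases at chip-typed sites per target.
- `ImputationResult` — posterior alternate-allele probabilities, hard
  calls, per-site info scores and filter flags.

## Alignment processing

**Projection.** Columns in which the rCRS row carries a gap are
insertion columns relative to the reference coordinate system and are
deleted from all rows; gaps in other rows are retained. This preserves
the standard mtDNA site numbering at the cost of discarding real
insertion alleles, which are outside the toolkit's variant model
(substitutions only). Projection is idempotent.

**Sequence QC.** A sequence is removed when it has ≥ 5 ambiguous
characters or ≥ 8 gaps. "Ambiguous" is any character outside
{A, C, G, T, −}: IUPAC degeneracy codes and N are treated alike, which
matches the downstream step that codes every non-ACGT state as missing.
Counts are taken after projection. The rCRS row is exempt — it is a
coordinate anchor, not a population sample — and is likewise excluded
from the panel's sample set.

**Variant extraction.** Gap and ambiguous states become missing; a
site is kept when at least two distinct alleles are observed among
non-missing entries. Duplicate haplotypes are retained on purpose:
identical sequences represent common genomes and carry frequency
information. The reference allele is always the rCRS base, even when
unobserved among the samples.

**MAF.** Minor allele frequency is computed over non-missing
haplotypes only (using the total would deflate MAF at incomplete
sites), as `(n − max allele count)/n`, capped at 0.5 for multiallelic
sites. This integer-ratio form keeps boundary cases exact: a singleton
in 1,000 haplotypes is exactly 0.001 and is removed by the strict
`MAF > 0.1%` filter. Stratification thresholds follow the conventional
> 1%, > 0.5%, > 0.1% grid.

**Multiallelic sites** are collapsed one-vs-rest to (ref, most frequent
alternate) before imputation and IMPUTE2 export; collapsed sites are
flagged. Rarer alternates fold into the reference class.

## Completeness

A character is "fully specified" when it is A, C, G or T; gaps count
as unspecified. C_a is the specified fraction of the whole matrix, C_r
and C_c the per-row and per-column fractions (their means equal C_a by
construction — asserted to 1e-12 in the tests), C_ij the fraction of
columns specified in both members of a pair. Pairs are exhaustive up to
200 sequences and a seeded random subsample (default 2,000 pairs)
above, since only min–max summaries are reported for large alignments.

## Imputation

With a zero recombination rate at every site the Li–Stephens copying
HMM has no transitions, so the hidden copied-template path is constant
and the model becomes an exact single-template mixture (see README for
the formulas). Implementation choices:

- **Copying error λ.** Default derives from the conditioning-set size
  K via the Watterson-style rule θ = 1/Σ_{i=1}^{K−1} 1/i,
  λ = θ/(2(K+θ)) — strictly decreasing in K, ≈ 6×10⁻⁴ at K = 150. λ is
  configurable in (0, 0.5); the default reproduces the usual behaviour
  that larger panels are copied more faithfully.
- **Conditioning set (`k_hap`).** Per target, the k_hap reference
  haplotypes with the smallest Hamming distance to the target over the
  mutually non-missing typed sites; ties break to the lower panel
  index for determinism. `k_hap ≥ K` uses the whole panel and equals
  direct enumeration (tested against an independent naive oracle to
  1e-9). The recommended default is k_hap = 500 with a reference
  filtered at MAF > 0.1%.
- **Numerics.** Weights are accumulated in log space with
  max-subtraction before exponentiation, so 16k-site products cannot
  underflow. Zero typed overlap yields uniform weights (the empty
  product).
- **Missing reference alleles.** At each site, haplotypes missing
  there are skipped and the weights renormalised over the carriers; if
  every conditioning haplotype is missing, the posterior falls back to
  the panel allele frequency and the call is flagged.
- **Typed sites** get a degenerate posterior on the observed allele; a
  target missing an observation at a typed site is imputed there.
- **Hard calls** are the argmax allele with exact ties going to the
  reference allele.
- **Info score.** The haploid form
  `1 − Σ p(1−p)/(N·θ̂(1−θ̂))` is used (denominator N·θ̂(1−θ̂), not
  2N·θ̂(1−θ̂): each haploid sample contributes one allele). θ̂ ∈ {0, 1}
  (a monomorphic, certain site) is defined as score 1; values are
  clamped to [0, 1]. Imputed sites with score ≤ 0.3 are filtered
  (boundary inclusive); typed sites are never filtered. Note this
  score is 0 whenever all targets share the same uncertain posterior —
  a chip that cannot distinguish the targets gives no per-sample
  information even if the cohort-level prediction is good.

## Haplogroup calling

A deliberate simplification of PhyloTree/HaploGrep-style assignment,
designed for concordance evaluation on panels with known clade
structure. A lineage table lists each label's parent and defining
variants (position, derived allele). A sample's score for a label is
the fraction of the label's *typed* defining variants in the derived
state; among labels with score ≥ 0.9 (default) and at least one typed
defining variant, the deepest label wins, with ties broken by higher
score then lexicographic order. Kulczynski-style quality weighting and
hotspot handling are intentionally out of scope.

Macro-collapsing uses longest-prefix matching against
{L0…L6, HV, JT}, else the first letter. Whether lineages J and T
should fold into the JT macrohaplogroup is genuinely ambiguous in
common usage; the prefix set is therefore a parameter, and the default
collapses only labels literally beginning "JT".

## Evaluation

Per-site MCC treats the collapsed alternate allele as the positive
class; truth entries missing for a sample are excluded from that
site's counts, and a zero denominator factor defines MCC = 0 (the
convention shared by scikit-learn, against which the implementation is
cross-checked). Only imputed sites passing the info filter are
evaluated. The mean MCC carries a normal-approximation 95% CI
(validated against a 10,000-replicate bootstrap). Haplogroup
concordance is the fraction of samples whose call matches the truth
label at the macro or full level; unassigned calls are discordant.
`parameter_sweep` emits one tidy row per (chip, k_hap, MAF)
combination; modelling of parameter effects (e.g. mixed-model ANOVA)
is left to external tools by design.

## Synthetic data generator

The generator produces what the evaluation needs — controllable,
exactly recoverable structure — rather than realistic evolution:

- Leaf clades are spread over up to 4 top-level clades joined by
  random bifurcating subtrees; labels follow haplogroup-style
  letter/digit alternation (A, A1, A1a …) so macro-collapsing a leaf
  label returns its top-level letter. The letter L is never used at
  the top level because L-lineages collapse to two-character macros.
- Every tree node carries `n_defining` substitutions, drawn without
  positional collision across the whole tree; every haplotype
  additionally carries Poisson-distributed private mutations at
  non-defining positions. Keeping private mutations off defining sites
  makes planted labels exactly recoverable from complete data, which
  several invariants assert.
- Defaults: sequence length 2,000 (a full-length 16,569 mode exists;
  the short default keeps panels dense and the suite fast), 8 clades ×
  25 haplotypes, 12 defining mutations per node, Poisson(3) private
  mutations per haplotype. These give panels whose site frequencies
  span the 0.1%/0.5%/1% MAF thresholds (singletons at 1/200 = 0.5%
  sit exactly on the middle cut) and a realistic mix of easy
  clade-informative and hard singleton sites.
- What it does **not** emulate: realistic mtDNA mutation spectra and
  hotspots, heteroplasmy, indel evolution (gaps appear only as planted
  QC noise), back-mutation on defining sites, and sequencing error.
  Passing tests therefore demonstrate correctness of the algorithms
  under clean clade structure, not expected accuracy on real cohorts.
- `inject_noise` plants exact numbers of QC-failing sequences (5
  ambiguity codes / 8 gaps by default — precisely on the removal
  thresholds) and returns the manifest for exact-recovery checks.
- `make_chip_definition` subsamples panel positions, optionally biased
  toward high-MAF sites via Gumbel-top-k sampling on `bias·log(MAF)`
  (uniform at bias 0, converging on the top-MAF set as bias → ∞),
  mimicking commercial array design.

## Workflow

`run_pipeline` chains build-panel → simulate-chip → impute →
assign-haplogroups → evaluate natively (no external workflow engine),
from a flat YAML config, writing a JSON manifest with a sha256 checksum
per output file. Every stage is deterministic given the config, so
identical configs produce identical checksums; no stage reads a file it
writes. Inputs are validated before any stage runs, and a stage failure
aborts with the stage name.

## Problem sizes

The test suite and the acceptance script run the full study at the
generator defaults (200 haplotypes × 2,000 bp, ~650 variant sites,
50-site chips, 50 held-out targets, 20 seeded replicates for the
recovery check) — sizes chosen so the whole suite completes in well
under a minute while every frequency threshold and code path is
exercised.

## Known limitations

- Substitutions only: insertions are discarded at projection and
  deletions survive merely as missing data.
- Heteroplasmy is out of scope; haploid calls only.
- The haplogroup caller requires a defining-variant table and does not
  implement full PhyloTree nomenclature.
- One-vs-rest collapse discards second and later alternate alleles at
  multiallelic sites for imputation and IMPUTE2 export (they are
  preserved in VCF).
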
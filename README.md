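# mitopanel

A toolkit for imputing missing mitochondrial DNA (mtDNA) single
nucleotide variants from genotyping-microarray data, for population and
medical geneticists who need complete mitochondrial genotypes — and
reliable haplogroup assignments — from partial chip data.

Microarrays probe only a few dozen to a few thousand mitochondrial
sites, often too few to assign a mitochondrial genome to its
phylogenetic lineage (haplogroup). Because the mitochondrial genome is
haploid and effectively non-recombining, the missing sites can be
imputed from a reference panel of complete haplotypes. `mitopanel`
covers the whole workflow:

- **Reference panel construction** — ingest an aligned FASTA of
  complete mtDNA sequences with an rCRS (revised Cambridge Reference
  Sequence) row, project onto rCRS coordinates (dropping insertion
  columns so the standard 1–16,569 site numbering is preserved), remove
  sequences with ≥ 5 ambiguous characters or ≥ 8 gaps, code remaining
  gaps/ambiguity as missing, drop invariant sites, and stratify by
  minor allele frequency (MAF > 1%, > 0.5%, > 0.1%).
- **Completeness statistics** — C_a / C_r / C_c / C_ij scores of the
  alignment.
- **Format I/O** — haploid VCF 4.2, IMPUTE2 `.hap/.legend/.sample/.gen`,
  and zero-rate recombination maps, with bit-exact round-trips.
- **In-silico microarrays** — mask truth haplotypes to the site content
  of a chip parsed from Oxford-style strand files.
- **Imputation** — the haploid copying model (below), with per-target
  conditioning-set selection (`k_hap`) and info-score filtering.
- **Haplogroup assignment** — a table-driven caller with
  macrohaplogroup collapsing (L0–L6, HV, JT, else first letter).
- **Evaluation** — per-site Matthews correlation coefficient (MCC),
  mean MCC with 95% CI, haplogroup concordance before/after imputation,
  and a (chip × k_hap × MAF) parameter sweep.
- **Synthetic data** — a seeded generator of clade-structured
  populations so the entire pipeline runs and is testable without any
  external downloads.

## The model

With the recombination rate fixed at r = 0 at every site — the correct
choice for mtDNA — the Li–Stephens haplotype-copying HMM collapses to a
single-template mixture. A target haplotype is modelled as one entire
reference haplotype copied with independent per-site error λ. Given the
target's typed alleles g and reference haplotypes h⁽¹⁾…h⁽ᴷ⁾, the
posterior copying weight of haplotype k is

    w_k ∝ ∏_{s typed} (1 − λ)^{1(h_s⁽ᵏ⁾ = g_s)} · λ^{1(h_s⁽ᵏ⁾ ≠ g_s)}

and the posterior probability of the alternate allele at an untyped
site s is

    P(alt at s) = Σ_k w_k · [(1 − λ)·1(h_s⁽ᵏ⁾ = alt) + λ·1(h_s⁽ᵏ⁾ = ref)].

No forward–backward pass or MCMC is required; the computation is exact.
Per-site certainty is summarised by the haploid info score
`1 − Σᵢ pᵢ(1 − pᵢ) / (N·θ̂(1 − θ̂))` with θ̂ the mean posterior alt
probability; imputed sites with info ≤ 0.3 are filtered.

The imputation engine is a scikit-learn-style estimator
(`HaplotypeImputer(k_hap, copying_error, info_threshold, maf_threshold)`
with `fit(panel)` / `predict(typed)`), alongside a frequency-only
`MajorAlleleImputer` baseline.

## Worked example

```python
import mitopanel as mp

pop = mp.simulate_population(n_clades=8, n_per_clade=25, seed=42)
truth = mp.extract_variant_sites(pop.to_alignment())
print(f"panel: {truth.n_sites} variant sites x {truth.n_samples} haplotypes")

chip = mp.make_chip_definition(truth, n_sites=50, seed=43)
targets = pop.sample_ids[::4][:50]
typed = mp.mask_to_chip(truth, chip, targets)

reference = truth.subset_samples(
    [s for s in truth.sample_ids if s not in set(targets)])
imputer = mp.HaplotypeImputer(k_hap=500, maf_threshold=0.001)
result = imputer.fit(reference).predict(typed)
print(f"lambda = {imputer.copying_error_:.5f}; "
      f"{int(result.imputed_sites.sum())} imputed sites pass the info filter")

report = mp.evaluate_run(
    truth, {s: pop.truth_labels[s] for s in targets}, typed, result,
    pop.haplogroup_table())
print(f"mean MCC = {report.mu_mcc:.3f} "
      f"(95% CI {report.mcc_ci[0]:.3f}, {report.mcc_ci[1]:.3f})")
```

prints

```
panel: 657 variant sites x 200 haplotypes
lambda = 0.00060; 134 imputed sites pass the info filter
mean MCC = 0.762 (95% CI 0.698, 0.826)
```

Here 200 simulated haplotypes from 8 clades yield 657 variant sites; 50
held-out targets are typed at only 50 chip sites, and the copying model
imputes the rest. The mean per-site MCC of 0.762 says imputed genotypes
correlate strongly with the held-out truth (a frequency-only baseline
scores 0.0 on the same sites), and macro-haplogroup concordance rises
from 0.88 (masked) to 1.00 (imputed) in the same run — exactly the
improvement imputation is meant to buy.

The same workflow is available from the shell:

```sh
mitopanel simulate --clades 8 --per-clade 25 --seed 42 --out fixtures/
mitopanel build-panel --msa fixtures/msa.fasta --rcrs-id rCRS --out panel/
mitopanel impute --panel panel/panel.vcf --typed typed.vcf --k-hap 500 \
    --maf 0.001 --out-gen imputed.gen --out-vcf imputed.vcf
mitopanel run --config run.yaml   # full pipeline with manifest
```

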
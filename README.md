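# tubahdr

Tumor-barcode sequencing analysis for **HDR-installed Kras variant
alleles** — from barcoded amplicon reads of bulk tumor-bearing tissue to
called tumors with absolute neoplastic-cell numbers, collision-corrected
sizes and per-variant oncogenicity statistics.

## The problem

A somatic cancer-modeling platform installs, by CRISPR/Cas9-assisted
homology-directed repair (HDR) at the endogenous *Kras* locus, one of 12
non-synonymous single-nucleotide mutations at codons 12/13 (or wild type)
together with a random 8-nucleotide barcode embedded in nearby degenerate
positions of a 22-nt region. Each resulting tumor is clonally marked by its
(variant, barcode) pair. Deep amplicon sequencing of bulk tissue, together
with a spike-in control of known cell number, turns read counts into
per-tumor cell numbers and lets one measure, in a single multiplexed
mouse, how strongly each Kras variant drives tumor growth.

This package implements the computational side of that platform:

* **Allele model** — the 60-nt amplicon geometry, 24,576-barcode space
  (per-position alphabets 4,4,4,4,4,4,3,2), exact read parsing, codon-usage
  and ortholog-identity scores.
* **Denoising** — divisive abundance-p-value clustering: a member sequence
  at Hamming distance *d* from a cluster of *A* reads has expected error
  abundance λ = *A*·(rate/3)^*d*; it founds a new cluster when
  P(Poisson(λ) ≥ count | ≥ 1) < ω_A (default 0.01). The per-base error
  rate is estimated from the 14 invariant flank nucleotides. "Shadow"
  clusters one mismatch from a ≥10,000× larger lesion are removed.
* **Absolute sizes** — cells_t = reads_t / reads_spike-in × 5×10⁵, with a
  100,000-cell cutoff for tumor counting (lung) or an internal 2×max-WT
  read cutoff (pancreas).
* **Collision model** — barcode probabilities from independent
  per-position nucleotide frequencies, p_i = Π_b f_{b,n} (21 free
  parameters); expected collisions C_i(p_i, N) = N·p_i + (1−p_i)^N − 1;
  the total tumor number N solved from N^(obs) = N − Σ_i C_i via Brent's
  method; each lesion's size divided by 1 + C_i.
* **Variant statistics** — tumor counts normalized by plasmid-library
  representation (98th-percentile barcode trim) and scaled to WT = 1;
  two-sided Fisher exact tests vs WT and G12D with Bonferroni correction;
  a structural-zero binomial-tail test when no WT tumors exist; bootstrap
  95% CIs; "many cells" Pearson χ².
* **Clonality mapping** — multi-region clone matching and metastasis
  linking through shared (variant, barcode) pairs, with collision hazards.
* **Mutational signatures** — 96-class trinucleotide context labeling and
  signature-based relative induction frequencies of the 12 codon 12/13
  mutations, used to normalize observed human mutation spectra.
* **Synthetic data** — a generator that emulates the assumed statistics
  (WT ~4× over-represented pool, per-position barcode skew, lognormal
  tumor sizes, known spike-in, ~10⁻⁴ per-base errors) and serializes
  ground truth for parameter-recovery tests.

## Worked example

Simulate a 4-mouse cohort under known per-variant oncogenicity
multipliers and analyze it end to end:

```python
from tubahdr.pipeline import run_simulated_experiment

res = run_simulated_experiment(n_mice=4, mean_tumors_per_mouse=60,
                               pool_depth=200_000, n_boot=500, seed=42)
print(res.summary[["tumor_count", "relative_to_wt",
                   "ci_low", "ci_high", "p_vs_wt"]].round(3))
```

```
         tumor_count  relative_to_wt  ci_low  ci_high  p_vs_wt
variant
G12A               9          13.720   3.817   42.607    0.000
G12C              13          19.941   6.749   55.222    0.000
G12D              32          48.503  16.991  115.195    0.000
G12R               9          13.571   3.770   42.145    0.000
G12S               3           4.492   0.012   17.970    0.728
G12V              23          35.135  11.457   91.580    0.000
G13A               2           3.089   0.000   12.355    1.000
G13C               1           1.541   0.000    6.165    1.000
G13D              15          22.425   6.734   59.799    0.000
G13R               7          10.640   2.280   33.440    0.004
G13S               2           3.008   0.000   12.030    1.000
G13V              21          31.544   9.013   84.118    0.000
WT                 2           1.000   1.000    1.000      NaN
```

`tumor_count` is the number of called tumors above 100,000 cells pooled
over mice; `relative_to_wt` is that count divided by the variant's
plasmid-library representation and scaled so WT = 1 (the oncogenicity
readout; the strongly driving variants G12D/G12V/G13V sit at the top, as
their simulation multipliers dictate); `ci_*` are bootstrap 95% bounds and
`p_vs_wt` the Bonferroni-corrected Fisher p-value against WT. Diagnostics
from the same run: flank-estimated error rate 9.9×10⁻⁵ per base
(simulated: 10⁻⁴), mean expected barcode-collision fraction 0.13%.

The same chain is available stage by stage from the shell:

```sh
tubahdr simulate --out sim --seed 3
tubahdr process sim/mouse00.fastq --out pileup.tsv
tubahdr call pileup.tsv --mode lung --out calls.tsv
tubahdr stats calls.tsv sim/pool.tsv --out summary.tsv
```

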
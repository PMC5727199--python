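# Methods

This note documents the models and procedures implemented in `tubahdr`,
the defaults they use, and what the synthetic-data generator does and does
not emulate.

## Amplicon geometry and the default allele design

The unit of analysis is a 60-nt merged amplicon core:

```
positions 1-16   lead context carrying the PAM* silent mutations
          17-19  Kras codon 12 (WT GGT)
          20-22  Kras codon 13 (WT GGC)
          23-44  22-nt barcoded region
          45-51  invariant 7-nt downstream flank
          52-60  trailing locus context
```

Within the barcoded region, eight wobble positions (region coordinates 1,
4, 7, …, 22) carry the random barcode and three anchor bases (positions 2,
11, 20) are fixed substitutions present in every HDR allele but absent
from the wild-type locus; all remaining bases equal wild type. The wobble
alphabets are {A,C,G,T} at positions 1–6, {A,C,G} at 7 and {A,T} at 8.
This is the unique alphabet-size profile for which an independent
per-position frequency model simultaneously spans 4⁶·3·2 = 24,576 barcodes
and has Σ(|alphabet|−1) = 21 free parameters; the *identity* of the two
restricted positions and of the anchor bases is a design choice of this
package (the published sequencing constructs are not fully specified at
that level) and every element is overridable through a YAML config
(`BarcodeDesign.from_yaml`). The spike-in normalization control is a G12V
allele with wobble barcode `CGGGAAGT`, representing 5×10⁵ cells per
sample.

Variant space: all single-nucleotide substitutions of GGT/GGC that change
the encoded amino acid — 12 of the 18 possible substitutions (the six
third-position changes are synonymous) — plus wild type, giving 13 allele
classes. Parsing is exact: a read is accepted only if every invariant base
matches, codons 12/13 decode to a known class, and each barcode base lies
in its alphabet; failures carry a reason code (`anchor_mismatch`,
`unknown_codon`, `bad_barcode_base`, `bad_length`).

## Read processing

Pairs are merged by a minimal fixed-offset overlap merger (the fragment
geometry is known), keeping the higher-quality base at overlap mismatches
and rejecting pairs with <90% overlap identity. Merged reads are located
by the 7-nt PAM* primer context; indels anywhere in the core shift the
fixed-length window and are rejected (`bad_length`) — there is no
indel-tolerant alignment, matching the fixed-length pileup approach. Reads
with any base below Q20 inside the clustering window are rejected (the
threshold is a package choice; the upstream tooling's value is not
specified). The clustering sequence is 42 nt: codons 12–13 (6) + barcoded
region (22) + 7-nt flanks on each side.

The residual per-base error rate is the read-weighted mismatch fraction
over the 14 invariant flank positions. Because the flanks are invariant by
design, every mismatch there is a sequencing/PCR error; the estimator is
unbiased under the iid-substitution error model (verified by simulation).

## Denoising and tumor calling

Clustering is greedy and divisive. Starting from a single cluster seeded
by the most abundant sequence:

1. each sequence is assigned to the cluster maximizing its expected error
   abundance λ = A·(e/3)^d, where A is the cluster read total, e the
   per-base error rate and d the Hamming distance to the center
   (assignment and cluster totals are alternated to a fixed point);
2. each non-center member receives an abundance p-value
   P(Poisson(λ) ≥ n | ≥ 1);
3. the smallest p-value below ω_A = 0.01 founds a new cluster; repeat.

Reads are conserved: cluster totals always sum to the pileup total.
Compared with full DADA2-style denoisers this implementation has no
quality-score dependence and no error-model self-consistency loop — the
error rate is fixed in advance from the invariant flanks, which removes
the main estimation loop — and uses a uniform substitution model. The
(e/3)^d factor omits the (1−e)^(L−d) survival term, which is ≈1 at
L = 42, e ≈ 10⁻⁴.

Shadow artifacts — recurrent errors of a very large lesion that would
otherwise appear as small spurious tumors — are clusters whose center is
within Hamming distance 1 of a cluster ≥10⁴× larger; they are discarded
(not reassigned, since they are artifacts, not misassigned reads) and the
removed fraction is reported. Cluster centers that fail allele parsing
(residual error sequences) are dropped with bookkeeping.

Absolute sizes: cells_t = reads_t / reads_spike-in × 5×10⁵. Tumor counting
uses a strict >100,000-cell cutoff (one fifth of the spike-in), below
which size estimates are unreliable; pancreas samples carry no spike-in
and instead use reads > 2× the largest wild-type call in the sample.
Dissected-tumor exclusion lists drop calls from size analyses while
keeping them in tumor-number analyses.

## Barcode-collision model

Within a mouse, barcode assignment is modeled as multinomial sampling of N
tumors over the barcode space with probabilities predicted from
independent per-position nucleotide frequencies, p_i = Π_b f_{b,n(i,b)}
(21 free parameters, fitted read-weighted from plasmid-library
sequencing). The expected number of extra tumors hiding behind observed
barcode i is

    C_i(p_i, N) = N·p_i + (1 − p_i)^N − 1,

and N is recovered from the observed distinct count by solving
N^(obs) = N − Σ_i C_i(p_i, N) with Brent's method (residual < 10⁻⁶; upper
bracket 100×N^(obs), doubled until the sign changes). The sum runs over
**all retained barcodes**, which makes the fixed point algebraically
well defined: N − Σ_all C_i equals the expected number of distinct
barcodes, B − Σ(1−p_i)^N. Each lesion's size is divided by 1 + C_i of its
barcode. Because the 10% most over-represented library barcodes (ranked
by observed count ÷ p_i, ties broken lexicographically) collide most,
they are excluded up front and the retained p_i renormalized to one;
barcodes containing a never-observed nucleotide (p_i = 0) are excluded
before solving. The model corrects the *average* size bias; it cannot
identify which specific calls were collisions, and no attempt is made to.

## Variant statistics

Per-variant representation is the library read fraction after dropping
(variant, barcode) rows above the 98th percentile of per-row read count,
computed pool-wide (not per variant). Relative tumor number is
(count_v/rep_v)/(count_WT/rep_WT). Enrichment tests are two-sided Fisher
exact tests on [[count_v, count_ref], [library reads_v, library
reads_ref]] — raw library read counts preserve exactness and use all
information — Bonferroni-corrected by 12 (the number of mutant variants).
When the reference count is structurally zero (no WT tumors), the test is
the exact binomial tail P(0 reference tumors | n = count_v,
p_ref = rep_ref/(rep_ref+rep_v)) = (1−p_ref)^count_v, doubled for a
two-sided report; this is a declared construction in the spirit of
structural-zero generalizations of Fisher's test, not a reproduction of
any specific published variant. Confidence intervals are percentile
bootstrap (default 2,000 resamples) over the tumor list pooled across
mice of a genotype. The genotype-spectrum comparison is an ordinary
("many cells") Pearson χ² on the variant × genotype count table, with a
warning when expected cells fall below 1.

## Clonality mapping

Clones are matched across samples by exact (variant, barcode) equality —
denoising upstream has already collapsed sequencing errors, so no fuzzy
matching is used. Groups spanning ≥2 primary regions are typed
region-continuity; groups containing a metastasis link the metastasis to
every primary candidate (source ambiguity is preserved, not resolved);
met-only groups are flagged. Within each sample the largest tumor is
scaled to relative size 1 and dot diameters are √(relative size) so that
dot area tracks size; no cross-sample size comparison is emitted without a
spike-in. Each cross-primary edge can be annotated with a collision
hazard — the probability under the frequency model that the shared pair
arose by two independent initiations given the two samples' tumor counts.

## Mutational-signature arithmetic

Substitutions are labeled in the 96-class pyrimidine-centric convention
(purine references reverse-complemented with their context). The relative
induction frequency of each of the 12 codon 12/13 mutations is the sum of
the included signatures' class probabilities, normalized within the 12;
observed human counts divided by these frequencies (renormalized) give a
mutation-rate-adjusted prevalence. The package ships only a synthetic
fixture-style signature table format and a TSV loader; analyses of the
published signature tables require the user-supplied file. A mutation
observed with zero induction probability in every included signature is
an error rather than being pseudo-counted.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

| quantity | default | rationale |
|---|---|---|
| WT:mutant pool ratio | 4 | pool built from four fragment sets, each containing WT |
| per-position nucleotide skew | ~±5 pp around uniform | synthesis-concentration imbalance |
| per-base substitution rate | 10⁻⁴ | residual post-merge error scale |
| tumor sizes | lognormal, median 2×10⁵ cells, σ = 0.5 log₁₀, floor 10³ | heavy tail consistent with read counts spanning ~5 orders of magnitude; no size law is prescribed by the platform, lognormal is the package's choice |
| spike-in | G12V `CGGGAAGT`, 5×10⁵ cells | known normalization control |
| sequencing depth | 4×10⁻⁴ reads/cell | puts the spike-in at ~200 reads |
| tumors per mouse | Poisson(150) | keeps desk-scale cohorts tractable while leaving collisions measurable |

Tumor variants are drawn proportional to pool representation × a
per-variant oncogenicity multiplier (defaults span 0.2–10 with a
near-null WT), barcodes from the pool's conditional barcode distribution
with replacement (collisions arise naturally), and everything is
bit-reproducible under a fixed seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: PCR jackpotting and amplicon-length bias (both
mitigated experimentally in the platform), quality-score structure
(constant Q37), indels and structural variation of the HDR allele,
Kras-locus copy-number amplification, contamination between samples, and
any genotype × variant interaction (genotypes differ only through size
parameters). Recovery results on synthetic cohorts therefore validate the
statistical machinery, not robustness to those real-world artifacts.

## Numerical choices and degenerate inputs

* Abundance p-values use the exact conditional Poisson tail; λ = 0 gives
  p = 0 (with a zero error rate every distinct sequence founds a cluster).
* Brent tolerance 10⁻⁹ with a 10⁻⁶ residual assertion; C_i clipped at 0
  against floating-point negatives.
* Ties in barcode exclusion and cluster seeding break lexicographically
  for determinism; processing is order-independent.
* Zero codon-usage frequencies map to a −∞ sentinel in log₂ fold change
  rather than being pseudo-counted.
* Pancreas samples without any WT call apply a zero threshold (all calls
  kept) with a warning.
* Empty pileups, missing spike-ins, all-zero multipliers and observed
  tumor counts exceeding the barcode space raise typed errors.

## Problem sizes used in the test and acceptance runs

Simulated experiments run at desk scale as the package's own choice of
study size: plasmid pools of 10⁶ reads, cohorts of 15 mice × ~150 tumors,
~2×10⁴ reads per bulk sample, 10⁵ Monte-Carlo replicates for the collision
check, and 200 null cohorts of 2,000 tumors for Fisher calibration (large
enough that the conditional test's discreteness is negligible). The
ortholog-identity operation is exercised on synthetic equal-length pairs;
comparing the real mouse/human KRAS translations requires user-supplied
FASTA files (no network access at test time, by design).

## Known limitations

* The denoiser is single-pass greedy; pathological pileups could admit
  better partitions that a full expectation-maximization denoiser would
  find.
* The collision model treats all tumors in a mouse as one multinomial
  draw over barcodes, ignoring that same-barcode tumors of *different*
  variants are in fact distinguishable; the correction is therefore
  slightly conservative.
* Collision correction divides sizes by an expectation; per-tumor
  collision indicators are unidentifiable and not attempted.
* The structural-zero test is a binomial-tail construction, exact under
  its stated null but not identical to any particular published
  generalization.
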
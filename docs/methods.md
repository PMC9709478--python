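# Methods

## Screening model

Read-through transcription is detected at interval resolution: the unit of
analysis is a directed adjacent gene pair — an upstream gene whose
transcription termination site (TTS) borders the intergenic gap, and the
next gene body beyond it. "Adjacent" means consecutive in coordinate order
per chromosome regardless of strand; interleaved opposite-strand genes
therefore break adjacency. Orientation follows from the definition of
read-through (transcription running past the TTS): a gene is an upstream
candidate only when its 3' end faces the gap, so same-strand neighbours
yield one cis pair, convergent neighbours two trans pairs (one per
direction) and divergent neighbours none. Overlapping or abutting gene
bodies yield no pair, because no intergenic interval exists. The screen
never estimates how far past the TTS transcription runs; it only
thresholds interval-level FPKM, which is what keeps it applicable to
ordinary coverage data.

Quantification follows bedtools-coverage semantics: a fragment (the outer
span of a properly paired read pair; unpaired reads count singly) counts
toward a feature when the intervals overlap by at least one base, in
half-open coordinates, with strand matching on by default because the
assumed library is strand-specific. Intergenic features take the upstream
gene's strand. FPKM uses the number of retained fragments in the sample as
the library size. Counting is implemented with sorted-endpoint
searchsorted arithmetic (count = #starts < feature end − #ends ≤ feature
start), which is exact for half-open intervals and is cross-checked
against a brute-force all-pairs oracle in the tests.

The screen itself is a conjunction of three tests against the
healthy-control baseline FPKM\* (arithmetic mean across controls, features
with zero coverage included as zeros):

* upstream expression strictly above the 25th percentile, computed per
  patient over the upstream-gene FPKM of all candidate pairs in that same
  patient (a cohort-pooled percentile would let globally quiet samples
  pass everything or nothing; the per-patient form is scale-free);
* intergenic fold change strictly above 5;
* downstream response: absolute FPKM > 1.5 when the control mean is zero,
  fold change > 1.5 otherwise.

All comparisons are strict. The zero-control-mean intergenic case is
genuinely ambiguous for silent gaps; the default policy fails the pair
when the patient also has zero signal and otherwise requires the patient
FPKM to exceed the threshold times the smallest nonzero control intergenic
mean over all pairs (a data-derived unit), while `zero_mean_epsilon > 0`
switches to a pseudocount denominator. Both policies are exposed; neither
changes behaviour on gaps with nonzero control coverage. Diagnostics
(per-step values, fold changes, branch taken) are materialised for every
pair × patient cell, including early failures, so heatmap-style outputs and
fold-change correlation analyses need no recomputation.

Recurrence ("called in strictly more than 30% of patients") and all
downstream statistics keep cis and trans calls distinguishable; the total
burden counts each *unordered* gene pair once, so the two directions of a
convergent pair cannot be double-counted.

## Statistics

Group comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration when both groups have ≤ 10 observations and the pooled sample
is tie-free, otherwise the tie-corrected normal approximation with
continuity correction (the convention of standard R practice, relevant at
the cohort sizes this pipeline targets). Correlations are Spearman with
average ranks; p-values come from exact permutation enumeration for n ≤ 9
and the t approximation otherwise. The 2×2 contingency test is Pearson
chi-square without continuity correction by default (a flag enables
Yates). Missing clinical values are deleted pairwise, and trait scans
report raw p-values without multiplicity correction — the scan is
descriptive, mirroring how such trait tables are usually reported.

The NETosis activity score is PC1 of the pathway genes detected (FPKM > 0)
in strictly more than half of the patients. Genes are z-scored before the
PCA by default: FPKM spans orders of magnitude and an unscaled PCA would
be dominated by a handful of high-expression genes; `center` and `none`
are available since the choice is not forced by the method. The sign of a
principal component is arbitrary, so it is fixed by a diagnostic
convention: per-gene Spearman correlations with PC1 are computed and the
component is flipped if the majority are positive (ties broken by the sign
of the correlation sum), making *lower* PC1 mean *higher* pathway
expression. Orientation changes signs only; magnitudes, loading norms and
explained variance are invariant, which the tests assert against a direct
eigendecomposition oracle.

lncRNA cis targets are coding genes whose span lies within 50 kb of the
lncRNA span on the same chromosome, strand ignored, distance measured
between nearest edges (signed; zero when overlapping). The window is
anchored on the gene spans rather than TSSs — with the window an order of
magnitude larger than a typical gene the difference is minor, and the span
anchor makes the relation symmetric. Trans targets require |Spearman R| >
0.9 and p < 0.05 (both strict) across shared samples, intersected with a
binding-evidence table (e.g. triplex-prediction output) when one is
supplied; binding is an AND by default, with a permissive flag-only mode.

## Synthetic cohort generator

The generator exists so that every stage has a ground truth. It emulates:

* a genome of non-overlapping genes (lognormal lengths ~2 kb, lognormal
  gaps ~2 kb, random strands, ~6% lncRNA biotype) — five chromosomes of
  100 genes by default, giving ≈ 500 candidate pairs;
* lognormal baseline expression across genes (sd 1.0 in log space),
  mean-one lognormal per-gene-per-sample biological noise (sd 0.25), and
  Poisson fragment sampling, with fragments contained in their source
  feature; rates are rescaled so the expected fragment total per sample
  equals the configured library size (40,000 — FPKM and every fold change
  are invariant to this scale, which is chosen to keep counts informative
  at desk-scale run times);
* low strand-specific Poisson background in every intergenic gap, drawn
  per gap *and strand* so the two directed features of a convergent gap
  have independent baselines;
* 50 planted read-through pairs, chosen among pairs whose upstream gene
  sits above the 70th baseline-expression percentile (read-through arises
  at active genes, and the screen's step 2 assumes as much). Each planted
  pair is active per patient with base probability 0.35 (lognormal
  patient-level spread, sd 0.3; multiplied by `prognosis_effect` = 2 in
  the death group, clipped to [0.02, 0.98]). An active cell receives extra
  intergenic fragments on the upstream strand calibrated to an expected
  intergenic fold change of 10 and extra downstream-gene fragments
  calibrated to a downstream fold change of 3. Both extras share a
  per-(pair, patient) mean-one lognormal jitter (sd 0.25) plus independent
  per-channel noise (sd 0.12) — the shared jitter is what produces the
  across-patient coupling between the two fold changes, standing in for
  the mechanical coupling a contiguous TTS-to-downstream fragment would
  create while keeping both calibration targets exact. These two noise
  scales are the calibration knobs for the fold-change-coupling band and
  planted-recovery checks;
* a composition correction: planted fragments inflate patient library
  sizes, which would deflate every patient FPKM relative to controls;
  planted rates are multiplied by the expected library ratio so the
  fold-change targets survive per-million normalisation;
* a NETosis block of 30 genes up-regulated ×2^1.5 in a random half of the
  patients, shipped in a gene-set file together with 20 unaffected decoy
  genes (so orientation diagnostics see both responsive and indifferent
  members);
* clinical traits through a Gaussian copula on the normal scores of true
  burden and of a noisy block-activity latent: neutrophil percentage
  couples to burden (Spearman target 0.4), PaCO2 positively and PaO2/FiO2
  negatively to activity (0.35 / −0.4), viral infection and AKI are more
  frequent in block-active patients, prognosis labels (27% death) feed the
  burden model above. Marginals are clipped normals with clinically
  plausible centres; controls receive healthy marginals and missing
  patient-only fields.

What the generator does **not** emulate: sequence content and alignment
error, exon structure (gene spans only), GC/length bias, batch effects,
overdispersion beyond lognormal-Poisson, partial read-through gradients,
or any correlation structure among non-planted pairs. Passing tests
therefore demonstrate that the pipeline recovers interval-level planted
signal under realistic count noise — not that it is robust to alignment
artefacts or annotation errors in real data.

A fixed seed determines every output byte, including written fixture
files; the pipeline records seed, parameters and input checksums in
per-stage provenance JSON (no timestamps, so reruns are idempotent).

## Problem sizes and defaults

The default conditions are 40 patients vs 20 controls (56 patients for the
prognosis-power analysis, split 15 death / 41 remission), ~500 candidate
pairs, 50 planted. At these sizes a full cohort simulates, quantifies and
screens in a few seconds, and the acceptance script's five-cohort recovery
study plus 220 burden-test replicates completes in well under a minute.
The `tiny` preset (20 genes, 6 samples) exists for integration and
determinism checks; `large` (1,200 genes, 80 samples) for scaling checks.

## Known limitations

* The screen is interval-level: a long upstream 3' UTR extension that
  never reaches the downstream gene can still pass step 3 if it elevates
  the whole gap's coverage.
* FPKM\* from small control groups is noisy; the fallback-unit policy for
  all-zero control gaps is a convention, not an estimate.
* Percentile step 2 is per patient; cohorts with wildly different library
  complexity may prefer a pooled variant, which is not implemented.
* Exact Spearman p-values enumerate permutations and are limited to n ≤ 9
  by factorial growth; beyond that the t approximation is used.
* The lncRNA trans test at the default |R| > 0.9 is extremely conservative
  at small n; with fewer than ~6 shared samples essentially nothing passes
  both the R and p thresholds.
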
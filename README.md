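# trtscreen

Patient-specific **transcriptional read-through (TRT)** screening for bulk
RNA-seq, with companion clinical analyses and a fully synthetic test bed.

Under cellular stress — viral infection prominently among the triggers —
RNA polymerase II can fail to terminate at a gene's transcription
termination site (TTS) and continue into the downstream intergenic region
and, in *cis* (same strand) or *trans* (opposite strand), into the next
gene. This package detects such events per patient from interval-level
coverage, quantifies each patient's read-through *burden*, and relates
burden and a NETosis (neutrophil extracellular trap formation) gene-set
activity score to clinical traits such as prognosis, viral infection,
neutrophil percentage and gas-exchange indices. It also predicts cis/trans
targets of lncRNAs by genomic proximity and co-expression.

## The screen

For each adjacent gene pair (upstream gene *u*, intergenic interval *i*,
downstream gene *d*) and each patient, with FPKM\* denoting the mean FPKM
across healthy controls:

1. **Candidates** — consecutive non-overlapping gene pairs per chromosome,
   directed so the upstream gene's TTS faces the gap (cis pairs on the same
   strand; convergent opposite-strand neighbours give two trans pairs,
   divergent ones none).
2. **Expressed upstream** — FPKM(*u*) strictly above the 25th percentile of
   upstream-gene FPKM over all candidate pairs in that patient (read-through
   arises at actively transcribed genes).
3. **Intergenic signal** — FC(*i*) = FPKM(*i*) / FPKM\*(*i*) > 5, evidence
   that transcription ran past the TTS.
4. **Downstream effect** — FPKM(*d*) > 1.5 when FPKM\*(*d*) = 0, otherwise
   FC(*d*) > 1.5.

A call requires all steps; a pair is *recurrent* when called in more than
30% of patients. Burden is the per-patient number of called pairs (cis,
trans, and their direction-free union). All thresholds live in a single
`ScreenParams` record. FPKM is fragments per kilobase of feature per
million mapped fragments, counted with ≥ 1 bp interval overlap
(bedtools-coverage semantics), strand-aware by default.

Companion analyses: per-pair Spearman correlation between intergenic and
downstream fold change; Wilcoxon rank-sum burden comparisons and Spearman
burden–trait correlations; a per-sample NETosis activity score as PC1 of
the pathway genes expressed in > 50% of patients, sign-fixed so that lower
PC1 = more active NETosis; and lncRNA target prediction (50 kb window for
cis, |Spearman R| > 0.9 with p < 0.05 plus optional binding evidence for
trans).

## Worked example

Everything below runs offline: the generator plants read-through events
with known ground truth (default: 40 patients, 20 controls, ~500 candidate
pairs, 50 planted pairs at intergenic fold change 10 and downstream fold
change 3).

```python
import trtscreen as t
from trtscreen.stats import trt_burden, compare_burden_groups, fc_correlation_per_pair

cohort = t.simulate_cohort(t.config_from_preset("default", seed=1))
result = t.call_trt(cohort.pairs, cohort.expr, cohort.patient_ids, cohort.control_ids)
recurrent = result.recurrent_pairs()

burden = trt_burden(result.cis_calls, result.trans_calls)
prognosis = cohort.clinical.loc[cohort.patient_ids, "prognosis"]
test = compare_burden_groups(burden["total"], prognosis)
fc = fc_correlation_per_pair(result.diagnostics, recurrent)

print(f"{len(cohort.genes)} genes, {len(cohort.pairs)} candidate pairs "
      f"({sum(p.pair_class == 'cis' for p in cohort.pairs)} cis)")
print(f"{int(result.calls.to_numpy().sum())} read-through calls, "
      f"{len(recurrent)} recurrent pairs (>30% of patients)")
print(f"burden by prognosis: W={test.statistic:.1f}, p={test.pvalue:.2e}")
print(f"median intergenic-vs-downstream FC coupling R = {fc['spearman_r'].median():.2f}")
```

which prints:

```text
500 genes, 493 candidate pairs (257 cis)
1050 read-through calls, 50 recurrent pairs (>30% of patients)
burden by prognosis: W=30.0, p=9.03e-05
median intergenic-vs-downstream FC coupling R = 0.84
```

All 50 planted pairs are recovered as recurrent; patients in the "death"
prognosis group carry roughly twice the burden (the planted effect), which
the Wilcoxon test detects; and the per-pair coupling between intergenic and
downstream fold change sits in the high-positive range expected when
read-through drives downstream transcription.

The same pipeline is scriptable from the shell:

```sh
trt simulate --preset tiny --seed 1 -o fixtures/
trt run --config pipeline.yaml          # pairs -> quantify -> screen -> stats -> ...
trt pairs --annotation genes.gtf -o out/
```

An empty `pipeline.yaml` runs the default synthetic preset end to end;
real data enter through the `inputs:` section (GTF/GFF3/BED annotation,
fragment BEDs or a precomputed FPKM TSV, a clinical TSV).

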
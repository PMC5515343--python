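# fieldscape

Histologically normal tissue adjacent to a breast tumor is routinely used
as a "normal" control, yet it can harbor occult tumor cells, field
(cancerization) effects, and its own stromal expression phenotype.
`fieldscape` is a multi-platform pipeline that quantifies these defects in
matched tumor / blood / adjacent-normal triplets and relates them — and the
active/inactive expression subtype of the adjacent tissue — to overall
survival. A synthetic-cohort generator with known ground truth makes every
stage testable by parameter recovery, with no external data downloads.

## Methods at a glance

* **Methylation.** For each patient, adjacent-normal beta values
  (β = M/(M+U) ∈ [0,1]) are regressed on the matched tumor betas across the
  500 probes most hyper-methylated in tumors. A slope > 0.4 flags
  tumor-like methylation; among flagged samples, residual s.e. < 1 is
  called *occult tumor*, otherwise *field effect*.
* **Copy number.** An adjacent segment is shared with the tumor when the
  two segments (both |log2| > 0.1, same sign of change) reciprocally
  overlap by ≥ 50% of each segment's length and the adjacent segment has no
  overlap with an amplitude-passing blood segment. Summed shared basepairs
  are tiered: > 100 kb → *evidence of tumor* (or *likely evidence* for
  tumor/adjacent pairs without blood), 1–100 kb → *small evidence*.
* **Mutations.** Somatic SNVs must reach ≥ 20× coverage in all three
  compartments, tumor VAF > 10%, Fisher exact p < 0.05 (tumor vs blood),
  and blood VAF < 5%. Burden in the adjacent normal is tiered from the
  fraction of detected variants (≥ 2 alt reads) with VAF > 1%:
  ≥ 50% → *high*, ≤ 10% → *low*, between → *moderate*, < 2 detected →
  *none*. RNA expression of tumor mutations is scored at ≥ 10× RNA depth
  with ≥ 2 variant reads.
* **Expression.** Upper-quartile (mRNA) and reads-per-million (miR)
  normalization, an RPM ≥ 1 in ≥ 10 libraries floor for mature strands,
  top-25%-variance feature selection, and NMF consensus clustering
  (Brunet multiplicative updates under a KL objective over random
  restarts). Silhouette widths are computed on 1 − consensus. Differential
  abundance uses a permutation Wilcoxon statistic with a plug-in FDR, then
  |FC| ≥ 1.5 and mean RPM ≥ 25 filters. Active/inactive subtypes come from
  nearest-centroid assignment (self-derived or user-supplied centroids).
* **Survival.** A patient has *any defect* when burden is moderate/high,
  methylation is occult-tumor, or copy number shows (likely) evidence.
  Kaplan–Meier curves with log-rank tests and Cox proportional-hazards
  models (Efron ties; covariates: subtype, nodal status, intrinsic tumor
  subtype, stage, size, age decade, any-defect) are censored at 10 years.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
100-patient cohort (`python analysis/01_simulate_cohort.py` through
`06_survival_integration.py`; tables land in `results/`). Output from a
run at the default seed:

```
ground truth: 13 occult-tumor patients, 34 field-effect, 5 CN-contaminated
call counts: {'normal': 87, 'occult_tumor': 13}
occult sensitivity (true fraction >= 0.4): 1.000
contaminated patients called evidence_of_tumor: 1.000 (n=5)
burden classes: {'none': 74, 'high': 24, 'moderate': 2}
moderate-or-high burden prevalence: 0.26
mRNA-miR concordance: 0.920 (generator concordance parameter 0.90)
any-defect prevalence: 0.40
ER-positive adjusted Cox: active-subtype HR 3.97 (95% CI 1.63-9.63, p=0.00231; n=63, events=35)
```

Every occult-tumor patient (mixture fraction ≥ 0.4) and every contaminated
copy-number profile is recovered; 26% of patients carry moderate-to-high
mutation burden; the miR and mRNA cluster solutions agree for 92% of
samples (the generator plants 90% concordance); and the adjusted Cox model
recovers an active-subtype hazard ratio near the planted value of 3 in the
ER-positive subset.

The same stages are exposed as a CLI
(`fieldscape simulate|methylation|cnv|mutations|expression|integrate`); run
`fieldscape --help` for options.

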
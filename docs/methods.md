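# Methods

This note records the models behind each pipeline stage, the defaults and
why they hold, what the synthetic generator does and does not emulate, and
the judgment calls made where the procedures left room.

## Occult-tumor regression (methylation)

Adjacent-tissue methylation is modeled as a two-component mixture: if a
fraction *f* of cells in the "normal" specimen are tumor cells, the
expected beta value at probe *p* is `f·tumor_p + (1−f)·normal_p`. Over
probes where tumor methylation varies strongly and normal methylation is
nearly constant — the tumor-hypermethylated probe set — the OLS slope of
adjacent on tumor estimates *f*. Thresholds: slope > 0.4 (tumor-like) and
residual s.e. < 1 (coherent fit → occult tumor; noisy fit → field effect),
both strict and configurable. Residual s.e. is `sqrt(RSS/(n−2))` over the
n probes used after NA removal (minimum 10).

Probe selection ranks shared probes by mean(tumor) − mean(normal) and
takes the top 500 positive and top 500 negative differences (ties broken
by probe id; zero differences never qualify). The regression itself uses
only the hyper-methylated 500; the combined 1,000-probe set exists for
ordered exports. The reference normal panel defaults to the adjacent
cohort itself, overridable by an external panel.

One consequence of working on the beta scale: since betas live in [0,1],
per-sample residual s.e. rarely approaches 1, so with the default
thresholds the field-effect tier is effectively reachable only by
lowering `rse_threshold`. The classification rule is kept as stated, and
the tier boundaries are exposed as parameters.

A confounding check correlates each sample's median beta over the hyper
probes with tumor cellularity (Pearson, two-sided); a near-zero r argues
the occult calls are not a cellularity artifact.

## Copy-number overlap

Coordinates are 0-based half-open internally (length = end − start); SEG
input dialect is declared (`one_closed` default, the common export
convention). Matching requires, for adjacent segment A and tumor segment
T: |log2| > 0.1 on both; same chromosome and sign of change; overlap ≥ 50%
of |A| and ≥ 50% of |T|. "No overlap with blood" is interpreted as: any
≥ 1 bp overlap with a blood segment passing the amplitude filter vetoes
the candidate — amplitude-neutral whole-chromosome blood segments common
in SEG files do not veto, since a literal reading would veto everything
against a genome-tiling blood profile. Each adjacent segment takes at most
one tumor partner (largest overlap; ties: longer tumor segment, then
leftmost). Sign concordance is required because a gain matched to a loss
cannot indicate shared clonality; it is switchable off.

Tiering of summed shared basepairs: the printed tier boundaries leave
exactly 100,000 bp unassigned ("1,000–99,999" and ">100,000"); that single
value is assigned to the evidence tier and logged. Pair mode (no blood)
can only reach *likely evidence*.

## Somatic filter cascade and burden

The Fisher exact test on the tumor-vs-blood 2×2 count table is computed
in-package as an exact hypergeometric sum, two-sided, including all tables
no more probable than the observed one under the standard 1+1e-7 relative
tie tolerance. Two-sidedness is a choice (the direction of interest is
known, but two-sided is the conservative default). Variants failing
coverage are recorded with reason `insufficient_coverage`, never raised.

The burden tiers as printed overlap (every "at least 2 mutations" clause
intersects). The implemented precedence — none (< 2 detected) → high
(fraction ≥ 0.5) → low (≤ 0.1) → moderate (otherwise) — maps every
(n, fraction) pair to exactly one class. The fraction's denominator
defaults to variants *detected* in the adjacent tissue (≥ 2 alt reads,
mirroring the RNA presence rule, since no DNA-side floor is stated); a
denominator over all filter-passing tumor mutations is available. Indels
are out of scope throughout.

## Expression subtyping

NMF uses the Brunet multiplicative updates for the KL objective,
implemented directly (the objective trace is exposed and is non-increasing
by construction; tests cross-check the converged objective against
scikit-learn's MU solver). Consensus clustering repeats NMF over seeded
random restarts; consensus[i,j] is the co-clustering frequency, and final
assignments cut an average-linkage tree of 1 − consensus into k groups —
a standard choice where the original tooling's assignment rule is not
restated. Cluster 1 is relabeled to be the largest. Silhouettes use the
textbook formula on d = 1 − consensus with singleton clusters assigned 0.

The permutation Wilcoxon test standardizes the rank-sum statistic per
feature and permutes class labels (all distinct label splits are
enumerated when fewer than `n_perms` exist). q-values use the plug-in
estimator: at each observed |statistic| threshold, the median permutation
count of exceedances divided by the observed count, then monotonized so
significance ordering is preserved. No null-proportion (π0) correction is
applied; under the null this leaves the estimator conservative, which the
FDR simulations reflect.

Fold changes are cluster-2/cluster-1 mean ratios with a 0.5 pseudo-count;
ratios below 1 are reported as negative reciprocals. The abundance filter
requires mean RPM ≥ 25 in at least one cluster.

Nearest-centroid subtype assignment (Spearman distance by default,
Euclidean available) accepts user-supplied centroid files — the published
active/inactive and PAM50 centroids are deliberately not shipped — or
derives centroids as per-cluster means from this cohort's own two-cluster
solution. Ties break to the lexicographically first label and are flagged.
Two-cluster concordance is agreement maximized over the label swap.

## Survival

Any-defect integrates only the three DNA platforms (moderate/high burden,
occult-tumor methylation, evidence/likely-evidence copy number); field
effects, small CN evidence, low burden and RNA positivity do not trigger
it. Missing platforms do not contribute; patients with no DNA platform are
excluded with a log entry. Follow-up is administratively censored at 10
years (events beyond the horizon become censored observations at 10).

Kaplan–Meier fits and the log-rank test come from lifelines; Cox models
use lifelines (Efron ties, the default) or scikit-survival (Breslow),
with Wald 95% CIs. Categorical covariates expand against fixed reference
levels: inactive subtype, node-negative, LumA, stage I, T1, age < 40, no
defect. Stages III and IV are collapsed to one factor level; the
stage-IV sensitivity refit identifies stage-IV patients from a raw-stage
column. Missing covariates are complete-case excluded with counts logged.
The association battery uses chi-square when all expected counts are ≥ 5,
Fisher exact for sparse 2×2 tables, and a pooled-variance t-test for age
(decade midpoints when only the decade factor is available).

## Synthetic cohorts

The generator encodes the data-generating assumptions each stage relies
on, using the simplest noise model consistent with each assay: Gaussian
probe noise on betas, binomial read counts at Poisson depths, Poisson
counts around log-normal expression means, exponential survival. A master
seed spawns per-patient substreams, so cohorts are byte-reproducible and
extensible without perturbing existing patients, and the ground-truth
table is always written beside the data.

Defaults (the study conditions):

* 100 patients; 2,000 probes with 550-probe hyper/hypo blocks whose tumor
  gain varies probe-to-probe (uniform 0.25–0.8) over a nearly flat normal
  baseline — the geometry that makes the regression slope estimate the
  mixture fraction. Probe noise s.d. 0.03. Default cohort mix: 15% occult
  (fraction uniform 0.4–0.9), 36% field effect (a random 10% probe subset
  shifted 0.3 toward tumor — a sparse signature, distinct from global
  mixing), 49% normal.
* 8 tumor segments per patient, lengths 150 kb–1 Mb, |log2| uniform
  0.2–1.0; contaminated adjacent copies are attenuated by 0.8 (a separate
  knob from the variant-fraction scale, which would push every copied
  segment below the amplitude filter); 10% of patients are contaminated by
  default. Optional germline CNVs are injected into all three profiles.
* 40 somatic SNVs per patient, tumor VAF uniform 0.13–0.60, depths Poisson
  with mean 200 (500 in recovery runs), blood error rate 1e-3. Adjacent
  VAF = tumor VAF × a per-patient scale drawn from a mixture (68% zero,
  8% at 0.005, 14% at 0.03, 10% at 0.08) so the cohort spans the
  none-to-high burden spectrum rather than collapsing to one class.
* 1,000 mRNA / 400 miR features; 10% of features shifted 1 log2 unit
  between subtypes; active probability 0.5; miR labels agree with mRNA
  labels with probability 0.90.
* Exponential survival at 0.05 events/year baseline with log-HR log(3)
  for the active subtype, censored at 10 years.

What the generator does **not** emulate: realistic genome coordinates or
linkage, array platform artifacts and batch effects, tissue-composition
confounding of methylation, overdispersed sequencing counts, correlated
features, or informative censoring. Passing recovery tests therefore
demonstrates that the estimators invert the stated generative model, not
that they are robust to everything real cohorts contain.

## Numerical choices and problem sizes

Consensus runs are seeded per restart from a spawned sequence; the
recovery tests use 10 survey / 100 final restarts and the desk-run
drivers 100 restarts, which on these cohort sizes already produce
near-binary consensus matrices (the 30/500 defaults remain the CLI
defaults). Permutation counts of 200–1,000 are used depending on context.
Simulation suites use 50–200 replicates with fixed seed lists; recovery
bands (e.g. Cox HR within [2.2, 4.0] for a true ratio of 3 at n=500)
reflect those sizes. OLS fits are checked against closed form at 1e-10,
the Fisher p against exact-rational enumeration at 1e-12, and the
product-limit estimator against 1 − ECDF at 1e-12 (float round-off of the
telescoping product).

## Known limitations

* The field-effect tier is threshold-dependent on the beta scale (see
  above); ranking by (slope, residual s.e.) is the more robust output.
* The burden tiers depend on sequencing depth through the detection floor;
  at shallow depth the detected-variant denominator is biased toward
  higher-VAF variants.
* Consensus-NMF assignments for k > 2 can be sensitive to the linkage cut
  when clusters are not well separated; the rank survey reports silhouette
  and dispersion summaries but k remains a user decision (default 2).
* The Cox model assumes proportional hazards and uses complete-case
  exclusion; no relapse-specific or competing-risks outcome is modeled.
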
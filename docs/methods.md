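# Methods

## Data model

A cohort is a triple: a **peptide catalog** (opaque `catalog_id`,
monoisotopic mass in Da, optional CE migration time, amino-acid sequence and
parent protein), a **sample table** (fluid AF/FU, gestational age in weeks
of amenorrhea, patient ID for AF/FU pairing, outcome and cohort labels), and
a samples × peptides **abundance matrix** of non-negative normalized signal
amplitudes where an exact 0 means "not detected". No distinction is made
between "absent" and "below detection limit", and no normalization stage is
provided — abundances are assumed normalized upstream; a sanity hook logs a
warning when per-sample totals differ by more than 10×.

Peptide identity across fluids is by catalog ID only. Matching independent
catalogs by mass/migration time is deliberately out of scope: the analyses
assume inputs already share an ID space.

## Gestational binning and the frequency filter

Gestational age is truncated to completed weeks (obstetric convention) and
assigned to one of eight closed integer intervals: 11–14, 15–17, 18–21,
22–24, 25–28, 29–31, 32–35, 36–39 WA. The intervals partition 11–39 WA, so
every in-range age maps to exactly one bin; out-of-range ages raise an error
listing the offending samples.

A fluid's peptidome is defined by the detection-frequency rule: a peptide is
kept iff the share of samples with a positive value reaches `min_freq`
(default 0.5) in at least one non-empty bin. The filter is per fluid by
definition and is applied to the merged sample set of each fluid (whether
the original studies filtered before or after merging is unknowable from the
published description; per-fluid-on-merged is the reading implemented). At
`min_freq = 0` the rule degenerates to "detected at least once": a bin must
have frequency both ≥ `min_freq` and > 0, which is equivalent to the plain
rule for any positive threshold. The filter is monotone in `min_freq` and
idempotent at a fixed threshold; both properties are tested.

## Overlap analysis

The Venn partition of the filtered column sets gives AF-only / common /
FU-only. The common peptides' share of AF *number* is 100·|common|/|AF|; the
share of AF *abundance* uses per-peptide means over all AF samples
**including zeros**, so rarely detected peptides dilute their own
contribution (a signal-share interpretation; detected-only means would
overweight sporadic peptides). Percentages are rounded half-up to integers
only at report time. Per-bin overlap reuses the frequency rule within the
bin's samples; a bin lacking samples in either fluid is reported missing
rather than zero, since an empty bin carries no evidence. "Most abundant"
peptide rankings use the mean abundance (summed abundance is equivalent at
fixed sample count).

## FU-origin attribution

Two rank-based analyses. The global view correlates per-peptide mean AF
abundance with per-peptide mean FU abundance (Spearman, ties mid-ranked)
over a peptide set. The paired screen computes, for every common peptide,
Spearman's ρ across fetuses with both fluids sampled, zeros included as true
zero abundances — rank methods tolerate the zero-inflated floor and no
published exclusion rule exists. A peptide is called FU-origin when ρ > 0
and the two-sided p < α (default 0.05); the two-sided test with a positivity
constraint is the conservative reading of "significantly positively
correlated", and under the null it selects at most α/2 of peptides in
expectation. No multiple-testing correction is applied by default,
mirroring a nominal-significance screen; peptides with zero variance in a
fluid, or detected in both fluids in fewer than `min_detected_pairs`
(default 3) pairs, are flagged degenerate and never selected. Because the
screen is rank-based it is invariant to strictly monotone transforms of
either fluid's abundances (tested).

## Panel derivation and validation

Candidates are screened on the discovery arm by a two-sided Wilcoxon
rank-sum test (exact null distribution for tie-free groups up to 25 each,
normal approximation with continuity correction otherwise) at α = 0.05,
ordered by p. The classifier is a random forest with 1000 trees (other
hyperparameters at scikit-learn defaults), deterministic given its seed. Its
score is the vote-fraction difference s = f(ESRD) − f(noESRD) ∈ [−1, 1], a
scale on which 0 is the natural cutoff. The cutoff may be kept at 0 or
re-optimized on training scores by Youden's J over midpoints of adjacent
unique scores, ties broken toward the candidate nearest 0 (both modes are
supported because published practice is ambiguous between a tuned and an a
priori cutoff; the pipeline default is optimization).

Validation reports the confusion table; sensitivity and specificity carry
exact two-sided Clopper–Pearson 95% CIs (beta quantiles; lower bound pinned
at 0 for 0 successes, upper at 1 for all successes). AUC is the Mann–Whitney
probability with ties worth ½; its CI and the two-sided test against 0.5
use DeLong's structural-component variance. When that variance is exactly 0
(perfect separation), the CI collapses to the point and p is reported as 0 —
a deliberate convention for the degenerate case. A small-sample permutation
alternative was considered and left out: the DeLong route is the standard
reporting family and the tests cross-check the AUC point estimate against
exhaustive pair counting. The bedside Schwartz estimate
eGFR = k·height/creatinine (k = 0.413, ml/min/1.73 m²) defines outcome
labels: noESRD iff eGFR strictly exceeds 15.

## In-silico digestion

Cleavage sites are 0-based bond indices: site *i* is the bond between
residues *i* and *i+1*, and only strictly internal bonds (1 ≤ i ≤ len−2)
are reported, so a cut never sits at a terminus. Built-in specificity
tables are simplified approximations of the PeptideCutter rules: trypsin
(after K/R unless P follows), high-specificity chymotrypsin (after F/Y/W
unless P follows), Arg-C (after R), pepsin pH > 2 (F or L on either side of
the bond) and pepsin pH 1.3 (F or L N-terminal to the bond only). Real
pepsin specificity is broader and context-dependent; neither table claims
to reproduce published degradability counts, and full exception tables can
be supplied via a YAML rules file. A peptide is "degradable" under a panel
iff any enzyme yields at least one internal site — monotone in the panel by
construction.

## Synthetic cohorts

The generator's defaults state the reference world: 216 AF and 64 FU
samples, 16 paired fetuses, 1831 shared / 837 AF-only / 1426 FU-only
peptides, a 67-peptide correlated subset, 7 outcome-associated peptides
with an 8× effect, gestational ages spanning 11–39 WA.

* **Masses** are log-normal with median 2500 Da and σ = 0.5, putting ≈ 90%
  of peptides inside 800–5000 Da, with means near 2.8 kDa — the regime of
  the measured distributions. About 23% of peptides carry a sequence, and
  annotated parents are dominated by collagen chains (~75%).
* **Abundance**: log X = θ_p + b·log(g) + σ·z, with a per-peptide baseline
  θ_p ~ N(μ, 1) (μ = `log_abundance_mean`, default 4), a multiplicative
  per-bin trend g = `ga_trend` (default 0.92 < 1, a monotone decline with
  gestational age) over bin index b, and cell noise σ = `log_abundance_sd`
  (default 1.0, a realistic ~e-fold CE-MS signal variation).
* **Detection** is independent Bernoulli thinning after the draw: AF
  detection probability rises across bins from 0.35 to 0.85 at 29–31 WA and
  plateaus (matching the observed increase of AF peptide counts to that bin);
  FU is flat at 0.7. A non-detect zeroes the cell — no LOD censoring model.
* **Planted correlation**: for paired fetuses, the correlated subset links
  AF to FU through a Gaussian copula on the log scale with Pearson
  ρ_P = 2·sin(π·ρ_S/6) so the expected Spearman correlation equals
  `corr_strength`; at `corr_strength = 1` the link is exact and noise-free.
* **Outcome effect**: flagged peptides (a subset of the correlated set, as
  FU-origin biomarkers should be) are multiplied by `outcome_effect_size`
  in ESRD samples of both fluids, after detection thinning.

One integer seed drives everything through deterministically spawned
sub-streams per matrix; identical configurations are bit-identical.

What the generator does **not** emulate: CE-MS noise physics, isotopes and
migration-time drift, abundance-dependent (LOD-censored) detection,
between-study batch structure, and correlated peptide families from shared
parent proteins. A green test therefore establishes that the statistical
machinery behaves as specified on its stated model — not that the biological
effect sizes of real cohorts are recoverable at these sample sizes.

### The separable ("no noise overlap") regime

With the default cell noise σ = 1.0, an 8× effect (log effect ≈ 2.1, about
2σ) still leaves the outcome classes overlapping per peptide, and small
validation arms can misclassify a sample. The end-to-end regression test of
the full pipeline therefore uses the stated strong-effect regime explicitly:
the 8× effect with σ = 0.25 (log effect ≈ 8 noise SDs), under which the
per-peptide class distributions are essentially disjoint and the validation
performance (100% sensitivity, ≥87.5% specificity, AUC ≥ 0.97) is stable
across seeds. Generator defaults are unchanged.

## Pipeline

`run_pipeline` wires the stages in dependency order from one `RunConfig`
(exactly one of a simulation config or a pair of cohort directories). All
randomness flows through two seeds — the data seed inside the simulation
config and the model seed for the forest — and the run summary records both,
a parameter hash (excluding the output path) and a SHA-256 hash per output
file; re-running an identical configuration reproduces identical hashes.
Stages never mutate each other's outputs. The origin and panel stages are
skipped with an explicit reason when their preconditions (paired samples;
outcome labels and a non-empty candidate set) are absent, rather than
failing a cohort that simply lacks those data.

## Numerical conventions

* Percentages: rounded half-up to integers at report time only.
* Spearman/Mann–Whitney/ANOVA delegate to scipy; ties are mid-ranked.
* ANOVA with zero within-group variance returns (F = ∞, p = 0) when group
  means differ and (F = 0, p = 1) when they do not.
* Youden ties: the cutoff nearest zero wins, then the smaller cutoff.
* Missing panel peptides at scoring time are imputed as 0 (not detected)
  with a warning rather than an error.

## Limitations

* No cross-catalog peptide matching; all inputs must share one ID space.
* The frequency filter's per-fluid-on-merged-samples reading is a choice;
  per-study filtering before merging could retain a different set.
* The published 12-peptide FU classifier is not re-fit here;
  `compare_classifiers` accepts any externally produced score vector.
* Digestion tables are simplified; quantitative or kinetic digestion is out
  of scope, as is protease inference from cleavage-site databases.
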
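"""Derive and validate a prognostic peptide panel on an outcome cohort.

Discovery arm (6 ESRD + 8 noESRD): Wilcoxon selection among FU-origin
peptides, then a 1000-tree random forest whose score is the ESRD-vs-noESRD
vote-fraction difference (so 0 is the natural cutoff). Validation arm
(8 + 8): sensitivity and specificity with exact 95% CIs, AUC with a DeLong
CI and a test against the no-discrimination value 0.5.
"""

from amniopep import (
    SimulationConfig,
    frequency_filter,
    generate_puv_cohort,
    optimize_cutoff,
    paired_origin_screen,
    score,
    select_candidates,
    selected_ids,
    train_classifier,
    validate_panel,
)

cohort = generate_puv_cohort(
    SimulationConfig(
        n_peptides_shared=120, n_peptides_af_only=20, n_peptides_fu_only=20,
        n_af_samples=46, n_fu_samples=20, n_paired=16,
        corr_subset_size=67, corr_strength=0.95,
        n_outcome_peptides=7, outcome_effect_size=8.0,
        log_abundance_sd=0.25, detection_prob=1.0, seed=1,
    ),
    n_discovery_esrd=6, n_discovery_noesrd=8,
    n_validation_esrd=8, n_validation_noesrd=8,
)
samples = cohort.samples
af = frequency_filter(cohort.af, samples[samples.fluid == "AF"])
fu = frequency_filter(cohort.fu, samples[samples.fluid == "FU"])

fu_origin = selected_ids(paired_origin_screen(af, fu, samples))
panel = select_candidates(af, samples, fu_origin, alpha=0.05)
print(f"{len(fu_origin)} FU-origin peptides; {len(panel)} survive the Wilcoxon screen")

model = train_classifier(af, samples, panel, n_trees=1000, seed=0)
meta = samples.set_index("sample_id")
disc = meta[(meta.cohort == "discovery") & meta.outcome.isin(["ESRD", "noESRD"])]
train_scores = score(model, af, disc.index)
model.cutoff = optimize_cutoff(train_scores, disc.loc[train_scores.index, "outcome"] == "ESRD")
print(f"training cutoff (Youden's J): {model.cutoff:+.3f}")

rep = validate_panel(model, af, samples)
print(f"validation sensitivity {rep.sensitivity_pct:.1f}% "
      f"[95% CI {rep.sens_ci_pct[0]:.0f}-{rep.sens_ci_pct[1]:.0f}]")
print(f"validation specificity {rep.specificity_pct:.1f}% "
      f"[95% CI {rep.spec_ci_pct[0]:.0f}-{rep.spec_ci_pct[1]:.0f}]")
print(f"AUC {rep.auc:.2f} [95% CI {rep.auc_ci[0]:.2f}-{rep.auc_ci[1]:.2f}], "
      f"p vs 0.5 = {rep.auc_p_vs_0_5:.2g}")
# a score above the cutoff predicts early end-stage renal disease
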
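# amniopep

Toolkit for comparing the **amniotic fluid (AF)** and **fetal urine (FU)**
peptidomes measured by CE-MS, and for deriving prognostic peptide panels for
fetal renal disease. It is aimed at researchers working with per-peptide
signal-amplitude matrices (samples × peptides on a shared peptide catalog)
who want to quantify how much of the AF peptidome originates from fetal
urine, and whether AF can serve as a surrogate for invasive FU sampling.

## What it computes

* **Detection-frequency filtering** — a peptide belongs to a fluid's
  peptidome iff it is detected (abundance > 0) in ≥ 50% of that fluid's
  samples within at least one gestational-age bin. Gestation is divided into
  eight periods of completed weeks of amenorrhea (WA): 11–14, 15–17, 18–21,
  22–24, 25–28, 29–31, 32–35, 36–39.
* **Overlap analysis** — the Venn partition (AF-only / common / FU-only),
  the common peptides' share of AF peptide number and of total AF abundance,
  per-bin overlap trajectories, mass summaries (mean ± SEM, median, share in
  800–5000 Da), parent-protein tables, Mann–Whitney group comparisons and
  one-way ANOVA trends across bins.
* **FU-origin screening** — per common peptide *i*, Spearman's
  ρᵢ = corr(rank AFᵢ, rank FUᵢ) across fetuses sampled in both fluids;
  peptides with ρᵢ > 0 and two-sided p < α (default 0.05) are called
  FU-origin. Zeros (non-detects) enter the ranks as true zero abundances.
* **Biomarker panels** — Wilcoxon rank-sum candidate selection on a
  discovery arm (ESRD vs noESRD outcome at two years), a 1000-tree random
  forest whose score is the vote-fraction difference
  s = f(ESRD) − f(noESRD) ∈ [−1, 1] (cutoff 0 by construction, optionally
  re-optimized by Youden's J), and validation with exact Clopper–Pearson 95%
  CIs for sensitivity/specificity, AUC = U/(n₁n₂) with a DeLong CI, and a
  two-sided test of AUC = 0.5.
* **In-silico digestion** — rule-based cleavage-site scanning (trypsin,
  chymotrypsin, Arg-C, pepsin) to ask whether FU-specific peptides could be
  degraded by proteases expected in AF.
* **Synthetic cohorts** — a seeded generator producing two-fluid cohorts
  with known ground truth: shared/exclusive peptides, log-normal abundances
  declining with gestational age, bin-dependent detection, a planted
  cross-fluid correlated subset (Gaussian copula calibrated to a target
  Spearman ρ) and outcome-associated peptides.

## Worked example

`python examples/biomarker_panel.py` generates a labelled cohort with the
reference design sizes (6 ESRD + 8 noESRD discovery, 8 + 8 validation) and a
strong planted 8× effect on 7 peptides, then derives and validates a panel:

```
86 FU-origin peptides; 7 survive the Wilcoxon screen
training cutoff (Youden's J): -0.007
validation sensitivity 100.0% [95% CI 63-100]
validation specificity 100.0% [95% CI 63-100]
AUC 1.00 [95% CI 1.00-1.00], p vs 0.5 = 0
```

Reading: of the peptides whose AF abundance tracks FU abundance in paired
fetuses, seven separate the outcome groups in discovery; the forest score
then classifies every validation fetus correctly, and the exact binomial CI
for 8/8 correct calls spans 63–100% — the price of an eight-patient arm.
The other scripts in `examples/` each demonstrate one capability
(filtering, overlap, origin screen, digestion, one-call pipeline).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, through the package's own `clopper_pearson`, the integer-percent
lower bounds of the two-sided 95% exact binomial confidence intervals for a
sensitivity of 8/8 and a specificity of 7/8, and writes them as JSON.
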
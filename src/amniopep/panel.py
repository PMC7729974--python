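"""Biomarker panel derivation and validation.

Workflow on an outcome-labelled cohort (ESRD vs noESRD at two years
postnatally, discovery/validation split):

1. :func:`select_candidates` — two-sided Wilcoxon rank-sum screen of the
   candidate peptides (typically the FU-origin set) on the discovery arm.
2. :func:`train_classifier` — random forest (1000 trees by default) on the
   discovery abundance sub-matrix.
3. :func:`score` — per-sample score = (fraction of trees voting ESRD) -
   (fraction voting noESRD), in [-1, 1], so 0 is the natural cutoff.
4. :func:`optimize_cutoff` — Youden's J over midpoints of adjacent training
   scores, ties broken toward the cutoff nearest 0.
5. :func:`validate_panel` — confusion counts on the validation arm with
   exact Clopper-Pearson 95% CIs for sensitivity and specificity, plus AUC
   with a DeLong CI and a two-sided test against the no-discrimination
   value 0.5.

:func:`schwartz_egfr` implements the paediatric bedside eGFR estimate used
to define the noESRD outcome (eGFR strictly above 15 ml/min/1.73m2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .errors import UsageError

logger = logging.getLogger(__name__)

POSITIVE = "ESRD"
NEGATIVE = "noESRD"


@dataclass
class PanelModel:
    """A trained random-forest panel with its score cutoff."""

    peptide_ids: tuple[str, ...]
    n_trees: int
    seed: int
    cutoff: float = 0.0
    forest: RandomForestClassifier = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.peptide_ids:
            raise UsageError("panel needs a non-empty peptide list")
        if self.n_trees < 1:
            raise UsageError("n_trees must be >= 1")


@dataclass(frozen=True)
class ValidationReport:
    sensitivity_pct: float
    specificity_pct: float
    sens_ci_pct: tuple[float, float]
    spec_ci_pct: tuple[float, float]
    auc: float
    auc_ci: tuple[float, float]
    auc_p_vs_0_5: float
    tp: int
    fn: int
    tn: int
    fp: int

    def summary(self) -> dict:
        return {
            "sensitivity_pct": self.sensitivity_pct,
            "sensitivity_ci_pct": list(self.sens_ci_pct),
            "specificity_pct": self.specificity_pct,
            "specificity_ci_pct": list(self.spec_ci_pct),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "auc_p_vs_0_5": self.auc_p_vs_0_5,
            "confusion": {"TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp},
        }


def _outcome_labels(samples: pd.DataFrame, sample_ids) -> pd.Series:
    meta = samples.set_index("sample_id").loc[sample_ids]
    labels = meta["outcome"]
    bad = set(labels.unique()) - {POSITIVE, NEGATIVE}
    if bad:
        raise UsageError(f"samples with non-outcome labels in scored set: {sorted(bad)}")
    return labels


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution for tie-free groups of up to 25 each; normal
    approximation with continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (not ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def select_candidates(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    candidate_ids,
    alpha: float = 0.05,
) -> list[str]:
    """Wilcoxon screen of candidates on the discovery arm, ordered by p.

    Keeps candidates whose ESRD vs noESRD abundance difference has a
    two-sided rank-sum p < ``alpha``. Candidates absent from the matrix are
    skipped with a warning.
    """
    meta = samples.set_index("sample_id")
    disc = meta[(meta["cohort"] == "discovery") & meta["outcome"].isin([POSITIVE, NEGATIVE])]
    disc = disc[disc.index.isin(matrix.index)]
    esrd = disc.index[disc["outcome"] == POSITIVE]
    noesrd = disc.index[disc["outcome"] == NEGATIVE]
    if len(esrd) == 0 or len(noesrd) == 0:
        raise UsageError("discovery arm must contain both ESRD and noESRD samples")
    ids = pd.Index(map(str, candidate_ids)).unique()
    missing = ids.difference(matrix.columns)
    if len(missing):
        logger.warning("%d candidate peptide(s) absent from the matrix; skipped", len(missing))
        ids = ids.difference(missing)
    hits: list[tuple[float, str]] = []
    for pid in ids:
        _, p = rank_sum_test(matrix.loc[esrd, pid], matrix.loc[noesrd, pid])
        if p < alpha:
            hits.append((p, pid))
    hits.sort()
    return [pid for _, pid in hits]


def train_classifier(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    peptide_ids,
    n_trees: int = 1000,
    seed: int = 0,
) -> PanelModel:
    """Fit the random-forest panel on the discovery arm (deterministic in seed)."""
    ids = tuple(map(str, peptide_ids))
    if not ids:
        raise UsageError("panel needs a non-empty peptide list")
    meta = samples.set_index("sample_id")
    disc = meta[(meta["cohort"] == "discovery") & meta["outcome"].isin([POSITIVE, NEGATIVE])]
    disc = disc[disc.index.isin(matrix.index)]
    counts = disc["outcome"].value_counts()
    if len(counts) < 2:
        raise UsageError("training set must contain both outcome classes")
    if (counts < 2).any():
        raise UsageError("training needs at least 2 samples per outcome class")
    X = matrix.loc[disc.index, list(ids)].to_numpy()
    y = (disc["outcome"] == POSITIVE).to_numpy()
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    return PanelModel(peptide_ids=ids, n_trees=n_trees, seed=seed, forest=forest)


def score(model: PanelModel, matrix: pd.DataFrame, sample_ids=None) -> pd.Series:
    """Vote-difference score per sample, in [-1, 1].

    Score = (fraction of trees voting ESRD) - (fraction voting noESRD);
    a sample is classified ESRD iff score > ``model.cutoff``. Panel peptides
    missing from the matrix are imputed as 0 (not detected) with a warning.
    """
    if model.forest is None:
        raise UsageError("model has not been trained")
    rows = matrix.index if sample_ids is None else pd.Index(sample_ids)
    if len(rows) == 0:
        raise UsageError("cannot score an empty sample set")
    ids = list(model.peptide_ids)
    missing = [p for p in ids if p not in matrix.columns]
    if missing:
        logger.warning("panel peptide(s) %s absent from matrix; imputed as 0", missing[:5])
    X = matrix.reindex(index=rows, columns=ids, fill_value=0.0).fillna(0.0).to_numpy()
    votes = np.mean([tree.predict(X) for tree in model.forest.estimators_], axis=0)
    # trees predict the encoded class (True=ESRD -> 1); votes is the ESRD fraction
    return pd.Series(2.0 * votes - 1.0, index=rows, name="score")


def classify(model: PanelModel, scores: pd.Series) -> pd.Series:
    return scores > model.cutoff


def optimize_cutoff(scores, labels) -> float:
    """Cutoff maximizing Youden's J over midpoints of adjacent unique scores.

    ``labels`` is boolean (True = positive/ESRD). Ties in J are broken
    toward the candidate nearest 0 (then toward the smaller cutoff). With a
    single unique score no midpoint exists and 0.0 is returned.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or (~y).all():
        raise UsageError("cutoff optimization needs both classes")
    uniq = np.unique(s)
    if uniq.size < 2:
        return 0.0
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = y.sum()
    n_neg = (~y).sum()
    best_c, best_j = None, -np.inf
    for c in candidates:
        pred = s > c
        j = (pred & y).sum() / n_pos + ((~pred) & ~y).sum() / n_neg - 1.0
        better = j > best_j + 1e-12
        tie = abs(j - best_j) <= 1e-12 and (
            abs(c) < abs(best_c) - 1e-12
            or (abs(abs(c) - abs(best_c)) <= 1e-12 and c < best_c)
        )
        if better or tie:
            best_c, best_j = float(c), float(j)
    return best_c


def clopper_pearson(successes: int, trials: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval (beta quantiles).

    Returns (lower, upper) as fractions; 0 successes pins the lower bound at
    0, ``trials`` successes pins the upper bound at 1.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise UsageError(f"invalid counts: {successes}/{trials}")
    if not 0 < conf < 1:
        raise UsageError("confidence must lie in (0, 1)")
    alpha = 1.0 - conf
    lower = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    upper = 1.0 if successes == trials else float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return lower, upper


def auc_with_ci(scores, labels, conf: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """AUC with a DeLong confidence interval and a two-sided test vs 0.5.

    AUC is the Mann-Whitney probability that a positive outscores a negative
    (ties count one half). The variance follows DeLong's structural-component
    estimator; with zero variance (perfect or fully degenerate separation)
    the CI collapses to the point and the p-value is 0 unless AUC = 0.5.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = s[y]
    neg = s[~y]
    if pos.size == 0 or neg.size == 0:
        raise UsageError("AUC needs both classes")
    psi = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = 0.0
    if pos.size > 1:
        var += v10.var(ddof=1) / pos.size
    if neg.size > 1:
        var += v01.var(ddof=1) / neg.size
    se = float(np.sqrt(var))
    if se == 0.0:
        p = 1.0 if auc == 0.5 else 0.0
        return auc, (auc, auc), p
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    return auc, ci, p


def compare_classifiers(scores_a, scores_b) -> tuple[float, float]:
    """Spearman correlation between two classifiers' scores on the same samples."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size != b.size:
        raise UsageError("score vectors must have the same length")
    if a.size < 3:
        raise UsageError("need at least 3 paired scores")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def validate_panel(
    model: PanelModel,
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    cohort: str = "validation",
    conf: float = 0.95,
) -> ValidationReport:
    """Score a held-out arm and report sensitivity/specificity/AUC with CIs."""
    meta = samples.set_index("sample_id")
    held = meta[(meta["cohort"] == cohort) & meta["outcome"].isin([POSITIVE, NEGATIVE])]
    held = held[held.index.isin(matrix.index)]
    if held.empty:
        raise UsageError(f"no outcome-labelled samples in cohort '{cohort}'")
    scores = score(model, matrix, held.index)
    labels = _outcome_labels(samples, held.index) == POSITIVE
    if labels.all() or (~labels).all():
        raise UsageError("validation arm must contain both outcome classes")
    pred = classify(model, scores)
    tp = int((pred & labels).sum())
    fn = int(((~pred) & labels).sum())
    tn = int(((~pred) & ~labels).sum())
    fp = int((pred & ~labels).sum())
    sens_ci = clopper_pearson(tp, tp + fn, conf)
    spec_ci = clopper_pearson(tn, tn + fp, conf)
    auc, auc_ci, auc_p = auc_with_ci(scores.to_numpy(), labels.to_numpy(), conf)
    return ValidationReport(
        sensitivity_pct=100.0 * tp / (tp + fn),
        specificity_pct=100.0 * tn / (tn + fp),
        sens_ci_pct=(100.0 * sens_ci[0], 100.0 * sens_ci[1]),
        spec_ci_pct=(100.0 * spec_ci[0], 100.0 * spec_ci[1]),
        auc=auc,
        auc_ci=auc_ci,
        auc_p_vs_0_5=auc_p,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


def schwartz_egfr(height_cm: float, serum_creatinine_mg_dl: float, k: float = 0.413) -> float:
    """Bedside Schwartz estimate of GFR: k * height / creatinine (ml/min/1.73m2)."""
    if height_cm <= 0 or serum_creatinine_mg_dl <= 0:
        raise UsageError("height and creatinine must be positive")
    return k * height_cm / serum_creatinine_mg_dl


def outcome_from_egfr(egfr: float, threshold: float = 15.0) -> str:
    """noESRD iff eGFR strictly exceeds the threshold (15 ml/min/1.73m2)."""
    return NEGATIVE if egfr > threshold else POSITIVE
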
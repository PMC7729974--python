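"""Panel workflow: selection, forest scoring, cutoff, exact CIs, AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from amniopep import (
    auc_with_ci,
    clopper_pearson,
    compare_classifiers,
    optimize_cutoff,
    schwartz_egfr,
    score,
    select_candidates,
    train_classifier,
    validate_panel,
)
from amniopep.errors import UsageError
from amniopep.panel import outcome_from_egfr
from conftest import brute_force_auc, brute_force_spearman


def _filtered(puv_cohort):
    from amniopep import frequency_filter

    samples = puv_cohort.samples
    return frequency_filter(puv_cohort.af, samples[samples["fluid"] == "AF"]), samples


class TestSelectCandidates:
    def test_planted_effect_recovered(self, puv_cohort):
        af, samples = _filtered(puv_cohort)
        sel = select_candidates(af, samples, puv_cohort.truth.corr_peptides)
        planted = set(puv_cohort.truth.outcome_peptides)
        assert planted <= set(sel)

    def test_null_rate_near_alpha(self, puv_cohort):
        af, samples = _filtered(puv_cohort)
        nulls = [p for p in puv_cohort.truth.corr_peptides
                 if p not in puv_cohort.truth.outcome_peptides]
        sel = select_candidates(af, samples, nulls, alpha=0.05)
        assert len(sel) / len(nulls) < 0.2

    def test_disjoint_candidates_empty_with_warning(self, puv_cohort, caplog):
        af, samples = _filtered(puv_cohort)
        with caplog.at_level("WARNING"):
            sel = select_candidates(af, samples, ["nope1", "nope2"])
        assert sel == []
        assert any("absent" in r.message for r in caplog.records)

    def test_single_class_rejected(self, puv_cohort):
        af, samples = _filtered(puv_cohort)
        mono = samples.copy()
        mono.loc[mono["cohort"] == "discovery", "outcome"] = "ESRD"
        with pytest.raises(UsageError):
            select_candidates(af, mono, puv_cohort.truth.outcome_peptides)


class TestForest:
    def test_determinism_same_seed(self, puv_cohort):
        af, samples = _filtered(puv_cohort)
        ids = list(puv_cohort.truth.outcome_peptides)
        m1 = train_classifier(af, samples, ids, n_trees=100, seed=5)
        m2 = train_classifier(af, samples, ids, n_trees=100, seed=5)
        s1 = score(m1, af)
        s2 = score(m2, af)
        pd.testing.assert_series_equal(s1, s2)

    def test_training_scores_separate_with_large_effect(self, puv_cohort):
        af, samples = _filtered(puv_cohort)
        ids = list(puv_cohort.truth.outcome_peptides)
        model = train_classifier(af, samples, ids, n_trees=200, seed=0)
        meta = samples.set_index("sample_id")
        disc = meta[(meta["cohort"] == "discovery") & meta["outcome"].isin(["ESRD", "noESRD"])]
        s = score(model, af, disc.index)
        esrd = s[disc["outcome"] == "ESRD"]
        noesrd = s[disc["outcome"] == "noESRD"]
        assert esrd.min() > noesrd.max()

    def test_scores_bounded(self, puv_cohort):
        af, samples = _filtered(puv_cohort)
        model = train_classifier(af, samples, list(puv_cohort.truth.outcome_peptides),
                                 n_trees=50, seed=1)
        s = score(model, af)
        assert ((s >= -1) & (s <= 1)).all()

    def test_missing_panel_peptide_imputed_zero(self, puv_cohort, caplog):
        af, samples = _filtered(puv_cohort)
        ids = list(puv_cohort.truth.outcome_peptides)
        model = train_classifier(af, samples, ids, n_trees=50, seed=1)
        with caplog.at_level("WARNING"):
            s = score(model, af.drop(columns=ids[:1]))
        assert len(s) == len(af)
        assert any("imputed" in r.message for r in caplog.records)


class TestOptimizeCutoff:
    def test_separated_midpoint(self):
        c = optimize_cutoff([-0.8, -0.6, 0.4, 0.9], [False, False, True, True])
        assert c == pytest.approx(-0.1)

    def test_identical_distributions_returns_nearest_zero(self):
        c = optimize_cutoff([-0.5, 0.5, -0.5, 0.5], [True, False, False, True])
        assert c == pytest.approx(0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_exhaustive_sweep(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=12).round(2)
        y = rng.random(12) < 0.5
        if y.all() or (~y).all():
            y[0] = not y[0]
        c = optimize_cutoff(s, y)

        def youden(cut):
            pred = s > cut
            return (pred & y).sum() / y.sum() + ((~pred) & ~y).sum() / (~y).sum() - 1

        uniq = np.unique(s)
        best = max(youden(m) for m in (uniq[:-1] + uniq[1:]) / 2) if uniq.size > 1 else 0.0
        assert youden(c) == pytest.approx(best)

    def test_classification_flips_at_cutoff(self, puv_cohort):
        af, samples = _filtered(puv_cohort)
        model = train_classifier(af, samples, list(puv_cohort.truth.outcome_peptides),
                                 n_trees=50, seed=1)
        s = score(model, af)
        model.cutoff = float(np.median(s))
        from amniopep.panel import classify

        pred = classify(model, s)
        assert (pred == (s > model.cutoff)).all()


class TestClopperPearson:
    def test_paper_sensitivity_interval(self):
        lo, hi = clopper_pearson(8, 8)
        assert round(100 * lo) == 63
        assert hi == 1.0

    def test_paper_specificity_interval(self):
        lo, hi = clopper_pearson(7, 8)
        assert round(100 * lo) == 47
        assert round(100 * hi) == 100

    def test_zero_successes_closed_form(self):
        lo, hi = clopper_pearson(0, 1)
        assert lo == 0.0
        assert hi == pytest.approx(0.975)  # 1 - 0.025^(1/1)

    @given(st.integers(1, 40), st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_bisection_oracle_and_contains_estimate(self, trials, data):
        successes = data.draw(st.integers(0, trials))
        lo, hi = clopper_pearson(successes, trials)
        p_hat = successes / trials
        assert lo <= p_hat <= hi

        # independent oracle: bisection on the binomial tail expressed via the
        # regularized incomplete beta (beta CDF), no quantile function used
        def bisect(f, a, b):
            for _ in range(80):
                m = (a + b) / 2
                if f(m) > 0:
                    b = m
                else:
                    a = m
            return (a + b) / 2

        if successes > 0:
            f_lo = lambda p: stats.beta.cdf(p, successes, trials - successes + 1) - 0.025
            assert lo == pytest.approx(bisect(f_lo, 0, 1), abs=1e-9)
        if successes < trials:
            f_hi = lambda p: stats.beta.cdf(p, successes + 1, trials - successes) - 0.975
            assert hi == pytest.approx(bisect(f_hi, 0, 1), abs=1e-9)

    def test_width_shrinks_with_trials(self):
        widths = []
        for n in (8, 32, 128):
            lo, hi = clopper_pearson(n // 2, n)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_invalid_counts_rejected(self):
        with pytest.raises(UsageError):
            clopper_pearson(5, 4)


class TestAuc:
    def test_perfect_separation(self):
        auc, ci, p = auc_with_ci([1, 2, 3, 10, 11], [False, False, False, True, True])
        assert auc == 1.0 and p == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        s = rng.integers(0, 6, n).astype(float)  # ties likely
        y = rng.random(n) < 0.5
        if y.all() or (~y).all():
            y[0] = not y[0]
        auc, _, _ = auc_with_ci(s, y)
        assert auc == pytest.approx(brute_force_auc(s, y), abs=1e-12)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=400)
        y = rng.random(400) < 0.5
        auc, ci, p = auc_with_ci(s, y)
        assert abs(auc - 0.5) < 0.1
        assert ci[0] <= auc <= ci[1]

    def test_one_class_rejected(self):
        with pytest.raises(UsageError):
            auc_with_ci([1, 2], [True, True])


class TestCompareClassifiers:
    def test_identity(self):
        rho, _ = compare_classifiers([1, 2, 3, 4], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)

    def test_reversal(self):
        rho, _ = compare_classifiers([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.random(15), rng.random(15)
        rho, _ = compare_classifiers(a, b)
        assert rho == pytest.approx(brute_force_spearman(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(UsageError):
            compare_classifiers([1, 2, 3], [1, 2])


class TestSchwartz:
    def test_direct_arithmetic(self):
        assert schwartz_egfr(100, 1.0) == pytest.approx(41.3)

    def test_outcome_threshold_is_strict(self):
        assert outcome_from_egfr(15.0) == "ESRD"
        assert outcome_from_egfr(15.01) == "noESRD"

    def test_creatinine_proportionality(self):
        assert schwartz_egfr(120, 2.0) == pytest.approx(schwartz_egfr(120, 1.0) / 2)

    def test_non_positive_rejected(self):
        with pytest.raises(UsageError):
            schwartz_egfr(0, 1.0)


def test_validation_report_invariants(puv_cohort):
    af, samples = _filtered(puv_cohort)
    sel = select_candidates(af, samples, puv_cohort.truth.corr_peptides)
    model = train_classifier(af, samples, sel, n_trees=200, seed=0)
    rep = validate_panel(model, af, samples)
    assert rep.sensitivity_pct == pytest.approx(100.0 * rep.tp / (rep.tp + rep.fn))
    assert rep.specificity_pct == pytest.approx(100.0 * rep.tn / (rep.tn + rep.fp))
    assert rep.sens_ci_pct[0] <= rep.sensitivity_pct <= rep.sens_ci_pct[1]
    assert rep.spec_ci_pct[0] <= rep.specificity_pct <= rep.spec_ci_pct[1]
    assert 0.0 <= rep.auc <= 1.0
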
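import numpy as np
import pandas as pd
import pytest

from amniopep import SimulationConfig, generate_cohort, generate_puv_cohort


@pytest.fixture(scope="session")
def small_config():
    """Compact two-fluid cohort: full detection, strong planted correlation."""
    return SimulationConfig(
        n_peptides_shared=40,
        n_peptides_af_only=10,
        n_peptides_fu_only=12,
        n_af_samples=30,
        n_fu_samples=20,
        n_paired=16,
        corr_subset_size=20,
        corr_strength=0.95,
        n_outcome_peptides=5,
        detection_prob=1.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def puv_cohort():
    """Outcome-labelled cohort in the separable regime (effect >> cell noise)."""
    cfg = SimulationConfig(
        n_peptides_shared=120,
        n_peptides_af_only=20,
        n_peptides_fu_only=20,
        n_af_samples=46,
        n_fu_samples=20,
        n_paired=16,
        corr_subset_size=67,
        corr_strength=0.95,
        n_outcome_peptides=7,
        outcome_effect_size=8.0,
        log_abundance_sd=0.25,
        detection_prob=1.0,
        seed=1,
    )
    return generate_puv_cohort(cfg)


@pytest.fixture()
def tiny_samples():
    """Hand-built sample table for two fluids across two bins."""
    rows = []
    for i, ga in enumerate([12, 13, 16, 17, 16, 12]):
        rows.append(
            dict(
                sample_id=f"s{i}",
                fluid="AF" if i < 4 else "FU",
                gestational_age_wa=ga,
                ga_bin=None,
                patient_id=f"p{i}",
                diagnosis="CAKUT",
                outcome="NA",
                cohort="NA",
            )
        )
    return pd.DataFrame(rows)


def brute_force_spearman(x, y):
    """Rank formula 1 - 6*sum(d^2)/(n(n^2-1)); valid for tie-free inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    d = rx - ry
    return 1.0 - 6.0 * float((d**2).sum()) / (n * (n**2 - 1))


def brute_force_auc(scores, labels):
    """Exhaustive pair counting with ties worth one half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
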
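"""Seeded synthetic two-fluid peptidome cohorts with known ground truth.

The generator emulates a CE-MS peptidomics cohort of amniotic fluid (AF) and
fetal urine (FU) samples:

* a peptide catalog partitioned into shared, AF-only and FU-only peptides,
  with log-normal masses centred so ~90% fall in 800-5000 Da, and a sequenced
  subset dominated by collagen fragments;
* log-normal abundances with a multiplicative decrease across gestational
  bins, and an AF detection probability that rises with gestational age up to
  the 29-31 WA bin and then plateaus;
* paired AF/FU samples from the same fetus, with a planted subset of shared
  peptides whose AF and FU abundances are linked through a Gaussian copula on
  the log scale, calibrated so the expected Spearman correlation equals
  ``corr_strength``;
* an outcome-associated peptide subset whose abundance is multiplied by
  ``outcome_effect_size`` in ESRD samples (used by :func:`generate_puv_cohort`).

Detection is modelled as independent Bernoulli thinning after the abundance
draw; a non-detect zeroes the cell. Everything is reproducible from the
single ``seed`` (sub-streams are spawned deterministically per matrix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .datamodel import (
    AA_ALPHABET,
    DEFAULT_SCHEME,
    GaBinScheme,
    Peptidome,
    assign_ga_bins,
    make_catalog,
)
from .errors import ConfigError

DetectionProb = Union[float, Mapping[str, object]]

#: Origin classes used in the ground truth.
SHARED_CORRELATED = "shared-correlated"
SHARED_UNCORRELATED = "shared-uncorrelated"
AF_ONLY = "AF-only"
FU_ONLY = "FU-only"

# AF detection rises until the 29-31 WA bin then plateaus; FU is flat.
_DEFAULT_AF_DETECTION = {
    "11-14": 0.35,
    "15-17": 0.45,
    "18-21": 0.55,
    "22-24": 0.65,
    "25-28": 0.75,
    "29-31": 0.85,
    "32-35": 0.85,
    "36-39": 0.85,
}

_PROTEIN_POOL = (
    ("Collagen alpha-1(I) chain", 0.35),
    ("Collagen alpha-2(I) chain", 0.20),
    ("Collagen alpha-1(III) chain", 0.20),
    ("Fibrinogen alpha chain", 0.05),
    ("Insulin-like growth factor II", 0.04),
    ("Insulin-like growth factor-binding protein 7", 0.04),
    ("Osteopontin", 0.03),
    ("Apolipoprotein A-I", 0.03),
    ("Hemoglobin subunit beta", 0.02),
    ("Inter-alpha-trypsin inhibitor heavy chain H4", 0.02),
    ("Thymosin beta-4", 0.01),
    ("Cornulin", 0.005),
    ("Heparin cofactor 2", 0.005),
)


def _default_detection() -> dict:
    return {"AF": dict(_DEFAULT_AF_DETECTION), "FU": 0.7}


@dataclass
class SimulationConfig:
    """Stated world for the synthetic cohort.

    Defaults mirror the reference cohort design: 216 AF and 64 FU samples, 16
    paired fetuses, 1831 shared / 837 AF-only / 1426 FU-only peptides, a
    67-peptide correlated subset and a 7-peptide outcome-associated panel.
    """

    n_peptides_shared: int = 1831
    n_peptides_af_only: int = 837
    n_peptides_fu_only: int = 1426
    n_af_samples: int = 216
    n_fu_samples: int = 64
    n_paired: int = 16
    ga_range: tuple[int, int] = (11, 39)
    log_abundance_mean: float = 4.0
    log_abundance_sd: float = 1.0
    #: per-fluid scalar or per-bin table; scalar applies to every bin
    detection_prob: DetectionProb = field(default_factory=_default_detection)
    corr_subset_size: int = 67
    corr_strength: float = 0.8
    outcome_effect_size: float = 8.0
    n_outcome_peptides: int = 7
    #: multiplicative abundance factor per successive gestational bin (<1 = decline)
    ga_trend: float = 0.92
    frac_sequenced: float = 0.23
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_peptides_shared,
            self.n_peptides_af_only,
            self.n_peptides_fu_only,
            self.n_af_samples,
            self.n_fu_samples,
            self.n_paired,
            self.corr_subset_size,
            self.n_outcome_peptides,
        )
        if any(c < 0 for c in counts):
            raise ConfigError("all counts must be >= 0")
        if self.corr_subset_size > self.n_peptides_shared:
            raise ConfigError("corr_subset_size cannot exceed n_peptides_shared")
        if self.n_outcome_peptides > self.n_peptides_shared:
            raise ConfigError("n_outcome_peptides cannot exceed n_peptides_shared")
        if self.n_paired > min(self.n_af_samples, self.n_fu_samples):
            raise ConfigError("n_paired cannot exceed the samples of either fluid")
        if not 0 < self.corr_strength <= 1:
            raise ConfigError("corr_strength must lie in (0, 1]")
        if self.outcome_effect_size <= 0:
            raise ConfigError("outcome_effect_size must be positive")
        if self.ga_trend <= 0:
            raise ConfigError("ga_trend must be positive")
        for p in _flatten_probs(self.detection_prob):
            if not 0 < p <= 1:
                raise ConfigError("detection probabilities must lie in (0, 1]")


def _flatten_probs(spec: DetectionProb):
    if isinstance(spec, (int, float)):
        yield float(spec)
        return
    for v in spec.values():
        yield from _flatten_probs(v)


def _resolve_detection(spec: DetectionProb, fluid: str, bin_labels) -> np.ndarray:
    """Detection probability per bin label for one fluid."""
    if isinstance(spec, Mapping) and ("AF" in spec or "FU" in spec):
        spec = spec.get(fluid, 1.0)
    if isinstance(spec, Mapping):
        missing = [b for b in bin_labels if b not in spec]
        if missing:
            raise ConfigError(f"detection_prob table missing bins {missing}")
        return np.array([float(spec[b]) for b in bin_labels])
    return np.full(len(bin_labels), float(spec))


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for a synthetic cohort."""

    peptide_class: pd.Series  # catalog_id -> origin class
    corr_peptides: tuple[str, ...]
    outcome_peptides: tuple[str, ...]
    sample_outcome: pd.Series  # sample_id -> ESRD / noESRD / NA


@dataclass(frozen=True)
class SyntheticCohort:
    catalog: pd.DataFrame
    samples: pd.DataFrame
    af: pd.DataFrame
    fu: pd.DataFrame
    truth: GroundTruth

    @property
    def af_peptidome(self) -> Peptidome:
        af_samples = self.samples[self.samples["fluid"] == "AF"]
        return Peptidome(self.catalog, af_samples.reset_index(drop=True), self.af)

    @property
    def fu_peptidome(self) -> Peptidome:
        fu_samples = self.samples[self.samples["fluid"] == "FU"]
        return Peptidome(self.catalog, fu_samples.reset_index(drop=True), self.fu)


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian with given Spearman rho."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _make_catalog(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.Series]:
    n = cfg.n_peptides_shared + cfg.n_peptides_af_only + cfg.n_peptides_fu_only
    ids = [f"pep{i:05d}" for i in range(n)]
    classes = np.array(
        [SHARED_CORRELATED] * cfg.corr_subset_size
        + [SHARED_UNCORRELATED] * (cfg.n_peptides_shared - cfg.corr_subset_size)
        + [AF_ONLY] * cfg.n_peptides_af_only
        + [FU_ONLY] * cfg.n_peptides_fu_only,
        dtype=object,
    )
    # mass ~ lognormal(median 2500 Da, sigma 0.5): ~90% inside 800-5000 Da
    mass = np.exp(rng.normal(math.log(2500.0), 0.5, size=n)).clip(min=500.0)
    migration = rng.uniform(10.0, 45.0, size=n).round(2)
    sequenced = rng.random(n) < cfg.frac_sequenced
    names, weights = zip(*_PROTEIN_POOL)
    weights = np.asarray(weights) / sum(weights)
    seqs: list = [None] * n
    prots: list = [None] * n
    aa = np.array(list(AA_ALPHABET))
    for i in np.flatnonzero(sequenced):
        length = max(7, int(round(mass[i] / 110.0)))
        seqs[i] = "".join(rng.choice(aa, size=length))
        prots[i] = names[int(rng.choice(len(names), p=weights))]
    catalog = make_catalog(
        pd.DataFrame(
            {
                "catalog_id": ids,
                "mass_da": mass.round(3),
                "migration_time": migration,
                "sequence": seqs,
                "protein_name": prots,
            }
        )
    )
    return catalog, pd.Series(classes, index=pd.Index(ids, name="catalog_id"), name="class")


def _make_samples(cfg: SimulationConfig, rng: np.random.Generator, scheme: GaBinScheme) -> pd.DataFrame:
    lo, hi = cfg.ga_range
    if lo < scheme.min_wa or hi > scheme.max_wa:
        raise ConfigError(f"ga_range {cfg.ga_range} outside the bin scheme")
    rows = []
    paired_ga = rng.uniform(lo, hi + 1.0, size=cfg.n_paired).clip(max=hi + 0.99)
    for i in range(cfg.n_af_samples):
        paired = i < cfg.n_paired
        ga = paired_ga[i] if paired else min(float(rng.uniform(lo, hi + 1.0)), hi + 0.99)
        rows.append(
            dict(
                sample_id=f"AF{i + 1:04d}",
                fluid="AF",
                gestational_age_wa=round(ga, 2),
                patient_id=f"PT{i + 1:04d}",
                diagnosis="PUV" if paired else "CAKUT",
                outcome="NA",
                cohort="NA",
            )
        )
    for j in range(cfg.n_fu_samples):
        paired = j < cfg.n_paired
        ga = paired_ga[j] if paired else min(float(rng.uniform(lo, hi + 1.0)), hi + 0.99)
        rows.append(
            dict(
                sample_id=f"FU{j + 1:04d}",
                fluid="FU",
                gestational_age_wa=round(ga, 2),
                patient_id=f"PT{j + 1:04d}" if paired else f"PU{j + 1:04d}",
                diagnosis="PUV",
                outcome="NA",
                cohort="NA",
            )
        )
    samples = pd.DataFrame(rows)
    samples["ga_bin"] = np.nan
    return assign_ga_bins(samples, scheme)


def generate_cohort(
    config: SimulationConfig, scheme: GaBinScheme = DEFAULT_SCHEME
) -> SyntheticCohort:
    """Draw a full two-fluid cohort with planted ground truth.

    Returns the catalog, the combined sample table, one abundance matrix per
    fluid (columns span the whole catalog; structural zeros for the other
    fluid's exclusive peptides) and the :class:`GroundTruth`.
    """
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_cat, rng_samp, rng_fu, rng_af, rng_det, _rng_out = map(np.random.default_rng, streams)

    catalog, classes = _make_catalog(cfg, rng_cat)
    samples = _make_samples(cfg, rng_samp, scheme)
    ids = catalog["catalog_id"].to_numpy()
    n_pep = len(ids)

    af_meta = samples[samples["fluid"] == "AF"].reset_index(drop=True)
    fu_meta = samples[samples["fluid"] == "FU"].reset_index(drop=True)
    bin_index = {label: k for k, label in enumerate(scheme.labels)}

    theta = rng_cat.normal(cfg.log_abundance_mean, 1.0, size=n_pep)
    log_trend = math.log(cfg.ga_trend)

    cls = classes.to_numpy()
    present_af = (cls != FU_ONLY)
    present_fu = (cls != AF_ONLY)
    corr_cols = np.flatnonzero(cls == SHARED_CORRELATED)
    rho_p = spearman_to_pearson(cfg.corr_strength)

    z_fu = rng_fu.standard_normal((len(fu_meta), n_pep))
    z_af = rng_af.standard_normal((len(af_meta), n_pep))
    if cfg.n_paired and len(corr_cols):
        # paired rows are the first n_paired of each fluid by construction
        pair_rows = np.arange(cfg.n_paired)
        eps = z_af[np.ix_(pair_rows, corr_cols)]
        z_af[np.ix_(pair_rows, corr_cols)] = (
            rho_p * z_fu[np.ix_(pair_rows, corr_cols)]
            + math.sqrt(max(0.0, 1.0 - rho_p**2)) * eps
        )

    def build(meta: pd.DataFrame, z: np.ndarray, present: np.ndarray, fluid: str) -> pd.DataFrame:
        b = meta["ga_bin"].map(bin_index).to_numpy()
        logx = theta[None, :] + b[:, None] * log_trend + cfg.log_abundance_sd * z
        x = np.exp(logx)
        x[:, ~present] = 0.0
        p_bins = _resolve_detection(cfg.detection_prob, fluid, scheme.labels)
        p = p_bins[b]
        detected = rng_det.random(x.shape) < p[:, None]
        x = np.where(detected, x, 0.0)
        return pd.DataFrame(x, index=pd.Index(meta["sample_id"], name="sample_id"), columns=ids)

    fu = build(fu_meta, z_fu, present_fu, "FU")
    af = build(af_meta, z_af, present_af, "AF")

    corr_ids = tuple(ids[corr_cols])
    outcome_ids = tuple(ids[corr_cols[: cfg.n_outcome_peptides]])
    truth = GroundTruth(
        peptide_class=classes,
        corr_peptides=corr_ids,
        outcome_peptides=outcome_ids,
        sample_outcome=pd.Series(
            "NA", index=pd.Index(samples["sample_id"], name="sample_id"), name="outcome"
        ),
    )
    return SyntheticCohort(catalog=catalog, samples=samples, af=af, fu=fu, truth=truth)


def generate_puv_cohort(
    config: SimulationConfig,
    n_discovery_esrd: int = 6,
    n_discovery_noesrd: int = 8,
    n_validation_esrd: int = 8,
    n_validation_noesrd: int = 8,
    scheme: GaBinScheme = DEFAULT_SCHEME,
) -> SyntheticCohort:
    """Cohort with outcome labels split into discovery and validation arms.

    The defaults replicate the reference design: 6 ESRD + 8 noESRD fetuses in
    discovery, 8 + 8 in validation. Outcome-flagged peptides have their
    abundance multiplied by ``config.outcome_effect_size`` in ESRD samples of
    both fluids.
    """
    arms = (n_discovery_esrd, n_discovery_noesrd, n_validation_esrd, n_validation_noesrd)
    if any(a < 1 for a in arms):
        raise ConfigError("each discovery/validation arm needs at least one patient")
    total = sum(arms)
    if total > config.n_af_samples:
        raise ConfigError(
            f"PUV design needs {total} AF samples but config provides {config.n_af_samples}"
        )
    cohort = generate_cohort(config, scheme=scheme)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])

    af_ids = cohort.samples.loc[cohort.samples["fluid"] == "AF", "sample_id"].to_numpy()
    puv = af_ids[:total].copy()
    rng.shuffle(puv)
    assignment = (
        [("discovery", "ESRD")] * n_discovery_esrd
        + [("discovery", "noESRD")] * n_discovery_noesrd
        + [("validation", "ESRD")] * n_validation_esrd
        + [("validation", "noESRD")] * n_validation_noesrd
    )
    samples = cohort.samples.set_index("sample_id")
    outcome_series = cohort.truth.sample_outcome.copy()
    esrd_samples = []
    for sid, (arm, outcome) in zip(puv, assignment):
        samples.loc[sid, ["cohort", "outcome", "diagnosis"]] = [arm, outcome, "PUV"]
        outcome_series.loc[sid] = outcome
        if outcome == "ESRD":
            esrd_samples.append(sid)

    af = cohort.af.copy()
    fu = cohort.fu.copy()
    flagged = list(cohort.truth.outcome_peptides)
    af.loc[af.index.isin(esrd_samples), flagged] *= config.outcome_effect_size
    # propagate the effect to the paired FU sample of ESRD fetuses
    esrd_patients = samples.loc[esrd_samples, "patient_id"]
    fu_rows = samples[(samples["fluid"] == "FU") & samples["patient_id"].isin(esrd_patients)]
    for sid in fu_rows.index:
        outcome_series.loc[sid] = "ESRD"
        samples.loc[sid, "outcome"] = "ESRD"
        fu.loc[sid, flagged] *= config.outcome_effect_size

    truth = replace(cohort.truth, sample_outcome=outcome_series)
    return SyntheticCohort(
        catalog=cohort.catalog,
        samples=samples.reset_index(),
        af=af,
        fu=fu,
        truth=truth,
    )
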
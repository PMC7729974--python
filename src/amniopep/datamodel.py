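"""Core data model for two-fluid peptidome cohorts.

The in-memory containers are plain pandas objects with fixed column names:

* **peptide catalog** — one row per peptide: ``catalog_id`` (opaque token,
  stored as string), ``mass_da`` (monoisotopic mass, Daltons), optional
  ``migration_time`` (CE migration time, minutes), ``sequence`` (upper-case
  20-letter amino-acid string) and ``protein_name`` (parent protein).
* **sample table** — one row per sample: ``sample_id``, ``fluid`` (``AF`` or
  ``FU``), ``gestational_age_wa`` (weeks of amenorrhea), derived ``ga_bin``,
  ``patient_id`` (shared across an AF/FU pair from the same fetus),
  ``diagnosis``, ``outcome`` (``ESRD`` / ``noESRD`` / ``NA``) and ``cohort``
  (``discovery`` / ``validation`` / ``NA``).
* **abundance matrix** — a samples x peptides ``DataFrame`` of non-negative
  normalized signal amplitudes; an exact 0 means "not detected".

This module owns the gestational-age bin scheme, bin assignment and the
detection-frequency filter that defines which peptides count as present in a
fluid.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, GestationalAgeError, UsageError

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_SEQ_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

CATALOG_COLUMNS = ("catalog_id", "mass_da", "migration_time", "sequence", "protein_name")
SAMPLE_COLUMNS = (
    "sample_id",
    "fluid",
    "gestational_age_wa",
    "ga_bin",
    "patient_id",
    "diagnosis",
    "outcome",
    "cohort",
)

#: Default gestational bin edges, closed integer intervals in completed weeks
#: of amenorrhea. Eight periods spanning 11-39 WA.
DEFAULT_BIN_EDGES = (
    (11, 14),
    (15, 17),
    (18, 21),
    (22, 24),
    (25, 28),
    (29, 31),
    (32, 35),
    (36, 39),
)


@dataclass(frozen=True)
class GaBinScheme:
    """Ordered, non-overlapping closed integer intervals over weeks of amenorrhea."""

    intervals: tuple[tuple[int, int], ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        if not self.intervals:
            raise UsageError("bin scheme must contain at least one interval")
        prev_hi = -math.inf
        for lo, hi in self.intervals:
            if lo > hi:
                raise UsageError(f"bin interval [{lo}, {hi}] is empty")
            if lo <= prev_hi:
                raise UsageError("bin intervals must be ascending and non-overlapping")
            prev_hi = hi

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"{lo}-{hi}" for lo, hi in self.intervals)

    @property
    def min_wa(self) -> int:
        return self.intervals[0][0]

    @property
    def max_wa(self) -> int:
        return self.intervals[-1][1]

    def bin_of(self, gestational_age_wa: float) -> str | None:
        """Bin label for an age, or None if outside every interval.

        Ages are truncated to completed weeks before lookup (obstetric
        convention): 14.9 WA is 14 completed weeks and falls in "11-14".
        """
        week = int(math.floor(gestational_age_wa))
        for (lo, hi), label in zip(self.intervals, self.labels):
            if lo <= week <= hi:
                return label
        return None


DEFAULT_SCHEME = GaBinScheme()


def make_catalog(records: pd.DataFrame | list[dict]) -> pd.DataFrame:
    """Normalize and validate a peptide catalog table."""
    cat = pd.DataFrame(records).copy()
    if "catalog_id" not in cat.columns or "mass_da" not in cat.columns:
        raise DataError("catalog requires catalog_id and mass_da columns")
    cat["catalog_id"] = cat["catalog_id"].astype(str)
    for col in CATALOG_COLUMNS:
        if col not in cat.columns:
            cat[col] = np.nan
    cat = cat.loc[:, list(CATALOG_COLUMNS)].reset_index(drop=True)
    validate_catalog(cat)
    return cat


def validate_catalog(catalog: pd.DataFrame) -> None:
    if catalog["catalog_id"].duplicated().any():
        dups = catalog.loc[catalog["catalog_id"].duplicated(), "catalog_id"].tolist()
        raise DataError(f"duplicate catalog_id values: {dups[:5]}")
    masses = pd.to_numeric(catalog["mass_da"], errors="coerce")
    if masses.isna().any() or (masses <= 0).any():
        raise DataError("mass_da must be a positive number for every peptide")
    seqs = catalog["sequence"].dropna()
    bad = [s for s in seqs if not _SEQ_RE.match(str(s))]
    if bad:
        raise DataError(f"invalid amino-acid sequence(s): {bad[:3]}")


def validate_samples(samples: pd.DataFrame) -> None:
    if samples["sample_id"].duplicated().any():
        raise DataError("sample_id values must be unique")
    bad_fluid = set(samples["fluid"].unique()) - {"AF", "FU"}
    if bad_fluid:
        raise DataError(f"fluid must be AF or FU, got {sorted(bad_fluid)}")
    with_pid = samples.dropna(subset=["patient_id"])
    per = with_pid.groupby(["patient_id", "fluid"]).size()
    if (per > 1).any():
        offending = per[per > 1].index.tolist()
        raise DataError(f"more than one sample per (patient, fluid): {offending[:5]}")


def validate_matrix(
    matrix: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    catalog: pd.DataFrame | None = None,
) -> None:
    """Check abundance-matrix invariants (non-negative, unique axes, resolvable keys)."""
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise DataError("abundance matrix axes must not contain duplicate keys")
    vals = matrix.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise DataError("abundance matrix must be numeric")
    if np.isnan(vals).any():
        raise DataError("abundance matrix must not contain NaN (encode non-detects as 0)")
    if (vals < 0).any():
        raise DataError("abundance values must be non-negative")
    if samples is not None:
        missing = matrix.index.difference(pd.Index(samples["sample_id"].astype(str)))
        if len(missing):
            raise DataError(f"matrix samples absent from sample table: {list(missing[:5])}")
    if catalog is not None:
        missing = matrix.columns.difference(pd.Index(catalog["catalog_id"].astype(str)))
        if len(missing):
            raise DataError(f"matrix peptides absent from catalog: {list(missing[:5])}")


def check_sample_totals(matrix: pd.DataFrame, max_ratio: float = 10.0) -> bool:
    """Sanity hook: warn when per-sample totals differ by more than ``max_ratio``.

    Abundances are assumed normalized upstream; a >10x spread in per-sample
    totals usually means unnormalized input. Returns True when the check
    passes quietly.
    """
    totals = matrix.sum(axis=1)
    positive = totals[totals > 0]
    if len(positive) < 2:
        return True
    ratio = positive.max() / positive.min()
    if ratio > max_ratio:
        logger.warning(
            "per-sample abundance totals differ by %.1fx (max %.3g / min %.3g); "
            "input may not be normalized",
            ratio,
            positive.max(),
            positive.min(),
        )
        return False
    return True


def assign_ga_bins(samples: pd.DataFrame, scheme: GaBinScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Return a copy of the sample table with ``ga_bin`` assigned from age.

    Raises :class:`GestationalAgeError` listing every sample whose completed
    weeks fall outside all intervals.
    """
    out = samples.copy()
    bins = out["gestational_age_wa"].map(scheme.bin_of)
    outside = out.loc[bins.isna(), "sample_id"].tolist()
    if outside:
        raise GestationalAgeError(outside)
    out["ga_bin"] = bins
    return out


def detection_frequency_by_bin(matrix: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-bin detection frequency (share of samples with abundance > 0).

    Rows are bin labels present in the sample table, columns peptides; only
    non-empty bins appear.
    """
    meta = samples.set_index("sample_id").loc[matrix.index]
    detected = matrix > 0
    return detected.groupby(meta["ga_bin"], observed=True).mean()


def frequency_filter(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    min_freq: float = 0.5,
) -> pd.DataFrame:
    """Detection-frequency filter defining a fluid's peptide set.

    A peptide is retained iff its detection frequency (share of samples with
    a positive value) reaches ``min_freq`` in at least one non-empty
    gestational bin. All samples must come from a single fluid and carry a
    ``ga_bin``. The sample axis is preserved unchanged.

    At ``min_freq = 0`` the rule degenerates to "detected at least once"
    (a bin frequency must be both >= 0 and > 0).
    """
    if not 0 <= min_freq <= 1:
        raise UsageError("min_freq must lie in [0, 1]")
    meta = samples.set_index("sample_id")
    try:
        meta = meta.loc[matrix.index]
    except KeyError as exc:
        raise DataError(f"matrix contains samples absent from the sample table: {exc}") from exc
    fluids = set(meta["fluid"].unique())
    if len(fluids) != 1:
        raise UsageError(
            f"frequency_filter is defined per fluid; got samples from {sorted(fluids)}"
        )
    if meta["ga_bin"].isna().any():
        raise UsageError("all samples must have ga_bin assigned (run assign_ga_bins first)")
    freq = detection_frequency_by_bin(matrix, samples)
    keep = ((freq >= min_freq) & (freq > 0)).any(axis=0)
    return matrix.loc[:, keep[keep].index]


@dataclass(frozen=True)
class Peptidome:
    """A consistent (catalog, samples, abundance matrix) triple for one cohort."""

    catalog: pd.DataFrame
    samples: pd.DataFrame
    matrix: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        validate_catalog(self.catalog)
        validate_samples(self.samples)
        validate_matrix(self.matrix, self.samples, self.catalog)
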
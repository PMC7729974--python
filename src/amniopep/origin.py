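"""Fetal-urine origin attribution for amniotic-fluid peptides.

Two complementary analyses:

* :func:`average_abundance_correlation` — Spearman correlation between the
  per-peptide mean AF abundance and the per-peptide mean FU abundance over a
  peptide set (the global, cohort-level view).
* :func:`paired_origin_screen` — per-peptide Spearman correlation of AF vs FU
  abundance across fetuses with both fluids sampled. A peptide is called
  "FU-origin" when its correlation is positive and its two-sided p-value
  falls below ``alpha``; zeros (non-detects) enter the ranks as true zero
  abundances.

Both are rank-based, so any strictly monotone transform of either fluid's
abundances leaves the results unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError


@dataclass(frozen=True)
class CorrelationResult:
    """Paired AF-FU association for one peptide."""

    catalog_id: str
    rho: float
    p_value: float
    n_pairs: int
    selected: bool
    #: True when rho is undefined (zero variance in a fluid) or too few
    #: detected pairs support the estimate
    degenerate: bool = False


def average_abundance_correlation(
    af: pd.DataFrame, fu: pd.DataFrame, peptide_ids
) -> tuple[float, float]:
    """Spearman correlation of per-peptide mean abundances across two fluids."""
    ids = pd.Index(map(str, peptide_ids)).unique()
    if len(ids) < 3:
        raise UsageError("need at least 3 peptides to correlate mean abundances")
    missing = ids.difference(af.columns).union(ids.difference(fu.columns))
    if len(missing):
        raise UsageError(f"peptide IDs absent from a matrix: {list(missing[:5])}")
    mean_af = af.loc[:, ids].mean(axis=0)
    mean_fu = fu.loc[:, ids].mean(axis=0)
    rho, p = stats.spearmanr(mean_af, mean_fu)
    return float(rho), float(p)


def paired_patients(samples: pd.DataFrame) -> pd.DataFrame:
    """Patients with exactly one AF and one FU sample.

    Returns a frame indexed by patient_id with columns ``af_sample`` and
    ``fu_sample``.
    """
    with_pid = samples.dropna(subset=["patient_id"])
    pivot = with_pid.pivot_table(
        index="patient_id", columns="fluid", values="sample_id", aggfunc="first"
    )
    if "AF" not in pivot.columns or "FU" not in pivot.columns:
        return pd.DataFrame(columns=["af_sample", "fu_sample"])
    pairs = pivot.dropna(subset=["AF", "FU"])
    return pairs.rename(columns={"AF": "af_sample", "FU": "fu_sample"})[
        ["af_sample", "fu_sample"]
    ]


def paired_origin_screen(
    af: pd.DataFrame,
    fu: pd.DataFrame,
    samples: pd.DataFrame,
    peptide_ids=None,
    alpha: float = 0.05,
    min_detected_pairs: int = 3,
) -> list[CorrelationResult]:
    """Per-peptide Spearman screen over paired AF/FU samples.

    ``peptide_ids`` defaults to the peptides common to both matrices (the
    overlap set). For each peptide the AF and FU abundances of every paired
    fetus are correlated, zeros included. A peptide is ``selected`` when
    rho > 0 and the two-sided p-value < ``alpha``; peptides with zero
    variance in either fluid, or detected (in both fluids at once) in fewer
    than ``min_detected_pairs`` pairs, are flagged degenerate and never
    selected. Results are sorted by p-value ascending, undefined last.
    """
    pairs = paired_patients(samples)
    pairs = pairs[pairs["af_sample"].isin(af.index) & pairs["fu_sample"].isin(fu.index)]
    if len(pairs) < 3:
        raise UsageError(
            f"paired screen needs >= 3 complete AF/FU pairs, found {len(pairs)}"
        )
    if peptide_ids is None:
        ids = af.columns.intersection(fu.columns)
    else:
        ids = pd.Index(map(str, peptide_ids)).unique()
        missing = ids.difference(af.columns).union(ids.difference(fu.columns))
        if len(missing):
            raise UsageError(f"peptide IDs absent from a matrix: {list(missing[:5])}")

    af_paired = af.loc[pairs["af_sample"], ids].to_numpy()
    fu_paired = fu.loc[pairs["fu_sample"], ids].to_numpy()
    n_pairs = len(pairs)

    results: list[CorrelationResult] = []
    for j, pid in enumerate(ids):
        x = af_paired[:, j]
        y = fu_paired[:, j]
        n_det = int(((x > 0) & (y > 0)).sum())
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            results.append(
                CorrelationResult(str(pid), float("nan"), float("nan"), n_pairs, False, True)
            )
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = stats.spearmanr(x, y)
        if not np.isfinite(rho):
            results.append(
                CorrelationResult(str(pid), float("nan"), float("nan"), n_pairs, False, True)
            )
            continue
        degenerate = n_det < min_detected_pairs
        selected = (not degenerate) and rho > 0 and p < alpha
        results.append(
            CorrelationResult(str(pid), float(rho), float(p), n_pairs, bool(selected), degenerate)
        )
    results.sort(key=lambda r: (np.isnan(r.p_value), r.p_value))
    return results


def screen_table(results: list[CorrelationResult]) -> pd.DataFrame:
    """Screen results as a tidy frame (one row per peptide)."""
    return pd.DataFrame(
        {
            "catalog_id": [r.catalog_id for r in results],
            "rho": [r.rho for r in results],
            "p_value": [r.p_value for r in results],
            "n_pairs": [r.n_pairs for r in results],
            "selected": [r.selected for r in results],
            "degenerate": [r.degenerate for r in results],
        }
    )


def selected_ids(results: list[CorrelationResult]) -> list[str]:
    return [r.catalog_id for r in results if r.selected]
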
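"""Two-fluid peptidome overlap analysis.

Given the frequency-filtered AF and FU abundance matrices, this module
computes the three-way Venn partition (AF-only / common / FU-only), its
gestational-age-stratified trajectory, mass-distribution summaries,
parent-protein tabulations and the standard group comparisons
(Mann-Whitney between two groups, one-way ANOVA across gestational bins).

A fluid's peptide set is simply the column set of its filtered matrix; the
share of AF abundance carried by the common peptides is computed from mean
abundances over samples, zeros (non-detects) included, so that rarely
detected peptides dilute their own share.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DEFAULT_SCHEME, GaBinScheme
from .errors import UsageError

logger = logging.getLogger(__name__)


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (report convention)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class VennPartition:
    """Three-way split of two fluids' peptide sets with AF-share summaries."""

    af_only_ids: frozenset
    common_ids: frozenset
    fu_only_ids: frozenset
    #: percent of the AF peptide number that is common, full precision
    pct_of_af_number: float
    #: percent of total AF abundance carried by common peptides (None when
    #: built from bare ID sets without abundances)
    pct_of_af_abundance: float | None = None

    @property
    def n_af_total(self) -> int:
        return len(self.af_only_ids) + len(self.common_ids)

    @property
    def n_fu_total(self) -> int:
        return len(self.fu_only_ids) + len(self.common_ids)

    @property
    def n_common(self) -> int:
        return len(self.common_ids)

    def report(self) -> dict:
        """Integer-rounded counts and percentages for display."""
        out = {
            "n_af_only": len(self.af_only_ids),
            "n_common": self.n_common,
            "n_fu_only": len(self.fu_only_ids),
            "n_af_total": self.n_af_total,
            "n_fu_total": self.n_fu_total,
            "pct_of_af_number": round_half_up(self.pct_of_af_number),
        }
        if self.pct_of_af_abundance is not None:
            out["pct_of_af_abundance"] = round_half_up(self.pct_of_af_abundance)
        return out


@dataclass(frozen=True)
class MassSummary:
    mean_da: float
    median_da: float
    sem_da: float
    fraction_in_800_5000: float
    n: int


def _as_id_set(x) -> frozenset:
    if isinstance(x, pd.DataFrame):
        return frozenset(map(str, x.columns))
    return frozenset(map(str, x))


def venn_partition(af, fu) -> VennPartition:
    """Partition the AF and FU peptide sets into exclusive and common parts.

    ``af`` and ``fu`` are either frequency-filtered abundance matrices
    (samples x peptides) or bare iterables of peptide IDs. With matrices the
    AF abundance share of the common peptides is also computed (mean over AF
    samples including zeros, summed over peptides).
    """
    af_ids = _as_id_set(af)
    fu_ids = _as_id_set(fu)
    common = af_ids & fu_ids
    if not common and af_ids and fu_ids:
        logger.warning(
            "AF and FU peptide sets share no IDs (%d vs %d peptides); "
            "inputs may not be on a common catalog",
            len(af_ids),
            len(fu_ids),
        )
    pct_number = 100.0 * len(common) / len(af_ids) if af_ids else float("nan")
    pct_abundance = None
    if isinstance(af, pd.DataFrame):
        means = af.mean(axis=0)
        total = means.sum()
        if total > 0:
            pct_abundance = 100.0 * means[means.index.isin(common)].sum() / total
    return VennPartition(
        af_only_ids=frozenset(af_ids - common),
        common_ids=frozenset(common),
        fu_only_ids=frozenset(fu_ids - common),
        pct_of_af_number=pct_number,
        pct_of_af_abundance=pct_abundance,
    )


def overlap_by_bin(
    af: pd.DataFrame,
    fu: pd.DataFrame,
    samples: pd.DataFrame,
    scheme: GaBinScheme = DEFAULT_SCHEME,
    min_freq: float = 0.5,
) -> dict[str, VennPartition]:
    """Per-gestational-bin Venn partitions, ordered by the scheme.

    Presence within a bin reuses the detection-frequency rule restricted to
    that bin's samples. Bins with zero samples in either fluid are omitted
    (missing, not zero).
    """
    meta = samples.set_index("sample_id")
    if meta["ga_bin"].isna().any():
        raise UsageError("all samples must have ga_bin assigned")
    out: dict[str, VennPartition] = {}
    for label in scheme.labels:
        af_ids = meta.index[(meta["fluid"] == "AF") & (meta["ga_bin"] == label)]
        fu_ids = meta.index[(meta["fluid"] == "FU") & (meta["ga_bin"] == label)]
        af_ids = af_ids.intersection(af.index)
        fu_ids = fu_ids.intersection(fu.index)
        if len(af_ids) == 0 or len(fu_ids) == 0:
            continue
        af_bin = af.loc[af_ids]
        fu_bin = fu.loc[fu_ids]
        af_present = _present_in_bin(af_bin, min_freq)
        fu_present = _present_in_bin(fu_bin, min_freq)
        part = venn_partition(af_bin.loc[:, af_present], fu_bin.loc[:, fu_present])
        out[label] = part
    return out


def _present_in_bin(bin_matrix: pd.DataFrame, min_freq: float) -> pd.Index:
    freq = (bin_matrix > 0).mean(axis=0)
    keep = (freq >= min_freq) & (freq > 0)
    return bin_matrix.columns[keep]


def mass_summary(catalog: pd.DataFrame, peptide_ids) -> MassSummary:
    """Mean/median/SEM of monoisotopic mass and the share inside [800, 5000] Da."""
    ids = pd.Index(map(str, peptide_ids))
    if len(ids) == 0:
        raise UsageError("mass summary of an empty peptide set is undefined")
    cat = catalog.set_index("catalog_id")
    missing = ids.difference(cat.index)
    if len(missing):
        raise UsageError(f"peptide IDs absent from catalog: {list(missing[:5])}")
    masses = cat.loc[ids, "mass_da"].astype(float)
    sem = float(masses.std(ddof=1) / math.sqrt(len(masses))) if len(masses) > 1 else 0.0
    return MassSummary(
        mean_da=float(masses.mean()),
        median_da=float(masses.median()),
        sem_da=sem,
        fraction_in_800_5000=float(((masses >= 800) & (masses <= 5000)).mean()),
        n=len(masses),
    )


def protein_origin_table(
    catalog: pd.DataFrame,
    peptide_ids,
    matrix: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, int]:
    """Tabulate parent proteins of a peptide set.

    Returns ``(table, n_unsequenced)``. The table has one row per parent
    protein with the peptide count and its share among *sequenced* peptides
    (peptides without a protein annotation are excluded from shares and
    counted separately). When an abundance matrix is given, an
    ``abundance_share`` column (mean abundance summed per protein, normalized
    over sequenced peptides) is added.
    """
    ids = pd.Index(map(str, peptide_ids))
    cat = catalog.set_index("catalog_id").reindex(ids)
    annotated = cat["protein_name"].notna()
    n_unsequenced = int((~annotated).sum())
    sequenced = cat[annotated]
    if sequenced.empty:
        empty = pd.DataFrame(columns=["protein_name", "n_peptides", "count_share"])
        return empty, n_unsequenced
    counts = (
        sequenced.groupby("protein_name")
        .size()
        .sort_values(ascending=False)
        .rename("n_peptides")
        .reset_index()
    )
    counts["count_share"] = counts["n_peptides"] / counts["n_peptides"].sum()
    if matrix is not None:
        means = matrix.mean(axis=0)
        seq_ids = sequenced.index
        per_protein = (
            means.reindex(seq_ids)
            .fillna(0.0)
            .groupby(sequenced["protein_name"])
            .sum()
        )
        total = per_protein.sum()
        counts["abundance_share"] = counts["protein_name"].map(
            per_protein / total if total > 0 else per_protein * 0.0
        )
    return counts, n_unsequenced


def compare_groups(values_a, values_b, test: str = "mann_whitney") -> tuple[float, float]:
    """Two-sided Mann-Whitney comparison of two value groups.

    Returns the U statistic of group A and the two-sided p-value (exact for
    small tie-free groups, normal approximation otherwise).
    """
    if test != "mann_whitney":
        raise UsageError(f"unsupported test '{test}'")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise UsageError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (not ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def trend_across_bins(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    scheme: GaBinScheme = DEFAULT_SCHEME,
) -> tuple[pd.DataFrame, float, float]:
    """Per-bin mean +/- SEM of per-sample mean abundance, with one-way ANOVA.

    Returns ``(table, F, p)`` where the table has one row per non-empty bin
    (columns ``ga_bin``, ``mean``, ``sem``, ``n``) ordered by the scheme.
    """
    meta = samples.set_index("sample_id").loc[matrix.index]
    per_sample = matrix.mean(axis=1)
    groups = []
    rows = []
    for label in scheme.labels:
        vals = per_sample[meta["ga_bin"] == label]
        if len(vals) == 0:
            continue
        groups.append(vals.to_numpy())
        sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append({"ga_bin": label, "mean": float(vals.mean()), "sem": sem, "n": len(vals)})
    if len(groups) < 2:
        raise UsageError("ANOVA across bins needs at least two non-empty bins")
    table = pd.DataFrame(rows)
    grand = np.concatenate(groups)
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    if within == 0.0:
        # degenerate: zero within-group variance
        return (table, float("inf"), 0.0) if between > 0 else (table, 0.0, 1.0)
    f, p = stats.f_oneway(*groups)
    return table, float(f), float(p)
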
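"""Data model, binning, frequency filter and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amniopep import DEFAULT_SCHEME, GaBinScheme, assign_ga_bins, frequency_filter
from amniopep.datamodel import Peptidome, detection_frequency_by_bin, make_catalog
from amniopep.errors import DataError, FormatError, GestationalAgeError, UsageError
from amniopep.io import read_matrix, read_peptidome, write_matrix, write_peptidome


class TestGaBins:
    @pytest.mark.parametrize(
        "age,label",
        [
            (11, "11-14"),
            (14, "11-14"),
            (14.9, "11-14"),  # truncated to completed weeks
            (15, "15-17"),
            (29, "29-31"),
            (39.5, "36-39"),
        ],
    )
    def test_bin_edges(self, age, label):
        assert DEFAULT_SCHEME.bin_of(age) == label

    def test_scheme_has_eight_closed_intervals(self):
        assert len(DEFAULT_SCHEME.intervals) == 8
        assert DEFAULT_SCHEME.labels[0] == "11-14"
        assert DEFAULT_SCHEME.labels[-1] == "36-39"

    @given(st.floats(min_value=11, max_value=39.99))
    @settings(max_examples=200, deadline=None)
    def test_bins_partition_the_range(self, age):
        # every in-range age maps to exactly one interval
        label = DEFAULT_SCHEME.bin_of(age)
        week = int(np.floor(age))
        hits = [(lo, hi) for lo, hi in DEFAULT_SCHEME.intervals if lo <= week <= hi]
        assert len(hits) == 1
        lo, hi = hits[0]
        assert label == f"{lo}-{hi}"

    def test_out_of_range_age_lists_offenders(self, tiny_samples):
        bad = tiny_samples.copy()
        bad.loc[0, "gestational_age_wa"] = 40
        with pytest.raises(GestationalAgeError) as err:
            assign_ga_bins(bad)
        assert "s0" in str(err.value)

    def test_overlapping_scheme_rejected(self):
        with pytest.raises(UsageError):
            GaBinScheme(((11, 15), (15, 17)))


class TestFrequencyFilter:
    def _cohort(self, values, gas):
        n = len(values)
        samples = pd.DataFrame(
            dict(
                sample_id=[f"s{i}" for i in range(n)],
                fluid="AF",
                gestational_age_wa=gas,
                ga_bin=None,
                patient_id=[f"p{i}" for i in range(n)],
                diagnosis="x",
                outcome="NA",
                cohort="NA",
            )
        )
        samples = assign_ga_bins(samples)
        matrix = pd.DataFrame(
            values, index=samples["sample_id"], columns=[f"pep{j}" for j in range(len(values[0]))]
        ).astype(float)
        return matrix, samples

    def test_half_in_one_bin_retained(self):
        # detected in 3 of 6 samples of one bin (50%), absent elsewhere
        vals = [[1.0], [2.0], [3.0], [0.0], [0.0], [0.0], [0.0], [0.0]]
        matrix, samples = self._cohort(vals, [12, 12, 12, 12, 12, 12, 16, 16])
        kept = frequency_filter(matrix, samples, 0.5)
        assert list(kept.columns) == ["pep0"]

    def test_below_threshold_everywhere_removed(self):
        vals = [[1.0], [1.0], [0.0], [0.0], [0.0], [1.0], [1.0], [0.0], [0.0], [0.0]]
        matrix, samples = self._cohort(vals, [12] * 5 + [16] * 5)
        assert frequency_filter(matrix, samples, 0.5).shape[1] == 0

    def test_zero_threshold_keeps_any_detection(self):
        vals = [[1.0, 0.0], [0.0, 0.0], [0.0, 0.0]]
        matrix, samples = self._cohort(vals, [12, 12, 16])
        kept = frequency_filter(matrix, samples, 0.0)
        assert list(kept.columns) == ["pep0"]  # never-detected peptide dropped

    def test_mixed_fluids_rejected(self, small_cohort):
        mixed = pd.concat([small_cohort.af.iloc[:4], small_cohort.fu.iloc[:4]])
        with pytest.raises(UsageError):
            frequency_filter(mixed, small_cohort.samples)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_monotone_and_idempotent(self, data):
        n_s, n_p = 8, 6
        vals = data.draw(
            st.lists(
                st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=n_p, max_size=n_p),
                min_size=n_s,
                max_size=n_s,
            )
        )
        gas = data.draw(st.lists(st.sampled_from([12, 16, 20]), min_size=n_s, max_size=n_s))
        matrix, samples = self._cohort(vals, gas)
        low = frequency_filter(matrix, samples, 0.3)
        high = frequency_filter(matrix, samples, 0.7)
        assert set(high.columns) <= set(low.columns)  # raising min_freq never adds
        again = frequency_filter(low, samples, 0.3)
        assert list(again.columns) == list(low.columns)  # idempotent

    def test_matches_exhaustive_per_bin_scan(self, small_cohort):
        cohort = small_cohort
        af_samples = cohort.samples[cohort.samples["fluid"] == "AF"]
        kept = frequency_filter(cohort.af, af_samples, 0.5)
        meta = af_samples.set_index("sample_id")
        expected = []
        for pid in cohort.af.columns:
            ok = False
            for label in meta["ga_bin"].unique():
                sub = cohort.af.loc[meta.index[meta["ga_bin"] == label], pid]
                if len(sub) and (sub > 0).mean() >= 0.5 and (sub > 0).any():
                    ok = True
            if ok:
                expected.append(pid)
        assert list(kept.columns) == expected


class TestIO:
    def test_wide_empty_cell_is_nondetect(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("catalog_id,s1,s2\npA,1.5,\npB,2.0,3.0\n")
        mat = read_matrix(path, "wide")
        assert mat.loc["s2", "pA"] == 0.0
        assert mat.loc["s2", "pB"] == 3.0

    def test_long_conflicting_duplicate_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("sample_id,catalog_id,abundance\ns1,p1,5.0\ns1,p1,6.0\n")
        with pytest.raises(DataError, match="conflicting"):
            read_matrix(path, "long")

    def test_long_consistent_duplicate_collapsed(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("sample_id,catalog_id,abundance\ns1,p1,5.0\ns1,p1,5.0\n")
        assert read_matrix(path, "long").loc["s1", "p1"] == 5.0

    def test_non_numeric_abundance_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("sample_id,catalog_id,abundance\ns1,p1,oops\n")
        with pytest.raises(DataError, match="non-numeric"):
            read_matrix(path, "long")

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("sample_id,abundance\ns1,5.0\n")
        with pytest.raises(FormatError, match="catalog_id"):
            read_matrix(path, "long")

    def test_roundtrip_preserves_cohort_exactly(self, small_cohort, tmp_path):
        pep = small_cohort.af_peptidome
        write_peptidome(tmp_path / "cohort", pep)
        back = read_peptidome(tmp_path / "cohort")
        pd.testing.assert_frame_equal(
            back.matrix.sort_index(axis=1), pep.matrix.sort_index(axis=1), check_names=False
        )
        assert list(back.catalog["catalog_id"]) == list(pep.catalog["catalog_id"])
        np.testing.assert_array_equal(
            back.catalog["mass_da"].to_numpy(), pep.catalog["mass_da"].to_numpy()
        )
        assert list(back.samples["sample_id"]) == list(pep.samples["sample_id"])

    def test_wide_long_roundtrip_agree(self, small_cohort, tmp_path):
        mat = small_cohort.fu
        write_matrix(tmp_path / "w.csv", mat, "wide")
        write_matrix(tmp_path / "l.csv", mat, "long")
        wide = read_matrix(tmp_path / "w.csv", "wide")
        long = read_matrix(tmp_path / "l.csv", "long")
        # long drops never-detected peptides by construction
        common = wide.columns.intersection(long.columns)
        pd.testing.assert_frame_equal(
            wide.loc[long.index, common],
            long.loc[:, common],
            check_names=False,
        )

    def test_negative_abundance_rejected(self, small_cohort):
        bad = small_cohort.af.copy()
        bad.iloc[0, 0] = -1.0
        with pytest.raises(DataError):
            Peptidome(small_cohort.catalog, small_cohort.af_peptidome.samples, bad)

    def test_catalog_requires_positive_mass(self):
        with pytest.raises(DataError):
            make_catalog(pd.DataFrame({"catalog_id": ["a"], "mass_da": [-5.0]}))


def test_detection_frequency_by_bin_matches_manual(tiny_samples):
    samples = assign_ga_bins(tiny_samples)
    af = samples[samples["fluid"] == "AF"]
    matrix = pd.DataFrame(
        [[1.0, 0.0], [0.0, 0.0], [2.0, 1.0], [3.0, 0.0]],
        index=af["sample_id"],
        columns=["a", "b"],
    )
    freq = detection_frequency_by_bin(matrix, af)
    assert freq.loc["11-14", "a"] == 0.5
    assert freq.loc["15-17", "a"] == 1.0
    assert freq.loc["15-17", "b"] == 0.5
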
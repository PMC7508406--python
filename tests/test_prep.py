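"""Record filtering and the harmonization / standardization transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from relaxsel.prep import (
    apply_filters,
    compute_abs_cv,
    compute_generations,
    harmonize_direction,
    shift_to_nonnegative,
    standardize_dataset,
    standardize_within,
    summarize_dataset,
    validate_records,
)


class TestComputeGenerations:
    def test_direct_quotient(self):
        assert compute_generations(100, 2) == 50

    def test_zero_elapsed_time(self):
        assert compute_generations(0, 5) == 0

    def test_nonpositive_maturity_rejected(self):
        with pytest.raises(ValueError):
            compute_generations(30, 0)


class TestFilters:
    def test_single_value_group_dropped(self, toy_records):
        kept, log = apply_filters(toy_records, min_values_per_trait=2)
        # (s2, fid) has one record -> dropped; 5 retained
        assert len(kept) == 5
        assert len(log) == 1
        assert "fewer than 2" in log[0]["reason"]
        assert log[0]["study_id"] == "s2"

    def test_high_fear_lines_dropped_with_reason(self, toy_records):
        df = toy_records.copy()
        df.loc[[0, 1], "selected_for_high_fear"] = True
        kept, log = apply_filters(df, min_values_per_trait=1)
        reasons = [e["reason"] for e in log]
        assert reasons.count("high-fear selection line") == 2
        assert not kept["selected_for_high_fear"].any()

    def test_dogs_removed_from_domestication(self, toy_records):
        df = toy_records.copy()
        df.loc[0, "species_id"] = "Canis_familiaris"
        kept, log = apply_filters(df, remove_dogs=True, min_values_per_trait=1)
        assert "Canis_familiaris" not in set(kept["species_id"])
        assert any("dog" in e["reason"] for e in log)

    def test_passthrough_when_all_pass(self, toy_records):
        df = toy_records[toy_records["study_id"] == "s1"].reset_index(drop=True)
        kept, log = apply_filters(df, min_values_per_trait=2)
        pd.testing.assert_frame_equal(kept, df)
        assert log == []

    def test_empty_input_no_error(self, toy_records):
        kept, log = apply_filters(toy_records.iloc[:0])
        assert kept.empty and log == []

    def test_count_conservation(self, toy_records):
        df = toy_records.copy()
        df.loc[0, "selected_for_high_fear"] = True
        kept, log = apply_filters(df, min_values_per_trait=2)
        assert len(kept) + len(log) == len(df)


class TestHarmonize:
    def test_latency_trait_inverted(self, toy_records):
        out = harmonize_direction(toy_records)
        # rows 3-4 carried direction -1
        assert out.loc[3, "raw_mean"] == 5.0
        assert out.loc[4, "raw_mean"] == 3.0
        assert out.loc[0, "raw_mean"] == 1.0  # direction +1 untouched

    def test_sd_unchanged_by_orientation(self, toy_records):
        out = harmonize_direction(toy_records)
        pd.testing.assert_series_equal(out["raw_sd"], toy_records["raw_sd"])


class TestShift:
    def _frame(self, means, trait="t"):
        n = len(means)
        return pd.DataFrame(
            {"context": ["captivity"] * n, "trait_id": [trait] * n,
             "raw_mean": means}
        )

    def test_negative_minimum_shifted_to_zero(self):
        out = shift_to_nonnegative(self._frame([-2.0, 0.0, 3.0]))
        assert list(out["raw_mean"]) == [0.0, 2.0, 5.0]

    def test_nonnegative_group_unchanged(self):
        out = shift_to_nonnegative(self._frame([1.0, 2.0]))
        assert list(out["raw_mean"]) == [1.0, 2.0]

    def test_singleton_negative(self):
        out = shift_to_nonnegative(self._frame([-1.5]))
        assert list(out["raw_mean"]) == [0.0]

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2, max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_pairwise_differences_preserved(self, means):
        out = shift_to_nonnegative(self._frame(means))
        orig = np.asarray(means)
        new = out["raw_mean"].to_numpy()
        np.testing.assert_allclose(
            np.subtract.outer(new, new), np.subtract.outer(orig, orig), atol=1e-6
        )


class TestStandardize:
    def _frame(self, means):
        n = len(means)
        return pd.DataFrame(
            {"context": ["captivity"] * n, "study_id": ["s"] * n,
             "trait_id": ["t"] * n, "raw_mean": means}
        )

    def test_three_point_group(self):
        out = standardize_within(self._frame([1.0, 2.0, 3.0]))
        assert list(out["standardized_mean"]) == [-1.0, 0.0, 1.0]

    def test_degenerate_group_zeroed_with_warning(self):
        with pytest.warns(UserWarning):
            out = standardize_within(self._frame([4.0, 4.0]))
        assert list(out["standardized_mean"]) == [0.0, 0.0]

    def test_zscore_property_and_idempotence(self, rng):
        vals = rng.normal(2.0, 3.0, 15)
        out = standardize_within(self._frame(vals))
        z = out["standardized_mean"]
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)
        # standardizing an already-standardized column changes nothing
        again = standardize_within(
            self._frame(z.to_numpy())
        )["standardized_mean"]
        np.testing.assert_allclose(again, z, atol=1e-12)


class TestAbsCV:
    def test_quotient_and_sign_invariance(self, toy_records):
        df = toy_records.copy()
        out, log = compute_abs_cv(df)
        assert out.loc[0, "abs_cv"] == pytest.approx(0.5)  # 0.5 / 1
        flipped = df.copy()
        flipped["raw_mean"] = -flipped["raw_mean"]
        out2, _ = compute_abs_cv(flipped)
        np.testing.assert_allclose(out["abs_cv"], out2["abs_cv"])

    def test_zero_mean_excluded(self, toy_records):
        df = toy_records.copy()
        df.loc[2, "raw_mean"] = 0.0
        out, log = compute_abs_cv(df)
        assert np.isnan(out.loc[2, "abs_cv"])
        assert len(log) == 1 and "zero mean" in log[0]["reason"]


class TestSummaries:
    def test_mean_records_per_study(self, toy_records):
        s = summarize_dataset(validate_records(toy_records))
        # studies s1 (5 records) and s2 (1 record) -> mean 3.0
        assert s.mean_records_per_study == pytest.approx(3.0)
        assert s.per_context["domestication"]["n_mean_records"] == 6

    def test_traits_per_study_counts_distinct(self, toy_records):
        s = summarize_dataset(validate_records(toy_records))
        # s1 has {fid, vig}, s2 has {fid} -> mean 1.5
        assert s.mean_traits_per_study == pytest.approx(1.5)


class TestFullPrep:
    def test_pipeline_output_schema(self, toy_records):
        std, log = standardize_dataset(toy_records)
        for col in ("standardized_mean", "abs_cv", "weight"):
            assert col in std.columns
        # per-group z-scores: mean 0, sd 1 in every retained group
        for _, g in std.groupby(["context", "study_id", "trait_id"]):
            assert g["standardized_mean"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_weighting_switch(self, toy_records):
        std_n, _ = standardize_dataset(toy_records, weighting="n")
        std_inv, _ = standardize_dataset(toy_records, weighting="inverse_n")
        np.testing.assert_allclose(
            std_n["weight"] * std_inv["weight"], np.ones(len(std_n))
        )
        with pytest.raises(ValueError):
            standardize_dataset(toy_records, weighting="bogus")
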
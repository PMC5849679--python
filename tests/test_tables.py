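"""Data model, IO, normalization and filtering rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phosbench import (
    IntensityTable,
    RatioTable,
    TableFormatError,
    TableParseError,
    read_intensity_table,
    write_intensity_table,
    quantile_normalize,
    filter_localization,
    effective_localization_prob,
    compute_log_ratios,
    filter_min_quantified,
    silac_channel_intensities,
    knn_impute,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

class TestCanonicalLongIO:
    def test_round_trip_identity(self, small_table, tmp_path):
        path = tmp_path / "table.tsv"
        write_intensity_table(small_table, path)
        back = read_intensity_table(path)
        pd.testing.assert_frame_equal(back.values, small_table.values)
        assert list(back.sample_meta["condition"]) == ["dox", "ctrl", "dox"]
        assert list(back.feature_meta["localization_prob"]) == [0.9, 0.5]

    def test_shape_and_missing(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "feature_id\tsample_id\tintensity\n"
            "a\ts1\t1.5\na\ts2\t2\na\ts3\t\n"
            "b\ts1\tNA\nb\ts2\t0\nb\ts3\t3\n"
        )
        t = read_intensity_table(path)
        assert t.shape == (2, 3)
        assert np.isnan(t.values.loc["a", "s3"])
        assert np.isnan(t.values.loc["b", "s1"])

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("feature_id\tsample_id\n" "a\ts1\n")
        with pytest.raises(TableFormatError, match="intensity"):
            read_intensity_table(path)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "feature_id\tsample_id\tintensity\na\ts1\toops\n"
        )
        with pytest.raises(TableParseError, match="oops"):
            read_intensity_table(path)


MAXQUANT_FIXTURE = (
    "id\tIntensity s1\tIntensity s2\tLocalization prob\tReverse\tPotential contaminant\n"
    "1\t100\t200\t0.9\t\t\n"
    "2\t300\t400\t0.5\t\t\n"
    "3\t500\t600\t0.99\t+\t\n"
    "4\t700\t800\t0.8\t\t+\n"
)


class TestMaxQuantDialect:
    def test_reverse_and_contaminant_rows_dropped(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text(MAXQUANT_FIXTURE)
        t = read_intensity_table(path, dialect="maxquant-sites")
        assert list(t.feature_ids) == ["1", "2"]
        assert list(t.sample_ids) == ["s1", "s2"]

    def test_localization_probability_pass_through(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text(MAXQUANT_FIXTURE)
        t = read_intensity_table(path, dialect="maxquant-sites")
        assert list(t.feature_meta["localization_prob"]) == [0.9, 0.5]

    def test_configurable_intensity_pattern(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text(
            "id\tReporter intensity corrected 1\tReporter intensity corrected 2\n"
            "1\t10\t20\n"
        )
        t = read_intensity_table(
            path,
            dialect="maxquant-sites",
            mapping={"intensity_pattern": r"^Reporter intensity corrected (\d+)$"},
        )
        assert t.shape == (1, 2)
        assert t.values.loc["1", "2"] == 20

    def test_missing_id_column(self, tmp_path):
        path = tmp_path / "sites.tsv"
        path.write_text("Intensity s1\n5\n")
        with pytest.raises(TableFormatError, match="'id'"):
            read_intensity_table(path, dialect="maxquant-sites")


def test_invariant_negative_intensity_rejected():
    with pytest.raises(TableFormatError, match="negative"):
        make_table([[-1.0, 2.0]])


def test_invariant_duplicate_feature_ids_rejected():
    values = pd.DataFrame([[1.0], [2.0]], index=["a", "a"], columns=["s1"])
    with pytest.raises(TableFormatError, match="duplicate"):
        IntensityTable(values)


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

class TestQuantileNormalize:
    def test_rank_mean_definition(self):
        t = make_table(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(t).values.to_numpy()
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out, expected)

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 2.0, 5.0])
        t = make_table(np.column_stack([col, col, col]))
        out = quantile_normalize(t).values.to_numpy()
        np.testing.assert_allclose(out, np.column_stack([col, col, col]))

    def test_against_sort_based_oracle(self, rng):
        X = rng.lognormal(0, 1, size=(50, 4))
        out = quantile_normalize(make_table(X)).values.to_numpy()
        # independent oracle: rank/sort/mean
        ref = np.sort(X, axis=0).mean(axis=1)
        expected = np.empty_like(X)
        for j in range(4):
            expected[np.argsort(X[:, j]), j] = ref
        np.testing.assert_allclose(out, expected)

    def test_idempotent_and_rank_preserving(self, rng):
        X = rng.normal(10, 3, size=(30, 3))
        once = quantile_normalize(make_table(X))
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)
        for j in range(3):
            assert (
                np.argsort(once.values.to_numpy()[:, j])
                == np.argsort(X[:, j])
            ).all()

    def test_missing_entries_stay_missing(self, rng):
        X = rng.normal(10, 3, size=(20, 3))
        X[3, 1] = np.nan
        X[7, 2] = np.nan
        out = quantile_normalize(make_table(X)).values.to_numpy()
        assert np.isnan(out[3, 1]) and np.isnan(out[7, 2])
        assert np.isnan(out).sum() == 2

    def test_ties_get_mean_of_tied_rank_targets(self):
        X = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(make_table(X)).values.to_numpy()
        ref = np.sort(X, axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        assert out[0, 0] == out[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out[2, 0] == pytest.approx(ref[2])

    def test_all_missing_column_is_an_error(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="s2"):
            quantile_normalize(make_table(X))


# ---------------------------------------------------------------------------
# Localization filter
# ---------------------------------------------------------------------------

class TestLocalizationFilter:
    def test_threshold_is_inclusive(self):
        t = make_table(
            np.ones((3, 2)), localization_prob=[0.80, 0.75, 0.74]
        )
        kept = filter_localization(t, 0.75)
        assert list(kept.feature_ids) == ["f1", "f2"]

    def test_all_missing_gives_empty_table(self):
        t = make_table(np.ones((2, 2)), localization_prob=[np.nan, np.nan])
        assert filter_localization(t, 0.5).shape == (0, 2)

    def test_mbr_zero_is_missing_evidence_not_failure(self):
        # per-replicate evidence: an MBR-transferred score of 0 is ignored,
        # the 0.9 replicate score carries the feature over the threshold
        assert effective_localization_prob([0.0, 0.9], [True, False]) == 0.9
        # a genuine (non-MBR) zero is a failing score
        assert effective_localization_prob([0.0, 0.9], [False, False]) == 0.0
        assert np.isnan(effective_localization_prob([0.0], [True]))

    def test_scalar_mbr_flagged_zero_dropped_as_missing(self):
        t = make_table(
            np.ones((2, 2)),
            localization_prob=[0.0, 0.8],
            localization_mbr_zero=[True, False],
        )
        kept = filter_localization(t, 0.75)
        assert list(kept.feature_ids) == ["f2"]


# ---------------------------------------------------------------------------
# Ratios
# ---------------------------------------------------------------------------

class TestLogRatios:
    def test_simple_arithmetic(self, small_table):
        ratios = compute_log_ratios(small_table, "dox", "ctrl")
        # replicate 1 pairs s1 (dox) with s2 (ctrl): 8 / 2 -> log2 = 2
        assert ratios.log2_ratios.loc["f1", "dox/ctrl:r1"] == pytest.approx(2.0)

    def test_missing_side_propagates(self, small_table):
        ratios = compute_log_ratios(small_table, "dox", "ctrl")
        # f2 has s3 (dox, rep 2) missing but no ctrl rep 2 at all: column absent
        assert list(ratios.log2_ratios.columns) == ["dox/ctrl:r1"]

    def test_zero_intensity_treated_as_missing(self):
        t = make_table(
            [[4.0, 0.0]], conditions=["dox", "ctrl"], replicates=[1, 1]
        )
        ratios = compute_log_ratios(t, "dox", "ctrl")
        assert np.isnan(ratios.log2_ratios.iloc[0, 0])

    def test_three_replicates_against_elementwise_oracle(self, rng):
        X = rng.lognormal(3, 1, size=(10, 6))
        X[rng.random((10, 6)) < 0.2] = np.nan
        t = make_table(
            X,
            conditions=["dox", "dox", "dox", "ctrl", "ctrl", "ctrl"],
            replicates=[1, 2, 3, 1, 2, 3],
        )
        ratios = compute_log_ratios(t, "dox", "ctrl").log2_ratios.to_numpy()
        assert ratios.shape == (10, 3)
        with np.errstate(invalid="ignore"):
            expected = np.log2(X[:, :3] / X[:, 3:])
        np.testing.assert_allclose(ratios, expected)

    def test_unknown_condition_label(self, small_table):
        with pytest.raises(ValueError, match="nope"):
            compute_log_ratios(small_table, "nope", "ctrl")


class TestMinQuantifiedFilter:
    @pytest.fixture
    def two_rep_feature(self):
        vals = pd.DataFrame(
            {"c:r1": [1.0, np.nan], "c:r2": [2.0, np.nan], "c:r3": [np.nan, np.nan]},
            index=["hit", "empty"],
        )
        return RatioTable(vals)

    def test_counting(self, two_rep_feature):
        assert list(filter_min_quantified(two_rep_feature, 2).feature_ids) == ["hit"]
        assert list(filter_min_quantified(two_rep_feature, 3).feature_ids) == []

    def test_min_one_drops_all_missing_rows(self, two_rep_feature):
        assert list(filter_min_quantified(two_rep_feature, 1).feature_ids) == ["hit"]

    def test_against_counting_oracle(self, rng):
        X = rng.normal(size=(40, 3))
        X[rng.random((40, 3)) < 0.4] = np.nan
        rt = RatioTable(pd.DataFrame(X, index=[f"f{i}" for i in range(40)]))
        for k in (1, 2, 3):
            kept = set(filter_min_quantified(rt, k).feature_ids)
            oracle = {
                f"f{i}" for i in range(40) if np.sum(~np.isnan(X[i])) >= k
            }
            assert kept == oracle

    def test_out_of_range(self, two_rep_feature):
        with pytest.raises(ValueError):
            filter_min_quantified(two_rep_feature, 4)
        with pytest.raises(ValueError):
            filter_min_quantified(two_rep_feature, 0)


def test_filter_chains_commute(rng):
    """Localization and min-replicate filters are row filters: order-free."""
    X = rng.lognormal(3, 1, size=(30, 6))
    X[rng.random((30, 6)) < 0.3] = np.nan
    probs = rng.random(30)
    t = make_table(
        X,
        conditions=["a", "a", "a", "b", "b", "b"],
        replicates=[1, 2, 3, 1, 2, 3],
        localization_prob=probs,
    )
    route1 = filter_min_quantified(
        compute_log_ratios(filter_localization(t, 0.5), "a", "b"), 2
    )
    all_ratios = filter_min_quantified(compute_log_ratios(t, "a", "b"), 2)
    keep = [f for f in all_ratios.feature_ids if f in set(filter_localization(t, 0.5).feature_ids)]
    route2 = all_ratios.log2_ratios.loc[keep]
    pd.testing.assert_frame_equal(route1.log2_ratios, route2)


# ---------------------------------------------------------------------------
# SILAC channel split
# ---------------------------------------------------------------------------

class TestSilacChannelIntensities:
    def test_symmetric_split(self):
        assert silac_channel_intensities(6.0, 1.0, 1.0) == (2.0, 2.0, 2.0)

    def test_hand_solved_constraint(self):
        # light * (1 + 2 + 4) = 14 -> light 2, medium 4, heavy 8
        assert silac_channel_intensities(14.0, 2.0, 4.0) == (2.0, 4.0, 8.0)

    def test_zero_total(self):
        assert silac_channel_intensities(0.0, 2.0, 4.0) == (0.0, 0.0, 0.0)

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(ValueError):
            silac_channel_intensities(1.0, 0.0, 1.0)

    @settings(deadline=None, max_examples=50)
    @given(
        total=st.floats(0, 1e9),
        rml=st.floats(1e-3, 1e3),
        rhl=st.floats(1e-3, 1e3),
    )
    def test_outputs_sum_to_total(self, total, rml, rhl):
        l, m, h = silac_channel_intensities(total, rml, rhl)
        assert l + m + h == pytest.approx(total, rel=1e-12, abs=1e-12)
        assert m == pytest.approx(l * rml, rel=1e-12, abs=1e-300)


# ---------------------------------------------------------------------------
# KNN imputation
# ---------------------------------------------------------------------------

def _knn_oracle(X, k):
    """Exhaustive-distance nearest-neighbour imputation."""
    X = X.copy()
    orig = X.copy()
    n = X.shape[0]
    for i, j in np.argwhere(np.isnan(orig)):
        cands = []
        for other in range(n):
            if other == i or np.isnan(orig[other, j]):
                continue
            joint = ~np.isnan(orig[i]) & ~np.isnan(orig[other])
            if not joint.any():
                continue
            dist = np.sqrt(np.sum((orig[i, joint] - orig[other, joint]) ** 2))
            cands.append((dist, other))
        cands.sort()
        if cands:
            X[i, j] = np.mean([orig[o, j] for _, o in cands[:k]])
    return X


class TestKnnImpute:
    def _rt(self, X):
        return RatioTable(pd.DataFrame(np.asarray(X, dtype=float)))

    def test_constant_neighborhood(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, np.nan]])
        out = knn_impute(self._rt(X), k=2).log2_ratios.to_numpy()
        assert out[2, 2] == pytest.approx(3.0)

    def test_fully_observed_is_identity(self, rng):
        X = rng.normal(size=(6, 4))
        out = knn_impute(self._rt(X), k=3).log2_ratios.to_numpy()
        np.testing.assert_array_equal(out, X)

    def test_against_brute_force_oracle(self, rng):
        X = rng.normal(size=(8, 4))
        holes = [(0, 1), (3, 2), (6, 0)]
        for i, j in holes:
            X[i, j] = np.nan
        out = knn_impute(self._rt(X), k=2).log2_ratios.to_numpy()
        np.testing.assert_allclose(out, _knn_oracle(X, 2))

    def test_observed_never_altered_and_bounded(self, rng):
        X = rng.normal(size=(15, 4))
        mask = rng.random((15, 4)) < 0.2
        X[mask] = np.nan
        out = knn_impute(self._rt(X), k=3).log2_ratios.to_numpy()
        obs = ~np.isnan(X)
        np.testing.assert_array_equal(out[obs], X[obs])
        imputed = np.isnan(X) & ~np.isnan(out)
        assert out[imputed].min() >= np.nanmin(X) - 1e-12
        assert out[imputed].max() <= np.nanmax(X) + 1e-12

    def test_k_clamped_with_warning(self):
        X = np.array([[1.0, 2.0], [1.5, np.nan], [2.0, 4.0]])
        with pytest.warns(UserWarning, match="clamped"):
            out = knn_impute(self._rt(X), k=10).log2_ratios.to_numpy()
        assert out[1, 1] == pytest.approx(3.0)

    def test_unimputable_hole_left_missing(self):
        X = np.array([[np.nan, np.nan], [np.nan, np.nan], [1.0, 2.0]])
        with pytest.warns(UserWarning, match="no computable neighbour"):
            out = knn_impute(self._rt(X), k=1).log2_ratios.to_numpy()
        assert np.isnan(out[0, 0]) and np.isnan(out[1, 1])
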
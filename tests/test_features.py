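import math

import numpy as np
import pandas as pd
import pytest

from pancox import DataError
from pancox.features import (FeatureConfig, FeatureMatrix, LAB_SUMMARY_NAMES,
                             approximate_entropy, encode_genomics, finalize_matrix,
                             make_meta, screen_features, summarize_lab_series,
                             zero_fill_out_of_scope)


def lab_table(sid, analyte, times, values, lln=0.0, uln=10.0):
    return pd.DataFrame({"subject_id": sid, "analyte_id": analyte,
                         "obs_time": times, "value": values,
                         "lln": lln, "uln": uln})


def naive_summaries(times, values, lln, uln, window, full_span, m=2, rf=0.2):
    """Definition-level recomputation, written independently of the package."""
    keep = [(t, v) for t, v in sorted(zip(times, values)) if -window <= t < 0]
    norm = [(v - lln) / (uln - lln) for _, v in keep]
    raw = [v for _, v in keep]
    ts = [t for t, _ in keep]
    out = {}
    n = len(norm)
    out["n_tests"] = float(n)
    out["test_rate"] = n / min(window, max(full_span, 1.0))
    if n == 0:
        for k in ("mean", "median", "variance", "max", "min", "apen",
                  "diff_last2", "slope_last2", "prop_abnormal"):
            out[k] = math.nan
        return out
    out["mean"] = sum(norm) / n
    srt = sorted(norm)
    out["median"] = (srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2)
    out["max"] = max(norm)
    out["min"] = min(norm)
    out["prop_abnormal"] = sum(1 for v in raw if v < lln or v > uln) / n
    if n >= 2:
        mu = out["mean"]
        out["variance"] = sum((v - mu) ** 2 for v in norm) / (n - 1)
        out["diff_last2"] = norm[-1] - norm[-2]
        dt = ts[-1] - ts[-2]
        out["slope_last2"] = (norm[-1] - norm[-2]) / dt if dt > 0 else math.nan
    else:
        out["variance"] = out["diff_last2"] = out["slope_last2"] = math.nan
    sd = float(np.std(norm))
    out["apen"] = naive_apen(norm, m, rf * sd)
    return out


def naive_apen(x, m, r):
    n = len(x)
    if n < m + 1:
        return math.nan
    if r <= 0:
        return 0.0

    def phi(k):
        total = 0.0
        count = n - k + 1
        for i in range(count):
            matches = 0
            for j in range(count):
                if max(abs(x[i + u] - x[j + u]) for u in range(k)) <= r:
                    matches += 1
            total += math.log(matches / count)
        return total / count

    return phi(m) - phi(m + 1)


class TestLabSummaries:
    def test_single_observation_at_uln(self):
        labs = lab_table("s1", "a", [-5.0], [10.0])
        out = summarize_lab_series(labs, 60).loc["s1"]
        for stat in ("mean", "median", "max", "min"):
            assert out[f"a_w60_{stat}"] == 1.0
        assert out["a_w60_n_tests"] == 1.0
        assert out["a_w60_prop_abnormal"] == 0.0  # limits are inclusive-normal
        for stat in ("variance", "diff_last2", "slope_last2"):
            assert np.isnan(out[f"a_w60_{stat}"])

    def test_limits_count_as_normal(self):
        labs = lab_table("s1", "a", [-10.0, -5.0], [0.0, 10.0])
        out = summarize_lab_series(labs, 60).loc["s1"]
        assert out["a_w60_prop_abnormal"] == 0.0

    def test_window_is_half_open(self):
        # obs at exactly -60 included, at 0 excluded
        labs = lab_table("s1", "a", [-60.0, 0.0], [5.0, 5.0])
        out = summarize_lab_series(labs, 60).loc["s1"]
        assert out["a_w60_n_tests"] == 1.0

    def test_irregular_series_matches_naive_oracle(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(-120, -0.5, 20))
        values = rng.normal(5, 3, 20)
        lln, uln = 2.0, 8.0
        labs = lab_table("s1", "a", times, values, lln, uln)
        out = summarize_lab_series(labs, 60).loc["s1"]
        oracle = naive_summaries(times, values, lln, uln, 60, -times.min())
        for stat in LAB_SUMMARY_NAMES:
            got = out[f"a_w60_{stat}"]
            want = oracle[stat]
            if math.isnan(want):
                assert np.isnan(got), stat
            else:
                assert got == pytest.approx(want, rel=1e-10), stat

    @pytest.mark.parametrize("seed", range(10))
    def test_property_random_series_match_oracle(self, seed):
        # 10 parametrized cases x 10 series = 100 random series total
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n = int(rng.integers(0, 15))
            times = np.sort(rng.uniform(-200, -0.01, n)).round(1)
            values = rng.normal(4, 4, n).round(2)
            labs = lab_table("s1", "a", times, values, 1.0, 7.0)
            if n == 0:
                continue
            window = int(rng.choice([60, 720]))
            out = summarize_lab_series(labs, window).loc["s1"]
            oracle = naive_summaries(times, values, 1.0, 7.0, window, -times.min())
            for stat in LAB_SUMMARY_NAMES:
                got, want = out[f"a_w{window}_{stat}"], oracle[stat]
                if isinstance(want, float) and math.isnan(want):
                    assert np.isnan(got), stat
                else:
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-12), stat

    def test_no_window_obs_counts_zero_values_missing(self):
        labs = lab_table("s1", "a", [-300.0], [5.0])
        out = summarize_lab_series(labs, 60).loc["s1"]
        assert out["a_w60_n_tests"] == 0.0
        assert out["a_w60_test_rate"] == 0.0
        assert np.isnan(out["a_w60_mean"])

    def test_bad_limits_raise(self):
        labs = lab_table("s1", "a", [-5.0], [5.0], lln=10.0, uln=2.0)
        with pytest.raises(DataError):
            summarize_lab_series(labs, 60)

    def test_nonfinite_values_raise(self):
        labs = lab_table("s1", "a", [-5.0], [np.inf])
        with pytest.raises(DataError):
            summarize_lab_series(labs, 60)


class TestApproximateEntropy:
    def test_constant_series_zero(self):
        assert approximate_entropy(np.full(10, 3.3), m=2) == 0.0

    def test_too_short_returns_nan(self):
        assert np.isnan(approximate_entropy(np.array([1.0, 2.0]), m=2))

    def test_hand_series_matches_enumeration(self):
        x = [0.1, 0.9, 0.2, 0.8, 0.15, 0.85]
        r = 0.2 * float(np.std(x))
        assert approximate_entropy(np.array(x), m=2, r=r) == pytest.approx(
            naive_apen(x, 2, r), abs=1e-12)

    def test_periodic_below_random_on_average(self):
        rng = np.random.default_rng(0)
        periodic, random_ = [], []
        for _ in range(100):
            n = 30
            phase = rng.uniform(0, 2 * np.pi)
            p = np.sin(np.arange(n) * np.pi / 2 + phase)
            u = rng.uniform(-1, 1, n)
            periodic.append(approximate_entropy(p, 2, r=0.2 * np.std(p)))
            random_.append(approximate_entropy(u, 2, r=0.2 * np.std(u)))
        assert np.mean(periodic) < np.mean(random_)


class TestEncodeGenomics:
    @staticmethod
    def _profiles(rows):
        return pd.DataFrame(rows, columns=["subject_id", "gene_id",
                                           "variant_class", "status"])

    @staticmethod
    def _embeddings():
        return pd.DataFrame([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]],
                            index=["G1", "G2", "G3"], columns=["e0", "e1"])

    def test_no_alterations_zero_pathways_and_embeddings(self):
        prof = self._profiles([("s1", "G1", "short_variant", 0),
                               ("s1", "G2", "copy_number", 0)])
        fm = encode_genomics(prof, {"p1": ("G1", "G2")}, self._embeddings())
        row = fm.values.loc["s1"]
        assert row["pathway_p1"] == 0.0
        assert row["embavg_e0"] == 0.0 and row["embavg_e1"] == 0.0

    def test_single_gene_embedding_equals_vector(self):
        prof = self._profiles([("s1", "G1", "short_variant", 1)])
        fm = encode_genomics(prof, {"p1": ("G1",)}, self._embeddings())
        assert fm.values.loc["s1", "embavg_e0"] == 1.0
        assert fm.values.loc["s1", "embavg_e1"] == 0.0
        assert fm.values.loc["s1", "pathway_p1"] == 1.0

    def test_three_genes_componentwise_mean(self):
        prof = self._profiles([("s1", "G1", "short_variant", 1),
                               ("s1", "G2", "copy_number", 1),
                               ("s1", "G3", "rearrangement", 1)])
        fm = encode_genomics(prof, {}, self._embeddings())
        assert fm.values.loc["s1", "embavg_e0"] == pytest.approx(0.5)
        assert fm.values.loc["s1", "embavg_e1"] == pytest.approx(0.5)

    def test_unmeasured_becomes_missing(self):
        prof = self._profiles([("s1", "G1", "short_variant", pd.NA),
                               ("s1", "G2", "short_variant", 1)])
        prof["status"] = prof["status"].astype("Int64")
        fm = encode_genomics(prof, {}, self._embeddings())
        assert np.isnan(fm.values.loc["s1", "G1_short_variant"])
        assert fm.values.loc["s1", "G2_short_variant"] == 1.0

    def test_missing_embedding_gene_named_in_error(self):
        prof = self._profiles([("s1", "G9", "short_variant", 1)])
        with pytest.raises(DataError, match="G9"):
            encode_genomics(prof, {}, self._embeddings())

    def test_duplicate_records_rejected(self):
        prof = self._profiles([("s1", "G1", "short_variant", 1),
                               ("s1", "G1", "short_variant", 0)])
        with pytest.raises(DataError):
            encode_genomics(prof, {}, self._embeddings())


def _matrix(values: pd.DataFrame, modality="treatment", scopes=None) -> FeatureMatrix:
    meta = make_meta(values.columns, modality)
    if scopes:
        for name, scope in scopes.items():
            meta.loc[name, "scope"] = scope
            meta.loc[name, "modality"] = "cancer_specific"
    return FeatureMatrix(values, meta)


class TestScreening:
    def test_dummy_count_threshold(self):
        n = 100
        vals = pd.DataFrame({
            "d19": [1.0] * 19 + [0.0] * (n - 19),
            "d20": [1.0] * 20 + [0.0] * (n - 20),
        }, index=[f"s{i}" for i in range(n)])
        out = screen_features(_matrix(vals), FeatureConfig(), list(vals.index))
        assert "d19" not in out.feature_names
        assert "d20" in out.feature_names
        reasons = {r["feature"]: r["reason"] for r in out.stats["screen_report"]}
        assert reasons["d19"] == "near_zero_variance"

    def test_missing_fraction_boundary(self):
        n = 100
        col31 = np.arange(n, dtype=float)
        col31[:31] = np.nan
        col29 = np.arange(n, dtype=float)
        col29[:29] = np.nan
        vals = pd.DataFrame({"m31": col31, "m29": col29},
                            index=[f"s{i}" for i in range(n)])
        out = screen_features(_matrix(vals), FeatureConfig(), list(vals.index))
        assert "m31" not in out.feature_names
        assert "m29" in out.feature_names

    def test_constant_removed(self):
        vals = pd.DataFrame({"c": np.ones(50), "x": np.arange(50.0)},
                            index=[f"s{i}" for i in range(50)])
        out = screen_features(_matrix(vals), FeatureConfig(), list(vals.index))
        assert out.feature_names == ["x"]

    def test_verdicts_use_training_rows_only(self):
        idx = [f"s{i}" for i in range(40)]
        vals = pd.DataFrame({"d": [1.0] * 25 + [0.0] * 15}, index=idx)
        # only 15 positives among training rows s10..s39 -> removed
        out = screen_features(_matrix(vals), FeatureConfig(), idx[10:])
        assert "d" not in out.feature_names


class TestFinalize:
    def test_outlier_truncated_at_three(self):
        idx = [f"s{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        x[0] = x[1:].mean() + 5 * x[1:].std(ddof=1)
        vals = pd.DataFrame({"x": x}, index=idx)
        out = finalize_matrix(_matrix(vals), idx[1:])
        assert out.values.loc["s0", "x"] == 3.0

    def test_cancer_specific_out_of_scope_zero(self):
        idx = ["s0", "s1", "s2", "s3"]
        vals = pd.DataFrame({"gleason": [7.0, 8.0, np.nan, np.nan]}, index=idx)
        fm = _matrix(vals, scopes={"gleason": ("prostate",)})
        cancers = pd.Series(["prostate", "prostate", "lung", "lung"], index=idx)
        out = zero_fill_out_of_scope(fm, cancers)
        assert (out.values.loc[["s2", "s3"], "gleason"] == 0.0).all()
        assert out.values.loc["s0", "gleason"] == 7.0

    def test_majority_reference_level_dropped(self):
        idx = [f"s{i}" for i in range(10)]
        vals = pd.DataFrame({"grade": ["M"] * 6 + ["A"] * 3 + ["B"]}, index=idx)
        out = finalize_matrix(_matrix(vals), idx)
        assert "grade=M" not in out.values.columns
        assert {"grade=A", "grade=B"} <= set(out.values.columns)
        assert set(np.unique(out.values[["grade=A", "grade=B"]])) <= {0.0, 1.0}

    def test_dummy_columns_pass_through(self):
        idx = [f"s{i}" for i in range(30)]
        vals = pd.DataFrame({"d": ([1.0] * 21 + [0.0] * 9)}, index=idx)
        out = finalize_matrix(_matrix(vals), idx)
        assert set(np.unique(out.values["d"])) == {0.0, 1.0}

    def test_refinalize_is_identity(self):
        idx = [f"s{i}" for i in range(25)]
        vals = pd.DataFrame({"x": np.random.default_rng(1).normal(size=25)}, index=idx)
        once = finalize_matrix(_matrix(vals), idx)
        twice = finalize_matrix(once, idx)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_zero_training_sd_errors(self):
        idx = [f"s{i}" for i in range(10)]
        vals = pd.DataFrame({"x": [1.0] * 5 + list(range(5))}, index=idx)
        with pytest.raises(DataError, match="zero training SD"):
            finalize_matrix(_matrix(vals), idx[:5])

    def test_fitted_stats_pure_function_of_training_rows(self):
        idx = [f"s{i}" for i in range(30)]
        rng = np.random.default_rng(2)
        vals = pd.DataFrame({"x": rng.normal(size=30)}, index=idx)
        out1 = finalize_matrix(_matrix(vals), idx[:20])
        vals2 = vals.copy()
        vals2.loc[idx[20:], "x"] += 100.0  # perturb test rows only
        out2 = finalize_matrix(_matrix(vals2), idx[:20])
        assert out1.stats["finalize"] == out2.stats["finalize"]
        pd.testing.assert_frame_equal(out1.values.loc[idx[:20]],
                                      out2.values.loc[idx[:20]])

    def test_feature_count_bookkeeping(self):
        idx = [f"s{i}" for i in range(30)]
        rng = np.random.default_rng(3)
        vals = pd.DataFrame({
            "x1": rng.normal(size=30),
            "x2": rng.normal(size=30),
            "cat3": rng.choice(["a", "b", "c"], size=30),
            "dummy": (rng.uniform(size=30) < 0.8).astype(float),
        }, index=idx)
        out = finalize_matrix(_matrix(vals), idx)
        n_levels = vals["cat3"].nunique()
        expected = 4 - 1 + (n_levels - 1)  # cat3 expands to levels-1 columns
        assert len(out.feature_names) == expected
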
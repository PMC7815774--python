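"""Statistical layer: planted-dependency importance recovery, binning,
nonparametric testing and location histograms."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scolisim import analytics
from scolisim.analytics import (
    FEATURES,
    bin_numeric,
    feature_importance,
    location_histogram,
    omnibus_and_pairwise,
)
from scolisim.geometry import LEVELS

PATTERNS = (
    "segmental",
    "convex_minimal",
    "apical_key_vertebrae",
    "alternate",
    "convex_alternate",
    "periapical_dropout",
    "convex_periapical_dropout",
)


def synthetic_records(n, rng, metric_fn, noise=1.0):
    """Record table with independent features and a planted metric."""
    df = pd.DataFrame(
        {
            "lenke": rng.integers(1, 7, n),
            "cobb": rng.uniform(36.8, 84.6, n),
            "pattern": rng.choice(PATTERNS, n),
            "instr_len": rng.integers(9, 14, n),
            "apex": rng.choice(LEVELS[5:12], n),
            "apex_rot": rng.uniform(0, 35, n),
            "upper_cur": rng.choice(LEVELS[2:8], n),
            "lower_cur": rng.choice(LEVELS[10:16], n),
            "convexity": rng.choice(["levo", "dextro"], n),
            "uiv": rng.choice(LEVELS[0:6], n),
            "liv": rng.choice(LEVELS[11:17], n),
            "d_ll": rng.choice([0.0, 10.0, 20.0, 30.0], n),
            "d_tk": rng.choice([0.0, 10.0, 20.0, 30.0], n),
            "stress_offset": rng.integers(-3, 4, n),
            "force_offset": rng.integers(-5, 6, n),
            "feasible": True,
        }
    )
    df["max_rod_stress"] = metric_fn(df) + noise * rng.normal(size=n)
    df["max_screw_force"] = df["max_rod_stress"]
    return df


class TestFeatureImportance:
    def test_planted_numeric_dependency(self):
        rng = np.random.default_rng(0)
        df = synthetic_records(2000, rng, lambda d: 3.0 * d["cobb"], noise=0.5)
        rep = feature_importance(df, "max_rod_stress", seed=0)
        assert rep.importances["cobb"] == 1.0
        assert (rep.importances.drop("cobb") < 0.05).all()

    def test_planted_categorical_dependency(self):
        rng = np.random.default_rng(1)
        offsets = {p: 10.0 * i for i, p in enumerate(PATTERNS)}
        df = synthetic_records(2000, rng, lambda d: d["pattern"].map(offsets), noise=0.5)
        rep = feature_importance(df, "max_rod_stress", seed=0)
        assert rep.importances.index[0] == "pattern"

    def test_duplicated_table_identical_report(self):
        rng = np.random.default_rng(2)
        df = synthetic_records(500, rng, lambda d: 2.0 * d["cobb"])
        a = feature_importance(df, "max_rod_stress", seed=3)
        b = feature_importance(df.copy(), "max_rod_stress", seed=3)
        pd.testing.assert_series_equal(a.importances, b.importances)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        df = synthetic_records(500, rng, lambda d: 2.0 * d["cobb"])
        a = feature_importance(df, "max_rod_stress", seed=3)
        b = feature_importance(
            df.sample(frac=1.0, random_state=0).reset_index(drop=True),
            "max_rod_stress",
            seed=3,
        )
        pd.testing.assert_series_equal(a.importances, b.importances)

    def test_constant_metric_degenerate(self):
        rng = np.random.default_rng(4)
        df = synthetic_records(300, rng, lambda d: 0.0, noise=0.0)
        rep = feature_importance(df, "max_rod_stress")
        assert rep.degenerate
        assert (rep.importances == 0.0).all()

    def test_normalization_max_is_one(self):
        rng = np.random.default_rng(5)
        df = synthetic_records(400, rng, lambda d: d["cobb"] + 0.3 * d["apex_rot"])
        rep = feature_importance(df, "max_rod_stress")
        assert rep.importances.max() == 1.0
        assert (rep.importances >= 0.0).all()
        assert set(rep.importances.index) == set(FEATURES)

    def test_planted_order_recovery_rate(self):
        """Importance ORDER matches planted effect magnitudes in >= 95%
        of 20 seeded runs (cobb > pattern > apex_rot)."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            offsets = {p: 8.0 * i for i, p in enumerate(PATTERNS)}
            df = synthetic_records(
                1200,
                rng,
                lambda d: 2.0 * d["cobb"] + d["pattern"].map(offsets) + 0.5 * d["apex_rot"],
                noise=2.0,
            )
            rep = feature_importance(df, "max_rod_stress", seed=seed)
            imp = rep.importances
            if imp["cobb"] > imp["pattern"] > imp["apex_rot"] > imp.drop(["cobb", "pattern", "apex_rot"]).max():
                hits += 1
        assert hits / 20 >= 0.95


class TestBinning:
    def test_half_open_bin_assignment(self):
        df = pd.DataFrame({"cobb": [37.0, 40.0, 44.9], "feasible": True})
        groups = bin_numeric(df, "cobb", 5.0, min_size=1)
        assert (35.0, 40.0) in groups
        assert list(groups[(40.0, 45.0)]["cobb"]) == [40.0, 44.9]

    def test_small_bins_dropped(self):
        df = pd.DataFrame({"cobb": [37.0, 37.5, 38.0, 52.0], "feasible": True})
        groups = bin_numeric(df, "cobb", 5.0)
        assert (50.0, 55.0) not in groups
        assert (35.0, 40.0) in groups

    def test_empty_table(self):
        assert bin_numeric(pd.DataFrame({"cobb": []}), "cobb", 5.0) == {}

    def test_non_numeric_feature_rejected(self):
        df = pd.DataFrame({"pattern": ["a", "b", "c"]})
        with pytest.raises(TypeError):
            bin_numeric(df, "pattern", 5.0)


class TestGroupTests:
    def test_type_one_error_calibration(self):
        """Kruskal-Wallis omnibus rejects at ~5% under the null."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = {k: rng.normal(size=20) for k in range(5)}
            rep = omnibus_and_pairwise(groups)
            if rep.omnibus_p < 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_power_for_separated_groups(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.0, 1.0, 50)
        b = rng.normal(3.0, 1.0, 50)
        rep = omnibus_and_pairwise({"a": a, "b": b})
        assert rep.omnibus_p < 0.05
        assert rep.pairwise_p.loc["a", "b"] < 1e-3

    def test_identical_groups_adjusted_p_is_one(self):
        x = np.arange(30.0)
        rep = omnibus_and_pairwise({"a": x, "b": x.copy(), "c": x + 5.0})
        if rep.pairwise_p is not None:
            assert rep.pairwise_p.loc["a", "b"] == 1.0

    def test_bonferroni_matches_hand_computation(self):
        """Three-group fixture: adjusted p = min(1, raw * 3)."""
        rng = np.random.default_rng(13)
        groups = {
            "a": rng.normal(0, 1, 25),
            "b": rng.normal(1.0, 1, 25),
            "c": rng.normal(2.0, 1, 25),
        }
        rep = omnibus_and_pairwise(groups)
        assert rep.pairwise_p is not None
        for la, lb in (("a", "b"), ("a", "c"), ("b", "c")):
            raw = stats.ranksums(groups[la], groups[lb]).pvalue
            assert rep.pairwise_p.loc[la, lb] == pytest.approx(min(1.0, raw * 3), rel=1e-12)
            assert rep.pairwise_p.loc[lb, la] == rep.pairwise_p.loc[la, lb]

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError):
            omnibus_and_pairwise({"a": [1.0, 2.0, 3.0]})


class TestLocationHistogram:
    def test_all_maxima_at_apex(self):
        df = pd.DataFrame({"stress_offset": [0] * 7, "feasible": True})
        counts = location_histogram(df, "stress")
        assert list(counts.index) == [0]
        assert counts.iloc[0] == 7

    def test_counts_conserve_records(self):
        rng = np.random.default_rng(14)
        df = synthetic_records(300, rng, lambda d: d["cobb"])
        counts = location_histogram(df, "force")
        assert counts.sum() == len(df)

    def test_unknown_kind_rejected(self):
        df = pd.DataFrame({"stress_offset": [0], "feasible": True})
        with pytest.raises(ValueError):
            location_histogram(df, "torque")
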
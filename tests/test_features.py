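import numpy as np
import pandas as pd
import pytest

from oracles import (
    band_power_bruteforce,
    moments_bruteforce,
    periodogram_bruteforce,
    zhist_bruteforce,
)
from stridelab.features import (
    DEFAULT_CATALOG,
    barometer_feature_names,
    build_catalog,
    build_instance_table,
    extract_baro_matrix,
    extract_barometer_features,
    extract_inertial_features,
    extract_inertial_matrix,
    inertial_feature_names,
    rank_features_oob,
    select_features,
)
from stridelab.preprocessing import Clip


def _random_clip(rng, scale=1.0):
    return scale * rng.normal(size=(500, 3))


def _make_clip(rng, activity="Walking", subject="S0", baro=True):
    return Clip(subject_id=subject, session="Lab1", environment="lab",
                activity=activity, start_s=0.0, bout_id="b0",
                accel=_random_clip(rng), gyro=_random_clip(rng),
                baro=rng.normal(1013, 0.05, 60) if baro else None,
                bout_duration_s=30.0)


class TestCatalogArithmetic:
    def test_total_counts(self):
        cat = build_catalog()
        assert cat.n_features == 270
        assert len(cat.by_sensor("acc")) == 131
        assert len(cat.by_sensor("gyr")) == 131
        assert len(cat.by_sensor("baro")) == 8
        assert len(set(cat.names)) == 270

    def test_per_axis_structure(self):
        names = inertial_feature_names("acc")
        assert len(names) == 131
        for axis in ("x", "y", "z"):
            per_axis = [n for n in names if n.startswith(f"acc_{axis}_")]
            assert len(per_axis) == 38
            assert sum(1 for n in per_axis if "_bp" in n) == 20
            assert sum(1 for n in per_axis if "zhist" in n) == 4

    def test_every_definition_row_covered(self):
        """Each row of the published feature tables maps to catalogue entries."""
        cat = DEFAULT_CATALOG
        inertial_defs = {"basic", "moments", "zscore_hist", "deriv_moments",
                         "spectrum_moments", "band_power", "pearson_corr",
                         "cross_product", "abs_cross_product",
                         "mean_squared_norm", "sum_axial_sd"}
        baro_defs = {"deriv_moments", "dispersion", "regression_slope"}
        for sensor, expected in (("acc", inertial_defs), ("gyr", inertial_defs),
                                 ("baro", baro_defs)):
            seen = {cat.definition_of[n] for n in cat.by_sensor(sensor)}
            assert expected <= seen

    def test_catalog_is_stable(self):
        assert build_catalog().names == build_catalog().names


class TestInertialFeatures:
    def test_returns_exactly_131_values(self, rng):
        vals = extract_inertial_features(_random_clip(rng), "acc")
        assert len(vals) == 131
        assert all(np.isfinite(v) for v in vals.values())

    def test_constant_clip_conventions(self):
        vals = extract_inertial_features(np.full((500, 3), 3.7), "acc")
        assert vals["acc_x_range"] == 0.0
        assert vals["acc_x_sd"] == 0.0
        assert vals["acc_x_skew"] == 0.0 and vals["acc_x_kurt"] == 0.0
        assert vals["acc_x_d_mean"] == 0.0 and vals["acc_x_d_sd"] == 0.0
        assert all(vals[f"acc_x_bp{i}"] == 0.0 for i in range(20))
        assert all(vals[f"acc_x_zhist{i}"] == 0.0 for i in range(4))
        assert vals["acc_corr_xy"] == 0.0
        assert vals["acc_msn"] == pytest.approx(3 * 3.7 ** 2)

    def test_pure_sine_band_power(self):
        t = np.arange(500) / 50.0
        clip = np.zeros((500, 3))
        clip[:, 0] = np.sin(2 * np.pi * 2.0 * t)
        vals = extract_inertial_features(clip, "acc")
        bands = np.array([vals[f"acc_x_bp{i}"] for i in range(20)])
        assert np.argmax(bands) == 4  # the [2.0, 2.5) Hz bin
        ref = band_power_bruteforce(clip[:, 0], 50.0, 2.0, 2.5)
        assert vals["acc_x_bp4"] == pytest.approx(ref, rel=1e-6)

    def test_moment_features_match_bruteforce(self, rng):
        """All moment-type features agree with naive reference code."""
        for _ in range(20):
            clip = _random_clip(rng, scale=rng.uniform(0.1, 5.0))
            vals = extract_inertial_features(clip, "acc")
            for ai, axis in enumerate("xyz"):
                x = clip[:, ai]
                mu, sd, skew, kurt = moments_bruteforce(x)
                assert vals[f"acc_{axis}_mean"] == pytest.approx(mu, rel=1e-9, abs=1e-12)
                assert vals[f"acc_{axis}_sd"] == pytest.approx(sd, rel=1e-9)
                assert vals[f"acc_{axis}_skew"] == pytest.approx(skew, rel=1e-9, abs=1e-12)
                assert vals[f"acc_{axis}_kurt"] == pytest.approx(kurt, rel=1e-9)
                q75, q25 = np.percentile(x, [75, 25])
                assert vals[f"acc_{axis}_iqr"] == pytest.approx(q75 - q25, rel=1e-9)
                zh = zhist_bruteforce(x)
                for i in range(4):
                    assert vals[f"acc_{axis}_zhist{i}"] == pytest.approx(zh[i], abs=1e-12)
                d = np.diff(x) * 50.0
                dm, dsd, dskew, dkurt = moments_bruteforce(d)
                assert vals[f"acc_{axis}_d_sd"] == pytest.approx(dsd, rel=1e-9)
                assert vals[f"acc_{axis}_d_kurt"] == pytest.approx(dkurt, rel=1e-9)
            x, y = clip[:, 0], clip[:, 1]
            assert vals["acc_corr_xy"] == pytest.approx(np.corrcoef(x, y)[0, 1], rel=1e-9)
            assert vals["acc_xprod_raw_xy"] == pytest.approx((x * y).mean(), rel=1e-9)
            rms = lambda a: np.sqrt((a ** 2).mean())
            assert vals["acc_xprod_norm_xy"] == pytest.approx(
                (x * y).mean() / (rms(x) * rms(y)), rel=1e-9)
            assert vals["acc_absxprod_raw_xy"] == pytest.approx(np.abs(x * y).mean(), rel=1e-9)
            assert vals["acc_sum_sd"] == pytest.approx(sum(clip[:, j].std() for j in range(3)), rel=1e-9)

    def test_spectrum_features_match_bruteforce(self, rng):
        clip = _random_clip(rng)
        vals = extract_inertial_features(clip, "gyr")
        freqs, p = periodogram_bruteforce(clip[:, 2], 50.0)
        mu, sd, skew, kurt = moments_bruteforce(p)
        assert vals["gyr_z_ps_mean"] == pytest.approx(mu, rel=1e-6)
        assert vals["gyr_z_ps_sd"] == pytest.approx(sd, rel=1e-6)
        assert vals["gyr_z_ps_skew"] == pytest.approx(skew, rel=1e-6)
        assert vals["gyr_z_ps_kurt"] == pytest.approx(kurt, rel=1e-6)
        for i in (0, 7, 19):
            ref = band_power_bruteforce(clip[:, 2], 50.0, 0.5 * i, 0.5 * (i + 1))
            assert vals[f"gyr_z_bp{i}"] == pytest.approx(ref, rel=1e-6)

    def test_mean_squared_norm_rotation_invariant(self, rng):
        from scipy.stats import special_ortho_group
        clip = _random_clip(rng)
        vals = extract_inertial_features(clip, "acc")
        for _ in range(5):
            R = special_ortho_group.rvs(3, random_state=rng.integers(2**31))
            rot = extract_inertial_features(clip @ R.T, "acc")
            assert rot["acc_msn"] == pytest.approx(vals["acc_msn"], rel=1e-9)
        # per-axis means are orientation-sensitive by design
        R = special_ortho_group.rvs(3, random_state=1)
        shifted = extract_inertial_features((clip + [3, 0, 0]) @ R.T, "acc")
        assert shifted["acc_x_mean"] != pytest.approx(vals["acc_x_mean"] + 3, rel=1e-3)

    def test_wrong_sample_count_raises(self, rng):
        with pytest.raises(ValueError):
            extract_inertial_matrix(rng.normal(size=(2, 400, 3)))


class TestBarometerFeatures:
    def test_linear_ramp(self):
        t = np.arange(60) / 6.0
        vals = extract_barometer_features(1000.0 + 0.1 * t)
        assert vals["baro_slope"] == pytest.approx(0.1, rel=1e-9)
        assert vals["baro_d_sd"] == pytest.approx(0.0, abs=1e-9)
        assert vals["baro_d_mean"] == pytest.approx(0.1, rel=1e-9)

    def test_constant_pressure_degenerate(self):
        vals = extract_barometer_features(np.full(60, 1013.0))
        assert all(v == 0.0 for v in vals.values())

    def test_exactly_eight_values(self, rng):
        vals = extract_barometer_features(rng.normal(1013, 1, 60))
        assert len(vals) == 8
        assert list(vals) == barometer_feature_names()

    def test_missing_barometer_gives_nan(self):
        vals = extract_barometer_features(None)
        assert len(vals) == 8 and all(np.isnan(v) for v in vals.values())

    def test_wrong_sample_count_raises(self, rng):
        with pytest.raises(ValueError):
            extract_baro_matrix(rng.normal(size=(1, 50)))


class TestInstanceTable:
    def test_shape_and_column_order(self, rng):
        clips = [_make_clip(rng) for _ in range(51)]
        table = build_instance_table(clips)
        feats = [c for c in table.columns if c in DEFAULT_CATALOG.names]
        assert table.shape[0] == 51
        assert feats == list(DEFAULT_CATALOG.names)

    def test_empty_clip_list_keeps_header(self):
        table = build_instance_table([])
        assert len(table) == 0
        assert list(DEFAULT_CATALOG.names)[-1] in table.columns

    def test_feature_subset_projection(self, rng):
        clips = [_make_clip(rng) for _ in range(5)]
        subset = list(DEFAULT_CATALOG.names[:151])
        table = build_instance_table(clips, feature_set=subset)
        feats = [c for c in table.columns if c in DEFAULT_CATALOG.names]
        assert len(feats) == 151

    def test_unknown_feature_rejected(self, rng):
        with pytest.raises(KeyError):
            build_instance_table([_make_clip(rng)], feature_set=["not_a_feature"])

    def test_missing_barometer_gives_nan_columns(self, rng):
        table = build_instance_table([_make_clip(rng, baro=False)])
        assert table[barometer_feature_names()].isna().all().all()


class TestFeatureRanking:
    def _table(self, rng, n=240, noise_features=50):
        y = np.repeat(["Sitting", "Walking", "StairsUp"], n // 3)
        informative = (y == "Walking") * 1.0 + (y == "StairsUp") * 2.0
        informative = informative + rng.normal(0, 0.05, n)
        data = {"activity": y, "signal": informative}
        for i in range(noise_features):
            data[f"noise{i}"] = rng.normal(size=n)
        return pd.DataFrame(data).sample(frac=1, random_state=0).reset_index(drop=True)

    def test_informative_feature_ranked_first(self, rng):
        ranking = rank_features_oob(self._table(rng), n_trees=20, seed=0)
        assert ranking.iloc[0]["feature"] == "signal"
        assert ranking.iloc[0]["importance"] > 0

    def test_deterministic_given_seed(self, rng):
        t = self._table(rng)
        r1 = rank_features_oob(t, n_trees=10, seed=3)
        r2 = rank_features_oob(t, n_trees=10, seed=3)
        assert list(r1.feature) == list(r2.feature)
        assert np.allclose(r1.importance, r2.importance)

    def test_single_class_rejected(self, rng):
        t = self._table(rng)
        t["activity"] = "Sitting"
        with pytest.raises(ValueError):
            rank_features_oob(t)

    def test_select_features(self, rng):
        ranking = rank_features_oob(self._table(rng), n_trees=10, seed=1)
        fs = select_features(ranking, 5)
        assert len(fs.names) == 5
        assert select_features(ranking, len(ranking)).names == tuple(ranking.feature)
        with pytest.raises(ValueError):
            select_features(ranking, 0)
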
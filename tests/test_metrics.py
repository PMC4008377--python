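import numpy as np
import pandas as pd
import pytest

from printpair import metrics as pm
from printpair.io import EmptyMaskError
from printpair.metrics import (
    FeatureStandardizer,
    RidgeReliabilityParams,
    assemble_features,
    area_ratio,
    block_contrast,
    block_intensity_sd,
    block_partition,
    collinearity_filter,
    deai,
    intensity_stats,
    michelson,
    pair_record,
    ridge_reliability,
    ridge_sum,
    total_area,
)

from oracles import block_oracle, intensity_oracle, michelson_oracle, sd


def full(shape, value):
    return np.full(shape, value, np.uint8), np.ones(shape, bool)


class TestElementaryMetrics:
    def test_total_area_counts_mask_pixels(self, rng):
        mask = rng.random((64, 64)) > 0.5
        mask[0, 0] = True
        count = sum(1 for r in range(64) for c in range(64) if mask[r][c])
        assert total_area(mask) == count

    def test_total_area_empty_mask_errors(self):
        with pytest.raises(EmptyMaskError):
            total_area(np.zeros((5, 5), bool))

    @pytest.mark.parametrize("la, ka, expected", [
        (5000, 10000, 0.5),
        (10000, 10000, 1.0),
        (12000, 10000, 1.2),  # latent larger than known is legal
    ])
    def test_area_ratio(self, la, ka, expected):
        lm = np.zeros((200, 200), bool)
        km = np.zeros((200, 200), bool)
        lm.flat[:la] = True
        km.flat[:ka] = True
        assert area_ratio(lm, km) == pytest.approx(expected)

    def test_intensity_stats_constant(self):
        img, mask = full((10, 10), 200)
        assert intensity_stats(img, mask) == (200.0, 0.0)

    def test_intensity_stats_bimodal(self):
        img = np.zeros((10, 10), np.uint8)
        img[:5] = 255
        mean, s = intensity_stats(img, np.ones((10, 10), bool))
        assert (mean, s) == (127.5, 127.5)

    def test_intensity_stats_match_pixel_loop(self, rng):
        img = rng.integers(0, 256, (5, 5)).astype(np.uint8)
        mask = np.ones((5, 5), bool)
        mean, s = intensity_stats(img, mask)
        omean, osd, _, _ = intensity_oracle(img, mask)
        assert mean == pytest.approx(omean)
        assert s == pytest.approx(osd)

    @pytest.mark.parametrize("value, expected", [
        (0, -127.5), (255, -127.5),
    ])
    def test_deai_extremes_are_symmetric(self, value, expected):
        img, mask = full((20, 20), value)
        assert deai(img, mask) == pytest.approx(expected)

    def test_deai_zero_at_balanced_mean(self):
        img = np.zeros((2, 2), np.uint8)
        img[0] = 255  # mean exactly 127.5
        assert deai(img, np.ones((2, 2), bool)) == 0.0

    def test_michelson_formula(self):
        img = np.full((10, 10), 100, np.uint8)
        img[0, 0] = 200
        assert michelson(img, np.ones((10, 10), bool)) == pytest.approx(1 / 3)

    def test_michelson_constant_zero(self):
        img, mask = full((10, 10), 90)
        assert michelson(img, mask) == 0.0

    def test_michelson_all_black_defined_zero_with_warning(self):
        img, mask = full((10, 10), 0)
        with pytest.warns(UserWarning):
            assert michelson(img, mask) == 0.0

    @pytest.mark.parametrize("rl, rk, expected", [
        (0.0, 0.0, 0.0), (1.0, 1.0, np.sqrt(2)), (0.6, 0.8, 1.0),
    ])
    def test_ridge_sum_euclidean(self, rl, rk, expected):
        assert ridge_sum(rl, rk) == pytest.approx(expected)


class TestBlocks:
    def test_full_100x100_gives_four_tiles(self):
        assert len(block_partition(np.ones((100, 100), bool))) == 4

    def test_60x60_keeps_only_the_full_tile(self):
        # partial tiles cover 20%, 20% and 4% of a full block: all dropped
        assert len(block_partition(np.ones((60, 60), bool))) == 1

    def test_small_mask_above_half_coverage_is_one_tile(self):
        mask = np.zeros((100, 100), bool)
        mask[10:50, 10:50] = True  # 1600 px = 64% of a 50x50 block
        assert len(block_partition(mask)) == 1

    def test_small_mask_below_half_coverage_errors(self):
        mask = np.zeros((100, 100), bool)
        mask[10:40, 10:40] = True  # 900 px = 36%
        with pytest.raises(EmptyMaskError):
            block_partition(mask)

    def test_block_intensity_sd_uniform_zero(self):
        img, mask = full((100, 100), 77)
        assert block_intensity_sd(img, mask) == 0.0

    def test_black_and_white_tiles(self):
        img = np.zeros((50, 100), np.uint8)
        img[:, 50:] = 255
        assert block_intensity_sd(img, np.ones((50, 100), bool)) == \
            pytest.approx(sd([0.0, 255.0]))

    def test_gradient_image_matches_block_oracle(self, rng):
        img = np.clip(
            np.add.outer(np.arange(150), np.arange(150)) + rng.integers(0, 30, (150, 150)),
            0, 255,
        ).astype(np.uint8)
        mask = rng.random((150, 150)) > 0.2
        mask[:50, :50] = True
        blocks = block_oracle(img, mask)
        means = [b[0] for b in blocks]
        michs = [b[1] for b in blocks]
        assert block_intensity_sd(img, mask) == pytest.approx(sd(means))
        bc_mean, bc_sd = block_contrast(img, mask)
        assert bc_mean == pytest.approx(sum(michs) / len(michs))
        assert bc_sd == pytest.approx(sd(michs))

    def test_checkerboard_has_unit_block_contrast_everywhere(self):
        img = (np.indices((100, 100)).sum(axis=0) % 2 * 255).astype(np.uint8)
        mean, s = block_contrast(img, np.ones((100, 100), bool))
        assert mean == pytest.approx(1.0)
        assert s == pytest.approx(0.0)

    def test_sparse_extremes_give_high_global_low_block_contrast(self):
        img = np.full((200, 200), 127, np.uint8)
        img[10, 10] = 255
        img[190, 190] = 0
        mask = np.ones((200, 200), bool)
        assert michelson(img, mask) == 1.0
        mean, _ = block_contrast(img, mask)
        assert mean < 0.2  # most blocks are pure gray

    def test_translation_invariance(self, rng):
        img = rng.integers(0, 256, (110, 110)).astype(np.uint8)
        mask = np.zeros((110, 110), bool)
        mask[5:105, 5:105] = True
        canvas1 = np.full((250, 250), 255, np.uint8)
        canvas2 = np.full((250, 250), 255, np.uint8)
        m1 = np.zeros((250, 250), bool)
        m2 = np.zeros((250, 250), bool)
        canvas1[10:120, 10:120], m1[10:120, 10:120] = img, mask
        canvas2[101:211, 93:203], m2[101:211, 93:203] = img, mask
        for f in (total_area, deai, michelson, block_intensity_sd):
            assert f(m1) == f(m2) if f is total_area else \
                f(canvas1, m1) == pytest.approx(f(canvas2, m2))
        assert block_contrast(canvas1, m1) == pytest.approx(block_contrast(canvas2, m2))
        assert ridge_reliability(canvas1, m1) == pytest.approx(ridge_reliability(canvas2, m2))


class TestRidgeReliability:
    def test_constant_image_has_no_oriented_energy(self):
        img = np.full((160, 160), 128, np.uint8)
        assert ridge_reliability(img, np.ones((160, 160), bool)) == 0.0

    def test_aligned_grating_is_nearly_all_reliable(self):
        n = 160
        x = np.arange(n)
        g = np.clip(np.rint(127.5 + 127.0 * np.sin(2 * np.pi * x / 9.0)), 0, 255)
        img = np.tile(g, (n, 1)).astype(np.uint8)
        assert ridge_reliability(img, np.ones((n, n), bool)) >= 0.95

    def test_noise_is_mostly_unreliable(self):
        vals = []
        for seed in range(10):
            img = np.random.default_rng(seed).integers(0, 256, (160, 160)).astype(np.uint8)
            vals.append(ridge_reliability(img, np.ones((160, 160), bool)))
        assert np.median(vals) < 0.2

    def test_range_is_proportion(self, whorl_print):
        img, mask, _ = whorl_print
        r = ridge_reliability(img, mask)
        assert 0.0 <= r <= 1.0

    def test_parameters_are_configurable(self, whorl_print):
        img, mask, _ = whorl_print
        strict = RidgeReliabilityParams(dominance_ratio=50.0)
        assert ridge_reliability(img, mask, strict) <= ridge_reliability(img, mask)


class TestFeatureAssembly:
    def _records(self, rng, n=30):
        recs = []
        for i in range(n):
            rec = {"pair_id": f"P{i:03d}"}
            for col in pm.PAIRED_CONTINUOUS:
                for s in ("L", "K"):
                    rec[f"{col}_{s}"] = float(rng.normal())
            for s in ("L", "K"):
                rec[f"core_{s}"] = int(rng.random() < 0.5)
                rec[f"delta_{s}"] = int(rng.random() < 0.5)
            rec["area_ratio"] = float(rng.uniform(0.2, 1.3))
            rec["ridge_sum"] = float(rng.uniform(0, np.sqrt(2)))
            recs.append(rec)
        return recs

    def test_standardized_columns_have_zero_mean_unit_sd(self, rng):
        df, _ = assemble_features(self._records(rng))
        for col in pm.continuous_columns(df):
            assert abs(df[col].mean()) < 1e-8
            assert abs(df[col].std(ddof=0) - 1.0) < 1e-8

    def test_interactions_are_products_of_standardized_mains(self, rng):
        df, _ = assemble_features(self._records(rng))
        for col in pm.interaction_columns(df):
            stem = col[:-len("_LxK")]
            np.testing.assert_allclose(
                df[col], df[f"{stem}_L"] * df[f"{stem}_K"], atol=1e-12
            )

    def test_binary_columns_stay_binary(self, rng):
        df, _ = assemble_features(self._records(rng))
        assert set(np.unique(df["core_L"])) <= {0, 1}

    def test_zero_variance_columns_dropped_with_warning(self, rng):
        recs = self._records(rng, n=6)
        for r in recs:
            r["michelson_K"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            df, _ = assemble_features(recs)
        assert "michelson_K" not in df.columns

    def test_standardizer_transfers_training_statistics(self, rng):
        recs = self._records(rng)
        df, scaler = assemble_features(recs[:20])
        held, _ = assemble_features(recs[20:], standardizer=scaler)
        raw = pd.DataFrame(recs[20:]).set_index("pair_id")
        col = "mean_intensity_L"
        expected = (raw[col] - scaler.means[col]) / scaler.sds[col]
        np.testing.assert_allclose(held[col], expected)

    def test_roundtrip_serialization(self, rng):
        _, scaler = assemble_features(self._records(rng))
        restored = FeatureStandardizer.from_dict(scaler.to_dict())
        pd.testing.assert_series_equal(scaler.means, restored.means)


class TestCollinearityFilter:
    def test_duplicated_column_drops_exactly_one(self, rng):
        df = pd.DataFrame(rng.standard_normal((50, 3)),
                          columns=["area_ratio", "ridge_sum", "mean_intensity_L"])
        df["mean_intensity_K"] = df["mean_intensity_L"]
        reduced, report = collinearity_filter(df)
        dropped = {r["dropped"] for r in report}
        assert len(dropped & {"mean_intensity_L", "mean_intensity_K"}) == 1

    def test_anticorrelated_pair_loses_one_member(self, rng):
        n = 100
        x = rng.standard_normal(n)
        df = pd.DataFrame({
            "mean_intensity_L": x,
            "sd_intensity_L": -0.9 * x + 0.2 * rng.standard_normal(n),
            "area_ratio": rng.standard_normal(n),
        })
        reduced, report = collinearity_filter(df)
        assert any(r["reason"] == "pairwise_r" for r in report)
        survivors = set(reduced.columns)
        assert len(survivors & {"mean_intensity_L", "sd_intensity_L"}) == 1

    def test_independent_gaussians_rarely_trigger_drops(self):
        clean = 0
        n_runs = 60
        for seed in range(n_runs):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(
                r.standard_normal((200, 5)),
                columns=["area_ratio", "ridge_sum", "deai_L", "deai_K",
                         "michelson_L"],
            )
            _, report = collinearity_filter(df)
            clean += not report
        assert clean / n_runs >= 0.95

    def test_survivor_vifs_below_limit(self, rng):
        base = rng.standard_normal((120, 4))
        df = pd.DataFrame(base, columns=["area_ratio", "ridge_sum",
                                         "deai_L", "deai_K"])
        df["michelson_L"] = df["area_ratio"] * 0.45 + df["ridge_sum"] * 0.45 \
            + 0.2 * rng.standard_normal(120)
        reduced, _ = collinearity_filter(df)
        vifs = pm.variance_inflation_factors(
            reduced, pm.continuous_columns(reduced))
        assert (vifs < 5.0).all()

    def test_too_few_columns_errors(self, rng):
        df = pd.DataFrame({"area_ratio": rng.standard_normal(10)})
        with pytest.raises(ValueError):
            collinearity_filter(df)
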
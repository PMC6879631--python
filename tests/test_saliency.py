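import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.stats import spearmanr

from digitrack.maps import AttentionMap, map_correlation
from digitrack.saliency import (FeatureStack, WeightVector,
                                compare_channel_weights,
                                learn_weights_regression,
                                learn_weights_wcorr, loo_cross_validate,
                                most_responsive_pixels, predict_saliency,
                                rank_channels, resize_feature_maps,
                                top_channel_match_pvalue)
from digitrack.synth import make_feature_bank

RASTER = (40, 40)


def make_mixture_dataset(k=16, n_images=12, snr=5.0, seed=0,
                         raster=RASTER):
    """Targets as noisy linear mixtures of a known channel bank."""
    rng = np.random.default_rng(seed)
    true_w = rng.normal(0, 1, k)
    stacks, targets = [], []
    for i in range(n_images):
        bank = make_feature_bank(raster, k, seed=1000 * seed + i)
        mix = np.tensordot(true_w, bank.maps, axes=1)
        noise = gaussian_filter(rng.standard_normal(raster), 4,
                                mode="reflect")
        noise *= mix.std() / (snr * noise.std())
        tgt = mix + noise
        tgt -= tgt.min()
        tgt /= tgt.max()
        stacks.append(bank)
        targets.append(AttentionMap(tgt, image_id=f"img{i}"))
    return true_w, stacks, targets


class TestResizeFeatureMaps:
    def test_constant_preserved(self):
        raw = np.full((1, 10, 10), 2.5)
        fs = resize_feature_maps(raw, (23, 31))
        np.testing.assert_allclose(fs.maps, 2.5)

    def test_bilinear_exact_on_ramp(self):
        yy, xx = np.mgrid[0:11, 0:11].astype(float)
        ramp = 2.0 * xx + 3.0 * yy + 1.0
        fs = resize_feature_maps(ramp[None], (21, 21))
        ty, tx = np.meshgrid(np.linspace(0, 10, 21),
                             np.linspace(0, 10, 21), indexing="ij")
        np.testing.assert_allclose(fs.maps[0], 2.0 * tx + 3.0 * ty + 1.0,
                                   atol=1e-10)

    def test_round_trip_correlation(self, rng):
        blob = gaussian_filter(rng.random((64, 64)), 6, mode="reflect")
        down = resize_feature_maps(blob[None], (16, 16))
        up = resize_feature_maps(down.maps, (64, 64))
        assert map_correlation(up.maps[0], blob) > 0.99

    def test_degenerate_target_rejected(self):
        with pytest.raises(ValueError):
            resize_feature_maps(np.zeros((1, 8, 8)), (1, 8))


class TestWcorr:
    def test_self_channel_weight_one(self, rng):
        bank = make_feature_bank(RASTER, 4, seed=1)
        target = bank.maps[2].copy()
        target -= target.min()
        target /= target.max()
        w = learn_weights_wcorr([bank], [AttentionMap(target)])
        assert w.weights[2] == pytest.approx(1.0)

    def test_negated_channel_weight_minus_one(self):
        bank = make_feature_bank(RASTER, 4, seed=2)
        target = -bank.maps[1]
        target -= target.min()
        target /= target.max()
        w = learn_weights_wcorr([bank], [AttentionMap(target)])
        assert w.weights[1] == pytest.approx(-1.0)

    def test_weights_in_unit_interval(self):
        _, stacks, targets = make_mixture_dataset(seed=3)
        w = learn_weights_wcorr(stacks, targets)
        assert np.all(np.abs(w.weights) <= 1.0)

    def test_affine_invariance(self):
        _, stacks, targets = make_mixture_dataset(n_images=4, seed=4)
        w1 = learn_weights_wcorr(stacks, targets)
        scaled = [AttentionMap(0.25 * t.grid + 0.5, image_id=t.image_id)
                  for t in targets]
        w2 = learn_weights_wcorr(stacks, scaled)
        np.testing.assert_allclose(w1.weights, w2.weights, atol=1e-10)

    def test_mixture_ranking_recovered(self):
        true_w, stacks, targets = make_mixture_dataset(k=8, n_images=15,
                                                       snr=5.0, seed=5)
        w = learn_weights_wcorr(stacks, targets)
        rho = spearmanr(w.weights, true_w).statistic
        assert rho > 0.9


class TestRegression:
    def test_single_channel_recovers_slope(self, rng):
        bank = make_feature_bank(RASTER, 1, seed=6)
        target = 0.7 * bank.maps[0]
        target -= target.min()
        w = learn_weights_regression(
            [bank], [AttentionMap(target / target.max())],
            cv=3, alphas=np.array([1e-12]))
        slope = 0.7 / target.max()  # normalization rescales the truth
        assert w.weights[0] == pytest.approx(slope, abs=1e-6)

    def test_sparse_noise_channels_near_zero(self):
        rng = np.random.default_rng(7)
        bank = make_feature_bank(RASTER, 6, seed=7)
        target = bank.maps[0] + 0.05 * rng.standard_normal(RASTER)
        target -= target.min()
        target /= target.max()
        w = learn_weights_regression([bank], [AttentionMap(target)], cv=3)
        informative = abs(w.weights[0])
        assert np.all(np.abs(w.weights[1:]) < 0.1 * informative)

    def test_degenerate_design_rejected(self):
        bank = FeatureStack(np.ones((2, 8, 8)))
        with pytest.raises(ValueError):
            learn_weights_regression([bank],
                                     [AttentionMap(np.ones((8, 8)))])

    def test_prediction_quality_close_to_wcorr(self):
        _, stacks, targets = make_mixture_dataset(k=8, n_images=8, snr=5.0,
                                                  seed=8)
        cc_w = loo_cross_validate(stacks, targets, learn_weights_wcorr)
        cc_r = loo_cross_validate(
            stacks, targets,
            lambda s, t: learn_weights_regression(s, t, cv=3))
        mean_w = np.mean([c for c in cc_w if c is not None])
        mean_r = np.mean([c for c in cc_r if c is not None])
        assert mean_r >= mean_w - 0.05


class TestPredictSaliency:
    def test_one_hot_returns_channel(self):
        bank = make_feature_bank(RASTER, 3, seed=9)
        w = WeightVector(np.array([0.0, 1.0, 0.0]))
        pred = predict_saliency(bank, w)
        # equal up to the affine (shift+scale) normalization
        assert map_correlation(pred.grid, bank.maps[1]) \
            == pytest.approx(1.0)

    def test_zero_weights_flagged_constant(self):
        bank = make_feature_bank(RASTER, 3, seed=10)
        pred = predict_saliency(bank, WeightVector(np.zeros(3)))
        assert pred.constant

    def test_matches_bruteforce_sum(self, rng):
        bank = make_feature_bank(RASTER, 5, seed=11)
        weights = rng.normal(0, 1, 5)
        pred = predict_saliency(bank, WeightVector(weights))
        brute = np.zeros(RASTER)
        for c in range(5):
            brute += weights[c] * bank.maps[c]
        brute -= brute.min()
        brute /= brute.max()
        np.testing.assert_allclose(pred.grid, brute, atol=1e-12)

    def test_k_mismatch_rejected(self):
        bank = make_feature_bank(RASTER, 3, seed=12)
        with pytest.raises(ValueError):
            predict_saliency(bank, WeightVector(np.ones(4)))


class TestLOO:
    def test_perfect_channel_gives_cc_one(self):
        # decorrelate the distractor channels from the target channel so
        # their wCorr weights are exactly zero
        stacks, targets = [], []
        for i in range(4):
            bank = make_feature_bank(RASTER, 3, seed=20 + i)
            flat = bank.maps.reshape(3, -1)
            flat -= flat.mean(axis=1, keepdims=True)
            q, _ = np.linalg.qr(flat.T)
            ortho = q.T.reshape(3, *RASTER)
            stack = FeatureStack(ortho)
            t = ortho[1] - ortho[1].min()
            targets.append(AttentionMap(t / t.max(), image_id=f"i{i}"))
            stacks.append(stack)
        scores = loo_cross_validate(stacks, targets)
        assert all(s == pytest.approx(1.0, abs=1e-6) for s in scores)

    def test_null_targets_give_cc_near_zero(self):
        rng = np.random.default_rng(21)
        stacks, targets = [], []
        for i in range(6):
            stacks.append(make_feature_bank(RASTER, 4, seed=40 + i))
            t = gaussian_filter(rng.random(RASTER), 3, mode="reflect")
            t -= t.min()
            targets.append(AttentionMap(t / t.max(), image_id=f"i{i}"))
        scores = loo_cross_validate(stacks, targets)
        assert abs(np.mean(scores)) < 0.25

    def test_matches_hand_rolled_loop(self):
        _, stacks, targets = make_mixture_dataset(k=6, n_images=5, seed=22)
        scores = loo_cross_validate(stacks, targets)
        for i in range(5):
            rest = [j for j in range(5) if j != i]
            w = learn_weights_wcorr([stacks[j] for j in rest],
                                    [targets[j] for j in rest])
            pred = predict_saliency(stacks[i], w)
            assert scores[i] == pytest.approx(
                map_correlation(pred.grid, targets[i].grid), abs=1e-12)

    def test_cc_rises_with_snr(self):
        means = []
        for snr in (0.5, 2.0, 8.0):
            _, stacks, targets = make_mixture_dataset(k=8, n_images=8,
                                                      snr=snr, seed=23)
            scores = loo_cross_validate(stacks, targets)
            means.append(np.mean([s for s in scores if s is not None]))
        assert means[0] < means[1] < means[2]

    def test_too_few_images_rejected(self):
        _, stacks, targets = make_mixture_dataset(n_images=2, seed=24)
        with pytest.raises(ValueError):
            loo_cross_validate(stacks, targets)


class TestRankChannels:
    def test_basic_ordering(self):
        order = rank_channels(WeightVector(np.array([0.2, 0.9, -0.3])))
        assert order == [2, 1, 3]

    def test_tie_broken_by_channel_id(self):
        order = rank_channels(WeightVector(np.zeros(4)))
        assert order == [1, 2, 3, 4]

    def test_recovery_top_channel(self):
        true_w, stacks, targets = make_mixture_dataset(k=8, n_images=15,
                                                       snr=5.0, seed=25)
        w = learn_weights_wcorr(stacks, targets)
        assert rank_channels(w)[0] == int(np.argmax(true_w)) + 1


class TestMostResponsivePixels:
    def test_full_fraction_full_mask(self):
        bank = make_feature_bank(RASTER, 2, seed=26)
        masks = most_responsive_pixels([bank], 0, 1.0)
        assert masks[0].all()

    def test_hot_blob_selected(self):
        chan = np.zeros(RASTER)
        chan[18:22, 18:22] = 1.0
        stack = FeatureStack(np.stack([chan]))
        masks = most_responsive_pixels([stack], 0, 0.01)
        ys, xs = np.nonzero(masks[0])
        assert np.all((ys >= 18) & (ys < 22) & (xs >= 18) & (xs < 22))

    def test_mask_area_matches_fraction(self, rng):
        chan = rng.random(RASTER)  # no ties
        stack = FeatureStack(np.stack([chan]))
        frac = 0.1
        masks = most_responsive_pixels([stack], 0, frac)
        area = masks[0].mean()
        assert abs(area - frac) <= 1.0 / chan.size + 1e-9

    def test_invalid_fraction_rejected(self):
        bank = make_feature_bank(RASTER, 1, seed=27)
        with pytest.raises(ValueError):
            most_responsive_pixels([bank], 0, 0.0)


class TestTopChannelPvalue:
    def test_256_channels(self):
        p = top_channel_match_pvalue(256)
        assert p == 1.0 / 256 == 0.00390625
        assert p < 0.004

    @pytest.mark.parametrize("k,expected", [(1, 1.0), (2, 0.5)])
    def test_small_k(self, k, expected):
        assert top_channel_match_pvalue(k) == expected

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            top_channel_match_pvalue(0)


class TestCompareChannelWeights:
    def test_identical_groups_p_one(self):
        g = np.tile(np.linspace(-1, 1, 8)[:, None], (1, 4))
        p = compare_channel_weights(g, g, 0)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(28)
        detected = 0
        n_sims = 40
        for _ in range(n_sims):
            a = rng.normal(0, 1, (22, 4))
            b = rng.normal(3, 1, (22, 4))  # 3 pooled SDs apart
            if compare_channel_weights(a, b, 2) < 0.001:
                detected += 1
        assert detected / n_sims >= 0.95

    def test_bonferroni_capped(self):
        rng = np.random.default_rng(29)
        a = rng.normal(0, 1, (10, 4))
        b = rng.normal(0, 1, (10, 4))
        p1 = compare_channel_weights(a, b, 1, n_tested_channels=1)
        pm = compare_channel_weights(a, b, 1, n_tested_channels=4)
        assert pm == pytest.approx(min(1.0, 4 * p1))
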
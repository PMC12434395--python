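import itertools

import numpy as np
import pandas as pd
import pytest

from atcost.simulate import SimConfig, gen_cn_series
from atcost.subclone import (
    SegmentProfile,
    SubcloneMixtureModel,
    bootstrap_ci,
    call_resistance_segments,
    correlate_burden,
    estimate_subclone_ratio,
    purity_correct,
    shift_matrix,
    subclone_growth_rate,
)


def make_profile(cns, sample_id="s", day=0.0, purity=1.0):
    n = len(cns)
    seg = pd.DataFrame(
        {
            "chromosome": ["1"] * n,
            "start": np.arange(n) * 1_000_000,
            "end": (np.arange(n) + 1) * 1_000_000,
            "copy_number": np.asarray(cns, dtype=float),
        }
    )
    return SegmentProfile(seg, sample_id, day, purity)


class TestPurityCorrect:
    def test_pure_sample_unchanged(self):
        p = make_profile([1, 2, 3, 4], purity=1.0)
        assert purity_correct(p) == pytest.approx([1, 2, 3, 4])

    def test_half_purity_mixture_inverted(self):
        # observed 3 at purity 0.5 with diploid contamination: tumor CN 4
        p = make_profile([3.0], purity=0.5)
        assert purity_correct(p) == pytest.approx([4.0])

    def test_negative_corrected_clipped_with_warning(self):
        p = make_profile([0.5], purity=0.5)  # would give -1.5
        with pytest.warns(UserWarning, match="clipping"):
            assert purity_correct(p) == pytest.approx([0.0])

    def test_invalid_purity_rejected(self):
        with pytest.raises(ValueError):
            make_profile([2.0], purity=0.0)

    def test_generator_round_trip_noiseless(self, noiseless_config):
        ser = gen_cn_series(30, 8, [0.0, 0.3], [0.7, 0.6], noiseless_config, days=[0, 60])
        gt = ser.ground_truth
        c0 = gt.extras["baseline_cn"]
        corrected = purity_correct(ser.later[0])
        expected = c0.copy()
        for j, d in gt.true_resistant_segments.items():
            expected[j] = (1 - 0.3) * c0[j] + 0.3 * (c0[j] + d)
        assert corrected == pytest.approx(expected, abs=1e-9)


class TestCallResistanceSegments:
    def test_identical_profiles_call_nothing(self):
        base = make_profile([2, 3, 4])
        later = make_profile([2, 3, 4], day=60)
        assert call_resistance_segments(base, [later]).size == 0

    def test_monotone_shift_included(self):
        base = make_profile([2.0, 2.0])
        l1 = make_profile([2.2, 2.0], day=30)
        l2 = make_profile([2.4, 2.0], day=60)
        called = call_resistance_segments(base, [l1, l2])
        assert called.tolist() == [0]

    def test_transient_decoy_excluded(self):
        base = make_profile([2.0])
        l1 = make_profile([2.4], day=30)  # up ...
        l2 = make_profile([2.0], day=60)  # ... and back: not resistance-specific
        assert call_resistance_segments(base, [l1, l2]).size == 0

    def test_generated_decoys_excluded_at_zero_noise(self, noiseless_config):
        ser = gen_cn_series(
            40, 10, [0.0, 0.2, 0.4, 0.6], [1.0, 1.0, 1.0, 1.0], noiseless_config,
            days=[0, 60, 120, 180], decoy_fraction=0.2,
        )
        called = set(call_resistance_segments(ser.baseline, ser.later).tolist())
        decoys = set(ser.ground_truth.decoy_segments)
        truth = set(ser.ground_truth.true_resistant_segments)
        assert called == truth
        assert not (called & decoys)

    def test_requires_later_samples(self):
        with pytest.raises(ValueError):
            call_resistance_segments(make_profile([2.0]), [])


def brute_force_mixture(X, penalty=0.0, delta_max=3):
    """Exhaustive enumeration over integer deltas (the independent oracle)."""
    best = None
    values = [d for d in range(-delta_max, delta_max + 1) if d != 0]
    for d in itertools.product(values, repeat=X.shape[1]):
        d = np.array(d)
        r = np.clip(X @ d / np.sum(d**2), 0.0, 1.0)
        sse = float(np.sum((X - np.outer(r, d)) ** 2))
        key = (round(sse + penalty * np.sum(np.abs(d)), 10), int(np.sum(np.abs(d))))
        if best is None or key < best[0]:
            best = (key, d, r)
    return best


class TestSubcloneMixtureModel:
    def test_single_segment_mixture_identity(self):
        est = SubcloneMixtureModel(np.array([[0.2], [0.4]])).fit()
        assert est.ratios == pytest.approx([0.2, 0.4])
        assert est.deltas == {0: 1}

    def test_parsimony_resolves_scale_degeneracy(self):
        # data from (delta=2, r=(0.2, 0.3)) equals (delta=1, r=(0.4, 0.6));
        # the minimal-|delta| solution must be reported
        est = SubcloneMixtureModel(np.array([[0.4], [0.6]])).fit()
        assert est.deltas == {0: 1}
        assert est.ratios == pytest.approx([0.4, 0.6])

    def test_scale_two_required_when_ratio_would_clip(self):
        # shifts (0.8, 1.2): only delta=2 fits exactly with r in [0, 1]
        est = SubcloneMixtureModel(np.array([[0.8], [1.2]])).fit()
        assert est.deltas == {0: 2}
        assert est.ratios == pytest.approx([0.4, 0.6])
        assert est.sse == pytest.approx(0.0, abs=1e-15)

    def test_mixed_deltas_recovered_exactly(self):
        X = np.outer([0.2, 0.4], [1, -2])
        est = SubcloneMixtureModel(X).fit()
        assert est.ratios == pytest.approx([0.2, 0.4])
        assert list(est.deltas.values()) == [1, -2]

    def test_all_zero_shifts_flagged(self):
        est = SubcloneMixtureModel(np.zeros((3, 4))).fit()
        assert est.ratios == pytest.approx([0, 0, 0])
        assert "no_emergent_subclone" in est.flags

    def test_matches_brute_force_on_small_noiseless_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = rng.integers(1, 4)
            T = rng.integers(2, 5)
            d = rng.choice([-2, -1, 1, 2], n)
            r = np.sort(rng.uniform(0.05, 0.8, T))
            X = np.outer(r, d)
            fit = SubcloneMixtureModel(X).fit()
            (key, d_best, _) = brute_force_mixture(X)
            assert fit.sse == pytest.approx(key[0], abs=1e-9)
            assert sum(abs(v) for v in fit.deltas.values()) <= key[1]


class TestEstimateAndBootstrap:
    def test_noiseless_recovery_exact(self, noiseless_config):
        ser = gen_cn_series(
            40, 12, [0.0, 0.1, 0.3, 0.6], [0.8, 0.7, 0.9, 0.75], noiseless_config,
            days=[0, 60, 120, 180],
        )
        segs = call_resistance_segments(ser.baseline, ser.later)
        est = estimate_subclone_ratio(ser.baseline, ser.later, segs)
        assert est.ratios == pytest.approx([0.1, 0.3, 0.6], abs=1e-6)
        for j, d in est.deltas.items():
            assert d == ser.ground_truth.true_resistant_segments[j]

    def test_noiseless_ci_width_tiny(self, noiseless_config):
        ser = gen_cn_series(
            40, 12, [0.0, 0.2, 0.5], [0.8, 0.7, 0.9], noiseless_config, days=[0, 60, 120]
        )
        segs = call_resistance_segments(ser.baseline, ser.later)
        est = bootstrap_ci(ser.baseline, ser.later, segs, seed=0)
        assert np.all(est.ci_high - est.ci_low < 1e-6)

    def test_few_segments_flagged_unstable(self):
        base = make_profile([2.0, 2.0, 2.0, 2.0])
        l1 = make_profile([2.2, 2.2, 2.4, 2.0], day=30)
        l2 = make_profile([2.4, 2.4, 2.8, 2.0], day=60)
        segs = call_resistance_segments(base, [l1, l2])
        assert segs.size == 3
        est = bootstrap_ci(base, [l1, l2], segs, seed=0)
        assert "ci_unstable" in est.flags

    def test_empty_segment_set_rejected(self):
        base = make_profile([2.0])
        later = make_profile([2.0], day=30)
        with pytest.raises(ValueError):
            estimate_subclone_ratio(base, [later], segments=np.array([], dtype=int))

    def test_two_sample_reliability_warning(self):
        base = make_profile([2.0, 2.0])
        l1 = make_profile([2.5, 2.0], day=30)
        with pytest.warns(UserWarning, match="two time points"):
            est = estimate_subclone_ratio(base, [l1])
        assert "two_sample_unreliable" in est.flags

    def test_ci_width_shrinks_with_more_segments(self):
        widths = {}
        for n_res in (10, 40):
            w = []
            for seed in range(4):
                cfg = SimConfig(seed=seed, cn_noise_sd=0.05)
                ser = gen_cn_series(
                    n_res + 40, n_res, [0.0, 0.2, 0.5], [0.7, 0.6, 0.8], cfg, days=[0, 60, 120]
                )
                segs = call_resistance_segments(ser.baseline, ser.later)
                est = bootstrap_ci(ser.baseline, ser.later, segs, seed=seed)
                w.append(np.mean(est.ci_high - est.ci_low))
            widths[n_res] = np.mean(w)
        assert widths[40] < widths[10]

    def test_harmonization_mismatch_rejected(self):
        base = make_profile([2.0, 2.0])
        bad = make_profile([2.0, 2.0, 2.0], day=30)
        with pytest.raises(ValueError, match="segmentation differs"):
            shift_matrix(base, [bad])


class TestGrowthRateAndBurden:
    def make_estimate(self, days, ratios):
        from atcost.subclone import SubcloneEstimate

        return SubcloneEstimate(
            sample_ids=[f"s{i}" for i in range(len(days))],
            days=np.asarray(days, dtype=float),
            ratios=np.asarray(ratios, dtype=float),
            deltas={0: 1},
        )

    def test_simple_rate(self):
        est = self.make_estimate([100, 200], [0.1, 0.3])
        table = subclone_growth_rate(est)
        assert table["rate_per_day"].to_numpy() == pytest.approx([0.002])

    def test_constant_ratio_zero_rate(self):
        est = self.make_estimate([10, 20, 30], [0.4, 0.4, 0.4])
        assert subclone_growth_rate(est)["rate_per_day"].to_numpy() == pytest.approx([0, 0])

    def test_three_samples_interval_vs_baseline_modes(self):
        est = self.make_estimate([60, 120, 180], [0.1, 0.3, 0.6])
        interval = subclone_growth_rate(est, baseline_day=0.0)
        # hand arithmetic: (0.1-0)/60, (0.3-0.1)/60, (0.6-0.3)/60
        assert interval["rate_per_day"].to_numpy() == pytest.approx(
            [0.1 / 60, 0.2 / 60, 0.3 / 60]
        )
        vs_base = subclone_growth_rate(est, mode="from_baseline", baseline_day=0.0)
        assert vs_base["rate_per_day"].to_numpy() == pytest.approx(
            [0.1 / 60, 0.3 / 120, 0.6 / 180]
        )

    def test_duplicate_days_rejected(self):
        est = self.make_estimate([60, 60], [0.1, 0.3])
        with pytest.raises(ValueError):
            subclone_growth_rate(est)

    def test_collinear_pairs_give_unit_correlation(self):
        rates = [0.001, 0.002, 0.004, 0.006]
        markers = [10 + 2e4 * r for r in rates]
        corr = correlate_burden(rates, markers)
        assert corr.r == pytest.approx(1.0)
        anti = correlate_burden(rates, [-m for m in markers])
        assert anti.r == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = 3 * x + rng.normal(size=12)
        corr = correlate_burden(x, y)
        expected = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert corr.r == pytest.approx(expected, abs=1e-12)
        assert corr.r_squared == pytest.approx(expected**2, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            correlate_burden([0.1, 0.2], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate_burden([0.1, 0.1, 0.1], [1.0, 2.0, 3.0])
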
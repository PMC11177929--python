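"""Content-modulation index: designation, cross-validation, epoch statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmv1.cmi import (HlPair, cmi_crossval, compute_cmi, condition_means,
                      delta_cmi_abs, designate_hl, epoch_rank_correlation,
                      epoch_rates, epoch_response_correlation,
                      normalize_response)
from wmv1.simulate import SimConfig, simulate_session


def poisson_rates(rng, means_per_condition, n_per_condition, n_electrodes=1):
    """Trial x electrode Poisson rate draws with per-condition means."""
    rates, labels = [], []
    for c, mu in enumerate(means_per_condition):
        draw = rng.poisson(np.full((n_per_condition, n_electrodes), mu * 1.0))
        rates.append(draw)
        labels += [f"c{c}"] * n_per_condition
    return np.concatenate(rates).astype(float), np.array(labels)


class TestEpochRates:
    def test_count_to_rate_conversion(self, default_session):
        _, s = default_session
        counts = s.spike_counts((700.0, 1700.0))
        rates = epoch_rates(s, (700.0, 1700.0))
        assert np.allclose(rates, counts / 1.0)  # 1000 ms -> sp/s == counts

    def test_simulated_rate_recovered(self):
        cfg = SimConfig(n_electrodes=1, n_trials_per_condition=125, seed=4,
                        stim_gain=np.ones((1, 4)),
                        delay_delta=np.full((1, 4), 2.0),
                        off_response_amp=0.0, incorrect_fraction=0.0)
        s = simulate_session(cfg)
        r = epoch_rates(s, (700.0, 1700.0))[:, 0]
        se = r.std(ddof=1) / np.sqrt(len(r))
        assert abs(r.mean() - 12.0) < 3 * se

    def test_bad_epoch(self, default_session):
        _, s = default_session
        with pytest.raises(ValueError):
            epoch_rates(s, (0.0, 10_000.0))


class TestDesignateHl:
    def test_argmax_argmin(self):
        rng = np.random.default_rng(0)
        rates, labels = poisson_rates(rng, [10, 6, 8, 7], 200)
        # conditions c0..c3 with means 10, 6, 8, 7
        pair = designate_hl(rates, labels)[0]
        assert (pair.cond_high, pair.cond_low) == ("c0", "c1")
        assert not pair.tied

    def test_tie_broken_by_label_order(self):
        rates = np.ones((8, 1))
        labels = np.array(list("AABBCCDD"))
        pair = designate_hl(rates, labels)[0]
        assert (pair.cond_high, pair.cond_low) == ("A", "B")
        assert pair.tied

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            designate_hl(np.ones((4, 1)), np.array(["A"] * 4))

    def test_designation_matches_configured_extremes(self):
        # delay delta spread >= 5 sp/s: designation recovers the configured
        # extremes for >= 95% of electrodes over 500 trials
        delay = np.tile([3.0, 1.0, -1.0, -3.0], (20, 1))  # spread 6 sp/s
        cfg = SimConfig(n_electrodes=20, n_trials_per_condition=125, seed=6,
                        stim_gain=np.ones((20, 4)), delay_delta=delay,
                        off_response_amp=0.0, incorrect_fraction=0.0)
        s = simulate_session(cfg)
        pairs = designate_hl(epoch_rates(s, (700.0, 1700.0)),
                             s.condition_labels())
        hits = sum(p.cond_high == "c0" and p.cond_low == "c3" for p in pairs)
        assert hits >= 19


class TestComputeCmi:
    def test_arithmetic(self):
        rates = np.array([[30.0], [30.0], [10.0], [10.0]])
        labels = np.array(["h", "h", "l", "l"])
        hl = [HlPair(0, "h", "l")]
        assert compute_cmi(rates, labels, hl)[0] == pytest.approx(0.5)

    def test_equal_means_give_zero(self):
        rates = np.array([[10.0], [10.0]])
        labels = np.array(["h", "l"])
        assert compute_cmi(rates, labels, [HlPair(0, "h", "l")])[0] == 0.0

    def test_cross_designation_sign_flip(self):
        # designation from another stage with swapped rates: CMI flips sign
        rates = np.array([[30.0], [10.0]])
        labels = np.array(["a", "b"])
        hl_fwd = [HlPair(0, "a", "b")]
        hl_rev = [HlPair(0, "b", "a")]
        assert compute_cmi(rates, labels, hl_fwd)[0] == pytest.approx(0.5)
        assert compute_cmi(rates, labels, hl_rev)[0] == pytest.approx(-0.5)

    def test_zero_sum_invalid(self):
        rates = np.zeros((4, 1))
        labels = np.array(["a", "a", "b", "b"])
        assert np.isnan(compute_cmi(rates, labels, [HlPair(0, "a", "b")])[0])

    rate_strategy = st.one_of(st.just(0.0), st.floats(0.01, 100))

    @settings(derandomize=True, max_examples=100)
    @given(rate_strategy, rate_strategy)
    def test_bounded_and_extreme_iff_zero_rate(self, fr_h, fr_l):
        if fr_h + fr_l == 0:
            return
        rates = np.array([[fr_h], [fr_l]])
        labels = np.array(["h", "l"])
        v = compute_cmi(rates, labels, [HlPair(0, "h", "l")])[0]
        assert -1.0 <= v <= 1.0
        assert (abs(v) == 1.0) == (min(fr_h, fr_l) == 0.0)

    def test_self_designation_non_negative(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            rates, labels = poisson_rates(rng, rng.uniform(2, 12, 4), 15, 3)
            hl = designate_hl(rates, labels)
            vals = compute_cmi(rates, labels, hl)
            assert (vals[~np.isnan(vals)] >= 0).all()


class TestDeltaCmi:
    def test_worked_electrode_values(self):
        # late-stage CMI closer to the reference task than early-stage CMI
        late = delta_cmi_abs(-0.015, -0.036)
        early = delta_cmi_abs(0.025, -0.036)
        assert late == pytest.approx(0.021, abs=1e-12)
        assert early == pytest.approx(0.061, abs=1e-12)
        assert late < early

    def test_symmetry_and_zero(self):
        assert delta_cmi_abs(0.3, 0.3) == 0.0
        assert delta_cmi_abs(0.2, -0.1) == delta_cmi_abs(-0.1, 0.2)

    def test_invalid_propagates(self):
        assert np.isnan(delta_cmi_abs(np.nan, 0.1))


class TestCrossval:
    def sets(self, rng, mu_correct, mu_other, n=200, n_el=10):
        rc, lc = poisson_rates(rng, mu_correct, n, n_el)
        ri, li = poisson_rates(rng, mu_other, max(10, n // 10), n_el)
        rf, lf = poisson_rates(rng, mu_other, n, n_el)
        return ({"correct": rc, "incorrect": ri, "fixation": rf},
                {"correct": lc, "incorrect": li, "fixation": lf})

    def test_null_everywhere_gives_zero(self):
        rng = np.random.default_rng(0)
        rates, labels = self.sets(rng, [10] * 4, [10] * 4)
        out = cmi_crossval(rates, labels, k=10, iters=100, seed=1)
        for name, vals in out.items():
            se = np.nanstd(vals, ddof=1) / np.sqrt(np.sum(~np.isnan(vals)))
            assert abs(np.nanmean(vals)) < 2 * se + 0.01, name

    def test_modulated_correct_exceeds_unmodulated_sets(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rates, labels = self.sets(rng, [13, 11, 9, 7], [10] * 4, n=120, n_el=8)
            out = cmi_crossval(rates, labels, k=10, iters=60, seed=seed)
            c = np.nanmean(out["correct"])
            if c > np.nanmean(out["incorrect"]) and c > np.nanmean(out["fixation"]):
                wins += 1
        assert wins >= 18

    def test_crossval_removes_selection_bias(self):
        # self-designated naive CMI is positively biased under the null;
        # the held-out designation must remove (most of) that bias
        rng = np.random.default_rng(2)
        rates, labels = poisson_rates(rng, [10] * 4, 100, 30)
        naive = compute_cmi(rates, labels, designate_hl(rates, labels))
        cv = cmi_crossval({"correct": rates}, {"correct": labels},
                          k=10, iters=100, seed=3)["correct"]
        bias_naive = np.nanmean(naive)
        bias_cv = abs(np.nanmean(cv))
        assert bias_naive > 0.02
        assert bias_naive > bias_cv

    def test_small_incorrect_set_adapts_folds(self):
        rng = np.random.default_rng(4)
        rc, lc = poisson_rates(rng, [10] * 4, 300, 2)
        ri, li = poisson_rates(rng, [10] * 4, 3, 2)  # ~1% of total
        out = cmi_crossval({"correct": rc, "incorrect": ri},
                           {"correct": lc, "incorrect": li},
                           k=20, iters=20, seed=5)
        assert np.isfinite(out["incorrect"]).all()


class TestAuxStatistics:
    def test_normalize_response_anchors(self):
        times = np.arange(-150.0, 300.0)
        psth = np.full(len(times), 5.0)
        psth[times >= 0] = 55.0
        psth[times >= 200] = 30.0
        out = normalize_response(psth, times)
        assert out[times < 0].mean() == pytest.approx(0.0)
        assert out.max() == pytest.approx(1.0)
        assert out[-1] == pytest.approx(0.5)

    def test_normalize_rejects_flat(self):
        times = np.arange(-150.0, 300.0)
        with pytest.raises(ValueError):
            normalize_response(np.full(len(times), 5.0), times)

    def test_rank_correlation_examples(self):
        labels = np.array(["a"] * 2 + ["b"] * 2 + ["c"] * 2 + ["d"] * 2)
        r1 = np.array([[1], [1], [2], [2], [3], [3], [4], [4]], dtype=float)
        assert epoch_rank_correlation(r1, r1, labels)[0] == pytest.approx(1.0)
        r2 = np.array([[2], [2], [1], [1], [4], [4], [3], [3]], dtype=float)
        assert epoch_rank_correlation(r1, r2, labels)[0] == pytest.approx(0.6)
        with pytest.raises(ValueError):
            epoch_rank_correlation(r1[:4], r1[:4], labels[:4])

    def test_rank_correlation_null_under_independent_rankings(self):
        rhos = []
        for seed in range(30):
            cfg = SimConfig(n_electrodes=6, n_trials_per_condition=60, seed=seed)
            s = simulate_session(cfg)
            labels = s.condition_labels()
            rhos.extend(epoch_rank_correlation(
                epoch_rates(s, (0.0, 200.0)), epoch_rates(s, (700.0, 1700.0)),
                labels))
        rhos = np.asarray(rhos)
        se = rhos.std(ddof=1) / np.sqrt(len(rhos))
        assert abs(rhos.mean()) < 2 * se + 0.02

    def test_response_correlation(self):
        rng = np.random.default_rng(0)
        labels = np.repeat([f"c{i}" for i in range(4)], 100)
        a = rng.poisson(10.0, (400, 1)).astype(float)
        b = rng.poisson(10.0, (400, 1)).astype(float)
        r_ind = epoch_response_correlation(a, b, labels)[0]
        assert abs(r_ind) < 2 / np.sqrt(100) + 0.05
        # identical epochs correlate perfectly
        assert epoch_response_correlation(a, a, labels)[0] == pytest.approx(1.0)
        # shared trial-wise gain induces positive correlation
        gain = rng.uniform(0.5, 1.5, (400, 1))
        a2 = rng.poisson(10.0 * gain)
        b2 = rng.poisson(10.0 * gain)
        assert epoch_response_correlation(a2, b2, labels)[0] > 0.1
        with pytest.raises(ValueError):
            epoch_response_correlation(a[:5], b[:5], labels[:5])
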
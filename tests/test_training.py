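"""Training protocol, metrics, statistics and profiling."""

import numpy as np
import pytest

from orientnn.model import OrientationNN
from orientnn.training import (
    TrainConfig,
    chronological_split,
    count_flops_per_frame,
    count_parameters,
    phase_error_profile,
    rmse_per_channel,
    storage_kb,
    train_on_trial,
    ttest_compare,
)


class TestChronologicalSplit:
    def test_sixty_twenty_twenty_on_100(self):
        tr, va, te = chronological_split(100)
        assert (list(tr), list(va), list(te)) == (
            list(range(60)), list(range(60, 80)), list(range(80, 100)))

    def test_full_trial_sizes(self):
        tr, va, te = chronological_split(25_200)
        assert (len(tr), len(va), len(te)) == (15_120, 5_040, 5_040)

    def test_partition_property_random_sizes(self, rng):
        for T in rng.integers(5, 10_000, size=50):
            tr, va, te = chronological_split(int(T))
            ids = np.concatenate([np.array(r, dtype=int) for r in (tr, va, te)])
            assert len(ids) == T
            np.testing.assert_array_equal(np.sort(ids), np.arange(T))
            assert tr.stop == va.start and va.stop == te.start

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            chronological_split(4)


class TestRMSE:
    def test_zero_for_equal(self, rng):
        y = rng.standard_normal((10, 12))
        np.testing.assert_array_equal(rmse_per_channel(y, y), np.zeros(12))

    def test_hand_computed_three_four(self):
        p = np.array([[3.0], [4.0]])
        t = np.zeros((2, 1))
        assert rmse_per_channel(p, t)[0] == pytest.approx(np.sqrt(12.5))

    def test_constant_offset_gives_offset(self, rng):
        t = rng.standard_normal((50, 12))
        p = t + 2.5
        np.testing.assert_allclose(rmse_per_channel(p, t), 2.5, atol=1e-12)

    def test_wrapping_applied(self):
        p = np.full((4, 12), 359.0)
        t = np.zeros((4, 12))
        np.testing.assert_allclose(rmse_per_channel(p, t), 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse_per_channel(np.zeros((0, 12)), np.zeros((0, 12)))

    def test_matches_from_definition_recomputation(self, rng):
        p = rng.uniform(-60, 60, (200, 12))
        t = rng.uniform(-60, 60, (200, 12))
        ref = np.array([
            np.sqrt(np.mean([(pi - ti) ** 2 for pi, ti in zip(p[:, j], t[:, j])]))
            for j in range(12)
        ])
        np.testing.assert_allclose(rmse_per_channel(p, t), ref, atol=1e-9)


class TestEfficiencyCensus:
    def test_orientationnn_counts(self):
        m = OrientationNN().build()
        assert count_parameters(m) == 2_760
        assert storage_kb(m) == 10.8

    def test_mlp_flops_closed_form_mac2(self):
        m = OrientationNN().build()
        assert count_flops_per_frame(m, "mac2", with_bias=False) == 4_608

    def test_mac1_is_half_of_mac2(self):
        m = OrientationNN().build()
        assert count_flops_per_frame(m, "mac1") * 2 == count_flops_per_frame(m, "mac2")

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            count_flops_per_frame(OrientationNN().build(), "macs")


class TestTTest:
    def test_identical_groups(self):
        r = ttest_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_shifted_groups(self):
        r = ttest_compare([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert r.t_statistic == pytest.approx(-1.0)
        assert r.df == 8
        assert r.mean_difference == pytest.approx(-1.0)

    def test_degenerate_equal_constants(self):
        r = ttest_compare([2.0, 2.0], [2.0, 2.0])
        assert (r.t_statistic, r.p_value) == (0.0, 1.0)

    def test_degenerate_distinct_constants(self):
        r = ttest_compare([1.0, 1.0], [2.0, 2.0])
        assert r.p_value == 0.0

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest_compare([1.0], [2.0, 3.0])

    def test_matches_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(0.8, 1.0, 10)
        r = ttest_compare(a, b)
        # brute-force permutation two-sided p on the mean difference
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        count = 0
        n_perm = 20_000
        prng = np.random.default_rng(0)
        for _ in range(n_perm):
            perm = prng.permutation(pooled)
            if abs(perm[:10].mean() - perm[10:].mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert r.p_value == pytest.approx(p_perm, abs=0.05)


class TestPhaseProfile:
    def test_zero_profile_for_equal(self, rng):
        y = rng.standard_normal((500, 12))
        phase = rng.uniform(0, 1, 500)
        prof = phase_error_profile(y, y, phase)
        assert np.nanmax(prof) == 0.0

    def test_constant_offset_everywhere(self, rng):
        y = rng.standard_normal((5000, 12))
        phase = np.mod(np.linspace(0, 10, 5000), 1.0)
        prof = phase_error_profile(y + 2.0, y, phase)
        np.testing.assert_allclose(prof[~np.isnan(prof)], 2.0, atol=1e-9)

    def test_error_localised_to_injected_phase_window(self, rng):
        T = 20_000
        phase = np.mod(np.linspace(0, 37, T), 1.0)
        y = np.zeros((T, 12))
        p = y.copy()
        window = (phase >= 0.5) & (phase < 0.6)
        p[window] += 3.0
        prof = phase_error_profile(p, y, phase)
        hot = np.nanmax(prof, axis=1) > 0
        assert hot[50:60].all()
        assert not hot[:50].any() and not hot[60:].any()

    def test_empty_bins_are_nan_not_zero(self):
        phase = np.array([0.005, 0.015])  # only bins 0 and 1 populated
        y = np.zeros((2, 12))
        prof = phase_error_profile(y, y, phase)
        assert np.isnan(prof[50]).all()
        assert not np.isnan(prof[0]).any()

    def test_out_of_range_phase_rejected(self):
        with pytest.raises(ValueError):
            phase_error_profile(np.zeros((2, 12)), np.zeros((2, 12)),
                                np.array([0.0, 1.0]))


class TestTrainLoop:
    def test_zero_learning_rate_leaves_parameters(self, clean_trial):
        m = OrientationNN(learning_rate=0.0, epochs=2, random_state=0)
        m.build()
        m2 = OrientationNN(learning_rate=0.0, epochs=2, random_state=0)
        m2.fit(clean_trial.sensor_stream[:600], clean_trial.angle_stream[:600])
        ref = OrientationNN(random_state=0).build()
        for pa, pb in zip(ref._trainable(), m2._trainable()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_loss_descends_on_offsets_trial(self, offsets_trial):
        m = OrientationNN(epochs=5, random_state=0)
        m, rep = train_on_trial(m, offsets_trial, TrainConfig(epochs=5, seed=0))
        hist = m.loss_history_["train"]
        assert hist[-1] < hist[0]
        assert len(hist) == 5
        assert len(m.loss_history_["val"]) == 5

    def test_reproducible_from_seed(self, offsets_trial):
        a = OrientationNN(epochs=2, random_state=3)
        b = OrientationNN(epochs=2, random_state=3)
        X = offsets_trial.sensor_stream[:500]
        y = offsets_trial.angle_stream[:500]
        a.fit(X, y)
        b.fit(X, y)
        assert a.loss_history_["train"] == b.loss_history_["train"]
        np.testing.assert_array_equal(a.predict(X[:7]), b.predict(X[:7]))

    def test_report_contents(self, offsets_trial):
        m = OrientationNN(epochs=2, random_state=0)
        _, rep = train_on_trial(m, offsets_trial, TrainConfig(epochs=2, seed=0))
        assert rep.per_channel_rmse.shape == (12,)
        assert rep.mean_rmse == pytest.approx(rep.per_channel_rmse.mean())
        assert rep.param_count == 2_760
        assert rep.storage_kb == 10.8
        assert rep.phase_error_profile.shape == (100, 12)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(split_fractions=(0.5, 0.2, 0.2))
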
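"""Physics-informed model: census, reduction identities, loss, gradients."""

import numpy as np
import pytest

from orientnn import autodiff as ad
from orientnn import so3
from orientnn.model import (
    OrientationNN,
    basic_joint_rotation,
    basic_module_angles,
    channel_weights_from_range,
    dynamic_offsets,
    joint_forward,
    model_forward,
    weighted_euler_loss,
)


@pytest.fixture()
def zero_model():
    """Model whose MLPs output exactly zero (pure physics prior)."""
    return OrientationNN(init_scale=0.0, random_state=0).build()


@pytest.fixture()
def small_model():
    return OrientationNN(random_state=0).build()


class TestBasicModule:
    def test_identity_child_returns_parent(self, rng):
        R = so3.random_rotation(rng, 10)
        np.testing.assert_allclose(basic_joint_rotation(R, np.broadcast_to(np.eye(3), R.shape)), R)

    def test_equal_orientations_give_identity(self, rng):
        R = so3.random_rotation(rng, 10)
        np.testing.assert_allclose(
            basic_joint_rotation(R, R), np.broadcast_to(np.eye(3), R.shape), atol=1e-12
        )

    def test_commuting_z_rotations(self):
        Rz = lambda a: so3.exp_map([0, 0, a])
        np.testing.assert_allclose(
            basic_joint_rotation(Rz(0.4), Rz(0.1)), Rz(0.3), atol=1e-12
        )


class TestParameterCensus:
    def test_total_and_per_joint_counts(self, small_model):
        assert small_model.n_parameters_ == 2760
        for j in small_model.joints_:
            assert j.n_parameters == 460  # 2 x 227 MLP + 2 x 3 calibration

    def test_mlp_shapes(self, small_model):
        j = small_model.joints_[0]
        assert j.mlp_pre["W1"].shape == (32, 3)
        assert j.mlp_pre["b1"].shape == (32,)
        assert j.mlp_pre["W2"].shape == (3, 32)
        assert j.mlp_pre["b2"].shape == (3,)

    def test_supervised_channel_partition(self, small_model):
        counts = {j.name: len(j.channels) for j in small_model.joints_}
        assert counts == {"hipR": 3, "hipL": 3, "kneeR": 1, "kneeL": 1,
                          "ankleR": 2, "ankleL": 2}
        covered = sorted(c for j in small_model.joints_ for c in j.channels)
        assert covered == list(range(12))


class TestDynamicOffsets:
    def test_zero_mlp_gives_identity_rotations(self, zero_model, rng):
        j = zero_model.joints_[0]
        R = ad.constant(so3.random_rotation(rng, 5))
        R_pre, R_post = dynamic_offsets(R, R, j.mlp_pre, j.mlp_post)
        np.testing.assert_allclose(R_pre.data, np.broadcast_to(np.eye(3), (5, 3, 3)), atol=1e-12)
        np.testing.assert_allclose(R_post.data, np.broadcast_to(np.eye(3), (5, 3, 3)), atol=1e-12)

    def test_constant_head_bias_rotation(self, zero_model, rng):
        j = zero_model.joints_[0]
        j.mlp_pre["b2"].data = np.array([0.0, 0.0, np.pi / 4])
        R = ad.constant(so3.random_rotation(rng, 5))
        R_pre, _ = dynamic_offsets(R, R, j.mlp_pre, j.mlp_post)
        expected = so3.exp_map([0, 0, np.pi / 4])
        np.testing.assert_allclose(
            R_pre.data, np.broadcast_to(expected, (5, 3, 3)), atol=1e-12
        )

    def test_outputs_always_valid_rotations(self, rng):
        m = OrientationNN(init_scale=0.5, random_state=3).build()
        j = m.joints_[0]
        R = ad.constant(so3.random_rotation(rng, 1000))
        R_pre, R_post = dynamic_offsets(R, R, j.mlp_pre, j.mlp_post)
        assert so3.is_rotation(R_pre.data, tol=1e-9).all()
        assert so3.is_rotation(R_post.data, tol=1e-9).all()


class TestReductionChain:
    def test_identity_calibration_zero_mlp_reduces_to_basic(self, zero_model, rng):
        RA = so3.random_rotation(rng, 50)
        RB = so3.random_rotation(rng, 50)
        for j in zero_model.joints_[:1]:
            eul = joint_forward(RA, RB, j).data
            ref, _ = so3.rot_to_euler_zyx(basic_joint_rotation(RA, RB))
            np.testing.assert_allclose(eul, ref, atol=1e-9)

    def test_zero_corruption_trial_reproduced_exactly(self, zero_model, clean_trial):
        pred = zero_model.predict(clean_trial.sensor_stream)
        assert np.abs(pred - clean_trial.angle_stream).max() < 1e-6

    def test_analytic_static_calibration_solves_offsets_trial(self, zero_model, offsets_trial):
        t = offsets_trial
        for j in zero_model.joints_:
            j.pre_vec.data = so3.log_map(t.true_offsets[j.parent].T)
            j.post_vec.data = so3.log_map(t.true_offsets[j.child])
        pred = zero_model.predict(t.sensor_stream)
        assert np.abs(pred - t.angle_stream).max() < 1e-6

    def test_fresh_default_model_is_near_basic_module(self, small_model, clean_trial):
        X = clean_trial.sensor_stream[:200]
        pred = small_model.predict(X)
        ref = basic_module_angles(X)
        assert np.abs(pred - ref).max() < 5.0  # small-init contract


class TestModelForward:
    def test_twelve_channels(self, small_model, clean_trial):
        pred = small_model.predict(clean_trial.sensor_stream[:10])
        assert pred.shape == (10, 12)

    def test_batched_equals_per_frame(self, small_model, clean_trial):
        X = clean_trial.sensor_stream[:20]
        batched = small_model.predict(X)
        single = np.vstack([small_model.predict(X[i:i + 1]) for i in range(20)])
        np.testing.assert_allclose(batched, single, atol=1e-12)

    def test_intermediate_rotations_valid(self, rng):
        m = OrientationNN(init_scale=0.3, random_state=1).build()
        X = so3.random_rotation(rng, (100, 7))
        for j in m.joints_:
            RA, RB = ad.constant(X[:, j.parent]), ad.constant(X[:, j.child])
            R_pre, R_post = dynamic_offsets(RA, RB, j.mlp_pre, j.mlp_post)
            core = (R_pre.data @ so3.exp_map(j.pre_vec.data) @ X[:, j.parent]
                    @ np.swapaxes(X[:, j.child], -1, -2)
                    @ so3.exp_map(j.post_vec.data) @ R_post.data)
            assert so3.is_rotation(core, tol=1e-9).all()


class TestWeightedEulerLoss:
    def test_zero_for_equal(self):
        p = np.zeros((5, 12))
        assert weighted_euler_loss(p, p, np.ones(12)) == 0.0

    def test_unit_weights_unit_errors(self):
        p = np.ones((1, 12))
        t = np.zeros((1, 12))
        assert weighted_euler_loss(p, t, np.ones(12)) == pytest.approx(12.0)

    def test_wrapping_treats_359_as_minus_one(self):
        p = np.full((1, 12), 359.0)
        t = np.zeros((1, 12))
        assert weighted_euler_loss(p, t, np.ones(12)) == pytest.approx(12.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_euler_loss(np.zeros((2, 12)), np.zeros((3, 12)), np.ones(12))

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_euler_loss(np.zeros((2, 12)), np.zeros((2, 12)), np.zeros(12))


class TestChannelWeights:
    def test_equal_ranges_give_unit_weights(self):
        np.testing.assert_allclose(channel_weights_from_range([30.0] * 12), 1.0)

    def test_two_channel_closed_form(self):
        np.testing.assert_allclose(
            channel_weights_from_range([10.0, 20.0]), [4 / 3, 2 / 3]
        )

    def test_normalisation_sums_to_channel_count(self, rng):
        r = rng.uniform(5, 80, 12)
        assert channel_weights_from_range(r).sum() == pytest.approx(12.0)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            channel_weights_from_range([10.0, 0.0])


def test_loss_gradient_matches_finite_differences(clean_trial):
    """Autodiff gradient of the training loss vs central differences, for a
    representative parameter from every parameter group of one joint."""
    m = OrientationNN(init_scale=0.05, random_state=2).build()
    X = clean_trial.sensor_stream[:32]
    y = clean_trial.angle_stream[:32] + 1.0  # avoid the |.| kink at zero

    def loss_value():
        pred = model_forward(X, m.joints_)
        return weighted_euler_loss(pred, ad.constant(y), m.channel_weights_)

    loss = loss_value()
    loss.backward()
    j = m.joints_[0]
    probes = [(j.pre_vec, 1), (j.post_vec, 0), (j.mlp_pre["W1"], 5),
              (j.mlp_pre["b2"], 2), (j.mlp_post["W2"], 7), (j.mlp_post["b1"], 11)]
    eps = 1e-6
    for p, flat_idx in probes:
        ana = p.grad.reshape(-1)[flat_idx]
        orig = p.data.copy()
        p.data = orig.copy()
        p.data.reshape(-1)[flat_idx] += eps
        up = loss_value().item()
        p.data = orig.copy()
        p.data.reshape(-1)[flat_idx] -= eps
        dn = loss_value().item()
        p.data = orig
        num = (up - dn) / (2 * eps)
        assert ana == pytest.approx(num, rel=1e-4, abs=1e-8), p.name


def test_fit_rejects_bad_shapes(clean_trial):
    m = OrientationNN(epochs=1)
    with pytest.raises(ValueError):
        m.fit(clean_trial.sensor_stream[:10], np.zeros((10, 7)))
    with pytest.raises(ValueError):
        m.fit(np.zeros((10, 6, 3, 3)), np.zeros((10, 12)))
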
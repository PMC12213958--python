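import numpy as np
import pytest

from erpsource.containers import EpochsSet
from erpsource.erp import locate_lsw_window
from erpsource.forward import LeadField
from erpsource.geometry import RoiMask, RoiMaskSet
from erpsource.inverse import (
    apply_inverse_window,
    cdr_scores,
    eloreta_weights,
    make_inverse_operator,
    roi_aggregate,
)
from erpsource.simulate import CONDITIONS


@pytest.fixture(scope="module")
def weights_tiny(lf_tiny):
    W, n_iter, converged = eloreta_weights(lf_tiny, alpha=0.0)
    assert converged
    return W


@pytest.fixture(scope="module")
def op_tiny(lf_tiny, weights_tiny):
    return make_inverse_operator(lf_tiny, weights_tiny, alpha=0.0)


class TestEloretaWeights:
    def test_blocks_symmetric_positive_definite(self, weights_tiny):
        for W in weights_tiny:
            np.testing.assert_allclose(W, W.T, atol=1e-12)
            assert np.linalg.eigvalsh(W).min() > 0

    def test_scale_invariance_of_fixed_point(self, lf_tiny):
        # scaling the lead field by c leaves the weight fixed point
        # unchanged (the pseudo-inverse contributes c^-2, cancelling the
        # c^2 from K^T M K), and scales the inverse operator by 1/c so
        # source estimates for identically generated data are unchanged
        sub = LeadField(lf_tiny.gain[:, :60], lf_tiny.channel_names, 20, 60)
        scaled = LeadField(3.0 * sub.gain, sub.channel_names, 20, 60)
        W1, _, _ = eloreta_weights(sub, alpha=0.0, tol=1e-10)
        W2, _, _ = eloreta_weights(scaled, alpha=0.0, tol=1e-10)
        np.testing.assert_allclose(W2, W1, rtol=1e-6)
        T1 = make_inverse_operator(sub, W1, alpha=0.0).operator
        T2 = make_inverse_operator(scaled, W2, alpha=0.0).operator
        np.testing.assert_allclose(T2, T1 / 3.0, rtol=1e-6)

    def test_duplicate_grid_points_get_identical_blocks(self, lf_tiny):
        gain = np.concatenate([lf_tiny.gain[:, :30], lf_tiny.gain[:, :30]], axis=1)
        lf = LeadField(gain, lf_tiny.channel_names, 20, 60)
        W, _, _ = eloreta_weights(lf, alpha=0.0)
        np.testing.assert_allclose(W[:10], W[10:], rtol=1e-8)

    def test_invalid_inputs_rejected(self, lf_tiny):
        bad = LeadField(np.full_like(lf_tiny.gain, np.nan),
                        lf_tiny.channel_names, lf_tiny.n_sources, 60)
        with pytest.raises(ValueError, match="finite"):
            eloreta_weights(bad)
        with pytest.raises(ValueError, match="alpha"):
            eloreta_weights(lf_tiny, alpha=-1.0)


class TestInverseOperator:
    def test_exact_localization_noiseless(self, lf_tiny, op_tiny, src_tiny, rng):
        # the defining eLORETA property, spot-checked on interior sources
        norms = np.linalg.norm(src_tiny.positions, axis=1)
        interior = np.flatnonzero(norms < 0.9 * norms.max())
        picks = rng.choice(interior, size=25, replace=False)
        hits = 0
        for j in picks:
            moment = rng.normal(size=3)
            phi = lf_tiny.block(j) @ moment
            mom = (op_tiny.operator @ phi).reshape(-1, 3)
            cdr = np.linalg.norm(mom, axis=1)
            hits += int(np.argmax(cdr) == j)
        assert hits / picks.size >= 0.95

    def test_zero_data_zero_moments(self, op_tiny):
        assert np.all(op_tiny.operator @ np.zeros(16) == 0.0)

    def test_linearity(self, op_tiny, rng):
        p1, p2 = rng.normal(size=(2, 16))
        lhs = op_tiny.operator @ (2.0 * p1 - 0.5 * p2)
        rhs = 2.0 * (op_tiny.operator @ p1) - 0.5 * (op_tiny.operator @ p2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12 * np.abs(lhs).max())

    def test_shape_mismatch_rejected(self, lf_tiny, weights_tiny):
        with pytest.raises(ValueError, match="shape"):
            make_inverse_operator(lf_tiny, weights_tiny[:-1])


def _epochs_for(op, data, conditions):
    n_tr, n_ch, n_s = data.shape
    times = -100.0 + 1000.0 / 512.0 * np.arange(n_s)
    return EpochsSet(np.asarray(data, float), conditions, times,
                     [f"c{i}" for i in range(n_ch)], 512.0)


class TestApplyInverse:
    def test_single_trial_equals_direct_projection(self, op_tiny, rng):
        data = rng.normal(size=(1, 16, 821))
        ep = _epochs_for(op_tiny, data, [CONDITIONS[0]])
        w = locate_lsw_window()
        mom = apply_inverse_window(op_tiny, ep, w, CONDITIONS[0])
        mask = ep.time_mask(w.start_ms, w.stop_ms)
        direct = (op_tiny.operator @ data[0][:, mask]).reshape(
            op_tiny.n_sources, 3, -1
        )
        np.testing.assert_allclose(mom, direct, atol=1e-12)

    def test_identical_conditions_identical_moments(self, op_tiny, rng):
        half = rng.normal(size=(2, 16, 821))
        data = np.concatenate([half, half])
        ep = _epochs_for(op_tiny, data, [CONDITIONS[0]] * 2 + [CONDITIONS[1]] * 2)
        w = locate_lsw_window()
        m1 = apply_inverse_window(op_tiny, ep, w, CONDITIONS[0])
        m2 = apply_inverse_window(op_tiny, ep, w, CONDITIONS[1])
        np.testing.assert_array_equal(m1, m2)

    def test_average_then_invert_equals_invert_then_average(self, op_tiny, rng):
        data = rng.normal(size=(4, 16, 821))
        ep = _epochs_for(op_tiny, data, [CONDITIONS[0]] * 4)
        w = locate_lsw_window()
        mom = apply_inverse_window(op_tiny, ep, w, CONDITIONS[0])
        mask = ep.time_mask(w.start_ms, w.stop_ms)
        per_trial = [
            (op_tiny.operator @ d[:, mask]).reshape(op_tiny.n_sources, 3, -1)
            for d in data
        ]
        np.testing.assert_allclose(mom, np.mean(per_trial, axis=0), atol=1e-10)

    def test_missing_condition_rejected(self, op_tiny, rng):
        ep = _epochs_for(op_tiny, rng.normal(size=(1, 16, 821)), [CONDITIONS[0]])
        with pytest.raises(ValueError, match="not present"):
            apply_inverse_window(op_tiny, ep, locate_lsw_window(), CONDITIONS[1])


class TestCdrScores:
    def test_constant_345_vector(self):
        mom = np.tile(np.array([3.0, 4.0, 0.0])[None, :, None], (2, 1, 7))
        np.testing.assert_allclose(cdr_scores(mom), [5.0, 5.0])

    def test_two_sample_average(self):
        mom = np.zeros((1, 3, 2))
        mom[0, :, 0] = [3.0, 4.0, 0.0]
        np.testing.assert_allclose(cdr_scores(mom), [2.5])

    def test_matches_brute_force(self, rng):
        mom = rng.normal(size=(9, 3, 11))
        brute = np.array(
            [np.mean([np.sqrt(v @ v) for v in mom[j].T]) for j in range(9)]
        )
        np.testing.assert_allclose(cdr_scores(mom), brute, rtol=1e-12)

    def test_scale_equivariance(self, rng):
        mom = rng.normal(size=(5, 3, 6))
        np.testing.assert_allclose(cdr_scores(-2.0 * mom), 2.0 * cdr_scores(mom),
                                   rtol=1e-12)
        assert np.all(cdr_scores(mom) >= 0)


class TestRoiAggregate:
    def _maskset(self, spec):
        return RoiMaskSet(
            {
                name: RoiMask(name, np.asarray(idx, int), "left", "MTL_atlas")
                for name, idx in spec.items()
            }
        )

    def test_singleton_and_mean(self):
        cdr = np.array([0.0, 1.0, 2.0, 6.0, 9.0])
        out = roi_aggregate(cdr, self._maskset({"one": [4], "three": [1, 2, 3]}))
        assert out["one"] == 9.0
        assert out["three"] == 3.0

    def test_uniform_field(self):
        cdr = np.full(10, 1.25)
        out = roi_aggregate(cdr, self._maskset({"a": [0, 5], "b": [2, 3, 4]}))
        assert all(v == 1.25 for v in out.values())

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_aggregate(np.ones(5), self._maskset({"nil": []}))
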
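import numpy as np
import pytest

from albring.hd_circuit import (
    Attractor,
    AttractorSpec,
    RscLoop,
    RscWeights,
    _bump_speed,
    build_attractor_weights,
    calibrate_velocity_gain,
    hebbian_update,
    normalize_rows,
)
from albring.world import wrap_deg

DT = 0.005


class TestAttractorWeights:
    def test_symmetric_matrix_is_circulant_and_even(self):
        w_sym, _ = build_attractor_weights(AttractorSpec(n=36))
        assert np.allclose(w_sym, w_sym.T)
        # circulant: every row is a rotation of the first
        for i in range(36):
            assert np.allclose(w_sym[i], np.roll(w_sym[0], i))

    def test_antisymmetric_matrix_is_odd(self):
        _, w_asym = build_attractor_weights(AttractorSpec(n=36))
        assert np.allclose(w_asym, -w_asym.T)
        assert np.allclose(np.diag(w_asym), 0.0)


class TestBumpDynamics:
    def test_bump_persists_at_rest(self, calibrated_spec):
        ring = Attractor(calibrated_spec)
        ring.seed_bump(-120.0)
        for _ in range(int(10.0 / DT)):
            ring.step(0.0, DT)
        assert abs(wrap_deg(ring.decode() + 120.0)) < 0.5

    def test_bump_shape_recovers_from_perturbation(self, calibrated_spec):
        ring = Attractor(calibrated_spec)
        ring.seed_bump(0.0)
        for _ in range(int(2.0 / DT)):
            ring.step(0.0, DT)
        template = ring.f.copy()
        ring.a += np.random.default_rng(4).normal(0, 0.2, calibrated_spec.n)
        for _ in range(int(10.0 / DT)):
            ring.step(0.0, DT)
        aligned = np.roll(ring.f, -int(round(ring.decode())))
        assert np.corrcoef(aligned, template)[0, 1] > 0.99

    def test_constant_rotation_advances_ten_revolutions(self, calibrated_spec):
        speed = _bump_speed(calibrated_spec, 60.0, DT, 10.0)
        total = speed * 60.0  # extrapolated 60 s of rotation
        assert total == pytest.approx(3600.0, rel=0.01)

    def test_feedback_pulls_bump_toward_offset_direction(self, calibrated_spec):
        # a feedback bump +20 deg away moves the decode monotonically there
        ring = Attractor(calibrated_spec)
        ring.seed_bump(0.0)
        for _ in range(int(1.0 / DT)):
            ring.step(0.0, DT)
        d = np.deg2rad(calibrated_spec.preferred - 20.0)
        fb = np.exp(10.0 * (np.cos(d) - 1.0))
        decodes = []
        for _ in range(int(3.0 / DT)):
            ring.step(0.0, DT, feedback=fb)
            decodes.append(ring.decode())
        assert decodes[-1] == pytest.approx(20.0, abs=2.0)
        diffs = np.diff(np.array(decodes))
        assert np.all(diffs >= -1e-6)

    def test_path_integration_gain_mismatch_accumulates_drift(self, calibrated_spec):
        import dataclasses

        spec = dataclasses.replace(calibrated_spec, pi_gain=1.05)
        drift = _bump_speed(spec, 60.0, DT, 10.0) - 60.0
        assert drift == pytest.approx(3.0, rel=0.1)  # 5% of 60 deg/s


class TestCalibration:
    def test_gain_matches_commanded_speed_within_one_percent(self, calibrated_spec):
        for om in (-120.0, -60.0, -30.0, 30.0, 60.0, 120.0):
            speed = _bump_speed(calibrated_spec, om, DT, 2.0)
            assert speed / om == pytest.approx(1.0, abs=0.01)

    def test_unstable_attractor_fails_loudly(self):
        bad = AttractorSpec(amp=0.0, inhibition=5.0)
        with pytest.raises(RuntimeError):
            calibrate_velocity_gain(bad)


class TestHebbianAndCapping:
    def test_zero_eta_no_change(self):
        W = np.ones((3, 4))
        hebbian_update(W, np.ones(3), np.ones(4), eta=0.0)
        assert np.array_equal(W, np.ones((3, 4)))

    def test_outer_product_growth(self):
        W = np.zeros((3, 4))
        post, pre = np.array([0.0, 1.0, 0.5]), np.array([1.0, 0.0, 0.0, 2.0])
        hebbian_update(W, post, pre, eta=0.1)
        assert np.allclose(W, 0.1 * np.outer(post, pre))

    def test_heterogeneous_eta_freezes_rows(self):
        W = np.zeros((2, 3))
        hebbian_update(W, np.ones(2), np.ones(3), eta=np.array([0.1, 0.0]))
        assert np.all(W[0] == 0.1) and np.all(W[1] == 0.0)

    def test_cap_only_shrinks_large_rows(self):
        W = np.array([[3.0, 4.0], [0.3, 0.4]])
        normalize_rows(W, w_max=1.0, mode="cap")
        assert np.linalg.norm(W[0]) == pytest.approx(1.0)
        assert np.allclose(W[1], [0.3, 0.4])  # below cap: untouched

    def test_printed_grow_mode_raises_small_rows(self):
        W = np.array([[3.0, 4.0], [0.3, 0.4]])
        normalize_rows(W, w_max=1.0, mode="grow")
        assert np.linalg.norm(W[0]) == pytest.approx(5.0)  # large row untouched
        assert np.linalg.norm(W[1]) == pytest.approx(1.0)

    def test_repeated_pairing_dominates_row_under_cap(self):
        # persistent co-activation of one (post, pre) pair converges to the
        # whole norm budget concentrated on that entry
        W = np.full((2, 5), 0.2)
        post = np.array([1.0, 0.0])
        pre = np.zeros(5)
        pre[3] = 1.0
        for _ in range(2000):
            hebbian_update(W, post, pre, eta=0.05)
            normalize_rows(W, w_max=1.0, mode="cap")
        assert W[0, 3] == pytest.approx(1.0, abs=1e-3)
        assert np.all(W[0, [0, 1, 2, 4]] < 0.05)

    def test_rows_never_exceed_cap_after_update(self, rng):
        W = rng.uniform(0, 1, (6, 8))
        for _ in range(100):
            hebbian_update(W, rng.uniform(0, 1, 6), rng.uniform(0, 1, 8), eta=0.2)
            normalize_rows(W, w_max=1.5, mode="cap")
            assert np.all(np.linalg.norm(W, axis=1) <= 1.5 + 1e-9)


class TestRscLoop:
    def test_grsc_inherits_unimodal_bump(self, calibrated_spec):
        ring = Attractor(calibrated_spec)
        ring.seed_bump(40.0)
        for _ in range(int(1.0 / DT)):
            ring.step(0.0, DT)
        n = calibrated_spec.n
        w = RscWeights(W_in2d=np.zeros((n, 10)), W_g2d=np.zeros((n, n)))
        loop = RscLoop(n, w)
        for _ in range(int(1.0 / DT)):
            loop.step(ring.f, np.zeros(10), DT)
        from albring.analysis import population_vector, unimodality_score

        assert abs(wrap_deg(population_vector(loop.f_g, calibrated_spec.preferred) - 40.0)) < 1.0
        assert unimodality_score(loop.f_g, 0.1)[0] == 1

    def test_silence_decays_without_drive(self):
        n = 20
        w = RscWeights(W_in2d=np.zeros((n, 5)), W_g2d=np.zeros((n, n)))
        loop = RscLoop(n, w)
        loop.a_d[:] = 1.0
        for _ in range(200):
            loop.step(np.zeros(n), np.zeros(5), DT)
        assert np.all(loop.f_d == 0.0)
        assert np.all(np.abs(loop.a_d) < 1e-3)
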
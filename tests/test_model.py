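"""Collaborative model: normalization, teaching, association, training loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comodal import (ModelParams, RunningStats, ScheduleParams, StimulusParams,
                     TeachingParams, assoc_output_and_hebb, build_model,
                     build_sequence, default_chunks, force_update,
                     init_state, integrated_output, normalize_output,
                     output_error, run_inference, step, teaching_signal, train)
from comodal.model import _run
from comodal.reservoir import ReservoirState

finite_vec = st.lists(
    st.floats(-5, 5, allow_nan=False, allow_infinity=False),
    min_size=3, max_size=3).map(np.array)


class TestRunningStats:
    def test_matches_brute_force_window(self, rng):
        win = 37
        stats = RunningStats(2, win)
        data = rng.normal(0, 2, (200, 2))
        for t, z in enumerate(data):
            stats.push(z)
            lo = max(0, t + 1 - win)
            window = data[lo:t + 1]
            assert np.allclose(stats.mean(), window.mean(axis=0), atol=1e-10)
            assert np.allclose(stats.std(), window.std(axis=0), atol=1e-10)

    def test_warm_after_full_window(self):
        stats = RunningStats(1, 10)
        for i in range(9):
            stats.push(np.array([float(i)]))
            assert not stats.warm
        stats.push(np.array([9.0]))
        assert stats.warm


class TestNormalizeOutput:
    def test_constant_series_guarded_to_zero(self):
        stats = RunningStats(3, 50)
        z = np.array([0.7, -1.0, 0.0])
        for _ in range(50):
            stats.push(z)
        assert np.all(normalize_output(z, stats) == 0)

    def test_sine_over_exact_window(self):
        win = 1000
        A = 0.8
        stats = RunningStats(1, win)
        t = np.arange(win)
        zs = A * np.sin(2 * np.pi * t / win)
        for z in zs:
            stats.push(np.array([z]))
        assert abs(stats.mean()[0]) < 1e-10
        assert abs(stats.std()[0] - A / np.sqrt(2)) < 1e-3
        out = normalize_output(np.array([A]), stats)
        assert abs(out[0] - A / (A / np.sqrt(2))) < 1e-2

    def test_matches_explicit_recomputation(self, rng):
        stats = RunningStats(3, 40)
        data = rng.normal(0, 1, (90, 3))
        for z in data:
            stats.push(z)
        window = data[-40:]
        expected = (data[-1] - window.mean(axis=0)) / window.std(axis=0)
        assert np.allclose(normalize_output(data[-1], stats), expected,
                           atol=1e-10)


class TestTeachingSignal:
    def test_zero_input_gives_zero(self):
        f = teaching_signal(np.zeros(3), TeachingParams())
        assert np.all(f == 0)

    def test_hand_evaluated_case(self):
        # zhat=(1,0,0), gamma=0.5, beta=3: winner tanh(1/3), losers clipped
        f = teaching_signal(np.array([1.0, 0.0, 0.0]), TeachingParams())
        assert np.allclose(f, [np.tanh(1 / 3), 0.0, 0.0], atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(finite_vec)
    def test_permutation_equivariance(self, zhat):
        teaching = TeachingParams()
        perm = np.array([2, 0, 1])
        f = teaching_signal(zhat, teaching)
        f_perm = teaching_signal(zhat[perm], teaching)
        assert np.allclose(f_perm, f[perm], atol=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(finite_vec)
    def test_strict_maximum_gets_largest_teacher(self, zhat):
        f = teaching_signal(zhat, TeachingParams())
        assert np.all((f >= 0) & (f < 1))
        i = int(np.argmax(zhat))
        if np.sum(zhat == zhat[i]) == 1:
            assert f[i] >= f.max() - 1e-12


class TestOutputsAndAssociation:
    def test_output_error_cases(self, rng):
        z = rng.normal(0, 1, 3)
        assert np.all(output_error(z, z) == 0)
        assert np.array_equal(output_error(np.array([1.0, 0, 0]), np.zeros(3)),
                              [1.0, 0, 0])
        f = rng.normal(0, 1, 3)
        assert np.allclose(output_error(z, f), z - f)
        with pytest.raises(ValueError):
            output_error(np.zeros(3), np.zeros(4))

    def test_integrated_output_identities(self, rng):
        v = rng.normal(0, 1, 3)
        assert np.allclose(integrated_output(v, v, 0.5), v)
        assert np.all(integrated_output(v, -v, 0.5) == 0)
        z1, z2 = rng.normal(0, 1, (2, 3))
        assert np.allclose(integrated_output(z1, z2, 0.5), 0.5 * (z1 + z2))

    def test_hebb_uniform_rates_freeze_weights(self, rng):
        w = (rng.uniform(0, 0.1, (3, 3)), rng.uniform(0, 0.1, (3, 3)))
        z = np.full(3, 0.4)
        o, (w1, w2) = assoc_output_and_hebb(z, z, w, dt=1.0, eta=0.1)
        assert np.allclose(w1, w[0], atol=1e-14)
        assert np.allclose(w2, w[1], atol=1e-14)

    def test_hebb_zero_output_freezes_weights(self, rng):
        w = (np.zeros((3, 3)), np.zeros((3, 3)))
        z1, z2 = rng.normal(0, 1, (2, 3))
        o, (w1, w2) = assoc_output_and_hebb(z1, z2, w, dt=1.0, eta=0.1)
        assert np.all(o == 0) and np.all(w1 == 0) and np.all(w2 == 0)

    def test_hebb_single_euler_step_hand_check(self):
        w1 = np.array([[0.1, 0.0, 0.0]] * 3)
        w2 = np.array([[0.0, 0.2, 0.0]] * 3)
        z1 = np.array([1.0, 0.0, 0.0])
        z2 = np.array([0.0, 0.5, 0.0])
        o, (n1, n2) = assoc_output_and_hebb(z1, z2, (w1, w2), dt=2.0, eta=0.5)
        o_hand = w1 @ z1 + w2 @ z2
        assert np.allclose(o, o_hand)
        dw1 = np.outer(o_hand, z1 - z1.sum() / 3)
        assert np.allclose(n1, w1 + 2.0 * 0.5 * dw1, atol=1e-14)

    @settings(deadline=None, derandomize=True)
    @given(finite_vec, finite_vec)
    def test_hebb_row_sums_conserved(self, z1, z2):
        rng = np.random.default_rng(0)
        w = (rng.uniform(0, 0.1, (3, 3)), rng.uniform(0, 0.1, (3, 3)))
        _, (w1, w2) = assoc_output_and_hebb(z1, z2, w, dt=1.0, eta=1.0)
        assert np.allclose(w1.sum(axis=1), w[0].sum(axis=1), atol=1e-10)
        assert np.allclose(w2.sum(axis=1), w[1].sum(axis=1), atol=1e-10)


class TestBuildModel:
    def params(self):
        return (ModelParams(N=50, S=15, I=26), ModelParams(N=40, S=15, I=30))

    def test_original_has_no_cross_matrices(self, rng):
        p1, p2 = self.params()
        m = build_model("original", p1, p2, TeachingParams(), rng)
        assert m.W_in_inter_1 is None and m.W_back_inter_1 is None
        assert m.R1 is None and m.assoc_w1 is None

    def test_a1_cross_density(self, rng):
        p1 = ModelParams(N=300, S=50, I=26)
        p2 = ModelParams(N=300, S=50, I=30)
        m = build_model("a1", p1, p2, TeachingParams(), rng)
        frac = (m.W_in_inter_1 != 0).mean()
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / m.W_in_inter_1.size)
        assert m.W_in_inter_2.shape == (300, 300)
        assert m.assoc_w1 is not None

    def test_a2_cross_feedback_bounded(self, rng):
        p1, p2 = self.params()
        m = build_model("a2", p1, p2, TeachingParams(), rng)
        assert m.W_back_inter_1.shape == (50, 3)
        assert np.all(np.abs(m.W_back_inter_1) <= 1.0)
        assert np.all(np.abs(m.W_back_inter_2) <= 1.0)

    def test_a3_readout_coupling(self, rng):
        p1, p2 = self.params()
        m = build_model("a3", p1, p2, TeachingParams(), rng)
        assert m.R1.shape == (3, 3) and m.R2.shape == (3, 3)
        assert np.all(np.abs(m.R1) <= 1.0)

    def test_unknown_variant_rejected(self, rng):
        p1, p2 = self.params()
        with pytest.raises(ValueError):
            build_model("a4", p1, p2, TeachingParams(), rng)


def _tiny_setup(variant, seed=0, C=6):
    stim = StimulusParams()
    p1 = ModelParams(N=30, S=8, I=26, k=0.2, force_interval=2)
    p2 = ModelParams(N=26, S=8, I=30, k=0.2, force_interval=2)
    teaching = TeachingParams(T=400.0)
    rng = np.random.default_rng(seed)
    model = build_model(variant, p1, p2, teaching, rng)
    track = build_sequence(ScheduleParams(C=C, seed=seed), default_chunks(), stim)
    return model, track


class TestTrainInference:
    def test_zero_length_track_returns_model_unchanged(self):
        model, track = _tiny_setup("original")
        track.modality1 = track.modality1[:0]
        track.modality2 = track.modality2[:0]
        w0 = model.rc1.W_out.copy()
        model2, log = train(model, track, seed=0)
        assert np.array_equal(model2.rc1.W_out, w0)
        assert log.z1.shape == (0, 3)

    def test_training_modifies_readouts_only(self):
        model, track = _tiny_setup("original")
        W0 = model.rc1.W.copy()
        back0 = model.rc1.W_back.copy()
        wout0 = model.rc1.W_out.copy()
        train(model, track, seed=1)
        assert np.array_equal(model.rc1.W, W0)
        assert np.array_equal(model.rc1.W_back, back0)
        assert not np.array_equal(model.rc1.W_out, wout0)

    def test_inference_deterministic_and_frozen(self):
        model, track = _tiny_setup("original")
        train(model, track, seed=1)
        wout = model.rc1.W_out.copy()
        a = run_inference(model, track, seed=5)
        b = run_inference(model, track, seed=5)
        assert np.array_equal(a.z1, b.z1) and np.array_equal(a.o, b.o)
        assert np.array_equal(model.rc1.W_out, wout)

    def test_width_mismatch_rejected(self):
        model, track = _tiny_setup("original")
        track.modality1 = track.modality1[:, :20]
        with pytest.raises(ValueError):
            run_inference(model, track, seed=0)

    def test_rate_snapshots_recorded_at_stride(self):
        model, track = _tiny_setup("original")
        res = run_inference(model, track, seed=3, record_stride=4)
        n = (track.n_steps + 3) // 4
        assert res.r1.shape == (n, 30) and res.r2.shape == (n, 26)
        assert np.all(np.abs(res.r1) <= 1)  # tanh rates (can round to 1.0)


@pytest.mark.parametrize("variant", ["original", "a1", "a2", "a3"])
def test_fused_kernel_matches_composed_operations(variant):
    """The compiled training loop reproduces the public per-step operations."""
    model, track = _tiny_setup(variant, seed=3, C=4)
    p1, p2 = model.rc1.params, model.rc2.params
    teaching = model.teaching
    win = teaching.window_steps(p1.dt)
    T = track.n_steps

    # reference pass composed from the public operations
    ref = model.copy()
    rng = np.random.default_rng(7)
    s1 = init_state(ref.rc1, rng)
    s2 = init_state(ref.rc2, rng)
    st1, st2 = RunningStats(3, win), RunningStats(3, win)
    noise1 = rng.standard_normal((T, p1.N))
    noise2 = rng.standard_normal((T, p2.N))
    z1_ref = np.empty((T, 3))
    f1_ref = np.empty((T, 3))
    o_ref = np.empty((T, 3))
    for t in range(T):
        z1 = ref.rc1.W_out @ s1.r
        z2 = ref.rc2.W_out @ s2.r
        if variant == "a3":
            z1, z2 = z1 + ref.R1 @ z2, z2 + ref.R2 @ z1
        st1.push(z1)
        st2.push(z2)
        f1 = np.zeros(3)
        f2 = np.zeros(3)
        if st1.warm:
            zh1 = normalize_output(z1, st1, teaching.sigma_floor)
            zh2 = normalize_output(z2, st2, teaching.sigma_floor)
            if variant == "original":
                f1, f2 = teaching_signal(zh2, teaching), teaching_signal(zh1, teaching)
            else:
                f1, f2 = teaching_signal(zh1, teaching), teaching_signal(zh2, teaching)
        if st1.warm and t % p1.force_interval == 0:
            force_update(ref.rc1, s1.r, output_error(z1, f1))
            force_update(ref.rc2, s2.r, output_error(z2, f2))
        if variant == "original":
            o = integrated_output(z1, z2, teaching.delta)
        else:
            o, (ref.assoc_w1, ref.assoc_w2) = assoc_output_and_hebb(
                z1, z2, (ref.assoc_w1, ref.assoc_w2), p1.dt,
                teaching.hebb_eta if st1.warm else 0.0)
        z1_ref[t], f1_ref[t], o_ref[t] = z1, f1, o
        extra1 = np.zeros(p1.N)
        extra2 = np.zeros(p2.N)
        if variant == "a1":
            extra1 = ref.W_in_inter_1 @ s2.r
            extra2 = ref.W_in_inter_2 @ s1.r
        elif variant == "a2":
            extra1 = ref.W_back_inter_1 @ z2
            extra2 = ref.W_back_inter_2 @ z1
        x1 = s1.x + (p1.dt / p1.tau) * (
            p1.g * (ref.rc1.W @ s1.r)
            + ref.rc1.in_weight * track.modality1[t][ref.rc1.in_index]
            + ref.rc1.W_back @ z1 + extra1 + p1.k * noise1[t] - s1.x)
        x2 = s2.x + (p2.dt / p2.tau) * (
            p2.g * (ref.rc2.W @ s2.r)
            + ref.rc2.in_weight * track.modality2[t][ref.rc2.in_index]
            + ref.rc2.W_back @ z2 + extra2 + p2.k * noise2[t] - s2.x)
        s1 = ReservoirState(x=x1, r=np.tanh(x1), z=z1)
        s2 = ReservoirState(x=x2, r=np.tanh(x2), z=z2)

    # fused pass (same noise stream: block_size > T, same generator state)
    fused = model.copy()
    res = _run(fused, track, np.random.default_rng(7), learn=True,
               block_size=10 ** 6)

    assert np.allclose(res.z1, z1_ref, atol=1e-9)
    assert np.allclose(res.f1, f1_ref, atol=1e-9)
    assert np.allclose(res.o, o_ref, atol=1e-9)
    assert np.allclose(fused.rc1.W_out, ref.rc1.W_out, atol=1e-9)
    assert np.allclose(fused.rc2.P, ref.rc2.P, atol=1e-9)
    if variant != "original":
        assert np.allclose(fused.assoc_w1, ref.assoc_w1, atol=1e-9)


def test_trained_model_checkpoint_roundtrip(tmp_path):
    model, track = _tiny_setup("a2", seed=5)
    train(model, track, seed=2)
    path = tmp_path / "model.h5"
    model.save(path)
    back = type(model).load(path)
    assert back.variant == "a2"
    assert np.allclose(back.rc1.W, model.rc1.W)
    assert np.allclose(back.rc1.W_out, model.rc1.W_out)
    assert np.allclose(back.rc2.P, model.rc2.P)
    assert np.allclose(back.W_back_inter_1, model.W_back_inter_1)
    assert np.allclose(back.assoc_w1, model.assoc_w1)
    assert back.rc1.params == model.rc1.params
    # a warm restart behaves identically
    a = run_inference(model, track, seed=9)
    b = run_inference(back, track, seed=9)
    assert np.allclose(a.o, b.o)
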
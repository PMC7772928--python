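"""Attention network: oracle equivalence, softmax laws, gradients, variants."""

import math

import numpy as np
import pytest

from pave.ehr_data import Demographics, Event, Patient
from pave.pave_model import (
    AttentionParams,
    ModelVariant,
    bce_loss,
    pattern_attend,
    predict_risk,
    self_attend,
)

from .conftest import make_model


def brute_force_self_attention(q, params):
    """Independent O(n^2 k) double-loop evaluation of the attention equations."""
    n, k = q.shape
    Q = np.array([q[i] @ params.W_Q + params.b_Q for i in range(n)])
    K = np.array([q[i] @ params.W_K + params.b_K for i in range(n)])
    V = np.array([q[i] @ params.W_V + params.b_V for i in range(n)])
    alpha = np.zeros((n, n))
    for i in range(n):
        beta = [float(Q[i] @ K[j]) for j in range(n)]
        denom = sum(math.exp(b) for b in beta)
        for j in range(n):
            alpha[i, j] = math.exp(beta[j]) / denom
    P = np.zeros((n, k))
    for i in range(n):
        P[i] = V[i].copy()
        for j in range(n):
            P[i] += alpha[i, j] * V[j]
    return P, alpha


class TestSelfAttend:
    def test_singleton_softmax_plus_residual(self):
        rng = np.random.default_rng(0)
        params = AttentionParams.init(4, rng)
        q = rng.normal(size=(1, 4))
        P, alpha = self_attend(q, params)
        assert np.allclose(alpha, [[1.0]])
        V = q[0] @ params.W_V + params.b_V
        assert np.allclose(P[0], 2.0 * V)

    def test_uniform_weights_when_scores_equal(self):
        rng = np.random.default_rng(1)
        params = AttentionParams.init(4, rng)
        params.W_Q[:] = 0.0
        params.b_Q[:] = 0.0  # all beta_ij = 0
        q = rng.normal(size=(2, 4))
        P, alpha = self_attend(q, params)
        assert np.allclose(alpha, 0.5)
        V = q @ params.W_V + params.b_V
        assert np.allclose(P[0], V[0] + 0.5 * (V[0] + V[1]))
        assert np.allclose(P[1], V[1] + 0.5 * (V[0] + V[1]))

    def test_brute_force_oracle_random_inputs(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(1, 6))
            k = 2 * int(rng.integers(1, 5))
            params = AttentionParams.init(k, rng)
            q = rng.normal(size=(n, k))
            P, alpha = self_attend(q, params)
            P2, alpha2 = brute_force_self_attention(q, params)
            assert np.abs(P - P2).max() < 1e-5
            assert np.abs(alpha - alpha2).max() < 1e-5

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        params = AttentionParams.init(6, rng)
        q = rng.normal(size=(7, 6))
        _, alpha = self_attend(q, params)
        assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-5)

    def test_empty_input_errors(self):
        rng = np.random.default_rng(4)
        params = AttentionParams.init(4, rng)
        with pytest.raises(ValueError):
            self_attend(np.zeros((0, 4)), params)

    def test_exclude_self_zeroes_diagonal(self):
        rng = np.random.default_rng(5)
        params = AttentionParams.init(4, rng)
        q = rng.normal(size=(3, 4))
        _, alpha = self_attend(q, params, include_self=False)
        assert np.allclose(np.diag(alpha), 0.0)
        assert np.allclose(alpha.sum(axis=1), 1.0)


class TestPatternAttend:
    def test_uniform_when_scores_equal(self):
        rng = np.random.default_rng(0)
        params = AttentionParams.init(4, rng)
        params.W_p[:] = 0.0
        P = rng.normal(size=(5, 4))
        h, gamma = pattern_attend(P, params)
        assert np.allclose(gamma, 0.2)
        assert np.allclose(h, P.mean(axis=0))

    def test_singleton(self):
        rng = np.random.default_rng(1)
        params = AttentionParams.init(4, rng)
        P = rng.normal(size=(1, 4))
        h, gamma = pattern_attend(P, params)
        assert gamma == pytest.approx([1.0])
        assert np.allclose(h, P[0])

    def test_hand_softmax(self):
        params = AttentionParams.init(2, np.random.default_rng(2))
        params.W_p[:] = [1.0, 0.0]
        params.b_p[...] = 0.0
        P = np.array([[math.log(3.0), 0.0], [0.0, 0.0]])
        _, gamma = pattern_attend(P, params)
        assert gamma == pytest.approx([0.75, 0.25], abs=1e-12)


class TestRiskAndLoss:
    def test_sigmoid_values(self):
        params = AttentionParams.init(2, np.random.default_rng(0))
        params.W_h[:] = [1.0, 0.0]
        params.b_h[...] = 0.0
        assert predict_risk(np.array([0.0, 5.0]), params) == pytest.approx(0.5)
        assert predict_risk(np.array([math.log(3.0), 0.0]), params) == pytest.approx(0.75)
        ys = [predict_risk(np.array([z, 0.0]), params) for z in (0.0, 2.0, 10.0, 30.0)]
        assert all(a < b for a, b in zip(ys, ys[1:])) and ys[-1] < 1.0

    def test_bce_closed_form(self):
        assert bce_loss(0.5, 1) == pytest.approx(math.log(2.0))
        assert bce_loss(0.9, 0) == pytest.approx(-math.log(0.1))
        assert bce_loss(1.0 - 1e-9, 1) < 1e-6
        with pytest.raises(ValueError):
            bce_loss(0.5, 2)


def encoded_permutation(enc, perm):
    """Apply one permutation jointly to all per-event arrays of an encoding."""
    from dataclasses import replace

    return replace(
        enc,
        var_idx=enc.var_idx[perm],
        real_mask=enc.real_mask[perm],
        v_t=enc.v_t[perm],
        v_ev=enc.v_ev[perm],
        s_norm=enc.s_norm[perm],
    )


class TestForward:
    def test_trace_softmax_conservation(self, variables, toy_patient):
        model = make_model(variables, k=8)
        trace = model.forward(toy_patient)
        assert np.allclose(trace.alpha.sum(axis=1), 1.0, atol=1e-5)
        assert trace.gamma.sum() == pytest.approx(1.0, abs=1e-5)
        assert 0.0 < trace.y < 1.0

    def test_permutation_invariance(self, variables, toy_patient):
        model = make_model(variables, k=8)
        enc = model.encode(toy_patient)
        y0 = model._forward(enc)["y"]
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = rng.permutation(len(toy_patient.events))
            y1 = model._forward(encoded_permutation(enc, perm))["y"]
            assert abs(y1 - y0) < 1e-5

    def test_duplicate_forward_is_deterministic(self, variables, toy_patient):
        model = make_model(variables, k=8)
        a, b = model.forward(toy_patient), model.forward(toy_patient)
        assert a.y == b.y
        assert np.array_equal(a.alpha, b.alpha)

    def test_empty_window_errors(self, variables):
        model = make_model(variables, k=8)
        demo = Demographics(gender="male", age_group="60-69")
        with pytest.raises(ValueError, match="empty window"):
            model.forward(Patient("e", demo, [], 0))

    def test_no_time_variant_ignores_times(self, variables):
        model = make_model(variables, k=8, variant=ModelVariant(False, True))
        demo = Demographics(gender="male", age_group="60-69")
        ev = lambda t0: [
            Event("heart_rate", 120.0, t0, 0),
            Event("resp_rate", 25.0, t0 + 3.0, 1),
        ]
        y_a = model.predict(Patient("a", demo, ev(0.0), 1))
        y_b = model.predict(Patient("b", demo, [
            Event("heart_rate", 120.0, 0.0, 0),
            Event("resp_rate", 25.0, 9.0, 1),  # different lag structure
        ], 1))
        assert y_a == y_b  # bit-stable: time never enters

    def test_full_model_sensitive_to_time(self, variables):
        model = make_model(variables, k=8)
        demo = Demographics(gender="male", age_group="60-69")
        y_a = model.predict(Patient("a", demo, [
            Event("heart_rate", 120.0, 0.0, 0), Event("resp_rate", 25.0, 3.0, 1)], 1))
        y_b = model.predict(Patient("b", demo, [
            Event("heart_rate", 120.0, 0.0, 0), Event("resp_rate", 25.0, 9.0, 1)], 1))
        assert y_a != y_b

    def test_translation_invariance_of_recency_lags(self, variables):
        # uniform time shifts leave recency lags, hence predictions, unchanged
        model = make_model(variables, k=8)
        demo = Demographics(gender="male", age_group="60-69")
        base = [Event("heart_rate", 120.0, 0.0, 0), Event("resp_rate", 25.0, 3.0, 1)]
        shifted = [Event(e.variable_id, e.value, e.time + 5.0, e.collection_id) for e in base]
        assert model.predict(Patient("a", demo, base, 1)) == model.predict(
            Patient("b", demo, shifted, 1)
        )


class TestGradients:
    @pytest.mark.parametrize(
        "variant", [ModelVariant(True, True), ModelVariant(False, True), ModelVariant(True, False)],
        ids=["full", "no-time", "no-value"],
    )
    def test_finite_difference_agreement(self, variables, toy_patient, variant):
        model = make_model(variables, k=6, seed=7, variant=variant)
        enc = model.encode(toy_patient)
        _, grads, _ = model.loss_and_grads(enc, 1)
        params = model.parameters()
        rng = np.random.default_rng(0)
        eps = 1e-6
        for name, arr in params.items():
            flat = arr.reshape(-1)
            picks = rng.choice(flat.size, size=min(10, flat.size), replace=False)
            for i in picks:
                orig = flat[i]
                flat[i] = orig + eps
                lp, _, _ = model.loss_and_grads(enc, 1)
                flat[i] = orig - eps
                lm, _, _ = model.loss_and_grads(enc, 1)
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - grads[name].reshape(-1)[i]) < 1e-4, name


class TestCheckpoint:
    def test_save_load_round_trip(self, variables, toy_patient, tmp_path):
        from pave.pave_model import PaveModel

        model = make_model(variables, k=8, seed=2)
        y = model.predict(toy_patient)
        path = tmp_path / "model.npz"
        model.save(path)
        back = PaveModel.load(path)
        assert back.predict(toy_patient) == y
        assert back.config.k == model.config.k
        assert back.stats.t_m == model.stats.t_m
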
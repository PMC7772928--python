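"""The PAVE network: self-attention over events, pattern attention, risk head.

Architecture (single attention layer, single head):

* per-event embeddings ``q_i`` from :mod:`pave.embeddings`;
* self-attention ``Q_i = q_i W_Q + b_Q`` (K, V likewise),
  ``beta_ij = Q_i . K_j``, ``alpha_i. = softmax_j(beta_ij)``,
  ``P_i = V_i + sum_j alpha_ij V_j`` — each ``P_i`` is a *pattern vector*
  pairing event i with the events it attends to;
* pattern attention ``theta_i = P_i . W_p + b_p``, ``gamma = softmax(theta)``,
  ``h = sum_i gamma_i P_i``;
* risk head ``y = sigmoid(h . W_h + b_h)`` trained with binary cross-entropy.

Raw attention scores are used without 1/sqrt(k) scaling and the softmax runs
over all events including the query itself (both switchable).

Two ablation variants are provided: the no-time-embedding variant feeds a
zero vector for ``v_t``, and the no-value-embedding variant replaces the
sinusoidal value embedding by a learned linear map of the min-max-normalized
scalar value (with per-variable training-split means standing in when a
scalar must be filled).

The whole network is plain numpy; gradients are computed by the explicit
reverse-mode pass in :meth:`PaveModel.loss_and_grads` (checked against
finite differences in the test suite).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .ehr_data import Patient, VariableSpec
from .embeddings import EmbeddingConfig, EmbeddingParams, sinusoid

EPS_LOGIT = 1e-7


def _softmax_rows(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class AttentionParams:
    """Learnable parameters of the attention stages and risk head."""

    W_Q: np.ndarray
    W_K: np.ndarray
    W_V: np.ndarray
    b_Q: np.ndarray
    b_K: np.ndarray
    b_V: np.ndarray
    W_p: np.ndarray  # (k,)
    b_p: np.ndarray  # ()
    W_h: np.ndarray  # (k,)
    b_h: np.ndarray  # ()

    @classmethod
    def init(cls, k: int, rng: np.random.Generator) -> "AttentionParams":
        bound = 1.0 / np.sqrt(k)
        u = lambda *shape: rng.uniform(-bound, bound, size=shape)
        return cls(
            W_Q=u(k, k), W_K=u(k, k), W_V=u(k, k),
            b_Q=np.zeros(k), b_K=np.zeros(k), b_V=np.zeros(k),
            W_p=u(k), b_p=np.zeros(()), W_h=u(k), b_h=np.zeros(()),
        )


@dataclass
class ModelVariant:
    """Which embedding channels are active.

    ``use_time_embedding=False`` is the no-time ablation; with
    ``use_value_embedding=False`` the sinusoidal value embedding is replaced
    by a learned linear map of the normalized scalar value.
    """

    use_time_embedding: bool = True
    use_value_embedding: bool = True

    @property
    def name(self) -> str:
        if self.use_time_embedding and self.use_value_embedding:
            return "PAVE"
        if not self.use_time_embedding and self.use_value_embedding:
            return "PAVE-T"
        if self.use_time_embedding and not self.use_value_embedding:
            return "PAVE-V"
        return "PAVE-TV"


PAVE = ModelVariant(True, True)
PAVE_NO_TIME = ModelVariant(False, True)
PAVE_NO_VALUE = ModelVariant(True, False)


@dataclass
class AttentionTrace:
    """Everything captured during one forward pass, for interpretation.

    ``alpha`` is the row-stochastic self-attention matrix, ``gamma`` the
    pattern weights, ``P`` the pattern vectors, ``h`` the patient vector and
    ``y`` the predicted risk in (0, 1).
    """

    alpha: np.ndarray  # (n, n)
    gamma: np.ndarray  # (n,)
    P: np.ndarray  # (n, k)
    h: np.ndarray  # (k,)
    y: float


# ---------------------------------------------------------------------------
# Stand-alone operations
# ---------------------------------------------------------------------------


def self_attend(
    q: np.ndarray,
    params: AttentionParams,
    *,
    include_self: bool = True,
    scale_scores: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Self-attention over event embeddings ``q`` (n, k) -> (P, alpha)."""
    P, alpha, _ = _self_attend_cached(q, params, include_self, scale_scores)
    return P, alpha


def _self_attend_cached(q, params, include_self, scale_scores):
    n = q.shape[0]
    if n == 0:
        raise ValueError("self_attend requires at least one event")
    Q = q @ params.W_Q + params.b_Q
    K = q @ params.W_K + params.b_K
    V = q @ params.W_V + params.b_V
    scale = 1.0 / np.sqrt(q.shape[1]) if scale_scores else 1.0
    beta = (Q @ K.T) * scale
    if not include_self and n > 1:
        np.fill_diagonal(beta, -np.inf)
    alpha = _softmax_rows(beta)
    P = V + alpha @ V
    return P, alpha, {"Q": Q, "K": K, "V": V, "scale": scale}


def pattern_attend(P: np.ndarray, params: AttentionParams) -> tuple[np.ndarray, np.ndarray]:
    """Pattern attention: weight pattern vectors into one patient vector h."""
    theta = P @ params.W_p + float(params.b_p)
    gamma = _softmax_rows(theta)
    return gamma @ P, gamma


def predict_risk(h: np.ndarray, params: AttentionParams) -> float:
    """Risk head: sigmoid of a linear readout of the patient vector."""
    z = float(h @ params.W_h + params.b_h)
    return float(1.0 / (1.0 + np.exp(-z)))


def bce_loss(y: float, y_true: int) -> float:
    """Binary cross-entropy, with the prediction clamped away from {0, 1}."""
    if y_true not in (0, 1):
        raise ValueError(f"y_true must be 0 or 1, got {y_true}")
    y = min(max(y, EPS_LOGIT), 1.0 - EPS_LOGIT)
    return float(-(y_true * np.log(y) + (1 - y_true) * np.log(1.0 - y)))


# ---------------------------------------------------------------------------
# Fitted normalization statistics (training split only)
# ---------------------------------------------------------------------------


@dataclass
class FittedStats:
    """Normalization constants derived from the training split only.

    Per-variable min/max for the value embedding (the empirical training
    range, widened to include the declared normal range and clipped to the
    declared physical bounds), per-variable means for the no-value-embedding
    variant, and the maximum time lag ``t_m``.
    """

    variables: dict[str, VariableSpec]
    means: dict[str, float]
    t_m: float

    @classmethod
    def fit(cls, patients: list[Patient], variables: dict[str, VariableSpec]) -> "FittedStats":
        from .ehr_data import compute_time_deltas

        values: dict[str, list[float]] = {v: [] for v in variables}
        t_m = 0.0
        for p in patients:
            if p.events:
                t_m = max(t_m, float(compute_time_deltas(p).max()))
            for e in p.events:
                values[e.variable_id].append(e.value)
        fitted: dict[str, VariableSpec] = {}
        means: dict[str, float] = {}
        for vid, spec in variables.items():
            if spec.kind != "real":
                fitted[vid] = spec
                continue
            obs = values[vid]
            lo = min(obs) if obs else spec.v_min
            hi = max(obs) if obs else spec.v_max
            if spec.normal_low is not None:
                lo = min(lo, spec.normal_low)
                hi = max(hi, spec.normal_high)
            lo = max(lo, spec.v_min)
            hi = min(hi, spec.v_max)
            if not lo < hi:
                lo, hi = spec.v_min, spec.v_max
            fitted[vid] = replace(spec, v_min=lo, v_max=hi)
            means[vid] = float(np.mean(obs)) if obs else 0.5 * (lo + hi)
        return cls(variables=fitted, means=means, t_m=max(t_m, 1e-6))


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


@dataclass
class _Encoded:
    """Fixed (non-learnable) per-patient arrays, precomputed once."""

    var_idx: np.ndarray  # (n,) int
    real_mask: np.ndarray  # (n,) float 0/1
    v_t: np.ndarray  # (n, k); zeros when the time channel is off
    v_ev: np.ndarray  # (n, k) sinusoidal value embedding; zeros at boolean rows
    s_norm: np.ndarray  # (n,) normalized scalar values (no-value-embedding path)
    demo_idx: np.ndarray  # (|d|,) int
    label: int
    patient_id: str


class PaveModel:
    """PAVE network with parameters, fitted stats and explicit gradients."""

    def __init__(
        self,
        vocab: list[str],
        demo_vocab: list[str],
        config: EmbeddingConfig,
        variant: ModelVariant = PAVE,
        seed: int = 0,
        *,
        include_self: bool = True,
        scale_scores: bool = False,
    ) -> None:
        rng = np.random.default_rng(seed)
        k = config.k
        self.config = config
        self.variant = variant
        self.include_self = include_self
        self.scale_scores = scale_scores
        self.emb = EmbeddingParams.init(vocab, demo_vocab, k, rng)
        self.att = AttentionParams.init(k, rng)
        bound = 1.0 / np.sqrt(k)
        self.w_val = rng.uniform(-bound, bound, size=k)  # no-value-embedding map
        self.b_val = np.zeros(k)
        self.stats: FittedStats | None = None

    # -- parameters ---------------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        """Live references to every trainable array (updated in place)."""
        p = {
            "event_table": self.emb.event_table,
            "demo_table": self.emb.demo_table,
            "W_v": self.emb.W_v, "W_e": self.emb.W_e, "b_e": self.emb.b_e,
            "W_vd": self.emb.W_vd, "W_ve": self.emb.W_ve,
            "W_qe": self.emb.W_qe, "W_qt": self.emb.W_qt, "W_qd": self.emb.W_qd,
            "b_q": self.emb.b_q,
            "W_Q": self.att.W_Q, "W_K": self.att.W_K, "W_V": self.att.W_V,
            "b_Q": self.att.b_Q, "b_K": self.att.b_K, "b_V": self.att.b_V,
            "W_p": self.att.W_p, "b_p": self.att.b_p,
            "W_h": self.att.W_h, "b_h": self.att.b_h,
        }
        if not self.variant.use_value_embedding:
            p["w_val"] = self.w_val
            p["b_val"] = self.b_val
        return p

    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())

    # -- fitting normalization stats ---------------------------------------

    def fit_stats(self, train_patients: list[Patient], variables: dict[str, VariableSpec]) -> None:
        """Derive min/max, means and t_m from the training split only."""
        self.stats = FittedStats.fit(train_patients, variables)
        self.config.t_m = self.stats.t_m

    # -- encoding -----------------------------------------------------------

    def encode(self, patient: Patient) -> _Encoded:
        """Precompute the fixed arrays for one patient window."""
        from .ehr_data import compute_time_deltas

        if self.stats is None:
            raise RuntimeError("call fit_stats() before encoding patients")
        if not patient.events:
            raise ValueError(f"patient {patient.patient_id}: empty window")
        n, k = len(patient.events), self.config.k
        var_idx = np.array(
            [self.emb.var_index[e.variable_id] for e in patient.events], dtype=int
        )
        specs = [self.stats.variables[e.variable_id] for e in patient.events]
        real_mask = np.array([1.0 if s.kind == "real" else 0.0 for s in specs])

        deltas = compute_time_deltas(patient)
        if self.variant.use_time_embedding:
            t_norm = np.clip(deltas, 0.0, self.config.t_m) / self.config.t_m
            v_t = sinusoid(t_norm, k, self.config.j_base)
        else:
            v_t = np.zeros((n, k))

        s_norm = np.zeros(n)
        v_ev = np.zeros((n, k))
        for i, (e, s) in enumerate(zip(patient.events, specs)):
            if s.kind != "real":
                continue
            v = s.clamp(e.value)
            s_norm[i] = (v - s.v_min) / (s.v_max - s.v_min)
        if self.variant.use_value_embedding:
            rows = real_mask > 0
            v_ev[rows] = sinusoid(s_norm[rows], k, self.config.j_base)

        demo_idx = np.array(
            [self.emb.demo_index[a] for a in patient.demographics.attributes()], dtype=int
        )
        return _Encoded(
            var_idx=var_idx, real_mask=real_mask, v_t=v_t, v_ev=v_ev,
            s_norm=s_norm, demo_idx=demo_idx, label=patient.label,
            patient_id=patient.patient_id,
        )

    # -- forward ------------------------------------------------------------

    def _forward(self, enc: _Encoded) -> dict:
        emb, att = self.emb, self.att
        m = enc.real_mask[:, None]
        E = emb.event_table[enc.var_idx]
        if self.variant.use_value_embedding:
            VV = enc.v_ev
        else:
            VV = enc.s_norm[:, None] * self.w_val + self.b_val
        lin = VV @ emb.W_v + E @ emb.W_e + emb.b_e
        Ve = m * lin + (1.0 - m) * E

        D = emb.demo_table[enc.demo_idx]  # (|d|, k)
        beta_d = (D @ emb.W_vd)[None, :] + (Ve @ emb.W_ve)[:, None]  # (n, |d|)
        Ad = _softmax_rows(beta_d)
        Vda = Ad @ D

        q = Ve @ emb.W_qe + enc.v_t @ emb.W_qt + Vda @ emb.W_qd + emb.b_q
        P, alpha, sa = _self_attend_cached(q, att, self.include_self, self.scale_scores)
        h, gamma = pattern_attend(P, att)
        y = predict_risk(h, att)
        return {
            "enc": enc, "E": E, "VV": VV, "lin": lin, "Ve": Ve, "D": D,
            "Ad": Ad, "Vda": Vda, "q": q, "P": P, "alpha": alpha,
            "Q": sa["Q"], "K": sa["K"], "V": sa["V"], "scale": sa["scale"],
            "gamma": gamma, "h": h, "y": y,
        }

    def forward(self, patient: Patient) -> AttentionTrace:
        """Run the network on one patient window and return the full trace."""
        c = self._forward(self.encode(patient))
        return AttentionTrace(alpha=c["alpha"], gamma=c["gamma"], P=c["P"], h=c["h"], y=c["y"])

    def predict(self, patient: Patient) -> float:
        return self.forward(patient).y

    # -- backward -----------------------------------------------------------

    def loss_and_grads(self, enc: _Encoded, y_true: int | None = None):
        """One forward + explicit reverse pass; returns (loss, grads, y).

        Gradient keys match :meth:`parameters`.
        """
        if y_true is None:
            y_true = enc.label
        c = self._forward(enc)
        emb, att = self.emb, self.att
        y = min(max(c["y"], EPS_LOGIT), 1.0 - EPS_LOGIT)
        loss = bce_loss(y, y_true)

        P, alpha, gamma, h = c["P"], c["alpha"], c["gamma"], c["h"]
        Q, K, V, q = c["Q"], c["K"], c["V"], c["q"]
        Ve, Vda, D, Ad = c["Ve"], c["Vda"], c["D"], c["Ad"]
        E, VV, m = c["E"], c["VV"], c["enc"].real_mask[:, None]
        enc_ = c["enc"]

        g: dict[str, np.ndarray] = {}
        # risk head (sigmoid + BCE collapse to y - y_true)
        dz = y - y_true
        g["W_h"] = dz * h
        g["b_h"] = np.asarray(dz)
        dh = dz * att.W_h

        # pattern attention
        dgamma = P @ dh
        dP = np.outer(gamma, dh)
        dtheta = gamma * (dgamma - float(gamma @ dgamma))
        g["W_p"] = P.T @ dtheta
        g["b_p"] = np.asarray(dtheta.sum())
        dP += np.outer(dtheta, att.W_p)

        # self-attention
        dV = dP + alpha.T @ dP
        dA = dP @ V.T
        dB = alpha * (dA - (alpha * dA).sum(axis=1, keepdims=True))
        dB *= c["scale"]
        dQ = dB @ K
        dK = dB.T @ Q
        g["W_Q"] = q.T @ dQ
        g["W_K"] = q.T @ dK
        g["W_V"] = q.T @ dV
        g["b_Q"] = dQ.sum(axis=0)
        g["b_K"] = dK.sum(axis=0)
        g["b_V"] = dV.sum(axis=0)
        dq = dQ @ att.W_Q.T + dK @ att.W_K.T + dV @ att.W_V.T

        # fusion layer
        g["W_qe"] = Ve.T @ dq
        g["W_qt"] = enc_.v_t.T @ dq
        g["W_qd"] = Vda.T @ dq
        g["b_q"] = dq.sum(axis=0)
        dVe = dq @ emb.W_qe.T
        dVda = dq @ emb.W_qd.T

        # demographic attention
        dAd = dVda @ D.T
        gD = Ad.T @ dVda
        dbeta = Ad * (dAd - (Ad * dAd).sum(axis=1, keepdims=True))
        g["W_vd"] = D.T @ dbeta.sum(axis=0)
        gD += np.outer(dbeta.sum(axis=0), emb.W_vd)
        g["W_ve"] = Ve.T @ dbeta.sum(axis=1)
        dVe += np.outer(dbeta.sum(axis=1), emb.W_ve)

        # value/event combination
        dlin = m * dVe
        g["W_v"] = VV.T @ dlin
        g["W_e"] = E.T @ dlin
        g["b_e"] = dlin.sum(axis=0)
        dE = dlin @ emb.W_e.T + (1.0 - m) * dVe
        if not self.variant.use_value_embedding:
            dVV = dlin @ emb.W_v.T
            g["w_val"] = (enc_.s_norm[:, None] * dVV).sum(axis=0)
            g["b_val"] = dVV.sum(axis=0)

        # embedding tables (scatter-add)
        g["event_table"] = np.zeros_like(emb.event_table)
        np.add.at(g["event_table"], enc_.var_idx, dE)
        g["demo_table"] = np.zeros_like(emb.demo_table)
        np.add.at(g["demo_table"], enc_.demo_idx, gD)
        return loss, g, c["y"]

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        """Save parameters, config, vocabularies and fitted stats (.npz)."""
        meta = {
            "vocab": self.emb.vocab,
            "demo_vocab": self.emb.demo_vocab,
            "k": self.config.k,
            "t_m": self.config.t_m,
            "j_base": self.config.j_base,
            "use_time_embedding": self.variant.use_time_embedding,
            "use_value_embedding": self.variant.use_value_embedding,
            "include_self": self.include_self,
            "scale_scores": self.scale_scores,
            "stats": None,
        }
        if self.stats is not None:
            meta["stats"] = {
                "t_m": self.stats.t_m,
                "means": self.stats.means,
                "variables": {
                    vid: {kk: vv for kk, vv in vars(s).items()}
                    for vid, s in self.stats.variables.items()
                },
            }
        arrays = {f"param_{k}": v for k, v in self.parameters().items()}
        arrays["w_val"] = self.w_val
        arrays["b_val"] = self.b_val
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "PaveModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        config = EmbeddingConfig(k=meta["k"], t_m=meta["t_m"], j_base=meta["j_base"])
        variant = ModelVariant(meta["use_time_embedding"], meta["use_value_embedding"])
        model = cls(
            meta["vocab"], meta["demo_vocab"], config, variant,
            include_self=meta["include_self"], scale_scores=meta["scale_scores"],
        )
        for name, arr in model.parameters().items():
            arr[...] = data[f"param_{name}"]
        model.w_val[...] = data["w_val"]
        model.b_val[...] = data["b_val"]
        if meta["stats"] is not None:
            st = meta["stats"]
            model.stats = FittedStats(
                variables={vid: VariableSpec(**rec) for vid, rec in st["variables"].items()},
                means=st["means"],
                t_m=st["t_m"],
            )
        return model
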
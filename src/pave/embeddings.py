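"""Sinusoidal time/value embeddings, demographic attention, and event fusion.

Each observed event is turned into a single vector ``q`` of dimension ``k``
by combining four ingredients:

* a **time embedding** ``v_t`` — a continuous sinusoidal encoding of the
  event's recency lag ``t`` (hours behind the most recent event), with the
  j-th dimension ``sin(t*j/(t_m*k))`` for even j and ``cos`` for odd j,
  where ``t_m`` is the maximum lag seen in training;
* a **value embedding** ``v_ev`` — the same encoding applied to the
  min-max-normalized measurement value, so a numeric value becomes a vector
  without any imputation of unobserved variables;
* a learned **event-type embedding** ``v_ee`` (one table row per variable),
  combined with ``v_ev`` by a linear layer into ``v_e`` (boolean events use
  the raw table row directly);
* a **demographic attention** output ``v_da`` — a softmax-weighted mix of
  the patient's demographic embedding rows, with weights conditioned on
  ``v_e`` so different events can attend to age vs gender differently.

``q = v_e W_qe + v_t W_qt + v_da W_qd + b_q``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ehr_data import Demographics, Event, VariableSpec

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    """Dimension and scaling constants for the sinusoidal embeddings.

    ``k`` is the embedding dimension (even, >= 2); ``t_m`` the maximum time
    lag in hours (lags above it are clamped); ``j_base`` the dimension index
    origin (0 by convention — dimension 0 is then constantly 0).
    """

    k: int = 32
    t_m: float = 48.0
    j_base: int = 0

    def __post_init__(self) -> None:
        if self.k < 2 or self.k % 2:
            raise ValueError(f"k must be even and >= 2, got {self.k}")
        if self.t_m <= 0:
            raise ValueError(f"t_m must be positive, got {self.t_m}")
        if self.j_base not in (0, 1):
            raise ValueError(f"j_base must be 0 or 1, got {self.j_base}")


def sinusoid(x_norm: np.ndarray, k: int, j_base: int = 0) -> np.ndarray:
    """Sinusoidal encoding of normalized scalars in [0, 1] -> shape (..., k).

    Dimension j (j = j_base .. j_base+k-1) is ``sin(x*j/k)`` for even j and
    ``cos(x*j/k)`` for odd j.  Arguments stay in [0, (j_base+k-1)/k] <= 1 for
    x in [0, 1], so the map is smooth, bounded in [-1, 1] and injective.
    """
    x = np.asarray(x_norm, dtype=float)[..., None]
    j = np.arange(j_base, j_base + k, dtype=float)
    arg = x * j / k
    out = np.where(j.astype(int) % 2 == 0, np.sin(arg), np.cos(arg))
    return out


def time_embed(t: float, config: EmbeddingConfig) -> np.ndarray:
    """Embed a recency lag ``t`` (hours) into a k-vector (Eq.-style sinusoid).

    ``t`` must be non-negative; lags above ``t_m`` are clamped with a warning.
    """
    if t < 0:
        raise ValueError(f"time lag must be non-negative, got {t}")
    if t > config.t_m:
        logger.warning("clamping time lag %g to t_m=%g", t, config.t_m)
        t = config.t_m
    return sinusoid(t / config.t_m, config.k, config.j_base)


def value_embed(value: float, spec: VariableSpec, config: EmbeddingConfig) -> np.ndarray:
    """Embed a real measurement value into a k-vector.

    The value is min-max normalized with the variable's own range, then
    passed through the same sinusoidal map as the time embedding; two values
    at the same normalized position in different variables embed identically.
    """
    if spec.kind != "real":
        raise ValueError(f"{spec.variable_id}: value_embed applies to real variables only")
    if spec.v_max == spec.v_min:
        raise ValueError(f"{spec.variable_id}: degenerate range v_min == v_max")
    v = spec.clamp(value)
    x = (v - spec.v_min) / (spec.v_max - spec.v_min)
    return sinusoid(x, config.k, config.j_base)


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], k: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(k)
    return rng.uniform(-bound, bound, size=shape)


@dataclass
class EmbeddingParams:
    """Learnable parameters of the embedding module.

    ``event_table`` holds one row per variable (the event-type embedding);
    ``demo_table`` one row per demographic category.  The remaining arrays
    are the linear layers fusing value, event, time and demographic vectors.
    """

    vocab: list[str]
    demo_vocab: list[str]
    event_table: np.ndarray  # (|vocab|, k)
    demo_table: np.ndarray  # (|demo_vocab|, k)
    W_v: np.ndarray  # (k, k)
    W_e: np.ndarray  # (k, k)
    b_e: np.ndarray  # (k,)
    W_vd: np.ndarray  # (k,)
    W_ve: np.ndarray  # (k,)
    W_qe: np.ndarray  # (k, k)
    W_qt: np.ndarray  # (k, k)
    W_qd: np.ndarray  # (k, k)
    b_q: np.ndarray  # (k,)
    var_index: dict[str, int] = field(default_factory=dict)
    demo_index: dict[str, int] = field(default_factory=dict)

    @classmethod
    def init(
        cls, vocab: list[str], demo_vocab: list[str], k: int, rng: np.random.Generator
    ) -> "EmbeddingParams":
        """Seeded uniform(-1/sqrt(k), 1/sqrt(k)) init; biases start at zero."""
        u = lambda *shape: _uniform_init(rng, shape, k)
        return cls(
            vocab=list(vocab),
            demo_vocab=list(demo_vocab),
            event_table=u(len(vocab), k),
            demo_table=u(len(demo_vocab), k),
            W_v=u(k, k),
            W_e=u(k, k),
            b_e=np.zeros(k),
            W_vd=u(k),
            W_ve=u(k),
            W_qe=u(k, k),
            W_qt=u(k, k),
            W_qd=u(k, k),
            b_q=np.zeros(k),
            var_index={v: i for i, v in enumerate(vocab)},
            demo_index={d: i for i, d in enumerate(demo_vocab)},
        )


@dataclass
class EventEmbedding:
    """All intermediate vectors produced while embedding one event."""

    v_t: np.ndarray
    v_ev: np.ndarray | None
    v_e: np.ndarray
    v_da: np.ndarray
    demo_weights: np.ndarray
    q: np.ndarray


def combine_event_value(
    event: Event, spec: VariableSpec, params: EmbeddingParams, config: EmbeddingConfig
) -> np.ndarray:
    """Fuse value and event-type embeddings into ``v_e``.

    Real variables: ``v_e = v_ev W_v + v_ee W_e + b_e``.  Boolean variables
    carry no magnitude, so the raw event-table row is used directly.
    """
    if event.variable_id not in params.var_index:
        raise KeyError(f"variable {event.variable_id!r} not in embedding vocabulary")
    v_ee = params.event_table[params.var_index[event.variable_id]]
    if spec.kind == "boolean":
        return v_ee
    v_ev = value_embed(event.value, spec, config)
    return v_ev @ params.W_v + v_ee @ params.W_e + params.b_e


def demographic_attend(
    demographics: Demographics, v_e: np.ndarray, params: EmbeddingParams
) -> tuple[np.ndarray, np.ndarray]:
    """Attend over the patient's demographic rows, conditioned on ``v_e``.

    Per attribute j: score ``beta_j = v_j^d . W_vd + v_e . W_ve``; weights
    ``alpha = softmax(beta)``; returns (sum_j alpha_j v_j^d, alpha).
    """
    rows = np.stack(
        [params.demo_table[params.demo_index[a]] for a in demographics.attributes()]
    )
    beta = rows @ params.W_vd + float(v_e @ params.W_ve)
    beta = beta - beta.max()
    alpha = np.exp(beta)
    alpha /= alpha.sum()
    return alpha @ rows, alpha


def embed_event(
    event: Event,
    t_delta: float,
    demographics: Demographics,
    spec: VariableSpec,
    params: EmbeddingParams,
    config: EmbeddingConfig,
) -> EventEmbedding:
    """Embed one event (value, recency lag, demographics) into ``q``.

    Reference per-event path; the model uses an equivalent vectorized route.
    """
    v_t = time_embed(t_delta, config)
    v_ev = value_embed(event.value, spec, config) if spec.kind == "real" else None
    v_e = combine_event_value(event, spec, params, config)
    v_da, demo_w = demographic_attend(demographics, v_e, params)
    q = v_e @ params.W_qe + v_t @ params.W_qt + v_da @ params.W_qd + params.b_q
    return EventEmbedding(v_t=v_t, v_ev=v_ev, v_e=v_e, v_da=v_da, demo_weights=demo_w, q=q)
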
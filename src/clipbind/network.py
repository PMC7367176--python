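"""Forward computation of the convolutional BLSTM binding model.

Architecture, per input sequence:

1. a bank of rectified 1D convolution filters (one filter per size,
   default sizes 4-8, no bias) scans whole one-hot bases (stride = one
   base on the linearized encoding);
2. winner-takes-all (WTA) enhancement of each filter's score vector: the
   single maximum is doubled, then every entry is squared;
3. track reconstruction: for each filter, the one-hot matrix is rebuilt
   with each base's 1 replaced by the enhanced score of the placement
   starting at that base;
4. the tracks plus the raw one-hot column of each base form one time-step
   input vector x_t of dimension 4*(n_filters + 1);
5. a bidirectional LSTM reads x_1..x_T forwards and backwards; row t of
   the hidden matrix H is [h_fwd_t ; h_bwd_t]; padded time steps are
   skipped by the recurrence (state carry-through), so the output is
   invariant to the amount of zero padding;
6. the output node is a single fixed sigmoid unit with weight 1.0 and no
   bias applied to the row sums of H, with padding rows zeroed out.

The per-position row sums (padding removed) are the binding profile;
``score = sigmoid(sum(profile))`` is the classification score.  Positive
profile values mark bases resembling the bound (class 1) training
sequences, negative values mark background-like bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from clipbind.encoding import EncodedSequence, encode_batch
from clipbind.seq_io import VOCABULARY, NamedSequence

DEFAULT_FILTER_SIZES = (4, 5, 6, 7, 8)
DEFAULT_HIDDEN_SIZE = 20
CONV_INIT = 0.01
BLSTM_INIT_STD = 0.01

_GATES = ("i", "f", "g", "o")


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ConvFilterBank:
    """One rectified convolution filter per size; no bias parameters.

    ``filters[k]`` has shape (m_k, 4) with columns in vocabulary order
    (A, C, G, U).
    """

    filters: list[np.ndarray]

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(w.shape[0] for w in self.filters)

    @property
    def max_size(self) -> int:
        return max(self.sizes)

    @classmethod
    def initialize(
        cls, sizes: Sequence[int] = DEFAULT_FILTER_SIZES, init: float = CONV_INIT
    ) -> "ConvFilterBank":
        return cls([np.full((m, 4), init, dtype=np.float64) for m in sizes])


@dataclass
class LSTMGateParams:
    """Parameters of one LSTM direction.

    Gates are stored concatenated in the order (input, forget, modulatory,
    output): ``W_x`` is (input_dim, 4*hidden), ``W_h`` is (hidden,
    4*hidden), ``b`` is (4*hidden,).  Per-gate views are exposed as
    ``W_xi``, ``W_hf``, ``b_g`` etc.
    """

    W_x: np.ndarray
    W_h: np.ndarray
    b: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_h.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_x.shape[0]

    def _slice(self, gate: str) -> slice:
        k = _GATES.index(gate)
        n = self.hidden_size
        return slice(k * n, (k + 1) * n)

    def __getattr__(self, name: str):
        # W_xi / W_hf / b_o style accessors
        if name.startswith("W_x") and len(name) == 4 and name[3] in _GATES:
            return self.W_x[:, self._slice(name[3])]
        if name.startswith("W_h") and len(name) == 4 and name[3] in _GATES:
            return self.W_h[:, self._slice(name[3])]
        if name.startswith("b_") and len(name) == 3 and name[2] in _GATES:
            return self.b[self._slice(name[2])]
        raise AttributeError(name)

    @classmethod
    def initialize(
        cls,
        input_dim: int,
        hidden_size: int,
        rng: np.random.Generator,
        std: float = BLSTM_INIT_STD,
    ) -> "LSTMGateParams":
        return cls(
            W_x=rng.normal(0.0, std, size=(input_dim, 4 * hidden_size)),
            W_h=rng.normal(0.0, std, size=(hidden_size, 4 * hidden_size)),
            b=rng.normal(0.0, std, size=4 * hidden_size),
        )


@dataclass
class LSTMState:
    """Hidden output ``h`` and cell ``c`` of one LSTM direction."""

    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zero(cls, hidden_size: int) -> "LSTMState":
        return cls(np.zeros(hidden_size), np.zeros(hidden_size))


@dataclass
class BindingProfile:
    """Per-nucleotide profile values (padding removed) and the score.

    Invariant: ``score == sigmoid(values.sum())`` up to floating point.
    """

    values: np.ndarray
    score: float


@dataclass
class ModelParams:
    """All model parameters.  ``output_weight`` is fixed at 1.0 and never
    receives gradient updates (the output node is bias-free)."""

    conv: ConvFilterBank
    fwd: LSTMGateParams
    bwd: LSTMGateParams
    output_weight: float = 1.0

    @property
    def filter_sizes(self) -> tuple[int, ...]:
        return self.conv.sizes

    @property
    def n_filters(self) -> int:
        return len(self.conv.filters)

    @property
    def input_dim(self) -> int:
        return 4 * (self.n_filters + 1)

    @property
    def hidden_size(self) -> int:
        return self.fwd.hidden_size

    @classmethod
    def initialize(
        cls,
        filter_sizes: Sequence[int] = DEFAULT_FILTER_SIZES,
        hidden_size: int = DEFAULT_HIDDEN_SIZE,
        rng: Optional[np.random.Generator] = None,
        conv_init: float = CONV_INIT,
        blstm_std: float = BLSTM_INIT_STD,
    ) -> "ModelParams":
        rng = np.random.default_rng(0) if rng is None else rng
        conv = ConvFilterBank.initialize(filter_sizes, conv_init)
        input_dim = 4 * (len(conv.filters) + 1)
        return cls(
            conv=conv,
            fwd=LSTMGateParams.initialize(input_dim, hidden_size, rng, blstm_std),
            bwd=LSTMGateParams.initialize(input_dim, hidden_size, rng, blstm_std),
        )

    def to_arrays(self) -> dict[str, np.ndarray]:
        arrays = {f"conv{k}": w for k, w in enumerate(self.conv.filters)}
        for tag, p in (("fwd", self.fwd), ("bwd", self.bwd)):
            arrays[f"{tag}_W_x"] = p.W_x
            arrays[f"{tag}_W_h"] = p.W_h
            arrays[f"{tag}_b"] = p.b
        return arrays

    @classmethod
    def from_arrays(
        cls,
        arrays: dict[str, np.ndarray],
        filter_sizes: Sequence[int],
        hidden_size: int,
        output_weight: float = 1.0,
    ) -> "ModelParams":
        conv = ConvFilterBank([arrays[f"conv{k}"] for k in range(len(filter_sizes))])
        fwd = LSTMGateParams(arrays["fwd_W_x"], arrays["fwd_W_h"], arrays["fwd_b"])
        bwd = LSTMGateParams(arrays["bwd_W_x"], arrays["bwd_W_h"], arrays["bwd_b"])
        if fwd.hidden_size != hidden_size:
            raise ValueError("hidden size inconsistent with stored arrays")
        return cls(conv=conv, fwd=fwd, bwd=bwd, output_weight=output_weight)

    def copy(self) -> "ModelParams":
        return ModelParams(
            conv=ConvFilterBank([w.copy() for w in self.conv.filters]),
            fwd=LSTMGateParams(self.fwd.W_x.copy(), self.fwd.W_h.copy(), self.fwd.b.copy()),
            bwd=LSTMGateParams(self.bwd.W_x.copy(), self.bwd.W_h.copy(), self.bwd.b.copy()),
            output_weight=self.output_weight,
        )


@dataclass
class ModelBundle:
    """Trained (or initialized) parameters plus configuration and provenance.

    ``config`` must carry ``max_length`` (the longest training sequence);
    encodings at prediction time are padded to it so that profiles and
    scores are comparable with training.
    """

    params: ModelParams
    config: dict
    vocabulary: tuple = VOCABULARY
    metadata: dict = field(default_factory=dict)

    @property
    def max_length(self) -> int:
        return int(self.config["max_length"])


# ---------------------------------------------------------------------------
# forward-pass operations
# ---------------------------------------------------------------------------

def conv_scan(enc: EncodedSequence, bank: ConvFilterBank) -> list[np.ndarray]:
    """Rectified convolution scores, one vector per filter.

    For a filter of size m on a padded length L there are L - m + 1
    whole-base placements; placement p covers padded positions p..p+m-1.
    """
    L = enc.padded_length
    out = []
    for W in bank.filters:
        m = W.shape[0]
        if m > L:
            raise ValueError(f"filter size {m} exceeds padded length {L}")
        n_place = L - m + 1
        pre = np.zeros(n_place)
        for i in range(m):
            pre += enc.onehot[i : i + n_place, :] @ W[i]
        out.append(np.maximum(pre, 0.0))
    return out


def wta_enhance(scores: np.ndarray) -> np.ndarray:
    """Winner-takes-all enhancement: double the single maximum entry (first
    occurrence on ties), then square every entry."""
    doubled = np.asarray(scores, dtype=np.float64).copy()
    doubled[int(np.argmax(doubled))] *= 2.0
    return doubled * doubled


def build_tracks(
    enhanced: Sequence[np.ndarray],
    enc: EncodedSequence,
    assignment: str = "start",
) -> list[np.ndarray]:
    """Rebuild one scaled one-hot track per filter.

    Under the default ``"start"`` rule the value assigned to padded position
    j is the enhanced score of the placement whose first position is j (the
    flank margins guarantee every real base has one).  The alternative
    ``"max_cover"`` rule assigns the maximum enhanced score over all
    placements covering j; it is kept for sensitivity analysis.
    """
    L = enc.padded_length
    tracks = []
    for e in enhanced:
        n_place = e.shape[0]
        m = L - n_place + 1
        assigned = np.zeros(L)
        if assignment == "start":
            assigned[:n_place] = e
        elif assignment == "max_cover":
            for j in range(L):
                lo = max(0, j - m + 1)
                hi = min(j, n_place - 1)
                if lo <= hi:
                    assigned[j] = e[lo : hi + 1].max()
        else:
            raise ValueError(f"unknown assignment rule {assignment!r}")
        tracks.append(enc.onehot * assigned[:, None])
    return tracks


def assemble_timesteps(
    tracks: Sequence[np.ndarray], enc: EncodedSequence
) -> np.ndarray:
    """Per-base time-step inputs: the filter tracks for base t followed by
    the raw one-hot column, dimension 4*(n_filters + 1)."""
    return np.concatenate([*tracks, enc.onehot], axis=1)


def lstm_step(x_t: np.ndarray, prev: LSTMState, p: LSTMGateParams) -> LSTMState:
    """One LSTM time step.

    i = sigma(W_xi x + W_hi h + b_i), f and o likewise, g = tanh(.),
    c = f*c_prev + i*g, h = o*tanh(c).
    """
    a = x_t @ p.W_x + prev.h @ p.W_h + p.b
    n = p.hidden_size
    i = sigmoid(a[0 * n : 1 * n])
    f = sigmoid(a[1 * n : 2 * n])
    g = np.tanh(a[2 * n : 3 * n])
    o = sigmoid(a[3 * n : 4 * n])
    c = f * prev.c + i * g
    return LSTMState(h=o * np.tanh(c), c=c)


def blstm_forward(
    xs: np.ndarray,
    fwd: LSTMGateParams,
    bwd: LSTMGateParams,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Bidirectional pass over time-step inputs ``xs`` of shape (T, D).

    Returns H of shape (T, 2*hidden): row t is the concatenation of the
    forward hidden vector at t and the (re-reversed) backward hidden vector
    at t.  Initial h and c are zero.

    When ``mask`` is given, padded time steps (mask 0) are skipped by the
    recurrence: the hidden and cell state carry through unchanged.  This
    makes profiles and scores invariant to the amount of zero padding
    around the real sequence.
    """
    T = xs.shape[0]
    if T < 1:
        raise ValueError("need at least one time step")
    state = LSTMState.zero(fwd.hidden_size)
    h_f = np.empty((T, fwd.hidden_size))
    for t in range(T):
        if mask is None or mask[t]:
            state = lstm_step(xs[t], state, fwd)
        h_f[t] = state.h
    state = LSTMState.zero(bwd.hidden_size)
    h_b = np.empty((T, bwd.hidden_size))
    for t in range(T - 1, -1, -1):
        if mask is None or mask[t]:
            state = lstm_step(xs[t], state, bwd)
        h_b[t] = state.h
    return np.concatenate([h_f, h_b], axis=1)


def profile_and_score(
    H: np.ndarray, enc: EncodedSequence, output_weight: float = 1.0
) -> BindingProfile:
    """Row-sum H, zero padding rows, keep real positions, score by sigmoid.

    ``values[j]`` is the profile value of the j-th real base; the score is
    ``sigmoid(output_weight * values.sum())`` with the weight fixed at 1.0.
    """
    row_sums = H.sum(axis=1) * enc.mask
    values = row_sums[enc.mask > 0]
    score = float(sigmoid(output_weight * values.sum()))
    return BindingProfile(values=values, score=score)


def forward(
    seq: NamedSequence,
    model: ModelParams,
    max_length: Optional[int] = None,
    assignment: str = "start",
) -> BindingProfile:
    """Full deterministic forward pass on a single sequence (no dropout)."""
    enc = encode_batch([seq], model.filter_sizes, max_length=max_length)[0]
    return forward_encoded(enc, model, assignment=assignment)


def forward_encoded(
    enc: EncodedSequence, model: ModelParams, assignment: str = "start"
) -> BindingProfile:
    """Forward pass on an already-encoded sequence."""
    scores = conv_scan(enc, model.conv)
    enhanced = [wta_enhance(s) for s in scores]
    tracks = build_tracks(enhanced, enc, assignment=assignment)
    xs = assemble_timesteps(tracks, enc)
    H = blstm_forward(xs, model.fwd, model.bwd, mask=enc.mask)
    return profile_and_score(H, enc, model.output_weight)


def predict_scores(
    seqs: Sequence[NamedSequence],
    bundle: ModelBundle,
) -> np.ndarray:
    """Classification scores for a batch of sequences under a trained bundle."""
    from clipbind._backprop import batch_predict  # local: training internals

    return batch_predict(seqs, bundle.params, bundle.max_length)
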
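"""Semi-supervised double-attention denoiser for diagnosis sequences.

The module scores every position of an embedded diagnosis sequence and drops
positions that look like noise diagnoses (short-lived, seasonally driven
codes such as influenza-like illnesses). Architecture:

1. a *full-sequence block* — forward and backward sigmoid recurrences whose
   concatenated states are projected back to the hidden size, capturing each
   code's role in the whole sequence;
2. a *noise block* — a single reverse-direction recurrence emphasizing the
   short-range structure in which noise codes live;
3. the two block outputs are mixed position-wise, ``v_t = alpha*h_t +
   beta*h_hat_t``, with the mixing weights taken from corpus conditional
   probabilities (trigger given noise history, and vice versa);
4. a scaled-dot-product attention layer over the mixed sequence, whose
   per-position attention mass ``a_i`` is turned into a keep-score
   ``f_s(a_i) = sigmoid(w'*a_i + b')``.

Training is semi-supervised: only positions whose code belongs to the known
noise set (label 1) or to the trigger/target sets (label 0) carry labels;
everything else contributes no label loss. At extraction time a position is
kept iff its keep-score strictly exceeds the threshold ``theta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._tensor import Adam, Tensor, concat
from .sequences import AlignedSequences, PAD_CODE, PatientRecord

__all__ = [
    "MixWeights", "Denoiser", "ExtractionRule", "extract", "train_denoiser",
]

_NEG = -1e9  # additive mask for padded attention logits


@dataclass
class MixWeights:
    """Mixing weights for the two first-layer blocks: ``v = a*h + b*h_hat``.

    By convention ``alpha`` is the probability of a trigger diagnosis given a
    noise-diagnosis history and ``beta`` the reverse conditional; both are
    estimated at the patient level from a training corpus.
    """

    alpha: float
    beta: float

    @classmethod
    def from_corpus(cls, records: Sequence[PatientRecord],
                    noise: Sequence[str], trigger: str) -> "MixWeights":
        noise = set(noise)
        n_a = n_b = n_ab = 0
        for rec in records:
            codes = set(rec.disease_positions())
            has_a = bool(codes & noise)
            has_b = trigger in codes
            n_a += has_a
            n_b += has_b
            n_ab += has_a and has_b
        alpha = n_ab / n_a if n_a else 0.0   # P(trigger | noise history)
        beta = n_ab / n_b if n_b else 0.0    # P(noise history | trigger)
        return cls(alpha=alpha, beta=beta)


@dataclass
class ExtractionRule:
    """Keep/drop rule: keep position i iff the dense score exceeds theta."""

    theta: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must lie strictly in (0, 1)")


def _sigmoid_rnn(X: Tensor, Wh: Tensor, Wx: Tensor, b: Tensor) -> Tensor:
    """Fused sigmoid RNN with hand-written backpropagation through time.

    A single tape node: the forward loop stores the hidden states and the
    backward pass replays them, which keeps long sequences cheap compared to
    taping every timestep.
    """
    Xd = X.data
    B, n, _ = Xd.shape
    q = b.data.shape[0]
    XP = Xd @ Wx.data.T + b.data  # input contribution, all steps at once
    H = np.empty((B, n, q))
    h = np.zeros((B, q))
    for t in range(n):
        h = 1.0 / (1.0 + np.exp(-(h @ Wh.data.T + XP[:, t])))
        H[:, t] = h

    def backward(g):
        dX = np.zeros_like(Xd)
        dWh = np.zeros_like(Wh.data)
        dWx = np.zeros_like(Wx.data)
        db = np.zeros_like(b.data)
        carry = np.zeros((B, q))
        for t in range(n - 1, -1, -1):
            gt = g[:, t] + carry
            pre = gt * H[:, t] * (1.0 - H[:, t])
            hprev = H[:, t - 1] if t > 0 else np.zeros((B, q))
            dWh += pre.T @ hprev
            dWx += pre.T @ Xd[:, t]
            db += pre.sum(axis=0)
            dX[:, t] = pre @ Wx.data
            carry = pre @ Wh.data
        return (dX, dWh, dWx, db)

    return X._make(H, (X, Wh, Wx, b), backward)


def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    scale = np.sqrt(6.0 / sum(shape[-2:])) if len(shape) > 1 else 0.1
    return rng.uniform(-scale, scale, size=shape)


class Denoiser:
    """Parameter bundle and forward pass of the double-attention module.

    ``p`` is the input (disease-embedding) dimension and ``q`` the hidden
    size. All parameters are seeded, so construction and training are
    reproducible.
    """

    def __init__(self, p: int, q: int = 32, seed: int = 0,
                 mix: MixWeights | None = None):
        self.p, self.q = p, q
        self.seed = seed
        self.mix_weights = mix or MixWeights(alpha=1.0, beta=0.2107)
        rng = np.random.default_rng(seed)

        def param(*shape):
            return Tensor(_glorot(rng, *shape), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        self.params: dict[str, Tensor] = {
            # full block: forward + backward recurrences, merge projection
            "Wh_f": param(q, q), "Wx_f": param(q, p), "b_f": zeros(q),
            "Wh_b": param(q, q), "Wx_b": param(q, p), "b_b": zeros(q),
            "Wy": param(q, 2 * q), "by": zeros(q),
            # noise block: reverse recurrence + output transform
            "Wh_n": param(q, q), "Wx_n": param(q, p), "b_n": zeros(q),
            "Wy_n": param(q, q), "by_n": zeros(q),
            # second-layer attention projections
            "Wq": param(q, q), "Wk": param(q, q), "Wv": param(q, q),
            # scoring affine on the (length-scaled) attention mass; w' starts
            # at 1 so "above-average mass = keep" is the initial orientation
            "w_score": Tensor(np.ones(1), requires_grad=True),
            "b_score": zeros(1),
        }

    # -- building blocks ------------------------------------------------------
    def _recurrence(self, X: Tensor, Wh: Tensor, Wx: Tensor, b: Tensor,
                    reverse: bool = False) -> Tensor:
        """Sigmoid recurrence h_t = sigma(Wh h_{t-1} + Wx x_t + b).

        ``X`` is (B, n, p); the result is (B, n, q) aligned to forward
        positions regardless of direction.
        """
        if reverse:
            return _sigmoid_rnn(X.flip(1), Wh, Wx, b).flip(1)
        return _sigmoid_rnn(X, Wh, Wx, b)

    def full_block(self, X: Tensor) -> Tensor:
        """Bidirectional block: concat(forward, backward) -> tanh projection."""
        if X.ndim != 3 or X.shape[-1] != self.p:
            raise ValueError(f"expected input of dimension {self.p}, "
                             f"got shape {X.shape}")
        p = self.params
        fwd = self._recurrence(X, p["Wh_f"], p["Wx_f"], p["b_f"])
        bwd = self._recurrence(X, p["Wh_b"], p["Wx_b"], p["b_b"], reverse=True)
        cat = concat([fwd, bwd], axis=2)
        return (cat @ p["Wy"].T + p["by"]).tanh()

    def noise_block(self, X: Tensor) -> Tensor:
        """Reverse-direction block, output re-aligned to forward positions."""
        if X.ndim != 3 or X.shape[-1] != self.p:
            raise ValueError(f"expected input of dimension {self.p}, "
                             f"got shape {X.shape}")
        p = self.params
        h = self._recurrence(X, p["Wh_n"], p["Wx_n"], p["b_n"], reverse=True)
        return (h @ p["Wy_n"].T + p["by_n"]).tanh()

    @staticmethod
    def mix(h: Tensor, h_hat: Tensor, mw: MixWeights) -> Tensor:
        """Position-wise linear mixing of the two block outputs."""
        if h.shape != h_hat.shape:
            raise ValueError("block outputs must share a shape")
        return h * mw.alpha + h_hat * mw.beta

    def second_attention(self, v: Tensor, pad_mask: np.ndarray
                         ) -> tuple[Tensor, Tensor]:
        """Scaled-dot-product attention over the mixed sequence.

        Returns the attended representations and the per-position attention
        mass ``a`` — the mean over (non-pad) query rows of the masked softmax
        matrix, renormalized to sum to one over non-pad positions.
        """
        pad_mask = np.asarray(pad_mask, dtype=float)  # (B, n); 1 = real
        if pad_mask.sum() == 0:
            raise ValueError("all positions are padded")
        p = self.params
        Q, K, V = v @ p["Wq"].T, v @ p["Wk"].T, v @ p["Wv"].T
        scale = 1.0 / np.sqrt(self.q)
        logits = (Q @ K.transpose(0, 2, 1)) * scale
        bias = (1.0 - pad_mask)[:, None, :] * _NEG  # mask key columns
        attn = (logits + Tensor(bias)).softmax(axis=-1)  # (B, n, n)
        attended = attn @ V
        n_query = pad_mask.sum(axis=1, keepdims=True)  # (B, 1)
        a = (attn * Tensor(pad_mask[:, :, None])).sum(axis=1) / Tensor(n_query)
        a = a * Tensor(pad_mask)
        a = a / a.sum(axis=1, keepdims=True)
        return attended, a

    def score(self, a: Tensor, pad_mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """Dense scores y_i = sigmoid(w'*(n*a_i) + b') and sequence score yhat.

        The attention mass is scaled by the number of real positions before
        the affine map, making the score length-invariant: a perfectly
        uniform sequence scores identically at every length (n*a_i = 1).
        """
        pad_mask = np.asarray(pad_mask, dtype=float)
        if pad_mask.sum() == 0:
            raise ValueError("all positions are padded")
        p = self.params
        n_real = pad_mask.sum(axis=1, keepdims=True)
        y = (a * Tensor(n_real) * p["w_score"] + p["b_score"]).sigmoid()
        y_hat = (y * Tensor(pad_mask)).sum(axis=1)
        return y, y_hat

    def forward(self, X: Tensor | np.ndarray, pad_mask: np.ndarray
                ) -> tuple[Tensor, Tensor, Tensor]:
        """Full pass: returns (a, y, yhat)."""
        X = X if isinstance(X, Tensor) else Tensor(X)
        h = self.full_block(X)
        h_hat = self.noise_block(X)
        v = self.mix(h, h_hat, self.mix_weights)
        _, a = self.second_attention(v, pad_mask)
        y, y_hat = self.score(a, pad_mask)
        return a, y, y_hat

    def keep_scores(self, X: np.ndarray, pad_mask: np.ndarray) -> np.ndarray:
        """Inference-only dense scores f_s(a_i), shape (B, n)."""
        _, y, _ = self.forward(Tensor(np.asarray(X)), pad_mask)
        return y.data

    # -- persistence -----------------------------------------------------------
    def save(self, path: str) -> None:
        blob = {
            "p": self.p, "q": self.q, "seed": self.seed,
            "alpha": self.mix_weights.alpha, "beta": self.mix_weights.beta,
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path: str) -> "Denoiser":
        with open(path) as fh:
            blob = json.load(fh)
        model = cls(p=blob["p"], q=blob["q"], seed=blob["seed"],
                    mix=MixWeights(alpha=blob["alpha"], beta=blob["beta"]))
        for k, v in blob["params"].items():
            model.params[k].data = np.asarray(v, dtype=np.float64)
        return model


def extract(seqs: AlignedSequences, scores: Sequence[float],
            rule: ExtractionRule, pad_value: str = PAD_CODE
            ) -> AlignedSequences:
    """Keep positions whose score strictly exceeds theta; re-pad to length.

    The kept entries retain their relative order (the denoised sequence is a
    subsequence of the original); VS/TIS entries travel with their positions.
    """
    if len(scores) != len(seqs):
        raise ValueError("scores and sequences must have equal length")
    keep = [i for i, s in enumerate(scores) if s > rule.theta]
    n = len(seqs)
    D = [seqs.D[i] for i in keep]
    VS = [seqs.VS[i] for i in keep]
    TIS = [seqs.TIS[i] for i in keep]
    pad = n - len(keep)
    return AlignedSequences(D=D + [pad_value] * pad, VS=VS + [0] * pad,
                            TIS=TIS + [0] * pad)


def train_denoiser(inputs: np.ndarray, labels: np.ndarray,
                   pad_mask: np.ndarray, model: Denoiser | None = None,
                   *, epochs: int = 5, batch_size: int = 32,
                   lr: float = 1e-3, seed: int = 0,
                   hidden: int = 32, mix: MixWeights | None = None
                   ) -> tuple[Denoiser, list[float]]:
    """Semi-supervised training of the denoiser.

    Parameters
    ----------
    inputs
        Embedded sequences, shape (N, L, p).
    labels
        Per-position labels, shape (N, L): 1 = known noise position, 0 =
        known trigger/target position, -1 = unlabeled (no loss contribution).
    pad_mask
        (N, L), 1 at real positions.

    The loss is the binary cross-entropy of ``1 - y_i`` (the "is noise"
    score) against the labels at labeled positions only. Returns the fitted
    model and the per-epoch mean loss trace. ``epochs=0`` leaves the
    parameters at their seeded initialization.
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    labels = np.asarray(labels)
    pad_mask = np.asarray(pad_mask, dtype=float)
    labeled = (labels >= 0) & (pad_mask > 0)
    if not labeled.any():
        raise ValueError("semi-supervised training requires at least one "
                         "labeled position")
    N, L, p_dim = inputs.shape
    if model is None:
        model = Denoiser(p=p_dim, q=hidden, seed=seed, mix=mix)
    opt = Adam(list(model.params.values()), lr=lr)
    rng = np.random.default_rng(seed)
    trace: list[float] = []
    eps = 1e-7
    for _ in range(epochs):
        order = rng.permutation(N)
        losses = []
        for start in range(0, N, batch_size):
            idx = order[start:start + batch_size]
            Xb = Tensor(inputs[idx])
            mask_b = pad_mask[idx]
            lab_b = labels[idx]
            sel = (lab_b >= 0) & (mask_b > 0)
            if not sel.any():
                continue
            _, y, _ = model.forward(Xb, mask_b)
            noise_score = 1.0 - y  # target: 1 at noise positions
            t = Tensor((lab_b == 1).astype(float) * sel)
            w = Tensor(sel.astype(float))
            clipped = noise_score * (1 - 2 * eps) + eps
            bce = -(t * clipped.log() + (Tensor(sel.astype(float)) - t)
                    * (1.0 - clipped).log())
            loss = (bce * w).sum() / sel.sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)) if losses else float("nan"))
    return model, trace


def position_labels(D: Sequence[str], noise: Sequence[str],
                    known_keep: Sequence[str]) -> np.ndarray:
    """Per-position semi-supervision labels for one padded code sequence.

    1 for codes in the noise set, 0 for codes in the trigger/target sets,
    -1 (unlabeled) elsewhere and at pads.
    """
    noise, keep = set(noise), set(known_keep)
    out = np.full(len(D), -1, dtype=int)
    for i, c in enumerate(D):
        if c in noise:
            out[i] = 1
        elif c in keep:
            out[i] = 0
    return out
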
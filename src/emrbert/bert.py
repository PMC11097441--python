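"""Compact BERT-style encoder over diagnosis sequences.

Diseases play the role of words and a patient's (denoised) diagnosis
sequence the role of a sentence. Three input channels are embedded and
summed: token embeddings of the disease codes, segment embeddings of the
visit indices, and positional embeddings of the bucketized day gaps between
visits. Pretraining couples two objectives:

* a masked-code model — selected positions are replaced by ``[MASK]`` with
  probability 0.70, by a random vocabulary code with probability 0.15, and
  kept with probability 0.15, and the encoder must recover the original code;
* trigger/target next-sentence prediction — a ``[SEP]`` token is inserted
  after the visit containing the k-th occurrence of the trigger disease, and
  the binary label records whether any target disease occurs after that
  visit within the horizon ``T``.

Fine-tuning and prediction reuse the next-sentence head: the model outputs
the probability that the target disease appears within ``T`` of the
separator point.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)

from ._tensor import Adam, Tensor
from .comorbidity import TriggerSpec
from .sequences import AlignedSequences, PatientRecord, derive_sequences

__all__ = [
    "Vocabulary", "InputEncoding", "MaskingPolicy", "NSPExample",
    "ModelConfig", "BertEncoder", "apply_mlm_mask", "make_nsp_example",
    "balance_pretraining", "pretrain", "finetune", "predict_proba",
    "evaluate",
]

PAD, CLS, SEP, MASK = "[PAD]", "[CLS]", "[SEP]", "[MASK]"
SPECIAL_TOKENS = (PAD, CLS, SEP, MASK)

#: day-gap bucket boundaries: 0, 1-7, 8-30, 31-90, 91-365, >365
TIME_BUCKET_EDGES = (1, 8, 31, 91, 366)


def bucketize_days(days: int) -> int:
    for b, edge in enumerate(TIME_BUCKET_EDGES):
        if days < edge:
            return b
    return len(TIME_BUCKET_EDGES)


class Vocabulary:
    """Bijective code<->id map with reserved low ids for special tokens."""

    def __init__(self, codes: Iterable[str]):
        self._tokens = list(SPECIAL_TOKENS)
        seen = set(self._tokens)
        for c in codes:
            if c not in seen:
                self._tokens.append(c)
                seen.add(c)
        self._ids = {t: i for i, t in enumerate(self._tokens)}

    def __len__(self) -> int:
        return len(self._tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._ids

    def id(self, token: str) -> int:
        return self._ids[token]

    def token(self, i: int) -> str:
        return self._tokens[i]

    @property
    def tokens(self) -> list[str]:
        return list(self._tokens)

    @property
    def n_special(self) -> int:
        return len(SPECIAL_TOKENS)

    def is_special_id(self, i: int) -> bool:
        return i < len(SPECIAL_TOKENS)

    def encode(self, codes: Sequence[str]) -> np.ndarray:
        return np.array([self._ids[c] for c in codes], dtype=np.int64)


@dataclass
class InputEncoding:
    """Aligned id channels of one sequence, all of length L."""

    token_ids: np.ndarray
    segment_ids: np.ndarray
    time_ids: np.ndarray
    pad_mask: np.ndarray  # 1 at real positions

    def __post_init__(self):
        n = len(self.token_ids)
        if not (len(self.segment_ids) == len(self.time_ids)
                == len(self.pad_mask) == n):
            raise ValueError("all channels must share one length")

    def __len__(self) -> int:
        return len(self.token_ids)

    def copy(self) -> "InputEncoding":
        return InputEncoding(self.token_ids.copy(), self.segment_ids.copy(),
                             self.time_ids.copy(), self.pad_mask.copy())


@dataclass(frozen=True)
class MaskingPolicy:
    """Fraction of positions entering the masked-code objective and the
    mask/random/keep split applied to a selected position."""

    p_select: float = 0.15
    p_mask: float = 0.70
    p_random: float = 0.15
    p_keep: float = 0.15

    def __post_init__(self):
        if not (0.0 <= self.p_select < 1.0):  # 0 = no masking (degenerate)
            raise ValueError("p_select must lie in [0, 1)")
        if abs(self.p_mask + self.p_random + self.p_keep - 1.0) > 1e-9:
            raise ValueError("mask/random/keep probabilities must sum to 1")


@dataclass
class NSPExample:
    encoding: InputEncoding
    label: int
    sep_date: dt.date
    horizon_days: int
    patient_id: str = ""


def encode_sequences(seqs: AlignedSequences, vocab: Vocabulary,
                     max_visit: int = 50) -> InputEncoding:
    """Encode an aligned triple (no [CLS]/[SEP] insertion, no padding)."""
    token_ids = vocab.encode(seqs.D)
    segment_ids = np.clip(np.asarray(seqs.VS, dtype=np.int64), 0, max_visit)
    time_ids = np.array([bucketize_days(t) for t in seqs.TIS], dtype=np.int64)
    pad_mask = (token_ids != vocab.id(PAD)).astype(np.int64)
    return InputEncoding(token_ids, segment_ids, time_ids, pad_mask)


def apply_mlm_mask(encoding: InputEncoding, policy: MaskingPolicy,
                   rng: np.random.Generator, vocab: Vocabulary
                   ) -> tuple[InputEncoding, dict[int, int]]:
    """Corrupt an encoding for the masked-code objective.

    Non-special, non-pad positions are selected independently with
    ``p_select``; a selected position is replaced by ``[MASK]`` w.p. 0.70,
    by a uniformly random non-special code (different from the original)
    w.p. 0.15, and kept w.p. 0.15. Returns the corrupted encoding and a map
    position -> original id at the selected positions.
    """
    out = encoding.copy()
    targets: dict[int, int] = {}
    n_codes = len(vocab) - vocab.n_special
    for i, tok in enumerate(encoding.token_ids):
        if encoding.pad_mask[i] == 0 or vocab.is_special_id(tok):
            continue
        if rng.random() >= policy.p_select:
            continue
        targets[i] = int(tok)
        u = rng.random()
        if u < policy.p_mask:
            out.token_ids[i] = vocab.id(MASK)
        elif u < policy.p_mask + policy.p_random:
            if n_codes > 1:
                while True:
                    cand = vocab.n_special + int(rng.integers(n_codes))
                    if cand != tok:
                        break
                out.token_ids[i] = cand
        # else: keep unchanged
    return out, targets


def _assemble(tokens: list[str], segments: list[int], times: list[int],
              vocab: Vocabulary, L: int, max_visit: int) -> InputEncoding:
    """[CLS] + body -> fixed length L (suffix kept on truncation)."""
    if len(tokens) > L - 1:
        tokens = tokens[-(L - 1):]
        segments = segments[-(L - 1):]
        times = times[-(L - 1):]
    tokens = [CLS] + tokens
    segments = [0] + segments
    times = [0] + times
    pad = L - len(tokens)
    token_ids = vocab.encode(tokens + [PAD] * pad)
    segment_ids = np.clip(np.array(segments + [0] * pad, dtype=np.int64),
                          0, max_visit)
    time_ids = np.array([bucketize_days(t) for t in times] + [0] * pad,
                        dtype=np.int64)
    pad_mask = np.zeros(L, dtype=np.int64)
    pad_mask[:L - pad] = 1
    return InputEncoding(token_ids, segment_ids, time_ids, pad_mask)


def make_nsp_example(record: PatientRecord, spec: TriggerSpec,
                     horizon_days: int, L: int, vocab: Vocabulary,
                     seqs: AlignedSequences | None = None,
                     max_visit: int = 50) -> NSPExample | None:
    """Build one next-sentence example from a patient record.

    If the trigger occurs at least ``k`` times, ``[SEP]`` is inserted after
    the visit containing the k-th occurrence and the label is 1 iff any
    target code occurs in a *later* visit dated within ``horizon_days`` of
    the separator visit. A patient carrying trigger or target codes but
    fewer than ``k`` trigger occurrences gets ``[SEP]`` appended at the end
    with label 0. A patient with neither trigger nor target codes is
    excluded (returns ``None``).

    The encoding contains the history up to and including ``[SEP]`` only;
    the label summarizes the future window, which is what the fine-tuned
    model must predict. ``seqs`` may carry a denoised aligned triple (with
    original visit indices) to encode in place of the raw history; the
    separator placement and the label are always determined on the raw
    record, so denoising changes the input features, never the supervision.
    """
    raw = derive_sequences(record)
    src = seqs if seqs is not None else raw
    occurrences = [i for i, c in enumerate(raw.D) if c == spec.trigger]
    all_codes = set(raw.D)
    if len(occurrences) >= spec.k:
        kth_visit = raw.VS[occurrences[spec.k - 1]]
        sep_date = record.visits[kth_visit - 1].date
        limit = sep_date + dt.timedelta(days=horizon_days)
        label = int(any(
            visit.date > sep_date and visit.date <= limit
            and any(c in spec.targets for c in visit.codes)
            for visit in record.visits))
        hist = [i for i, v in enumerate(src.VS) if v <= kth_visit]
        sep_seg = kth_visit
    elif spec.trigger in all_codes or (all_codes & spec.targets):
        label = 0
        sep_date = record.visits[-1].date
        hist = list(range(len(src.D)))
        sep_seg = src.VS[-1] if src.VS else 0
    else:
        return None
    tokens = [src.D[i] for i in hist] + [SEP]
    segments = [src.VS[i] for i in hist] + [sep_seg]
    times = [src.TIS[i] for i in hist] + [0]
    enc = _assemble(tokens, segments, times, vocab, L, max_visit)
    return NSPExample(encoding=enc, label=label, sep_date=sep_date,
                      horizon_days=horizon_days, patient_id=record.patient_id)


def balance_pretraining(examples: Sequence[NSPExample],
                        positive_fraction: float = 0.20,
                        rng: np.random.Generator | None = None
                        ) -> list[NSPExample]:
    """Stratified sample with the requested positive composition.

    Sampling is without replacement within each class and deterministic
    under a seeded generator. When one class is too small to realize the
    fraction exactly, the best achievable composition is returned (with a
    warning via the return size).
    """
    rng = rng or np.random.default_rng(0)
    pos = [e for e in examples if e.label == 1]
    neg = [e for e in examples if e.label == 0]
    if positive_fraction >= 1.0:
        return list(pos)
    if positive_fraction <= 0.0:
        return list(neg)
    # largest total n with round(n*f) positives available
    n_pos = len(pos)
    n_neg = len(neg)
    want_pos = min(n_pos, int(round(positive_fraction / (1 - positive_fraction)
                                    * n_neg)))
    want_neg = min(n_neg, int(round(want_pos * (1 - positive_fraction)
                                    / positive_fraction))) if want_pos else n_neg
    take_pos = [pos[i] for i in rng.permutation(n_pos)[:want_pos]]
    take_neg = [neg[i] for i in rng.permutation(n_neg)[:want_neg]]
    out = take_pos + take_neg
    order = rng.permutation(len(out))
    return [out[i] for i in order]


@dataclass
class ModelConfig:
    layers: int = 2
    heads: int = 2
    hidden: int = 64
    max_len: int = 75
    max_visit: int = 50
    n_time_buckets: int = len(TIME_BUCKET_EDGES) + 1
    ffn: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.hidden % self.heads:
            raise ValueError("hidden size must be divisible by heads")
        if self.max_len < 4:
            raise ValueError("max_len must be >= 4")
        if self.ffn is None:
            self.ffn = 4 * self.hidden


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps).sqrt() * gamma + beta


class BertEncoder:
    """Small transformer encoder with MLM and next-sentence heads."""

    def __init__(self, vocab: Vocabulary, config: ModelConfig | None = None):
        self.vocab = vocab
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        h = cfg.hidden

        def param(*shape, scale=0.02):
            return Tensor(rng.normal(0.0, scale, size=shape),
                          requires_grad=True)

        def ones(*shape):
            return Tensor(np.ones(shape), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        P: dict[str, Tensor] = {
            "tok_emb": param(len(vocab), h),
            "seg_emb": param(cfg.max_visit + 1, h),
            "time_emb": param(cfg.n_time_buckets, h),
            "emb_ln_g": ones(h), "emb_ln_b": zeros(h),
        }
        for l in range(cfg.layers):
            P.update({
                f"l{l}_Wq": param(h, h), f"l{l}_bq": zeros(h),
                f"l{l}_Wk": param(h, h), f"l{l}_bk": zeros(h),
                f"l{l}_Wv": param(h, h), f"l{l}_bv": zeros(h),
                f"l{l}_Wo": param(h, h), f"l{l}_bo": zeros(h),
                f"l{l}_ln1_g": ones(h), f"l{l}_ln1_b": zeros(h),
                f"l{l}_W1": param(cfg.ffn, h), f"l{l}_b1": zeros(cfg.ffn),
                f"l{l}_W2": param(h, cfg.ffn), f"l{l}_b2": zeros(h),
                f"l{l}_ln2_g": ones(h), f"l{l}_ln2_b": zeros(h),
            })
        P.update({
            "mlm_W": param(len(vocab), h), "mlm_b": zeros(len(vocab)),
            "pool_W": param(h, h), "pool_b": zeros(h),
            "nsp_w": param(h, scale=0.1), "nsp_b": zeros(1),
        })
        self.params = P

    # -- forward ---------------------------------------------------------------
    def encode(self, token_ids: np.ndarray, segment_ids: np.ndarray,
               time_ids: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        """Hidden states (B, n, hidden) for a batch of id arrays."""
        P, cfg = self.params, self.config
        x = (P["tok_emb"].take_rows(token_ids)
             + P["seg_emb"].take_rows(segment_ids)
             + P["time_emb"].take_rows(time_ids))
        x = _layer_norm(x, P["emb_ln_g"], P["emb_ln_b"])
        B, n = token_ids.shape
        heads, dh = cfg.heads, cfg.hidden // cfg.heads
        bias = ((1.0 - pad_mask.astype(float))[:, None, None, :]) * -1e9
        for l in range(cfg.layers):
            Q = (x @ P[f"l{l}_Wq"].T + P[f"l{l}_bq"])
            K = (x @ P[f"l{l}_Wk"].T + P[f"l{l}_bk"])
            V = (x @ P[f"l{l}_Wv"].T + P[f"l{l}_bv"])

            def split(t):
                return t.reshape(B, n, heads, dh).transpose(0, 2, 1, 3)

            Qh, Kh, Vh = split(Q), split(K), split(V)
            logits = Qh @ Kh.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh))
            attn = (logits + Tensor(bias)).softmax(axis=-1)
            ctx = (attn @ Vh).transpose(0, 2, 1, 3).reshape(B, n, cfg.hidden)
            x = _layer_norm(x + (ctx @ P[f"l{l}_Wo"].T + P[f"l{l}_bo"]),
                            P[f"l{l}_ln1_g"], P[f"l{l}_ln1_b"])
            ff = ((x @ P[f"l{l}_W1"].T + P[f"l{l}_b1"]).gelu()
                  @ P[f"l{l}_W2"].T + P[f"l{l}_b2"])
            x = _layer_norm(x + ff, P[f"l{l}_ln2_g"], P[f"l{l}_ln2_b"])
        return x

    def mlm_logits(self, hidden: Tensor) -> Tensor:
        return hidden @ self.params["mlm_W"].T + self.params["mlm_b"]

    def nsp_logit(self, hidden: Tensor) -> Tensor:
        """Binary next-sentence logit from the [CLS] position."""
        cls = hidden[:, 0, :]
        pooled = (cls @ self.params["pool_W"].T
                  + self.params["pool_b"]).tanh()
        return pooled @ self.params["nsp_w"] + self.params["nsp_b"]

    # -- persistence -----------------------------------------------------------
    def save(self, path: str) -> None:
        blob = {
            "config": {k: v for k, v in self.config.__dict__.items()},
            "vocab": self.vocab.tokens,
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path: str) -> "BertEncoder":
        with open(path) as fh:
            blob = json.load(fh)
        vocab = Vocabulary(blob["vocab"][len(SPECIAL_TOKENS):])
        model = cls(vocab, ModelConfig(**blob["config"]))
        for k, v in blob["params"].items():
            model.params[k].data = np.asarray(v, dtype=np.float64)
        return model

    def clone(self) -> "BertEncoder":
        other = BertEncoder(self.vocab, replace(self.config))
        for k, v in self.params.items():
            other.params[k].data = v.data.copy()
        return other


def _batch_arrays(encodings: Sequence[InputEncoding]):
    return (np.stack([e.token_ids for e in encodings]),
            np.stack([e.segment_ids for e in encodings]),
            np.stack([e.time_ids for e in encodings]),
            np.stack([e.pad_mask for e in encodings]))


def _bce_from_logit(logit: Tensor, labels: np.ndarray) -> Tensor:
    y = np.asarray(labels, dtype=float)
    p = logit.sigmoid() * (1 - 2e-7) + 1e-7
    return -(Tensor(y) * p.log()
             + Tensor(1.0 - y) * (1.0 - p).log()).mean()


def pretrain(model: BertEncoder, examples: Sequence[NSPExample],
             policy: MaskingPolicy | None = None, *, epochs: int = 3,
             batch_size: int = 16, lr: float = 1e-3, seed: int = 0,
             mlm_weight: float = 1.0, nsp_weight: float = 1.0
             ) -> tuple[BertEncoder, list[float]]:
    """Joint masked-code + next-sentence pretraining.

    Returns the model and the per-epoch mean total-loss trace. ``epochs=0``
    leaves the seeded initialization untouched.
    """
    if not examples:
        raise ValueError("pretraining corpus is empty")
    for e in examples:
        if e.encoding.token_ids.max() >= len(model.vocab):
            raise ValueError("corpus vocabulary exceeds model vocabulary")
    policy = policy or MaskingPolicy()
    vocab = model.vocab
    opt = Adam(list(model.params.values()), lr=lr)
    rng = np.random.default_rng(seed)
    trace: list[float] = []
    N = len(examples)
    for _ in range(epochs):
        order = rng.permutation(N)
        losses = []
        for start in range(0, N, batch_size):
            batch = [examples[i] for i in order[start:start + batch_size]]
            corrupted, target_maps = [], []
            for ex in batch:
                enc, tmap = apply_mlm_mask(ex.encoding, policy, rng, vocab)
                corrupted.append(enc)
                target_maps.append(tmap)
            tok, seg, tim, mask = _batch_arrays(corrupted)
            hidden = model.encode(tok, seg, tim, mask)
            # MLM: cross-entropy at selected positions
            rows, cols, tgts = [], [], []
            for b, tmap in enumerate(target_maps):
                for pos, orig in tmap.items():
                    rows.append(b)
                    cols.append(pos)
                    tgts.append(orig)
            loss = Tensor(0.0)
            if tgts:
                logits = model.mlm_logits(
                    hidden[np.array(rows), np.array(cols)])
                logp = logits.log_softmax(axis=-1)
                onehot = np.zeros((len(tgts), len(vocab)))
                onehot[np.arange(len(tgts)), tgts] = 1.0
                mlm_loss = -(logp * Tensor(onehot)).sum() * (1.0 / len(tgts))
                loss = loss + mlm_loss * mlm_weight
            nsp_labels = np.array([ex.label for ex in batch], dtype=float)
            nsp_loss = _bce_from_logit(model.nsp_logit(hidden), nsp_labels)
            loss = loss + nsp_loss * nsp_weight
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
    return model, trace


def finetune(model: BertEncoder, examples: Sequence[NSPExample], *,
             epochs: int = 3, batch_size: int = 16, lr: float = 1e-3,
             seed: int = 0, freeze_body: bool = False
             ) -> tuple[BertEncoder, list[float]]:
    """Fine-tune the next-sentence / prediction head (optionally body too)."""
    if not examples:
        raise ValueError("fine-tuning set is empty")
    head_keys = {"pool_W", "pool_b", "nsp_w", "nsp_b"}
    params = [v for k, v in model.params.items()
              if not freeze_body or k in head_keys]
    opt = Adam(params, lr=lr)
    rng = np.random.default_rng(seed)
    trace: list[float] = []
    N = len(examples)
    for _ in range(epochs):
        order = rng.permutation(N)
        losses = []
        for start in range(0, N, batch_size):
            batch = [examples[i] for i in order[start:start + batch_size]]
            tok, seg, tim, mask = _batch_arrays([e.encoding for e in batch])
            hidden = model.encode(tok, seg, tim, mask)
            labels = np.array([e.label for e in batch], dtype=float)
            loss = _bce_from_logit(model.nsp_logit(hidden), labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)))
    return model, trace


def predict_proba(model: BertEncoder,
                  examples: Sequence[NSPExample],
                  batch_size: int = 64) -> np.ndarray:
    """P(label = 1) for each example, deterministic at inference."""
    out = []
    for start in range(0, len(examples), batch_size):
        batch = examples[start:start + batch_size]
        tok, seg, tim, mask = _batch_arrays([e.encoding for e in batch])
        hidden = model.encode(tok, seg, tim, mask)
        logit = model.nsp_logit(hidden)
        out.append(1.0 / (1.0 + np.exp(-logit.data)))
    return np.concatenate(out) if out else np.array([])


def evaluate(probabilities: Sequence[float], labels: Sequence[int],
             threshold: float = 0.5) -> dict[str, float | None]:
    """AUC-ROC, accuracy, precision, recall and F1 at a decision threshold.

    With a single observed class the AUC is undefined and reported as None.
    """
    probs = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape != labels.shape:
        raise ValueError("probabilities and labels must align")
    preds = (probs >= threshold).astype(int)
    auc = (float(roc_auc_score(labels, probs))
           if len(np.unique(labels)) == 2 else None)
    return {
        "auc_roc": auc,
        "accuracy": float(accuracy_score(labels, preds)),
        "precision": float(precision_score(labels, preds, zero_division=0)),
        "recall": float(recall_score(labels, preds, zero_division=0)),
        "f1": float(f1_score(labels, preds, zero_division=0)),
    }
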
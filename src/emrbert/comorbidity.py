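"""Comorbidity mining, the weighted disease graph, and disease embeddings.

A *comorbidity* of a trigger disease is any other disease that manifests
after the trigger has occurred ``k`` times in the same patient's flattened
diagnosis sequence. Trigger diseases and their mined targets form an
undirected graph whose edge weight compares the two diseases' frequency-ranked
comorbidity lists (a rank-order-statistics distance), each common comorbidity
weighted by its Shannon entropy across patients. Disease vectors are learned
from the graph with uniform random walks and a skip-gram objective, so that
diseases sharing comorbidity structure land near each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .sequences import PatientRecord

__all__ = [
    "TriggerSpec", "ComorbidityGraph", "DiseaseEmbedding",
    "find_comorbidities", "select_triggers", "shannon_entropy",
    "edge_weight", "build_graph", "embed_graph",
]


@dataclass(frozen=True)
class TriggerSpec:
    """A trigger disease, its occurrence threshold k and its target set."""

    trigger: str
    k: int
    targets: frozenset[str]

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.trigger in self.targets:
            raise ValueError("trigger must not be one of its own targets")


def _kth_occurrence(D: Sequence[str], code: str, k: int) -> int | None:
    """0-based position of the k-th occurrence of ``code`` in ``D``."""
    seen = 0
    for i, c in enumerate(D):
        if c == code:
            seen += 1
            if seen == k:
                return i
    return None


def find_comorbidities(records: Iterable[PatientRecord], trigger: str,
                       k: int = 2) -> dict[str, int]:
    """Per-target patient-support counts for one trigger disease.

    A disease ``u != trigger`` counts once for a patient when some occurrence
    of ``u`` sits at a strictly later flattened position than the k-th
    occurrence of the trigger. Patients with fewer than ``k`` trigger
    occurrences contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    support: dict[str, int] = {}
    for rec in records:
        D = rec.disease_positions()
        pos = _kth_occurrence(D, trigger, k)
        if pos is None:
            continue
        for u in set(D[pos + 1:]):
            if u != trigger:
                support[u] = support.get(u, 0) + 1
    return support


def patient_prevalence(records: Sequence[PatientRecord]) -> dict[str, float]:
    """Fraction of patients carrying each code at least once."""
    counts: dict[str, int] = {}
    for rec in records:
        for code in set(rec.disease_positions()):
            counts[code] = counts.get(code, 0) + 1
    n = len(records)
    return {c: v / n for c, v in counts.items()}


def select_triggers(records: Sequence[PatientRecord],
                    noise: Iterable[str] = (),
                    k: int = 2,
                    min_prevalence: float = 0.01) -> set[TriggerSpec]:
    """Select trigger diseases and their mined target sets.

    A disease qualifies when it (a) appears more than twice within at least
    one patient's record, (b) has a non-empty comorbidity set, (c) is not a
    noise disease, and (d) occurs in at least ``min_prevalence`` of patients.
    """
    if not records:
        raise ValueError("records must be non-empty")
    noise = frozenset(noise)
    prevalence = patient_prevalence(records)
    # (a): max within-patient occurrence count > 2
    max_count: dict[str, int] = {}
    for rec in records:
        D = rec.disease_positions()
        for code in set(D):
            c = D.count(code)
            if c > max_count.get(code, 0):
                max_count[code] = c
    out: set[TriggerSpec] = set()
    for code, mc in max_count.items():
        if mc <= 2 or code in noise or prevalence[code] < min_prevalence:
            continue
        targets = frozenset(find_comorbidities(records, code, k)) - noise
        if targets:
            out.add(TriggerSpec(trigger=code, k=k, targets=targets))
    return out


def shannon_entropy(records: Sequence[PatientRecord], disease: str,
                    entropy_fn: Callable[[float], float] | None = None) -> float:
    """Entropy of a disease's presence/absence across patients (bits).

    The default reference distribution is binary patient prevalence:
    ``F = -p log2 p - (1-p) log2 (1-p)`` with ``p`` the fraction of patients
    carrying the disease. An alternative ``entropy_fn(p)`` may be supplied.
    """
    p = patient_prevalence(records).get(disease)
    if p is None:
        raise ValueError(f"disease {disease!r} not observed in records")
    if entropy_fn is not None:
        return entropy_fn(p)
    return _binary_entropy(p)


def _binary_entropy(p: float) -> float:
    if p in (0.0, 1.0):
        return 0.0
    return -p * math.log2(p) - (1 - p) * math.log2(1 - p)


def edge_weight(u: str, v: str,
                rank_lists: Mapping[str, Sequence[str]],
                entropies: Mapping[str, float]) -> float | None:
    """Rank-distance weight between two diseases.

    Over the ``N_uv`` comorbidities common to ``u`` and ``v``, averages the
    absolute difference of their 1-based ranks in the two frequency-ordered
    lists, each term scaled by that comorbidity's entropy. Returns ``None``
    when the diseases share no comorbidity (weight undefined).
    """
    ru = {c: i + 1 for i, c in enumerate(rank_lists.get(u, ()))}
    rv = {c: i + 1 for i, c in enumerate(rank_lists.get(v, ()))}
    common = set(ru) & set(rv)
    if not common:
        return None
    return sum(abs(ru[c] - rv[c]) * entropies[c] for c in common) / len(common)


@dataclass
class ComorbidityGraph:
    """Weighted undirected disease graph plus the rank lists and entropies
    that define its edge weights."""

    graph: nx.Graph
    rank_lists: dict[str, list[str]] = field(default_factory=dict)
    entropies: dict[str, float] = field(default_factory=dict)

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def to_edge_tsv(self, target) -> None:
        close = isinstance(target, str)
        fh = open(target, "w") if close else target
        try:
            fh.write("u\tv\tweight\tn_common\tfallback\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['weight']:.6g}\t{d['n_common']}"
                         f"\t{int(d['fallback'])}\n")
        finally:
            if close:
                fh.close()


def _rank_list(records: Sequence[PatientRecord], disease: str, k: int,
               noise: frozenset[str]) -> list[str]:
    """Frequency-ordered comorbidity list (support desc, code asc on ties)."""
    support = find_comorbidities(records, disease, k)
    items = [(c, s) for c, s in support.items() if c not in noise]
    items.sort(key=lambda cs: (-cs[1], cs[0]))
    return [c for c, _ in items]


def build_graph(records: Sequence[PatientRecord],
                triggers: Iterable[TriggerSpec],
                noise: Iterable[str] = ()) -> ComorbidityGraph:
    """Assemble the comorbidity graph from trigger specs.

    Vertices are the triggers and their targets (noise diseases excluded);
    an edge joins ``u`` and ``v`` whenever one is a target of the other. An
    edge whose endpoints share no comorbidity keeps its place in the graph
    but gets the maximum observed finite weight plus one (flagged
    ``fallback``), penalizing unrelated pairs during the embedding walks.
    """
    triggers = list(triggers)
    if not triggers:
        raise ValueError("at least one trigger is required")
    noise = frozenset(noise)
    G = nx.Graph()
    for spec in triggers:
        if spec.trigger in noise:
            continue
        G.add_node(spec.trigger)
        for t in spec.targets - noise:
            G.add_node(t)
            G.add_edge(spec.trigger, t)

    prevalence = patient_prevalence(records) if records else {}
    rank_lists = {v: _rank_list(records, v, triggers[0].k, noise)
                  for v in G.nodes} if records else {v: [] for v in G.nodes}
    entropies = {c: _binary_entropy(prevalence.get(c, 0.0))
                 for lst in rank_lists.values() for c in lst}

    pending = []
    finite_max = 0.0
    for u, v in G.edges:
        w = edge_weight(u, v, rank_lists, entropies)
        n_common = len(set(rank_lists.get(u, ())) & set(rank_lists.get(v, ())))
        if w is None:
            pending.append((u, v))
            G.edges[u, v].update(n_common=0, fallback=True)
        else:
            finite_max = max(finite_max, w)
            G.edges[u, v].update(weight=w, n_common=n_common, fallback=False)
    for u, v in pending:
        G.edges[u, v]["weight"] = finite_max + 1.0
    return ComorbidityGraph(graph=G, rank_lists=rank_lists, entropies=entropies)


@dataclass
class DiseaseEmbedding:
    """Vocabulary-aligned embedding matrix, one row per disease code."""

    vocab: list[str]
    vectors: np.ndarray

    def __post_init__(self):
        if len(self.vocab) != self.vectors.shape[0]:
            raise ValueError("one vector row per vocabulary code required")
        self._index = {c: i for i, c in enumerate(self.vocab)}

    def __getitem__(self, code: str) -> np.ndarray:
        return self.vectors[self._index[code]]

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def matrix_for(self, codes: Sequence[str]) -> np.ndarray:
        return self.vectors[[self._index[c] for c in codes]]

    def save_text(self, matrix_path: str, vocab_path: str) -> None:
        """Headerless text matrix plus sidecar vocabulary (word2vec-like)."""
        np.savetxt(matrix_path, self.vectors, fmt="%.8g")
        with open(vocab_path, "w") as fh:
            fh.write("\n".join(self.vocab) + "\n")

    @classmethod
    def load_text(cls, matrix_path: str, vocab_path: str) -> "DiseaseEmbedding":
        vectors = np.atleast_2d(np.loadtxt(matrix_path))
        with open(vocab_path) as fh:
            vocab = [line.strip() for line in fh if line.strip()]
        return cls(vocab=vocab, vectors=vectors)


def _random_walks(G: nx.Graph, rng: np.random.Generator,
                  n_walks: int, walk_length: int) -> list[list[str]]:
    nodes = sorted(G.nodes)
    # step probability favors low-weight (i.e. close) neighbours
    nbrs = {u: sorted(G.neighbors(u)) for u in nodes}
    probs = {}
    for u in nodes:
        if nbrs[u]:
            w = np.array([1.0 / (1.0 + G.edges[u, v]["weight"])
                          for v in nbrs[u]])
            probs[u] = w / w.sum()
    walks = []
    for _ in range(n_walks):
        for start in nodes:
            walk = [start]
            while len(walk) < walk_length and nbrs[walk[-1]]:
                u = walk[-1]
                walk.append(nbrs[u][rng.choice(len(nbrs[u]), p=probs[u])])
            walks.append(walk)
    return walks


def embed_graph(G: ComorbidityGraph | nx.Graph, d_emb: int = 64,
                seed: int = 0, n_walks: int = 10, walk_length: int = 20,
                window: int = 5, epochs: int = 5, lr: float = 0.025,
                n_negative: int = 5,
                vocab: Sequence[str] | None = None) -> DiseaseEmbedding:
    """Random-walk skip-gram embedding of the comorbidity graph.

    Uniformly seeded and single-threaded, hence bitwise deterministic for a
    fixed seed. Codes in ``vocab`` that are absent from the graph receive
    seeded random rows (scaled like untrained vectors), so every vocabulary
    code has a representation.
    """
    nxg = G.graph if isinstance(G, ComorbidityGraph) else G
    if nxg.number_of_nodes() == 0:
        raise ValueError("graph must have at least one vertex")
    rng = np.random.default_rng(seed)
    nodes = sorted(nxg.nodes)
    idx = {c: i for i, c in enumerate(nodes)}
    n = len(nodes)
    W_in = (rng.random((n, d_emb)) - 0.5) / d_emb
    W_out = np.zeros((n, d_emb))

    walks = _random_walks(nxg, rng, n_walks, walk_length)
    # (center, context) pairs from sliding windows
    pairs = []
    for walk in walks:
        ids = [idx[c] for c in walk]
        for i, center in enumerate(ids):
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j != i:
                    pairs.append((center, ids[j]))
    if pairs:
        pairs = np.array(pairs)
        counts = np.bincount(pairs[:, 0], minlength=n).astype(float)
        noise_dist = counts ** 0.75
        noise_dist /= noise_dist.sum()
        for _ in range(epochs):
            order = rng.permutation(len(pairs))
            negs = rng.choice(n, size=(len(pairs), n_negative), p=noise_dist)
            for row, (c, o) in enumerate(pairs[order]):
                vc = W_in[c]
                targets = np.concatenate(([o], negs[row]))
                labels = np.zeros(n_negative + 1)
                labels[0] = 1.0
                out = W_out[targets]
                scores = 1.0 / (1.0 + np.exp(-out @ vc))
                gscore = (scores - labels) * lr
                gin = gscore @ out
                W_out[targets] -= np.outer(gscore, vc)
                W_in[c] -= gin

    # L2-normalize trained vectors (cosine geometry); codes outside the
    # graph keep a small random init, so "has comorbidity structure" is
    # visible in the representation scale
    norms = np.linalg.norm(W_in, axis=1, keepdims=True)
    W_in = W_in / np.maximum(norms, 1e-12)
    full_vocab = list(nodes)
    vectors = [W_in]
    if vocab is not None:
        extra = [c for c in vocab if c not in idx]
        if extra:
            vectors.append((rng.random((len(extra), d_emb)) - 0.5) / d_emb)
            full_vocab += extra
    return DiseaseEmbedding(vocab=full_vocab, vectors=np.vstack(vectors))
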
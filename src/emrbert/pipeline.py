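"""End-to-end orchestration: records -> graph -> denoiser -> encoder -> metrics.

These helpers tie the stages together the way the command-line interface and
the evaluation scripts use them: mine the comorbidity graph and disease
embeddings from a cohort, train the denoiser semi-supervised on the noise /
trigger-target label scheme, denoise every sequence, build next-sentence
examples, pretrain and fine-tune the encoder, and score a held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bert import (BertEncoder, MaskingPolicy, ModelConfig, NSPExample,
                   Vocabulary, balance_pretraining, evaluate, finetune,
                   make_nsp_example, predict_proba, pretrain)
from .comorbidity import (DiseaseEmbedding, TriggerSpec, build_graph,
                          embed_graph, select_triggers)
from .denoiser import (Denoiser, ExtractionRule, MixWeights, extract,
                       position_labels, train_denoiser)
from .sequences import (AlignedSequences, PAD_CODE, PatientRecord,
                        derive_sequences, pad_or_truncate)

__all__ = ["PipelineSettings", "CohortArtifacts", "prepare_cohort",
           "fit_denoiser", "denoise_cohort", "build_examples",
           "train_and_evaluate", "noise_recovery_auc",
           "denoising_ablation"]


@dataclass
class PipelineSettings:
    """Defaults mirror the study conditions: k=2, 1-year horizon, length 75."""

    spec: TriggerSpec | None = None
    noise_codes: tuple[str, ...] = ()
    horizon_days: int = 365
    max_len: int = 75
    d_emb: int = 64
    denoiser_hidden: int = 32
    theta: float = 0.5
    alpha: float | None = None   # None = estimate from the corpus
    beta: float | None = None
    denoiser_epochs: int = 4
    pretrain_epochs: int = 2
    finetune_epochs: int = 16
    batch_size: int = 16
    lr: float = 2e-3
    positive_fraction: float = 0.20
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0


@dataclass
class CohortArtifacts:
    vocab: Vocabulary
    embedding: DiseaseEmbedding
    sequences: dict[str, AlignedSequences]
    manifest: dict


def prepare_cohort(records: Sequence[PatientRecord],
                   settings: PipelineSettings) -> CohortArtifacts:
    """Parse-side preprocessing: sequences, graph, embeddings, manifest."""
    all_codes = sorted({c for r in records for c in r.disease_positions()})
    vocab = Vocabulary(all_codes)
    triggers = select_triggers(records, noise=settings.noise_codes,
                               k=settings.spec.k if settings.spec else 2)
    if triggers:
        graph = build_graph(records, triggers, noise=settings.noise_codes)
        embedding = embed_graph(graph, d_emb=settings.d_emb,
                                seed=settings.seed, vocab=all_codes)
        n_edges = graph.graph.number_of_edges()
    else:
        rng = np.random.default_rng(settings.seed)
        embedding = DiseaseEmbedding(
            vocab=all_codes,
            vectors=(rng.random((len(all_codes), settings.d_emb)) - 0.5)
            / settings.d_emb)
        n_edges = 0
    seqs = {r.patient_id: derive_sequences(r) for r in records}
    manifest = {
        "n_patients": len(records),
        "n_codes": len(all_codes),
        "n_triggers": len(triggers),
        "n_edges": n_edges,
        "seed": settings.seed,
    }
    return CohortArtifacts(vocab=vocab, embedding=embedding,
                           sequences=seqs, manifest=manifest)


def _embed_padded(seq_list: Sequence[AlignedSequences],
                  embedding: DiseaseEmbedding, L: int | None = None
                  ) -> tuple[np.ndarray, np.ndarray, list[AlignedSequences]]:
    """Pad/truncate, then stack embedding rows (zeros at pads).

    ``L=None`` pads to the longest sequence in the batch — the denoiser
    processes full histories; truncation to the encoder length happens only
    when examples are assembled.
    """
    if L is None:
        L = max((len(s) for s in seq_list), default=1)
    p = embedding.vectors.shape[1]
    N = len(seq_list)
    X = np.zeros((N, L, p))
    mask = np.zeros((N, L))
    padded = []
    for i, s in enumerate(seq_list):
        ps = pad_or_truncate(s, L)
        padded.append(ps)
        for j, code in enumerate(ps.D):
            if code != PAD_CODE:
                X[i, j] = embedding[code]
                mask[i, j] = 1.0
    return X, mask, padded


def fit_denoiser(records: Sequence[PatientRecord], art: CohortArtifacts,
                 settings: PipelineSettings) -> tuple[Denoiser, list[float]]:
    """Train the denoiser on noise-set vs trigger/target position labels."""
    spec = settings.spec
    seq_list = [art.sequences[r.patient_id] for r in records]
    X, mask, padded = _embed_padded(seq_list, art.embedding)
    known_keep = {spec.trigger} | set(spec.targets) if spec else set()
    labels = np.stack([position_labels(s.D, settings.noise_codes, known_keep)
                       for s in padded])
    if settings.alpha is None or settings.beta is None:
        mix = MixWeights.from_corpus(records, settings.noise_codes,
                                     spec.trigger if spec else "")
    else:
        mix = MixWeights(alpha=settings.alpha, beta=settings.beta)
    return train_denoiser(X, labels, mask, epochs=settings.denoiser_epochs,
                          batch_size=settings.batch_size, lr=settings.lr,
                          seed=settings.seed, hidden=settings.denoiser_hidden,
                          mix=mix)


def denoise_cohort(records: Sequence[PatientRecord], art: CohortArtifacts,
                   model: Denoiser, settings: PipelineSettings
                   ) -> dict[str, AlignedSequences]:
    """Denoised (pad-stripped) aligned sequences per patient."""
    rule = ExtractionRule(theta=settings.theta)
    seq_list = [art.sequences[r.patient_id] for r in records]
    X, mask, padded = _embed_padded(seq_list, art.embedding)
    out: dict[str, AlignedSequences] = {}
    B = 128
    for start in range(0, len(records), B):
        scores = model.keep_scores(X[start:start + B], mask[start:start + B])
        for i, rec in enumerate(records[start:start + B]):
            s = padded[start + i]
            real = int(mask[start + i].sum())
            ext = extract(AlignedSequences(D=s.D[:real], VS=s.VS[:real],
                                           TIS=s.TIS[:real]),
                          scores[i, :real], rule)
            keep = [j for j, c in enumerate(ext.D) if c != PAD_CODE]
            out[rec.patient_id] = AlignedSequences(
                D=[ext.D[j] for j in keep], VS=[ext.VS[j] for j in keep],
                TIS=[ext.TIS[j] for j in keep])
    return out


def build_examples(records: Sequence[PatientRecord], art: CohortArtifacts,
                   settings: PipelineSettings,
                   denoised: dict[str, AlignedSequences] | None = None
                   ) -> list[NSPExample]:
    out = []
    for rec in records:
        seqs = denoised.get(rec.patient_id) if denoised else None
        if seqs is not None and not seqs.D:
            seqs = art.sequences[rec.patient_id]  # denoiser dropped everything
        ex = make_nsp_example(rec, settings.spec, settings.horizon_days,
                              settings.max_len, art.vocab, seqs=seqs,
                              max_visit=settings.model.max_visit)
        if ex is not None:
            out.append(ex)
    return out


def train_and_evaluate(records: Sequence[PatientRecord],
                       settings: PipelineSettings, *,
                       use_denoiser: bool = True,
                       eval_labels: dict[str, int] | None = None,
                       val_fraction: float = 0.3) -> dict:
    """Full pipeline on one cohort; returns metrics and artifacts.

    ``eval_labels`` may supply external ground-truth labels (e.g. from the
    cohort generator) to score against; by default the examples' own labels
    are used. The validation split is deterministic under the settings seed.
    """
    art = prepare_cohort(records, settings)
    denoised = None
    den_model = None
    if use_denoiser:
        den_model, _ = fit_denoiser(records, art, settings)
        denoised = denoise_cohort(records, art, den_model, settings)
    examples = build_examples(records, art, settings, denoised=denoised)
    if not examples:
        raise ValueError("no scoreable patients in the cohort")
    rng = np.random.default_rng(settings.seed)
    order = rng.permutation(len(examples))
    n_val = max(1, int(round(val_fraction * len(examples))))
    val = [examples[i] for i in order[:n_val]]
    train = [examples[i] for i in order[n_val:]]

    model = BertEncoder(art.vocab, ModelConfig(
        layers=settings.model.layers, heads=settings.model.heads,
        hidden=settings.model.hidden, max_len=settings.max_len,
        max_visit=settings.model.max_visit, seed=settings.seed))
    pre_corpus = balance_pretraining(
        train, positive_fraction=settings.positive_fraction,
        rng=np.random.default_rng(settings.seed))
    if pre_corpus:
        model, _ = pretrain(model, pre_corpus, MaskingPolicy(),
                            epochs=settings.pretrain_epochs,
                            batch_size=settings.batch_size, lr=settings.lr,
                            seed=settings.seed)
    model, _ = finetune(model, train, epochs=settings.finetune_epochs,
                        batch_size=settings.batch_size, lr=settings.lr,
                        seed=settings.seed)
    probs = predict_proba(model, val)
    if eval_labels is not None:
        labels = [eval_labels.get(e.patient_id, e.label) for e in val]
    else:
        labels = [e.label for e in val]
    metrics = evaluate(probs, labels)
    return {
        "metrics": metrics,
        "n_train": len(train),
        "n_val": len(val),
        "artifacts": art,
        "denoiser": den_model,
        "model": model,
    }


def noise_recovery_auc(records, ground_truth_flags, settings: PipelineSettings
                       ) -> float:
    """Position-level noise discrimination of the trained denoiser.

    Trains the denoiser on the cohort's semi-supervised labels and measures
    how well ``1 - f_s`` ranks true noise positions above the rest
    (AUC-ROC over all real positions).
    """
    from sklearn.metrics import roc_auc_score

    art = prepare_cohort(records, settings)
    model, _ = fit_denoiser(records, art, settings)
    seq_list = [art.sequences[r.patient_id] for r in records]
    X, mask, _ = _embed_padded(seq_list, art.embedding)
    scores, truth = [], []
    for start in range(0, len(records), 128):
        sc = model.keep_scores(X[start:start + 128], mask[start:start + 128])
        for i, rec in enumerate(records[start:start + 128]):
            flags = ground_truth_flags[rec.patient_id]
            real = int(mask[start + i].sum())
            scores.extend(1.0 - sc[i, :real])
            truth.extend(flags[-real:])
    return float(roc_auc_score(truth, scores))


def denoising_ablation(records, ground_truth_labels,
                       settings: PipelineSettings) -> dict:
    """Validation metrics of the full pipeline vs. the same pipeline with
    the denoiser disabled, scored against external cohort labels."""
    on = train_and_evaluate(records, settings, use_denoiser=True,
                            eval_labels=ground_truth_labels)
    off = train_and_evaluate(records, settings, use_denoiser=False,
                             eval_labels=ground_truth_labels)
    return {"denoised": on["metrics"], "raw": off["metrics"]}
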
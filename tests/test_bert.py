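"""Encoder inputs, masking, next-sentence labeling, training and metrics."""

import datetime as dt

import numpy as np
import pytest

from emrbert.bert import (CLS, MASK, PAD, SEP, BertEncoder, InputEncoding,
                          MaskingPolicy, ModelConfig, Vocabulary,
                          apply_mlm_mask, balance_pretraining, bucketize_days,
                          evaluate, finetune, make_nsp_example, predict_proba,
                          pretrain)
from emrbert.comorbidity import TriggerSpec
from emrbert.sequences import PatientRecord, Visit

SPEC = TriggerSpec(trigger="401.9", k=2, targets=frozenset({"250.0"}))


def record_from(dated_codes):
    return PatientRecord("p", [Visit(d, tuple(cs)) for d, cs in dated_codes])


def vocab_for(*codes):
    return Vocabulary(sorted(set(codes) | {"401.9", "250.0", "530.8"}))


class TestVocabulary:
    def test_special_tokens_have_reserved_low_ids(self):
        v = vocab_for()
        assert [v.id(t) for t in (PAD, CLS, SEP, MASK)] == [0, 1, 2, 3]

    def test_bijective_mapping(self):
        v = vocab_for("272.4")
        for i in range(len(v)):
            assert v.id(v.token(i)) == i


class TestBucketize:
    @pytest.mark.parametrize("days,bucket", [
        (0, 0), (1, 1), (7, 1), (8, 2), (30, 2), (31, 3), (90, 3),
        (91, 4), (365, 4), (366, 5), (4000, 5)])
    def test_boundaries(self, days, bucket):
        assert bucketize_days(days) == bucket


def toy_encoding(vocab, codes, pad_to=None):
    n = len(codes)
    L = pad_to or n
    token_ids = np.array([vocab.id(c) for c in codes] + [0] * (L - n))
    pad_mask = np.array([1] * n + [0] * (L - n))
    return InputEncoding(token_ids, np.ones(L, dtype=int),
                         np.zeros(L, dtype=int), pad_mask)


class TestApplyMlmMask:
    def test_zero_selection_is_identity(self):
        v = vocab_for()
        enc = toy_encoding(v, ["401.9", "250.0", "530.8"])
        out, targets = apply_mlm_mask(enc, MaskingPolicy(p_select=0.0),
                                      np.random.default_rng(0), v)
        assert targets == {}
        np.testing.assert_array_equal(out.token_ids, enc.token_ids)

    def test_specials_and_pads_never_masked(self):
        v = vocab_for()
        enc = toy_encoding(v, [CLS, "401.9", SEP, "250.0"], pad_to=8)
        rng = np.random.default_rng(0)
        for _ in range(50):
            out, targets = apply_mlm_mask(enc, MaskingPolicy(p_select=0.9),
                                          rng, v)
            assert out.token_ids[0] == v.id(CLS)
            assert out.token_ids[2] == v.id(SEP)
            assert np.all(out.token_ids[4:] == v.id(PAD))
            assert set(targets) <= {1, 3}

    def test_corruption_only_at_selected_positions(self):
        v = vocab_for("272.4", "414.9", "437.0")
        codes = ["401.9", "250.0", "530.8", "272.4", "414.9"] * 4
        enc = toy_encoding(v, codes)
        out, targets = apply_mlm_mask(enc, MaskingPolicy(p_select=0.5),
                                      np.random.default_rng(1), v)
        changed = np.nonzero(out.token_ids != enc.token_ids)[0]
        assert set(changed) <= set(targets)
        for pos, orig in targets.items():
            assert orig == enc.token_ids[pos]

    def test_stream_replay_oracle(self):
        """An independent re-implementation consuming the identical random
        stream reproduces the exact replacement pattern."""
        v = vocab_for("272.4", "414.9")
        codes = ["401.9", "250.0", "530.8", "272.4", "414.9",
                 "401.9", "250.0", "530.8", "272.4", "414.9"]
        enc = toy_encoding(v, codes)
        policy = MaskingPolicy(p_select=0.4)
        got, targets = apply_mlm_mask(enc, policy,
                                      np.random.default_rng(7), v)
        # replay: same stream contract (one draw to select; on selection one
        # draw for the branch; random-branch draws ints until != original)
        rng = np.random.default_rng(7)
        expect = enc.token_ids.copy()
        expect_targets = {}
        n_codes = len(v) - v.n_special
        for i, tok in enumerate(enc.token_ids):
            if rng.random() >= policy.p_select:
                continue
            expect_targets[i] = int(tok)
            u = rng.random()
            if u < 0.70:
                expect[i] = v.id(MASK)
            elif u < 0.85:
                while True:
                    cand = v.n_special + int(rng.integers(n_codes))
                    if cand != tok:
                        break
                expect[i] = cand
        np.testing.assert_array_equal(got.token_ids, expect)
        assert targets == expect_targets

    def test_policy_probabilities_validated(self):
        with pytest.raises(ValueError):
            MaskingPolicy(p_mask=0.5, p_random=0.2, p_keep=0.2)


class TestMakeNspExample:
    V = vocab_for("272.4", "465.9")
    D0 = dt.date(2015, 1, 1)

    def _ex(self, dated_codes, horizon=365, L=20, spec=SPEC):
        return make_nsp_example(record_from(dated_codes), spec, horizon, L,
                                self.V)

    def test_trigger_twice_then_target_within_horizon_is_positive(self):
        ex = self._ex([
            (self.D0, ["401.9"]),
            (self.D0 + dt.timedelta(days=30), ["401.9"]),
            (self.D0 + dt.timedelta(days=120), ["250.0"]),
        ])
        assert ex.label == 1

    def test_trigger_twice_without_later_target_is_negative(self):
        ex = self._ex([
            (self.D0, ["401.9"]),
            (self.D0 + dt.timedelta(days=30), ["401.9", "530.8"]),
            (self.D0 + dt.timedelta(days=120), ["272.4"]),
        ])
        assert ex.label == 0

    def test_target_beyond_horizon_is_negative(self):
        ex = self._ex([
            (self.D0, ["401.9"]),
            (self.D0 + dt.timedelta(days=30), ["401.9"]),
            (self.D0 + dt.timedelta(days=500), ["250.0"]),
        ])
        assert ex.label == 0

    def test_under_k_appends_sep_with_label_zero(self):
        ex = self._ex([
            (self.D0, ["401.9"]),
            (self.D0 + dt.timedelta(days=60), ["250.0"]),
        ])
        assert ex is not None and ex.label == 0
        toks = [self.V.token(i) for i, m in
                zip(ex.encoding.token_ids, ex.encoding.pad_mask) if m]
        assert toks[-1] == SEP  # separator at the very end

    def test_patient_without_trigger_or_target_is_excluded(self):
        assert self._ex([(self.D0, ["530.8"]),
                         (self.D0 + dt.timedelta(days=10), ["465.9"])]) is None

    def test_same_visit_target_does_not_count_as_after_sep(self):
        ex = self._ex([
            (self.D0, ["401.9"]),
            (self.D0 + dt.timedelta(days=30), ["401.9", "250.0"]),
        ])
        assert ex.label == 0

    def test_exactly_one_sep_and_one_cls(self):
        ex = self._ex([
            (self.D0, ["401.9", "530.8"]),
            (self.D0 + dt.timedelta(days=30), ["401.9"]),
            (self.D0 + dt.timedelta(days=90), ["250.0"]),
        ])
        toks = list(ex.encoding.token_ids)
        assert toks.count(self.V.id(SEP)) == 1
        assert toks.count(self.V.id(CLS)) == 1
        assert toks[0] == self.V.id(CLS)

    def test_history_stops_at_separator_visit(self):
        ex = self._ex([
            (self.D0, ["401.9"]),
            (self.D0 + dt.timedelta(days=30), ["401.9"]),
            (self.D0 + dt.timedelta(days=90), ["250.0", "272.4"]),
        ])
        toks = [self.V.token(i) for i, m in
                zip(ex.encoding.token_ids, ex.encoding.pad_mask) if m]
        assert "250.0" not in toks and "272.4" not in toks

    def test_label_one_implies_target_in_window_by_rescan(self, small_cohort,
                                                          trigger_spec):
        records, _ = small_cohort
        codes = sorted({c for r in records for c in r.disease_positions()})
        vocab = Vocabulary(codes)
        for rec in records:
            ex = make_nsp_example(rec, trigger_spec, 365, 75, vocab)
            if ex is None or ex.label == 0:
                continue
            limit = ex.sep_date + dt.timedelta(days=365)
            assert any(v.date > ex.sep_date and v.date <= limit
                       and any(c in trigger_spec.targets for c in v.codes)
                       for v in rec.visits)

    def test_truncation_keeps_separator_and_recent_suffix(self):
        visits = [(self.D0 + dt.timedelta(days=7 * i), ["530.8"])
                  for i in range(30)]
        visits += [(self.D0 + dt.timedelta(days=300), ["401.9"]),
                   (self.D0 + dt.timedelta(days=330), ["401.9"])]
        ex = self._ex(visits, L=10)
        assert len(ex.encoding.token_ids) == 10
        toks = [self.V.token(i) for i in ex.encoding.token_ids]
        assert toks[0] == CLS and toks[-1] == SEP


class TestBalancePretraining:
    def _examples(self, n_pos, n_neg):
        enc = toy_encoding(vocab_for(), ["401.9"])
        from emrbert.bert import NSPExample
        mk = lambda lab, i: NSPExample(enc, lab, dt.date(2015, 1, 1), 365,
                                       f"p{lab}_{i}")
        return ([mk(1, i) for i in range(n_pos)]
                + [mk(0, i) for i in range(n_neg)])

    def test_exact_twenty_percent_composition(self):
        out = balance_pretraining(self._examples(40, 80), 0.20,
                                  np.random.default_rng(0))
        labels = [e.label for e in out]
        assert sum(labels) == 20 and len(out) == 100

    def test_all_positive_with_fraction_one_is_identity_sample(self):
        exs = self._examples(15, 0)
        out = balance_pretraining(exs, 1.0, np.random.default_rng(0))
        assert {e.patient_id for e in out} == {e.patient_id for e in exs}

    def test_deterministic_under_seed(self):
        exs = self._examples(100, 400)
        a = balance_pretraining(exs, 0.2, np.random.default_rng(5))
        b = balance_pretraining(exs, 0.2, np.random.default_rng(5))
        assert [e.patient_id for e in a] == [e.patient_id for e in b]

    def test_scarce_class_gives_best_achievable(self):
        out = balance_pretraining(self._examples(1, 80), 0.2,
                                  np.random.default_rng(0))
        labels = [e.label for e in out]
        assert sum(labels) == 1 and len(out) == 5


def tiny_corpus(vocab, n=24, seed=0):
    """Deterministic trigger->target rule: label = trigger appears twice."""
    rng = np.random.default_rng(seed)
    examples = []
    d0 = dt.date(2015, 1, 1)
    for i in range(n):
        k_occurrences = 2 if i % 2 == 0 else 1
        codes = ["401.9"] * k_occurrences + ["530.8"] * 3
        rng.shuffle(codes)
        visits = [(d0 + dt.timedelta(days=10 * j), [c])
                  for j, c in enumerate(codes)]
        if k_occurrences == 2:
            visits.append((d0 + dt.timedelta(days=90), ["250.0"]))
        rec = record_from(visits)
        rec.patient_id = f"p{i}"
        ex = make_nsp_example(rec, SPEC, 365, 12, vocab)
        assert ex is not None
        examples.append(ex)
    return examples


class TestPretrain:
    def test_zero_epochs_is_seeded_initialization(self):
        v = vocab_for()
        model = BertEncoder(v, ModelConfig(hidden=16, heads=2, seed=3))
        ref = BertEncoder(v, ModelConfig(hidden=16, heads=2, seed=3))
        model, trace = pretrain(model, tiny_corpus(v), epochs=0)
        assert trace == []
        for k in ref.params:
            np.testing.assert_array_equal(model.params[k].data,
                                          ref.params[k].data)

    def test_loss_descends_on_tiny_corpus(self):
        v = vocab_for()
        model = BertEncoder(v, ModelConfig(hidden=16, heads=2, seed=0))
        _, trace = pretrain(model, tiny_corpus(v), epochs=4, batch_size=8,
                            lr=2e-3, seed=0)
        assert trace[-1] < trace[0]

    def test_empty_corpus_rejected(self):
        v = vocab_for()
        with pytest.raises(ValueError):
            pretrain(BertEncoder(v, ModelConfig(hidden=16, heads=2)), [])

    def test_vocab_mismatch_rejected(self):
        big = vocab_for("272.4", "414.9", "437.0", "465.9")
        small = vocab_for()
        corpus = tiny_corpus(big)
        # force an id beyond the small vocabulary
        corpus[0].encoding.token_ids[1] = len(small) + 2
        with pytest.raises(ValueError):
            pretrain(BertEncoder(small, ModelConfig(hidden=16, heads=2)),
                     corpus)


class TestFinetunePredict:
    def test_separable_rule_is_learned(self):
        v = vocab_for()
        corpus = tiny_corpus(v, n=32)
        model = BertEncoder(v, ModelConfig(hidden=16, heads=2, max_len=12,
                                           seed=0))
        model, _ = finetune(model, corpus, epochs=30, batch_size=8,
                            lr=3e-3, seed=0)
        probs = predict_proba(model, corpus)
        metrics = evaluate(probs, [e.label for e in corpus])
        assert metrics["accuracy"] == 1.0

    def test_zero_epochs_keeps_body(self):
        v = vocab_for()
        model = BertEncoder(v, ModelConfig(hidden=16, heads=2, seed=1))
        before = model.params["tok_emb"].data.copy()
        model, _ = finetune(model, tiny_corpus(v), epochs=0)
        np.testing.assert_array_equal(model.params["tok_emb"].data, before)

    def test_freeze_body_touches_only_head(self):
        v = vocab_for()
        model = BertEncoder(v, ModelConfig(hidden=16, heads=2, seed=1))
        body_before = {k: p.data.copy() for k, p in model.params.items()}
        model, _ = finetune(model, tiny_corpus(v), epochs=1,
                            freeze_body=True)
        head = {"pool_W", "pool_b", "nsp_w", "nsp_b"}
        for k, before in body_before.items():
            if k in head:
                continue
            np.testing.assert_array_equal(model.params[k].data, before)
        assert not np.array_equal(model.params["nsp_w"].data,
                                  body_before["nsp_w"])

    def test_prediction_is_deterministic_and_bounded(self):
        v = vocab_for()
        corpus = tiny_corpus(v, n=8)
        model = BertEncoder(v, ModelConfig(hidden=16, heads=2, seed=0))
        p1 = predict_proba(model, corpus)
        p2 = predict_proba(model, corpus)
        np.testing.assert_array_equal(p1, p2)
        assert np.all((p1 >= 0) & (p1 <= 1))


class TestEvaluate:
    def test_perfect_separation(self):
        m = evaluate([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert all(m[k] == 1.0 for k in
                   ("auc_roc", "accuracy", "precision", "recall", "f1"))

    def test_constant_probability_gives_chance_auc(self):
        m = evaluate([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert m["auc_roc"] == pytest.approx(0.5)

    def test_fixed_confusion_table(self):
        # TP=3, FP=1, FN=1, TN=5
        probs = [0.9] * 3 + [0.9] + [0.1] + [0.1] * 5
        labels = [1] * 3 + [0] + [1] + [0] * 5
        m = evaluate(probs, labels)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.75)

    def test_single_class_auc_undefined(self):
        m = evaluate([0.2, 0.7], [0, 0])
        assert m["auc_roc"] is None

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0.5], [1, 0])


class TestCheckpointRoundTrip:
    def test_save_load_preserves_forward(self, tmp_path):
        v = vocab_for()
        model = BertEncoder(v, ModelConfig(hidden=16, heads=2, seed=0))
        corpus = tiny_corpus(v, n=4)
        path = str(tmp_path / "encoder.json")
        model.save(path)
        back = BertEncoder.load(path)
        np.testing.assert_array_equal(predict_proba(model, corpus),
                                      predict_proba(back, corpus))
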
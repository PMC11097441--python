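# emrbert

Disease prediction from electronic medical records (EMRs), with a
semi-supervised attention denoiser that filters uninformative diagnoses
before a compact BERT-style encoder predicts a patient's next disease.

Administrative claims sequences are dominated by short-lived, seasonally
driven diagnoses — influenza-like illnesses above all — that say little
about a patient's underlying condition. When diagnosis sequences are
treated as sentences and diseases as words, these codes behave like
stuttered words: they dilute the context a sequence model can use. This
package is for researchers working with coded diagnosis histories
(ICD-9-style claims or EHR extracts) who want to predict whether a target
comorbidity will appear within a time horizon, while explicitly filtering
such noise diagnoses instead of feeding the raw sequence to the model.

## The model

A patient's record `EMR_p = ⟨(dt_i, d_{i,1}, …, d_{i,m_i})⟩` is flattened
into three aligned channels: the disease sequence `D` (codes in visit
order), the visit sequence `VS` (1-based visit index per code), and the
time-interval sequence `TIS` (day gap to the previous visit on each visit's
first code, 0 elsewhere).

**Comorbidity graph.** A target disease is a comorbidity of a trigger
disease when it manifests after the trigger's k-th occurrence in a
patient's sequence (k = 2 by default). Triggers and their targets form an
undirected graph whose edge weight is a rank-order distance,

    wt(u, v) = (1 / N_uv) · Σ_k |R_{u,k} − R_{v,k}| · F_k,

summed over the `N_uv` comorbidities common to `u` and `v`, where `R_{u,k}`
is the 1-based rank of comorbidity `k` in `u`'s frequency-ordered
comorbidity list and `F_k` its Shannon entropy across patients. Disease
vectors are learned from this graph by random-walk skip-gram embedding, so
codes excluded from the graph (the noise list) remain visibly different
from codes with comorbidity structure.

**Denoiser.** Two first-layer blocks read the embedded sequence: a
bidirectional sigmoid recurrence capturing each code's role in the whole
sequence, and a reverse-direction recurrence emphasizing the short-range
patterns noise codes live in. Their outputs are mixed, `v_t = α·h_t +
β·ĥ_t`, with `α = P(trigger | noise history)` and `β = P(noise history |
trigger)` estimated from the corpus. A scaled-dot-product attention layer
over the mixed sequence yields a per-position attention mass `a_i`; the
dense score `f_s(a_i) = sigmoid(w′·(n·a_i) + b′)` is trained
semi-supervised — binary cross-entropy only at positions whose code is in
the known noise set (drop) or the trigger/target sets (keep) — and a
position survives extraction iff `f_s(a_i) > θ` (θ = 0.5).

**Encoder.** The denoised triple feeds a small transformer encoder: token
embeddings from `D`, segment embeddings from `VS`, positional embeddings
from bucketized `TIS`. Pretraining couples a masked-code objective
(selected codes are replaced by `[MASK]` with probability 0.70, a random
code with 0.15, kept with 0.15) with trigger/target next-sentence
prediction: `[SEP]` is inserted after the visit containing the trigger's
k-th occurrence and the label records whether any target disease follows
within the horizon T (1 year by default); the pretraining corpus is
rebalanced to 20% positives. Fine-tuning and prediction reuse the
next-sentence head, and evaluation reports AUC-ROC, accuracy, precision,
recall and F1.

No real patient data ships with or is required by the package: a synthetic
cohort generator emulates the relevant structure (noise codes with
single-peak ~10-day revisit intervals, chronic codes with multi-peak
revisit intervals, a planted trigger→target rule, configurable noise
prevalence) together with ground-truth noise flags and labels.

## Worked example

```python
import io
from emrbert import parse_emr, derive_sequences

table = """patient_id,date,dx1,dx2,dx3
A,2013-11-11,250.0,EPS,EPS
A,2013-11-21,726.0,438.5,847.0
A,2013-12-05,250.0,EPS,EPS
A,2013-12-09,414.0,401.9,250.0
"""
seqs = derive_sequences(parse_emr(io.StringIO(table))[0])
print(seqs.D)   # ['250.0', '726.0', '438.5', '847.0', '250.0', '414.0', '401.9', '250.0']
print(seqs.VS)  # [1, 2, 2, 2, 3, 4, 4, 4]
print(seqs.TIS) # [0, 10, 0, 0, 14, 4, 0, 0]
```

The three diagnoses on 2013-11-21 share visit index 2, and the 10-day gap
from the previous visit sits on that visit's first code. With trigger
250.0 and k = 2, code 401.9 is recognized as a comorbidity because it
appears after the second occurrence of 250.0.

The `examples/` directory holds one short script per capability; the
end-to-end one prints, on a 400-patient synthetic cohort (seed 1):

```
with denoising:      auc_roc 0.807  accuracy 0.735  recall 0.762
without denoising:   auc_roc 0.739  accuracy 0.639  recall 0.595
```

i.e. filtering the influenza-like codes keeps the trigger history inside
the encoder window and fewer true future-comorbidity cases are missed.

A thin CLI wraps the same pipeline:

```bash
emrbert simulate --n-patients 400 --seed 1 --out-dir cohort
emrbert preprocess --emr cohort/emr.csv --out-dir pre
emrbert train --emr cohort/emr.csv --out-dir run        # add --no-denoise to ablate
emrbert eval --emr cohort/emr.csv --model run/encoder.json
```

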
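# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic cohorts do and do not emulate, and the numerical
and design decisions taken where more than one reading was defensible.

## Sequence transforms

A record is an ordered list of dated visits, each a non-empty tuple of
ICD-9 codes. The three derived channels (`D`, `VS`, `TIS`) are aligned
position-by-position; `TIS` places the day gap to the previous visit on the
first code of each visit (0 within a visit, and 0 for the first visit,
whose reference date is itself). Calendar days are used throughout;
time-of-day is ignored.

Code normalization truncates to the category plus one decimal digit
(XXX.X). Codes listed verbatim in a configured set (the noise list itself
contains five-digit codes such as 464.00 and 466.11) are kept exactly as
listed; truncation applies only to codes outside those sets. Normalization
is idempotent, and malformed tokens raise a parse error naming the value
and row.

When sequences are brought to a fixed length, truncation keeps the most
recent suffix: the model predicts the future, and recent history dominates.
Padding appends a reserved `[PAD]` sentinel with 0 in the `VS`/`TIS`
channels. Within-visit code order is preserved as given in the input.

## Comorbidity graph

`find_comorbidities` counts a disease once per patient when some occurrence
sits strictly after the k-th trigger occurrence in the flattened sequence;
same-visit codes listed after the trigger's k-th occurrence count as after
(position granularity, not visit granularity). Trigger selection requires
(a) more than two occurrences within at least one patient, (b) a non-empty
comorbidity set, (c) absence from the noise list, and (d) patient
prevalence of at least 1%.

Rank lists order each disease's comorbidities by patient-support count,
descending, with ties broken by code order so ranking is deterministic.
The edge weight averages `|R_u,k − R_v,k| · F_k` over common comorbidities
k, where ranks are the comorbidity's 1-based positions in the two lists.
`F_k` defaults to the binary entropy of patient prevalence (the reference
distribution is pluggable). An edge whose endpoints share no comorbidity
is kept — adjacency is defined by the trigger/target relation, not by the
weight — and receives the maximum observed finite weight plus one, flagged
in exports, which penalizes unrelated pairs during the embedding walks.

The embedding is a random-walk skip-gram (10 walks per node, walk length
20, window 5, 64 dimensions, 5 negative samples, 5 epochs): walk steps
prefer low-weight (closer) neighbours with probability proportional to
`1/(1+wt)`. Trained vectors are L2-normalized, so cosine geometry carries
the graph structure; vocabulary codes absent from the graph receive small
seeded random rows. The scale difference is deliberate: a code with
comorbidity structure is visibly different, in the representation itself,
from one without — which is what makes the semi-supervised denoiser
generalize from the labeled noise codes to unlabeled short-episode codes.

## Denoiser

Hidden recurrences use the logistic function; block outputs use tanh. The
"bidirectional" full block is realized as forward and backward recurrences
concatenated and projected back to the hidden size; the noise block is a
single reverse-direction recurrence with its own output transform, outputs
re-aligned to forward positions. Mixing is position-wise:
`v_t = α h_t + β ĥ_t`, with `α = P(trigger | noise-history)` and
`β = P(noise-history | trigger)` estimated at patient level from the
training corpus (override with fixed values if desired).

The second layer is standard scaled-dot-product attention with learned
Q/K/V projections of `v_t` and `dim_k` equal to the hidden size. The
per-position attention mass `a_i` is the column mean of the masked softmax
matrix over non-pad query rows, renormalized to sum to one over non-pad
positions. The dense score is an affine-plus-sigmoid on the
*length-scaled* mass, `f_s(a_i) = σ(w′·(n·a_i) + b′)`: multiplying by the
number of real positions makes the score length-invariant (a perfectly
uniform sequence scores identically at every length), without which the
O(1/n) scale of softmax masses forces impractically large weights. `w′`
is initialized at 1 so "above-average mass means keep" is the starting
orientation; training then mostly learns to suppress the mass of noise
positions. Extraction keeps position i iff `f_s(a_i) > θ` strictly
("exceeds"), θ = 0.5 by default and configurable.

Semi-supervision: label 1 where the code is in the noise set, label 0
where it is the trigger or a target, no label elsewhere. The loss is
binary cross-entropy of `1 − f_s` against these labels at labeled positions
only. Training uses Adam (defaults: 4 epochs, batch 32 sequences,
learning rate 2e-3), is single-threaded and seeded, and is therefore
reproducible. The sequence-level score `ŷ = Σ y_i` is exposed as a
diagnostic only.

In the pipeline the denoiser processes *full-length* sequences; truncation
to the encoder length happens afterwards, when examples are assembled.
This ordering is the point of the module: removing noise first means the
fixed encoder window reaches deeper into real history.

## Encoder and objectives

The encoder is a pre-activation-free, post-layer-norm transformer (2
layers, 2 heads, hidden 64, feed-forward 256, GELU) — a desk-scale choice;
length 75 is the default (the flattening of roughly a year of records at
up to three codes per visit), with longer windows supported. Inputs sum
three learned embeddings: code tokens, visit indices capped at 50, and day
gaps bucketized on {0, 1–7, 8–30, 31–90, 91–365, >365}.

Masked-code corruption selects non-special positions independently with
probability 0.15 (the conventional rate; the split conditional on
selection is 0.70 mask / 0.15 random / 0.15 keep as printed). Random
replacement draws uniformly from non-special vocabulary excluding the
original code; `[CLS]`, `[SEP]` and pads are never touched.

Next-sentence examples: `[SEP]` goes after the visit containing the k-th
trigger occurrence; the label is 1 iff any configured target occurs in a
later visit dated within T of the separator visit (a same-visit target
does not count as "after"). A patient with trigger or target codes but
fewer than k trigger occurrences gets `[SEP]` at the end and label 0; a
patient with neither is excluded. Two readings were open here and both are
resolved the same way: (i) the encoding contains the history up to and
including `[SEP]` only — the label summarizes the future window, and
feeding post-separator visits to the encoder would leak the label into the
input of a model whose downstream task is to predict an unseen future;
(ii) separator placement and label are always computed on the raw record —
denoising changes the input features, never the supervision. Pretraining
rebalances the corpus to 20% positives by stratified sampling without
replacement (exact up to rounding; the best achievable composition is
returned when a class is too small). Pretraining optimizes masked-code
cross-entropy plus the next-sentence binary loss jointly; fine-tuning
optimizes the next-sentence head (body updated too unless frozen). Because
hard thresholded extraction is not differentiable, the denoiser is trained
on its own semi-supervised objective rather than through the classifier's
gradient.

Training defaults (Adam, lr 2e-3, pretrain 2 epochs, fine-tune 16 epochs,
batch 16) were sized for single-CPU runs on cohorts of a few hundred
patients. The classification head uses small random initialization; a
zero-initialized head vector blocks gradient flow into the pooled
representation and produced threshold-brittle, sometimes collapsed
classifiers.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, not
any real population:

* noise diagnoses (the packaged influenza-like list) occur in short
  episodes; within-episode revisit gaps are log-normal with median 10 days
  (σ = 0.3), giving the single-peak revisit-interval shape near 10 days;
* chronic diagnoses (trigger, targets, and a 20-code filler panel) recur
  with gaps from a four-component normal mixture (peaks 28/91/182/364
  days, weights 0.35/0.30/0.20/0.15) — the multi-peak follow-up pattern;
  onset is uniform over the observation window (2013–2016);
* one planted causal rule: a patient whose trigger has occurred k times
  develops a uniformly drawn target within the horizon with probability
  `rule_strength` (default 0.7); with the complementary probability any
  target occurrences in that window are removed;
* the noise-position fraction is controlled per patient to hit the
  configured prevalence (default 0.205, the patient-level rate of
  influenza-like diagnoses in the emulated cohort) within ±2% at n = 1,000;
* visit structure: diagnoses within 2 days consolidate into one visit, and
  half the chronic panel is co-managed on another member's follow-up
  schedule, reproducing multi-code encounters (≈1.5 codes per visit,
  sequence lengths averaging ≈51 with a heavy tail; the per-patient visit
  target is drawn from N(27.34, 20.93²), clipped).

Ground truth ships with every cohort: per-position noise flags and the
per-patient label under the configured trigger spec, cross-checked exactly
against the example builder. Deliberately not emulated: demographics,
code hierarchies, regional/coding-version drift, care-seeking behaviour,
and any correlation between noise burden and outcome. Passing tests on
these cohorts show the machinery recovers planted structure under the
stated conditions; they say nothing about performance on real claims data.

## Evaluation properties and problem sizes

Two cohort-level properties are asserted by the test suite at sizes chosen
for a single CPU: (1) the trained denoiser's `1 − f_s` ranking separates
true noise positions from the rest with AUC ≥ 0.8, averaged over three
seeds on 2,000-patient cohorts; (2) the full pipeline's held-out recall
(scored against generator ground truth, threshold 0.5, 30% validation
split) exceeds the denoising-disabled variant's, averaged over three seeds
on 400-patient cohorts. The recall gap has a concrete mechanism here:
noise inflates histories past the encoder window, hiding early trigger
occurrences from the raw model, while the denoised model sees them.

## Known limitations

* The denoiser's keep/drop decision is a monotone function of scalar
  attention mass, and softmax mass is conserved; strongly up-weighted
  labeled keep-positions can crowd out unlabeled ones. The oriented
  initialization and length scaling mitigate but do not remove this.
* Unlabeled codes are judged by representation geometry; a genuinely
  informative code absent from the comorbidity graph looks like noise.
* ICD-10, procedure and drug codes are out of scope; the horizon label
  uses calendar days only.
* The NumPy training stack is single-threaded float64; it is sized for
  desk-scale experiments, not for cohorts of hundreds of thousands of
  patients.
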
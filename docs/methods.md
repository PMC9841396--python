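# Methods

## Model

The classifier is a TextCNN with a single-logit head. Tokens are
embedded in ℝ^e (default e = 50, uniform ±0.1 initialisation,
trainable; the pad row is frozen at zero). For each ngram length
n ∈ {1, 2, 3, 5} a bank of 36 filters (144 total) convolves the
embedded sequence; each filter's activations are max-pooled over all
fully in-bounds windows of the (pad-extended) document — documents
shorter than the largest ngram are right-padded — and ties take the
smallest window index so that reports are reproducible. The pooled
activation times the filter's FC weight is the filter logit lₖ; the
sample logit is L = Σ lₖ + bias and the patient probability is
P₁ = e^L/(e^(−L)+e^L) = σ(2L).

Equivalence with the standard two-logit head is exact: for any pooled
activation vector, softmax(logit₁, logit₀) equals σ(2·logit_δ) with
logit_δ = logit₁ − (logit₀+logit₁)/2, so a trained two-logit FC layer
converts to the single-logit form by element-wise halfway distances
(`convert_two_logit_head`). The per-filter decomposition

    lₖ = cos θ · ‖x_window‖ · Impₖ · sign(FCₖ) + bₖ·FCₖ

is implemented with the convolution kernel bias bₖ kept as an explicit
additive term, making the reconstruction exact to float rounding
rather than approximate; the kernel biases are retained in the model
because they help optimisation. A zero-magnitude window (all pad
tokens) reports cosine 0 by convention, and the filter logit then
equals the kernel-bias term. A `pre_fc_relu` flag (default off) clamps
negative pooled activations before FC scaling; the decomposition is
defined on the unclamped path.

No deep-learning framework is used: the forward pass, the max-pool
gradient routing and the analytic backward pass are written in numpy.
This keeps the decomposition, ablation arithmetic and training loop in
one small auditable codebase and makes bit-level reproducibility easy
to guarantee.

## Training

Binary cross-entropy on σ(2L), optimised with Adam (β = 0.9/0.999,
decoupled weight decay 1e-4 on embeddings and weights, not biases)
under a 1-Cycle schedule: linear warm-up from peak/25 to the peak
learning rate over the first half of the steps, linear anneal to
peak/10⁴ over the second half. Defaults: peak 5e-3, 10 epochs, batch
size 32 (a peak of 1e-3 visibly underfits this from-scratch model on
the synthetic corpora). Splitting is by *patient*: patients are
shuffled under the split seed and partitioned 75/15/10 into
train/validate/holdout; `forced_overlap` plants copies of a chosen
fraction of holdout patients' notes into train (doc ids flagged
`#leak`) to simulate leakage while leaving holdout itself intact.
Vocabularies are built from the train split only (frequency-then-
lexicographic order, reserved pad/OOV ids). `run_experiment_iterations`
repeats split→train→evaluate with derived seeds (default 10 iterations)
and reports holdout AUC mean ± sd. Everything — generator, splits,
batching, initialisation — is driven by explicit seeds; two runs with
the same seeds produce byte-identical corpora, weight hashes and HTML
reports (fixed thread count).

## ZF dictionaries and metrics

`calc_zf_dict` records, per filter and dataset: every document's filter
logit, label and max-pool location, and the top 4 *distinct* max-pool
ngrams ranked by their largest per-instance logit (duplicates of the
same token sequence are collapsed; the cosine and magnitude shown for
a distinct ngram come from its maximum-logit instance). Occurrence
counts are overlapping sliding-window matches over the cleaned,
tokenised dataset, split by class. Per-filter AUC is the Mann–Whitney
concordance (ties 0.5, computed from ranks); logit deltas use the mean
or the median, with even-length medians the midpoint of the central
order statistics. Ranking is descending on the chosen key with ties
broken by ascending filter index. The HTML report is rendered with
deterministic 3-decimal formatting and inline styles; every displayed
number is taken from the ZF dictionaries / metrics, never recomputed in
the renderer. The delta-scatter outlier rule is a swappable policy;
the default flags a filter when its cross-dataset delta difference
falls outside median ± 3·1.4826·MAD, or when its deltas flip sign with
both magnitudes above the median absolute delta. The rule is a design
choice — drift diagnosis, not a calibrated test.

## Synthetic corpus

The generator emulates the three ingredients the diagnostics target:
discriminative ngrams inserted per note with class-conditional rates,
template boilerplate inserted at equal rates in both classes, and a
`patient name <first> <last>` span opening every note, with one unique
synthetic name per patient, 2–4 notes per patient and ~500 patients by
default. Default discriminative rates are deliberately weak (0.35/0.10
and 0.25/0.08; validate AUC ≈ 0.6) to emulate the hard clinical regime
in which models overfit to names and template artifacts — the regime
the leakage diagnostic presumes. Strongly separable corpora for the
feature-recovery checks raise those rates explicitly (a single feature
present in 90% of patient notes and 5% of controls caps the per-note
Bayes AUC near 0.93, so "cleanly separable" requires either cleaner
rates or multiple features). What the generator does *not* model:
realistic clinical syntax, co-reference, note-length distributions,
shared names across patients, or names appearing outside the fixed
template. Passing tests therefore demonstrate the mechanics of the
method, not its performance on real notes.

## Leakage estimation

For each forced-overlap level the pipeline trains a fresh model,
computes the train-split ZF dictionary and scores every filter by how
well its top activations match the name template. Matching is
*offset-aware*: a trained filter aligns the template at some fixed
position in its window — `patient name <first> <last> ·` and
`name <first> <last> · ·` are both name extractors — so a filter's
score is the fraction of its top activations whose tokens match the
(possibly window-truncated) template anchor at the filter's modal
offset, and the name slice is derived from that offset.

Extraction pools the anchored spans of the whole *bank* of filters
with match fraction ≥ 0.25 rather than a single filter. This is a
consequence of hard max-pool routing: a filter only receives gradients
for windows it already wins, so name memorisation fragments across
several filters and any single one covers only a minority of the
names; the union recovers nearly all of them, and in this corpus an
anchored span always contains a true name (the anchor token only
occurs in the template), so widening the bank adds recall without
false positives. Spans whose window does not contain the anchor are
discarded as filler. The estimate is the fraction of distinct holdout
names present among train names (holdout-side denominator;
deduplication makes it invariant to duplicating notes). The best
single filter is still identified and reported per level, and a manual
`name_filter` override bypasses the bank. Across levels 0/10/30/50%
the Pearson correlation between injected and estimated overlap is
≥ 0.99 on the development seeds.

## Numerical and design notes

- Token positions are 0-based; windows are half-open [j, j+n).
- `sign(FC_k) = +1` is reported with a warning when FC_k is exactly 0.
- Decomposition reconstruction tolerance: 1e-5 relative; head
  conversion: 1e-6 absolute on probabilities; ablation identity: exact
  up to 1e-6 float accumulation.
- Cleaning lowercases, transliterates to ASCII via Unicode
  decomposition, strips everything outside `[a-z0-9 ]` and collapses
  whitespace; it is idempotent, and tokenisation is whitespace
  splitting.
- Checkpoints are single `.npz` archives holding the config (JSON) and
  all weight arrays; the weight round-trip is bit-exact.
- Problem sizes used by the test suite and the acceptance script
  (25–500 patients, 2–10 training epochs) were chosen to exercise each
  property at the smallest scale where it is meaningful.

## Limitations

The toolkit is binary-only (multi-class would need one-vs-rest
extensions), assumes a single additive classification layer, and the
leakage diagnostic only detects leakage expressed through the
designated name template. Correlations reported on the synthetic
corpus say nothing quantitative about real clinical notes, where names
are multi-form, templates vary and signal/noise ratios differ.
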
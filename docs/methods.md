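# Methods

This note records the modeling choices behind `crfbridge`: what each
component assumes, which knobs matter, what the synthetic data does and
does not emulate, and where the design was genuinely open.

## Linear-chain CRF

The tagger is the standard log-linear chain model: per-position emission
potentials `W_f · f(y_l, x)` over a sparse feature space and
position-independent transition potentials `W_g[y_{l-1}, y_l]`, globally
normalized. Inference is exact; all recursions run in log space
(`scipy.special.logsumexp`), position marginals are renormalized to kill
residual round-off, and Viterbi breaks ties toward the lower label index
(first-argmax), which makes decoding deterministic on degenerate
all-equal scores.

Features per position are the three-word unigram window
(w_{i-1}, w_i, w_{i+1}) and the two adjacent bigrams, binary-valued, with
explicit `<BOS>`/`<EOS>` sentinels at sentence boundaries. Licensed
ontology features (medical metathesaurus candidates, medication codes,
parse trees, lemmas) are out of scope; the `hooks` mechanism accepts any
token-level annotator (gazetteer membership, character shapes, coarse
tags) and feeds the same sparse space. Word-embedding features occupy
dense columns (`EMB[j]`) in the same index, disjoint from template names
by construction. With index growth disabled (prediction time), unseen
feature names are silently dropped, so the test-time space never exceeds
the training space.

Training is per-sentence AdaGrad on the L2-regularized negative
log-likelihood. Defaults: step 0.1, ε 1e-8, λ 1e-3 — chosen for stable
convergence on the toy tasks in the test suite and exposed in
`TrainConfig`. The λ‖W‖²/2 penalty is on the full objective; each
per-sentence update carries λ/N so the stochastic gradient is unbiased.
Early stopping monitors development macro-F1 *excluding NA* (the quantity
the tagger is ultimately judged on) with patience 5 by default; the
returned weights are those of the best dev epoch. With an empty dev set
the monitor falls back to (negative) training loss. `max_epochs = 0`
returns the initialization verbatim, which the transfer tests rely on.

## Label-correlation bridge

The printed form of a chain CRF's per-token layer is a multinomial
logistic model, which is what makes the bridge work: the frozen source
emission matrix `W_s` produces **raw linear scores** `a = W_s f(x)`, and a
second multinomial logistic layer `W_t` learns target labels from `a`.
The scores are deliberately not softmaxed between layers — linearity is
what makes `W_t W_s` an *exact* initialization rather than an
approximation (verified to 1e-12 in the tests). The bridge is trained by
AdaGrad from zero initialization on per-token cross-entropy; the loss is
convex, so no early stopping is needed at this stage.

At initialization of the target CRF:

* the composed NA row is reset to zero — NA dominates token frequency and
  would otherwise bias decoding toward the majority class from step one.
  The reset is applied once, on the composed emission row; fine-tuning
  may move it afterward.
* transitions start at zero: label co-occurrence patterns are domain- and
  task-specific and are not transferred.

Feature-space alignment between domains: target corpora are featurized
against the source model's feature index with growth enabled, and the
bridge's frozen copy of `W_s` is zero-padded to the grown width. This is
the simplest scheme that preserves exact composition (new features
contribute nothing to source scores) while letting fine-tuning learn
target-only vocabulary. The bridge owns the grown copy; the source model
object is never mutated (checked bit-for-bit in the tests).

Fine-tuning uses the same AdaGrad/early-stopping trainer. Early stopping
here is load-bearing beyond regularization: the composed initialization
is the transferred knowledge, and unlimited fine-tuning on a tiny target
corpus would simply converge to the cold-start optimum (the loss is
convex) and forget it. The abundant-data test demonstrates exactly this:
with 500 target sentences, transfer and cold start land within 0.05
macro-F1 of each other.

## Skip-gram embeddings and incremental adaptation

Skip-gram with negative sampling, sequential SGD, no hierarchical
softmax, no asynchronous threading — determinism at desk scale was
preferred over throughput, so a fixed seed yields bit-identical models.
Defaults mirror the settings commonly found best for named-entity work:
d = 200, window 5, k = 10 negatives, initial rate 0.05, 20 epochs, with a
linear rate decay floored at 1e-4 of the initial rate. Input vectors
start uniform in (−0.5/d, 0.5/d); output vectors start at zero.

Noise distribution: raw unigram (`noise_exponent = 1.0`) by default, with
the conventional 0.75 smoothing available in config. Frequent-word
subsampling exists behind a config flag and is off by default. The
unknown vector v₀ is an ordinary `<unk>` vocabulary entry absorbing words
below `min_count` (default 1, i.e. everything is kept and `<unk>` stays
at its initialization unless rare words exist); how v₀ should be obtained
is genuinely open, and making it a trainable ordinary row is the simplest
internally consistent answer.

Digit normalization replaces each maximal digit run of length m with
`NUM<m>` (`08-08-1988 → NUM2-NUM2-NUM4`), collapsing dates, phone numbers
and bed numbers into shared length patterns before embedding training.

Incremental adaptation: new words (V₁∖V₀) are appended with
averaged-initialization vectors — the per-dimension mean over all
positions of the first sentence containing the word, unknown neighbors
contributing v₀ — and train under α_new(t) = 0.2·(1−t/n). Words already
known (V₀∩V₁) train under α_old(t) = 0.2·(|V₁∖V₀|/|V₀∪V₁|)·(1−t/n): the
more new material, the more the old vectors are allowed to move. A
word's rate class applies to whichever of its parameter blocks an update
touches. Noise words are drawn from the *new* corpus's unigram
distribution only, which (together with the restriction of centers and
contexts to the new corpus) guarantees that vectors of words absent from
the new corpus are bit-identical afterwards. The published description
of the split schedule contains two inconsistent decay expressions for new
words; the implementation uses the reading above — new words start at
0.2, old words at the vocabulary-fraction-scaled rate, both linear — which
matches the accompanying prose, without claiming it is the only possible
reading.

## Evaluation

Token-level only: no span semantics are defined for this task (one label
per word, headings not BIO-encoded). Per-class P/R/F1 come from pooled
token counts (computed via scikit-learn with zero-division → 0); macro
averages exclude NA by default and NA F1 is reported separately, because
filtering irrelevant content and filling rare slots are different jobs; a
flag folds NA in. Schema classes absent from both gold and prediction
contribute zero to macro averages by default (`drop_absent` removes them
instead).

The Wilcoxon signed-rank test drops zero differences, requires ≥ 5
informative pairs, and enumerates the exact 2ⁿ sign-assignment null for
n ≤ 12 (valid under tied |d| since average ranks are held fixed); larger
n uses the normal approximation with tie and continuity corrections. The
intended pairing unit is per-document macro-F1. Baselines: uniform
random labels and the majority training label (frequency ties break
lexicographically).

## Synthetic data

The generator reproduces the *structural* properties that the transfer
method needs: a coarse source schema, a target schema refining it
(every target label refines exactly one source label; validated), a
dominant NA class (60 % of tokens by default), small disjoint per-label
lexicons of synthetic stems, and the key correlation — source-domain
entity tokens are drawn from the union of their refinements' sub-lexicons,
so a model that knows a word is PERSON has real information about
GIVEN_NAME vs LAST_NAME being the only options. A 5 % noise rate emits
tokens from the wrong lexicon; filler vocabularies overlap 50 % between
domains. By construction, conditioning on the true source label strictly
reduces target-label uncertainty, which is the property the
transfer-benefit experiment measures.

What it does **not** emulate: real clinical phraseology, speech-recognition
errors, spelling variation, document structure, or realistic label
imbalance beyond NA dominance. Passing the transfer-benefit test
therefore shows the *mechanism* works when source and target labels are
genuinely correlated; it does not predict effect sizes on real handover
text.

The topic-text generator (two groups of interchangeable content words
plus shared function words) gives embedding tests a ground-truth
similarity structure: within-topic cosine similarity must exceed
between-topic.

## Reference problem sizes

The benchmark drivers run at sizes chosen so the entire suite and the
reproduction script each complete in minutes on one CPU while keeping the
measured effects far from their decision thresholds:

* transfer benefit: source 500 train / 50 dev, target 10 / 50 / 200,
  10 paired seeds, source trained 15 epochs (patience 3), target 20
  (patience 5). Typical outcome: transfer ≈ 0.36 macro-F1 vs cold ≈ 0.09,
  median gap ≈ +0.27.
* topic separation: 150 sentences, 2 × 10 topic words, d = 16, 10 epochs,
  10 seeds; within-vs-between cosine margins are ≈ +0.9.
* exact-inference and gradient oracles: 100 random chains with L ≤ 6,
  |Y| ≤ 5 against full enumeration; 50 finite-difference points per
  objective.

## Known limitations

* Dense AdaGrad accumulators make training cost proportional to |Y|·F per
  sentence; fine for desk-scale feature spaces (10³–10⁴), wasteful beyond.
* The CRF is first-order with label-pair-only transitions, matching the
  model it implements; no feature-conjoined transitions.
* The bridge assumes the source model's feature templates are reused
  verbatim on the target domain; transferring across tokenizations is out
  of scope.
* Skip-gram training is single-threaded by design; corpora beyond a few
  hundred thousand tokens are impractical here.
* JSON model serialization stores dense weight matrices; compact formats
  were not a goal.
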
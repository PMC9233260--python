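# Methods

This note documents the models, parameters and design choices behind
`pamt`, and what the synthetic-data experiments do and do not show.

## Classification model

The classifier is a Bernoulli naïve Bayes (BNB) over boolean
term-presence features. For a document vector **x** ∈ {0,1}ᵀ and class
k ∈ {PAMT, non-PAMT},

    score(k) = log πₖ + Σₜ [ xₜ log P(t|k) + (1 − xₜ) log(1 − P(t|k)) ]

with P(t|k) = (n_kt + α)/(n_k + 2α), where n_kt is the number of
class-k training documents containing t and n_k the number of class-k
documents. α = 1 by default (Laplace / add-one smoothing), which keeps
every conditional strictly inside (0, 1) so no log is ever taken of
zero; no other hyperparameter exists. Class priors πₖ are the
empirical training frequencies by default; a `uniform` option is
provided because either convention is defensible for a deployed triage
tool (empirical priors encode the sampling design of the training
corpus, not the street prevalence of major trauma).

**Tie-break.** An exact posterior tie is resolved to PAMT. In triage,
the asymmetric cost is undertriage — missing a severe case — so the
indifference point goes to the sensitive side. The alternative is a
constructor argument, and the equivalence tests against scikit-learn's
`BernoulliNB` (which breaks ties the other way) exempt mathematical
ties for exactly this reason.

**Rule gate.** The hybrid enhancement classifies a document as PAMT
outright when it contains at least m = 2 of the expert keywords,
deferring to the BNB otherwise. "Contains at least 2 of the words" is
read as two *distinct* keyword types (a single keyword repeated does
not fire); a `token_occurrences` mode implements the other reading.
The gate operates on preprocessed tokens, so expert keywords must be
supplied in canonical (post-synonym-grouping) form. The gate can only
add positive predictions, hence the provable per-fold invariant
sensitivity(PAMT variant) ≥ sensitivity(variant C) when both share one
fitted BNB.

## Feature engineering

Term importance is raw-count tf times idf(t) = ln(N/df(t)), maximised
over documents; the top K = 160 terms are kept, ties broken by
bytewise term order so selection is deterministic and
locale-independent. Max-over-documents was chosen as the default
aggregate because a single emphatic document is what makes a word
salient in short urgent calls; sum-over-documents is a config
alternative, as are sub-linear tf (1 + ln tf) and smoothed idf
(ln((1+N)/(1+df)) + 1). With raw tf and plain idf a term present in
every document scores 0 and is never selected ahead of any informative
term.

Note a structural property visible in the synthetic experiments:
severity keywords typically occur once per document, so their max
tf·idf is modest, and pure tf–idf selection (variant B) can miss them
in favour of rare repeated background words. That is precisely the
failure mode the expert-keyword union (variant C) and the rule gate
(PAMT variant) exist to repair, and the synthetic variant ranking
reproduces it.

## Evaluation protocol

Repeated random subsampling cross-validation with a *fixed validation
composition*: each of R = 100 repeats holds out exactly 3 positives
and 7 negatives, drawn without replacement, trains on the remaining
104 (39/65) and scores the held-out 10. Two identities then hold
exactly for any predictor and are asserted in the tests:

    mean acc    = (3·mean sens + 7·mean spec) / 10
    mean youden = mean sens + mean spec − 1

Repeats with no predicted positives (or negatives) leave PPV (NPV)
undefined; such repeats are excluded from that metric's mean and
counted, never imputed as 0 — imputation would bias the mean by an
arbitrary amount that grows with the number of degenerate repeats.

**Feature-selection leakage.** The default `shared_space` mode selects
one feature space on the whole corpus and reuses it across repeats,
matching the single fixed 160-word space of the original protocol; it
leaks validation documents into selection, so a `strict` mode
re-selects within each training fold. The default logs a warning.

**RNG discipline.** One master seed; repeat r uses the stream seeded
`seed + r` for its split, so repeats are reproducible independently
and in parallel. The learning-curve subset draw uses a separate stream
seeded `[seed, r, size]` so that requesting the full pool coincides
bit-for-bit with `rrs_cv`.

**Certainty stratification.** Each case's certainty level is the
number of raters (of 6) certain of their own judgment. A case's model
correctness is the fraction of validation appearances predicted
correctly, aggregated over all repeats in which it was held out;
per-level accuracy averages these per-case fractions. This
fraction-correct aggregation was chosen for determinism and because it
weights each case equally regardless of how often the sampler held it
out. Levels 5–6 pool into "certain", 0–4 into "uncertain".

## Synthetic corpus generator

The generator emulates the structure the classifier assumes, with
defaults fixed at the study conditions: 114 cases, 42 positive;
a 7000-term Zipf background vocabulary (exponent 1.1); and per-document
token counts from a truncated normal (mean 40, SD 17.8, min 5) chosen
so that rendered texts — 5-character pseudo-words joined by spaces,
≈ 6 characters per token — have character lengths near mean 241,
SD 107. Twelve severity keywords carry the class signal, each included
independently with probability p_pos in positive and p_neg in negative
documents (defaults span p_pos 0.08–0.35 against p_neg 0.01–0.15,
moderate gaps that keep the classes overlapping the way real triage
calls are). Conditional independence given the class is exactly the
BNB assumption, which is what makes parameter recovery a meaningful
check; a `correlated_pairs` mode deliberately violates it to exercise
the co-occurrence analysis and robustness. The simulated expert list
is the most discriminative 80 % of the keywords (by p_pos − p_neg),
modelling experts who name the strong cues but miss weaker ones.

Certainty votes are Bernoulli draws whose probability rises linearly
with the document's distinct keyword count (base 0.15, slope 0.15),
each vote replaced by a fair coin with probability 0.1; a noiseless
step rule is available for exact tests.

What the generator does **not** model: Mandarin morphology and real
segmentation ambiguity, caller emotion and disfluency, keyword
burstiness, label noise in the on-scene EMT ground truth, and any
dependence of document length on class. Passing tests therefore
demonstrate correctness of the algorithms and protocol, not field
performance on real dispatch audio.

`bayes_optimal_accuracy` computes the generator-implied ceiling: the
Bayes rule over keyword presence patterns (background words carry no
signal), with decision priors defaulting to the corpus prevalence —
what an empirically-primed BNB trained on this corpus converges to —
and expected accuracy weighted 3:7 like the validation folds. Exact
enumeration over the 2ᴷ patterns is used up to K = 20 keywords, a
Monte-Carlo estimate beyond.

## Numerical and degenerate-input choices

- Log-space scoring throughout; `log1p(−p)` for the absent-term branch.
- Degenerate keyword probabilities (0 or 1) are handled in the Bayes
  oracle by elementwise selection of log-ratio terms, avoiding
  0 · ∞ = NaN.
- Correlation of constant indicator columns is reported as NaN
  ("undefined"), never silently zeroed.
- Synonym maps must be single-step (no variant chains); violations are
  rejected at lexicon load because chained maps would make the result
  depend on application order.
- Empty text segments to an empty token list; an empty corpus is
  rejected wherever document frequencies are needed.
- Model serialization stores probabilities as full-precision `repr`
  strings, so a reloaded model reproduces predictions bit-exactly.

## Problem sizes used in tests and the acceptance script

Parameter-recovery and Bayes-convergence experiments use 2000
documents per class with a 500-term background vocabulary and 150
evaluation repeats; the recovery band is a family-wise 95 % binomial
band (Bonferroni over the 24 keyword × class cells) plus the Laplace
shrinkage term, and the accuracy comparison allows 0.03 ≈ three
Monte-Carlo standard errors of the repeat mean plus the finite-corpus
deviation of empirical keyword rates. Structural checks run at the
study size (114/42) with 100 repeats. These sizes make every claim
testable while keeping the default suite fast.

## Known limitations

- The default tokenizer is a whitespace/longest-match stand-in for a
  real Mandarin segmenter; segmentation-dictionary weights are treated
  as presence-only merge forcing, since a weight-sensitive merge policy
  is meaningful only inside a full segmenter.
- `shared_space` evaluation overstates validation performance whenever
  feature selection is informative; use `strict` for honest
  generalisation estimates.
- The five alternative classifiers sometimes compared against this
  method (k-NN, decision tree, SVM, multinomial NB, MLP) are not
  re-implemented; any external predictor can be evaluated under the
  same harness through the `model_builder` contract of `rrs_cv`.
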
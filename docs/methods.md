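# Methods

This note documents the models, numerical conventions and design choices
behind the package, in the spirit of the methods documentation of
statsmodels or scanpy: what is computed, under which assumptions, with
which defaults, and what the synthetic experiments do and do not show.

## Evaluation measures

All evaluation is label-based. For each label `l`, predictions against gold
yield `tp_l`, `fp_l`, `fn_l` (true negatives are implicit and never
needed). Micro-F is the F1 of the label-summed counts; macro-F the
unweighted mean of per-label F1. An F-measure whose denominator is zero — a
label absent from both gold and prediction — is defined as 0, the dominant
convention in multi-label toolkits; the definition is applied consistently
in both the micro and macro aggregates. `micro_f_after_swap` evaluates the
micro-F of a configuration in which exactly one label's counts are
replaced, in O(1) from the aggregate totals; it agrees exactly (not
approximately) with full recomputation and is what makes per-label
candidate search over 10^4 labels tractable.

## The selection procedure

One-pass selection against the all-M1 background is the default and
mirrors the method's four-step scheme: predict with all models on
validation, find per label the models whose substitution improves the
global measure, test each such candidate against M1 with McNemar, switch on
a rejected null. Cyclic refinement — revisiting labels against the current
composite until a cycle changes nothing — is available as an explicit
opt-in (`StrategySpec(cyclic=True)`), since the cycling idea appears in the
lineage of the method rather than in its main scheme. Every accepted change
strictly improves the current validation measure, so the refinement's
metric trace is non-decreasing and the cycle cap guarantees termination.

Decisions and tie-breaks, all deterministic:

* Global best, and any tie among candidates, resolves by input order
  (first model wins); reproducibility is preferred over arbitrary orders.
* Correctness in the McNemar test is the binary decision for the single
  label under test, not the full label set — the only reading consistent
  with per-label selection.
* Among several rejected nulls the winner has the smallest Holm-adjusted
  p, then smallest raw p, then earliest input position.
* The Holm family is the set of candidate comparisons for one label: those
  are the hypotheses decided jointly when that label's model is chosen.
* Labels never seen in the validation gold stay with M1, untested.
* Default `alpha = 0.1`, the published operating point; it is deliberately
  liberal, and the trade-off is visible in the examples (more switches,
  some of which do not survive on test data).

## Statistical core

The chi-square branch uses `|n01 − n10|²/(n01+n10)` with a chi-square(1)
upper tail and requires at least 20 discordant pairs; below that the
binomial approximation is poor and the exact mid-P test is used:
`p = 2·P(X ≤ k) − P(X = k)` with `k = min(n01, n10)` and
`X ~ Binomial(n01+n10, ½)`, clamped to [0, 1]. This is the standard
two-sided mid-P definition (Fagerland et al.); it evaluates to exactly 1 in
the symmetric case. Zero discordant pairs yield p = 1 with an explicit
"no discordance" flag: no disagreement is no evidence for switching, which
matches the method's conservative philosophy. Because extreme statistics
underflow double precision, p-values are floored at the smallest normal
float; the true tail probabilities are strictly positive, and the floor
keeps the `alpha → 0+` limit exact (nothing is ever rejected).

The precision/recall variant uses one-sided two-proportion z-tests with
pooled variance (via statsmodels) at significance `1 − confidence`,
applying the published rule: switch to B iff one of precision/recall is
strictly significantly better and the other not significantly worse. When
a measure's denominator is zero for either model the comparison abstains.
The exact form of the historical test is under-specified; the pooled
one-sided z is a standard reading, and the variant is flagged as the
conservative, essentially historical baseline it is.

## Component models

* **Preprocessing.** Unigrams and bigrams over the concatenated title and
  body after stop-word removal (scikit-learn's English list; stop words are
  removed before bigram formation) and duplicate-document removal. N-grams
  in fewer than 5 documents or more than half the corpus are dropped;
  exactly half stays in. tf-idf uses raw term frequency times smoothed idf
  (`1 + ln((1+N)/(1+df))`), no length normalization; the sub-variant is not
  dictated by the method, so one is fixed and documented. Zoning multiplies
  the weights of title n-grams and of n-grams textually equal to a
  controlled-vocabulary term; the multipliers compose when both apply. The
  printed multipliers "log2" and "log1.25" are self-contradictory with the
  stated intent of *increasing* the weight (ln 2 ≈ 0.69 < 1), so the
  defaults are 2.0 and 1.25 with the literal `ln 2` / `ln 1.25` available
  as presets (`LITERAL_ZONING`).
* **Tuned one-vs-rest SVMs.** Squared-hinge dual linear SVMs
  (scikit-learn's LinearSVC, equivalent to liblinear's L2-regularized
  L2-loss dual solver). Vanilla: C = 1, uniform weights. Tuned: C = 0.33
  and positive-class weight `w_l = 1 + 30/pos_l` for labels with fewer than
  100 positives (the boundary itself gets weight 1); the negative class
  always weighs 1. Labels with no positives (or no negatives) are recorded
  as degenerate and predict the constant class.
* **Meta-Labeler.** First level: the Vanilla SVM bank provides a per-label
  decision score, ranking labels per document. Second level: a linear SVR
  trained on the same feature space predicts the document's label count;
  the emitted set is the top `k = round(count)` labels, rounding half up,
  clamped to [1, L]. The count regressor sees the document feature vector
  only (consistent with "same feature space"), not the first-level scores.

## Synthetic data

The generator reproduces the two statistics that drive the method's
behavior: label frequencies following a Zipf law and a mean label
cardinality of about 13. Marginals are `p_r ∝ r^(−s)` over frequency ranks,
rescaled so `Σ p_r` equals the target cardinality; parameter combinations
whose rescaled top-rank probability exceeds 1 are rejected with guidance
(e.g. exponent 1.0 with 500 labels at cardinality 13 is infeasible — the
defaults use exponent 0.7 at 500 labels, and the large recovery scenarios
exponent 0.9 at 5,000 labels, which yields both ≥500-positive and
<10-positive labels at 20,000 instances). Labels are drawn independently
per instance; real label sets are correlated, but the selection method
never models correlations, so independence suffices for its test surface.
Cardinality is matched in expectation; the approximately Gaussian shape of
the per-document counts emerges from the summed Bernoullis.

Model predictions are derived from gold via per-label sensitivity and
false-positive rates, which gives recovery experiments a known ground
truth. Scenarios plant one globally dominant model and challengers that are
strictly better (sensitivity +0.3 at equal false-positive rate) on
designated labels; in the rare draw where the dominant model is not
empirically best, the scenario reseeds with a logged warning, never
silently. The text-corpus generator gives each label a few signature
tokens; documents concatenate the signature runs of their gold labels
(contiguously, so within-run bigrams are label-correlated rather than
shuffle noise) plus optional background tokens, and titles over-sample
signature terms. Documents with empty label sets are excluded.

What passing synthetic tests shows: the selection machinery switches where
planted truth says it should, stays conservative where evidence is thin,
and its guarantees hold under realistic label-frequency skew. What it does
not show: behavior under label correlations, concept drift, or real text
ambiguity — no synthetic corpus stands in for MEDLINE-scale evaluation.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so the
statistical claims are sharp while a full run stays around a minute: 1,000
random fixtures for metric exactness; 100 random scenarios (200–2,000
instances, 50–500 labels, 2–4 models) for the guarantee and containment
properties; ten 20,000-instance × 5,000-label scenarios for recovery; a
400-document corpus for the Meta-Labeler pipeline. The exhaustive mid-P
check covers every discordant configuration below the chi-square threshold.

## Known limitations

* The validation-set guarantee for micro-F is verified empirically across
  randomized scenarios (improving swaps compose additively in the
  improvement condition); it is not a formal theorem of this package.
* The proportion-test variant is intentionally minimal and conservative;
  it exists to demonstrate why it was abandoned.
* `improve_f_select` optimizes per-label F, which optimizes macro-F but can
  (and in the examples does) hurt micro-F relative to the global best
  model; it carries no guarantee.
* Training one LinearSVC per label is quadratic-ish in practice for dense
  candidate sets; the component module targets desk-scale corpora, not the
  4-million-document regime.
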
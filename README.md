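# mule-ensemble

Per-label model selection for large-scale multi-label classification,
validated by McNemar significance tests.

## The problem

Large-scale semantic indexing — the motivating application is assigning
MeSH descriptors to biomedical abstracts — is an extreme multi-label task:
tens of thousands of labels whose frequencies follow a power law, with a
mean of about 13 labels per document. Different classifiers (one-vs-rest
linear SVMs, ranking-plus-thresholding models, probabilistic topic models)
have complementary strengths across labels, so an attractive ensemble is to
pick, per label, the model that predicts it best on a validation set. The
catch: for the huge majority of rare labels that choice rests on a handful
of validation instances and mostly chases noise.

## The method

Let `M1` be the model with the best *global* measure on validation (micro-F
or macro-F, built from per-label true positives, false positives and false
negatives):

```
F1(l)    = 2·tp_l / (2·tp_l + fp_l + fn_l)
micro-F  = 2·Σ_l tp_l / (2·Σ_l tp_l + Σ_l fp_l + Σ_l fn_l)
macro-F  = (1/L) Σ_l F1(l)
```

Every label defaults to `M1`. A label `l` is reassigned to another model
`M_i` only if both

1. substituting `M_i` for `M1` on `l` alone strictly improves the global
   measure, and
2. a McNemar test on the paired per-instance decisions for `l` rejects the
   null of equal accuracy at level `α` (default 0.1), after Holm step-down
   correction across the candidates compared for that label.

The McNemar statistic is `|n01 − n10|² / (n01 + n10)` over the discordant
counts, referred to chi-square(1); with fewer than 20 discordant pairs the
exact binomial mid-P test `2·P(X ≤ min(n01,n10)) − P(X = min(n01,n10))`,
`X ~ Binomial(n01+n10, ½)`, is used instead. If several candidates pass,
the one with the smallest (adjusted, then raw) p-value wins. The selected
assignment is then applied column-wise to the test-set predictions.

Removing the significance gate gives the "improve micro-F" baseline;
assigning each label to the model with the best per-label F1 gives the
"improve F" baseline; a precision/recall two-proportion z-test variant is
included for study. The package also implements the published component
models (rare-label class weighting `w_l = 1 + 30/pos_l` below 100
positives, the two-level Meta-Labeler, tf-idf preprocessing with title and
MeSH-term zoning) and a synthetic generator reproducing the corpus's
power-law label statistics so everything is testable without the corpus.

## Worked example

`examples/03_ensemble_selection.py` generates a 4,000-document validation
split over 400 power-law labels with one dominant model (M1) and two
challengers that are genuinely better on 30 designated labels, then runs
the three strategies and applies each assignment to a held-out test split:

```
model              val micro-F  test micro-F
M1                     0.70862       0.71264
M2                     0.65314       0.65768
M3                     0.64906       0.64968
MULE (alpha=0.1)       0.74000       0.74149   switched  30 of 400 labels
improve micro-F        0.74362       0.73503   switched  97 of 400 labels
improve F              0.74358       0.73571   switched  92 of 400 labels
```

The no-test baselines look marginally better on validation — they switch
three times as many labels, absorbing validation noise — but the
significance-gated ensemble carries essentially all of its improvement to
the test split and beats both baselines there. That conservativeness is the
method's point. The other examples cover the evaluation measures, the two
McNemar branches with Holm correction, and the Meta-Labeler text pipeline.

A command-line interface wraps the same operations:

```
mule simulate --out-dir scenario --seed 7
mule select --gold scenario/gold.tsv --pred M1=scenario/val_M1.tsv \
     --pred M2=scenario/val_M2.tsv --pred M3=scenario/val_M3.tsv \
     --strategy mule --alpha 0.1 --out assignment.tsv
mule apply --assignment assignment.tsv --gold scenario/test_gold.tsv \
     --pred M1=scenario/test_M1.tsv --pred M2=scenario/test_M2.tsv \
     --pred M3=scenario/test_M3.tsv --out ensemble_test.tsv
mule eval --gold scenario/test_gold.tsv --pred ensemble_test.tsv
```

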
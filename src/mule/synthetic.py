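"""Synthetic multi-label data with the statistical structure of large-scale
biomedical semantic indexing.

The generators emulate the two dominant features of MeSH-style corpora: a
power-law (Zipf) distribution of label frequencies — most labels have very
few positive instances — and a per-document label cardinality of about 13.
Gold assignments draw each label independently per instance from a Zipf
marginal rescaled to the target expected cardinality. Prediction matrices
are derived from gold through per-label sensitivity / false-positive-rate
profiles, which gives the recovery tests a known ground truth: a scenario
builds one globally dominant model plus challengers that are strictly
better on designated labels.

A companion text-corpus generator feeds the component-model pipeline: each
label owns a few signature tokens, documents mix the signature terms of
their gold labels with background noise, and titles over-sample signature
terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .matrices import LabelMatrix, ModelPredictions
from .metrics import confusion_counts, micro_f

__all__ = [
    "GeneratorSpec",
    "ModelProfile",
    "ScenarioResult",
    "label_probabilities",
    "generate_gold",
    "generate_predictions",
    "generate_scenario",
    "generate_text_corpus",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the gold-assignment generator.

    zipf_exponent is the slope of the rank–frequency law;
    target_cardinality is the expected number of labels per instance
    (about 13 in MeSH-indexed abstracts). The Zipf marginals are rescaled so
    the expected cardinality matches; combinations whose rescaled top-rank
    probability would exceed 1 are rejected.
    """

    n_instances: int
    n_labels: int
    zipf_exponent: float = 0.7
    target_cardinality: float = 13.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_labels < 2:
            raise ValueError("n_labels must be >= 2")
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if not 0 < self.target_cardinality < self.n_labels:
            raise ValueError("target_cardinality must lie in (0, n_labels)")


@dataclass(frozen=True)
class ModelProfile:
    """Per-model, per-label error specification for prediction synthesis.

    sensitivity[l] is the probability a gold-positive cell is predicted
    positive; false_positive_rate[l] the probability a gold-negative cell
    is. designated_better_labels marks the labels on which this model is,
    by construction, strictly better than the dominant model.
    """

    model_id: str
    sensitivity: np.ndarray
    false_positive_rate: np.ndarray
    designated_better_labels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        sens = np.asarray(self.sensitivity, dtype=float)
        fpr = np.asarray(self.false_positive_rate, dtype=float)
        object.__setattr__(self, "sensitivity", sens)
        object.__setattr__(self, "false_positive_rate", fpr)
        if sens.shape != fpr.shape:
            raise ValueError("sensitivity and false_positive_rate shapes differ")
        for name, arr in (("sensitivity", sens), ("false_positive_rate", fpr)):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class ScenarioResult:
    """A generated validation/test experiment with known ground truth."""

    gold: LabelMatrix
    predictions: tuple[ModelPredictions, ...]
    truth: dict[int, str]  # designated label -> challenger that is truly better
    profiles: tuple[ModelProfile, ...]
    test_gold: LabelMatrix | None = None
    test_predictions: tuple[ModelPredictions, ...] | None = None


def label_probabilities(spec: GeneratorSpec) -> np.ndarray:
    """Per-label Bernoulli marginals: Zipf over ranks, rescaled so the
    probabilities sum to the target cardinality."""
    ranks = np.arange(1, spec.n_labels + 1, dtype=float)
    weights = ranks ** (-spec.zipf_exponent)
    p = weights * (spec.target_cardinality / weights.sum())
    if p[0] > 1.0:
        raise ValueError(
            f"rescaled top-rank probability {p[0]:.3f} exceeds 1; lower "
            "target_cardinality or zipf_exponent (or add labels)"
        )
    return p


def generate_gold(spec: GeneratorSpec) -> LabelMatrix:
    """Draw a gold assignment: independent Bernoulli per (instance, label)
    with Zipf marginals; reproducible from the spec's seed."""
    p = label_probabilities(spec)
    rng = np.random.default_rng(spec.seed)
    cols_i, cols_l = [], []
    for l in range(spec.n_labels):
        hits = np.nonzero(rng.random(spec.n_instances) < p[l])[0]
        cols_i.append(hits)
        cols_l.append(np.full(hits.size, l, dtype=np.int64))
    rows = np.concatenate(cols_i) if cols_i else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols_l) if cols_l else np.empty(0, dtype=np.int64)
    m = sp.coo_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)),
        shape=(spec.n_instances, spec.n_labels),
    )
    return LabelMatrix(m)


def generate_predictions(
    gold: LabelMatrix, profile: ModelProfile, seed: int
) -> ModelPredictions:
    """Corrupt gold into a model's predictions by the profile's per-label
    sensitivity and false-positive rate, with independent draws."""
    n_instances, n_labels = gold.shape
    if profile.sensitivity.shape[0] != n_labels:
        raise ValueError("profile dimensions do not match gold")
    rng = np.random.default_rng(seed)
    rows, cols = [], []
    for l in range(n_labels):
        pos = gold.column_indices(l)
        keep = pos[rng.random(pos.size) < profile.sensitivity[l]]
        fpr = profile.false_positive_rate[l]
        if fpr > 0:
            neg_mask = np.ones(n_instances, dtype=bool)
            neg_mask[pos] = False
            neg = np.nonzero(neg_mask)[0]
            fire = neg[rng.random(neg.size) < fpr]
        else:
            fire = np.empty(0, dtype=np.int64)
        hits = np.concatenate([keep, fire])
        rows.append(hits)
        cols.append(np.full(hits.size, l, dtype=np.int64))
    r = np.concatenate(rows) if rows else np.empty(0, dtype=np.int64)
    c = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    m = sp.coo_matrix(
        (np.ones(r.size, dtype=np.int8), (r, c)), shape=(n_instances, n_labels)
    )
    return ModelPredictions(model_id=profile.model_id, predictions=LabelMatrix(m))


def _scenario_profiles(
    spec: GeneratorSpec,
    n_models: int,
    n_designated_frequent: int,
    n_designated_rare: int,
    sensitivity_gap: float,
    base_sensitivity: float,
    challenger_sensitivity: float,
    false_positive_rate: float,
    rng: np.random.Generator,
) -> tuple[tuple[ModelProfile, ...], dict[int, str]]:
    L = spec.n_labels
    n_chal = n_models - 1
    # frequent designated labels come from the head ranks, rare ones from the
    # tail; both avoid rank overlap
    freq_pool = np.arange(0, min(L, max(4 * n_designated_frequent, 40)))
    rare_pool = np.arange(max(L - max(4 * n_designated_rare, 40), len(freq_pool)), L)
    freq_sel = rng.choice(freq_pool, size=min(n_designated_frequent, freq_pool.size), replace=False)
    rare_sel = rng.choice(rare_pool, size=min(n_designated_rare, rare_pool.size), replace=False)
    designated = np.concatenate([freq_sel, rare_sel])

    profiles = []
    m1_sens = np.full(L, base_sensitivity)
    m1_fpr = np.full(L, false_positive_rate)
    profiles.append(
        ModelProfile(model_id="M1", sensitivity=m1_sens, false_positive_rate=m1_fpr)
    )
    truth: dict[int, str] = {}
    assigned: dict[int, list[int]] = {i: [] for i in range(1, n_models)}
    for j, l in enumerate(designated):
        assigned[1 + (j % n_chal)].append(int(l))
    for i in range(1, n_models):
        model_id = f"M{i + 1}"
        sens = np.full(L, challenger_sensitivity)
        mine = assigned[i]
        sens[mine] = min(base_sensitivity + sensitivity_gap, 1.0)
        profiles.append(
            ModelProfile(
                model_id=model_id,
                sensitivity=sens,
                false_positive_rate=m1_fpr.copy(),
                designated_better_labels=frozenset(mine),
            )
        )
        for l in mine:
            truth[l] = model_id
    return tuple(profiles), truth


def generate_scenario(
    spec: GeneratorSpec,
    n_models: int = 3,
    n_designated_frequent: int = 20,
    n_designated_rare: int = 20,
    sensitivity_gap: float = 0.3,
    base_sensitivity: float = 0.6,
    challenger_sensitivity: float = 0.5,
    false_positive_rate: float = 0.003,
    seed: int | None = None,
    with_test_split: bool = False,
    test_instances: int | None = None,
    max_reseeds: int = 5,
) -> ScenarioResult:
    """Build a desk-scale selection experiment with known ground truth.

    Model M1 is globally dominant by construction (challengers have lower
    sensitivity everywhere except their designated labels, where they are
    better by ``sensitivity_gap`` at equal false-positive rate). The result
    carries the designated-better map so recovery can be scored. In the rare
    event a sampled dataset leaves M1 not globally best by micro-F, the draw
    is reseeded (logged, never silent).
    """
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    base_seed = spec.seed if seed is None else seed
    for attempt in range(max_reseeds):
        s = base_seed + 1_000_003 * attempt
        rng = np.random.default_rng(s)
        profiles, truth = _scenario_profiles(
            spec,
            n_models,
            n_designated_frequent,
            n_designated_rare,
            sensitivity_gap,
            base_sensitivity,
            challenger_sensitivity,
            false_positive_rate,
            rng,
        )
        gold = generate_gold(
            GeneratorSpec(
                n_instances=spec.n_instances,
                n_labels=spec.n_labels,
                zipf_exponent=spec.zipf_exponent,
                target_cardinality=spec.target_cardinality,
                seed=s,
            )
        )
        preds = tuple(
            generate_predictions(gold, prof, seed=s + 17 * (i + 1))
            for i, prof in enumerate(profiles)
        )
        scores = [micro_f(confusion_counts(p.predictions, gold)) for p in preds]
        if int(np.argmax(scores)) == 0:
            result = ScenarioResult(
                gold=gold, predictions=preds, truth=truth, profiles=profiles
            )
            if with_test_split:
                n_test = test_instances or spec.n_instances // 2
                test_gold = generate_gold(
                    GeneratorSpec(
                        n_instances=n_test,
                        n_labels=spec.n_labels,
                        zipf_exponent=spec.zipf_exponent,
                        target_cardinality=spec.target_cardinality,
                        seed=s + 777,
                    )
                )
                test_preds = tuple(
                    generate_predictions(test_gold, prof, seed=s + 31 * (i + 1))
                    for i, prof in enumerate(profiles)
                )
                result = ScenarioResult(
                    gold=gold,
                    predictions=preds,
                    truth=truth,
                    profiles=profiles,
                    test_gold=test_gold,
                    test_predictions=test_preds,
                )
            return result
        logger.warning(
            "scenario draw with seed %d left %s globally best; reseeding",
            s,
            preds[int(np.argmax(scores))].model_id,
        )
    raise RuntimeError(
        f"could not build a scenario with M1 globally best in {max_reseeds} draws"
    )


# ---------------------------------------------------------------------------
# toy text corpora for the component-model pipeline


def generate_text_corpus(
    spec: GeneratorSpec,
    signature_terms_per_label: int = 4,
    signature_repeats: int = 3,
    background_vocabulary: int = 120,
    noise_tokens_per_doc: int = 0,
    title_terms: int = 4,
    seed: int | None = None,
):
    """Generate documents whose text encodes their gold labels.

    Each label owns ``signature_terms_per_label`` unique tokens; a document's
    body repeats the signature terms of each of its gold labels
    ``signature_repeats`` times plus ``noise_tokens_per_doc`` background
    tokens; the title samples signature terms only. Documents drawing an
    empty label set are excluded by construction. With zero noise a linear
    one-vs-rest learner can reach near-perfect validation micro-F.
    """
    from .components import Document  # local import to avoid a cycle

    s = spec.seed if seed is None else seed
    rng = np.random.default_rng(s)
    gold = generate_gold(
        GeneratorSpec(
            n_instances=spec.n_instances,
            n_labels=spec.n_labels,
            zipf_exponent=spec.zipf_exponent,
            target_cardinality=spec.target_cardinality,
            seed=s,
        )
    )
    signatures = [
        [f"sig{l:03d}t{j}" for j in range(signature_terms_per_label)]
        for l in range(spec.n_labels)
    ]
    background = [f"noise{j:03d}" for j in range(background_vocabulary)]
    journals = ["j-alpha", "j-beta", "j-gamma"]
    docs = []
    csr = gold.tocsc().tocsr()
    for d in range(spec.n_instances):
        labels = csr.indices[csr.indptr[d] : csr.indptr[d + 1]].tolist()
        if not labels:
            continue
        # keep signature runs contiguous: the bigrams inside a label's run
        # are then perfectly label-correlated instead of shuffle noise
        body: list[str] = []
        for l in labels:
            body.extend(signatures[l] * signature_repeats)
        if noise_tokens_per_doc:
            body.extend(rng.choice(background, size=noise_tokens_per_doc).tolist())
        pool = [t for l in labels for t in signatures[l]]
        title = rng.choice(pool, size=min(title_terms, len(pool)), replace=False).tolist()
        docs.append(
            Document(
                doc_id=f"d{d:06d}",
                title_tokens=tuple(title),
                body_tokens=tuple(body),
                journal=journals[int(rng.integers(len(journals)))],
                year=2010 + int(rng.integers(5)),
                gold_labels=frozenset(int(l) for l in labels),
            )
        )
    return docs
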
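"""Per-label model selection strategies for multi-label ensembles.

The central idea: trust the globally best model M1 for every label, and
reassign a label to another component model only when that model both
improves the global evaluation measure (micro-F or macro-F) when substituted
for this one label, and is significantly better than M1 on the label's
per-instance decisions under a McNemar test at level alpha, with Holm
correction across the candidates compared for the label. Because the
decision for a rare label rests on very few validation instances, the
significance gate makes the ensemble far more conservative — and more robust
on unseen data — than picking the per-label winner outright.

Also provided: the no-test "improve metric" baseline (identical machinery,
significance gate removed), the per-label-F baseline (each label goes to
the model with the best per-label F1 on validation), the precision/recall
proportion-test variant, an optional cyclic refinement that re-examines
labels against the current ensemble until a fixed point, and application of
an assignment to held-out predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .matrices import ConfusionCounts, LabelMatrix, ModelPredictions
from .metrics import confusion_counts, f1, macro_f, micro_f, per_label_f1
from .significance import (
    PairedOutcome,
    holm_adjust,
    mcnemar,
    proportion_compare,
)

__all__ = [
    "StrategySpec",
    "CandidateEvidence",
    "EnsembleAssignment",
    "global_best",
    "candidate_models",
    "mule_select",
    "improve_metric_select",
    "improve_f_select",
    "proportion_select",
    "cyclic_refine",
    "apply_assignment",
    "assignment_counts",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("mule", "improve-metric", "improve-f", "proportion")
METRICS = ("micro-f", "macro-f")


@dataclass(frozen=True)
class StrategySpec:
    """Configuration of one ensemble-selection run.

    alpha is the McNemar significance level (the published operating point
    is 0.1); confidence drives the proportion-test variant; cyclic enables
    fixed-point refinement against the evolving ensemble configuration.
    """

    strategy: str = "mule"
    metric: str = "micro-f"
    alpha: float = 0.1
    confidence: float = 0.95
    cyclic: bool = False
    max_cycles: int = 10

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.strategy == "mule" and not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.strategy == "proportion" and not 0.5 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0.5, 1)")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


@dataclass(frozen=True)
class CandidateEvidence:
    """Per-candidate record backing one label's selection decision."""

    model_id: str
    metric_delta: float
    n01: int | None = None
    n10: int | None = None
    p_raw: float | None = None
    p_adjusted: float | None = None
    branch: str | None = None
    rejected: bool | None = None


@dataclass(frozen=True)
class EnsembleAssignment:
    """Map label → selected model, with the evidence behind each switch."""

    model_ids: tuple[str, ...]
    global_best: str
    selected: tuple[str, ...]
    strategy: str
    metric: str
    alpha: float | None = None
    confidence: float | None = None
    evidence: Mapping[int, tuple[CandidateEvidence, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.selected) - set(self.model_ids)
        if unknown:
            raise ValueError(f"selected models {sorted(unknown)} not in the model set")

    @property
    def n_labels(self) -> int:
        return len(self.selected)

    def switched_labels(self) -> list[int]:
        return [l for l, m in enumerate(self.selected) if m != self.global_best]

    def labels_per_model(self) -> dict[str, int]:
        out = {m: 0 for m in self.model_ids}
        for m in self.selected:
            out[m] += 1
        return out


# ---------------------------------------------------------------------------
# shared internals


def _check_inputs(preds: Sequence[ModelPredictions], gold: LabelMatrix) -> None:
    if len(preds) == 0:
        raise ValueError("at least one component model is required")
    ids = [p.model_id for p in preds]
    if len(set(ids)) != len(ids):
        raise ValueError("model_ids must be unique")
    for p in preds:
        p.check_aligned(gold)


def _metric_value(counts: ConfusionCounts, metric: str) -> float:
    return micro_f(counts) if metric == "micro-f" else macro_f(counts)


def _swap_deltas(
    counts: Sequence[ConfusionCounts], base_idx: int, metric: str
) -> np.ndarray:
    """Delta of the global metric when one label is rerouted to each model.

    Returns an (n_models, n_labels) array: entry (i, l) is the change in the
    global metric when label l alone is predicted by model i instead of the
    base model (all other labels staying with the base).
    """
    base = counts[base_idx]
    n_labels = base.n_labels
    deltas = np.zeros((len(counts), n_labels), dtype=float)
    if metric == "micro-f":
        T_tp, T_fp, T_fn = base.totals()
        base_val = f1(T_tp, T_fp, T_fn)
        for i, c in enumerate(counts):
            if i == base_idx:
                continue
            num = 2.0 * (T_tp - base.tp + c.tp)
            den = num + (T_fp - base.fp + c.fp) + (T_fn - base.fn + c.fn)
            vals = np.where(den > 0, num / np.maximum(den, 1), 0.0)
            deltas[i] = vals - base_val
    else:
        f_base = per_label_f1(base)
        for i, c in enumerate(counts):
            if i == base_idx:
                continue
            deltas[i] = (per_label_f1(c) - f_base) / n_labels
    return deltas


def _error_pattern(pred: LabelMatrix, gold: LabelMatrix) -> sp.csc_matrix:
    """Sparse indicator of cells where the prediction disagrees with gold."""
    d = (pred.tocsc() - gold.tocsc()).tocsc()
    if d.nnz:
        d.data = np.abs(d.data)
    return d


def _discordance_vs(
    err_base: sp.csc_matrix, err_other: sp.csc_matrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-label (n01, n10, n11) of (base, other) paired correctness.

    n01: base correct, other wrong; n10: other correct, base wrong;
    n11: both wrong.
    """
    both = np.asarray(err_base.multiply(err_other).sum(axis=0)).ravel().astype(np.int64)
    e_base = np.asarray(err_base.sum(axis=0)).ravel().astype(np.int64)
    e_other = np.asarray(err_other.sum(axis=0)).ravel().astype(np.int64)
    return e_other - both, e_base - both, both


# ---------------------------------------------------------------------------
# public operations


def global_best(
    preds: Sequence[ModelPredictions], gold: LabelMatrix, metric: str = "micro-f"
) -> str:
    """Identify M1: the model maximizing the global metric on validation.

    Ties break by input order (first wins) for reproducibility.
    """
    _check_inputs(preds, gold)
    scores = [_metric_value(confusion_counts(p.predictions, gold), metric) for p in preds]
    return preds[int(np.argmax(scores))].model_id


def candidate_models(
    preds: Sequence[ModelPredictions],
    gold: LabelMatrix,
    metric: str,
    m1: str,
    label: int,
) -> list[tuple[str, float]]:
    """Models whose substitution for one label strictly improves the metric.

    The substitution is evaluated against the all-M1 background; the result
    pairs each qualifying model with its (positive) metric improvement, in
    input order.
    """
    _check_inputs(preds, gold)
    ids = [p.model_id for p in preds]
    if m1 not in ids:
        raise ValueError(f"model {m1!r} not in the model set")
    m1_idx = ids.index(m1)
    counts = [confusion_counts(p.predictions, gold) for p in preds]
    deltas = _swap_deltas(counts, m1_idx, metric)
    return [
        (ids[i], float(deltas[i, label]))
        for i in range(len(preds))
        if i != m1_idx and deltas[i, label] > 0.0
    ]


def _select_against_m1(
    preds: Sequence[ModelPredictions],
    gold: LabelMatrix,
    spec: StrategySpec,
    use_test: bool,
) -> EnsembleAssignment:
    """Shared one-pass selection core for mule and improve-metric."""
    _check_inputs(preds, gold)
    ids = tuple(p.model_id for p in preds)
    counts = [confusion_counts(p.predictions, gold) for p in preds]
    scores = [_metric_value(c, spec.metric) for c in counts]
    m1_idx = int(np.argmax(scores))
    m1 = ids[m1_idx]
    n_labels = gold.n_labels
    deltas = _swap_deltas(counts, m1_idx, spec.metric)
    gold_freq = gold.label_counts()

    discord: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    if use_test:
        errs = [_error_pattern(p.predictions, gold) for p in preds]
        for i in range(len(preds)):
            if i != m1_idx:
                discord[i] = _discordance_vs(errs[m1_idx], errs[i])

    selected = [m1] * n_labels
    evidence: dict[int, tuple[CandidateEvidence, ...]] = {}
    n_instances = gold.n_instances
    for l in range(n_labels):
        if gold_freq[l] == 0:
            # labels never seen in the validation gold stay with M1, untested
            continue
        cand_idx = [
            i for i in range(len(preds)) if i != m1_idx and deltas[i, l] > 0.0
        ]
        if not cand_idx:
            continue
        if not use_test:
            best = max(cand_idx, key=lambda i: (deltas[i, l], -i))
            selected[l] = ids[best]
            evidence[l] = tuple(
                CandidateEvidence(model_id=ids[i], metric_delta=float(deltas[i, l]))
                for i in cand_idx
            )
            continue
        records = []
        raw_ps = []
        for i in cand_idx:
            n01 = int(discord[i][0][l])
            n10 = int(discord[i][1][l])
            n11 = int(discord[i][2][l])
            outcome = PairedOutcome(
                n00=n_instances - n01 - n10 - n11, n01=n01, n10=n10, n11=n11
            )
            res = mcnemar(outcome)
            raw_ps.append(res.p_value)
            records.append((i, n01, n10, res))
        adj = holm_adjust(raw_ps)
        ev = []
        winner = None
        winner_key = None
        for (i, n01, n10, res), p_adj, p_raw in zip(records, adj, raw_ps):
            rejected = p_adj <= spec.alpha
            ev.append(
                CandidateEvidence(
                    model_id=ids[i],
                    metric_delta=float(deltas[i, l]),
                    n01=n01,
                    n10=n10,
                    p_raw=float(p_raw),
                    p_adjusted=float(p_adj),
                    branch=res.branch,
                    rejected=rejected,
                )
            )
            if rejected:
                key = (p_adj, p_raw, i)
                if winner_key is None or key < winner_key:
                    winner_key = key
                    winner = i
        if winner is not None:
            selected[l] = ids[winner]
        evidence[l] = tuple(ev)

    return EnsembleAssignment(
        model_ids=ids,
        global_best=m1,
        selected=tuple(selected),
        strategy=spec.strategy,
        metric=spec.metric,
        alpha=spec.alpha if use_test else None,
        evidence=evidence,
    )


def mule_select(
    preds: Sequence[ModelPredictions], gold: LabelMatrix, spec: StrategySpec
) -> EnsembleAssignment:
    """One-pass MULE selection on a validation split.

    Per label: default to M1; among the models whose substitution improves
    the global metric, run McNemar (chi-square or exact mid-P, routed on the
    discordant count) on per-label paired correctness against M1,
    Holm-adjust within the label, and switch to the candidate with a
    rejected null at level alpha — if several, the one with the lowest
    (adjusted, then raw) p-value. Deterministic given inputs.
    """
    if spec.strategy != "mule":
        raise ValueError("mule_select requires spec.strategy == 'mule'")
    out = _select_against_m1(preds, gold, spec, use_test=True)
    if spec.cyclic:
        out = cyclic_refine(out, preds, gold, spec)
    return out


def improve_metric_select(
    preds: Sequence[ModelPredictions], gold: LabelMatrix, spec: StrategySpec
) -> EnsembleAssignment:
    """No-test baseline: per label, the candidate with the largest positive
    metric delta; M1 when none improves. Equivalent to MULE with the
    significance gate removed."""
    if spec.strategy != "improve-metric":
        raise ValueError("improve_metric_select requires spec.strategy == 'improve-metric'")
    out = _select_against_m1(preds, gold, spec, use_test=False)
    if spec.cyclic:
        out = cyclic_refine(out, preds, gold, spec)
    return out


def improve_f_select(
    preds: Sequence[ModelPredictions], gold: LabelMatrix, metric: str = "micro-f"
) -> EnsembleAssignment:
    """Per-label-F baseline: each label goes to the model with the highest
    per-label F1 on validation; ties retain M1 when M1 is among the tied,
    else the first model in input order."""
    _check_inputs(preds, gold)
    ids = tuple(p.model_id for p in preds)
    counts = [confusion_counts(p.predictions, gold) for p in preds]
    scores = [_metric_value(c, metric) for c in counts]
    m1_idx = int(np.argmax(scores))
    per_label = np.vstack([per_label_f1(c) for c in counts])  # models × labels
    selected = []
    evidence: dict[int, tuple[CandidateEvidence, ...]] = {}
    for l in range(gold.n_labels):
        col = per_label[:, l]
        best_val = col.max()
        if col[m1_idx] == best_val:
            winner = m1_idx
        else:
            winner = int(np.argmax(col))
        selected.append(ids[winner])
        if winner != m1_idx:
            evidence[l] = (
                CandidateEvidence(
                    model_id=ids[winner],
                    metric_delta=float(best_val - col[m1_idx]),
                ),
            )
    return EnsembleAssignment(
        model_ids=ids,
        global_best=ids[m1_idx],
        selected=tuple(selected),
        strategy="improve-f",
        metric=metric,
        evidence=evidence,
    )


def proportion_select(
    preds: Sequence[ModelPredictions], gold: LabelMatrix, spec: StrategySpec
) -> EnsembleAssignment:
    """Precision/recall proportion-test variant.

    Keep M1 for a label unless some model B is significantly better on one
    of precision/recall and not significantly worse on the other (one-sided
    two-proportion z-tests at 1 − confidence); the first qualifying model in
    input order wins. Historically too conservative, retained for study.
    """
    if spec.strategy != "proportion":
        raise ValueError("proportion_select requires spec.strategy == 'proportion'")
    _check_inputs(preds, gold)
    ids = tuple(p.model_id for p in preds)
    counts = [confusion_counts(p.predictions, gold) for p in preds]
    scores = [_metric_value(c, spec.metric) for c in counts]
    m1_idx = int(np.argmax(scores))
    selected = []
    evidence: dict[int, tuple[CandidateEvidence, ...]] = {}
    for l in range(gold.n_labels):
        a = counts[m1_idx].label(l)
        winner = m1_idx
        ev = []
        for i in range(len(preds)):
            if i == m1_idx:
                continue
            cmp = proportion_compare(a, counts[i].label(l), spec.confidence)
            ev.append(
                CandidateEvidence(
                    model_id=ids[i],
                    metric_delta=0.0,
                    branch=f"precision:{cmp.precision};recall:{cmp.recall}",
                    rejected=cmp.switch,
                )
            )
            if cmp.switch:
                winner = i
                break
        selected.append(ids[winner])
        if ev:
            evidence[l] = tuple(ev)
    return EnsembleAssignment(
        model_ids=ids,
        global_best=ids[m1_idx],
        selected=tuple(selected),
        strategy="proportion",
        metric=spec.metric,
        confidence=spec.confidence,
        evidence=evidence,
    )


def cyclic_refine(
    assignment: EnsembleAssignment,
    preds: Sequence[ModelPredictions],
    gold: LabelMatrix,
    spec: StrategySpec,
) -> EnsembleAssignment:
    """Fixed-point refinement against the evolving ensemble configuration.

    Labels are revisited cyclically; each label's selection is re-decided
    against the *current* composite (not the all-M1 background) with the
    strategy's own rule, until a full cycle changes nothing or max_cycles is
    reached. Every accepted change strictly improves the validation metric,
    so the metric trace over cycles is non-decreasing and termination is
    guaranteed by the cycle cap.
    """
    _check_inputs(preds, gold)
    ids = tuple(p.model_id for p in preds)
    idx_of = {m: i for i, m in enumerate(ids)}
    counts = [confusion_counts(p.predictions, gold) for p in preds]
    n_labels = gold.n_labels
    n_instances = gold.n_instances
    use_test = spec.strategy == "mule"
    errs = [_error_pattern(p.predictions, gold) for p in preds] if use_test else None

    sel = np.array([idx_of[m] for m in assignment.selected], dtype=np.int64)
    # current aggregate (micro) or per-label f1 (macro) of the composite
    cur_tp = np.array([counts[sel[l]].tp[l] for l in range(n_labels)], dtype=np.int64)
    cur_fp = np.array([counts[sel[l]].fp[l] for l in range(n_labels)], dtype=np.int64)
    cur_fn = np.array([counts[sel[l]].fn[l] for l in range(n_labels)], dtype=np.int64)

    for _cycle in range(spec.max_cycles):
        changed = False
        for l in range(n_labels):
            cur = int(sel[l])
            if spec.metric == "micro-f":
                T = (int(cur_tp.sum()), int(cur_fp.sum()), int(cur_fn.sum()))
                base_val = f1(*T)
                old = (int(cur_tp[l]), int(cur_fp[l]), int(cur_fn[l]))
                deltas = {}
                for i in range(len(preds)):
                    if i == cur:
                        continue
                    new = counts[i].label(l)
                    val = f1(T[0] - old[0] + new[0], T[1] - old[1] + new[1], T[2] - old[2] + new[2])
                    deltas[i] = val - base_val
            else:
                base_f = f1(*(int(cur_tp[l]), int(cur_fp[l]), int(cur_fn[l])))
                deltas = {
                    i: (f1(*counts[i].label(l)) - base_f) / n_labels
                    for i in range(len(preds))
                    if i != cur
                }
            cand = [i for i, d in deltas.items() if d > 0.0]
            if not cand:
                continue
            if use_test:
                records, raw_ps = [], []
                for i in cand:
                    n01, n10, n11 = _pair_counts_label(errs[cur], errs[i], l)
                    res = mcnemar(
                        PairedOutcome(
                            n00=n_instances - n01 - n10 - n11, n01=n01, n10=n10, n11=n11
                        )
                    )
                    raw_ps.append(res.p_value)
                    records.append(i)
                adj = holm_adjust(raw_ps)
                winner, winner_key = None, None
                for i, p_adj, p_raw in zip(records, adj, raw_ps):
                    if p_adj <= spec.alpha:
                        key = (p_adj, p_raw, i)
                        if winner_key is None or key < winner_key:
                            winner_key, winner = key, i
                if winner is None:
                    continue
            else:
                winner = max(cand, key=lambda i: (deltas[i], -i))
            sel[l] = winner
            cur_tp[l], cur_fp[l], cur_fn[l] = counts[winner].label(l)
            changed = True
        if not changed:
            break

    return EnsembleAssignment(
        model_ids=ids,
        global_best=assignment.global_best,
        selected=tuple(ids[i] for i in sel),
        strategy=assignment.strategy,
        metric=spec.metric,
        alpha=assignment.alpha,
        confidence=assignment.confidence,
        evidence={},
    )


def _pair_counts_label(
    err_a: sp.csc_matrix, err_b: sp.csc_matrix, label: int
) -> tuple[int, int, int]:
    ia = err_a.indices[err_a.indptr[label] : err_a.indptr[label + 1]]
    ib = err_b.indices[err_b.indptr[label] : err_b.indptr[label + 1]]
    both = np.intersect1d(ia, ib, assume_unique=True).size
    return int(ib.size - both), int(ia.size - both), int(both)


def apply_assignment(
    assignment: EnsembleAssignment, preds: Sequence[ModelPredictions]
) -> LabelMatrix:
    """Compose the ensemble's prediction matrix on a new split.

    Each label's column is taken from the model the assignment selected for
    it; every referenced model must be present among ``preds``.
    """
    by_id = {p.model_id: p for p in preds}
    missing = [m for m in set(assignment.selected) if m not in by_id]
    if missing:
        raise KeyError(f"no test predictions for model(s): {sorted(missing)}")
    shapes = {p.predictions.shape for p in preds}
    if len(shapes) != 1:
        raise ValueError("test prediction matrices disagree in shape")
    (n_instances, n_labels) = shapes.pop()
    if n_labels != assignment.n_labels:
        raise ValueError(
            f"assignment covers {assignment.n_labels} labels, "
            f"test predictions have {n_labels}"
        )
    sel = np.array(
        [assignment.model_ids.index(m) for m in assignment.selected], dtype=np.int64
    )
    mats = {assignment.model_ids.index(p.model_id): p.predictions.tocsc() for p in preds
            if p.model_id in set(assignment.selected)}
    blocks, order = [], []
    for i, mat in mats.items():
        cols = np.where(sel == i)[0]
        if cols.size:
            blocks.append(mat[:, cols])
            order.append(cols)
    if not blocks:
        return LabelMatrix(sp.csc_matrix((n_instances, n_labels), dtype=np.int8))
    stacked = sp.hstack(blocks, format="csc")
    perm = np.concatenate(order)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    return LabelMatrix(stacked[:, inv])


def assignment_counts(
    assignment: EnsembleAssignment,
    preds: Sequence[ModelPredictions],
    gold: LabelMatrix,
) -> ConfusionCounts:
    """Confusion counts of the composite assignment against gold."""
    composite = apply_assignment(assignment, preds)
    return confusion_counts(composite, gold)
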
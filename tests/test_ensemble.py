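import numpy as np
import pytest

from mule import (
    LabelMatrix,
    ModelPredictions,
    StrategySpec,
    apply_assignment,
    assignment_counts,
    candidate_models,
    confusion_counts,
    cyclic_refine,
    f1,
    global_best,
    improve_f_select,
    improve_metric_select,
    macro_f,
    micro_f,
    mule_select,
    proportion_select,
)
from mule.synthetic import GeneratorSpec, generate_scenario

from conftest import random_label_matrix, random_models


def brute_force_substitution(preds, gold, m1_id, label, metric="micro-f"):
    """Full-recompute oracle: metric change of rerouting one label."""
    by_id = {p.model_id: p for p in preds}
    base = by_id[m1_id].predictions
    fn = micro_f if metric == "micro-f" else macro_f
    base_val = fn(confusion_counts(base, gold))
    out = []
    for p in preds:
        if p.model_id == m1_id:
            continue
        merged = base.with_columns_from(p.predictions, [label])
        delta = fn(confusion_counts(merged, gold)) - base_val
        if delta > 0:
            out.append((p.model_id, delta))
    return out


class TestGlobalBest:
    def test_singleton(self, rng):
        gold = random_label_matrix(rng, 30, 5)
        preds = random_models(rng, gold, 1)
        assert global_best(preds, gold) == "R0"

    def test_perfect_model_wins(self, rng):
        gold = random_label_matrix(rng, 60, 8)
        preds = random_models(rng, gold, 2, flip=0.2)
        preds.insert(1, ModelPredictions("exact", gold))
        assert global_best(preds, gold) == "exact"

    @pytest.mark.parametrize("metric", ["micro-f", "macro-f"])
    def test_argmax_oracle(self, rng, metric):
        gold = random_label_matrix(rng, 200, 30)
        preds = random_models(rng, gold, 3, flip=0.1)
        fn = micro_f if metric == "micro-f" else macro_f
        scores = [fn(confusion_counts(p.predictions, gold)) for p in preds]
        assert global_best(preds, gold, metric) == preds[int(np.argmax(scores))].model_id

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            global_best([], random_label_matrix(rng, 5, 3))


class TestCandidateModels:
    def test_identical_models_yield_none(self, rng):
        gold = random_label_matrix(rng, 40, 6)
        m = random_label_matrix(rng, 40, 6)
        preds = [ModelPredictions("A", m), ModelPredictions("B", m)]
        assert candidate_models(preds, gold, "micro-f", "A", 2) == []

    def test_exact_model_listed_with_positive_delta(self, rng):
        gold = random_label_matrix(rng, 60, 5, density=0.3)
        noisy = random_models(rng, gold, 1, flip=0.25)[0]
        preds = [ModelPredictions("m1", noisy.predictions), ModelPredictions("oracle", gold)]
        cands = candidate_models(preds, gold, "micro-f", "m1", 0)
        assert cands and cands[0][0] == "oracle" and cands[0][1] > 0

    @pytest.mark.parametrize("metric", ["micro-f", "macro-f"])
    def test_matches_full_recompute(self, rng, metric):
        gold = random_label_matrix(rng, 80, 12)
        preds = random_models(rng, gold, 3, flip=0.12)
        m1 = global_best(preds, gold, metric)
        for label in range(12):
            got = candidate_models(preds, gold, metric, m1, label)
            expect = brute_force_substitution(preds, gold, m1, label, metric)
            assert [m for m, _ in got] == [m for m, _ in expect]
            assert [d for _, d in got] == pytest.approx([d for _, d in expect], abs=1e-12)

    def test_unknown_m1_rejected(self, rng):
        gold = random_label_matrix(rng, 10, 3)
        with pytest.raises(ValueError):
            candidate_models(random_models(rng, gold, 2), gold, "micro-f", "nope", 0)


class TestMuleSelect:
    def test_vanishing_alpha_keeps_m1_everywhere(self, small_scenario):
        a = mule_select(
            small_scenario.predictions,
            small_scenario.gold,
            StrategySpec(alpha=5e-324),
        )
        assert a.switched_labels() == []

    def test_identical_models_keep_m1(self, rng):
        gold = random_label_matrix(rng, 50, 8)
        m = random_label_matrix(rng, 50, 8)
        preds = [ModelPredictions("A", m), ModelPredictions("B", m)]
        a = mule_select(preds, gold, StrategySpec())
        assert a.switched_labels() == []
        assert a.global_best == "A"

    def test_constructed_overwhelming_challenger_is_selected(self):
        # M1 errs on 200 instances of label 0; B matches gold there,
        # so n10 = 200, n01 = 0 and the null is rejected far below 0.1
        n = 400
        gold = np.zeros((n, 3), dtype=int)
        gold[:200, 0] = 1
        gold[:, 1] = 1  # keep M1 globally best via label 1
        m1 = gold.copy()
        m1[:200, 0] = 0
        b = gold.copy()
        b[:, 1] = 0
        preds = [
            ModelPredictions("M1", LabelMatrix.from_dense(m1)),
            ModelPredictions("B", LabelMatrix.from_dense(b)),
        ]
        a = mule_select(preds, LabelMatrix.from_dense(gold), StrategySpec(alpha=0.1))
        assert a.global_best == "M1"
        assert a.selected[0] == "B"
        ev = a.evidence[0][0]
        assert ev.n10 == 200 and ev.n01 == 0 and ev.p_adjusted < 1e-10

    def test_switch_evidence_is_significant_and_improving(self, small_scenario):
        a = mule_select(small_scenario.predictions, small_scenario.gold, StrategySpec())
        for l in a.switched_labels():
            ev = [e for e in a.evidence[l] if e.model_id == a.selected[l]]
            assert len(ev) == 1
            assert ev[0].rejected and ev[0].p_adjusted <= 0.1 and ev[0].metric_delta > 0

    def test_alpha_monotonicity(self, small_scenario):
        sets = []
        for alpha in (0.01, 0.05, 0.1, 0.5):
            a = mule_select(
                small_scenario.predictions, small_scenario.gold, StrategySpec(alpha=alpha)
            )
            sets.append(set(a.switched_labels()))
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_determinism(self, small_scenario):
        spec = StrategySpec()
        a = mule_select(small_scenario.predictions, small_scenario.gold, spec)
        b = mule_select(small_scenario.predictions, small_scenario.gold, spec)
        assert a == b

    def test_invalid_alpha_rejected(self, rng):
        with pytest.raises(ValueError):
            StrategySpec(alpha=0.0)
        with pytest.raises(ValueError):
            StrategySpec(alpha=1.5)


class TestImproveMetric:
    def test_switch_set_contains_mule(self, small_scenario):
        mule = mule_select(small_scenario.predictions, small_scenario.gold, StrategySpec())
        imp = improve_metric_select(
            small_scenario.predictions,
            small_scenario.gold,
            StrategySpec(strategy="improve-metric"),
        )
        assert set(mule.switched_labels()) <= set(imp.switched_labels())

    def test_no_improvement_keeps_m1(self, rng):
        gold = random_label_matrix(rng, 40, 6)
        worse = random_models(rng, gold, 1, flip=0.3)[0]
        preds = [ModelPredictions("exact", gold), ModelPredictions("noisy", worse.predictions)]
        a = improve_metric_select(preds, gold, StrategySpec(strategy="improve-metric"))
        assert a.switched_labels() == []

    def test_alpha_one_matches_switch_set(self, small_scenario):
        # with alpha = 1 every candidate's null is "rejected" (p <= 1), so
        # MULE switches exactly the labels improve-metric switches
        two = list(small_scenario.predictions[:2])
        mule = mule_select(two, small_scenario.gold, StrategySpec(alpha=1.0))
        imp = improve_metric_select(
            two, small_scenario.gold, StrategySpec(strategy="improve-metric")
        )
        assert mule.selected == imp.selected


class TestImproveF:
    def test_equals_exhaustive_per_label_argmax(self, rng):
        gold = random_label_matrix(rng, 120, 15)
        preds = random_models(rng, gold, 3, flip=0.15)
        a = improve_f_select(preds, gold)
        m1 = global_best(preds, gold)
        counts = [confusion_counts(p.predictions, gold) for p in preds]
        for l in range(15):
            scores = [f1(*c.label(l)) for c in counts]
            best = max(scores)
            winner = a.selected[l]
            ids = [p.model_id for p in preds]
            assert scores[ids.index(winner)] == pytest.approx(best, abs=1e-15)
            if scores[ids.index(m1)] == best:
                assert winner == m1

    def test_label_absent_everywhere_stays_m1(self, rng):
        gold = np.zeros((30, 4), dtype=int)
        gold[:, :3] = (rng.random((30, 3)) < 0.4).astype(int)
        g = LabelMatrix.from_dense(gold)
        preds = random_models(rng, g, 2, flip=0.1)
        # strip label 3 from every prediction too
        stripped = []
        for p in preds:
            d = p.predictions.toarray().copy()
            d[:, 3] = 0
            stripped.append(ModelPredictions(p.model_id, LabelMatrix.from_dense(d)))
        a = improve_f_select(stripped, g)
        assert a.selected[3] == a.global_best

    def test_single_model(self, rng):
        gold = random_label_matrix(rng, 20, 5)
        preds = random_models(rng, gold, 1)
        a = improve_f_select(preds, gold)
        assert set(a.selected) == {"R0"}


class TestProportionSelect:
    def test_identical_models_keep_m1(self, rng):
        gold = random_label_matrix(rng, 50, 6)
        m = random_label_matrix(rng, 50, 6)
        preds = [ModelPredictions("A", m), ModelPredictions("B", m)]
        a = proportion_select(preds, gold, StrategySpec(strategy="proportion"))
        assert a.switched_labels() == []

    def test_tiny_validation_set_keeps_m1(self, rng):
        gold = random_label_matrix(rng, 10, 5, density=0.4)
        preds = random_models(rng, gold, 3, flip=0.2)
        a = proportion_select(preds, gold, StrategySpec(strategy="proportion", confidence=0.95))
        assert a.switched_labels() == []

    def test_overwhelming_advantage_switches(self, rng):
        # label 0 frequent; M1 misses half its positives, B is exact on it
        n = 600
        gold = np.zeros((n, 3), dtype=int)
        gold[:400, 0] = 1
        gold[:, 1] = 1
        m1 = gold.copy()
        m1[:200, 0] = 0
        b = gold.copy()
        b[:, 1] = 0
        preds = [
            ModelPredictions("M1", LabelMatrix.from_dense(m1)),
            ModelPredictions("B", LabelMatrix.from_dense(b)),
        ]
        a = proportion_select(
            preds, LabelMatrix.from_dense(gold), StrategySpec(strategy="proportion")
        )
        assert a.global_best == "M1"
        assert a.selected[0] == "B"


class TestCyclic:
    def test_fixed_point_unchanged(self, small_scenario):
        spec = StrategySpec(cyclic=True, max_cycles=5)
        a = mule_select(small_scenario.predictions, small_scenario.gold, StrategySpec())
        refined = cyclic_refine(a, small_scenario.predictions, small_scenario.gold, spec)
        again = cyclic_refine(refined, small_scenario.predictions, small_scenario.gold, spec)
        assert refined.selected == again.selected

    def test_metric_never_decreases(self, small_scenario):
        preds, gold = small_scenario.predictions, small_scenario.gold
        base = mule_select(preds, gold, StrategySpec())
        val = micro_f(assignment_counts(base, preds, gold))
        prev = val
        for cycles in (1, 2, 4):
            refined = cyclic_refine(
                base, preds, gold, StrategySpec(cyclic=True, max_cycles=cycles)
            )
            cur = micro_f(assignment_counts(refined, preds, gold))
            assert cur >= prev - 1e-12
            prev = cur

    def test_beats_best_single_model(self, small_scenario):
        preds, gold = small_scenario.predictions, small_scenario.gold
        refined = mule_select(preds, gold, StrategySpec(cyclic=True, max_cycles=5))
        best_single = max(micro_f(confusion_counts(p.predictions, gold)) for p in preds)
        assert micro_f(assignment_counts(refined, preds, gold)) >= best_single - 1e-12


class TestApply:
    def test_all_m1_is_identity(self, small_scenario):
        preds, gold = small_scenario.predictions, small_scenario.gold
        a = mule_select(preds, gold, StrategySpec(alpha=5e-324))
        assert apply_assignment(a, preds) == preds[0].predictions

    def test_checkerboard_columns(self, rng):
        gold = random_label_matrix(rng, 30, 8)
        preds = random_models(rng, gold, 2)
        a = improve_f_select(preds, gold)
        forced = a.__class__(
            model_ids=a.model_ids,
            global_best=a.global_best,
            selected=tuple("R0" if l % 2 == 0 else "R1" for l in range(8)),
            strategy=a.strategy,
            metric=a.metric,
        )
        composite = apply_assignment(forced, preds)
        for l in range(8):
            src = preds[l % 2].predictions
            assert np.array_equal(composite.column(l), src.column(l))

    def test_empty_test_set(self, rng):
        gold = random_label_matrix(rng, 20, 4)
        preds = random_models(rng, gold, 2)
        a = improve_f_select(preds, gold)
        empty = [
            ModelPredictions(p.model_id, LabelMatrix.from_dense(np.zeros((0, 4))))
            for p in preds
        ]
        out = apply_assignment(a, empty)
        assert out.shape == (0, 4)

    def test_missing_model_named(self, rng):
        gold = random_label_matrix(rng, 30, 6)
        preds = random_models(rng, gold, 2, flip=0.3)
        preds.append(ModelPredictions("oracle", gold))
        a = improve_f_select(preds, gold)
        assert "oracle" in set(a.selected)
        with pytest.raises(KeyError, match="oracle"):
            apply_assignment(a, preds[:2])


class TestValidationGuarantee:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("metric", ["micro-f", "macro-f"])
    def test_selection_never_below_best_single(self, seed, metric):
        spec = GeneratorSpec(
            n_instances=800, n_labels=80, zipf_exponent=0.5,
            target_cardinality=13.0, seed=seed,
        )
        sc = generate_scenario(spec, n_models=3, seed=seed)
        fn = micro_f if metric == "micro-f" else macro_f
        best = max(fn(confusion_counts(p.predictions, sc.gold)) for p in sc.predictions)
        for strat, select in (
            ("mule", mule_select),
            ("improve-metric", improve_metric_select),
        ):
            a = select(sc.predictions, sc.gold, StrategySpec(strategy=strat, metric=metric))
            assert fn(assignment_counts(a, sc.predictions, sc.gold)) >= best - 1e-12
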
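"""Decision-tree scoring, ranking, normalization and sensitivity."""

import itertools
import warnings

import numpy as np
import pytest

import zooprior as zp
from zooprior import scoring
from zooprior.ahp import CriterionWeights
from zooprior.config_io import (
    AnswerScale,
    AnswerTable,
    Criterion,
    PrioritizationConfig,
    Question,
)
from zooprior.errors import ValidationError


def make_config(scales, diseases=("d1",)):
    """Config with criteria q0..q{n-1} carrying the given scales."""
    crits = tuple(Criterion(f"q{i}", f"Q{i}") for i in range(len(scales)))
    qs = tuple(
        Question(c.id, f"{c.id}?", s) for c, s in zip(crits, scales)
    )
    return PrioritizationConfig(crits, qs, diseases)


def seq_weights(ids):
    n = len(ids)
    return CriterionWeights(
        ranking=tuple(ids),
        priorities={c: (n - i) / (n * (n + 1) / 2) for i, c in enumerate(ids)},
        weights={c: float(n - i) for i, c in enumerate(ids)},
    )


YN = AnswerScale("binomial", ("no", "yes"), "yes")
COLLAB = AnswerScale("multinomial", ("neither", "at least one", "both"))
QUART = AnswerScale("multinomial", ("<10%", "10-50%", ">50-75%", ">75%"))


class TestAnswerScore:
    def test_binomial_full_score_answer_scores_one(self):
        q = Question("severity", "cfr>10%?", YN)
        assert zp.answer_score(q, "yes").raw_score == 1.0
        assert zp.answer_score(q, "no").raw_score == 0.0

    def test_multinomial_highest_category_scores_one(self):
        q = Question("collaborate", "labs?", COLLAB)
        sc = zp.answer_score(q, "both")
        assert sc.raw_score == pytest.approx(3 / 3)
        assert (sc.ordinal_position, sc.n_categories) == (3, 3)

    def test_multinomial_position_over_categories(self):
        q = Question("econ", "cfr?", QUART)
        assert zp.answer_score(q, "10-50%").raw_score == pytest.approx(2 / 4)

    def test_unknown_label_rejected(self):
        q = Question("collaborate", "labs?", COLLAB)
        with pytest.raises(ValidationError, match="'maybe'"):
            zp.answer_score(q, "maybe")


class TestWeightedQuestionScore:
    @pytest.mark.parametrize(
        "question,label,weight,expected",
        [
            (Question("c", "labs?", COLLAB), "both", 2, 2.0),
            (Question("s", "cfr?", YN), "yes", 5, 5.0),
            (Question("e", "cfr?", QUART), "10-50%", 3, 1.5),
            (Question("c", "labs?", COLLAB), "at least one", 2, 2 * 2 / 3),
        ],
    )
    def test_weight_times_raw_score(self, question, label, weight, expected):
        sc = zp.answer_score(question, label)
        assert zp.weighted_question_score(sc, weight) == pytest.approx(expected)

    def test_negative_weight_rejected(self):
        sc = zp.answer_score(Question("s", "?", YN), "yes")
        with pytest.raises(ValidationError):
            zp.weighted_question_score(sc, -1)


class TestScoreDisease:
    def test_worked_example_rabies_scores_eight(
        self, country_x, country_x_weights
    ):
        config, _, answers = country_x
        trace = zp.score_disease("Rabies", answers, country_x_weights, config)
        assert trace.total == 8.0
        contributions = [e.weighted_score for e in trace.entries]
        assert contributions == [5.0, 0.0, 0.0, 2.0, 1.0]

    def test_trace_visits_criteria_in_descending_weight_order(
        self, country_x, country_x_weights
    ):
        config, _, answers = country_x
        trace = zp.score_disease("Rabies", answers, country_x_weights, config)
        ws = [e.weight for e in trace.entries]
        assert ws == sorted(ws, reverse=True)
        assert trace.entries[0].criterion_id == "severity"

    def test_all_lowest_binomial_answers_score_zero(self):
        config = make_config([YN] * 5)
        answers = AnswerTable({"d1": {f"q{i}": "no" for i in range(5)}})
        trace = zp.score_disease(
            "d1", answers, seq_weights(config.criterion_ids), config
        )
        assert trace.total == 0.0

    def test_all_highest_answers_reach_sum_of_weights(self):
        config = make_config([YN, COLLAB, YN, QUART, YN])
        top = {"q0": "yes", "q1": "both", "q2": "yes", "q3": ">75%", "q4": "yes"}
        trace = zp.score_disease(
            "d1", AnswerTable({"d1": top}),
            seq_weights(config.criterion_ids), config,
        )
        assert trace.total == pytest.approx(15.0)

    def test_missing_answer_names_disease_and_question(self):
        config = make_config([YN, YN])
        answers = AnswerTable({"d1": {"q0": "yes"}})
        with pytest.raises(ValidationError, match="'d1'.*'q1'"):
            zp.score_disease(
                "d1", answers, seq_weights(config.criterion_ids), config
            )


def traces_from_totals(totals, names=None):
    names = names or [f"d{i}" for i in range(len(totals))]
    return [
        scoring.ScoreTrace(disease=n, entries=(), total=float(t))
        for n, t in zip(names, totals)
    ]


class TestRankDiseases:
    def test_normalization_against_maximum(self):
        ranked = zp.rank_diseases(traces_from_totals([8, 4, 2]))
        assert [e.normalized for e in ranked.entries] == [1.0, 0.5, 0.25]
        assert ranked.t_max == 8

    def test_single_disease_ranks_first_with_unit_score(self):
        ranked = zp.rank_diseases(traces_from_totals([3.5]))
        assert ranked.entries[0].rank == 1
        assert ranked.entries[0].normalized == 1.0

    def test_competition_ranking_on_ties(self):
        ranked = zp.rank_diseases(traces_from_totals([8, 8, 3]))
        assert [e.rank for e in ranked.entries] == [1, 1, 3]

    def test_tied_diseases_keep_configured_order(self):
        ranked = zp.rank_diseases(
            traces_from_totals([5, 8, 5], names=["a", "b", "c"])
        )
        assert [e.disease for e in ranked.entries] == ["b", "a", "c"]

    def test_all_zero_totals_warn_and_define_zero(self):
        with pytest.warns(UserWarning, match="zero"):
            ranked = zp.rank_diseases(traces_from_totals([0, 0]))
        assert all(e.normalized == 0.0 for e in ranked.entries)

    def test_renormalizing_a_normalized_list_changes_nothing(self):
        first = zp.rank_diseases(traces_from_totals([8, 4, 2]))
        again = zp.rank_diseases(
            traces_from_totals(
                [e.normalized for e in first.entries],
                names=[e.disease for e in first.entries],
            )
        )
        assert [e.normalized for e in again.entries] == [
            e.normalized for e in first.entries
        ]
        assert [e.rank for e in again.entries] == [
            e.rank for e in first.entries
        ]

    def test_max_possible_normalization(self, country_x, country_x_weights):
        config, _, answers = country_x
        traces = zp.score_all(answers, country_x_weights, config)
        ranked = zp.rank_diseases(traces, normalization="max_possible")
        by_disease = {e.disease: e for e in ranked.entries}
        assert by_disease["Rabies"].normalized == pytest.approx(8 / 15)


class TestSensitivityScan:
    def test_rank_inert_constant_criterion(self):
        config = make_config([YN, YN, COLLAB], diseases=("d1", "d2", "d3"))
        rows = {
            "d1": {"q0": "yes", "q1": "yes", "q2": "neither"},
            "d2": {"q0": "yes", "q1": "no", "q2": "neither"},
            "d3": {"q0": "no", "q1": "no", "q2": "neither"},
        }
        res = zp.sensitivity_scan(
            AnswerTable(rows), seq_weights(config.criterion_ids), config
        )
        assert res["q2"].rank_changes == 0

    def test_single_disease_never_changes_rank(self, country_x, country_x_weights):
        config, _, answers = country_x
        one = AnswerTable({"Rabies": answers.rows["Rabies"]})
        cfg_one = PrioritizationConfig(
            config.criteria, config.questions, ("Rabies",), config.metadata
        )
        res = zp.sensitivity_scan(one, country_x_weights, cfg_one)
        assert all(r.rank_changes == 0 for r in res.values())

    def test_matches_brute_force_leave_one_out_oracle(self):
        rng = np.random.default_rng(5)
        scales = [YN, COLLAB, YN, QUART]
        diseases = tuple(f"d{i}" for i in range(10))
        config = make_config(scales, diseases=diseases)
        rows = {
            d: {
                f"q{i}": scales[i].categories[
                    rng.integers(len(scales[i].categories))
                ]
                for i in range(4)
            }
            for d in diseases
        }
        answers = AnswerTable(rows)
        weights = seq_weights(config.criterion_ids)
        res = zp.sensitivity_scan(answers, weights, config)

        # oracle: direct sum(w*s) re-scoring per left-out criterion
        def raw(scale, label):
            k = scale.categories.index(label) + 1
            if scale.kind == "binomial":
                return 1.0 if label == scale.full_score_category else 0.0
            return k / len(scale.categories)

        def ranks(totals):
            out = {}
            for d, t in totals.items():
                out[d] = 1 + sum(
                    1 for u in totals.values() if u > t + 1e-9
                )
            return out

        base = {
            d: sum(
                weights.weights[f"q{i}"] * raw(scales[i], rows[d][f"q{i}"])
                for i in range(4)
            )
            for d in diseases
        }
        base_ranks = ranks(base)
        for left_out in config.criterion_ids:
            remaining = [c for c in config.criterion_ids if c != left_out]
            w = {c: float(len(remaining) - i) for i, c in enumerate(remaining)}
            totals = {
                d: sum(
                    w[c] * raw(scales[int(c[1])], rows[d][c]) for c in remaining
                )
                for d in diseases
            }
            oracle_changes = sum(
                1
                for d in diseases
                if ranks(totals)[d] != base_ranks[d]
            )
            assert res[left_out].rank_changes == oracle_changes
            pkg_totals = {
                e.disease: e.total for e in res[left_out].ranked.entries
            }
            for d in diseases:
                assert pkg_totals[d] == pytest.approx(totals[d])

    def test_requires_at_least_two_criteria(self):
        config = make_config([YN, YN])
        answers = AnswerTable({"d1": {"q0": "no", "q1": "no"}})
        w = seq_weights(("q0",))
        with pytest.raises(ValidationError, match="at least 2"):
            zp.sensitivity_scan(answers, w, config)

    def test_decision_tree_order_does_not_affect_totals(
        self, country_x, country_x_weights
    ):
        # every disease traverses every node: visiting criteria in any
        # order yields the same total, only the trace presentation moves
        config, _, answers = country_x
        w = country_x_weights
        reversed_w = CriterionWeights(
            ranking=tuple(reversed(w.ranking)),
            priorities=w.priorities,
            weights=w.weights,
        )
        for d in config.diseases:
            t1 = zp.score_disease(d, answers, w, config).total
            t2 = zp.score_disease(d, answers, reversed_w, config).total
            assert t1 == pytest.approx(t2, abs=1e-12)
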
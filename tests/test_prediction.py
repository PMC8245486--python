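"""Predictors, assembly rules, simplex/L1 error metrics, and study evaluation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutassembly import (
    CompositionVector,
    apply_assembly_rule,
    arithmetic_mean_prediction,
    evaluate_predictions,
    l1_error,
    make_ground_truth,
    predict_from_monocultures,
    predict_pairwise,
    replicate_noise_floor,
    simplex_error,
    simulate_study,
    survivors_from_fractions,
)
from gutassembly.composition import PairwiseOutcome
from gutassembly.data_model import ValidationError


def comp(species, fractions):
    return CompositionVector(tuple(species), tuple(fractions))


class TestMonoculturePrediction:
    def test_equal_monocultures_give_uniform(self):
        pred = predict_from_monocultures({"A": 5.0, "B": 5.0, "C": 5.0}, "ABC")
        assert pred.fractions == pytest.approx((1 / 3,) * 3)

    def test_proportional_normalization(self):
        pred = predict_from_monocultures({"A": 2000, "B": 1000, "C": 1000}, "ABC")
        assert pred.fractions == pytest.approx((0.5, 0.25, 0.25))

    def test_eight_species_matches_hand_normalization(self):
        rng = np.random.default_rng(1)
        sp = tuple(f"s{i}" for i in range(8))
        means = {s: float(rng.lognormal(7, 1)) for s in sp}
        pred = predict_from_monocultures(means, sp)
        tot = sum(means.values())
        assert pred.fractions == pytest.approx(tuple(means[s] / tot for s in sp))

    def test_all_zero_means_rejected(self):
        with pytest.raises(ValidationError):
            predict_from_monocultures({"A": 0.0, "B": 0.0}, "AB")


class TestArithmeticMeanPrediction:
    def test_flat_matrix_gives_uniform_trio(self):
        pf = {p: 0.5 for p in itertools.combinations("ABC", 2)}
        pred = arithmetic_mean_prediction(pf, "ABC")
        assert pred.fractions == pytest.approx((1 / 3,) * 3)

    def test_hand_evaluated_trio(self):
        # i beats j and k outright, j and k even: means (1, 1/4, 1/4) -> (2/3, 1/6, 1/6)
        pf = {("i", "j"): 1.0, ("i", "k"): 1.0, ("j", "k"): 0.5}
        pred = arithmetic_mean_prediction(pf, ("i", "j", "k"))
        assert pred.fractions == pytest.approx((2 / 3, 1 / 6, 1 / 6))

    @pytest.mark.parametrize("n", range(2, 9))
    def test_unnormalized_means_sum_to_n_over_2(self, n):
        """The trio normalization constant 2/3 generalizes: sum of means = n/2."""
        rng = np.random.default_rng(n)
        sp = tuple(f"s{i}" for i in range(n))
        pf = {p: float(rng.uniform()) for p in itertools.combinations(sp, 2)}
        full = {**pf, **{(b, a): 1 - v for (a, b), v in pf.items()}}
        means = [
            np.mean([full[(i, j)] for j in sp if j != i]) for i in sp
        ]
        assert sum(means) == pytest.approx(n / 2)

    def test_pair_returns_pair_fractions_exactly(self):
        pf = {("A", "B"): 0.76}
        pred = arithmetic_mean_prediction(pf, ("A", "B"))
        assert pred.fractions == pytest.approx((0.76, 0.24))

    def test_missing_pair_named_in_error(self):
        pf = {("A", "B"): 0.7}
        with pytest.raises(ValidationError, match="C"):
            arithmetic_mean_prediction(pf, ("A", "B", "C"))


def outcome(pair, category):
    return PairwiseOutcome(
        pair=pair,
        environment="worm",
        host_strain="AU37",
        mean_fractions=(0.5, 0.5),
        sem_fractions=(0.0, 0.0),
        replicate_fractions=np.array([0.5]),
        category=category,
    )


class TestAssemblyRule:
    def test_no_exclusions_keeps_everyone(self):
        ocs = [outcome(p, "coexistence") for p in itertools.combinations("ABC", 2)]
        assert apply_assembly_rule(ocs, "ABC") == ("A", "B", "C")

    def test_doubly_excluded_species_dropped_and_pair_fractions_used(self):
        # k loses both its pairs; the trio prediction collapses to the i-j fractions
        pf = {("i", "j"): 0.6, ("i", "k"): 0.99, ("j", "k"): 0.99}
        res = predict_pairwise(pf, ("i", "j", "k"), rule=True, threshold=0.02)
        assert res.survivors == ("i", "j")
        assert res.predicted.fractions == pytest.approx((0.6, 0.4, 0.0))

    def test_variants_differ_on_chain_exclusions(self):
        # a excludes b, b excludes c; nobody excluded in *all* pairs
        cats = {
            ("a", "b"): "exclusion_of_b",
            ("b", "c"): "exclusion_of_c",
            ("a", "c"): "coexistence",
            ("a", "d"): "coexistence",
            ("b", "d"): "coexistence",
            ("c", "d"): "coexistence",
            ("a", "e"): "coexistence",
            ("b", "e"): "coexistence",
            ("c", "e"): "coexistence",
            ("d", "e"): "coexistence",
        }
        ocs = [outcome(p, c) for p, c in cats.items()]
        comm = ("a", "b", "c", "d", "e")
        assert apply_assembly_rule(ocs, comm, "excluded_in_all") == comm
        # iterative oracle: remove one excluded species at a time, re-checking
        # after each removal (c's only excluder is b, so dropping b rescues c)
        surv = list(comm)
        excl = {("b", "a"), ("c", "b")}  # (loser, winner)
        while True:
            drop = [i for i in surv if any((i, j) in excl for j in surv if j != i)]
            if not drop:
                break
            surv.remove(drop[0])
        got = apply_assembly_rule(ocs, comm, "excluded_by_any_survivor")
        assert set(got) == set(surv) == {"a", "c", "d", "e"}

    def test_idempotent_on_own_survivors(self):
        rng = np.random.default_rng(5)
        sp = tuple(f"s{i}" for i in range(6))
        pf = {p: float(rng.choice([0.01, 0.3, 0.99])) for p in itertools.combinations(sp, 2)}
        for variant in ("excluded_in_all", "excluded_by_any_survivor"):
            surv = survivors_from_fractions(pf, sp, 0.02, variant)
            again = survivors_from_fractions(pf, surv, 0.02, variant)
            assert again == surv

    def test_override_category_respected(self):
        # an override keeping a rare species as coexisting protects it from the rule
        ocs = [
            outcome(("i", "k"), "exclusion_of_k"),
            outcome(("j", "k"), "coexistence"),
            outcome(("i", "j"), "coexistence"),
        ]
        assert apply_assembly_rule(ocs, ("i", "j", "k")) == ("i", "j", "k")


class TestErrorMetrics:
    def test_identical_vectors_zero(self):
        a = comp("ABC", (0.2, 0.3, 0.5))
        assert simplex_error(a, a) == 0.0
        assert l1_error(a, a) == 0.0

    def test_vertex_to_vertex_is_maximal(self):
        a = comp("ABC", (1, 0, 0))
        b = comp("ABC", (0, 1, 0))
        assert simplex_error(a, b) == pytest.approx(1.0)
        assert l1_error(a, b) == pytest.approx(1.0)

    def test_printed_trio_vs_uniform_hand_value(self):
        a = comp("ABC", (0.55, 0.42, 0.03))
        b = comp("ABC", (1 / 3, 1 / 3, 1 / 3))
        expected = math.sqrt(
            (0.55 - 1 / 3) ** 2 + (0.42 - 1 / 3) ** 2 + (0.03 - 1 / 3) ** 2
        ) / math.sqrt(2)
        assert simplex_error(a, b) == pytest.approx(expected)
        assert expected == pytest.approx(0.271, abs=5e-4)

    def test_l1_hand_value(self):
        a = comp("ABC", (0.5, 0.3, 0.2))
        b = comp("ABC", (0.2, 0.5, 0.3))
        assert l1_error(a, b) == pytest.approx(0.3)

    def test_mismatched_species_sets_rejected(self):
        with pytest.raises(ValidationError):
            simplex_error(comp("AB", (0.5, 0.5)), comp("AC", (0.5, 0.5)))

    def test_species_order_does_not_matter(self):
        a = comp("ABC", (0.5, 0.3, 0.2))
        b = comp("CBA", (0.1, 0.4, 0.5))
        assert simplex_error(a, b) == pytest.approx(
            simplex_error(a, b.reorder(("A", "B", "C")))
        )

    @given(
        x=st.lists(st.floats(0.001, 1, allow_nan=False), min_size=2, max_size=8),
        y=st.lists(st.floats(0.001, 1, allow_nan=False), min_size=2, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_symmetry_identity(self, x, y):
        """Both metrics are in [0,1], symmetric, zero iff equal."""
        n = min(len(x), len(y))
        a = np.array(x[:n]) / np.sum(x[:n])
        b = np.array(y[:n]) / np.sum(y[:n])
        for err in (simplex_error, l1_error):
            v = err(a, b)
            assert 0.0 <= v <= 1.0 + 1e-12
            assert v == pytest.approx(err(b, a))
            assert err(a, a) == 0.0
            if not np.allclose(a, b):
                assert v > 0


class TestNoiseFloor:
    def test_identical_replicates_zero(self):
        reps = [comp("AB", (0.6, 0.4))] * 3
        assert replicate_noise_floor(reps) == pytest.approx(0.0)

    def test_symmetric_replicates_equal_distance(self):
        reps = [comp("AB", (0.7, 0.3)), comp("AB", (0.5, 0.5))]
        floor = replicate_noise_floor(reps)
        assert floor == pytest.approx(simplex_error((0.7, 0.3), (0.6, 0.4)))

    def test_four_replicates_hand_mean(self):
        rng = np.random.default_rng(2)
        reps = [rng.dirichlet([5, 5, 5]) for _ in range(4)]
        mean = np.mean(reps, axis=0)
        expected = np.mean([simplex_error(r, mean) for r in reps])
        assert replicate_noise_floor(reps) == pytest.approx(expected)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError):
            replicate_noise_floor([comp("AB", (0.5, 0.5))])


class TestEvaluatePredictions:
    def test_noiseless_self_consistency(self, noiseless_study):
        errs = evaluate_predictions(noiseless_study, methods=("pairwise_rule",))
        assert (errs["error"] < 1e-9).all()

    def test_uniform_measurement_gives_uninformed_error_zero(self):
        gt = make_ground_truth(
            3,
            mode="supplied",
            params={
                "F": [[0.5, 0.5, 0.5], [0.5, 0.5, 0.5], [0.5, 0.5, 0.5]],
                "cv_total": 0.0,
                "colonies_counted": None,
            },
            seed=4,
        )
        study = simulate_study(
            gt, design={"trios": "all", "octet": None, "n_replicates": {"mono": 2, "pair": 2, "trio": 2}}
        )
        errs = evaluate_predictions(study, methods=("uninformed",))
        assert (errs["error"] < 1e-12).all()

    def test_matches_straight_line_reimplementation(self, default_study):
        """Mean errors agree with an independent per-trio loop with no shared code."""
        from gutassembly.composition import build_competition_matrix, replicate_fractions
        from gutassembly.data_model import Condition

        table = default_study.cfu_table
        errs = evaluate_predictions(table, methods=("uninformed", "pairwise",))
        M = build_competition_matrix(table)
        by_method = errs.groupby("method")["error"].mean()

        oracle = {"uninformed": [], "pairwise": []}
        for cond in table.conditions():
            if cond.n_species < 3:
                continue
            sp = cond.fed_community
            wide = table.replicate_counts(cond)
            fr = wide.div(wide.sum(axis=1), axis=0).to_numpy()
            meas = fr.mean(axis=0)
            meas = meas / meas.sum()
            n = len(sp)
            oracle["uninformed"].append(
                np.linalg.norm(meas - np.ones(n) / n) / math.sqrt(2)
            )
            means = np.array(
                [np.mean([M.get(i, j) for j in sp if j != i]) for i in sp]
            )
            pred = means / means.sum()
            oracle["pairwise"].append(np.linalg.norm(meas - pred) / math.sqrt(2))
        for method in oracle:
            assert by_method[method] == pytest.approx(np.mean(oracle[method]))

    def test_method_lacking_inputs_yields_nan_not_abort(self, default_study):
        # media pairs were never simulated: the pairwise matrix is missing
        errs = evaluate_predictions(
            default_study.cfu_table,
            methods=("uninformed", "pairwise"),
            pair_environment="media",
            pair_host_strain=None,
        )
        un = errs[errs["method"] == "uninformed"]["error"]
        pw = errs[errs["method"] == "pairwise"]["error"]
        assert un.notna().all() and pw.isna().all()

    def test_error_grows_with_higher_order_strength(self):
        """Stronger higher-order perturbations make pairwise predictions worse."""
        means = {}
        for eps in (0.0, 0.3):
            gt = make_ground_truth(
                5,
                params={"epsilon_hoi": eps, "cv_total": 0.1, "colonies_counted": 1000},
                seed=17,
            )
            study = simulate_study(
                gt,
                design={"trios": "all", "octet": None,
                        "n_replicates": {"mono": 4, "pair": 4, "trio": 4}},
                seed=17,
            )
            errs = evaluate_predictions(study, methods=("pairwise_rule",))
            means[eps] = errs["error"].mean()
        assert means[0.3] > means[0.0]
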
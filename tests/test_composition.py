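"""Fractional abundances, outcome classification, relative yields, null model."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gutassembly import (
    CFUTable,
    Condition,
    build_competition_matrix,
    classify_pair,
    community_size_check,
    competitive_ability,
    fdr_adjust,
    null_deviation_test,
    null_expectation_pair,
    relative_yield,
    replicate_fractions,
)
from gutassembly.composition import (
    CompetitionMatrix,
    null_combination_fractions,
    pair_outcome,
)
from gutassembly.data_model import ValidationError
from test_data_model import make_pair_table


class TestReplicateFractions:
    def test_even_counts_give_half_half(self):
        table, cond = make_pair_table([(100, 100)])
        rf = replicate_fractions(table, cond)
        assert rf.fractions[0] == pytest.approx([0.5, 0.5])

    def test_zero_count_boundary(self):
        table, cond = make_pair_table([(0, 500)])
        rf = replicate_fractions(table, cond)
        assert rf.fractions[0] == pytest.approx([0.0, 1.0])

    def test_trio_fractions_match_printed_pattern(self):
        # a trio at 55/42/3% composition
        cond = Condition("worm", ("Ea", "Sm", "Pf"), "AU37")
        rows = [(cond, s, 1, c) for s, c in zip(("Ea", "Sm", "Pf"), (55, 42, 3))]
        table = CFUTable.from_rows(rows)
        rf = replicate_fractions(table, cond)
        assert rf.fractions[0] == pytest.approx([0.55, 0.42, 0.03])

    def test_zero_total_replicates_flagged_and_excluded(self):
        table, cond = make_pair_table([(10, 10), (0, 0), (30, 10)])
        rf = replicate_fractions(table, cond)
        assert rf.excluded_replicates == (2,)
        assert len(rf.fractions) == 2

    def test_all_zero_total_is_error(self):
        table, cond = make_pair_table([(0, 0), (0, 0)])
        with pytest.raises(ValidationError, match="zero total"):
            replicate_fractions(table, cond)

    def test_pair_fractions_sum_to_one_exactly(self, default_study):
        table = default_study.cfu_table
        for cond in table.conditions():
            if cond.n_species != 2:
                continue
            rf = replicate_fractions(table, cond)
            assert np.all(rf.fractions.sum(axis=1) == pytest.approx(1.0, abs=1e-12))


class TestClassifyPair:
    def test_even_pair_coexists(self):
        cat, ov, _ = classify_pair((0.5, 0.5), ("A", "B"))
        assert cat == "coexistence" and not ov

    def test_sub_threshold_minority_excluded(self):
        cat, ov, _ = classify_pair((0.983, 0.017), ("A", "B"))
        assert cat == "exclusion_of_B" and not ov

    def test_override_replaces_rule(self):
        # a rare species confirmed in several replicates may be kept as coexisting
        cat, ov, note = classify_pair(
            (0.983, 0.017),
            ("Pf", "Ea"),
            overrides=[(("Pf", "Ea"), "coexistence", "presence reassured")],
        )
        assert cat == "coexistence" and ov and note

    def test_threshold_range_enforced(self):
        with pytest.raises(ValidationError):
            classify_pair((0.6, 0.4), ("A", "B"), threshold=0.7)

    @given(
        f=st.floats(0.0, 0.5, allow_nan=False),
        t1=st.floats(0.001, 0.49, allow_nan=False),
        t2=st.floats(0.001, 0.49, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_threshold(self, f, t1, t2):
        """Raising the threshold never converts an exclusion into a coexistence."""
        lo, hi = sorted((t1, t2))
        cat_lo, _, _ = classify_pair((1 - f, f), ("A", "B"), threshold=lo)
        cat_hi, _, _ = classify_pair((1 - f, f), ("A", "B"), threshold=hi)
        if cat_lo != "coexistence":
            assert cat_hi != "coexistence"


class TestRelativeYield:
    def test_identical_populations_give_log_ry_zero(self):
        ry = relative_yield([999, 999], [999, 999], n_boot=50, seed=1)
        assert ry.log_ry_mean == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_single_values_exact(self):
        ry = relative_yield([999], [0], n_boot=100, seed=1)
        assert ry.log_ry_mean == pytest.approx(math.log(1 / 1000))
        assert ry.log_ry_sem == pytest.approx(0.0, abs=1e-12)

    def test_length_two_exhaustive_enumeration_oracle(self):
        """Bootstrap mean converges to the average over all 16 joint resamples."""
        mono, co = [9, 11], [19, 21]
        vals = []
        for mi in itertools.product(mono, repeat=2):
            mono_mean = np.mean([m + 1 for m in mi])
            for ci in itertools.product(co, repeat=2):
                vals.append(np.mean([math.log((c + 1) / mono_mean) for c in ci]))
        oracle_mean = np.mean(vals)
        oracle_sd = np.std(vals)  # population sd over the 16 equally likely outcomes
        assert oracle_mean == pytest.approx(math.log(2), abs=0.05)
        ry = relative_yield(mono, co, n_boot=200_000, seed=2)
        mc_se = oracle_sd / math.sqrt(200_000)
        assert ry.log_ry_mean == pytest.approx(oracle_mean, abs=4 * mc_se)
        assert ry.log_ry_sem == pytest.approx(oracle_sd, rel=0.02)

    def test_bootstrap_converges_to_plug_in_value(self):
        """With many iterations the mean approaches the full-list plug-in value."""
        rng = np.random.default_rng(3)
        mono = rng.lognormal(7, 0.4, 8)
        co = rng.lognormal(6, 0.4, 4)
        plug_in = np.mean(np.log((co + 1))) - math.log(np.mean(mono + 1))
        ry = relative_yield(mono, co, n_boot=100_000, seed=3)
        # bootstrap mean is biased only at O(1/n); allow 3 bootstrap s.e.
        assert abs(ry.log_ry_mean - plug_in) < 3 * ry.log_ry_sem

    def test_n_boot_floor(self):
        with pytest.raises(ValidationError):
            relative_yield([1], [1], n_boot=1)


class TestCompetitiveAbility:
    def make_matrix(self, entries, species):
        F = {pair: f for pair, f in entries.items()}
        return CompetitionMatrix.from_fractions(F, species)

    def test_total_winner_has_ability_one(self):
        M = self.make_matrix({("A", "B"): 1.0, ("A", "C"): 1.0, ("B", "C"): 0.5}, "ABC")
        assert competitive_ability(M, "A")[0] == pytest.approx(1.0)

    def test_row_arithmetic(self):
        M = self.make_matrix(
            {("A", "B"): 1.0, ("A", "C"): 0.5, ("A", "D"): 0.0,
             ("B", "C"): 0.5, ("B", "D"): 0.5, ("C", "D"): 0.5},
            "ABCD",
        )
        assert competitive_ability(M, "A")[0] == pytest.approx(0.5)

    def test_four_species_hand_enumeration(self):
        rng = np.random.default_rng(4)
        sp = ("A", "B", "C", "D")
        entries = {p: rng.uniform() for p in itertools.combinations(sp, 2)}
        M = self.make_matrix(entries, sp)
        for i in sp:
            expected = np.mean(
                [entries.get((i, j), 1 - entries.get((j, i), np.nan)) for j in sp if j != i]
            )
            assert competitive_ability(M, i)[0] == pytest.approx(expected)

    def test_sem_propagation(self, default_study):
        M = build_competition_matrix(default_study.cfu_table)
        i = M.species_ids[0]
        sems = [M.sem.loc[i, j] for j in M.species_ids if j != i]
        _, sem = competitive_ability(M, i)
        assert sem == pytest.approx(math.sqrt(np.sum(np.square(sems))) / len(sems))


class TestNullExpectation:
    def test_single_combination(self):
        mean, _ = null_expectation_pair([100], [300])
        assert mean == pytest.approx(0.25)

    def test_symmetry_for_identical_lists(self):
        mean, _ = null_expectation_pair([5, 10, 20], [5, 10, 20])
        assert mean == pytest.approx(0.5)

    def test_two_combination_enumeration(self):
        mean, _ = null_expectation_pair([100, 200], [400])
        assert mean == pytest.approx((100 / 500 + 200 / 600) / 2)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(8)
        a = rng.lognormal(6, 1, 5)
        b = rng.lognormal(7, 1, 3)
        fr = null_combination_fractions(a, b)
        oracle = [x / (x + y) for x in a for y in b]
        assert sorted(fr) == pytest.approx(sorted(oracle))
        mean, sem = null_expectation_pair(a, b)
        assert mean == pytest.approx(np.mean(oracle))
        assert sem == pytest.approx(np.std(oracle, ddof=1) / math.sqrt(3))

    def test_double_zero_contributes_half(self):
        fr = null_combination_fractions([0.0], [0.0])
        assert fr[0] == 0.5


class TestWelchAndFDR:
    def test_identical_samples(self):
        t, p = null_deviation_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_samples_significant(self):
        t, p = null_deviation_test([1, 2, 3], [1001, 1002, 1003])
        assert p < 0.01

    def test_matches_closed_form_welch(self):
        a = np.array([0.2, 0.3, 0.25])
        b = np.array([0.6, 0.55, 0.7])
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_exp = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p_exp = 2 * stats.t.sf(abs(t_exp), df)
        t, p = null_deviation_test(a, b)
        assert t == pytest.approx(t_exp) and p == pytest.approx(p_exp)

    def test_effective_n_override_matches_hand_formula(self):
        a = np.array([0.2, 0.3, 0.25, 0.28])
        b = np.array([0.5, 0.6, 0.55, 0.52, 0.58, 0.61])
        n_b = 3
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / n_b
        t_exp = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / (n_b - 1))
        p_exp = 2 * stats.t.sf(abs(t_exp), df)
        t, p = null_deviation_test(a, b, n_b=n_b)
        assert t == pytest.approx(t_exp) and p == pytest.approx(p_exp)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            null_deviation_test([1], [1, 2])

    def test_fdr_single_test_unchanged(self):
        assert fdr_adjust([0.05])[0] == pytest.approx(0.05)

    def test_fdr_equal_ps_fixed_point(self):
        assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_fdr_matches_hand_step_up(self):
        p = [0.01, 0.02, 0.03, 0.04]
        # BH step-up: p_(i) * m / i, then running minimum from the largest
        raw = [0.01 * 4 / 1, 0.02 * 4 / 2, 0.03 * 4 / 3, 0.04 * 4 / 4]
        expected = [min(raw[i:]) for i in range(4)]
        assert fdr_adjust(p) == pytest.approx(expected)

    def test_fdr_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_adjust([0.5, 1.2])


class TestCommunitySize:
    def _study_table(self):
        cond_p = Condition("worm", ("A", "B"), "AU37")
        cond_a = Condition("worm", ("A",), "AU37")
        cond_b = Condition("worm", ("B",), "AU37")
        rows = []
        for rep, (a, b) in enumerate([(100, 50), (80, 70)], 1):
            rows += [(cond_p, "A", rep, a), (cond_p, "B", rep, b)]
        for rep, v in enumerate([100, 100], 1):
            rows.append((cond_a, "A", rep, v))
        for rep, v in enumerate([200, 200], 1):
            rows.append((cond_b, "B", rep, v))
        return CFUTable.from_rows(rows), cond_p

    def test_ratio_and_flag(self):
        table, cond = self._study_table()
        rec = community_size_check(table, cond)
        assert rec["co_total"] == pytest.approx(150.0)
        assert rec["max_mono"] == pytest.approx(200.0)
        assert rec["ratio"] == pytest.approx(0.75)
        assert rec["flag"] == "lower"

    def test_missing_monoculture_is_error(self):
        table, cond = make_pair_table([(10, 10)])
        with pytest.raises(ValidationError, match="monoculture"):
            community_size_check(table, cond)

    def test_strong_competition_yields_mostly_lower_totals(self, default_study):
        """Suppressive interactions drive most co-culture totals below the top monoculture."""
        table = default_study.cfu_table
        flags = []
        for cond in table.conditions():
            if cond.n_species == 2:
                flags.append(community_size_check(table, cond)["flag"])
        assert flags.count("lower") > len(flags) / 2


class TestPairOutcome:
    def test_outcome_and_override_wiring(self, default_study):
        table = default_study.cfu_table
        cond = next(c for c in table.conditions() if c.n_species == 2)
        oc = pair_outcome(table, cond)
        assert oc.mean_fractions[0] + oc.mean_fractions[1] == pytest.approx(1.0)
        forced = pair_outcome(
            table, cond, overrides=[(tuple(cond.fed_community), "coexistence", "manual")]
        )
        assert forced.category == "coexistence" and forced.override_applied
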
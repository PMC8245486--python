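"""Reusable study-level experiments over the synthetic generator.

These bundle multi-study simulation campaigns used by the analysis drivers
and the acceptance checks: type-I calibration of the monoculture null-model
test, and the ordering of prediction errors across methods on
pairwise-consistent ground truths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import child_seed
from .composition import null_combination_fractions, null_deviation_test
from .prediction import evaluate_predictions
from .synthetic import make_ground_truth, simulate_condition, simulate_study

__all__ = [
    "no_interaction_rejection_rates",
    "prediction_error_ordering",
]


def no_interaction_rejection_rates(
    n_studies: int = 200,
    n_species: int = 5,
    n_mono: int = 8,
    n_co: int = 4,
    alpha: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Per-study rejection rates of the null-model test when the null is true.

    Each study simulates monoculture colonization for ``n_species`` species
    (lognormal replicate noise around the carrying capacity) and constructs
    every pair's "co-culture" fractions from *additional independent
    monoculture draws* — exactly the non-interacting world the null model
    assumes.  Each pair is then tested (measured fractions vs enumerated
    null-combination fractions, effective null n = the monoculture replicate
    count) and the fraction of rejections at ``alpha`` recorded.  A
    calibrated test rejects at rate ~alpha.
    """
    rates = np.empty(n_studies)
    for s in range(n_studies):
        gt = make_ground_truth(
            n_species,
            params={"cv_total": 0.5, "colonies_counted": None},
            seed=child_seed(seed, "null_study", s),
        )
        draws = {}
        for sp in gt.species_ids:
            rows = simulate_condition(
                gt, (sp,), n_replicates=n_mono + n_co, seed=child_seed(seed, "mono", s)
            )
            draws[sp] = np.array([c for _, _, _, c in rows])
        rej = 0
        n_tests = 0
        species = gt.species_ids
        for a in range(n_species):
            for b in range(a + 1, n_species):
                i, j = species[a], species[b]
                mono_i, extra_i = draws[i][:n_mono], draws[i][n_mono:]
                mono_j, extra_j = draws[j][:n_mono], draws[j][n_mono:]
                pair_fr = extra_i / (extra_i + extra_j)
                combos = null_combination_fractions(mono_i, mono_j)
                _, p = null_deviation_test(
                    pair_fr, combos, n_b=min(len(mono_i), len(mono_j))
                )
                rej += p < alpha
                n_tests += 1
        rates[s] = rej / n_tests
    return rates


def prediction_error_ordering(
    n_studies: int = 50,
    n_species: int = 6,
    epsilon_hoi: float = 0.0,
    metric: str = "simplex",
    seed: int = 0,
) -> pd.DataFrame:
    """Mean trio prediction error per method over repeated simulated studies.

    Each study draws a hierarchical ground truth with study-default noise
    (cv 0.3, 100 colonies counted) and ``epsilon_hoi`` higher-order
    strength, simulates all monocultures, pairs, and trios, and evaluates
    the uninformed, monoculture-null, and pairwise (with/without assembly
    rule) predictors.  One row per study with per-method mean errors and the
    mean replicate noise floor.
    """
    recs = []
    for s in range(n_studies):
        gt = make_ground_truth(
            n_species,
            params={"epsilon_hoi": epsilon_hoi},
            seed=child_seed(seed, "ordering_truth", s),
        )
        study = simulate_study(
            gt,
            design={
                "trios": "all",
                "octet": None,
                "n_replicates": {"mono": 8, "pair": 4, "trio": 4},
            },
            seed=child_seed(seed, "ordering_study", s),
        )
        errs = evaluate_predictions(
            study,
            methods=("uninformed", "monoculture_null", "pairwise", "pairwise_rule"),
            metric=metric,
        )
        row = errs.groupby("method")["error"].mean().to_dict()
        row["noise_floor"] = errs.drop_duplicates("community")["noise_floor"].mean()
        row["study"] = s
        recs.append(row)
    return pd.DataFrame(recs)
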
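"""Cross-environment and cross-host comparisons, and phylogeny–trait correlation.

Pairwise outcomes measured in the host gut and in liquid media (or in two
host strains differing in immune competence) are compared pair by pair with
Welch tests and category-shift counts, and globally through correlations of
per-species competitive abilities.  Trait differences (monoculture
colonization, competitive ability) are related to phylogeny via Mantel
permutation tests on distance matrices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from .composition import (
    PairwiseOutcome,
    build_competition_matrix,
    competitive_abilities,
    null_deviation_test,
    replicate_fractions,
)
from .data_model import CFUTable, Condition, PhyloDistances, ValidationError
from .prediction import l1_error, replicate_noise_floor

__all__ = [
    "EnvironmentComparison",
    "compare_environments",
    "trait_dissimilarity",
    "mantel_test",
    "compare_host_strains",
]


@dataclass
class EnvironmentComparison:
    """Per-pair and summary comparison of outcomes between two environments."""

    per_pair: pd.DataFrame
    ability_spearman: tuple[float, float]
    ability_pearson: tuple[float, float]
    n_significant: int
    shift_counts: dict[str, int]
    n_skipped: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.per_pair)


def _outcome_index(
    outcomes: Sequence[PairwiseOutcome],
) -> dict[frozenset, PairwiseOutcome]:
    return {frozenset(oc.pair): oc for oc in outcomes}


def _abilities_from_outcomes(outcomes: Sequence[PairwiseOutcome]) -> pd.Series:
    per_species: dict[str, list[float]] = {}
    for oc in outcomes:
        i, j = oc.pair
        per_species.setdefault(i, []).append(oc.mean_fractions[0])
        per_species.setdefault(j, []).append(oc.mean_fractions[1])
    return pd.Series({s: float(np.mean(v)) for s, v in per_species.items()})


def _shift(cat_a: str, cat_b: str) -> str:
    coex_a = cat_a == "coexistence"
    coex_b = cat_b == "coexistence"
    if coex_a == coex_b:
        return "none"
    return "coexist_to_exclude" if coex_a else "exclude_to_coexist"


def compare_environments(
    outcomes_a: Sequence[PairwiseOutcome],
    outcomes_b: Sequence[PairwiseOutcome],
    alpha: float = 0.05,
) -> EnvironmentComparison:
    """Pair-by-pair comparison of classified outcomes in two environments.

    For every pair present in both: Welch's t on replicate fractions of the
    (consistently oriented) first species, and the category shift from
    environment A to B.  Shift counts only consider pairs with p < alpha.
    Globally, Spearman and Pearson correlations of per-species competitive
    abilities across environments.
    """
    ix_a = _outcome_index(outcomes_a)
    ix_b = _outcome_index(outcomes_b)
    shared = sorted(set(ix_a) & set(ix_b), key=lambda p: tuple(sorted(p)))
    n_skipped = len(set(ix_a) ^ set(ix_b))
    recs = []
    for key in shared:
        oa, ob = ix_a[key], ix_b[key]
        fa = oa.replicate_fractions
        # orient B's replicate fractions to A's first species
        fb = ob.replicate_fractions if ob.pair == oa.pair else 1.0 - ob.replicate_fractions
        if len(fa) >= 2 and len(fb) >= 2:
            t, p = null_deviation_test(fa, fb)
        else:
            t, p = math.nan, math.nan
        sh = _shift(oa.category, ob.category)
        recs.append(
            {
                "pair": "-".join(oa.pair),
                "F_a": oa.mean_fractions[0],
                "F_b": ob.fraction_of(oa.pair[0]),
                "category_a": oa.category,
                "category_b": ob.category,
                "welch_t": t,
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
                "category_shift": sh,
            }
        )
    per_pair = pd.DataFrame(recs)
    sig = per_pair[per_pair["significant"]] if len(per_pair) else per_pair
    shift_counts = {
        "none": 0,
        "coexist_to_exclude": 0,
        "exclude_to_coexist": 0,
    }
    for sh in sig["category_shift"] if len(sig) else []:
        shift_counts[sh] += 1

    ab_a = _abilities_from_outcomes(outcomes_a)
    ab_b = _abilities_from_outcomes(outcomes_b)
    common = sorted(set(ab_a.index) & set(ab_b.index))
    if len(common) >= 3:
        rs = stats.spearmanr(ab_a[common], ab_b[common])
        rp = stats.pearsonr(ab_a[common], ab_b[common])
        spearman = (float(rs.statistic), float(rs.pvalue))
        pearson = (float(rp.statistic), float(rp.pvalue))
    else:
        spearman = pearson = (math.nan, math.nan)
    return EnvironmentComparison(
        per_pair=per_pair,
        ability_spearman=spearman,
        ability_pearson=pearson,
        n_significant=int(len(sig)),
        shift_counts=shift_counts,
        n_skipped=n_skipped,
    )


def trait_dissimilarity(
    values: Mapping[str, float], kind: str = "normalized_difference"
) -> pd.DataFrame:
    """Symmetric pairwise dissimilarity matrix of a per-species trait.

    fold_difference_log10
        |log10(v_i / v_j)| — for positive traits such as monoculture
        population sizes; 100 vs 10,000 CFU gives 2.
    normalized_difference
        |v_i - v_j| / max(v_i, v_j) — scale-free: abilities 0.8 vs 0.4 are
        as different as 0.2 vs 0.1 (both 0.5).
    """
    sp = list(values)
    v = np.array([float(values[s]) for s in sp])
    if kind == "fold_difference_log10":
        if (v <= 0).any():
            bad = [s for s, x in zip(sp, v) if x <= 0]
            raise ValidationError(f"fold difference requires positive values; bad: {bad}")
        lg = np.log10(v)
        d = np.abs(lg[:, None] - lg[None, :])
    elif kind == "normalized_difference":
        d = np.abs(v[:, None] - v[None, :]) / np.maximum(v[:, None], v[None, :])
        np.fill_diagonal(d, 0.0)
    else:
        raise ValidationError(f"unknown dissimilarity kind {kind!r}")
    return pd.DataFrame(d, index=sp, columns=sp)


def mantel_test(
    X,
    Y,
    correlation: str = "spearman",
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided Mantel permutation test between two distance matrices.

    The statistic is the chosen correlation (Spearman or Pearson) over the
    upper-triangle entries; the null permutes the row/column labels of Y
    jointly.  p = (1 + #{permuted >= observed}) / (1 + n_perm), testing
    positive association.
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Ya = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    if Xa.shape != Ya.shape or Xa.shape[0] != Xa.shape[1]:
        raise ValidationError("mantel_test requires matching square matrices")
    n = Xa.shape[0]
    if n < 4:
        raise ValidationError("mantel_test requires at least 4 species")
    for name, m in (("X", Xa), ("Y", Ya)):
        if not np.allclose(m, m.T):
            raise ValidationError(f"{name} is not symmetric")
    if correlation not in ("spearman", "pearson"):
        raise ValidationError(f"correlation must be spearman or pearson")
    iu = np.triu_indices(n, k=1)

    def corr(a, b):
        if correlation == "spearman":
            return float(stats.spearmanr(a, b).statistic)
        return float(stats.pearsonr(a, b).statistic)

    observed = corr(Xa[iu], Ya[iu])
    rng = child_rng(seed, "mantel")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Yp = Ya[np.ix_(perm, perm)]
        if corr(Xa[iu], Yp[iu]) >= observed - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return observed, p


def compare_host_strains(
    cfu_a: CFUTable,
    cfu_b: CFUTable,
    host_a: str = "AU37",
    host_b: str = "SS104",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Compare colonization between two host strains (e.g. immune mutants).

    Reports per-species monoculture population ratios (B/A) with bootstrap
    CIs, the correlation of mean pair fractions across strains, and — for
    every multispecies community measured in both — the L1 distance between
    the mean compositions together with each strain's replicate noise floor.
    Fractions are invariant to any global scaling of one strain's counts, so
    a uniform immune suppression of population sizes leaves the composition
    comparison untouched.
    """
    rng = child_rng(seed, "host_strains")

    def monos(table: CFUTable, host: str) -> dict[str, np.ndarray]:
        out = {}
        for cond in table.conditions():
            if cond.n_species == 1 and cond.environment == "worm" and cond.host_strain == host:
                sp = cond.fed_community[0]
                out[sp] = table.replicate_counts(cond)[sp].to_numpy(dtype=float)
        return out

    mono_a, mono_b = monos(cfu_a, host_a), monos(cfu_b, host_b)
    shared_sp = sorted(set(mono_a) & set(mono_b))
    ratios = []
    for sp in shared_sp:
        a, b = mono_a[sp], mono_b[sp]
        ratio = float((b.mean() + 1) / (a.mean() + 1))
        boots = []
        for _ in range(n_boot):
            ra = rng.choice(a, size=len(a), replace=True).mean() + 1
            rb = rng.choice(b, size=len(b), replace=True).mean() + 1
            boots.append(rb / ra)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ratios.append(
            {"species_id": sp, "ratio_b_over_a": ratio, "ci_lo": float(lo), "ci_hi": float(hi)}
        )
    mono_ratios = pd.DataFrame(ratios)

    # correlation of per-pair mean fractions
    def pair_fracs(table: CFUTable, host: str) -> dict[tuple[str, str], float]:
        try:
            M = build_competition_matrix(table, "worm", host)
        except ValidationError:
            return {}
        return {
            (i, j): M.get(i, j)
            for i, j in itertools.combinations(M.species_ids, 2)
            if np.isfinite(M.F.loc[i, j])
        }

    pf_a, pf_b = pair_fracs(cfu_a, host_a), pair_fracs(cfu_b, host_b)
    shared_pairs = sorted(set(pf_a) & set(pf_b))
    if len(shared_pairs) >= 3:
        va = [pf_a[p] for p in shared_pairs]
        vb = [pf_b[p] for p in shared_pairs]
        r = stats.pearsonr(va, vb)
        frac_corr = (float(r.statistic), float(r.pvalue))
    else:
        frac_corr = (math.nan, math.nan)

    # matched multispecies compositions
    def multis(table: CFUTable, host: str) -> dict[tuple[str, ...], Condition]:
        return {
            c.fed_community: c
            for c in table.conditions()
            if c.n_species >= 3 and c.environment == "worm" and c.host_strain == host
        }

    ma, mb = multis(cfu_a, host_a), multis(cfu_b, host_b)
    comps = []
    for comm in sorted(set(ma) & set(mb)):
        rf_a = replicate_fractions(cfu_a, ma[comm])
        rf_b = replicate_fractions(cfu_b, mb[comm])
        dist = l1_error(rf_a.mean(), rf_b.mean().reorder(rf_a.species_ids))
        comps.append(
            {
                "community": "-".join(comm),
                "l1_distance": dist,
                "noise_floor_a": replicate_noise_floor(list(rf_a.fractions), "l1")
                if len(rf_a.fractions) >= 2
                else math.nan,
                "noise_floor_b": replicate_noise_floor(list(rf_b.fractions), "l1")
                if len(rf_b.fractions) >= 2
                else math.nan,
            }
        )
    if not shared_sp and not shared_pairs and not comps:
        raise ValidationError("no overlapping conditions between the two strains")
    return {
        "host_a": host_a,
        "host_b": host_b,
        "monoculture_ratios": mono_ratios,
        "pair_fraction_correlation": frac_corr,
        "n_shared_pairs": len(shared_pairs),
        "multispecies": pd.DataFrame(comps),
    }
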
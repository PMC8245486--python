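"""Per-condition composition summaries and pairwise interaction statistics.

Given replicate CFU counts this module computes fractional abundances,
classifies pair outcomes as coexistence or competitive exclusion against a
detection-motivated threshold (default 2%, just above the ~1% limit set by
the number of colonies counted), estimates relative yields by joint
bootstrap over co-culture and monoculture counts, summarizes competitive
ability, and tests measured pair compositions against a non-interacting
null model built purely from monoculture population sizes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import child_rng
from .data_model import (
    CFUTable,
    CompositionVector,
    Condition,
    ValidationError,
    mean_and_sem,
)

__all__ = [
    "ReplicateFractions",
    "PairwiseOutcome",
    "RelativeYield",
    "CompetitionMatrix",
    "replicate_fractions",
    "classify_pair",
    "pair_outcome",
    "pairwise_outcomes",
    "relative_yield",
    "competitive_ability",
    "null_combination_fractions",
    "null_expectation_pair",
    "null_deviation_test",
    "fdr_adjust",
    "community_size_check",
    "build_competition_matrix",
    "null_model_report",
]

COEXISTENCE = "coexistence"


def exclusion_of(species_id: str) -> str:
    return f"exclusion_of_{species_id}"


@dataclass
class ReplicateFractions:
    """Per-replicate compositions of one condition.

    Zero-total replicates (a worm batch with no CFU) carry no compositional
    information; they are excluded from the fraction matrix but recorded in
    ``excluded_replicates``.
    """

    condition: Condition
    species_ids: tuple[str, ...]
    fractions: np.ndarray  # (n_used_replicates, n_species)
    replicates: tuple[int, ...]
    excluded_replicates: tuple[int, ...] = ()

    def vectors(self) -> list[CompositionVector]:
        return [
            CompositionVector.from_counts(self.species_ids, row)
            for row in self.fractions
        ]

    def mean(self) -> CompositionVector:
        m = self.fractions.mean(axis=0)
        return CompositionVector(tuple(self.species_ids), tuple((m / m.sum()).tolist()))

    def sem(self) -> np.ndarray:
        if len(self.fractions) < 2:
            return np.full(self.fractions.shape[1], np.nan)
        return self.fractions.std(axis=0, ddof=1) / math.sqrt(len(self.fractions))


@dataclass
class PairwiseOutcome:
    """Classified outcome of one two-species co-culture condition."""

    pair: tuple[str, str]
    environment: str
    host_strain: str | None
    mean_fractions: tuple[float, float]
    sem_fractions: tuple[float, float]
    replicate_fractions: np.ndarray  # fractions of pair[0], one per replicate
    category: str
    override_applied: bool = False
    note: str = ""

    def fraction_of(self, species_id: str) -> float:
        if species_id == self.pair[0]:
            return self.mean_fractions[0]
        if species_id == self.pair[1]:
            return self.mean_fractions[1]
        raise KeyError(species_id)

    @property
    def coexists(self) -> bool:
        return self.category == COEXISTENCE


@dataclass
class RelativeYield:
    """Bootstrap estimate of log relative yield of a focal species in co-culture."""

    focal: str
    partner: str
    log_ry_mean: float
    log_ry_sem: float
    n_boot: int


class CompetitionMatrix:
    """Mean pairwise fractional abundances with s.e.m. and replicate backing.

    ``F.loc[i, j]`` is the mean fraction of species i in co-culture with j;
    complementarity ``F[i,j] + F[j,i] == 1`` holds wherever both are
    measured.  ``replicate_fractions[(i, j)]`` holds per-replicate fractions
    of i with j.
    """

    def __init__(
        self,
        species_ids: Sequence[str],
        F: pd.DataFrame,
        sem: pd.DataFrame,
        replicate_fractions: Mapping[tuple[str, str], np.ndarray] | None = None,
        source: str = "",
    ):
        self.species_ids = tuple(species_ids)
        self.F = F
        self.sem = sem
        self.replicate_fractions = dict(replicate_fractions or {})
        self.source = source

    def measured_pairs(self) -> list[tuple[str, str]]:
        return [
            (i, j)
            for i, j in itertools.combinations(self.species_ids, 2)
            if np.isfinite(self.F.loc[i, j])
        ]

    def is_complete(self) -> bool:
        return len(self.measured_pairs()) == math.comb(len(self.species_ids), 2)

    def get(self, i: str, j: str) -> float:
        v = self.F.loc[i, j]
        if not np.isfinite(v):
            raise KeyError(f"pair ({i}, {j}) not measured")
        return float(v)

    def relabel(self, mapping: Mapping[str, str]) -> "CompetitionMatrix":
        sp = tuple(mapping[s] for s in self.species_ids)
        F = self.F.rename(index=mapping, columns=mapping)
        sem = self.sem.rename(index=mapping, columns=mapping)
        reps = {
            (mapping[i], mapping[j]): v for (i, j), v in self.replicate_fractions.items()
        }
        return CompetitionMatrix(sp, F, sem, reps, self.source)

    @classmethod
    def from_fractions(
        cls,
        pair_fractions: Mapping[tuple[str, str], float],
        species_ids: Sequence[str] | None = None,
        source: str = "",
    ) -> "CompetitionMatrix":
        """Build from a {(i, j): mean fraction of i with j} mapping."""
        if species_ids is None:
            species_ids = sorted({s for p in pair_fractions for s in p})
        sp = tuple(species_ids)
        F = pd.DataFrame(np.nan, index=sp, columns=sp)
        for (i, j), f in pair_fractions.items():
            F.loc[i, j] = f
            if (j, i) not in pair_fractions:
                F.loc[j, i] = 1.0 - f
        sem = pd.DataFrame(np.nan, index=sp, columns=sp)
        return cls(sp, F, sem, source=source)


# ---------------------------------------------------------------------------
# fractional abundances and outcome classification


def replicate_fractions(cfu: CFUTable, condition: Condition) -> ReplicateFractions:
    """Per-replicate fractional abundances of one condition."""
    wide = cfu.replicate_counts(condition)
    totals = wide.sum(axis=1)
    used = totals > 0
    if not used.any():
        raise ValidationError(
            f"all replicates of condition {condition} have zero total CFU"
        )
    fr = wide[used].div(totals[used], axis=0)
    return ReplicateFractions(
        condition=condition,
        species_ids=tuple(condition.fed_community),
        fractions=fr.to_numpy(dtype=float),
        replicates=tuple(int(r) for r in wide.index[used]),
        excluded_replicates=tuple(int(r) for r in wide.index[~used]),
    )


def classify_pair(
    mean_fractions: Sequence[float],
    pair: tuple[str, str],
    threshold: float = 0.02,
    overrides: Iterable[tuple[tuple[str, str], str, str]] = (),
) -> tuple[str, bool, str]:
    """Coexistence/exclusion classification of a pair's mean composition.

    The pair coexists when the rarer species' mean fraction exceeds
    ``threshold``; otherwise the minority is competitively excluded.
    ``overrides`` is a list of ((i, j), category, note) entries that replace
    the rule for specific pairs (e.g. when the presence of a rare species is
    confirmed in multiple replicates despite a sub-threshold mean).

    Returns (category, override_applied, note).
    """
    if not 0.0 < threshold < 0.5:
        raise ValidationError(f"threshold must lie in (0, 0.5), got {threshold}")
    if len(mean_fractions) != 2 or len(pair) != 2:
        raise ValidationError("classify_pair needs exactly two species")
    for ov_pair, category, note in overrides:
        if set(ov_pair) == set(pair):
            return category, True, note
    f0, f1 = float(mean_fractions[0]), float(mean_fractions[1])
    minority = 0 if f0 <= f1 else 1
    if mean_fractions[minority] > threshold:
        return COEXISTENCE, False, ""
    return exclusion_of(pair[minority]), False, ""


def pair_outcome(
    cfu: CFUTable,
    condition: Condition,
    threshold: float = 0.02,
    overrides: Iterable[tuple[tuple[str, str], str, str]] = (),
) -> PairwiseOutcome:
    """Full classified outcome of one two-species condition."""
    if condition.n_species != 2:
        raise ValidationError(f"condition {condition} is not a pair")
    rf = replicate_fractions(cfu, condition)
    mean = rf.mean()
    sem = rf.sem()
    category, applied, note = classify_pair(
        mean.fractions, tuple(condition.fed_community), threshold, overrides
    )
    return PairwiseOutcome(
        pair=tuple(condition.fed_community),
        environment=condition.environment,
        host_strain=condition.host_strain,
        mean_fractions=(mean.fractions[0], mean.fractions[1]),
        sem_fractions=(float(sem[0]), float(sem[1])),
        replicate_fractions=rf.fractions[:, 0].copy(),
        category=category,
        override_applied=applied,
        note=note,
    )


def pairwise_outcomes(
    cfu: CFUTable,
    environment: str = "worm",
    host_strain: str | None = "AU37",
    threshold: float = 0.02,
    overrides: Iterable[tuple[tuple[str, str], str, str]] = (),
) -> list[PairwiseOutcome]:
    """Classified outcomes of every two-species condition in one environment."""
    out = []
    for cond in cfu.conditions():
        if cond.n_species != 2:
            continue
        if cond.environment != environment:
            continue
        if environment == "worm" and cond.host_strain != host_strain:
            continue
        out.append(pair_outcome(cfu, cond, threshold, overrides))
    return out


# ---------------------------------------------------------------------------
# relative yield


def relative_yield(
    mono_counts: Sequence[float],
    co_counts: Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    focal: str = "",
    partner: str = "",
) -> RelativeYield:
    """Bootstrap log relative yield of a species in co-culture.

    Each bootstrap iteration resamples the co-culture and monoculture count
    vectors with replacement and evaluates

        log RY = < log((N_co + 1) / <N_mono + 1>) >

    i.e. the mean over resampled co-culture counts of the log ratio to the
    resampled monoculture mean (+1 pseudocounts keep everything finite; the
    log scale makes the calculation symmetric in numerator/denominator
    choice).  Reported mean and s.e. are the mean and standard deviation of
    the bootstrap distribution.  Natural log.
    """
    mono = np.asarray(mono_counts, dtype=float)
    co = np.asarray(co_counts, dtype=float)
    if mono.size == 0 or co.size == 0:
        raise ValidationError("relative_yield requires non-empty count lists")
    if n_boot < 2:
        raise ValidationError("n_boot must be at least 2")
    rng = child_rng(seed, "relative_yield", focal, partner)
    co_idx = rng.integers(0, co.size, size=(n_boot, co.size))
    mono_idx = rng.integers(0, mono.size, size=(n_boot, mono.size))
    mono_means = (mono[mono_idx] + 1.0).mean(axis=1)
    vals = np.log(co[co_idx] + 1.0).mean(axis=1) - np.log(mono_means)
    return RelativeYield(
        focal=focal,
        partner=partner,
        log_ry_mean=float(vals.mean()),
        log_ry_sem=float(vals.std(ddof=1)),
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# competitive ability


def competitive_ability(M: CompetitionMatrix, species_id: str) -> tuple[float, float]:
    """Mean fractional abundance of a species across all its measured co-cultures.

    The s.e. is propagated from the per-pair s.e.m.s as sqrt(sum sem^2)/m
    over the m opponents.
    """
    fs, sems = [], []
    for j in M.species_ids:
        if j == species_id:
            continue
        v = M.F.loc[species_id, j]
        if np.isfinite(v):
            fs.append(float(v))
            sems.append(float(M.sem.loc[species_id, j]))
    if not fs:
        raise ValidationError(f"species {species_id} has no measured opponents")
    mean = float(np.mean(fs))
    sems = np.asarray(sems)
    sem = float(np.sqrt(np.nansum(sems**2)) / len(fs)) if len(sems) else math.nan
    return mean, sem


def competitive_abilities(M: CompetitionMatrix) -> pd.DataFrame:
    """Competitive ability of every species, as a tidy table."""
    recs = []
    for s in M.species_ids:
        mean, sem = competitive_ability(M, s)
        recs.append({"species_id": s, "ability": mean, "sem": sem})
    return pd.DataFrame(recs).set_index("species_id")


# ---------------------------------------------------------------------------
# monoculture null model


def null_combination_fractions(
    mono_i: Sequence[float], mono_j: Sequence[float]
) -> np.ndarray:
    """Fraction of species i over all ordered monoculture replicate combinations.

    The non-interacting null assumes each species reaches its monoculture
    population size; a pair composition is then N_i / (N_i + N_j) for every
    combination of one replicate of each.  A combination with both counts
    zero contributes 0.5 (symmetric ignorance; cannot occur on realistic
    inputs).
    """
    a = np.asarray(mono_i, dtype=float)
    b = np.asarray(mono_j, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("null expectation requires non-empty monoculture lists")
    A = a[:, None]
    B = b[None, :]
    tot = A + B
    with np.errstate(invalid="ignore", divide="ignore"):
        fr = np.where(tot > 0, A / np.where(tot > 0, tot, 1.0), 0.5)
    return fr.ravel()


def null_expectation_pair(
    mono_i: Sequence[float], mono_j: Sequence[float]
) -> tuple[float, float]:
    """Mean and s.e.m. of the non-interacting null fraction of species i.

    The s.e.m. uses n equal to the least number of monoculture replicates
    (the combinations are not independent samples; the smaller replicate
    pool limits the information content).
    """
    fr = null_combination_fractions(mono_i, mono_j)
    n_min = min(len(mono_i), len(mono_j))
    _, sem = mean_and_sem(fr, n_override=n_min)
    return float(fr.mean()), sem


def null_deviation_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    n_b: int | None = None,
) -> tuple[float, float]:
    """Welch's unequal-variance two-sample t test (two-sided).

    ``n_b`` overrides the effective sample size of the second sample in the
    standard error and Welch–Satterthwaite degrees of freedom.  This is used
    when the second sample is the enumerated null-combination fractions,
    whose elements are not independent: the effective n is the least number
    of monoculture replicates, matching the null s.e.m. convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("null_deviation_test requires >= 2 values per sample")
    if n_b is None:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    if n_b < 2:
        raise ValidationError("effective n_b must be >= 2")
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / n_b
    se = math.sqrt(va + vb)
    if se == 0:
        return 0.0, 1.0
    t = (a.mean() - b.mean()) / se
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def community_size_check(
    cfu: CFUTable, pair_condition: Condition
) -> dict[str, float | str]:
    """Compare total co-culture community size against the larger monoculture.

    Low relative yields could in principle reflect competition for fixed
    space; a co-culture total below the larger monoculture mean indicates
    suppression beyond a shared capacity ceiling.
    """
    if pair_condition.n_species != 2:
        raise ValidationError("community_size_check expects a pair condition")
    co_total = float(
        cfu.replicate_counts(pair_condition).sum(axis=1).mean()
    )
    mono_means = []
    for sp in pair_condition.fed_community:
        mono_cond = Condition(
            environment=pair_condition.environment,
            fed_community=(sp,),
            host_strain=pair_condition.host_strain,
            unit=pair_condition.unit,
        )
        try:
            wide = cfu.replicate_counts(mono_cond)
        except KeyError as e:
            raise ValidationError(
                f"monoculture of {sp} missing for {pair_condition}"
            ) from e
        mono_means.append(float(wide[sp].mean()))
    max_mono = max(mono_means)
    ratio = co_total / max_mono if max_mono > 0 else math.inf
    return {
        "pair": "-".join(pair_condition.fed_community),
        "co_total": co_total,
        "max_mono": max_mono,
        "ratio": ratio,
        "flag": "lower" if ratio < 1 else "not_lower",
    }


# ---------------------------------------------------------------------------
# assembling the competition matrix and the per-pair null-model report


def build_competition_matrix(
    cfu: CFUTable,
    environment: str = "worm",
    host_strain: str | None = "AU37",
    species_ids: Sequence[str] | None = None,
) -> CompetitionMatrix:
    """Mean pair fraction matrix from all two-species conditions in one environment."""
    F_entries: dict[tuple[str, str], tuple[float, float, np.ndarray]] = {}
    for cond in cfu.conditions():
        if cond.n_species != 2 or cond.environment != environment:
            continue
        if environment == "worm" and cond.host_strain != host_strain:
            continue
        rf = replicate_fractions(cfu, cond)
        mean = rf.mean()
        sem = rf.sem()
        i, j = cond.fed_community
        F_entries[(i, j)] = (mean.fractions[0], float(sem[0]), rf.fractions[:, 0].copy())
        F_entries[(j, i)] = (mean.fractions[1], float(sem[1]), rf.fractions[:, 1].copy())
    if not F_entries:
        raise ValidationError(
            f"no pair conditions found for environment={environment!r}, "
            f"host_strain={host_strain!r}"
        )
    if species_ids is None:
        species_ids = sorted({s for p in F_entries for s in p})
    sp = tuple(species_ids)
    F = pd.DataFrame(np.nan, index=sp, columns=sp)
    sem = pd.DataFrame(np.nan, index=sp, columns=sp)
    reps = {}
    for (i, j), (f, se, rfr) in F_entries.items():
        F.loc[i, j] = f
        sem.loc[i, j] = se
        reps[(i, j)] = rfr
    tag = environment if host_strain is None else f"{environment}/{host_strain}"
    return CompetitionMatrix(sp, F, sem, reps, source=tag)


def null_model_report(
    cfu: CFUTable,
    environment: str = "worm",
    host_strain: str | None = "AU37",
    threshold: float = 0.02,
    overrides: Iterable[tuple[tuple[str, str], str, str]] = (),
) -> pd.DataFrame:
    """Per-pair comparison of measured compositions against the monoculture null.

    One row per pair: measured mean fraction (of the first species), null
    expectation with its s.e.m., Welch t and p (effective null n = least
    monoculture replicate count), BH-FDR-adjusted p, and the outcome
    category.
    """
    recs = []
    for oc in pairwise_outcomes(cfu, environment, host_strain, threshold, overrides):
        i, j = oc.pair
        mono = {}
        for sp in oc.pair:
            cond = Condition(
                environment=environment,
                fed_community=(sp,),
                host_strain=host_strain if environment == "worm" else None,
                unit="cfu_per_worm" if environment == "worm" else "cfu_per_ml",
            )
            mono[sp] = cfu.replicate_counts(cond)[sp].to_numpy(dtype=float)
        null_fr = null_combination_fractions(mono[i], mono[j])
        null_mean, null_sem = null_expectation_pair(mono[i], mono[j])
        n_min = min(len(mono[i]), len(mono[j]))
        if len(oc.replicate_fractions) >= 2 and n_min >= 2:
            t, p = null_deviation_test(oc.replicate_fractions, null_fr, n_b=n_min)
        else:
            t, p = math.nan, math.nan
        recs.append(
            {
                "pair": f"{i}-{j}",
                "species_i": i,
                "species_j": j,
                "measured_F_i": oc.mean_fractions[0],
                "measured_sem_i": oc.sem_fractions[0],
                "null_F_i": null_mean,
                "null_sem_i": null_sem,
                "welch_t": t,
                "p": p,
                "category": oc.category,
                "override_applied": oc.override_applied,
            }
        )
    df = pd.DataFrame(recs)
    if len(df):
        ok = df["p"].notna()
        df["p_fdr"] = np.nan
        if ok.any():
            df.loc[ok, "p_fdr"] = fdr_adjust(df.loc[ok, "p"].to_numpy())
    return df
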
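"""Prediction of trio and multispecies compositions, assembly rules, and errors.

Three families of predictors for the composition of an n-species community:

* uninformed — every species at 1/n;
* monoculture null — each species reaches its monoculture population size,
  fractions are normalized monoculture means;
* normalized arithmetic mean — each species' predicted fraction is the mean
  of its pairwise fractions against the other community members, normalized
  to sum to one (the unnormalized means always sum to n/2, so for trios the
  normalization constant is exactly 2/3).

The *assembly rule* refines the pairwise predictor: a species competitively
excluded in its constituent co-cultures is removed before normalization
(default variant: removed only when excluded in *every* one of its
within-community pairs; an iterative variant drops species excluded by any
remaining member until a fixed point).

Errors between predicted and measured compositions are either the Euclidean
distance in the simplex normalized by its maximum sqrt(2), or the L1
(Manhattan) distance normalized by its maximum 2; both live in [0, 1].
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .data_model import CompositionVector, ValidationError

__all__ = [
    "PredictionResult",
    "PredictionError",
    "predict_from_monocultures",
    "arithmetic_mean_prediction",
    "survivors_from_fractions",
    "apply_assembly_rule",
    "predict_pairwise",
    "simplex_error",
    "l1_error",
    "prediction_error",
    "replicate_noise_floor",
    "evaluate_predictions",
    "bootstrap_cloud_mono",
    "bootstrap_cloud_pairwise",
]

METRICS = ("simplex", "l1")


@dataclass
class PredictionResult:
    community: tuple[str, ...]
    method: str
    predicted: CompositionVector
    survivors: tuple[str, ...]
    cloud: list[CompositionVector] = field(default_factory=list)
    assembly_rule_applied: bool = False


@dataclass
class PredictionError:
    metric: str
    value: float
    ci: tuple[float, float] | None = None
    noise_floor: float | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.value <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# predictors


def predict_from_monocultures(
    mono_means: Mapping[str, float], community: Sequence[str]
) -> CompositionVector:
    """Non-interacting prediction: fractions proportional to monoculture sizes."""
    community = tuple(community)
    missing = [s for s in community if s not in mono_means]
    if missing:
        raise ValidationError(f"no monoculture data for {missing}")
    means = np.array([float(mono_means[s]) for s in community])
    if means.sum() <= 0:
        raise ValidationError("all monoculture means are zero")
    return CompositionVector.from_counts(community, means)


def _pair_fraction_lookup(
    pair_fractions: Mapping[tuple[str, str], float], i: str, j: str
) -> float:
    if (i, j) in pair_fractions:
        return float(pair_fractions[(i, j)])
    if (j, i) in pair_fractions:
        return 1.0 - float(pair_fractions[(j, i)])
    raise ValidationError(f"pair ({i}, {j}) has no measured fractions")


def _as_pair_fractions(M) -> Mapping[tuple[str, str], float]:
    """Accept either a CompetitionMatrix or a {(i, j): F_i|j} mapping."""
    if hasattr(M, "F"):
        return {
            (i, j): float(M.F.loc[i, j])
            for i in M.species_ids
            for j in M.species_ids
            if i != j and np.isfinite(M.F.loc[i, j])
        }
    return M


def arithmetic_mean_prediction(M, community: Sequence[str]) -> CompositionVector:
    """Normalized arithmetic mean of pairwise fractions within the community.

    m_i = mean over community opponents j of F[i][j]; predicted fraction is
    m_i / sum(m).  The unnormalized means always sum to n/2, so for a trio
    the normalization constant is exactly 2/3; at n = 2 this returns the
    pair fractions themselves.
    """
    community = tuple(community)
    if len(community) < 2:
        raise ValidationError("arithmetic_mean_prediction needs >= 2 species")
    pf = _as_pair_fractions(M)
    means = np.array(
        [
            np.mean([_pair_fraction_lookup(pf, i, j) for j in community if j != i])
            for i in community
        ]
    )
    return CompositionVector.from_counts(community, means)


def survivors_from_fractions(
    pair_fractions: Mapping[tuple[str, str], float],
    community: Sequence[str],
    threshold: float = 0.02,
    variant: str = "excluded_in_all",
) -> tuple[str, ...]:
    """Assembly-rule survivor set from mean pair fractions.

    A species is *excluded by* an opponent when its mean fraction in that
    pair is at or below ``threshold``.  Variants:

    excluded_in_all
        Drop a species only if it is excluded in every one of its
        within-community pairs (the default).
    excluded_by_any_survivor
        Iteratively drop species excluded by a remaining member, one at a
        time (the one with the most surviving excluders first, ties broken
        by community order), until a fixed point.  One-at-a-time removal
        matters: a species whose only excluder is itself dropped is
        retained.
    """
    community = tuple(community)
    if len(community) == 1:
        return community
    pf = _as_pair_fractions(pair_fractions) if hasattr(pair_fractions, "F") else pair_fractions

    def excluded_by(i: str, j: str) -> bool:
        return _pair_fraction_lookup(pf, i, j) <= threshold

    if variant == "excluded_in_all":
        surv = tuple(
            i
            for i in community
            if not all(excluded_by(i, j) for j in community if j != i)
        )
        if not surv:
            raise ValidationError("assembly rule dropped every species")
        return surv
    if variant == "excluded_by_any_survivor":
        surv = _iterative_survivors(community, excluded_by)
        if not surv:
            raise ValidationError("assembly rule dropped every species")
        return surv
    raise ValidationError(f"unknown assembly-rule variant {variant!r}")


def _iterative_survivors(community, excluded_by) -> tuple[str, ...]:
    surv = list(community)
    while True:
        n_excluders = {
            i: sum(excluded_by(i, j) for j in surv if j != i) for i in surv
        }
        candidates = [i for i in surv if n_excluders[i] > 0]
        if not candidates:
            return tuple(surv)
        worst = max(candidates, key=lambda i: (n_excluders[i], -surv.index(i)))
        surv.remove(worst)
        if not surv:
            return ()


def apply_assembly_rule(
    outcomes: Iterable,
    community: Sequence[str],
    variant: str = "excluded_in_all",
) -> tuple[str, ...]:
    """Survivor set from classified pairwise outcomes.

    ``outcomes`` are PairwiseOutcome records (their categories, including
    any overrides, define the exclusion relation: category
    ``exclusion_of_<i>`` means i is excluded by its partner).
    """
    community = tuple(community)
    excl: dict[tuple[str, str], bool] = {}
    for oc in outcomes:
        i, j = oc.pair
        excl[(i, j)] = oc.category == f"exclusion_of_{i}"
        excl[(j, i)] = oc.category == f"exclusion_of_{j}"
    need = [
        (i, j) for i, j in itertools.combinations(community, 2) if (i, j) not in excl
    ]
    if need:
        raise ValidationError(f"pairs not classified: {need}")

    def excluded_by(i: str, j: str) -> bool:
        return excl[(i, j)]

    if variant == "excluded_in_all":
        surv = tuple(
            i
            for i in community
            if not all(excluded_by(i, j) for j in community if j != i)
        )
    elif variant == "excluded_by_any_survivor":
        surv = _iterative_survivors(community, excluded_by)
    else:
        raise ValidationError(f"unknown assembly-rule variant {variant!r}")
    if not surv:
        raise ValidationError("assembly rule dropped every species")
    return surv


def predict_pairwise(
    M,
    community: Sequence[str],
    rule: bool = True,
    threshold: float = 0.02,
    variant: str = "excluded_in_all",
    outcomes: Iterable | None = None,
    method: str = "pairwise",
) -> PredictionResult:
    """Arithmetic-mean prediction with optional assembly rule.

    Survivors come from classified ``outcomes`` when given (respecting
    overrides), otherwise from the threshold applied to the mean fractions.
    Pairs involving dropped species are excluded from the means; the
    prediction is renormalized over survivors, dropped species get fraction
    zero.
    """
    community = tuple(community)
    pf = _as_pair_fractions(M)
    if rule:
        if outcomes is not None:
            surv = apply_assembly_rule(outcomes, community, variant)
        else:
            surv = survivors_from_fractions(pf, community, threshold, variant)
    else:
        surv = community
    if len(surv) == 1:
        fractions = [1.0 if s in surv else 0.0 for s in community]
        pred = CompositionVector(community, tuple(fractions))
    else:
        sub = arithmetic_mean_prediction(pf, surv).as_dict()
        pred = CompositionVector(
            community, tuple(sub.get(s, 0.0) for s in community)
        )
    return PredictionResult(
        community=community,
        method=method,
        predicted=pred,
        survivors=surv,
        assembly_rule_applied=rule,
    )


# ---------------------------------------------------------------------------
# error metrics


def _aligned(pred, meas) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pred, CompositionVector) and isinstance(meas, CompositionVector):
        if set(pred.species_ids) != set(meas.species_ids):
            raise ValidationError(
                f"species sets differ: {sorted(pred.species_ids)} vs "
                f"{sorted(meas.species_ids)}"
            )
        meas = meas.reorder(pred.species_ids)
        return pred.as_array(), meas.as_array()
    a = np.asarray(pred, dtype=float)
    b = np.asarray(meas, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch {a.shape} vs {b.shape}")
    return a, b


def simplex_error(pred, meas) -> float:
    """Euclidean distance in the simplex, normalized by the maximal sqrt(2).

    The maximum distance between two compositions is attained between two
    vertices and equals sqrt(2) for any community size, so the normalized
    error lies in [0, 1].
    """
    a, b = _aligned(pred, meas)
    return float(np.linalg.norm(a - b) / math.sqrt(2.0))


def l1_error(pred, meas) -> float:
    """L1 (Manhattan) distance between compositions, normalized by its maximum 2."""
    a, b = _aligned(pred, meas)
    return float(np.abs(a - b).sum() / 2.0)


def prediction_error(pred, meas, metric: str = "simplex") -> float:
    if metric == "simplex":
        return simplex_error(pred, meas)
    if metric == "l1":
        return l1_error(pred, meas)
    raise ValidationError(f"metric must be one of {METRICS}, got {metric!r}")


def replicate_noise_floor(
    replicate_compositions: Sequence, metric: str = "simplex"
) -> float:
    """Mean distance between each replicate composition and the replicate mean.

    Batch-to-batch variability bounds any predictor from below: a prediction
    cannot be expected to match a measured mean more closely than individual
    replicates do.
    """
    comps = list(replicate_compositions)
    if len(comps) < 2:
        raise ValidationError("noise floor requires >= 2 replicate compositions")
    if isinstance(comps[0], CompositionVector):
        sp = comps[0].species_ids
        arr = np.stack([c.reorder(sp).as_array() for c in comps])
    else:
        arr = np.stack([np.asarray(c, dtype=float) for c in comps])
    mean = arr.mean(axis=0)
    return float(np.mean([prediction_error(row, mean, metric) for row in arr]))


# ---------------------------------------------------------------------------
# bootstrap clouds


def bootstrap_cloud_mono(
    mono_replicates: Mapping[str, Sequence[float]],
    community: Sequence[str],
    n_boot: int = 400,
    seed: int = 0,
) -> list[CompositionVector]:
    """Bootstrap cloud of the monoculture prediction (resampling replicates)."""
    community = tuple(community)
    rng = child_rng(seed, "cloud_mono", *community)
    reps = {s: np.asarray(mono_replicates[s], dtype=float) for s in community}
    cloud = []
    for _ in range(n_boot):
        means = {
            s: float(rng.choice(reps[s], size=len(reps[s]), replace=True).mean())
            for s in community
        }
        if sum(means.values()) <= 0:
            continue
        cloud.append(predict_from_monocultures(means, community))
    return cloud


def bootstrap_cloud_pairwise(
    replicate_pair_fractions: Mapping[tuple[str, str], Sequence[float]],
    community: Sequence[str],
    survivors: Sequence[str] | None = None,
    n_boot: int = 400,
    seed: int = 0,
) -> list[CompositionVector]:
    """Bootstrap cloud of the arithmetic-mean prediction.

    ``replicate_pair_fractions[(i, j)]`` holds per-replicate fractions of i
    in co-culture with j.  Each iteration resamples every pair's replicates,
    recomputes the mean fraction matrix, and re-runs the prediction over a
    fixed survivor set (point-estimate survivors by default), so the cloud
    reflects compositional uncertainty rather than rule flips.
    """
    community = tuple(community)
    surv = tuple(survivors) if survivors is not None else community
    rng = child_rng(seed, "cloud_pairwise", *community)
    reps = {
        pair: np.asarray(v, dtype=float)
        for pair, v in replicate_pair_fractions.items()
    }
    cloud = []
    for _ in range(n_boot):
        pf = {}
        for (i, j), v in reps.items():
            pf[(i, j)] = float(rng.choice(v, size=len(v), replace=True).mean())
        if len(surv) == 1:
            comp = CompositionVector(
                community, tuple(1.0 if s in surv else 0.0 for s in community)
            )
        else:
            sub = arithmetic_mean_prediction(pf, surv).as_dict()
            comp = CompositionVector(
                community, tuple(sub.get(s, 0.0) for s in community)
            )
        cloud.append(comp)
    return cloud


# ---------------------------------------------------------------------------
# study-level evaluation


def evaluate_predictions(
    cfu,
    communities: Sequence[Sequence[str]] | None = None,
    methods: Sequence[str] = (
        "uninformed",
        "monoculture_null",
        "pairwise",
        "pairwise_rule",
    ),
    metric: str = "simplex",
    environment: str = "worm",
    host_strain: str | None = "AU37",
    pair_environment: str | None = None,
    pair_host_strain: str | None = "AU37",
    threshold: float = 0.02,
    variant: str = "excluded_in_all",
) -> pd.DataFrame:
    """Prediction errors for every measured multispecies community in a table.

    Method tokens: ``uninformed`` (1/n each), ``monoculture_null``
    (normalized monoculture means), ``pairwise`` (normalized arithmetic mean
    without assembly rule), ``pairwise_rule`` (with it).  ``pair_environment``
    lets the pairwise predictors draw their fraction matrix from a different
    environment than the measured communities (e.g. predict worm trios from
    media pairs); it defaults to ``environment``.

    Returns one row per (community, method) with the prediction error and
    the community's replicate noise floor; a method lacking inputs yields a
    NaN error rather than aborting the run.
    """
    from .composition import build_competition_matrix, replicate_fractions
    from .data_model import CFUTable, Condition

    if isinstance(cfu, CFUTable):
        table = cfu
    else:  # SimulatedStudy
        table = cfu.cfu_table

    pair_env = pair_environment or environment
    pair_host = pair_host_strain if pair_env == "worm" else None
    unit = "cfu_per_worm" if environment == "worm" else "cfu_per_ml"
    host = host_strain if environment == "worm" else None

    if communities is None:
        communities = [
            c.fed_community
            for c in table.conditions()
            if c.n_species >= 3 and c.environment == environment and c.host_strain == host
        ]

    try:
        M = build_competition_matrix(table, pair_env, pair_host)
    except ValidationError:
        M = None
    mono_means: dict[str, float] = {}
    for cond in table.conditions():
        if cond.n_species == 1 and cond.environment == environment and cond.host_strain == host:
            sp = cond.fed_community[0]
            mono_means[sp] = float(table.replicate_counts(cond)[sp].mean())

    recs = []
    for comm in communities:
        comm = tuple(comm)
        cond = Condition(environment, comm, host, unit)
        rf = replicate_fractions(table, cond)
        measured = rf.mean()
        floor = (
            replicate_noise_floor(list(rf.fractions), metric)
            if len(rf.fractions) >= 2
            else math.nan
        )
        for method in methods:
            err = math.nan
            try:
                if method == "uninformed":
                    pred = CompositionVector(
                        comm, tuple([1.0 / len(comm)] * len(comm))
                    )
                elif method == "monoculture_null":
                    pred = predict_from_monocultures(mono_means, comm)
                elif method == "pairwise":
                    pred = predict_pairwise(M, comm, rule=False).predicted
                elif method == "pairwise_rule":
                    pred = predict_pairwise(
                        M, comm, rule=True, threshold=threshold, variant=variant
                    ).predicted
                else:
                    raise ValidationError(f"unknown method {method!r}")
                err = prediction_error(pred, measured, metric)
            except (ValidationError, KeyError, TypeError):
                err = math.nan
            recs.append(
                {
                    "community": "-".join(comm),
                    "n_species": len(comm),
                    "method": method,
                    "metric": metric,
                    "error": err,
                    "noise_floor": floor,
                }
            )
    return pd.DataFrame(recs)
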
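"""Competitive-hierarchy quantification and intransitivity detection.

The pairwise fraction matrix defines a tournament: ranking species by
competitive ability (mean fraction across co-cultures), the *hierarchy
score* is the mean fraction of the higher-ranked species over all ranked
pairs — 1 for a strict pecking order, 0.5 for no ordering at all.
Significance comes from a permutation null that reassigns the measured
fraction values (with their complements) to pair slots, preserving the
multiset of fractional abundances, and re-derives each null matrix's own
ranking before scoring.

Intransitivity is a rock–paper–scissors cycle among three species: in the
strict sense each species competitively excludes the next (fraction of the
loser at or below the detection threshold); in the relaxed sense it merely
outnumbers it (fraction > 0.5).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .composition import CompetitionMatrix, competitive_abilities
from .data_model import ValidationError

__all__ = [
    "HierarchyResult",
    "IntransitivityReport",
    "hierarchy_score",
    "find_intransitive_trios",
]


@dataclass
class HierarchyResult:
    score: float
    ranking: tuple[str, ...]
    null_scores: np.ndarray
    p_value: float
    n_perm: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.score <= 1.0
        assert 0.0 < self.p_value <= 1.0


@dataclass
class IntransitivityReport:
    mode: str
    cycles: list[tuple[str, str, str]]
    n_trios_scanned: int
    indeterminate: list[tuple[str, str, str]] = field(default_factory=list)


def _ranking(
    M: CompetitionMatrix, mono_means: Mapping[str, float] | None = None
) -> tuple[str, ...]:
    """Species sorted by competitive ability, descending.

    Ties broken by larger monoculture mean (when provided), then
    lexicographic species id — deterministic.
    """
    ab = competitive_abilities(M)["ability"]
    mono = mono_means or {}

    def key(s: str):
        return (-ab[s], -float(mono.get(s, 0.0)), s)

    return tuple(sorted(M.species_ids, key=key))


def _score_given_ranking(F: np.ndarray, order: np.ndarray) -> float:
    """Mean fraction of the higher-ranked species over all ordered pairs."""
    vals = [
        F[order[a], order[b]]
        for a in range(len(order))
        for b in range(a + 1, len(order))
    ]
    return float(np.mean(vals))


def hierarchy_score(
    M: CompetitionMatrix,
    n_perm: int = 100_000,
    seed: int = 0,
    mono_means: Mapping[str, float] | None = None,
    score_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> HierarchyResult:
    """Hierarchy score of a competition matrix with a permutation null.

    The null reassigns the measured fraction/complement values to random
    pair slots with random orientation ("random matrices with the same
    distribution of fractional abundances"); each null matrix is re-ranked
    by its own competitive abilities before scoring, so the null does not
    inherit the observed ordering.  p = (1 + #{null >= observed}) /
    (1 + n_perm).

    ``score_fn(F, order)`` may replace the default score (mean
    winner-fraction over ranked pairs) with another variant.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not M.is_complete():
        missing = set(itertools.combinations(M.species_ids, 2)) - {
            tuple(sorted(p)) for p in M.measured_pairs()
        }
        raise ValidationError(f"unmeasured pairs: {sorted(missing)}")

    sp = M.species_ids
    n = len(sp)
    F = M.F.loc[list(sp), list(sp)].to_numpy(dtype=float)
    np.fill_diagonal(F, 0.0)

    ranking = _ranking(M, mono_means)
    order = np.array([sp.index(s) for s in ranking])
    fn = score_fn or _score_given_ranking
    observed = fn(F, order)

    pairs = list(itertools.combinations(range(n), 2))
    m = len(pairs)
    v = np.array([F[a, b] for a, b in pairs])
    a_idx = np.array([a for a, _ in pairs])
    b_idx = np.array([b for _, b in pairs])
    rng = child_rng(seed, "hierarchy_null")

    if score_fn is None:
        null_scores = _null_scores_vectorized(v, a_idx, b_idx, n, n_perm, rng)
    else:
        null_scores = np.empty(n_perm)
        for k in range(n_perm):
            w = v[rng.permutation(m)]
            flip = rng.random(m) < 0.5
            w = np.where(flip, 1.0 - w, w)
            Fk = np.zeros((n, n))
            Fk[a_idx, b_idx] = w
            Fk[b_idx, a_idx] = 1.0 - w
            ab = Fk.sum(axis=1) / (n - 1)
            order_k = np.lexsort((np.arange(n), -ab))
            null_scores[k] = fn(Fk, order_k)

    p = (1.0 + float((null_scores >= observed - 1e-12).sum())) / (1.0 + n_perm)
    return HierarchyResult(
        score=observed,
        ranking=ranking,
        null_scores=null_scores,
        p_value=p,
        n_perm=n_perm,
    )


def _null_scores_vectorized(
    v: np.ndarray,
    a_idx: np.ndarray,
    b_idx: np.ndarray,
    n: int,
    n_perm: int,
    rng: np.random.Generator,
    batch: int = 20_000,
) -> np.ndarray:
    """Permutation-null hierarchy scores, batched over permutations.

    For each permutation the measured values are shuffled across pair slots
    and randomly oriented; competitive abilities, the implied ranking, and
    the score are computed with array ops (ties in null abilities have
    probability zero for continuous fraction values; argsort order breaks
    any that occur deterministically).
    """
    m = len(v)
    out = np.empty(n_perm)
    done = 0
    inc_a = np.zeros((m, n))
    inc_b = np.zeros((m, n))
    inc_a[np.arange(m), a_idx] = 1.0
    inc_b[np.arange(m), b_idx] = 1.0
    while done < n_perm:
        B = min(batch, n_perm - done)
        idx = np.argsort(rng.random((B, m)), axis=1)
        W = v[idx]
        flip = rng.random((B, m)) < 0.5
        W = np.where(flip, 1.0 - W, W)
        ability = W @ inc_a + (1.0 - W) @ inc_b  # row sums per species
        # rank position of each species (0 = top) per permutation
        order = np.argsort(-ability, axis=1, kind="stable")
        rank = np.empty_like(order)
        rows = np.arange(B)[:, None]
        rank[rows, order] = np.arange(n)[None, :]
        a_rank = rank[:, a_idx]
        b_rank = rank[:, b_idx]
        winner_frac = np.where(a_rank < b_rank, W, 1.0 - W)
        out[done : done + B] = winner_frac.mean(axis=1)
        done += B
    return out


def find_intransitive_trios(
    M: CompetitionMatrix,
    mode: str = "strict",
    exclusion_threshold: float = 0.02,
) -> IntransitivityReport:
    """Scan all trios of a competition matrix for rock–paper–scissors cycles.

    strict:  a beats b iff b's fraction against a is at or below the
             exclusion threshold (full competitive exclusion).
    relaxed: a beats b iff F[a][b] > 0.5; an exact 0.5 tie makes the trio
             indeterminate rather than a cycle.
    """
    if mode not in ("strict", "relaxed"):
        raise ValidationError(f"mode must be 'strict' or 'relaxed', got {mode!r}")
    sp = M.species_ids

    def beats(a: str, b: str) -> bool | None:
        f_ab = M.get(a, b)
        if mode == "strict":
            return (1.0 - f_ab) <= exclusion_threshold
        if f_ab == 0.5:
            return None
        return f_ab > 0.5

    cycles, indeterminate = [], []
    n_scanned = 0
    for trio in itertools.combinations(sp, 3):
        n_scanned += 1
        rel = {}
        tie = False
        for a, b in itertools.permutations(trio, 2):
            r = beats(a, b)
            if r is None:
                tie = True
            rel[(a, b)] = bool(r)
        if tie:
            indeterminate.append(trio)
            continue
        a, b, c = trio
        if rel[(a, b)] and rel[(b, c)] and rel[(c, a)]:
            cycles.append((a, b, c))
        elif rel[(b, a)] and rel[(a, c)] and rel[(c, b)]:
            cycles.append((a, c, b))
    return IntransitivityReport(
        mode=mode,
        cycles=cycles,
        n_trios_scanned=n_scanned,
        indeterminate=indeterminate,
    )
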
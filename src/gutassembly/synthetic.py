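"""Synthetic colonization experiments with known ground truth.

The generator emulates the statistical structure of bottom-up host
colonization assays: per-species carrying capacities spanning roughly two
orders of magnitude (200–20,000 CFU/worm), pairwise fractional abundances
drawn from a (possibly hierarchical) competition structure, lognormal
batch-to-batch variation in total community size, and colony-counting noise
that yields a detection limit inversely proportional to the number of
colonies counted (~1–2% at 50–100 colonies).

Multispecies (trio and larger) compositions follow the pairwise-consistent
expectation — the assembly-rule-filtered normalized arithmetic mean of the
true pair fractions — perturbed by a Dirichlet draw whose spread is
controlled by a single higher-order-interaction knob ``epsilon_hoi``:
0 means pairwise outcomes fully determine larger communities, larger values
progressively decouple them.

There is no mechanistic within-host dynamics here (no generalized
Lotka–Volterra integration, no spatial structure, no priority effects);
the generator targets the *observable* layer the analysis consumes.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import child_rng
from .data_model import CFUTable, Condition, ValidationError
from .prediction import survivors_from_fractions

__all__ = [
    "GroundTruth",
    "SimulatedStudy",
    "make_ground_truth",
    "simulate_condition",
    "simulate_study",
    "DEFAULT_DESIGN",
]

#: default carrying-capacity range (CFU/worm), spanning two orders of magnitude
K_RANGE = (2e2, 2e4)

#: replicate counts mirroring a typical colonization study design
DEFAULT_DESIGN: dict = {
    "monocultures": True,
    "pairs": "all",
    "trios": "first6",  # all trios of the first six species
    "octet": "first8",  # one community of the first eight species
    "n_replicates": {"mono": 8, "pair": 4, "trio": 4, "multi": 3},
    "environments": ["worm"],
    "host_strain": "AU37",
}


@dataclass
class GroundTruth:
    """Parameter bundle fully determining a simulated study.

    Attributes
    ----------
    species_ids : tuple of str
    K : dict
        Carrying capacity per species on the CFU/worm scale.
    s : dict
        Latent competitive score per species (hierarchical mode).
    F_true : pandas.DataFrame
        True pairwise fraction matrix; ``F_true[j][i]`` (row i, column j) is
        the fraction of species i when co-cultured with j, and
        ``F[i,j] + F[j,i] == 1``.
    epsilon_hoi : float
        Higher-order perturbation magnitude in [0, 1].
    cv_total : float
        Coefficient of variation of the total community size per replicate.
    colonies_counted : int or None
        Multinomial sampling depth of the colony count; None disables
        counting noise (infinite depth).
    F_media : pandas.DataFrame or None
        Optional environment-specific pair fractions used for media
        conditions; defaults to ``F_true``.
    """

    species_ids: tuple[str, ...]
    K: dict[str, float]
    s: dict[str, float]
    F_true: pd.DataFrame
    epsilon_hoi: float = 0.0
    cv_total: float = 0.3
    colonies_counted: int | None = 100
    seed: int = 0
    F_media: pd.DataFrame | None = None
    exclusion_threshold: float = 0.02

    def __post_init__(self) -> None:
        if not all(k > 0 for k in self.K.values()):
            raise ValidationError("carrying capacities must be positive")
        if not 0.0 <= self.epsilon_hoi <= 1.0:
            raise ValidationError("epsilon_hoi must lie in [0, 1]")
        F = self.F_true.to_numpy(dtype=float)
        if not np.allclose(F + F.T, 1.0, atol=1e-9):
            raise ValidationError("F_true[i][j] + F_true[j][i] must equal 1")

    def F_for(self, environment: str) -> pd.DataFrame:
        if environment == "media" and self.F_media is not None:
            return self.F_media
        return self.F_true

    def pair_fractions(self, environment: str = "worm") -> dict[tuple[str, str], float]:
        F = self.F_for(environment)
        return {
            (i, j): float(F.loc[i, j])
            for i in self.species_ids
            for j in self.species_ids
            if i != j
        }

    def survivors(self, community: Sequence[str], environment: str = "worm") -> tuple[str, ...]:
        """Assembly-rule survivor set: drop species excluded in all their pairs."""
        return survivors_from_fractions(
            self.pair_fractions(environment), community, self.exclusion_threshold
        )

    def pairwise_expectation(
        self, community: Sequence[str], environment: str = "worm"
    ) -> tuple[tuple[str, ...], np.ndarray]:
        """Assembly-rule-consistent normalized arithmetic mean of true pair fractions.

        Returns (survivors, fractions over the *full* community, zeros for
        dropped species).  The survivor filter applies only to communities of
        three or more species: a pair's composition is its fraction matrix
        entry itself, however small (exclusion is a downstream classification,
        not a generative rule).
        """
        community = tuple(community)
        if len(community) == 1:
            return community, np.ones(1)
        if len(community) == 2:
            F = self.F_for(environment)
            f = float(F.loc[community[0], community[1]])
            return community, np.array([f, 1.0 - f])
        surv = self.survivors(community, environment)
        F = self.F_for(environment)
        if len(surv) == 1:
            means = np.array([1.0 if i in surv else 0.0 for i in community])
        else:
            means = np.array(
                [
                    np.mean([F.loc[i, j] for j in surv if j != i]) if i in surv else 0.0
                    for i in community
                ]
            )
        return surv, means / means.sum()

    def expected_composition(
        self, community: Sequence[str], environment: str = "worm"
    ) -> np.ndarray:
        """True expected composition of a community, including the higher-order term.

        For communities of three or more species the pairwise-consistent
        expectation is perturbed by a Dirichlet draw with concentration
        ``1/epsilon_hoi`` (no perturbation at epsilon 0).  The draw is a
        fixed property of the ground truth (seeded by community), so the
        same community always has the same true composition.
        """
        community = tuple(community)
        _, expected = self.pairwise_expectation(community, environment)
        if self.epsilon_hoi <= 0 or len(community) < 3:
            return expected
        rng = child_rng(self.seed, "hoi", environment, *sorted(community))
        pos = expected > 0
        conc = expected[pos] / self.epsilon_hoi
        draw = rng.dirichlet(conc)
        out = np.zeros_like(expected)
        out[pos] = draw
        return out

    def expected_total(self, community: Sequence[str], environment: str = "worm") -> float:
        """Composition-weighted mean of surviving members' carrying capacities."""
        comp = self.expected_composition(community, environment)
        K = np.array([self.K[s] for s in community])
        return float(np.dot(comp, K))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species_ids": list(self.species_ids),
            "K": {k: float(v) for k, v in self.K.items()},
            "s": {k: float(v) for k, v in self.s.items()},
            "F_true": self.F_true.to_numpy().tolist(),
            "F_media": None if self.F_media is None else self.F_media.to_numpy().tolist(),
            "epsilon_hoi": self.epsilon_hoi,
            "cv_total": self.cv_total,
            "colonies_counted": self.colonies_counted,
            "seed": self.seed,
            "exclusion_threshold": self.exclusion_threshold,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        sp = tuple(d["species_ids"])
        mk = lambda m: None if m is None else pd.DataFrame(np.asarray(m), index=sp, columns=sp)
        return cls(
            species_ids=sp,
            K=dict(d["K"]),
            s=dict(d["s"]),
            F_true=mk(d["F_true"]),
            F_media=mk(d.get("F_media")),
            epsilon_hoi=float(d["epsilon_hoi"]),
            cv_total=float(d["cv_total"]),
            colonies_counted=d["colonies_counted"],
            seed=int(d["seed"]),
            exclusion_threshold=float(d.get("exclusion_threshold", 0.02)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SimulatedStudy:
    """A complete simulated colonization study: ground truth plus its CFU table."""

    ground_truth: GroundTruth
    cfu_table: CFUTable
    design: dict = field(default_factory=dict)


def _logistic(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(x)


def make_ground_truth(
    n_species: int,
    mode: str = "hierarchical",
    params: Mapping | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw a ground truth for a simulated colonization study.

    Modes
    -----
    hierarchical
        Each species gets a latent competitive score s_i; pair fractions are
        ``F[i][j] = logistic((s_i - s_j) / tau)``, so small ``tau`` gives
        strict dominance and equal scores give 0.5 everywhere.  Scores are
        drawn correlated with log carrying capacity (``rho_K``, default 0.8),
        reflecting that good monoculture colonizers tend to be good
        competitors.
    random_matrix
        ``F[i][j]`` drawn uniformly on (0, 1) independently per pair — the
        null case with no competitive ordering.
    supplied
        ``params['F']`` provides the fraction matrix directly.

    Parameters recognized in ``params``: tau (default 0.4), rho_K (0.8),
    k_range ((2e2, 2e4)), epsilon_hoi (0.0), cv_total (0.3),
    colonies_counted (100), s (per-species scores for hierarchical mode),
    K (per-species carrying capacities), F (supplied mode).
    """
    if n_species < 2:
        raise ValidationError("need at least two species")
    params = dict(params or {})
    rng = child_rng(seed, "ground_truth", mode)
    species = tuple(params.get("species_ids", [f"sp{i:02d}" for i in range(n_species)]))
    if len(species) != n_species:
        raise ValidationError("species_ids length must equal n_species")

    k_lo, k_hi = params.get("k_range", K_RANGE)
    if "K" in params:
        K = {s: float(params["K"][s]) for s in species}
    else:
        logk = rng.uniform(math.log10(k_lo), math.log10(k_hi), size=n_species)
        K = {s: float(10.0 ** lk) for s, lk in zip(species, logk)}

    tau = float(params.get("tau", 0.4))
    F = pd.DataFrame(np.full((n_species, n_species), np.nan), index=species, columns=species)
    if mode == "hierarchical":
        if "s" in params:
            s_vals = np.array([params["s"][sp] for sp in species], dtype=float)
        else:
            rho = float(params.get("rho_K", 0.8))
            logk = np.log10(np.array([K[sp] for sp in species]))
            z_k = (logk - logk.mean()) / (logk.std() if logk.std() > 0 else 1.0)
            z = rng.standard_normal(n_species)
            s_vals = rho * z_k + math.sqrt(max(0.0, 1.0 - rho**2)) * z
        s = {sp: float(v) for sp, v in zip(species, s_vals)}
        for a, b in itertools.combinations(range(n_species), 2):
            f = float(_logistic(np.array([(s_vals[a] - s_vals[b]) / max(tau, 1e-12)]))[0])
            if tau <= 0:  # strict dominance limit
                f = 1.0 if s_vals[a] > s_vals[b] else (0.5 if s_vals[a] == s_vals[b] else 0.0)
            F.iloc[a, b] = f
            F.iloc[b, a] = 1.0 - f
    elif mode == "random_matrix":
        s = {sp: 0.0 for sp in species}
        for a, b in itertools.combinations(range(n_species), 2):
            f = float(rng.uniform())
            F.iloc[a, b] = f
            F.iloc[b, a] = 1.0 - f
    elif mode == "supplied":
        s = {sp: float(params.get("s", {}).get(sp, 0.0)) for sp in species}
        F = pd.DataFrame(np.asarray(params["F"], dtype=float), index=species, columns=species)
    else:
        raise ValidationError(f"unknown ground-truth mode {mode!r}")
    np.fill_diagonal(F.values, np.nan)

    F_media = None
    if "F_media" in params:
        F_media = pd.DataFrame(
            np.asarray(params["F_media"], dtype=float), index=species, columns=species
        )

    return GroundTruth(
        species_ids=species,
        K=K,
        s=s,
        F_true=_complete_diag(F),
        F_media=F_media,
        epsilon_hoi=float(params.get("epsilon_hoi", 0.0)),
        cv_total=float(params.get("cv_total", 0.3)),
        colonies_counted=params.get("colonies_counted", 100),
        seed=seed,
    )


def _complete_diag(F: pd.DataFrame) -> pd.DataFrame:
    """Set the (unused) diagonal to 0.5 so the complementarity check passes."""
    out = F.copy()
    np.fill_diagonal(out.values, 0.5)
    return out


def simulate_condition(
    gt: GroundTruth,
    community: Sequence[str],
    n_replicates: int,
    environment: str = "worm",
    seed: int = 0,
    host_strain: str | None = "AU37",
    k_scale: Mapping[str, float] | None = None,
) -> list[tuple[Condition, str, int, float]]:
    """Simulate replicate CFU counts for one condition.

    Observation model per replicate: total ~ lognormal(mean = expected total,
    cv = ``gt.cv_total``); observed counts = total x (multinomial colony
    sample of depth ``gt.colonies_counted``, normalized).  Species whose true
    fraction falls below ~1/colonies_counted are therefore frequently
    unobserved, reproducing a count-depth-dependent detection limit.
    ``k_scale`` multiplies carrying capacities per species (host-strain
    effects such as immune suppression).
    """
    community = tuple(community)
    if not community:
        raise ValidationError("community must be non-empty")
    unknown = set(community) - set(gt.species_ids)
    if unknown:
        raise ValidationError(f"unknown species in community: {sorted(unknown)}")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")

    comp = gt.expected_composition(community, environment)
    K = np.array([gt.K[s] for s in community])
    if k_scale:
        K = K * np.array([float(k_scale.get(s, 1.0)) for s in community])
    total = float(np.dot(comp, K)) if len(community) > 1 else float(K[0])

    unit = "cfu_per_worm" if environment == "worm" else "cfu_per_ml"
    cond = Condition(
        environment=environment,
        fed_community=community,
        host_strain=host_strain if environment == "worm" else None,
        unit=unit,
    )
    rng = child_rng(seed, "condition", environment, host_strain, *community)
    rows = []
    for rep in range(1, n_replicates + 1):
        if gt.cv_total > 0:
            sigma = math.sqrt(math.log(1.0 + gt.cv_total**2))
            t = total * rng.lognormal(-0.5 * sigma**2, sigma)
        else:
            t = total
        if gt.colonies_counted is None or not np.isfinite(gt.colonies_counted):
            counts = t * comp
        else:
            depth = int(gt.colonies_counted)
            colonies = rng.multinomial(depth, comp)
            counts = t * colonies / depth
        for sp, c in zip(community, counts):
            rows.append((cond, sp, rep, float(c)))
    return rows


def _resolve_communities(gt: GroundTruth, design: Mapping) -> dict[str, list[tuple[str, ...]]]:
    sp = gt.species_ids
    out: dict[str, list[tuple[str, ...]]] = {"mono": [], "pair": [], "trio": [], "multi": []}
    if design.get("monocultures", True):
        out["mono"] = [(s,) for s in sp]
    pairs = design.get("pairs", "all")
    if pairs == "all":
        out["pair"] = list(itertools.combinations(sp, 2))
    elif pairs:
        out["pair"] = [tuple(p) for p in pairs]
    trios = design.get("trios")
    if trios == "first6":
        base = sp[: min(6, len(sp))]
        out["trio"] = list(itertools.combinations(base, 3))
    elif trios == "all":
        out["trio"] = list(itertools.combinations(sp, 3))
    elif trios:
        out["trio"] = [tuple(t) for t in trios]
    octet = design.get("octet")
    if octet == "first8":
        if len(sp) >= 8:
            out["multi"] = [tuple(sp[:8])]
    elif octet:
        out["multi"] = [tuple(octet)]
    for kind, comms in out.items():
        for comm in comms:
            unknown = set(comm) - set(sp)
            if unknown:
                raise ValidationError(
                    f"design requests unknown species {sorted(unknown)} in {kind} {comm}"
                )
    return out


def simulate_study(
    gt: GroundTruth, design: Mapping | None = None, seed: int = 0
) -> SimulatedStudy:
    """Simulate a full study: monocultures, pairs, optional trios and one octet.

    The default design mirrors a typical bottom-up colonization study:
    all monocultures (8 replicates), all pairs (4), all trios of the first
    six species (4), and one eight-species community (3), in the worm
    environment for one host strain.  ``design['environments']`` may add
    ``'media'`` (using ``gt.F_media`` when set); ``design['host_strains']``
    may list several worm strains with optional per-strain carrying-capacity
    multipliers in ``design['host_k_scale']``.
    """
    design = {**DEFAULT_DESIGN, **(design or {})}
    comms = _resolve_communities(gt, design)
    n_rep = {**DEFAULT_DESIGN["n_replicates"], **design.get("n_replicates", {})}
    hosts = design.get("host_strains") or [design.get("host_strain", "AU37")]
    k_scales = design.get("host_k_scale", {})

    rows: list[tuple[Condition, str, int, float]] = []
    for env in design["environments"]:
        env_hosts = hosts if env == "worm" else [None]
        for host in env_hosts:
            for kind, communities in comms.items():
                for comm in communities:
                    rows.extend(
                        simulate_condition(
                            gt,
                            comm,
                            n_replicates=int(n_rep[kind]),
                            environment=env,
                            seed=seed,
                            host_strain=host,
                            k_scale=k_scales.get(host),
                        )
                    )
    table = CFUTable.from_rows(rows)
    return SimulatedStudy(ground_truth=gt, cfu_table=table, design=dict(design))
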
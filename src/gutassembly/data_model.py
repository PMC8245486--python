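"""Domain types, table and tree I/O, and validation shared by every analysis stage.

The raw substrate of the whole pipeline is a *CFU table*: one row per
{environment, host strain, fed community, species, replicate} holding a
colony-forming-unit count (CFU/worm for in-vivo conditions, CFU/mL for
in-vitro media cultures).  Everything downstream — fractional abundances,
pairwise outcomes, relative yields, hierarchy, predictions — is a function
of this table, a species metadata table, and optionally a phylogenetic tree.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SpeciesInfo",
    "Condition",
    "CFUTable",
    "PhyloDistances",
    "CompositionVector",
    "SchemaError",
    "ValidationError",
    "read_cfu_table",
    "write_cfu_table",
    "read_species_table",
    "read_tree_distances",
    "mean_and_sem",
]

#: canonical column order of the on-disk CFU table
CFU_COLUMNS = (
    "environment",
    "host_strain",
    "community",
    "species_id",
    "replicate",
    "count",
    "unit",
)

#: separator used to join species ids into the ``community`` column
COMMUNITY_SEP = ";"

ENVIRONMENTS = ("worm", "media")
UNITS = ("cfu_per_worm", "cfu_per_ml")
ORIGINS = ("native", "non_native")


class SchemaError(ValueError):
    """A required column cannot be resolved in an input table."""


class ValidationError(ValueError):
    """Input data violates a structural invariant (negative count, missing row...)."""


@dataclass(frozen=True)
class SpeciesInfo:
    """Metadata for one bacterial species/isolate.

    ``origin`` distinguishes isolates taken from wild *C. elegans*
    intestines (``native``) from laboratory strains with no prior worm
    association (``non_native``).
    """

    species_id: str
    label: str = ""
    origin: str = "non_native"
    collection: str = ""
    taxonomy: str = ""

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValidationError(
                f"origin must be one of {ORIGINS}, got {self.origin!r}"
            )


@dataclass(frozen=True)
class Condition:
    """One experimental condition: which community was fed, where, to whom.

    ``host_strain`` is present exactly when ``environment == 'worm'`` (e.g.
    AU37, SS104, N2); media cultures carry no host.
    """

    environment: str
    fed_community: tuple[str, ...]
    host_strain: str | None = None
    unit: str = "cfu_per_worm"

    def __post_init__(self) -> None:
        if self.environment not in ENVIRONMENTS:
            raise ValidationError(
                f"environment must be one of {ENVIRONMENTS}, got {self.environment!r}"
            )
        if self.unit not in UNITS:
            raise ValidationError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if not self.fed_community:
            raise ValidationError("fed_community must be non-empty")
        if len(set(self.fed_community)) != len(self.fed_community):
            raise ValidationError(
                f"fed_community has duplicates: {self.fed_community}"
            )
        if (self.environment == "worm") != (self.host_strain is not None):
            raise ValidationError(
                "host_strain must be present iff environment == 'worm' "
                f"(environment={self.environment!r}, host_strain={self.host_strain!r})"
            )

    @property
    def community_key(self) -> str:
        return COMMUNITY_SEP.join(self.fed_community)

    @property
    def n_species(self) -> int:
        return len(self.fed_community)

    def __str__(self) -> str:  # compact, used in error messages and reports
        host = f"/{self.host_strain}" if self.host_strain else ""
        return f"{self.environment}{host}:{self.community_key}"


@dataclass(frozen=True)
class CompositionVector:
    """A point on the simplex: non-negative fractions over a species set, summing to 1."""

    species_ids: tuple[str, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.species_ids) != len(self.fractions):
            raise ValidationError("species_ids and fractions differ in length")
        fr = np.asarray(self.fractions, dtype=float)
        if (fr < 0).any():
            raise ValidationError(f"fractions must be non-negative, got {fr}")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValidationError(f"fractions must sum to 1, got sum {fr.sum()!r}")

    @classmethod
    def from_counts(
        cls, species_ids: Sequence[str], counts: Sequence[float]
    ) -> "CompositionVector":
        c = np.asarray(counts, dtype=float)
        total = c.sum()
        if total <= 0:
            raise ValidationError("cannot form a composition from zero-total counts")
        fr = c / total
        # renormalize exactly so the sum-to-1 invariant holds bit-for-bit
        fr = fr / fr.sum()
        return cls(tuple(species_ids), tuple(fr.tolist()))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.species_ids, self.fractions))

    def reorder(self, species_ids: Sequence[str]) -> "CompositionVector":
        """Return the same composition with species listed in the given order."""
        d = self.as_dict()
        if set(species_ids) != set(self.species_ids):
            raise ValidationError(
                f"species sets differ: {sorted(species_ids)} vs {sorted(self.species_ids)}"
            )
        return CompositionVector(
            tuple(species_ids), tuple(d[s] for s in species_ids)
        )


class CFUTable:
    """Replicate-level CFU counts, one row per (condition, species, replicate).

    Thin wrapper over a tidy :class:`pandas.DataFrame` with the canonical
    columns.  Validation guarantees that every (condition, replicate) carries
    exactly one row per species in the fed community and that counts are
    non-negative; downstream code can then index without defensive checks.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.loc[:, list(CFU_COLUMNS)].copy()
        df["count"] = df["count"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        df["host_strain"] = df["host_strain"].where(pd.notna(df["host_strain"]), None)
        df["host_strain"] = df["host_strain"].replace({"": None})
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_rows(
        cls,
        rows: Iterable[tuple[Condition, str, int, float]],
        validate: bool = True,
    ) -> "CFUTable":
        """Build from (condition, species_id, replicate, count) tuples."""
        recs = [
            {
                "environment": cond.environment,
                "host_strain": cond.host_strain,
                "community": cond.community_key,
                "species_id": sp,
                "replicate": rep,
                "count": cnt,
                "unit": cond.unit,
            }
            for cond, sp, rep, cnt in rows
        ]
        return cls(pd.DataFrame.from_records(recs, columns=list(CFU_COLUMNS)), validate)

    def validate(self) -> None:
        df = self.df
        neg = df[df["count"] < 0]
        if len(neg):
            i = neg.index[0]
            raise ValidationError(
                f"negative count {df.loc[i, 'count']} at row {i} "
                f"(species {df.loc[i, 'species_id']}, replicate {df.loc[i, 'replicate']})"
            )
        bad_env = set(df["environment"]) - set(ENVIRONMENTS)
        if bad_env:
            raise ValidationError(f"unknown environment values: {sorted(bad_env)}")
        for (env, host, comm, unit), grp in df.groupby(
            ["environment", "host_strain", "community", "unit"], dropna=False
        ):
            host = None if pd.isna(host) else host
            cond = Condition(env, tuple(comm.split(COMMUNITY_SEP)), host, unit)
            fed = set(cond.fed_community)
            extra = set(grp["species_id"]) - fed
            if extra:
                raise ValidationError(
                    f"species {sorted(extra)} recorded under condition {cond} "
                    "but absent from its fed community"
                )
            for rep, rgrp in grp.groupby("replicate"):
                seen = set(rgrp["species_id"])
                if seen != fed:
                    missing = sorted(fed - seen)
                    raise ValidationError(
                        f"condition {cond}, replicate {rep}: missing rows for species "
                        f"{missing}"
                    )
                if len(rgrp) != len(fed):
                    raise ValidationError(
                        f"condition {cond}, replicate {rep}: duplicate species rows"
                    )

    # -- access -------------------------------------------------------------

    def conditions(self) -> list[Condition]:
        out = []
        for (env, host, comm, unit), _ in self.df.groupby(
            ["environment", "host_strain", "community", "unit"], dropna=False
        ):
            host = None if pd.isna(host) else host
            out.append(Condition(env, tuple(comm.split(COMMUNITY_SEP)), host, unit))
        return out

    def _mask(self, cond: Condition) -> pd.Series:
        df = self.df
        host_match = (
            df["host_strain"].isna() | (df["host_strain"] == None)  # noqa: E711
            if cond.host_strain is None
            else (df["host_strain"] == cond.host_strain)
        )
        return (
            (df["environment"] == cond.environment)
            & host_match
            & (df["community"] == cond.community_key)
            & (df["unit"] == cond.unit)
        )

    def condition_rows(self, cond: Condition) -> pd.DataFrame:
        sub = self.df[self._mask(cond)]
        if sub.empty:
            raise KeyError(f"condition {cond} not present in table")
        return sub

    def replicate_counts(self, cond: Condition) -> pd.DataFrame:
        """Counts as a (replicate x species) matrix, species in fed order."""
        sub = self.condition_rows(cond)
        wide = sub.pivot(index="replicate", columns="species_id", values="count")
        return wide.loc[:, list(cond.fed_community)]

    def monoculture_counts(self, species_id: str, **cond_kw) -> np.ndarray:
        """Replicate counts of a species fed alone.

        ``cond_kw`` fixes environment/host_strain/unit (defaults: worm, any host
        rejected — pass explicitly)."""
        cond = Condition(fed_community=(species_id,), **cond_kw)
        wide = self.replicate_counts(cond)
        return wide[species_id].to_numpy(dtype=float)

    def subset(self, mask: pd.Series) -> "CFUTable":
        return CFUTable(self.df[mask], validate=False)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CFUTable):
            return NotImplemented
        a = self.df.sort_values(list(CFU_COLUMNS)).reset_index(drop=True)
        b = other.df.sort_values(list(CFU_COLUMNS)).reset_index(drop=True)
        return a.equals(b)


@dataclass
class PhyloDistances:
    """Patristic (branch-length path) distances between species.

    ``d[i][j]`` is the sum of branch lengths on the tree path between leaves
    i and j; symmetric with zero diagonal.
    """

    species_ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.species_ids)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("distance matrix diagonal is not zero")
        if (self.d < 0).any():
            raise ValidationError("negative patristic distance")

    def get(self, i: str, j: str) -> float:
        ix = {s: k for k, s in enumerate(self.species_ids)}
        return float(self.d[ix[i], ix[j]])

    def subset(self, species_ids: Sequence[str]) -> "PhyloDistances":
        ix = {s: k for k, s in enumerate(self.species_ids)}
        missing = [s for s in species_ids if s not in ix]
        if missing:
            raise ValidationError(f"species not in distance matrix: {missing}")
        idx = [ix[s] for s in species_ids]
        return PhyloDistances(tuple(species_ids), self.d[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# I/O


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def read_cfu_table(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> CFUTable:
    """Read a replicate-level CFU table from CSV (default) or TSV (.tsv).

    ``schema`` maps canonical column names to the file's column names, e.g.
    ``{"count": "cfu"}``; unmapped columns are looked up under their
    canonical names.  The ``community`` column holds ``;``-joined species ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(
        path, sep=_sep_for(path), dtype={"community": str}, float_precision="round_trip"
    )
    schema = dict(schema or {})
    rename = {}
    for canon in CFU_COLUMNS:
        src = schema.get(canon, canon)
        if src not in raw.columns:
            if canon in ("host_strain", "unit"):  # optional with defaults
                raw[canon] = None if canon == "host_strain" else "cfu_per_worm"
                continue
            raise SchemaError(
                f"required column {canon!r} (file column {src!r}) not found in {path}"
            )
        rename[src] = canon
    raw = raw.rename(columns=rename)
    return CFUTable(raw)


def write_cfu_table(table: CFUTable, path: str | Path) -> None:
    """Write a CFU table to CSV/TSV at full precision (round-trip safe)."""
    df = table.df.copy()
    df["count"] = [repr(float(c)) for c in df["count"]]
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_species_table(path: str | Path) -> dict[str, SpeciesInfo]:
    """Read species metadata (species_id, label, origin, collection, taxonomy)."""
    df = pd.read_csv(path, sep=_sep_for(path)).fillna("")
    if "species_id" not in df.columns or "origin" not in df.columns:
        raise SchemaError("species table needs at least species_id and origin columns")
    out = {}
    for _, row in df.iterrows():
        info = SpeciesInfo(
            species_id=str(row["species_id"]),
            label=str(row.get("label", "")),
            origin=str(row["origin"]),
            collection=str(row.get("collection", "")),
            taxonomy=str(row.get("taxonomy", "")),
        )
        if info.species_id in out:
            raise ValidationError(f"duplicate species_id {info.species_id!r}")
        out[info.species_id] = info
    return out


def read_tree_distances(
    source: str | Path,
    alias: Mapping[str, str] | None = None,
    species_ids: Sequence[str] | None = None,
) -> PhyloDistances:
    """Patristic distance matrix from a newick tree with branch lengths.

    ``alias`` maps leaf labels to species ids (exact string match otherwise).
    ``species_ids`` restricts and orders the output; by default all leaves in
    tree order are used.
    """
    src = str(source)
    if "\n" not in src and Path(src).exists():
        tree = dendropy.Tree.get(path=src, schema="newick")
    else:
        tree = dendropy.Tree.get(data=src, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValidationError("tree has edges without branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    alias = dict(alias or {})
    taxa = {}
    for taxon in tree.taxon_namespace:
        name = alias.get(taxon.label, taxon.label)
        taxa[name] = taxon
    if species_ids is None:
        species_ids = list(taxa)
    missing = [s for s in species_ids if s not in taxa]
    if missing:
        raise ValidationError(
            f"species not found among tree leaves: {missing}; leaves are {sorted(taxa)}"
        )
    n = len(species_ids)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = pdm.patristic_distance(
                taxa[species_ids[a]], taxa[species_ids[b]]
            )
    return PhyloDistances(tuple(species_ids), d)


# ---------------------------------------------------------------------------
# basic statistics


def mean_and_sem(
    values: Sequence[float], n_override: int | None = None
) -> tuple[float, float]:
    """Arithmetic mean and s.e.m. of replicate values.

    The standard error is the sample standard deviation divided by sqrt(n),
    where n defaults to the number of values but can be overridden — the
    convention for monoculture-based null expectations is to use the least
    number of monoculture replicates.  A single value yields s.e.m. NaN
    (not available).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("mean_and_sem requires at least one value")
    if n_override is not None and n_override < 1:
        raise ValidationError(f"n_override must be positive, got {n_override}")
    mean = float(v.mean())
    if v.size == 1:
        return mean, math.nan
    n = n_override if n_override is not None else v.size
    return mean, float(v.std(ddof=1) / math.sqrt(n))
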
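"""Typed species-trait tables, derived traits, and model-frame assembly.

The analysis consumes a species x trait table with three column kinds:

* ``continuous`` — real-valued measurements (days, grams, degrees ...),
* ``ordered`` — integer-coded ordinal scales (e.g. range restriction 1-5),
* ``nominal`` — unordered categories (e.g. habitat, foraging guild).

Missing cells are permitted anywhere and are passed through to the tree
learner, which handles them natively; no imputation is performed.

The default schema mirrors the 17-trait avian life-history table the
pipeline was designed around: nine continuous traits (incubation period,
fledge period, clutch size, broods per year, body mass, clutch as % of
female body mass, migration distance, lifespan, residual testes mass),
three ordered scales (breeding range, wintering range, breeding
coloniality) and five nominal traits (stage at hatch, migration route,
social mating system, habitat, foraging guild).

Derived-trait helpers implement the two computed traits: residual testes
mass (residuals of a log10-log10 ordinary least-squares regression of
testes mass on body mass, the standard allometric size correction) and
migration distance (absolute difference in degrees latitude between
breeding- and wintering-range midpoints).

The response is built from a species -> receptor-subtype map and a subtype
-> EC50 table: by default the per-species response is the z-scored log10
EC50, a dimensionless value that is monotone in EC50 (larger EC50, i.e.
lower sensitivity, gives a larger response) and invariant to the EC50
unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .eigenspace import PhyloCoordinates

__all__ = [
    "CONTINUOUS",
    "ORDERED",
    "NOMINAL",
    "DEFAULT_TRAIT_SCHEMA",
    "TraitTable",
    "ResponseVector",
    "ModelFrame",
    "residual_testes_mass",
    "migration_distance",
    "range_midpoint",
    "build_response",
    "build_model_frame",
]

CONTINUOUS = "continuous"
ORDERED = "ordered"
NOMINAL = "nominal"

#: Column schema of the canonical 17-trait table. Ordered entries list their
#: integer codes; nominal entries list their level labels.
DEFAULT_TRAIT_SCHEMA: dict = {
    "incubation_period": {"kind": CONTINUOUS},
    "fledge_period": {"kind": CONTINUOUS},
    "stage_at_hatch": {"kind": NOMINAL, "levels": ["precocial", "altricial"]},
    "clutch_size": {"kind": CONTINUOUS},
    "broods_per_year": {"kind": CONTINUOUS},
    "body_mass": {"kind": CONTINUOUS},
    "clutch_pct_female_mass": {"kind": CONTINUOUS},
    "migration_route": {
        "kind": NOMINAL,
        "levels": [
            "non_migratory",
            "continental",
            "coastal",
            "continental_and_coastal",
            "coastal_and_oceanic",
            "all_routes",
        ],
    },
    "migration_distance": {"kind": CONTINUOUS},
    "breeding_range": {"kind": ORDERED, "levels": [1, 2, 3, 4, 5]},
    "wintering_range": {"kind": ORDERED, "levels": [1, 2, 3, 4, 5]},
    "residual_testes_mass": {"kind": CONTINUOUS},
    "social_mating_system": {
        "kind": NOMINAL,
        "levels": [
            "polyandrous",
            "monogamous",
            "mostly_monogamous",
            "polygynous",
            "lekking_promiscuous",
            "cooperative_breeder",
        ],
    },
    "breeding_coloniality": {"kind": ORDERED, "levels": [0, 1, 2]},
    "habitat": {
        "kind": NOMINAL,
        "levels": [
            "urban",
            "forest",
            "grassland",
            "lake_pond",
            "marsh",
            "mountain",
            "ocean",
            "open_woodland",
            "scrub",
            "shoreline",
        ],
    },
    "foraging_guild": {
        "kind": NOMINAL,
        "levels": [
            "carnivorous",
            "herbivorous",
            "insectivorous",
            "invertivorous",
            "omnivorous",
            "piscivorous",
        ],
    },
    "lifespan": {"kind": CONTINUOUS},
}


def load_schema(path) -> dict:
    """Load a column schema from a YAML file (name -> {kind, levels})."""
    schema = yaml.safe_load(Path(path).read_text())
    for name, spec in schema.items():
        if spec.get("kind") not in (CONTINUOUS, ORDERED, NOMINAL):
            raise ValueError(f"column {name}: unknown kind {spec.get('kind')!r}")
        if spec["kind"] in (ORDERED, NOMINAL) and not spec.get("levels"):
            raise ValueError(f"column {name}: {spec['kind']} needs levels")
    return schema


@dataclass
class TraitTable:
    """A species x trait table with a declared column schema.

    ``data`` is indexed by species label; every column must appear in the
    schema, ordered codes must fall in their declared code list, and nominal
    values in their declared level list (NaN/empty = missing).
    """

    data: pd.DataFrame
    schema: dict

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = sorted(self.data.index[self.data.index.duplicated()])
            raise ValueError(f"duplicate species labels: {dupes}")
        unknown = [c for c in self.data.columns if c not in self.schema]
        if unknown:
            raise ValueError(f"columns missing from schema: {unknown}")
        for name in self.data.columns:
            spec = self.schema[name]
            col = self.data[name]
            present = col.dropna()
            if spec["kind"] == CONTINUOUS:
                self.data[name] = pd.to_numeric(col, errors="raise")
            elif spec["kind"] == ORDERED:
                bad = set(present) - set(spec["levels"])
                if bad:
                    raise ValueError(
                        f"column {name}: codes {sorted(bad)} outside "
                        f"declared levels {spec['levels']}"
                    )
            else:
                bad = set(present) - set(spec["levels"])
                if bad:
                    raise ValueError(
                        f"column {name}: values {sorted(bad)} not in "
                        f"declared levels"
                    )

    @property
    def species(self) -> list:
        return list(self.data.index)

    @classmethod
    def read_csv(cls, path, schema) -> "TraitTable":
        if not isinstance(schema, Mapping):
            schema = load_schema(schema)
        df = pd.read_csv(path, index_col=0)
        return cls(data=df, schema=dict(schema))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="species")


# ---------------------------------------------------------------------------
# Derived traits
# ---------------------------------------------------------------------------

def residual_testes_mass(
    testes_mass: pd.Series, body_mass: pd.Series, log: bool = True
) -> pd.Series:
    """Size-corrected testes mass: OLS residuals of testes on body mass.

    By default both masses are log10-transformed first (the allometric
    convention); set ``log=False`` for a raw-scale regression. The fit uses
    complete cases only; species missing either input get a missing
    residual.

    Raises
    ------
    ValueError
        If fewer than 3 complete cases are available, or any mass is
        nonpositive (on the log scale, a nonpositive mass is undefined).
    """
    testes_mass, body_mass = testes_mass.align(body_mass)
    complete = testes_mass.notna() & body_mass.notna()
    if int(complete.sum()) < 3:
        raise ValueError(
            f"need >= 3 species with both masses, got {int(complete.sum())}"
        )
    t = testes_mass[complete].astype(float)
    b = body_mass[complete].astype(float)
    if (t <= 0).any() or (b <= 0).any():
        bad = sorted(t.index[(t <= 0) | (b <= 0)])
        raise ValueError(f"nonpositive mass for species {bad}")
    if log:
        t = np.log10(t)
        b = np.log10(b)
    slope, intercept = np.polyfit(b.to_numpy(), t.to_numpy(), deg=1)
    resid = t - (intercept + slope * b)
    return resid.reindex(testes_mass.index)


def range_midpoint(north_extent, south_extent):
    """Median latitude between a range's north and south extents."""
    north = np.asarray(north_extent, dtype=float)
    south = np.asarray(south_extent, dtype=float)
    for lat in (north, south):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitudes must lie in [-90, 90]")
    return (north + south) / 2.0


def migration_distance(breeding_midpoint_lat, wintering_midpoint_lat):
    """Migration distance in degrees latitude between range midpoints.

    The absolute difference between the breeding- and wintering-range
    midpoint latitudes; 0 for non-migratory species whose midpoints
    coincide. Accepts scalars or arrays.
    """
    b = np.asarray(breeding_midpoint_lat, dtype=float)
    w = np.asarray(wintering_midpoint_lat, dtype=float)
    for lat in (b, w):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitudes must lie in [-90, 90]")
    out = np.abs(b - w)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Response construction
# ---------------------------------------------------------------------------

@dataclass
class ResponseVector:
    """Per-species transformed sensitivity proxy.

    ``values[i]`` is the (by default z-scored log10) EC50 of the receptor
    subtype carried by ``species[i]``: larger values mean a less sensitive
    subtype. ``provenance`` records species -> subtype -> raw EC50.
    """

    species: list
    values: np.ndarray
    provenance: pd.DataFrame
    transform: str = "zscore_log10"

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.species, name="response")


def build_response(
    subtype_by_species: Mapping,
    ec50_by_subtype: Mapping,
    transform: str = "zscore_log10",
) -> ResponseVector:
    """Map species through their subtype's EC50 into a response vector.

    ``transform`` is one of ``"raw"``, ``"log10"`` or ``"zscore_log10"``
    (default). All transforms are monotone increasing in EC50, so species
    sharing a subtype share a response value and the number of distinct
    response values is at most the number of subtypes.

    Raises
    ------
    KeyError
        If a species' subtype has no EC50 entry.
    ValueError
        If any EC50 is nonpositive, or all species share one subtype (the
        response would be degenerate).
    """
    if transform not in ("raw", "log10", "zscore_log10"):
        raise ValueError(f"unknown transform {transform!r}")
    species = list(subtype_by_species)
    subtypes = []
    ec50 = np.empty(len(species))
    for i, sp in enumerate(species):
        st = subtype_by_species[sp]
        if st not in ec50_by_subtype:
            raise KeyError(f"species {sp!r}: subtype {st!r} has no EC50")
        subtypes.append(st)
        ec50[i] = ec50_by_subtype[st]
    if np.any(ec50 <= 0):
        raise ValueError("EC50 values must be positive")
    if len(set(subtypes)) < 2:
        raise ValueError(
            "all species share a single subtype; response is degenerate"
        )
    if transform == "raw":
        values = ec50.copy()
    else:
        values = np.log10(ec50)
        if transform == "zscore_log10":
            sd = values.std()  # population SD: the scale is descriptive
            if sd == 0:
                raise ValueError("response has zero variance")
            values = (values - values.mean()) / sd
    provenance = pd.DataFrame(
        {"subtype": subtypes, "ec50": ec50}, index=pd.Index(species, name="species")
    )
    return ResponseVector(
        species=species, values=values, provenance=provenance,
        transform=transform,
    )


# ---------------------------------------------------------------------------
# Model frame
# ---------------------------------------------------------------------------

@dataclass
class ModelFrame:
    """Numeric predictor matrix plus per-column metadata for the learner.

    Continuous and ordered columns are stored as floats (NaN = missing);
    nominal columns are stored as float level codes, indices into
    ``levels[name]`` (NaN = missing) — the tree learner splits on level
    subsets directly, so no dummy expansion is performed. ``groups`` tags
    every column as either ``"trait"`` or ``"phylogeny"``.
    """

    X: np.ndarray
    columns: list
    kinds: list
    levels: dict
    groups: list
    species: list

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if not (len(self.columns) == len(self.kinds) == len(self.groups) == p):
            raise ValueError("column metadata lengths do not match the matrix")
        if len(self.species) != n:
            raise ValueError("species list does not match the matrix rows")
        bad = set(self.groups) - {"trait", "phylogeny"}
        if bad:
            raise ValueError(f"unknown column groups: {sorted(bad)}")

    @property
    def n_levels(self) -> dict:
        return {c: len(v) for c, v in self.levels.items()}

    @property
    def group_map(self) -> dict:
        return dict(zip(self.columns, self.groups))

    def column_index(self, name) -> int:
        return self.columns.index(name)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=self.species, columns=self.columns)
        for name, levels in self.levels.items():
            codes = df[name]
            df[name] = [
                levels[int(c)] if np.isfinite(c) else np.nan for c in codes
            ]
        return df


def build_model_frame(
    traits: TraitTable, coords: PhyloCoordinates | None
) -> ModelFrame:
    """Concatenate trait columns and selected eigenvectors into one frame.

    Rows are aligned by species label (the trait table's order wins);
    passing ``coords=None`` or a zero-column coordinate set yields a
    trait-only frame.

    Raises
    ------
    ValueError
        If the trait table's and coordinates' species sets differ, listing
        the offending labels.
    """
    species = traits.species
    if coords is not None and coords.k > 0:
        missing = sorted(set(species) - set(coords.labels))
        extra = sorted(set(coords.labels) - set(species))
        if missing or extra:
            raise ValueError(
                f"species mismatch between traits and coordinates "
                f"(traits-only: {missing}, coordinates-only: {extra})"
            )
    columns: list = []
    kinds: list = []
    groups: list = []
    levels: dict = {}
    mats: list = []
    for name in traits.data.columns:
        spec = traits.schema[name]
        col = traits.data[name]
        if spec["kind"] == CONTINUOUS:
            mats.append(col.astype(float).to_numpy())
            kinds.append(CONTINUOUS)
        elif spec["kind"] == ORDERED:
            mats.append(col.astype(float).to_numpy())
            kinds.append(ORDERED)
        else:
            lut = {lev: i for i, lev in enumerate(spec["levels"])}
            codes = np.array(
                [lut[v] if pd.notna(v) else np.nan for v in col], dtype=float
            )
            mats.append(codes)
            kinds.append(NOMINAL)
            levels[name] = list(spec["levels"])
        columns.append(name)
        groups.append("trait")
    if coords is not None and coords.k > 0:
        scores = coords.to_dataframe().reindex(species)
        for name in scores.columns:
            mats.append(scores[name].to_numpy(dtype=float))
            columns.append(name)
            kinds.append(CONTINUOUS)
            groups.append("phylogeny")
    X = np.column_stack(mats) if mats else np.empty((len(species), 0))
    return ModelFrame(
        X=X, columns=columns, kinds=kinds, levels=levels, groups=groups,
        species=list(species),
    )
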
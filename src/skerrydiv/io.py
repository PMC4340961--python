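"""Survey-grid domain types, delimited-table readers/writers, and the
square-inclusion / record-reassignment rules applied before analysis.

The sampling unit throughout is a 1 km^2 grid square described by four
environmental covariates (distance to open sea, archipelago width,
shoreline length, land area).  Species occurrences are strict 0/1
presence-absence; each species carries a habitat classification
(coastal specialist vs. generalist) and a national red-list status.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateLabelError,
    MissingColumnError,
    MissingTraitError,
    NoRetainedSquaresError,
    PresenceValueError,
    ValidationError,
    VocabularyError,
)

SQUARE_AREA_M2 = 1_000_000.0
CLASSIFICATIONS = ("specialist", "generalist")
REDLIST_STATUSES = ("none", "NT", "VU")

#: Species groups accepted by the richness / dissimilarity routines.
GROUPS = (
    "all",
    "specialist",
    "generalist",
    "redlist_all",
    "redlist_specialist",
    "redlist_generalist",
)

SQUARE_COLUMNS = [
    "square_id", "x", "y", "land_area_m2", "shoreline_m", "dist_sea_m", "width_m",
]
TRAIT_COLUMNS = ["species", "classification", "redlist"]
LONG_OCC_COLUMNS = ["square_id", "species", "present"]


@dataclass(frozen=True)
class SquareRecord:
    """One 1 km^2 grid square: identity, centroid, and the four covariates."""

    square_id: str
    x: float
    y: float
    land_area: float   # m^2 of land within the square
    shoreline: float   # total shoreline length, m
    dist_sea: float    # distance from midpoint to open sea, m
    width: float       # archipelago width = dist to mainland + dist_sea, m

    def __post_init__(self) -> None:
        if not (0.0 <= self.land_area <= SQUARE_AREA_M2):
            raise ValidationError(
                f"square {self.square_id!r}: land_area {self.land_area} "
                f"outside [0, {SQUARE_AREA_M2:.0f}] m^2"
            )
        if self.shoreline < 0 or self.dist_sea < 0:
            raise ValidationError(
                f"square {self.square_id!r}: negative shoreline or dist_sea"
            )
        if self.width < self.dist_sea - 1e-9:
            raise ValidationError(
                f"square {self.square_id!r}: width {self.width} < dist_sea "
                f"{self.dist_sea}"
            )


@dataclass(frozen=True)
class SpeciesTrait:
    """Habitat classification and red-list status of one species."""

    species: str
    classification: str
    redlist: str = "none"

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise VocabularyError(
                f"species {self.species!r}: classification "
                f"{self.classification!r} not in {CLASSIFICATIONS}"
            )
        if self.redlist not in REDLIST_STATUSES:
            raise VocabularyError(
                f"species {self.species!r}: redlist {self.redlist!r} "
                f"not in {REDLIST_STATUSES}"
            )


class OccurrenceMatrix:
    """Squares x species 0/1 matrix with per-species trait annotations.

    Backed by a pandas DataFrame (index = square ids, columns = species,
    int8 values in {0, 1}) plus a trait table aligned to the species axis.
    """

    def __init__(self, presence: pd.DataFrame, traits: Sequence[SpeciesTrait]):
        presence = presence.copy()
        if presence.index.has_duplicates:
            dupes = presence.index[presence.index.duplicated()].tolist()
            raise DuplicateLabelError(f"duplicate square ids: {dupes}")
        if presence.columns.has_duplicates:
            dupes = presence.columns[presence.columns.duplicated()].tolist()
            raise DuplicateLabelError(f"duplicate species: {dupes}")
        vals = presence.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PresenceValueError(
                f"presence value {vals[i, j]!r} at square "
                f"{presence.index[i]!r}, species {presence.columns[j]!r} "
                "is not 0/1"
            )
        trait_map = {t.species: t for t in traits}
        if len(trait_map) != len(list(traits)):
            raise DuplicateLabelError("duplicate species in trait records")
        orphans = [s for s in presence.columns if s not in trait_map]
        if orphans:
            raise MissingTraitError(f"species lacking trait records: {orphans}")
        self.presence = presence.astype(np.int8)
        self.traits = {s: trait_map[s] for s in presence.columns}

    @property
    def squares(self) -> list[str]:
        return list(self.presence.index)

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    def trait_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "classification": [t.classification for t in self.traits.values()],
                "redlist": [t.redlist for t in self.traits.values()],
            },
            index=pd.Index(self.traits.keys(), name="species"),
        )

    def group_species(self, group: str) -> list[str]:
        """Species belonging to one of the analysis groups in GROUPS."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        out = []
        for s, t in self.traits.items():
            listed = t.redlist != "none"
            if group == "all":
                keep = True
            elif group in CLASSIFICATIONS:
                keep = t.classification == group
            elif group == "redlist_all":
                keep = listed
            else:  # redlist_specialist / redlist_generalist
                keep = listed and t.classification == group.split("_", 1)[1]
            if keep:
                out.append(s)
        return out

    def restrict(self, squares: Sequence[str]) -> "OccurrenceMatrix":
        return OccurrenceMatrix(self.presence.loc[list(squares)], list(self.traits.values()))

    def equals(self, other: "OccurrenceMatrix") -> bool:
        return (
            self.presence.equals(other.presence) and self.traits == other.traits
        )


@dataclass
class SurveyDataset:
    """A survey grid plus its occurrence matrix.

    ``provenance`` is free-form metadata (seed, generator parameters, file
    source); it is deliberately excluded from dataset equality.
    """

    grid: list[SquareRecord]
    occ: OccurrenceMatrix
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid_ids = [s.square_id for s in self.grid]
        if len(set(grid_ids)) != len(grid_ids):
            raise DuplicateLabelError("duplicate square ids in grid")
        if grid_ids != self.occ.squares:
            raise ValidationError(
                "grid square ids and occurrence rows are not the same "
                "ordered set"
            )

    @property
    def square_ids(self) -> list[str]:
        return [s.square_id for s in self.grid]

    def squares_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "square_id": s.square_id, "x": s.x, "y": s.y,
                    "land_area_m2": s.land_area, "shoreline_m": s.shoreline,
                    "dist_sea_m": s.dist_sea, "width_m": s.width,
                }
                for s in self.grid
            ]
        ).set_index("square_id")

    def covariate_frame(self) -> pd.DataFrame:
        """The four environmental covariates, indexed by square id."""
        f = self.squares_frame()
        return f[["dist_sea_m", "width_m", "shoreline_m", "land_area_m2"]].rename(
            columns={
                "dist_sea_m": "dist_sea", "width_m": "width",
                "shoreline_m": "shoreline", "land_area_m2": "land_area",
            }
        )

    def equals(self, other: "SurveyDataset") -> bool:
        return self.grid == other.grid and self.occ.equals(other.occ)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")


def _coerce_presence(df: pd.DataFrame, path) -> pd.DataFrame:
    def bad(cell, sq, sp):
        return PresenceValueError(
            f"{path}: presence value {cell!r} at square {sq!r}, "
            f"species {sp!r} is not 0/1"
        )

    out = df.copy()
    for col in out.columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        ok = coerced.isin((0, 1))
        if not ok.all():
            i = int(np.argmax(~ok.to_numpy()))
            raise bad(out[col].iloc[i], out.index[i], col)
        out[col] = coerced.astype(np.int8)
    return out


def read_dataset(squares_path, occurrence_path, traits_path) -> SurveyDataset:
    """Read the three delimited tables into a validated SurveyDataset.

    The occurrence table may be in long form (square_id, species, present)
    or in wide form (first column square_id, one column per species).
    """
    squares_df = pd.read_csv(squares_path, float_precision="round_trip")
    _require_columns(squares_df, SQUARE_COLUMNS, squares_path)
    if squares_df["square_id"].duplicated().any():
        dupes = squares_df.loc[squares_df["square_id"].duplicated(), "square_id"]
        raise DuplicateLabelError(f"{squares_path}: duplicate square ids {list(dupes)}")
    grid = [
        SquareRecord(
            square_id=str(r.square_id), x=float(r.x), y=float(r.y),
            land_area=float(r.land_area_m2), shoreline=float(r.shoreline_m),
            dist_sea=float(r.dist_sea_m), width=float(r.width_m),
        )
        for r in squares_df.itertuples(index=False)
    ]

    traits_df = pd.read_csv(traits_path)
    _require_columns(traits_df, TRAIT_COLUMNS, traits_path)
    if traits_df["species"].duplicated().any():
        dupes = traits_df.loc[traits_df["species"].duplicated(), "species"]
        raise DuplicateLabelError(f"{traits_path}: duplicate species {list(dupes)}")
    traits = [
        SpeciesTrait(str(r.species), str(r.classification), str(r.redlist))
        for r in traits_df.fillna({"redlist": "none"}).itertuples(index=False)
    ]
    trait_names = {t.species for t in traits}

    occ_df = pd.read_csv(occurrence_path)
    if list(occ_df.columns) == LONG_OCC_COLUMNS:
        pairs = occ_df[["square_id", "species"]].astype(str)
        if pairs.duplicated().any():
            raise DuplicateLabelError(
                f"{occurrence_path}: duplicate (square, species) rows"
            )
        wide = occ_df.assign(
            square_id=pairs["square_id"], species=pairs["species"]
        ).pivot(index="square_id", columns="species", values="present")
        wide = wide.fillna(0)
    else:
        first = occ_df.columns[0]
        if first != "square_id":
            raise MissingColumnError(
                f"{occurrence_path}: first column must be 'square_id' "
                f"(got {first!r})"
            )
        wide = occ_df.set_index("square_id")
        wide.index = wide.index.astype(str)
    wide = _coerce_presence(wide, occurrence_path)

    orphans = sorted(set(wide.columns) - trait_names)
    if orphans:
        raise MissingTraitError(
            f"{occurrence_path}: species lacking trait records: {orphans}"
        )

    grid_ids = [s.square_id for s in grid]
    if set(grid_ids) != set(wide.index):
        raise ValidationError(
            "square ids differ between squares table and occurrence table"
        )
    wide = wide.reindex(grid_ids)
    # Keep the occurrence column order; traits restricted to observed species.
    used = [t for t in traits if t.species in set(wide.columns)]
    occ = OccurrenceMatrix(wide, used)
    return SurveyDataset(
        grid=grid, occ=occ,
        provenance={"source": {"squares": str(squares_path),
                               "occurrences": str(occurrence_path),
                               "traits": str(traits_path)}},
    )


def write_dataset(ds: SurveyDataset, out_dir) -> dict[str, Path]:
    """Write squares/occurrences/traits CSVs; read_dataset round-trips."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "squares": out / "squares.csv",
        "occurrences": out / "occurrences.csv",
        "traits": out / "traits.csv",
    }
    ds.squares_frame().reset_index().to_csv(paths["squares"], index=False)
    ds.occ.presence.rename_axis("square_id").reset_index().to_csv(
        paths["occurrences"], index=False
    )
    ds.occ.trait_frame().reset_index().to_csv(paths["traits"], index=False)
    return paths


def load_coastal_bird_traits() -> pd.DataFrame:
    """The published occurrence counts and classifications of the 48
    coastal breeding bird species surveyed on the 4,646-square grid
    (columns: species, occurrences, classification, redlist)."""
    ref = importlib.resources.files("skerrydiv.data") / "coastal_birds.csv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p)
    return df


def filter_squares(
    ds: SurveyDataset,
    min_shoreline: float = 25.0,
    require_land_and_water: bool = True,
) -> tuple[SurveyDataset, list[str]]:
    """Apply the survey's square-inclusion rules.

    A square is retained when its shoreline is at least ``min_shoreline``
    metres (inclusive) and, if ``require_land_and_water``, it contains both
    land and water (0 < land_area < 1 km^2).  Returns the filtered dataset
    and the excluded square ids; reassignment of the excluded squares'
    records is a separate step (see :func:`reassign_records`).
    """
    retained, excluded = [], []
    for s in ds.grid:
        ok = s.shoreline >= min_shoreline
        if require_land_and_water:
            ok = ok and 0.0 < s.land_area < SQUARE_AREA_M2
        (retained if ok else excluded).append(s)
    kept_ids = [s.square_id for s in retained]
    out = SurveyDataset(
        grid=retained,
        occ=ds.occ.restrict(kept_ids),
        provenance=dict(ds.provenance),
    )
    return out, [s.square_id for s in excluded]


def reassign_records(ds: SurveyDataset, excluded: Sequence[str]) -> OccurrenceMatrix:
    """Move records from excluded squares to the nearest retained square.

    Each species present in an excluded square is marked present in the
    retained square whose centroid is nearest (Euclidean); presence merges
    by logical OR.  Distance ties go to the lexicographically smallest
    square id.  Returns the matrix restricted to retained squares.
    """
    excluded_set = set(excluded)
    unknown = excluded_set - set(ds.square_ids)
    if unknown:
        raise ValidationError(f"excluded ids not in dataset: {sorted(unknown)}")
    retained = [s for s in ds.grid if s.square_id not in excluded_set]
    if not retained:
        raise NoRetainedSquaresError("no retained squares to receive records")
    kept_ids = [s.square_id for s in retained]
    pres = ds.occ.presence.loc[kept_ids].copy()

    rx = np.array([s.x for s in retained])
    ry = np.array([s.y for s in retained])
    for s in ds.grid:
        if s.square_id not in excluded_set:
            continue
        row = ds.occ.presence.loc[s.square_id]
        if row.sum() == 0:
            continue
        d2 = (rx - s.x) ** 2 + (ry - s.y) ** 2
        # nearest retained centroid; ties to lexicographically smallest id
        best = min(range(len(kept_ids)), key=lambda i: (d2[i], kept_ids[i]))
        target = kept_ids[best]
        pres.loc[target] = np.maximum(pres.loc[target].to_numpy(), row.to_numpy())
    return OccurrenceMatrix(pres, list(ds.occ.traits.values()))
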
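"""Domain types shared by every analysis stage.

The study design these types encode: a herd of suckler cows from several
breeds grazes a sequence of alpine pastures, each pasture subdivided into
one paddock per breed.  Anatomy is measured once per cow (weights at turn-in
and turn-out, claw-base outlines traced from calibrated photographs of the
left feet); movement is recorded continuously (GPS fixes at a nominal 15 s
interval, pedometer step counts and lying time); foraging is observed as
bite sequences (one plant taxon per recorded bite).  A taxon table carries
Briemle forage-quality indicator values (1–9) and, for taxa that are field
groups of hard-to-distinguish species, per-pasture member abundances from
vegetation relevées.

All spatial coordinates must already be in a projected metric CRS; the
package performs no geodetic transforms.  Timestamps are integer seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon


class ValidationError(ValueError):
    """A record or bundle violates a structural invariant."""


class DegenerateDataError(ValueError):
    """Data are structurally valid but statistically degenerate
    (zero variance, empty group, single-taxon diet, ...)."""


class Foot(str, Enum):
    FORE = "fore"
    HIND = "hind"


class Claw(str, Enum):
    MEDIAL = "medial"
    LATERAL = "lateral"


class PlantGroup(str, Enum):
    BROAD_GRASS = "broad_grass"
    FINE_GRASS = "fine_grass"
    LEGUME = "legume"
    THISTLE = "thistle"
    SHRUB = "shrub"
    OTHER = "other"


@dataclass(frozen=True)
class CowRecord:
    """One study animal: identity, breed, weights and pasture exposure."""

    cow_id: str
    breed: str
    age_months: float
    weight_start: float  # kg, at turn-in
    weight_end: float    # kg, after the grazing period
    days_on_pasture: int

    def __post_init__(self) -> None:
        if self.weight_start <= 0 or self.weight_end <= 0:
            raise ValidationError(f"cow {self.cow_id}: weights must be > 0")
        if self.age_months <= 0:
            raise ValidationError(f"cow {self.cow_id}: age must be > 0")
        if self.days_on_pasture < 1:
            raise ValidationError(f"cow {self.cow_id}: days_on_pasture must be >= 1")


@dataclass(frozen=True)
class ClawOutline:
    """Traced outline of one claw base, vertices in calibrated cm."""

    cow_id: str
    foot: Foot
    claw: Claw
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValidationError(
                f"claw outline {self.cow_id}/{self.foot.value}/{self.claw.value}: "
                f"needs >= 3 vertices, got {len(self.vertices)}"
            )
        if not Polygon(self.vertices).is_simple:
            raise ValidationError(
                f"claw outline {self.cow_id}/{self.foot.value}/{self.claw.value}: "
                "polygon is self-intersecting"
            )


@dataclass(frozen=True)
class PedometerInterval:
    cow_id: str
    paddock_id: str
    duration_s: int
    steps: int
    lying_s: int

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError(f"pedometer {self.cow_id}: duration must be > 0")
        if not (0 <= self.lying_s <= self.duration_s):
            raise ValidationError(
                f"pedometer {self.cow_id}: lying_s {self.lying_s} outside "
                f"[0, {self.duration_s}]"
            )
        if self.steps < 0:
            raise ValidationError(f"pedometer {self.cow_id}: steps must be >= 0")


@dataclass
class TaxonTable:
    """Plant taxa with Briemle quality values and group membership.

    ``taxa`` columns: taxon_id, kind ('species'|'group'), quality (1–9 for
    species, NaN for groups), plant_group.
    ``members`` columns: group_id, species_id, pasture_id, abundance —
    relevée relative abundances of group members, summing to 1 per
    (group, pasture).
    """

    taxa: pd.DataFrame
    members: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["group_id", "species_id", "pasture_id", "abundance"]
        )
    )

    def __post_init__(self) -> None:
        required = {"taxon_id", "kind", "quality", "plant_group"}
        missing = required - set(self.taxa.columns)
        if missing:
            raise ValidationError(f"taxon table missing columns {sorted(missing)}")
        if self.taxa["taxon_id"].duplicated().any():
            dup = self.taxa.loc[self.taxa["taxon_id"].duplicated(), "taxon_id"]
            raise ValidationError(f"duplicate taxon_id: {sorted(set(dup))}")
        species = self.taxa[self.taxa["kind"] == "species"]
        bad = species[(species["quality"] < 1) | (species["quality"] > 9)]
        if len(bad):
            raise ValidationError(
                f"Briemle quality outside [1, 9] for {sorted(bad['taxon_id'])}"
            )
        if len(self.members):
            sums = self.members.groupby(["group_id", "pasture_id"])["abundance"].sum()
            off = sums[(sums - 1.0).abs() > 1e-9]
            if len(off):
                raise ValidationError(
                    "group member abundances do not sum to 1 for "
                    f"{list(off.index)}"
                )

    @property
    def ids(self) -> set[str]:
        return set(self.taxa["taxon_id"])

    def plant_group_of(self, taxon_id: str) -> str:
        row = self.taxa.loc[self.taxa["taxon_id"] == taxon_id]
        if row.empty:
            raise ValidationError(f"unknown taxon {taxon_id!r}")
        return str(row["plant_group"].iloc[0])


@dataclass
class PaddockGeometry:
    """One fenced paddock: boundary polygon, DEM, water points.

    The DEM is a regular grid in the same projected CRS: ``dem`` is a 2-D
    array indexed [row, col] with row 0 at the *south* edge, lower-left
    corner at (dem_x0, dem_y0), square cells of ``dem_cell`` metres.
    """

    paddock_id: str
    pasture_id: str
    boundary: Polygon
    water_points: tuple[tuple[float, float], ...]
    dem: np.ndarray
    dem_x0: float
    dem_y0: float
    dem_cell: float

    def __post_init__(self) -> None:
        if not self.boundary.is_valid or self.boundary.is_empty:
            raise ValidationError(f"paddock {self.paddock_id}: invalid boundary")
        if len(self.water_points) == 0:
            raise ValidationError(f"paddock {self.paddock_id}: no water points")
        self.dem = np.asarray(self.dem, dtype=float)
        if self.dem.ndim != 2:
            raise ValidationError(f"paddock {self.paddock_id}: DEM must be 2-D")
        ny, nx = self.dem.shape
        minx, miny, maxx, maxy = self.boundary.bounds
        if (
            minx < self.dem_x0
            or miny < self.dem_y0
            or maxx > self.dem_x0 + nx * self.dem_cell
            or maxy > self.dem_y0 + ny * self.dem_cell
        ):
            raise ValidationError(
                f"paddock {self.paddock_id}: DEM does not cover the boundary"
            )

    @property
    def area_ha(self) -> float:
        return self.boundary.area / 1e4


@dataclass
class StudyBundle:
    """Everything one grazing study needs, cross-validated.

    tracks columns: cow_id, paddock_id, t (int s), x, y (projected m)
    pedometer columns: cow_id, paddock_id, duration_s, steps, lying_s
    bites columns: cow_id, pasture_id, sequence_index, taxon_id
    """

    cows: list[CowRecord]
    claws: list[ClawOutline]
    tracks: pd.DataFrame
    pedometer: pd.DataFrame
    bites: pd.DataFrame
    taxa: TaxonTable
    paddocks: dict[str, PaddockGeometry]

    def __post_init__(self) -> None:
        validate_bundle(self)

    def cow(self, cow_id: str) -> CowRecord:
        for c in self.cows:
            if c.cow_id == cow_id:
                return c
        raise KeyError(cow_id)

    @property
    def pasture_of(self) -> dict[str, str]:
        return {pid: p.pasture_id for pid, p in self.paddocks.items()}


def validate_bundle(bundle: StudyBundle) -> None:
    """Total referential and ordering validation; raises on first violation,
    naming the offending record."""
    cow_ids = [c.cow_id for c in bundle.cows]
    if len(set(cow_ids)) != len(cow_ids):
        dups = sorted({c for c in cow_ids if cow_ids.count(c) > 1})
        raise ValidationError(f"duplicate cow_id: {dups}")
    known_cows = set(cow_ids)
    known_paddocks = set(bundle.paddocks)
    known_pastures = {p.pasture_id for p in bundle.paddocks.values()}
    taxon_ids = bundle.taxa.ids

    for o in bundle.claws:
        if o.cow_id not in known_cows:
            raise ValidationError(f"claw outline references unknown cow {o.cow_id!r}")

    for name, df, cow_col in (
        ("tracks", bundle.tracks, "cow_id"),
        ("pedometer", bundle.pedometer, "cow_id"),
    ):
        if len(df) == 0:
            continue
        unknown = set(df[cow_col]) - known_cows
        if unknown:
            raise ValidationError(f"{name} reference unknown cows {sorted(unknown)}")
        unknown_p = set(df["paddock_id"]) - known_paddocks
        if unknown_p:
            raise ValidationError(
                f"{name} reference unknown paddocks {sorted(unknown_p)}"
            )

    if len(bundle.bites):
        unknown = set(bundle.bites["cow_id"]) - known_cows
        if unknown:
            raise ValidationError(f"bites reference unknown cows {sorted(unknown)}")
        unknown_pa = set(bundle.bites["pasture_id"]) - known_pastures
        if unknown_pa:
            raise ValidationError(
                f"bites reference unknown pastures {sorted(unknown_pa)}"
            )
        bad = bundle.bites[~bundle.bites["taxon_id"].isin(taxon_ids)]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"bite row (cow {row['cow_id']}, pasture {row['pasture_id']}, "
                f"index {row['sequence_index']}) references unknown taxon "
                f"{row['taxon_id']!r}"
            )

    if len(bundle.tracks):
        for (cow, pad), grp in bundle.tracks.groupby(["cow_id", "paddock_id"]):
            t = grp["t"].to_numpy()
            diffs = np.diff(t)
            if (diffs <= 0).any():
                i = int(np.argmax(diffs <= 0))
                raise ValidationError(
                    f"non-monotone timestamps for cow {cow} in paddock {pad} "
                    f"at record {i + 1} (t={t[i + 1]} after t={t[i]})"
                )


def cows_frame(cows: Sequence[CowRecord]) -> pd.DataFrame:
    """Tabular view of a list of cow records."""
    return pd.DataFrame(
        {
            "cow_id": [c.cow_id for c in cows],
            "breed": [c.breed for c in cows],
            "age_months": [c.age_months for c in cows],
            "weight_start": [c.weight_start for c in cows],
            "weight_end": [c.weight_end for c in cows],
            "days_on_pasture": [c.days_on_pasture for c in cows],
        }
    )
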
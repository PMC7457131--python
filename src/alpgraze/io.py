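"""File readers and writers for every record type, plus study configuration.

Formats are deliberately plain: comma-separated UTF-8 CSV with a mandatory
header for tabular records, Esri ASCII grid for DEMs, WKT for paddock
boundaries, YAML for the study configuration.  All coordinates must already
be projected metric; the package performs no CRS transforms.  Column names
can be remapped per file via a ``columns:`` mapping in the config, so the
readers adapt to externally deposited layouts.

A study config looks like::

    cows: cows.csv
    claws: claws.csv
    gps: gps.csv
    pedometer: pedometer.csv
    bites: bites.csv
    taxa: taxa.csv
    group_members: group_members.csv
    paddocks: paddocks.csv        # paddock_id,pasture_id,wkt,dem,water
    columns:
      gps: {timestamp: t}         # optional per-file renames
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from shapely import wkt as shapely_wkt

from .records import (
    Claw,
    ClawOutline,
    CowRecord,
    Foot,
    PaddockGeometry,
    StudyBundle,
    TaxonTable,
    ValidationError,
    cows_frame,
)


def _read_csv(path: Path, renames: dict[str, str] | None = None) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"missing file: {path}")
    df = pd.read_csv(path)
    if renames:
        df = df.rename(columns=renames)
    return df


# ---------------------------------------------------------------------------
# per-type readers / writers


def read_cows(path: Path, renames=None) -> list[CowRecord]:
    df = _read_csv(Path(path), renames)
    return [
        CowRecord(
            cow_id=str(r.cow_id), breed=str(r.breed),
            age_months=float(r.age_months),
            weight_start=float(r.weight_start), weight_end=float(r.weight_end),
            days_on_pasture=int(r.days_on_pasture),
        )
        for r in df.itertuples()
    ]


def write_cows(cows, path: Path) -> None:
    cows_frame(cows).to_csv(path, index=False)


def read_claws(path: Path, renames=None) -> list[ClawOutline]:
    """Claw vertices CSV: cow_id, foot, claw, vertex_index, x_cm, y_cm."""
    df = _read_csv(Path(path), renames)
    outlines = []
    for (cow, foot, claw), grp in df.groupby(["cow_id", "foot", "claw"], sort=True):
        grp = grp.sort_values("vertex_index")
        outlines.append(
            ClawOutline(
                cow_id=str(cow), foot=Foot(foot), claw=Claw(claw),
                vertices=tuple(zip(grp["x_cm"], grp["y_cm"])),
            )
        )
    return outlines


def write_claws(claws, path: Path) -> None:
    rows = []
    for o in claws:
        for i, (x, y) in enumerate(o.vertices):
            rows.append(
                {
                    "cow_id": o.cow_id, "foot": o.foot.value, "claw": o.claw.value,
                    "vertex_index": i, "x_cm": x, "y_cm": y,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gps(path: Path, renames=None) -> pd.DataFrame:
    """GPS fixes CSV: cow_id, paddock_id, t (integer s), x, y (projected m).

    Rejects duplicate or decreasing timestamps per cow x paddock, naming
    the cow and the offending line.
    """
    df = _read_csv(Path(path), renames)
    df["t"] = df["t"].astype(np.int64)
    for (cow, pad), grp in df.groupby(["cow_id", "paddock_id"]):
        t = grp["t"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            line = int(grp.index[bad[0] + 1]) + 2  # header + 1-based
            raise ValidationError(
                f"GPS file {path}: non-monotone timestamp for cow {cow} "
                f"(paddock {pad}) at line {line}"
            )
    return df


def write_gps(tracks: pd.DataFrame, path: Path) -> None:
    tracks.to_csv(path, index=False)


def read_pedometer(path: Path, renames=None) -> pd.DataFrame:
    df = _read_csv(Path(path), renames)
    bad = df[(df["lying_s"] < 0) | (df["lying_s"] > df["duration_s"])]
    if len(bad):
        raise ValidationError(
            f"pedometer file {path}: lying_s outside [0, duration_s] at row "
            f"{int(bad.index[0])}"
        )
    return df


def read_bites(path: Path, renames=None) -> pd.DataFrame:
    return _read_csv(Path(path), renames)


def read_taxa(
    taxa_path: Path, members_path: Path | None = None, renames=None
) -> TaxonTable:
    taxa = _read_csv(Path(taxa_path), renames)
    members = (
        _read_csv(Path(members_path))
        if members_path
        else pd.DataFrame(columns=["group_id", "species_id", "pasture_id", "abundance"])
    )
    return TaxonTable(taxa=taxa, members=members)


def write_taxa(taxa: TaxonTable, taxa_path: Path, members_path: Path) -> None:
    taxa.taxa.to_csv(taxa_path, index=False)
    taxa.members.to_csv(members_path, index=False)


# ---------------------------------------------------------------------------
# rasters and geometry


def read_esri_ascii(path: Path) -> tuple[np.ndarray, float, float, float]:
    """Read an Esri ASCII grid; returns (array row 0 = south, x0, y0, cell)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"missing file: {path}")
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, val = lines[i].split()[:2]
        header[key.lower()] = float(val)
        i += 1
    data = np.loadtxt(lines[i:])
    data = np.atleast_2d(data)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        raise ValidationError(
            f"{path}: grid shape {data.shape} does not match header "
            f"({nrows}, {ncols})"
        )
    # ASCII grids store row 0 at the north edge; flip to south-origin
    return data[::-1].copy(), header["xllcorner"], header["yllcorner"], header["cellsize"]


def write_esri_ascii(
    path: Path, values: np.ndarray, x0: float, y0: float, cell: float,
    nodata: float = -9999.0,
) -> None:
    values = np.asarray(values, dtype=float)
    ny, nx = values.shape
    with open(path, "w") as fh:
        fh.write(
            f"ncols {nx}\nnrows {ny}\nxllcorner {x0!r}\nyllcorner {y0!r}\n"
            f"cellsize {cell!r}\nNODATA_value {nodata!r}\n"
        )
        for row in values[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_paddocks(path: Path, base_dir: Path) -> dict[str, PaddockGeometry]:
    """Paddock index CSV: paddock_id, pasture_id, wkt, dem, water.

    ``dem`` is a path to an Esri ASCII grid relative to the index file;
    ``water`` is a semicolon-separated list of ``x y`` pairs.
    """
    df = _read_csv(Path(path))
    paddocks = {}
    for r in df.itertuples():
        boundary = shapely_wkt.loads(r.wkt)
        dem, x0, y0, cell = read_esri_ascii(base_dir / r.dem)
        water = tuple(
            tuple(float(v) for v in pair.split())
            for pair in str(r.water).split(";")
        )
        paddocks[str(r.paddock_id)] = PaddockGeometry(
            paddock_id=str(r.paddock_id), pasture_id=str(r.pasture_id),
            boundary=boundary, water_points=water,
            dem=dem, dem_x0=x0, dem_y0=y0, dem_cell=cell,
        )
    return paddocks


def write_paddocks(
    paddocks: dict[str, PaddockGeometry], path: Path, base_dir: Path
) -> None:
    rows = []
    for pid, p in paddocks.items():
        dem_name = f"dem_{pid}.asc"
        write_esri_ascii(base_dir / dem_name, p.dem, p.dem_x0, p.dem_y0, p.dem_cell)
        rows.append(
            {
                "paddock_id": pid,
                "pasture_id": p.pasture_id,
                "wkt": p.boundary.wkt,
                "dem": dem_name,
                "water": ";".join(f"{x!r} {y!r}" for x, y in p.water_points),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# whole study


def read_study(config_path: Path) -> StudyBundle:
    """Load and cross-validate a whole study from a YAML config.

    Every GPS/pedometer/bite record must reference a known cow, paddock and
    taxon; violations raise :class:`ValidationError` naming the offender.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent
    col = cfg.get("columns", {}) or {}

    def p(key: str) -> Path:
        return base / cfg[key]

    bundle = StudyBundle(
        cows=read_cows(p("cows"), col.get("cows")),
        claws=read_claws(p("claws"), col.get("claws")),
        tracks=read_gps(p("gps"), col.get("gps")),
        pedometer=read_pedometer(p("pedometer"), col.get("pedometer")),
        bites=read_bites(p("bites"), col.get("bites")),
        taxa=read_taxa(
            p("taxa"),
            base / cfg["group_members"] if cfg.get("group_members") else None,
            col.get("taxa"),
        ),
        paddocks=read_paddocks(p("paddocks"), base),
    )
    return bundle


def write_study(bundle: StudyBundle, out_dir: Path) -> Path:
    """Write a bundle as the exact file set :func:`read_study` reads;
    returns the config path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_cows(bundle.cows, out_dir / "cows.csv")
    write_claws(bundle.claws, out_dir / "claws.csv")
    write_gps(bundle.tracks, out_dir / "gps.csv")
    bundle.pedometer.to_csv(out_dir / "pedometer.csv", index=False)
    bundle.bites.to_csv(out_dir / "bites.csv", index=False)
    write_taxa(bundle.taxa, out_dir / "taxa.csv", out_dir / "group_members.csv")
    write_paddocks(bundle.paddocks, out_dir / "paddocks.csv", out_dir)
    cfg = {
        "cows": "cows.csv",
        "claws": "claws.csv",
        "gps": "gps.csv",
        "pedometer": "pedometer.csv",
        "bites": "bites.csv",
        "taxa": "taxa.csv",
        "group_members": "group_members.csv",
        "paddocks": "paddocks.csv",
    }
    cfg_path = out_dir / "study.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(
    tables: dict[str, pd.DataFrame], out_dir: Path, metadata: dict | None = None
) -> dict:
    """Write one CSV per named table plus a JSON manifest with run metadata
    (seed, config hash, row counts).  Returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"tables": {}, "metadata": metadata or {}}
    for name, df in tables.items():
        fname = f"{name}.csv"
        df.to_csv(out_dir / fname, index=False)
        manifest["tables"][name] = {"file": fname, "rows": int(len(df))}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
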
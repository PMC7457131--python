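"""Claw-base area, static pressure, weight change, metabolic stocking.

The claw base of each cow is measured from traced outlines of the left
fore- and hindfoot (medial and lateral claw each).  Taking the left claws
as proxies for the right ones, the four left-claw areas are doubled and
summed to give the total supporting area A (cm²).  Static pressure is the
body weight divided by A (kg/cm²; the factor g is deliberately not applied,
so this is a pressure of *mass* — multiply by 98.0665 for kPa).  Herd-level
stocking arithmetic normalises metabolic body mass W^0.75 to a 600 kg
reference cow (livestock units, LU).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .records import Claw, ClawOutline, CowRecord, Foot, ValidationError

#: Reference body weight of one livestock unit, kg.
LU_REFERENCE_KG = 600.0

#: Multiply a kg/cm² mass-pressure by this to get kPa.
KG_PER_CM2_TO_KPA = 98.0665


def polygon_area(vertices: Sequence[tuple[float, float]]) -> float:
    """Area (cm²) of a simple polygon given its ordered vertices.

    Orientation-independent (absolute shoelace area). Raises
    :class:`ValidationError` for fewer than 3 vertices or a
    self-intersecting outline.
    """
    if len(vertices) < 3:
        raise ValidationError(f"polygon needs >= 3 vertices, got {len(vertices)}")
    poly = Polygon(vertices)
    if not poly.is_simple:
        raise ValidationError("polygon is self-intersecting")
    return float(poly.area)


def total_claw_base(outlines: Iterable[ClawOutline]) -> float:
    """Total claw-base area of one cow, cm².

    Expects exactly the four left-side outlines (fore/hind x medial/lateral);
    the left side proxies the right, so the summed area is doubled.
    """
    outlines = list(outlines)
    seen: dict[tuple[Foot, Claw], float] = {}
    for o in outlines:
        key = (o.foot, o.claw)
        if key in seen:
            raise ValidationError(
                f"duplicate outline for {o.foot.value}/{o.claw.value}"
                + (f" (cow {o.cow_id})" if o.cow_id else "")
            )
        seen[key] = polygon_area(o.vertices)
    expected = {(f, c) for f in Foot for c in Claw}
    missing = expected - set(seen)
    if missing:
        names = sorted(f"{f.value}/{c.value}" for f, c in missing)
        raise ValidationError(f"missing claw outline(s): {', '.join(names)}")
    return 2.0 * sum(seen.values())


def static_pressure(weight_kg: float, claw_base_cm2: float) -> float:
    """Static pressure of body mass on the ground, kg/cm²."""
    if weight_kg <= 0:
        raise ValidationError(f"weight must be > 0, got {weight_kg}")
    if claw_base_cm2 <= 0:
        raise ValidationError(f"claw base must be > 0, got {claw_base_cm2}")
    return weight_kg / claw_base_cm2


def daily_weight_change(w_start_kg: float, w_end_kg: float, days: float) -> float:
    """Average body-weight change over the grazing period, kg/day
    (negative = loss)."""
    if days < 1:
        raise ValidationError(f"days must be >= 1, got {days}")
    return (w_end_kg - w_start_kg) / days


def metabolic_lu(weight_kg: float, reference_kg: float = LU_REFERENCE_KG) -> float:
    """Livestock units: metabolic body mass normalised to the reference cow,
    (W / 600 kg)^0.75."""
    if weight_kg <= 0:
        raise ValidationError(f"weight must be > 0, got {weight_kg}")
    return float((weight_kg / reference_kg) ** 0.75)


def stocking_density(lus: Sequence[float], area_ha: float) -> float:
    """Herd stocking density, LU/ha."""
    if len(lus) == 0:
        raise ValidationError("empty herd")
    if area_ha <= 0:
        raise ValidationError(f"area must be > 0 ha, got {area_ha}")
    return float(np.sum(lus)) / area_ha


def anatomy_table(
    cows: Sequence[CowRecord],
    claws: Sequence[ClawOutline],
    pressure_weight: str = "end",
) -> pd.DataFrame:
    """Per-cow anatomy metrics.

    ``pressure_weight`` selects which weighing enters the pressure quotient:
    "end" (default; claw base is measured at the end of the season) or
    "start".

    Columns: cow_id, breed, weight (the selected one), claw_base_cm2,
    static_pressure, weight_change_kg_d, metabolic_lu.
    """
    if pressure_weight not in ("start", "end"):
        raise ValueError("pressure_weight must be 'start' or 'end'")
    by_cow: dict[str, list[ClawOutline]] = {}
    for o in claws:
        by_cow.setdefault(o.cow_id, []).append(o)
    rows = []
    for c in cows:
        base = total_claw_base(by_cow.get(c.cow_id, []))
        w = c.weight_end if pressure_weight == "end" else c.weight_start
        rows.append(
            {
                "cow_id": c.cow_id,
                "breed": c.breed,
                "weight": w,
                "claw_base_cm2": base,
                "static_pressure": static_pressure(w, base),
                "weight_change_kg_d": daily_weight_change(
                    c.weight_start, c.weight_end, c.days_on_pasture
                ),
                "metabolic_lu": metabolic_lu(w),
            }
        )
    return pd.DataFrame(rows)
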
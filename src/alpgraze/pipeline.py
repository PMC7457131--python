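"""Orchestration: bundle -> per-cow metrics -> breed comparisons -> allometry.

`run_study` sequences the analysis stages on a validated bundle (field data
or synthetic): anatomy metrics per cow, movement and diet metrics per cow
and pasture, Tukey range tests between breeds (on per-animal means over all
pastures as well as per pasture), a breed x paddock-size ANOVA for the
movement variables, and standardized-major-axis comparisons for a standard
set of nine trait pairs spanning anatomy, movement, and foraging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allometry import anova_breed_size, grouped_allometry, sma_fit, tukey_pairwise
from .anatomy import anatomy_table
from .foraging import diet_profile
from .io import config_hash
from .movement import movement_metrics
from .records import DegenerateDataError, StudyBundle

#: The nine standard allometric (x, y) pairs reported by the pipeline.
DEFAULT_ALLOMETRY_PAIRS: list[tuple[str, str]] = [
    ("weight", "claw_base_cm2"),
    ("forage_quality", "weight_change_kg_d"),
    ("selection_evenness", "lying_ratio"),
    ("space_evenness", "selection_evenness"),
    ("space_evenness", "forage_quality"),
    ("forage_quality", "selection_evenness"),
    ("steps_per_h", "space_evenness"),
    ("steps_per_h", "selection_evenness"),
    ("steps_per_h", "forage_quality"),
]

#: Variables compared between breeds with Tukey range tests.
TUKEY_VARIABLES = [
    "weight", "claw_base_cm2", "static_pressure", "weight_change_kg_d",
    "steps_per_h", "lying_ratio", "speed_m_h", "space_evenness",
    "selection_evenness", "forage_quality", "slope_coef", "water_coef",
]


@dataclass
class StudyReport:
    per_cow_pasture: pd.DataFrame
    per_cow: pd.DataFrame
    tukey: pd.DataFrame
    anova: pd.DataFrame
    allometry: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "per_cow_pasture": self.per_cow_pasture,
            "per_cow": self.per_cow,
            "tukey": self.tukey,
            "anova": self.anova,
            "allometry": self.allometry,
        }


def per_cow_pasture_metrics(bundle: StudyBundle) -> pd.DataFrame:
    """Movement and diet metrics for every cow x pasture with data."""
    breed_of = {c.cow_id: c.breed for c in bundle.cows}
    pasture_of = bundle.pasture_of
    rows = []
    track_groups = dict(iter(bundle.tracks.groupby(["cow_id", "paddock_id"])))
    pedo_groups = (
        dict(iter(bundle.pedometer.groupby(["cow_id", "paddock_id"])))
        if len(bundle.pedometer)
        else {}
    )
    for (cow, pad), fixes in sorted(track_groups.items()):
        paddock = bundle.paddocks[pad]
        m = movement_metrics(fixes, pedo_groups.get((cow, pad)), paddock)
        row = {
            "cow_id": cow,
            "breed": breed_of[cow],
            "paddock_id": pad,
            "pasture_id": pasture_of[pad],
            "paddock_size_ha": paddock.area_ha,
            "space_evenness": m["camargo_evenness"],
            **{
                k: m[k]
                for k in (
                    "speed_m_h", "distance_m", "steps_per_h", "lying_ratio",
                    "slope_coef", "water_coef", "n_fixes", "n_outside",
                )
            },
        }
        try:
            d = diet_profile(bundle.bites, bundle.taxa, cow, pasture_of[pad])
            row["forage_quality"] = d.quality_score
            row["selection_evenness"] = d.selection_evenness
            row["n_bites"] = d.n_bites
            for g, share in d.group_shares.items():
                row[f"share_{g}"] = share
        except DegenerateDataError:
            row["forage_quality"] = np.nan
            row["selection_evenness"] = np.nan
            row["n_bites"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


def per_cow_metrics(bundle: StudyBundle, pcp: pd.DataFrame | None = None) -> pd.DataFrame:
    """Anatomy metrics joined with per-animal means over all pastures."""
    if pcp is None:
        pcp = per_cow_pasture_metrics(bundle)
    anat = anatomy_table(bundle.cows, bundle.claws)
    behav_cols = [
        c
        for c in (
            "speed_m_h", "steps_per_h", "lying_ratio", "space_evenness",
            "selection_evenness", "forage_quality", "slope_coef", "water_coef",
        )
        if c in pcp.columns
    ]
    means = pcp.groupby("cow_id")[behav_cols].mean().reset_index()
    return anat.merge(means, on="cow_id", how="left")


def breed_tukey(
    per_cow: pd.DataFrame,
    pcp: pd.DataFrame,
    variables: list[str] = TUKEY_VARIABLES,
) -> pd.DataFrame:
    """Tukey range tests between breeds: per-animal overall means plus
    separate tests within each pasture."""
    frames = []

    def run(df: pd.DataFrame, var: str, scope: str):
        groups = {
            b: sub[var].dropna().to_numpy()
            for b, sub in df.groupby("breed")
            if sub[var].notna().sum() >= 2
        }
        if len(groups) < 2:
            return
        t = tukey_pairwise(groups)
        t.insert(0, "scope", scope)
        t.insert(0, "variable", var)
        frames.append(t)

    for var in variables:
        if var in per_cow.columns:
            run(per_cow, var, "overall")
        if var in pcp.columns:
            for pasture, sub in pcp.groupby("pasture_id"):
                run(sub, var, str(pasture))
    if not frames:
        return pd.DataFrame(
            columns=["variable", "scope", "group_a", "group_b", "mean_diff", "q", "p_adj"]
        )
    return pd.concat(frames, ignore_index=True)


def movement_anova(pcp: pd.DataFrame) -> pd.DataFrame:
    """Breed x paddock-size sequential ANOVA for the movement variables."""
    frames = []
    for var in ("steps_per_h", "speed_m_h", "space_evenness", "lying_ratio"):
        if var not in pcp.columns:
            continue
        sub = pcp.dropna(subset=[var])
        if sub.empty or sub["breed"].nunique() < 2:
            continue
        try:
            tab = anova_breed_size(sub, var).reset_index(names="term")
        except DegenerateDataError:
            continue
        tab.insert(0, "variable", var)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def allometry_pairs(
    per_cow: pd.DataFrame,
    pairs: list[tuple[str, str]] = DEFAULT_ALLOMETRY_PAIRS,
    group_col: str = "breed",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Overall SMA fit plus breed-wise slope/shift/elevation tests for each
    trait pair.  Pairs with missing or degenerate data are flagged in the
    ``status`` column rather than aborting the batch."""
    rows = []
    for xvar, yvar in pairs:
        row: dict = {"x": xvar, "y": yvar, "status": "ok"}
        if xvar not in per_cow.columns or yvar not in per_cow.columns:
            row["status"] = "missing_variable"
            rows.append(row)
            continue
        sub = per_cow.dropna(subset=[xvar, yvar])
        try:
            overall = sma_fit(sub[xvar], sub[yvar])
            row.update(
                n=overall.n, slope=overall.slope, intercept=overall.intercept,
                r_squared=overall.r_squared,
            )
            groups = {
                str(b): (g[xvar].to_numpy(), g[yvar].to_numpy())
                for b, g in sub.groupby(group_col)
            }
            ga = grouped_allometry(groups, alpha=alpha)
            row.update(
                common_slope=ga.common.b_common,
                slope_p=ga.common.p_value,
                common_slope_rejected=ga.common_slope_rejected,
                shift_p=ga.shift.p_value,
                elevation_p=ga.elevation.p_value,
            )
        except DegenerateDataError as exc:
            row["status"] = f"degenerate: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    bundle: StudyBundle,
    seed: int | None = None,
    pairs: list[tuple[str, str]] = DEFAULT_ALLOMETRY_PAIRS,
) -> StudyReport:
    """Run every analysis stage on a validated study bundle."""
    pcp = per_cow_pasture_metrics(bundle)
    per_cow = per_cow_metrics(bundle, pcp)
    report = StudyReport(
        per_cow_pasture=pcp,
        per_cow=per_cow,
        tukey=breed_tukey(per_cow, pcp),
        anova=movement_anova(pcp),
        allometry=allometry_pairs(per_cow, pairs=pairs),
        metadata={
            "seed": seed,
            "n_cows": len(bundle.cows),
            "n_paddocks": len(bundle.paddocks),
            "config_hash": config_hash(
                {"pairs": pairs, "n_cows": len(bundle.cows)}
            ),
        },
    )
    return report
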
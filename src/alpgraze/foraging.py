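"""Diet composition, quality scoring, and selection evenness.

Bite sequences (one recorded taxon per bite) are reduced to per-cow,
per-pasture diet proportions.  Forage quality is scored on the Briemle
indicator scale (1–9) as the consumption-weighted mean of taxon values;
for field groups of hard-to-distinguish species the group's value is the
relevée-abundance-weighted mean of its members' values, resolved per
pasture.  Selectivity is summarised by Pielou's evenness J of the consumed
taxa: J near 1 means the cow ate taxa in nearly equal shares, small J means
a concentrated, selective diet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .records import DegenerateDataError, TaxonTable, ValidationError


@dataclass
class DietProfile:
    """Reduced diet of one cow on one pasture."""

    cow_id: str
    pasture_id: str
    proportions: pd.Series        # index taxon_id, sums to 1
    quality_score: float          # Q, Briemle scale
    selection_evenness: float     # Pielou J; NaN if undefined
    evenness_defined: bool        # False for a single-taxon diet
    group_shares: pd.Series       # index plant_group, sums to 1
    n_bites: int


def relative_consumption(taxa_sequence: Sequence[str]) -> pd.Series:
    """Diet proportions p_s = bites on taxon s / total bites.

    Order-invariant; the result sums to exactly 1.
    """
    if len(taxa_sequence) == 0:
        raise DegenerateDataError("empty bite sequence")
    counts = pd.Series(taxa_sequence).value_counts().sort_index()
    return counts / counts.sum()


def group_quality(members: Sequence[tuple[float, float]]) -> float:
    """Effective Briemle value of a species group on one pasture:
    Σ a_m q_m over members (q_m, a_m), abundances summing to 1."""
    if len(members) == 0:
        raise ValidationError("group has no members")
    qs = np.array([q for q, _ in members], dtype=float)
    abund = np.array([a for _, a in members], dtype=float)
    if abs(abund.sum() - 1.0) > 1e-9:
        raise ValidationError(f"member abundances sum to {abund.sum()}, not 1")
    return float(np.dot(qs, abund))


def resolve_quality(taxa: TaxonTable, pasture_id: str) -> pd.Series:
    """Briemle quality per taxon on one pasture: species use their own
    value, groups the abundance-weighted mean of their members' values."""
    q = taxa.taxa.set_index("taxon_id")["quality"].astype(float).copy()
    species_q = q.to_dict()
    for gid in taxa.taxa.loc[taxa.taxa["kind"] == "group", "taxon_id"]:
        mem = taxa.members[
            (taxa.members["group_id"] == gid)
            & (taxa.members["pasture_id"] == pasture_id)
        ]
        if mem.empty:
            raise ValidationError(
                f"group {gid!r} has no member abundances for pasture {pasture_id!r}"
            )
        pairs = [
            (species_q[row["species_id"]], row["abundance"])
            for _, row in mem.iterrows()
        ]
        q.loc[gid] = group_quality(pairs)
    return q


def diet_quality(
    proportions: pd.Series, taxa: TaxonTable, pasture_id: str
) -> float:
    """Average Briemle quality of the consumed forage, Q = Σ p_s q_s."""
    q = resolve_quality(taxa, pasture_id)
    missing = [t for t in proportions.index if t not in q.index or math.isnan(q[t])]
    if missing:
        raise ValidationError(f"no quality value for taxa {sorted(missing)}")
    return float((proportions * q.reindex(proportions.index)).sum())


def selection_evenness(proportions: pd.Series | np.ndarray) -> tuple[float, bool]:
    """Pielou's evenness of the consumed taxa.

    J = (−Σ p ln p) / ln S over the S taxa with p > 0.  Returns
    ``(J, True)``, or ``(nan, False)`` for a single-taxon diet where
    ln S = 0 leaves J undefined.
    """
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise DegenerateDataError("no positive proportions")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"proportions sum to {p.sum()}, not 1")
    if p.size == 1:
        return float("nan"), False
    shannon = float(-(p * np.log(p)).sum())
    return shannon / math.log(p.size), True


def group_shares(proportions: pd.Series, taxa: TaxonTable) -> pd.Series:
    """Diet share per plant group (broad grasses, legumes, thistles,
    shrubs, ...): the sum of proportions of the taxa mapped to each group."""
    groups = taxa.taxa.set_index("taxon_id")["plant_group"]
    missing = [t for t in proportions.index if t not in groups.index]
    if missing:
        raise ValidationError(f"taxa without plant group: {sorted(missing)}")
    return proportions.groupby(proportions.index.map(groups)).sum()


def diet_profile(
    bites: pd.DataFrame, taxa: TaxonTable, cow_id: str, pasture_id: str
) -> DietProfile:
    """Full diet reduction for one cow x pasture from a bites table
    (columns cow_id, pasture_id, taxon_id)."""
    sel = bites[(bites["cow_id"] == cow_id) & (bites["pasture_id"] == pasture_id)]
    props = relative_consumption(list(sel["taxon_id"]))
    j, defined = selection_evenness(props)
    return DietProfile(
        cow_id=cow_id,
        pasture_id=pasture_id,
        proportions=props,
        quality_score=diet_quality(props, taxa, pasture_id),
        selection_evenness=j,
        evenness_defined=defined,
        group_shares=group_shares(props, taxa),
        n_bites=len(sel),
    )


def fit_selectivity(
    diet_counts: pd.Series, availability: pd.Series, quality: pd.Series
) -> float:
    """Profile-likelihood estimate of the quality-selectivity temperature.

    Model: a bite lands on taxon s with probability
    ∝ availability_s · exp(τ · q_s).  Given observed bite counts this is a
    one-parameter multinomial likelihood in τ, maximised numerically.
    τ = 0 is neutral (diet mirrors availability); larger τ means stronger
    preference for high-quality taxa.
    """
    idx = diet_counts.index
    n = diet_counts.to_numpy(dtype=float)
    a = availability.reindex(idx).to_numpy(dtype=float)
    q = quality.reindex(idx).to_numpy(dtype=float)
    if np.any(np.isnan(a)) or np.any(np.isnan(q)):
        raise ValidationError("availability/quality missing for some consumed taxa")
    if n.sum() <= 0:
        raise DegenerateDataError("no bites")

    def nll(tau: float) -> float:
        logw = np.log(a) + tau * q
        logw -= logw.max()
        logp = logw - np.log(np.exp(logw).sum())
        return float(-(n * logp).sum())

    res = minimize_scalar(nll, bounds=(-10.0, 10.0), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)
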
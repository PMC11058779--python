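"""Fish ecological entities from guild triples.

An ecological entity is a cluster of fish species whose three ecological guild
labels — trophic, habitat, and tolerance — match exactly.  Entities, rather
than individual species, are the unit of the community analysis: they capture
the dominance of trait combinations while smoothing over species-level
idiosyncrasy.

Guild vocabularies
------------------
trophic    : Omn (omnivore), Ins (insectivore), Car (carnivore)
habitat    : BT (benthic), RB (riffle benthic), RB-WC (riffle benthic and
             water column), WC (water column)
tolerance  : SS (sensitive), IS (intermediate), TS (tolerant)

A guild table also carries a ``native`` flag per species; it plays no role in
entity construction and is used only by the biotic-integrity metrics.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import round_half_up

TROPHIC_GUILDS = ("Omn", "Ins", "Car")
HABITAT_GUILDS = ("BT", "RB", "RB-WC", "WC")
TOLERANCE_GUILDS = ("SS", "IS", "TS")

GUILD_FIELDS = ("trophic", "habitat", "tolerance")
_GUILD_LEVELS = {
    "trophic": TROPHIC_GUILDS,
    "habitat": HABITAT_GUILDS,
    "tolerance": TOLERANCE_GUILDS,
}


def validate_guild_table(guilds: pd.DataFrame) -> pd.DataFrame:
    """Validate a species -> guild assignment table.

    Expects a DataFrame indexed by species id (or with a ``species_id``
    column) with columns ``trophic``, ``habitat``, ``tolerance`` and
    optionally ``native`` (default True).  Returns a normalized copy.
    """
    g = guilds.copy()
    if "species_id" in g.columns:
        g = g.set_index("species_id")
    if g.empty:
        raise ValueError("guild table is empty")
    if g.index.duplicated().any():
        dups = g.index[g.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate species ids in guild table: {dups}")
    for field in GUILD_FIELDS:
        if field not in g.columns:
            raise ValueError(f"guild table lacks required column {field!r}")
        col = g[field]
        bad = g.index[col.isna()].tolist()
        if bad:
            raise ValueError(f"missing {field} label for species {bad}")
        levels = _GUILD_LEVELS[field]
        unknown = g.index[~col.isin(levels)].tolist()
        if unknown:
            raise ValueError(
                f"unknown {field} label for species {unknown}; "
                f"allowed: {levels}"
            )
    if "native" not in g.columns:
        g["native"] = True
    g["native"] = g["native"].astype(bool)
    return g[["trophic", "habitat", "tolerance", "native"]]


def build_entities(guilds: pd.DataFrame) -> pd.DataFrame:
    """Group species into ecological entities by exact guild-triple match.

    Entities are numbered FE-1, FE-2, ... in order of descending member
    count, ties broken by lexicographic (trophic, habitat, tolerance) label
    order — a deterministic convention; the grouping itself does not depend
    on it.

    Returns a catalog DataFrame indexed by ``entity_id`` with columns
    ``trophic``, ``habitat``, ``tolerance``, ``n_species``, ``members``
    (a tuple of species ids).
    """
    g = validate_guild_table(guilds)
    grouped = g.groupby(list(GUILD_FIELDS), sort=True, observed=True)
    rows = []
    for triple, sub in grouped:
        rows.append(
            {
                "trophic": triple[0],
                "habitat": triple[1],
                "tolerance": triple[2],
                "n_species": len(sub),
                "members": tuple(sub.index),
            }
        )
    cat = pd.DataFrame(rows)
    cat = cat.sort_values(
        by=["n_species", "trophic", "habitat", "tolerance"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    cat.index = pd.Index(
        [f"FE-{i + 1}" for i in range(len(cat))], name="entity_id"
    )
    return cat


def validate_abundance(
    abund: pd.DataFrame, anomalies: pd.DataFrame | None = None
) -> None:
    """Check a site x species count matrix (and optional parallel anomalies)."""
    if abund.index.duplicated().any():
        raise ValueError("duplicate site ids in abundance matrix")
    if abund.columns.duplicated().any():
        raise ValueError("duplicate species columns in abundance matrix")
    vals = abund.to_numpy()
    if np.any(vals < 0):
        raise ValueError("abundance matrix contains negative counts")
    if anomalies is not None:
        if not abund.index.equals(anomalies.index) or not abund.columns.equals(
            anomalies.columns
        ):
            raise ValueError("anomalies matrix shape/labels differ from counts")
        avals = anomalies.to_numpy()
        if np.any(avals < 0):
            raise ValueError("anomalies matrix contains negative counts")
        if np.any(avals > vals):
            raise ValueError("anomalies exceed counts for some (site, species)")


def entity_abundance(abund: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a site x species count matrix to site x entity counts.

    Every species column must belong to some catalog entity; orphans are a
    hard error (silently dropping them would break the conservation of total
    individuals between the species and entity matrices).
    """
    validate_abundance(abund)
    member_of: dict[str, str] = {}
    for eid, row in catalog.iterrows():
        for sp in row["members"]:
            member_of[sp] = eid
    orphans = [sp for sp in abund.columns if sp not in member_of]
    if orphans:
        raise ValueError(f"species absent from entity catalog: {orphans}")
    out = pd.DataFrame(
        0, index=abund.index, columns=catalog.index, dtype=abund.to_numpy().dtype
    )
    for sp in abund.columns:
        out[member_of[sp]] += abund[sp]
    return out


def relative_abundance(
    em: pd.DataFrame,
    scope: str = "per_site",
    groups: Mapping[str, object] | pd.Series | None = None,
    decimals: int | None = 1,
):
    """Relative abundance (% of individuals) per entity within a scope.

    scope:
      - ``per_site``: each site sums to 100 (site x entity DataFrame)
      - ``per_group``: sites pooled by ``groups`` labels (group x entity)
      - ``entire``: pooled over all sites (Series per entity)

    Percentages are reported to one decimal, half-up, matching survey-table
    convention; pass ``decimals=None`` for unrounded values.
    """
    if scope == "per_site":
        totals = em.sum(axis=1)
        _check_positive_totals(totals, "site")
        ra = em.div(totals, axis=0) * 100.0
    elif scope == "per_group":
        if groups is None:
            raise ValueError("scope='per_group' requires a site->group mapping")
        grp = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
        missing = em.index.difference(grp.index)
        if len(missing):
            raise ValueError(f"sites without group label: {list(missing)}")
        pooled = em.groupby(grp.reindex(em.index)).sum()
        totals = pooled.sum(axis=1)
        _check_positive_totals(totals, "group")
        ra = pooled.div(totals, axis=0) * 100.0
    elif scope == "entire":
        pooled = em.sum(axis=0)
        total = pooled.sum()
        if total <= 0:
            raise ValueError("relative abundance undefined: no individuals")
        ra = pooled / total * 100.0
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if decimals is not None:
        if isinstance(ra, pd.Series):
            ra = pd.Series(round_half_up(ra.to_numpy(), decimals), index=ra.index)
        else:
            ra = pd.DataFrame(
                round_half_up(ra.to_numpy(), decimals),
                index=ra.index,
                columns=ra.columns,
            )
    return ra


def _check_positive_totals(totals: pd.Series, unit: str) -> None:
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(
            f"relative abundance undefined for {unit}(s) with zero total: {zero}"
        )


def entity_occupancy(em: pd.DataFrame, decimals: int | None = 1) -> pd.Series:
    """Per-entity percentage of sites where the entity was observed."""
    if len(em.index) == 0:
        raise ValueError("occupancy requires at least one site")
    occ = (em > 0).sum(axis=0) / len(em.index) * 100.0
    if decimals is not None:
        occ = pd.Series(round_half_up(occ.to_numpy(), decimals), index=occ.index)
    return occ


def entity_richness(
    em: pd.DataFrame, groups: Mapping[str, object] | pd.Series | None = None
):
    """Number of entities with a positive total, overall or per group."""
    if groups is None:
        return int((em.sum(axis=0) > 0).sum())
    grp = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    missing = em.index.difference(grp.index)
    if len(missing):
        raise ValueError(f"sites without group label: {list(missing)}")
    pooled = em.groupby(grp.reindex(em.index)).sum()
    return (pooled > 0).sum(axis=1).astype(int)


class EcologicalEntities(BaseEstimator, TransformerMixin):
    """Transformer from species abundance matrices to entity abundance.

    ``fit`` takes the guild assignment table and builds the entity catalog;
    ``transform`` aggregates a site x species count matrix to site x entity.

    Attributes
    ----------
    catalog_ : DataFrame
        Entity catalog (see :func:`build_entities`).
    n_entities_ : int
    """

    def fit(self, X: pd.DataFrame, y=None):
        self.catalog_ = build_entities(X)
        self.n_entities_ = len(self.catalog_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "catalog_"):
            raise ValueError("EcologicalEntities is not fitted")
        return entity_abundance(X, self.catalog_)
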
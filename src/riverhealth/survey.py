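"""Published regional survey summary used as a worked example.

A fish survey of 41 wadable stream sites in a temperate river basin recorded
4622 individuals of 50 species, which group into 19 ecological entities by
exact guild-triple match.  The per-entity summary below (guild triple, member
species count, total individuals over the whole region) and the per-cluster
individual totals are shipped as package data: they drive the worked example
in the README and serve as a realistic target structure for the synthetic
generator's default guild plan.

Species identities are not part of the summary; only entity-level totals are.
"""

from __future__ import annotations

import pandas as pd

# (trophic, habitat, tolerance, n_species, total individuals region-wide)
_ENTITY_ROWS = [
    ("Omn", "WC", "IS", 8, 406),
    ("Omn", "WC", "TS", 6, 217),
    ("Ins", "WC", "IS", 5, 175),
    ("Omn", "BT", "TS", 4, 32),
    ("Ins", "RB", "SS", 3, 82),
    ("Ins", "WC", "TS", 3, 170),
    ("Ins", "RB", "IS", 3, 287),
    ("Ins", "RB-WC", "IS", 2, 219),
    ("Ins", "BT", "IS", 2, 263),
    ("Car", "WC", "TS", 2, 93),
    ("Car", "BT", "TS", 2, 3),
    ("Car", "BT", "IS", 2, 70),
    ("Car", "BT", "SS", 2, 33),
    ("Omn", "RB", "IS", 1, 62),
    ("Omn", "RB", "SS", 1, 49),
    ("Ins", "RB-WC", "SS", 1, 353),
    ("Omn", "RB-WC", "IS", 1, 2022),
    ("Car", "RB-WC", "TS", 1, 77),
    ("Ins", "BT", "TS", 1, 9),
]

#: Individuals per chemical spatial cluster (SC-1 ... SC-5), all entities pooled.
CLUSTER_TOTAL_INDIVIDUALS = pd.Series(
    [621, 1213, 1147, 751, 890],
    index=[f"SC-{i}" for i in range(1, 6)],
    name="total_individuals",
)

#: Number of survey sites.
N_SITES = 41


def regional_entity_summary() -> pd.DataFrame:
    """Entity-level summary of the regional survey.

    Returns a DataFrame indexed FE-1..FE-19 (survey numbering) with columns
    ``trophic``, ``habitat``, ``tolerance``, ``n_species``,
    ``total_individuals``.
    """
    df = pd.DataFrame(
        _ENTITY_ROWS,
        columns=["trophic", "habitat", "tolerance", "n_species", "total_individuals"],
    )
    df.index = pd.Index([f"FE-{i + 1}" for i in range(len(df))], name="entity_id")
    return df


def guild_plan() -> list[tuple[str, str, str, int]]:
    """The survey's guild composition as a synthetic-generator plan.

    One (trophic, habitat, tolerance, n_species) tuple per entity; the member
    counts sum to the survey's 50 species.
    """
    return [(t, h, tol, n) for t, h, tol, n, _ in _ENTITY_ROWS]
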
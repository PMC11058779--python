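"""CSV / JSON readers and writers for the pipeline's tables.

All tabular interchange is header-ed UTF-8 CSV: guild tables, wide abundance
matrices (first column ``site_id``), chemistry and covariate tables, square
distance matrices, entity catalogs (members ';'-joined), and criteria/band
configuration as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .guilds import validate_abundance, validate_guild_table
from .indices import MetricCriterion, validate_bands

CHEM_COLUMNS = [
    "WT", "DO", "EC", "TSS", "TOC", "BOD", "TN",
    "NH4_N", "NO3_N", "TP", "PO4_P", "TN_TP", "Chl_a",
]


def read_guilds(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise ValueError(f"{path}: guild CSV requires a species_id column")
    return validate_guild_table(df)


def write_guilds(guilds: pd.DataFrame, path) -> None:
    guilds.rename_axis("species_id").reset_index().to_csv(path, index=False)


def read_abundance(path, anomalies_path=None):
    """Wide abundance CSV (site_id + one column per species); optional
    parallel anomalies CSV of identical shape."""
    abund = pd.read_csv(path).set_index("site_id")
    anomalies = None
    if anomalies_path is not None:
        anomalies = pd.read_csv(anomalies_path).set_index("site_id")
    validate_abundance(abund, anomalies)
    return (abund, anomalies) if anomalies_path is not None else (abund, None)


def write_abundance(abund: pd.DataFrame, path) -> None:
    abund.rename_axis("site_id").reset_index().to_csv(path, index=False)


def read_chemistry(path) -> pd.DataFrame:
    chem = pd.read_csv(path).set_index("site_id")
    missing = [c for c in CHEM_COLUMNS if c not in chem.columns]
    if missing:
        raise ValueError(f"{path}: chemistry CSV lacks columns {missing}")
    if (chem[CHEM_COLUMNS] < 0).any().any():
        raise ValueError(f"{path}: chemistry values must be non-negative")
    return chem[CHEM_COLUMNS]


def write_chemistry(chem: pd.DataFrame, path) -> None:
    chem.rename_axis("site_id").reset_index().to_csv(path, index=False)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("site_id")


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.rename_axis("site_id").reset_index().to_csv(path, index=False)


def write_catalog(catalog: pd.DataFrame, path) -> None:
    out = catalog.copy()
    out["members"] = out["members"].map(";".join)
    out.rename_axis("entity_id").reset_index().to_csv(path, index=False)


def read_catalog(path) -> pd.DataFrame:
    cat = pd.read_csv(path).set_index("entity_id")
    cat["members"] = cat["members"].map(lambda s: tuple(s.split(";")))
    return cat


def write_distance_matrix(dm: pd.DataFrame, path) -> None:
    dm.rename_axis("site_id").to_csv(path)


def read_distance_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_criteria(path) -> tuple[dict, list]:
    """Criteria config JSON: {"criteria": {metric: {direction, cut1, cut2}},
    "bands": [[lo, hi, label], ...]}; validated at load."""
    with open(path) as fh:
        cfg = json.load(fh)
    criteria = {
        m: MetricCriterion(spec["direction"], float(spec["cut1"]), float(spec["cut2"]))
        for m, spec in cfg.get("criteria", {}).items()
    }
    bands = [tuple(b) for b in cfg.get("bands", [])]
    if bands:
        validate_bands(bands)
    return criteria, bands


def write_criteria(criteria: dict, bands, path) -> None:
    cfg = {
        "criteria": {
            m: {"direction": c.direction, "cut1": c.cut1, "cut2": c.cut2}
            for m, c in criteria.items()
        },
        "bands": [list(b) for b in bands],
    }
    Path(path).write_text(json.dumps(cfg, indent=2))
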
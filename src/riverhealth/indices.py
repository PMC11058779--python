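"""Multimetric health indices: chemical (mWPI) and fish-based (mIBI-F).

Both indices follow the classic discrete scoring scheme: each metric is
assigned 5, 3, or 1 against two concentration/value cut points, and the metric
scores are summed.  The water pollution index (mWPI) scores seven chemical
metrics covering the nutrient regime (TN, TP, TN:TP), organic matter (BOD),
suspended solids and ionic content (TSS, EC), and primary productivity
(sestonic chlorophyll-a); its total spans 7-35 and a higher score means better
chemical health.  The fish index of biotic integrity (mIBI-F) scores eight
community metrics spanning species richness/composition, trophic composition,
and abundance/individual health; its total spans 8-40.

The numeric 5/3/1 cut points are configuration, not dogma: regional programs
publish their own.  The defaults shipped here are documented package choices
(see docs/methods.md) and every scoring routine takes an explicit criteria
set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .guilds import validate_abundance, validate_guild_table

LOWER_IS_BETTER = "lower_is_better"
HIGHER_IS_BETTER = "higher_is_better"

#: Chemistry columns expected by the mWPI (units in parentheses).
MWPI_METRICS = ("TN", "TP", "TN_TP", "BOD", "TSS", "EC", "Chl_a")

#: The eight fish community metrics.
MIBIF_METRICS = ("M1_NS", "M2_RB", "M3_SS", "M4_pTS", "M5_pOmn", "M6_pNIns", "M7_NSI", "M8_pAno")


@dataclass(frozen=True)
class MetricCriterion:
    """Two ordered cut points mapping a metric value to a 5/3/1 score.

    For ``lower_is_better``: value <= cut1 -> 5, <= cut2 -> 3, else 1.
    For ``higher_is_better``: value >= cut2 -> 5, >= cut1 -> 3, else 1.
    Values equal to a cut take the better score.
    """

    direction: str
    cut1: float
    cut2: float

    def __post_init__(self):
        if self.direction not in (LOWER_IS_BETTER, HIGHER_IS_BETTER):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not (self.cut1 < self.cut2):
            raise ValueError(
                f"criterion cuts must be strictly increasing, got {self.cut1}, {self.cut2}"
            )


def score_metric(value: float, criterion: MetricCriterion) -> int:
    """Discrete 5/3/1 score of one metric value."""
    if not math.isfinite(value):
        raise ValueError(f"cannot score non-finite metric value {value!r}")
    if criterion.direction == LOWER_IS_BETTER:
        if value <= criterion.cut1:
            return 5
        if value <= criterion.cut2:
            return 3
        return 1
    if value >= criterion.cut2:
        return 5
    if value >= criterion.cut1:
        return 3
    return 1


# --- default criteria -------------------------------------------------------
# Chemical cuts (units as in ChemistryTable: TP and Chl-a in ug/L, the rest
# mg/L or dimensionless).  Chosen so the per-cluster score ranges of a
# temperate wadable-stream survey are reproduced; see docs/methods.md.
DEFAULT_MWPI_CRITERIA: dict[str, MetricCriterion] = {
    "TN": MetricCriterion(LOWER_IS_BETTER, 2.0, 4.0),
    "TP": MetricCriterion(LOWER_IS_BETTER, 30.0, 100.0),
    "TN_TP": MetricCriterion(HIGHER_IS_BETTER, 50.0, 100.0),
    "BOD": MetricCriterion(LOWER_IS_BETTER, 1.0, 3.0),
    "TSS": MetricCriterion(LOWER_IS_BETTER, 5.0, 10.0),
    "EC": MetricCriterion(LOWER_IS_BETTER, 200.0, 450.0),
    "Chl_a": MetricCriterion(LOWER_IS_BETTER, 5.0, 25.0),
}

DEFAULT_MIBIF_CRITERIA: dict[str, MetricCriterion] = {
    "M1_NS": MetricCriterion(HIGHER_IS_BETTER, 5.0, 10.0),
    "M2_RB": MetricCriterion(HIGHER_IS_BETTER, 1.0, 3.0),
    "M3_SS": MetricCriterion(HIGHER_IS_BETTER, 1.0, 3.0),
    "M4_pTS": MetricCriterion(LOWER_IS_BETTER, 20.0, 45.0),
    "M5_pOmn": MetricCriterion(LOWER_IS_BETTER, 25.0, 50.0),
    "M6_pNIns": MetricCriterion(HIGHER_IS_BETTER, 20.0, 45.0),
    "M7_NSI": MetricCriterion(HIGHER_IS_BETTER, 50.0, 100.0),
    "M8_pAno": MetricCriterion(LOWER_IS_BETTER, 1.0, 5.0),
}

#: Health classes from worst to best.
HEALTH_CLASSES = ("very poor", "poor", "fair", "good", "excellent")

#: Default class bands: ordered (lo, hi, label) with inclusive integer bounds.
DEFAULT_MWPI_BANDS: tuple[tuple[int, int, str], ...] = (
    (7, 13, "very poor"),
    (14, 19, "poor"),
    (20, 25, "fair"),
    (26, 30, "good"),
    (31, 35, "excellent"),
)

DEFAULT_MIBIF_BANDS: tuple[tuple[int, int, str], ...] = (
    (8, 13, "very poor"),
    (14, 19, "poor"),
    (20, 26, "fair"),
    (27, 33, "good"),
    (34, 40, "excellent"),
)


def validate_bands(bands: Sequence[tuple[int, int, str]]) -> None:
    """Bands must be contiguous, non-overlapping, and ordered worst->best."""
    if not bands:
        raise ValueError("empty band configuration")
    order = [HEALTH_CLASSES.index(b[2]) for b in bands]
    if order != sorted(order):
        raise ValueError("bands must be ordered from worst to best class")
    for (lo, hi, _), (lo2, _hi2, _) in zip(bands, bands[1:]):
        if hi + 1 != lo2:
            raise ValueError(
                f"bands must tile the score range without gap/overlap; "
                f"found [..,{hi}] followed by [{lo2},..]"
            )
        if lo > hi:
            raise ValueError(f"band [{lo},{hi}] is empty")


def classify_health(total: int, bands: Sequence[tuple[int, int, str]]) -> str:
    """Map an index total onto its health class via the band table."""
    validate_bands(bands)
    for lo, hi, label in bands:
        if lo <= total <= hi:
            return label
    raise ValueError(f"total {total} outside banded range [{bands[0][0]},{bands[-1][1]}]")


# --- fish community metrics -------------------------------------------------

def compute_biological_metrics(
    abund: pd.DataFrame,
    guilds: pd.DataFrame,
    anomalies: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site values of the eight fish community metrics.

    M1: native species richness; M2: riffle-benthic (habitat exactly RB)
    species richness; M3: sensitive species richness; M4: % individuals of
    tolerant species; M5: % individuals of omnivores; M6: % individuals of
    native insectivores; M7: number of native individuals; M8: % individuals
    with anomalies.

    Sites with zero individuals have undefined percentage metrics: they are
    returned with NaN metric values and ``defined=False`` rather than a
    fabricated score.
    """
    g = validate_guild_table(guilds)
    validate_abundance(abund, anomalies)
    missing = [sp for sp in abund.columns if sp not in g.index]
    if missing:
        raise ValueError(f"species without guild assignment: {missing}")
    g = g.loc[list(abund.columns)]
    counts = abund.to_numpy(dtype=float)
    native = g["native"].to_numpy()
    tol = g["tolerance"].to_numpy()
    tro = g["trophic"].to_numpy()
    hab = g["habitat"].to_numpy()
    present = counts > 0
    total = counts.sum(axis=1)

    m1 = (present & native).sum(axis=1)
    m2 = (present & (hab == "RB")).sum(axis=1)
    m3 = (present & (tol == "SS")).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m4 = counts[:, tol == "TS"].sum(axis=1) / total * 100.0
        m5 = counts[:, tro == "Omn"].sum(axis=1) / total * 100.0
        m6 = counts[:, (tro == "Ins") & native].sum(axis=1) / total * 100.0
    m7 = counts[:, native].sum(axis=1)
    if anomalies is not None:
        anom_total = anomalies.to_numpy(dtype=float).sum(axis=1)
    else:
        anom_total = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        m8 = anom_total / total * 100.0

    out = pd.DataFrame(
        {
            "M1_NS": m1,
            "M2_RB": m2,
            "M3_SS": m3,
            "M4_pTS": m4,
            "M5_pOmn": m5,
            "M6_pNIns": m6,
            "M7_NSI": m7,
            "M8_pAno": m8,
        },
        index=abund.index,
    )
    out["defined"] = total > 0
    out.loc[~out["defined"], ["M4_pTS", "M5_pOmn", "M6_pNIns", "M8_pAno"]] = np.nan
    return out


# --- index scoring ----------------------------------------------------------

def _score_frame(
    values: pd.DataFrame,
    metrics: Sequence[str],
    criteria: Mapping[str, MetricCriterion],
    bands: Sequence[tuple[int, int, str]],
) -> pd.DataFrame:
    for m in metrics:
        if m not in values.columns:
            raise ValueError(f"missing metric column {m!r}")
        if m not in criteria:
            raise ValueError(f"no criterion configured for metric {m!r}")
    validate_bands(bands)
    out = values.loc[:, list(metrics)].copy()
    for m in metrics:
        out[f"{m}_score"] = [score_metric(v, criteria[m]) for v in values[m]]
    score_cols = [f"{m}_score" for m in metrics]
    out["total"] = out[score_cols].sum(axis=1).astype(int)
    out["health_class"] = [classify_health(t, bands) for t in out["total"]]
    return out


def mwpi_score(
    chem: pd.DataFrame,
    criteria: Mapping[str, MetricCriterion] | None = None,
    bands: Sequence[tuple[int, int, str]] | None = None,
) -> pd.DataFrame:
    """Score the seven-metric water pollution index per site.

    ``chem`` must carry the columns in :data:`MWPI_METRICS`.  Returns metric
    values, per-metric scores, the total (7-35), and the health class.
    """
    criteria = dict(DEFAULT_MWPI_CRITERIA if criteria is None else criteria)
    bands = DEFAULT_MWPI_BANDS if bands is None else bands
    return _score_frame(chem, MWPI_METRICS, criteria, bands)


def mibif_score(
    metrics: pd.DataFrame,
    criteria: Mapping[str, MetricCriterion] | None = None,
    bands: Sequence[tuple[int, int, str]] | None = None,
) -> pd.DataFrame:
    """Score the eight-metric fish index of biotic integrity per site.

    ``metrics`` is the output of :func:`compute_biological_metrics`; sites
    with undefined metrics (zero individuals) are dropped with a warning
    column rather than scored.
    """
    criteria = dict(DEFAULT_MIBIF_CRITERIA if criteria is None else criteria)
    bands = DEFAULT_MIBIF_BANDS if bands is None else bands
    vals = metrics
    if "defined" in metrics.columns:
        vals = metrics.loc[metrics["defined"], list(MIBIF_METRICS)]
    return _score_frame(vals, MIBIF_METRICS, criteria, bands)


class WaterPollutionIndex(BaseEstimator, TransformerMixin):
    """Transformer scoring site chemistry with the mWPI.

    Parameters
    ----------
    criteria, bands : optional overrides of the shipped defaults.
    """

    def __init__(self, criteria=None, bands=None):
        self.criteria = criteria
        self.bands = bands

    def fit(self, X=None, y=None):
        self.criteria_ = dict(DEFAULT_MWPI_CRITERIA if self.criteria is None else self.criteria)
        self.bands_ = DEFAULT_MWPI_BANDS if self.bands is None else tuple(self.bands)
        validate_bands(self.bands_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "criteria_"):
            self.fit()
        return mwpi_score(X, self.criteria_, self.bands_)


class BioticIntegrityIndex(BaseEstimator, TransformerMixin):
    """Transformer scoring fish communities with the mIBI-F.

    ``fit`` takes the guild table; ``transform`` takes the site x species
    abundance matrix (and optionally a parallel anomalies matrix).
    """

    def __init__(self, criteria=None, bands=None):
        self.criteria = criteria
        self.bands = bands

    def fit(self, X: pd.DataFrame, y=None):
        self.guilds_ = validate_guild_table(X)
        self.criteria_ = dict(DEFAULT_MIBIF_CRITERIA if self.criteria is None else self.criteria)
        self.bands_ = DEFAULT_MIBIF_BANDS if self.bands is None else tuple(self.bands)
        validate_bands(self.bands_)
        return self

    def transform(
        self, X: pd.DataFrame, anomalies: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        if not hasattr(self, "guilds_"):
            raise ValueError("BioticIntegrityIndex is not fitted")
        metrics = compute_biological_metrics(X, self.guilds_, anomalies)
        return mibif_score(metrics, self.criteria_, self.bands_)
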
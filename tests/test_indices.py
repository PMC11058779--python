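"""Metric computation, 5/3/1 scoring, index totals, and health banding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverhealth.indices import (
    DEFAULT_MIBIF_BANDS,
    DEFAULT_MIBIF_CRITERIA,
    DEFAULT_MWPI_BANDS,
    DEFAULT_MWPI_CRITERIA,
    MIBIF_METRICS,
    MWPI_METRICS,
    MetricCriterion,
    classify_health,
    compute_biological_metrics,
    mibif_score,
    mwpi_score,
    score_metric,
    validate_bands,
)


class TestScoreMetric:
    def test_extremes(self):
        crit = MetricCriterion("lower_is_better", 1.0, 3.0)
        assert score_metric(0.5, crit) == 5
        assert score_metric(10.0, crit) == 1

    def test_boundary_takes_better_score(self):
        lo = MetricCriterion("lower_is_better", 1.0, 3.0)
        assert score_metric(1.0, lo) == 5
        assert score_metric(3.0, lo) == 3
        hi = MetricCriterion("higher_is_better", 1.0, 3.0)
        assert score_metric(3.0, hi) == 5
        assert score_metric(1.0, hi) == 3

    def test_sweep_matches_interval_membership(self):
        crit = MetricCriterion("higher_is_better", 2.0, 7.0)
        for v in np.linspace(-5, 15, 201):
            if v >= 7.0:
                expected = 5
            elif v >= 2.0:
                expected = 3
            else:
                expected = 1
            assert score_metric(v, crit) == expected

    def test_non_finite_raises(self):
        crit = MetricCriterion("lower_is_better", 1.0, 2.0)
        with pytest.raises(ValueError):
            score_metric(float("nan"), crit)

    def test_invalid_cut_order_raises(self):
        with pytest.raises(ValueError):
            MetricCriterion("lower_is_better", 3.0, 1.0)


class TestBiologicalMetrics:
    def test_single_guild_community(self):
        guilds = pd.DataFrame(
            {"species_id": ["z"], "trophic": ["Omn"], "habitat": ["WC"],
             "tolerance": ["TS"], "native": [True]}
        )
        abund = pd.DataFrame({"z": [10]}, index=["s1"])
        m = compute_biological_metrics(abund, guilds)
        row = m.loc["s1"]
        assert row["M1_NS"] == 1 and row["M2_RB"] == 0 and row["M3_SS"] == 0
        assert row["M4_pTS"] == 100.0 and row["M5_pOmn"] == 100.0
        assert row["M6_pNIns"] == 0.0 and row["M7_NSI"] == 10 and row["M8_pAno"] == 0.0

    def test_anomaly_percentage(self):
        guilds = pd.DataFrame(
            {"species_id": ["z"], "trophic": ["Ins"], "habitat": ["RB"],
             "tolerance": ["IS"], "native": [True]}
        )
        abund = pd.DataFrame({"z": [50]}, index=["s1"])
        anom = pd.DataFrame({"z": [1]}, index=["s1"])
        m = compute_biological_metrics(abund, guilds, anom)
        assert m.loc["s1", "M8_pAno"] == pytest.approx(2.0)

    def test_random_community_matches_per_individual_recount(self, rng, bundle):
        m = compute_biological_metrics(bundle.abundance, bundle.guilds, bundle.anomalies)
        g = bundle.guilds
        site = bundle.abundance.index[7]
        counts = bundle.abundance.loc[site]
        # brute-force: expand to individuals
        individuals = []
        for sp, c in counts.items():
            individuals += [sp] * int(c)
        total = len(individuals)
        ts = sum(1 for sp in individuals if g.loc[sp, "tolerance"] == "TS")
        omn = sum(1 for sp in individuals if g.loc[sp, "trophic"] == "Omn")
        nins = sum(
            1 for sp in individuals
            if g.loc[sp, "trophic"] == "Ins" and g.loc[sp, "native"]
        )
        native_ind = sum(1 for sp in individuals if g.loc[sp, "native"])
        assert m.loc[site, "M4_pTS"] == pytest.approx(100 * ts / total)
        assert m.loc[site, "M5_pOmn"] == pytest.approx(100 * omn / total)
        assert m.loc[site, "M6_pNIns"] == pytest.approx(100 * nins / total)
        assert m.loc[site, "M7_NSI"] == native_ind
        present = counts[counts > 0].index
        assert m.loc[site, "M1_NS"] == sum(g.loc[sp, "native"] for sp in present)
        assert m.loc[site, "M2_RB"] == sum(g.loc[sp, "habitat"] == "RB" for sp in present)
        assert m.loc[site, "M3_SS"] == sum(g.loc[sp, "tolerance"] == "SS" for sp in present)

    def test_riffle_benthic_excludes_dual_habitat(self):
        guilds = pd.DataFrame(
            {"species_id": ["r", "rw"], "trophic": ["Ins"] * 2,
             "habitat": ["RB", "RB-WC"], "tolerance": ["IS"] * 2, "native": [True] * 2}
        )
        abund = pd.DataFrame({"r": [1], "rw": [1]}, index=["s1"])
        m = compute_biological_metrics(abund, guilds)
        assert m.loc["s1", "M2_RB"] == 1

    def test_zero_individual_site_flagged_not_scored(self):
        guilds = pd.DataFrame(
            {"species_id": ["z"], "trophic": ["Omn"], "habitat": ["WC"],
             "tolerance": ["TS"], "native": [True]}
        )
        abund = pd.DataFrame({"z": [0, 4]}, index=["empty", "ok"])
        m = compute_biological_metrics(abund, guilds)
        assert not m.loc["empty", "defined"]
        assert np.isnan(m.loc["empty", "M4_pTS"])
        scored = mibif_score(m)
        assert "empty" not in scored.index and "ok" in scored.index


class TestIndexTotals:
    def test_mwpi_corner_totals(self):
        best = {"TN": 0.1, "TP": 5.0, "TN_TP": 500.0, "BOD": 0.1,
                "TSS": 0.5, "EC": 50.0, "Chl_a": 0.5}
        worst = {"TN": 99.0, "TP": 999.0, "TN_TP": 1.0, "BOD": 99.0,
                 "TSS": 99.0, "EC": 9999.0, "Chl_a": 999.0}
        chem = pd.DataFrame([best, worst], index=["clean", "dirty"])
        res = mwpi_score(chem)
        assert res.loc["clean", "total"] == 35
        assert res.loc["dirty", "total"] == 7
        assert res.loc["clean", "health_class"] == "excellent"
        assert res.loc["dirty", "health_class"] == "very poor"

    def test_mibif_corner_totals(self):
        best = {"M1_NS": 20, "M2_RB": 9, "M3_SS": 9, "M4_pTS": 0.0,
                "M5_pOmn": 0.0, "M6_pNIns": 90.0, "M7_NSI": 500, "M8_pAno": 0.0}
        worst = {"M1_NS": 0, "M2_RB": 0, "M3_SS": 0, "M4_pTS": 100.0,
                 "M5_pOmn": 100.0, "M6_pNIns": 0.0, "M7_NSI": 0, "M8_pAno": 50.0}
        metrics = pd.DataFrame([best, worst], index=["best", "worst"])
        res = mibif_score(metrics)
        assert res.loc["best", "total"] == 40
        assert res.loc["worst", "total"] == 8

    def test_total_is_sum_of_metric_scores(self, bundle):
        res = mwpi_score(bundle.chemistry)
        score_cols = [f"{m}_score" for m in MWPI_METRICS]
        assert (res["total"] == res[score_cols].sum(axis=1)).all()

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1e4, allow_nan=False), min_size=7, max_size=7))
    def test_property_mwpi_bounds(self, values):
        chem = pd.DataFrame([dict(zip(MWPI_METRICS, values))], index=["s"])
        total = mwpi_score(chem)["total"].iloc[0]
        assert 7 <= total <= 35
        assert total % 2 == 1  # sum of seven odd scores is odd

    def test_monotone_in_single_metric_improvement(self, rng):
        base = {m: 10.0 for m in MWPI_METRICS}
        chem = pd.DataFrame([base], index=["s"])
        t0 = mwpi_score(chem)["total"].iloc[0]
        for m in MWPI_METRICS:
            crit = DEFAULT_MWPI_CRITERIA[m]
            better = dict(base)
            # move far in the better direction
            better[m] = 0.0 if crit.direction == "lower_is_better" else 1e6
            t1 = mwpi_score(pd.DataFrame([better], index=["s"]))["total"].iloc[0]
            assert t1 >= t0


class TestBands:
    def test_band_lookup_monotone_sweep(self):
        order = {c: i for i, c in enumerate(
            ["very poor", "poor", "fair", "good", "excellent"])}
        prev = -1
        for total in range(7, 36):
            cls = classify_health(total, DEFAULT_MWPI_BANDS)
            assert order[cls] >= prev
            prev = order[cls]

    def test_gap_and_overlap_rejected(self):
        with pytest.raises(ValueError):
            validate_bands([(7, 13, "very poor"), (15, 35, "poor")])  # gap
        with pytest.raises(ValueError):
            validate_bands([(7, 20, "very poor"), (20, 35, "poor")])  # overlap

    def test_mibif_bands_cover_range(self):
        for total in range(8, 41):
            classify_health(total, DEFAULT_MIBIF_BANDS)


def test_default_criteria_cover_all_metrics():
    assert set(DEFAULT_MWPI_CRITERIA) == set(MWPI_METRICS)
    assert set(DEFAULT_MIBIF_CRITERIA) == set(MIBIF_METRICS)
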
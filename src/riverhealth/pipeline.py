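"""End-to-end orchestration: validate inputs, run every stage, emit a report.

The pipeline chains the stages in the order of the analysis: chemical
clustering -> index scoring (mWPI, mIBI-F) -> ecological entities -> two NMDS
ordinations (entity relative abundances; range-standardized biotic-integrity
metric values) -> regressions of the axes on chemical indicators -> the
environment correlation screen.  Every stage writes a CSV under the output
directory and the run report (JSON) records decisions, seeds, and stress
diagnostics, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as rio
from .clustering import WardClustering, cluster_summary, order_clusters_by_score, to_newick
from .gradient import environment_screen, regress_axes_on_indicators
from .guilds import EcologicalEntities, entity_occupancy, entity_richness, relative_abundance
from .indices import BioticIntegrityIndex, WaterPollutionIndex, compute_biological_metrics, MIBIF_METRICS
from .ordination import NMDS, range_standardize

logger = logging.getLogger("riverhealth")

#: The chemical health indicators regressed against ordination axes.
DEFAULT_INDICATORS = ["EC", "TSS", "BOD", "TP", "TN_TP", "Chl_a"]

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_NUMERICAL = 3


@dataclass
class RunConfig:
    abundance: str
    guilds: str
    chemistry: str
    covariates: str | None = None
    anomalies: str | None = None
    criteria: str | None = None
    out_dir: str = "riverhealth_out"
    n_clusters: int = 5
    nmds_components: int = 2
    nmds_starts: int = 20
    nmds_max_iter: int = 300
    nmds_tol: float = 1e-7
    seed: int = 0
    log_indicators: bool = True
    indicators: list = field(default_factory=lambda: list(DEFAULT_INDICATORS))
    strict: bool = False  # fail on NMDS non-convergence


def validate_inputs(cfg: RunConfig) -> list[str]:
    """Cross-check the input tables; returns a list of all problems found."""
    errors: list[str] = []
    try:
        abund, anomalies = rio.read_abundance(cfg.abundance, cfg.anomalies)
    except Exception as exc:  # collect, don't raise: report everything at once
        errors.append(f"abundance: {exc}")
        abund = None
    try:
        guilds = rio.read_guilds(cfg.guilds)
    except Exception as exc:
        errors.append(f"guilds: {exc}")
        guilds = None
    try:
        chem = rio.read_chemistry(cfg.chemistry)
    except Exception as exc:
        errors.append(f"chemistry: {exc}")
        chem = None
    if abund is not None and guilds is not None:
        orphans = [sp for sp in abund.columns if sp not in guilds.index]
        if orphans:
            errors.append(f"species in abundance but not in guild table: {orphans}")
    if abund is not None and chem is not None:
        only_a = abund.index.difference(chem.index).tolist()
        only_c = chem.index.difference(abund.index).tolist()
        if only_a:
            errors.append(f"sites with abundance but no chemistry: {only_a}")
        if only_c:
            errors.append(f"sites with chemistry but no abundance: {only_c}")
        if chem.index.duplicated().any():
            errors.append("duplicate site rows in chemistry table")
    if cfg.covariates is not None:
        try:
            rio.read_covariates(cfg.covariates)
        except Exception as exc:
            errors.append(f"covariates: {exc}")
    if cfg.criteria is not None:
        try:
            rio.read_criteria(cfg.criteria)
        except Exception as exc:
            errors.append(f"criteria: {exc}")
    return errors


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the report dict (also written as JSON)."""
    errors = validate_inputs(cfg)
    if errors:
        raise ValueError("input validation failed:\n" + "\n".join(errors))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    abund, anomalies = rio.read_abundance(cfg.abundance, cfg.anomalies)
    guilds = rio.read_guilds(cfg.guilds)
    chem = rio.read_chemistry(cfg.chemistry)
    covariates = rio.read_covariates(cfg.covariates) if cfg.covariates else None
    criteria = bands = None
    if cfg.criteria:
        criteria, bands = rio.read_criteria(cfg.criteria)

    report: dict = {"stages": {}, "decisions": [], "seed": cfg.seed}

    # --- chemical clustering + mWPI --------------------------------------
    logger.info("stage: chemical clustering (k=%d)", cfg.n_clusters)
    wpi = WaterPollutionIndex(criteria=criteria or None, bands=bands or None).fit()
    mwpi = wpi.transform(chem)
    clusterer = WardClustering(n_clusters=cfg.n_clusters).fit(chem)
    labels = order_clusters_by_score(clusterer.labels_, mwpi["total"])
    labels.index.name = "site_id"
    labels.to_frame().assign(cluster=lambda d: "SC-" + d["cluster"].astype(str)).to_csv(
        out / "clusters.csv"
    )
    (out / "dendrogram.nwk").write_text(to_newick(clusterer.dendrogram_))
    pd.DataFrame(
        clusterer.dendrogram_.linkage,
        columns=["left", "right", "height", "size"],
    ).rename_axis("step").to_csv(out / "dendrogram_merges.csv")
    cluster_summary(chem, labels).to_csv(out / "cluster_summary.csv", index=False)
    mwpi.rename_axis("site_id").to_csv(out / "mwpi.csv")
    report["decisions"].append("clusters renumbered by descending mean mWPI (SC-1 cleanest)")
    report["stages"]["clustering"] = {"k": cfg.n_clusters, "n_sites": len(labels)}

    # --- biological metrics + mIBI-F -------------------------------------
    logger.info("stage: biotic integrity index")
    metrics = compute_biological_metrics(abund, guilds, anomalies)
    zero_sites = metrics.index[~metrics["defined"]].tolist()
    if zero_sites:
        logger.warning("sites without fish excluded from biological stages: %s", zero_sites)
        report["decisions"].append(f"zero-fish sites excluded from biological stages: {zero_sites}")
    ibi = BioticIntegrityIndex().fit(guilds)
    mibif = ibi.transform(abund, anomalies)
    mibif.rename_axis("site_id").to_csv(out / "mibif.csv")
    report["stages"]["mibif"] = {"n_sites": len(mibif), "excluded": zero_sites}

    # --- ecological entities ----------------------------------------------
    logger.info("stage: ecological entities")
    ent = EcologicalEntities().fit(guilds)
    em = ent.transform(abund)
    rio.write_catalog(ent.catalog_, out / "entity_catalog.csv")
    rio.write_abundance(em, out / "entity_abundance.csv")
    ra_site = relative_abundance(em.loc[metrics["defined"]], scope="per_site", decimals=None)
    occupancy = entity_occupancy(em)
    summary = pd.DataFrame(
        {
            "occupancy_pct": occupancy,
            "total_individuals": em.sum(axis=0),
            "ra_entire_pct": relative_abundance(em, scope="entire"),
        }
    )
    summary.rename_axis("entity_id").to_csv(out / "entity_summary.csv")
    report["stages"]["entities"] = {
        "n_entities": ent.n_entities_,
        "regional_richness": entity_richness(em),
    }

    # --- ordinations -------------------------------------------------------
    logger.info("stage: NMDS ordinations")
    seeds = {"fe": cfg.seed, "mibif": cfg.seed + 1}
    nmds_fe = NMDS(
        n_components=cfg.nmds_components,
        n_starts=cfg.nmds_starts,
        max_iter=cfg.nmds_max_iter,
        tol=cfg.nmds_tol,
        random_state=seeds["fe"],
    ).fit(ra_site)
    metric_table = range_standardize(metrics.loc[metrics["defined"], list(MIBIF_METRICS)])
    nmds_mibif = NMDS(
        n_components=cfg.nmds_components,
        n_starts=cfg.nmds_starts,
        max_iter=cfg.nmds_max_iter,
        tol=cfg.nmds_tol,
        random_state=seeds["mibif"],
    ).fit(metric_table)
    if cfg.strict and not (nmds_fe.result_.converged and nmds_mibif.result_.converged):
        raise RuntimeError("NMDS failed to converge (strict mode)")
    for name, fitted in (("fe", nmds_fe), ("mibif", nmds_mibif)):
        fitted.embedding_.rename_axis("site_id").to_csv(out / f"nmds_{name}.csv")
        meta = {
            "stress": fitted.stress_,
            "converged": fitted.result_.converged,
            "n_iter": fitted.result_.n_iter,
            "n_starts": fitted.result_.n_starts,
            "best_start": fitted.result_.best_start,
            "seed": seeds[name],
            "degenerate": fitted.result_.degenerate,
            "input": "entity relative abundance" if name == "fe" else "range-standardized mIBI-F metric values",
        }
        (out / f"nmds_{name}_meta.json").write_text(json.dumps(meta, indent=2))
        report["stages"][f"nmds_{name}"] = meta
    report["decisions"].append(
        "mIBI-F ordination input range-standardized to [0,1] per metric before Bray-Curtis"
    )

    # --- regressions and screen -------------------------------------------
    logger.info("stage: gradient statistics")
    regs = []
    for name, fitted in (("FE", nmds_fe), ("mIBI-F", nmds_mibif)):
        r = regress_axes_on_indicators(
            fitted.embedding_, chem, cfg.indicators, log_transform=cfg.log_indicators
        )
        r.insert(0, "ordination", name)
        regs.append(r)
    regressions = pd.concat(regs, ignore_index=True)
    regressions.to_csv(out / "regressions.csv", index=False)
    report["stages"]["regressions"] = {"n_models": len(regressions)}

    screen_table = pd.DataFrame(
        {
            "NMDS1_FE": nmds_fe.embedding_["NMDS1"],
            "NMDS2_FE": nmds_fe.embedding_["NMDS2"],
            "NMDS1_mIBIF": nmds_mibif.embedding_["NMDS1"],
            "NMDS2_mIBIF": nmds_mibif.embedding_["NMDS2"],
            "mIBIF_total": mibif["total"],
            "mWPI_total": mwpi["total"],
        }
    )
    if covariates is not None:
        screen_table = screen_table.join(covariates)
    screen = environment_screen(screen_table)
    screen.to_csv(out / "environment_screen.csv", index=False)
    report["stages"]["screen"] = {"n_pairs": len(screen)}

    report["outputs"] = sorted(p.name for p in out.iterdir())
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
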
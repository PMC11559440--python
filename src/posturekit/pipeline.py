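"""End-to-end orchestration: ingest -> clean -> consolidate -> smooth -> stats -> cluster."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cleaning, cluster, io, report, stats
from .groups import consolidate, smooth_majority_vote

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    recordings: list[str]
    admissions: str
    out_dir: str = "posturekit_out"
    lenient: bool = False
    analysis_day_hours: float = stats.ANALYSIS_DAY_HOURS
    dt_start_hour: int = stats.DT_START_HOUR
    dt_end_hour: int = stats.DT_END_HOUR
    extend_to_device_stream: bool = False
    cluster_sets: list[str] = field(default_factory=lambda: ["wd", "dt", "nt", "combined"])
    k_min: int = 2
    k_max: int = 10
    restarts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.analysis_day_hours <= 24:
            raise ValueError("analysis_day_hours must lie in (0, 24]")
        if (self.dt_end_hour - self.dt_start_hour) % 24 != 12:
            raise ValueError("daytime window must span 12 hours")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if isinstance(raw.get("recordings"), str):
            raw["recordings"] = [raw["recordings"]]
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write artifacts, and return them in memory.

    Stage counts are logged as the pipeline progresses; any failure
    aborts with the stage name.  Output is deterministic under a fixed
    seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    stage = "ingest"
    try:
        records, rejected = io.read_recordings(config.recordings, lenient=config.lenient)
        admissions = io.read_admissions(config.admissions)
        logger.info("ingest: %d recordings (%d rejected), %d patients, %d admissions",
                    len(records), len(rejected), records["mrn"].nunique(), len(admissions))

        stage = "clean"
        clean, cleaning_report = cleaning.apply_exclusions(
            records, admissions, extend_to_device_stream=config.extend_to_device_stream
        )
        cleaning_report.write_json(out / "flow.json")
        io.write_recordings(clean, out / "clean.csv")
        logger.info("clean: %d -> %d recordings, %d -> %d patients",
                    cleaning_report.recordings_in, cleaning_report.recordings_out,
                    cleaning_report.patients_in, cleaning_report.patients_out)

        stage = "preprocess"
        series = smooth_majority_vote(consolidate(clean))
        series_out = series.copy()
        series_out["timestamp"] = series_out["timestamp"].dt.strftime(io.TIMESTAMP_FORMAT)
        series_out.to_csv(out / "groups.csv", index=False)

        stage = "stats"
        summaries, quantity = stats.summarize_patients(
            series,
            threshold_hours=config.analysis_day_hours,
            dt_start=config.dt_start_hour,
            dt_end=config.dt_end_hour,
        )
        summaries.to_csv(out / "summaries.csv", index=False)
        quantity.to_csv(out / "quantity.csv", index=False)
        logger.info("stats: %d of %d patients retained (>=1 analysis day)",
                    len(summaries), len(quantity))

        stage = "cluster"
        cluster_results = {}
        for i, set_name in enumerate(config.cluster_sets):
            X = cluster.feature_matrix(summaries, set_name)
            result = cluster.fit_kmeans_select(
                X,
                k_range=range(config.k_min, config.k_max + 1),
                restarts=config.restarts,
                seed=config.seed + i,
                feature_set=set_name,
            )
            table = cluster.cluster_table(result, X)
            table.to_csv(out / f"cluster_{set_name}.csv")
            result.labels.to_csv(out / f"cluster_{set_name}_labels.csv")
            cluster_results[set_name] = result
            logger.info("cluster[%s]: k=%d, silhouette=%.3f",
                        set_name, result.k, result.silhouette_overall)

        stage = "report"
        demo = report.demographics_table(admissions, summaries["mrn"])
        demo.to_csv(out / "demographics.csv")
        quart = report.quartile_table(summaries)
        quart.to_csv(out / "quartiles.csv")
        report.scatter_export(summaries).to_csv(out / "scatter.csv", index=False)
        qreport = report.quantity_report(quantity, summaries["mrn"])
        try:
            intercept, slope = stats.quantity_regression(
                quantity[quantity["mrn"].isin(set(summaries["mrn"]))]
            )
        except ValueError:
            logger.warning("quantity regression skipped: degenerate design")
            intercept = slope = None
        (out / "quantity_report.json").write_text(
            json.dumps(
                {
                    "n_patients": qreport["n_patients"],
                    "median_total_days": qreport["median_total_days"],
                    "median_analysis_days": qreport["median_analysis_days"],
                    "regression_intercept": intercept,
                    "regression_slope": slope,
                },
                indent=2,
            )
            + "\n"
        )
    except Exception:
        logger.exception("pipeline aborted at stage %r", stage)
        raise

    artifacts.update(
        records=records,
        rejected=rejected,
        clean=clean,
        cleaning_report=cleaning_report,
        series=series,
        summaries=summaries,
        quantity=quantity,
        clusters=cluster_results,
        demographics=demo,
        quartiles=quart,
    )
    return artifacts
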
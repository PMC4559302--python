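"""End-to-end orchestration: index → standardize → select → cluster → compare.

`run_pipeline` executes the full analysis on a county table: build the SES
deprivation index from its four components, z-score the clustering
candidates, run greedy BIC variable selection, keep the BIC-best mixture on
the selected variables, then test clustering variables and outcomes across
the resulting clusters (ANOVA + Tukey–Kramer) and summarize each cluster.
Every artifact is written with the config hash and seed recorded, and
identical config + seed yields identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import ComparisonReport, compare_clusters, summarize_clusters
from .data import read_county_csv
from .indices import SES_COMPONENTS, ses_index, standardize
from .mixture import COVARIANCE_TYPES, ClusteringSolution
from .selection import VariableSelectionResult, greedy_select

logger = logging.getLogger("areamix")

DEFAULT_CANDIDATES = [
    "unemployment_pct",
    "pop_density",
    "median_income",
    "ses_index",
    "low_access_pct",
]
DEFAULT_OUTCOMES = ["obesity_pct", "diabetes_pct"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (loadable from YAML/JSON)."""

    input_path: str | None = None
    clustering_candidates: list[str] = field(
        default_factory=lambda: list(DEFAULT_CANDIDATES))
    ses_components: list[str] = field(
        default_factory=lambda: list(SES_COMPONENTS))
    outcomes: list[str] = field(default_factory=lambda: list(DEFAULT_OUTCOMES))
    k_min: int = 1
    k_max: int = 9
    covariance_types: list[str] = field(
        default_factory=lambda: list(COVARIANCE_TYPES))
    alpha: float = 0.001
    seed: int = 0
    output_dir: str | None = None
    stratum_column: str | None = None

    def __post_init__(self):
        roster = (self.clustering_candidates + self.ses_components
                  + self.outcomes)
        if len(set(self.clustering_candidates)) != len(self.clustering_candidates):
            raise ValueError("duplicate clustering candidate names")
        if len(set(roster)) != len(roster):
            raise ValueError("variable roster names must be distinct")
        unknown = set(self.covariance_types) - set(COVARIANCE_TYPES)
        if unknown:
            raise ValueError(f"unknown covariance types: {sorted(unknown)}")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        payload = (json.loads(text) if str(path).endswith(".json")
                   else yaml.safe_load(text))
        return cls(**payload)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        Excludes input/output paths so that the same analysis written to a
        different location remains byte-identical.
        """
        payload = {k: v for k, v in self.to_dict().items()
                   if k not in ("input_path", "output_dir")}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """All artifacts of one pipeline run plus provenance."""

    config: PipelineConfig
    selection: VariableSelectionResult
    solution: ClusteringSolution
    comparison: ComparisonReport
    summaries: list
    table: pd.DataFrame
    stratum: str | None = None

    def provenance(self) -> dict:
        return {
            "software": f"areamix {__version__}",
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "stratum": self.stratum,
            "config": self.config.to_dict(),
        }

    def summary(self) -> str:
        parts = []
        if self.stratum:
            parts.append(f"Stratum: {self.stratum}")
        parts += [self.selection.summary(), "", self.comparison.summary(), ""]
        parts.append("Cluster descriptions (low/medium/high vs other clusters):")
        for s in self.summaries:
            levels = ", ".join(f"{k}={v}" for k, v in s.levels.items())
            parts.append(f"  cluster {s.cluster} (n={s.size}, {s.nchs_label}): "
                         f"{levels}")
        return "\n".join(parts)


def _run_single(table: pd.DataFrame, config: PipelineConfig,
                stratum: str | None = None) -> RunReport:
    t0 = time.time()
    table = table.reset_index(drop=True).copy()
    if "ses_index" in config.clustering_candidates:
        table["ses_index"] = ses_index(table[config.ses_components].rename(
            columns=dict(zip(config.ses_components, SES_COMPONENTS))))
    logger.info("indices built (%.2fs)", time.time() - t0)

    fm = standardize(table, config.clustering_candidates)
    k_range = range(config.k_min, config.k_max + 1)
    selection = greedy_select(fm, k_range=k_range,
                              covariance_types=config.covariance_types,
                              seed=config.seed)
    logger.info("variable selection done: %s (%.2fs)",
                selection.selected, time.time() - t0)
    solution = selection.final_solution
    compare_vars = list(selection.selected) + list(config.outcomes)
    comparison = compare_clusters(table, solution.labels, compare_vars,
                                  alpha=config.alpha)
    summaries = summarize_clusters(solution.labels, table,
                                   selection.selected, config.outcomes)
    logger.info("comparison done (%.2fs)", time.time() - t0)
    return RunReport(config=config, selection=selection, solution=solution,
                     comparison=comparison, summaries=summaries, table=table,
                     stratum=stratum)


def run_pipeline(config: PipelineConfig, table: pd.DataFrame | None = None):
    """Run the full analysis; returns a RunReport (or a dict per stratum).

    `table` may be passed directly; otherwise `config.input_path` is read and
    validated. With `stratum_column` set, the table is partitioned and the
    pipeline run independently per stratum (each stratum re-standardizes and
    re-selects on its own units).
    """
    if table is None:
        if config.input_path is None:
            raise ValueError("either a table or config.input_path is required")
        table = read_county_csv(config.input_path)
    if config.stratum_column:
        reports = {}
        for value, sub in table.groupby(config.stratum_column, sort=True):
            reports[str(value)] = _run_single(sub, config, stratum=str(value))
        if config.output_dir:
            for value, rep in reports.items():
                write_report(rep, Path(config.output_dir) / str(value))
        return reports
    report = _run_single(table, config)
    if config.output_dir:
        write_report(report, config.output_dir)
    return report


def write_report(report: RunReport, outdir):
    """Write labels, BIC table, model, comparison tables, and provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = (f"areamix config={report.config.config_hash()} "
           f"seed={report.config.seed}")

    def _csv(df: pd.DataFrame, name: str):
        with open(outdir / name, "w") as fh:
            fh.write(f"# {tag}\n")
            df.to_csv(fh, index=False)

    _csv(pd.DataFrame({"county_id": report.table["county_id"],
                       "cluster": report.solution.labels}), "labels.csv")
    _csv(report.solution.bic_table.reset_index(), "bic_table.csv")
    _csv(report.comparison.anova_frame(), "anova.csv")
    _csv(report.comparison.tukey_frame(), "tukey.csv")
    _csv(pd.DataFrame([{"cluster": s.cluster, "size": s.size,
                        "nchs_label": s.nchs_label, **s.levels}
                       for s in report.summaries]), "cluster_summary.csv")
    trace = pd.DataFrame([{"action": s.action, "variable": s.variable,
                           "evidence": s.evidence,
                           "current_set": "|".join(s.current_set)}
                          for s in report.selection.trace])
    _csv(trace, "selection_trace.csv")

    model = report.solution.model
    with open(outdir / "model.json", "w") as fh:
        json.dump({
            "provenance": report.provenance(),
            "k": model.k,
            "covariance_type": model.covariance_type,
            "weights": model.weights.tolist(),
            "means": model.means.tolist(),
            "covariances": model.covariances.tolist(),
            "loglik": model.loglik,
            "n_params": model.n_params,
            "bic": model.bic,
            "selected_variables": report.selection.selected,
        }, fh, indent=2)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(report.provenance(), fh, indent=2)
    (outdir / "summary.txt").write_text(f"# {tag}\n" + report.summary() + "\n")
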
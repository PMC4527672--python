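"""End-to-end orchestration: summaries -> sex screen -> lineage cascade ->
environment screen -> robust lineage set, with optional subsampling
divergence, plus TSV/JSON reporting.

Every tunable of the analysis lives in :class:`PipelineConfig`; the defaults
are the frozen "paper mode" (alpha = 0.01, species-level pooling, matched
chimpanzee environment contrast, type-7 quantiles, auto exact/asymptotic
rank-sum) and the effective configuration is embedded in every report so any
count is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .cohort import Cohort, Dialect, read_cohort
from .environment import EnvironmentFlags, environment_flags, robust_lineage_set
from .lineage import ClassificationReport, SpeciesTree, classify_all
from .resampling import DEFAULT_PAIRS, divergence_analysis
from .sex import sex_differences
from .stats import table1

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

log = logging.getLogger("seroclade")


@dataclass
class PipelineConfig:
    """Frozen defaults reproduce the documented paper mode."""

    alpha: float = 0.01
    lineage_scope: str = "species"          # or "subspecies"
    full_polarity: bool = False
    strict_environment: bool = False
    chimp_scope: str = "matched"            # or "pooled_wild"
    quantile_method: str = "linear"
    wilcoxon_method: str = "auto"           # "auto" | "exact" | "asymptotic"
    exact_threshold: int = 25
    continuity: bool = False
    sex_denominator: str = "testable"       # or "total"
    percentile_threshold: int = 20
    run_resampling: bool = False
    resample_pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    resample_k: int = 8
    resample_draws: int = 1000
    seed: int = 0

    def test_kwargs(self) -> dict:
        return {
            "method": self.wilcoxon_method,
            "exact_threshold": self.exact_threshold,
            "continuity": self.continuity,
        }

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        doc = dataclasses.asdict(self)
        doc["resample_pairs"] = [list(p) for p in self.resample_pairs]
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "resample_pairs" in doc:
            doc["resample_pairs"] = tuple(tuple(p) for p in doc["resample_pairs"])
        return cls(**doc)


@dataclass
class PipelineReport:
    config: PipelineConfig
    summary_table: pd.DataFrame
    sex_table: object
    classification: ClassificationReport
    env_flags: EnvironmentFlags
    robust: object
    resampling: Optional[dict] = None

    def headline(self) -> dict:
        """Machine-readable summary of the run."""
        head = {
            "lineage_counts": dict(self.classification.counts),
            "not_classifiable": [m for m, _ in self.classification.not_classifiable],
            "env_flag_counts": self.env_flags.summary(),
            "robust_markers": list(self.robust.robust),
            "excluded_markers": [
                {"biomarker": m, "offending_species": sp} for m, sp in self.robust.excluded
            ],
            "sex_percent_by_group": {
                g: round(float(row["percent"]), 2)
                for g, row in self.sex_table.per_group.iterrows()
            },
            "config": _config_doc(self.config),
        }
        if self.resampling is not None:
            head["divergence_median_p"] = self.resampling["median_p"]
        return head

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = []

        def emit(frame: pd.DataFrame, name: str, **kw) -> None:
            frame.to_csv(out / name, sep="\t", **kw)
            manifest.append(name)

        emit(self.summary_table, "summary_table.tsv")
        emit(self.sex_table.per_test, "sex_per_test.tsv", index=False)
        emit(self.sex_table.per_group, "sex_per_group.tsv")
        emit(self.env_flags.table, "environment_flags.tsv")
        assign_rows = [
            {
                "biomarker": a.biomarker,
                "category": a.category,
                "ambiguous": a.ambiguous,
                "conditions": "; ".join(f"{s.condition}: p={s.p_value:.4g} [{'ok' if s.passed else 'fail'}]"
                                         for s in a.trace),
            }
            for a in self.classification.assignments
        ]
        emit(pd.DataFrame.from_records(assign_rows), "lineage_assignments.tsv", index=False)
        if self.resampling is not None:
            for pair, dist in self.resampling["distributions"].items():
                emit(dist.table, f"pvalues_{pair[0]}_vs_{pair[1]}.tsv", index=False)
            emit(self.resampling["comparisons"], "divergence_comparisons.tsv", index=False)
        (out / "headline.json").write_text(json.dumps(self.headline(), indent=2, default=str))
        manifest.append("headline.json")
        self.config.to_yaml(out / "effective_config.yaml")
        manifest.append("effective_config.yaml")
        (out / "MANIFEST").write_text("\n".join(manifest) + "\ncomplete\n")
        return out


def _config_doc(config: PipelineConfig) -> dict:
    doc = dataclasses.asdict(config)
    doc["resample_pairs"] = [list(p) for p in config.resample_pairs]
    return doc


def run_pipeline(
    cohort: Cohort | str | Path,
    config: PipelineConfig | None = None,
    *,
    dialect: Dialect | None = None,
    tree: SpeciesTree | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Execute the full analysis on a cohort (object or file path)."""
    config = config or PipelineConfig()
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort, dialect)
    tree = tree or SpeciesTree.default()
    tkw = config.test_kwargs()

    log.info("pipeline: %d subjects, %d biomarkers; alpha=%s, scope=%s, chimp_scope=%s",
             cohort.n_subjects(), len(cohort.biomarkers), config.alpha,
             config.lineage_scope, config.chimp_scope)

    summary = table1(cohort, percentile_threshold=config.percentile_threshold,
                     quantile_method=config.quantile_method)
    sex_table = sex_differences(cohort, config.alpha, denominator=config.sex_denominator, **tkw)
    classification = classify_all(
        cohort, tree, config.alpha,
        scope=config.lineage_scope,
        full_polarity=config.full_polarity,
        strict_environment=config.strict_environment,
        **tkw,
    )
    env = environment_flags(cohort, config.alpha, chimp_scope=config.chimp_scope, **tkw)
    robust = robust_lineage_set(classification.assignments, env)
    resampling = None
    if config.run_resampling:
        resampling = divergence_analysis(
            cohort, config.resample_pairs,
            k=config.resample_k, n_draws=config.resample_draws, seed=config.seed, **tkw,
        )
    report = PipelineReport(
        config=config,
        summary_table=summary,
        sex_table=sex_table,
        classification=classification,
        env_flags=env,
        robust=robust,
        resampling=resampling,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
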
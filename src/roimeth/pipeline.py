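"""End-to-end pipeline: quantify -> filter -> export/plots -> score -> compare.

Configuration lives in one YAML file (flat keys, see
:class:`PipelineConfig`); CLI flags override it.  Every run writes a
resolved-config copy, a manifest with the config hash and package version,
and a run log next to the outputs, so a rerun with the same config
reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, PipelineError
from .genome_io import read_fasta, read_regions
from .ihc import read_ihc_readings, score_cohort, scores_to_long
from .quantify import (
    export_tables,
    filter_all_zero_regions,
    load_and_quantify,
    plot_region_profiles,
)
from .simulate import METHYLATION_GROUPS, read_design
from .stats import compare_groups, results_to_frame

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and statistics options of one run."""

    fasta: str
    regions: str
    calls_dir: str
    design: str
    ihc_readings: str | None = None
    out_dir: str = "roimeth_out"
    min_coverage: int = 1
    meth_fraction_threshold: float = 0.5
    quantile_rule: str = "linear"
    test_mode: str = "auto"
    bh: bool = False
    paired_plots: bool = True
    aggregation_rule: str = "median"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc))

    def validate(self) -> None:
        for label in ("fasta", "regions", "calls_dir", "design"):
            value = getattr(self, label)
            if value is None or not Path(value).exists():
                raise ConfigurationError(f"{label} path does not exist: {value!r}")
        if self.ihc_readings is not None and not Path(self.ihc_readings).exists():
            raise ConfigurationError(
                f"ihc_readings path does not exist: {self.ihc_readings!r}"
            )
        if self.min_coverage < 1:
            raise ConfigurationError("min_coverage must be >= 1")
        if not 0.0 < self.meth_fraction_threshold <= 1.0:
            raise ConfigurationError("meth_fraction_threshold must be in (0, 1]")

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.resolved_yaml().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Paths of everything one run produced."""

    out_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    plots: list[Path] = field(default_factory=list)
    comparisons: Path | None = None
    manifest: Path | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow; any stage error aborts naming the stage."""
    config.validate()  # before any computation
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out_dir=out_dir)

    log_path = out_dir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("roimeth")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("roimeth %s, config hash %s", __version__, config.config_hash())

        stage = "load-inputs"
        try:
            reference = read_fasta(config.fasta)
            regions = read_regions(config.regions)
            design = read_design(config.design)
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

        stage = "quantify"
        meth_samples = list(
            design.loc[design["group"].isin(METHYLATION_GROUPS), "sample_id"]
        )
        try:
            matrix = load_and_quantify(
                regions, reference, config.calls_dir, meth_samples,
                config.min_coverage, config.meth_fraction_threshold,
            )
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

        stage = "filter"
        matrix = filter_all_zero_regions(matrix)

        stage = "export"
        try:
            result.tables.update(export_tables(matrix, out_dir))
        except OSError as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

        stage = "plot"
        plots_dir = out_dir / "plots"
        result.plots.extend(plot_region_profiles(matrix, design, plots_dir, paired=False))
        if config.paired_plots:
            result.plots.extend(
                plot_region_profiles(matrix, design, plots_dir / "paired", paired=True)
            )

        measures = matrix.to_long()
        stage = "score-ihc"
        if config.ihc_readings is not None:
            try:
                readings = read_ihc_readings(config.ihc_readings)
                scores = score_cohort(readings, design, rule=config.aggregation_rule)
            except Exception as exc:
                raise PipelineError(f"stage {stage}: {exc}") from exc
            scores_path = out_dir / "ihc_complex_scores.tsv"
            scores.to_csv(scores_path, sep="\t", index=False)
            result.tables["ihc_scores"] = scores_path
            measures = pd.concat([measures, scores_to_long(scores)], ignore_index=True)

        stage = "compare"
        try:
            comparisons = compare_groups(
                measures, design, quantile_rule=config.quantile_rule,
                mode=config.test_mode, bh=config.bh,
            )
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc
        comp_path = out_dir / "comparisons.tsv"
        results_to_frame(comparisons).to_csv(comp_path, sep="\t", index=False)
        result.comparisons = comp_path

        stage = "provenance"
        (out_dir / "resolved_config.yaml").write_text(config.resolved_yaml())
        manifest = {
            "roimeth_version": __version__,
            "config_hash": config.config_hash(),
            "outputs": sorted(
                str(p.relative_to(out_dir))
                for p in out_dir.rglob("*") if p.is_file()
            ),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        result.manifest = manifest_path
        logger.info("pipeline finished: %d table(s), %d plot(s)",
                    len(result.tables), len(result.plots))
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
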
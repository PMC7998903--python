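"""Region-of-interest methylation quantification.

The statistic: for one sample and one genomic region of interest (gROI,
promoter + gene of a marker), count the captured methylated CpG sites and
divide by *all possible* CpG sites of the region — enumerated from the
reference genome, not from the sample's coverage — times 100.  Uncovered and
unmethylated sites both contribute 0 to the numerator but stay in the
denominator, so sparse FFPE coverage depresses the percentage rather than
inflating its variance.

A site is *captured* when its coverage reaches ``min_coverage`` (default 1)
and *methylated* when its methylated-read fraction reaches
``meth_fraction_threshold`` (default 0.5).  Both are configurable;
``ANY_READ_THRESHOLD`` gives the "any methylated read" preset.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PipelineError, ValidationError
from .genome_io import (
    CpGSite,
    GenomicRegion,
    SampleCalls,
    SiteCall,
    enumerate_cpg_sites,
)

logger = logging.getLogger(__name__)

#: threshold preset making any methylated read count the site as methylated
ANY_READ_THRESHOLD = 1e-9


class SiteState(enum.Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    UNCOVERED = "uncovered"


def site_methylation_state(
    call: SiteCall | None,
    min_coverage: int = 1,
    meth_fraction_threshold: float = 0.5,
) -> SiteState:
    """Classify one site call as methylated / unmethylated / uncovered.

    ``call=None`` (site absent from the sample) is uncovered.  Total on valid
    input; thresholds are validated once here.
    """
    if min_coverage < 1:
        raise ValidationError("min_coverage must be >= 1")
    if not 0.0 < meth_fraction_threshold <= 1.0:
        raise ValidationError("meth_fraction_threshold must be in (0, 1]")
    if call is None or call.coverage < min_coverage:
        return SiteState.UNCOVERED
    fraction = call.count_methylated / call.coverage
    return SiteState.METHYLATED if fraction >= meth_fraction_threshold else SiteState.UNMETHYLATED


def region_methylation_percent(
    region: GenomicRegion,
    sites: Sequence[CpGSite],
    calls: Mapping[CpGSite, SiteCall],
    min_coverage: int = 1,
    meth_fraction_threshold: float = 0.5,
) -> tuple[float, int, int]:
    """Percentage of the region's possible CpG sites captured as methylated.

    Returns ``(percent, numerator, denominator)`` where the denominator is the
    reference CpG count of the region (``len(sites)``) and the numerator is
    the number of those sites whose call is methylated.  A region without any
    possible CpG site raises :class:`ValidationError` (callers mark it
    missing).
    """
    denominator = len(sites)
    if denominator == 0:
        raise ValidationError(f"region {region.name!r} has zero possible CpG sites")
    numerator = sum(
        1
        for site in sites
        if site_methylation_state(calls.get(site), min_coverage, meth_fraction_threshold)
        is SiteState.METHYLATED
    )
    return 100.0 * numerator / denominator, numerator, denominator


@dataclass
class RegionMethylationMatrix:
    """Regions x samples methylation-percentage table plus its building blocks.

    ``values`` holds percentages in [0, 100] (NaN where a region is missing,
    i.e. has no possible CpG site); ``numerators`` the captured-methylated
    site counts; ``denominators`` the reference CpG count per region, shared
    by all samples.
    """

    values: pd.DataFrame
    numerators: pd.DataFrame
    denominators: pd.Series
    regions: list[GenomicRegion] = field(default_factory=list)

    @property
    def region_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_long(self, measure_suffix: str = "meth_pct") -> pd.DataFrame:
        """Tidy (sample_id, measure, value) view for the comparison battery."""
        long = (
            self.values.reset_index(names="region")
            .melt(id_vars="region", var_name="sample_id", value_name="value")
            .dropna(subset=["value"])
        )
        long["measure"] = long["region"] + ":" + measure_suffix
        return long[["sample_id", "measure", "value"]].reset_index(drop=True)


def quantify_cohort(
    regions: Sequence[GenomicRegion],
    reference: Mapping[str, str],
    sample_calls: Mapping[str, SampleCalls],
    min_coverage: int = 1,
    meth_fraction_threshold: float = 0.5,
) -> RegionMethylationMatrix:
    """Quantify every region in every sample against one shared reference.

    Region denominators are reference-determined, hence identical across
    samples.  Zero-CpG regions are kept as all-NaN rows with a warning; they
    are excluded from downstream statistics.
    """
    sample_ids = list(sample_calls)
    region_sites: dict[str, list[CpGSite]] = {}
    for region in regions:
        if region.chrom not in reference:
            raise PipelineError(
                f"region {region.name!r} references unknown chromosome {region.chrom!r}"
            )
        region_sites[region.name] = enumerate_cpg_sites(reference[region.chrom], region)

    values = pd.DataFrame(
        np.nan, index=[r.name for r in regions], columns=sample_ids, dtype=float
    )
    numerators = pd.DataFrame(0, index=values.index, columns=sample_ids, dtype=int)
    denominators = pd.Series(
        {r.name: len(region_sites[r.name]) for r in regions}, name="n_possible_cpg"
    )
    for region in regions:
        sites = region_sites[region.name]
        if not sites:
            logger.warning(
                "region %s has zero possible CpG sites; marked missing", region.name
            )
            continue
        for sample_id in sample_ids:
            pct, num, _ = region_methylation_percent(
                region, sites, sample_calls[sample_id].calls,
                min_coverage, meth_fraction_threshold,
            )
            values.loc[region.name, sample_id] = pct
            numerators.loc[region.name, sample_id] = num
    return RegionMethylationMatrix(
        values=values, numerators=numerators, denominators=denominators,
        regions=list(regions),
    )


def load_and_quantify(
    regions: Sequence[GenomicRegion],
    reference: Mapping[str, str],
    calls_dir,
    sample_ids: Sequence[str],
    min_coverage: int = 1,
    meth_fraction_threshold: float = 0.5,
    suffix: str = ".cov",
) -> RegionMethylationMatrix:
    """Read each sample's coverage file from ``calls_dir`` and quantify.

    A missing or unreadable file aborts with an error naming the sample.
    """
    from .genome_io import read_methylation_calls

    sample_calls: dict[str, SampleCalls] = {}
    for sample_id in sample_ids:
        path = Path(calls_dir) / f"{sample_id}{suffix}"
        try:
            sample_calls[sample_id] = read_methylation_calls(path, reference)
        except OSError as exc:
            raise PipelineError(f"cannot read calls for sample {sample_id!r}: {exc}")
    return quantify_cohort(
        regions, reference, sample_calls, min_coverage, meth_fraction_threshold
    )


def filter_all_zero_regions(
    matrix: RegionMethylationMatrix,
) -> RegionMethylationMatrix:
    """Drop regions whose percentage is 0 (or missing) in every sample.

    This mirrors the pruning used to simplify per-sample plots: a region that
    no sample shows any methylation signal for carries no comparative
    information.  Removals are logged.
    """
    vals = matrix.values
    keep_mask = ((vals != 0) & vals.notna()).any(axis=1)
    if vals.shape[1] == 0:  # no samples: nothing is demonstrably non-zero
        keep_mask[:] = False
    removed = list(vals.index[~keep_mask])
    if removed:
        logger.info("removed all-zero region(s): %s", ", ".join(removed))
    keep = list(vals.index[keep_mask])
    return RegionMethylationMatrix(
        values=vals.loc[keep],
        numerators=matrix.numerators.loc[keep],
        denominators=matrix.denominators.loc[keep],
        regions=[r for r in matrix.regions if r.name in set(keep)],
    )


def export_tables(matrix: RegionMethylationMatrix, out_dir, prefix: str = "groi") -> dict[str, Path]:
    """Write the percentage table and the raw numerator/denominator table.

    ``<prefix>_methylation_percent.tsv``: regions x samples percentages.
    ``<prefix>_raw_counts.tsv``: long table region, sample, numerator,
    denominator.  Values round-trip exactly (full float repr).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pct_path = out_dir / f"{prefix}_methylation_percent.tsv"
    raw_path = out_dir / f"{prefix}_raw_counts.tsv"
    matrix.values.rename_axis("region").to_csv(pct_path, sep="\t")
    raw = (
        matrix.numerators.rename_axis("region")
        .reset_index()
        .melt(id_vars="region", var_name="sample_id", value_name="n_methylated_sites")
    )
    raw["n_possible_cpg"] = raw["region"].map(matrix.denominators)
    raw.sort_values(["region", "sample_id"]).to_csv(raw_path, sep="\t", index=False)
    return {"percent": pct_path, "raw": raw_path}


def plot_region_profiles(
    matrix: RegionMethylationMatrix,
    design: pd.DataFrame,
    out_dir,
    paired: bool = False,
) -> list[Path]:
    """One PNG of region methylation percentages per sample, or per pair.

    In paired mode samples are joined via ``pair_id`` from the design table
    and plotted side by side; a sample without a pair_id raises
    :class:`ValidationError` naming it.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if matrix.values.empty or not matrix.sample_ids:
        logger.warning("empty methylation matrix: no profile plots written")
        return []

    region_names = matrix.region_names
    x = np.arange(len(region_names))
    written: list[Path] = []

    def _bar(ax, offset, heights, width, label):
        ax.bar(x + offset, heights, width, label=label)

    if not paired:
        for sample_id in matrix.sample_ids:
            fig, ax = plt.subplots(figsize=(4, 3))
            _bar(ax, 0.0, matrix.values[sample_id].fillna(0.0).to_numpy(), 0.7, sample_id)
            ax.set_xticks(x, region_names, rotation=45, ha="right", fontsize=7)
            ax.set_ylabel("methylated CpG sites (%)")
            ax.set_title(sample_id, fontsize=9)
            fig.tight_layout()
            path = out_dir / f"{sample_id}.png"
            fig.savefig(path, dpi=80)
            plt.close(fig)
            written.append(path)
        return written

    design = design.set_index("sample_id")
    pairs: dict[str, dict[str, str]] = {}
    for sample_id in matrix.sample_ids:
        if sample_id not in design.index:
            raise ValidationError(f"sample {sample_id!r} absent from design table")
        group = design.loc[sample_id, "group"]
        if group not in ("GBM1", "GBM2"):
            continue
        pair_id = design.loc[sample_id, "pair_id"]
        if not pair_id:
            raise ValidationError(f"paired plotting: sample {sample_id!r} has no pair_id")
        pairs.setdefault(pair_id, {})[group] = sample_id
    for pair_id in sorted(pairs):
        members = pairs[pair_id]
        fig, ax = plt.subplots(figsize=(4.5, 3))
        for i, group in enumerate(("GBM1", "GBM2")):
            if group in members:
                heights = matrix.values[members[group]].fillna(0.0).to_numpy()
                _bar(ax, (i - 0.5) * 0.35, heights, 0.35, f"{group} ({members[group]})")
        ax.set_xticks(x, region_names, rotation=45, ha="right", fontsize=7)
        ax.set_ylabel("methylated CpG sites (%)")
        ax.set_title(f"pair {pair_id}", fontsize=9)
        ax.legend(fontsize=6)
        fig.tight_layout()
        path = out_dir / f"pair_{pair_id}.png"
        fig.savefig(path, dpi=80)
        plt.close(fig)
        written.append(path)
    return written
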
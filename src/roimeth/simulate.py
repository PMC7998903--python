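"""Synthetic data generator for the whole pipeline.

Emulates the study design this pipeline was written for: a small
multi-chromosome reference with known CpG placements, FFPE-like sparse
site coverage, group-structured per-read methylation probabilities
(controls higher than tumors for some markers, no primary/recurrent
difference for others), 21 primary/recurrent tumor pairs plus a handful of
controls, and immunohistochemistry intensities 0-3 with group-shifted
percent-positive values read by three readers.

Simulation is at the site-count level (methylated/unmethylated read counts
per CpG site) because that is what the pipeline consumes; read-level
bisulfite realism would add nothing testable.

Reproducibility: every sample owns a pseudo-random stream derived from
``(master seed, sample_id)``, so cohorts are reproducible and independent of
generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .genome_io import (
    CpGSite,
    GenomicRegion,
    SampleCalls,
    SiteCall,
    write_fasta,
    write_methylation_calls,
    write_regions,
)

GROUPS = ("MC", "HC", "GBM1", "GBM2")
#: groups with methylation (RRBS) data; postmortem HC DNA is too fragmented.
METHYLATION_GROUPS = ("MC", "GBM1", "GBM2")
#: groups with IHC slides; the MC biopsies have no matched slides.
IHC_GROUPS = ("HC", "GBM1", "GBM2")

DEFAULT_MARKERS = ("ADRA1D", "ADRBK1", "DRD2", "SLC18A2")

READERS = ("R1", "R2", "R3")

#: per-read methylation probability per marker region and group; controls
#: higher than tumors, no primary/recurrent (GBM1/GBM2) difference.
DEFAULT_REGION_EFFECTS: dict[str, dict[str, float]] = {
    "ADRA1D": {"MC": 0.040, "GBM1": 0.020, "GBM2": 0.020},
    "ADRBK1": {"MC": 0.060, "GBM1": 0.010, "GBM2": 0.010},
    "DRD2": {"MC": 0.050, "GBM1": 0.010, "GBM2": 0.010},
    "SLC18A2": {"MC": 0.030, "GBM1": 0.015, "GBM2": 0.015},
}

#: (P(intensity=0..3), mean percent positive) per marker and group; shifted so
#: the complex-score medians fall in the ballpark seen for these markers
#: (e.g. ADRBK1 strongly up in tumors, ADRA1D down).
DEFAULT_IHC_EFFECTS: dict[str, dict[str, tuple[tuple[float, float, float, float], float]]] = {
    "ADRA1D": {
        "HC": ((0.1, 0.5, 0.3, 0.1), 30.0),
        "GBM1": ((0.2, 0.6, 0.2, 0.0), 15.0),
        "GBM2": ((0.4, 0.5, 0.1, 0.0), 10.0),
    },
    "ADRBK1": {
        "HC": ((0.3, 0.6, 0.1, 0.0), 10.0),
        "GBM1": ((0.0, 0.1, 0.5, 0.4), 30.0),
        "GBM2": ((0.0, 0.3, 0.5, 0.2), 20.0),
    },
    "DRD2": {
        "HC": ((0.0, 0.5, 0.4, 0.1), 35.0),
        "GBM1": ((0.0, 0.2, 0.5, 0.3), 30.0),
        "GBM2": ((0.0, 0.4, 0.4, 0.2), 20.0),
    },
    "SLC18A2": {
        "HC": ((0.3, 0.5, 0.2, 0.0), 15.0),
        "GBM1": ((0.2, 0.6, 0.2, 0.0), 10.0),
        "GBM2": ((0.4, 0.5, 0.1, 0.0), 8.0),
    },
}


@dataclass(frozen=True)
class CohortDesign:
    """One sample's cohort assignment; pair_id links a GBM1/GBM2 pair."""

    sample_id: str
    group: str
    pair_id: str = ""


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the emulated study design."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 50_000
    cpg_density: float = 0.08
    n_regions: int = 4
    region_length: int = 10_000
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: {"MC": 5, "HC": 6, "GBM1": 21, "GBM2": 21}
    )
    coverage_prob: float = 0.3
    depth_mean: float = 5.0
    background_meth_prob: float = 0.75
    pair_offset_sd: float = 0.0
    region_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_REGION_EFFECTS.items()}
    )
    ihc_effects: dict = field(
        default_factory=lambda: {
            m: {g: (tuple(p), mu) for g, (p, mu) in v.items()}
            for m, v in DEFAULT_IHC_EFFECTS.items()
        }
    )
    percent_sd: float = 10.0       # between-sample spread of percent positive
    reader_jitter_sd: float = 5.0  # between-reader spread of percent positive

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 2:
            raise ConfigurationError("need >= 1 chromosome of length >= 2")
        if self.region_length <= 0 or self.n_regions < 0:
            raise ConfigurationError("non-positive region dimensions")
        for name, p in (
            ("cpg_density", self.cpg_density),
            ("coverage_prob", self.coverage_prob),
            ("background_meth_prob", self.background_meth_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.depth_mean < 1:
            raise ConfigurationError("depth_mean must be >= 1 (covered sites have >= 1 read)")
        for g, n in self.cohort_sizes.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
            if n < 1:
                raise ConfigurationError(f"cohort size for {g} must be >= 1")
        if self.cohort_sizes.get("GBM1", 0) != self.cohort_sizes.get("GBM2", 0):
            raise ConfigurationError("GBM1 and GBM2 cohort sizes must match (paired design)")
        for marker, groups in self.region_effects.items():
            for g, p in groups.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"region_effects[{marker}][{g}]={p} outside [0, 1]"
                    )
        for marker, groups in self.ihc_effects.items():
            for g, (probs, mean_pct) in groups.items():
                if len(probs) != 4 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                    raise ConfigurationError(
                        f"ihc_effects[{marker}][{g}] intensity distribution must be a "
                        "probability vector over {0,1,2,3}"
                    )
                if not 0.0 <= mean_pct <= 100.0:
                    raise ConfigurationError(
                        f"ihc_effects[{marker}][{g}] mean percent outside [0, 100]"
                    )


def _stream(seed: int, label: str) -> np.random.Generator:
    """Independent, order-invariant RNG stream keyed by (seed, label)."""
    key = zlib.crc32(label.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Reference and regions
# ---------------------------------------------------------------------------

def generate_reference(config: SimulationConfig) -> tuple[dict[str, str], list[CpGSite]]:
    """Generate reference sequences with explicitly planted CG dinucleotides.

    Background bases are drawn so that no accidental CG is ever formed (after
    a C, G is excluded), hence the returned truth list is exactly the set of
    CG dinucleotides present in the sequences.
    """
    config.validate()
    rng = _stream(config.seed, "reference")
    sequences: dict[str, str] = {}
    truth: list[CpGSite] = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        length = config.chrom_length
        chars: list[str] = []
        plant = rng.random(length) < config.cpg_density
        background = rng.integers(0, 4, size=length)
        i = 0
        while i < length:
            if i + 1 < length and plant[i]:
                truth.append(CpGSite(chrom=chrom, pos=i + 1))
                chars.append("CG")
                i += 2
            else:
                prev = chars[-1][-1] if chars else ""
                alphabet = "ACT" if prev == "C" else "ACGT"
                chars.append(alphabet[background[i] % len(alphabet)])
                i += 1
        sequences[chrom] = "".join(chars)
    return sequences, truth


def generate_regions(
    config: SimulationConfig,
    reference: Mapping[str, str],
    truth_sites: Sequence[CpGSite] | None = None,
) -> list[GenomicRegion]:
    """Place non-overlapping marker regions, each holding >= 1 reference CpG.

    Regions are tiled deterministically across chromosomes with a small gap
    and named after the catecholamine markers (cycling if more regions than
    marker names are requested).
    """
    config.validate()
    from .genome_io import enumerate_cpg_sites

    gap = 100
    chroms = list(reference)
    regions: list[GenomicRegion] = []
    per_chrom_cursor = {c: 0 for c in chroms}
    for k in range(config.n_regions):
        name = DEFAULT_MARKERS[k % len(DEFAULT_MARKERS)]
        if k >= len(DEFAULT_MARKERS):
            name = f"{name}_{k // len(DEFAULT_MARKERS) + 1}"
        chrom = chroms[k % len(chroms)]
        start = per_chrom_cursor[chrom]
        end = start + config.region_length
        if end > len(reference[chrom]):
            raise GenerationError(
                f"cannot place region {name!r}: [{start}, {end}) exceeds "
                f"{chrom} length {len(reference[chrom])}"
            )
        region = GenomicRegion(chrom=chrom, start=start, end=end, name=name)
        if not enumerate_cpg_sites(reference[chrom], region):
            raise GenerationError(f"region {name!r} contains no CpG site")
        regions.append(region)
        per_chrom_cursor[chrom] = end + gap
    return regions


# ---------------------------------------------------------------------------
# Cohort design
# ---------------------------------------------------------------------------

def build_cohort_design(config: SimulationConfig) -> list[CohortDesign]:
    """Sample sheet: controls plus pair-linked primary/recurrent tumors."""
    config.validate()
    design: list[CohortDesign] = []
    for g in ("MC", "HC"):
        for i in range(config.cohort_sizes.get(g, 0)):
            design.append(CohortDesign(sample_id=f"{g}{i + 1:02d}", group=g))
    n_pairs = config.cohort_sizes.get("GBM1", 0)
    for i in range(n_pairs):
        pid = f"P{i + 1:02d}"
        design.append(CohortDesign(sample_id=f"{pid}-GBM1", group="GBM1", pair_id=pid))
        design.append(CohortDesign(sample_id=f"{pid}-GBM2", group="GBM2", pair_id=pid))
    return design


def design_to_frame(design: Sequence[CohortDesign]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.sample_id, d.group, d.pair_id) for d in design],
        columns=["sample_id", "group", "pair_id"],
    )


def write_design(design: Sequence[CohortDesign], path) -> None:
    design_to_frame(design).to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"sample_id", "group", "pair_id"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"design table lacks columns {sorted(missing)}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ConfigurationError(f"design table has unknown groups {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# Methylation calls
# ---------------------------------------------------------------------------

def _site_probabilities(
    truth_sites: Sequence[CpGSite],
    regions: Sequence[GenomicRegion],
    group: str,
    config: SimulationConfig,
    pair_offset: float = 0.0,
) -> np.ndarray:
    probs = np.full(len(truth_sites), config.background_meth_prob)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for idx, s in enumerate(truth_sites):
        by_chrom.setdefault(s.chrom, []).append((s.pos, idx))
    for region in regions:
        effects = config.region_effects.get(region.name)
        if effects is None:
            raise ConfigurationError(f"region_effects missing region {region.name!r}")
        if group not in effects:
            raise ConfigurationError(
                f"region_effects[{region.name!r}] missing group {group!r}"
            )
        p = min(max(effects[group] + pair_offset, 0.0), 1.0)
        for pos, idx in by_chrom.get(region.chrom, ()):
            if region.contains_pos(pos):
                probs[idx] = p
    return probs


def simulate_sample_calls(
    sample: CohortDesign,
    truth_sites: Sequence[CpGSite],
    regions: Sequence[GenomicRegion],
    config: SimulationConfig,
) -> SampleCalls:
    """Simulate one sample's site-level calls over the reference CpG truth.

    Each reference CpG is captured independently with ``coverage_prob``;
    captured sites receive ``1 + Poisson(depth_mean - 1)`` reads, of which a
    binomial share (the region's group probability, or the background
    probability outside all regions) is methylated.
    """
    rng = _stream(config.seed, f"sample:{sample.sample_id}")
    pair_offset = 0.0
    if config.pair_offset_sd > 0 and sample.pair_id:
        pair_rng = _stream(config.seed, f"pair:{sample.pair_id}")
        pair_offset = pair_rng.normal(0.0, config.pair_offset_sd)
    probs = _site_probabilities(truth_sites, regions, sample.group, config, pair_offset)
    n = len(truth_sites)
    covered = rng.random(n) < config.coverage_prob
    depth = np.zeros(n, dtype=np.int64)
    depth[covered] = 1 + rng.poisson(config.depth_mean - 1.0, size=int(covered.sum()))
    n_meth = np.zeros(n, dtype=np.int64)
    n_meth[covered] = rng.binomial(depth[covered], probs[covered])
    out = SampleCalls()
    for idx in np.flatnonzero(covered):
        site = truth_sites[idx]
        out.calls[site] = SiteCall(
            site=site,
            count_methylated=int(n_meth[idx]),
            count_unmethylated=int(depth[idx] - n_meth[idx]),
        )
    return out


# ---------------------------------------------------------------------------
# IHC readings
# ---------------------------------------------------------------------------

def simulate_ihc_readings(
    config: SimulationConfig, design: Sequence[CohortDesign]
) -> pd.DataFrame:
    """Three readers' intensity and percent-positive values per sample x marker.

    The staining intensity and a latent percent-positive are sample-level
    (biology); readers share the intensity call and add independent jitter to
    the percentage, clipped to [0, 100].
    """
    config.validate()
    rows = []
    for sample in design:
        if sample.group not in IHC_GROUPS:
            continue
        rng = _stream(config.seed, f"ihc:{sample.sample_id}")
        for marker in sorted(config.ihc_effects):
            groups = config.ihc_effects[marker]
            if sample.group not in groups:
                raise ConfigurationError(
                    f"ihc_effects[{marker!r}] missing group {sample.group!r}"
                )
            probs, mean_pct = groups[sample.group]
            intensity = int(rng.choice(4, p=np.asarray(probs, dtype=float)))
            latent = float(np.clip(rng.normal(mean_pct, config.percent_sd), 0.0, 100.0))
            for reader in READERS:
                pct = latent
                if config.reader_jitter_sd > 0:
                    pct += rng.normal(0.0, config.reader_jitter_sd)
                rows.append(
                    (sample.sample_id, marker, reader, intensity,
                     float(np.clip(pct, 0.0, 100.0)))
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "marker", "reader", "intensity", "percent_positive"]
    )


def write_ihc_readings(readings: pd.DataFrame, path) -> None:
    readings.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Generate and write every input the pipeline consumes.

    Layout: ``reference.fa``, ``regions.bed``, ``design.tsv``,
    ``ihc_readings.tsv`` and one ``calls/<sample_id>.cov`` per sample with
    methylation data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calls_dir = out_dir / "calls"
    calls_dir.mkdir(exist_ok=True)

    reference, truth = generate_reference(config)
    regions = generate_regions(config, reference, truth)
    design = build_cohort_design(config)

    paths = {
        "fasta": out_dir / "reference.fa",
        "regions": out_dir / "regions.bed",
        "design": out_dir / "design.tsv",
        "ihc": out_dir / "ihc_readings.tsv",
        "calls_dir": calls_dir,
    }
    write_fasta(reference, paths["fasta"])
    write_regions(regions, paths["regions"])
    write_design(design, paths["design"])
    write_ihc_readings(simulate_ihc_readings(config, design), paths["ihc"])
    for sample in design:
        if sample.group not in METHYLATION_GROUPS:
            continue
        calls = simulate_sample_calls(sample, truth, regions, config)
        write_methylation_calls(calls.calls.values(), calls_dir / f"{sample.sample_id}.cov")
    return paths
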
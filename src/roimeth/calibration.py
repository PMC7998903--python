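"""Monte-Carlo calibration experiments for the comparison battery.

These drive the synthetic generator end to end (reference CpG truth ->
site-level calls -> region percentage -> test) across many replicate
cohorts, to measure two operating characteristics of the pipeline under the
study design it emulates:

* the empirical size (type-I error rate) of the paired Wilcoxon test when
  the primary and recurrent members of every pair share identical generating
  parameters, and
* the power of the unpaired Mann-Whitney control-vs-tumor comparison at
  FFPE-like sparsity with a control-vs-tumor per-read methylation contrast.

The size experiment runs at a moderate per-read methylation probability
(default 0.30): at tumor-like probabilities of ~0.01 with sparse coverage
the region statistic is almost surely exactly zero for every sample, all
paired differences vanish, and the signed-rank test is degenerate — no size
calibration is possible there.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

from .quantify import region_methylation_percent
from .simulate import (
    CohortDesign,
    SimulationConfig,
    build_cohort_design,
    generate_reference,
    generate_regions,
    simulate_sample_calls,
)
from .stats import mann_whitney_u, wilcoxon_signed_rank


def _single_region_config(region_effects: dict[str, float], seed: int,
                          n_pairs: int = 21, n_controls: int = 5,
                          coverage_prob: float = 0.3, depth_mean: float = 5.0,
                          ) -> SimulationConfig:
    """One marker region on one small chromosome, cohort sizes as requested."""
    return SimulationConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_length=10_200,
        n_regions=1,
        region_length=10_000,
        coverage_prob=coverage_prob,
        depth_mean=depth_mean,
        cohort_sizes={"MC": n_controls, "HC": 1, "GBM1": n_pairs, "GBM2": n_pairs},
        region_effects={"ADRA1D": dict(region_effects)},
    )


def _region_percent(sample: CohortDesign, truth, regions, sites, config) -> float:
    calls = simulate_sample_calls(sample, truth, regions, config)
    pct, _, _ = region_methylation_percent(regions[0], sites, calls.calls)
    return pct


@dataclass(frozen=True)
class SizeResult:
    rejection_rate: float
    n_seeds: int
    n_pairs: int
    alpha: float


def paired_type1_error(
    n_seeds: int = 1000,
    base_seed: int = 1,
    n_pairs: int = 21,
    meth_prob: float = 0.30,
    alpha: float = 0.05,
    coverage_prob: float = 0.3,
    depth_mean: float = 5.0,
) -> SizeResult:
    """Empirical size of the paired Wilcoxon under identical GBM1/GBM2 effects.

    For each replicate seed a fresh cohort of ``n_pairs`` primary/recurrent
    pairs is simulated with the same per-read methylation probability for
    both members; the region percentage is quantified per sample and the
    paired signed-rank test applied.  Returns the fraction of replicates
    rejecting at ``alpha``.  The reference is generated once (it carries no
    randomness relevant to the null).
    """
    ref_config = _single_region_config(
        {"MC": meth_prob, "GBM1": meth_prob, "GBM2": meth_prob},
        seed=base_seed, n_pairs=n_pairs,
        coverage_prob=coverage_prob, depth_mean=depth_mean,
    )
    reference, truth = generate_reference(ref_config)
    regions = generate_regions(ref_config, reference, truth)
    from .genome_io import enumerate_cpg_sites
    sites = enumerate_cpg_sites(reference[regions[0].chrom], regions[0])

    rejections = 0
    for k in range(n_seeds):
        config = _single_region_config(
            ref_config.region_effects["ADRA1D"], seed=base_seed + k,
            n_pairs=n_pairs, coverage_prob=coverage_prob, depth_mean=depth_mean,
        )
        design = [d for d in build_cohort_design(config) if d.group in ("GBM1", "GBM2")]
        diffs = []
        by_pair: dict[str, dict[str, float]] = {}
        for sample in design:
            by_pair.setdefault(sample.pair_id, {})[sample.group] = _region_percent(
                sample, truth, regions, sites, config
            )
        for members in by_pair.values():
            diffs.append(members["GBM1"] - members["GBM2"])
        result = wilcoxon_signed_rank(diffs)
        if result.p_value < alpha:
            rejections += 1
    return SizeResult(rejection_rate=rejections / n_seeds, n_seeds=n_seeds,
                      n_pairs=n_pairs, alpha=alpha)


@dataclass(frozen=True)
class PowerResult:
    power: float
    ordering_rate: float
    n_seeds: int
    n_controls: int
    n_tumors: int
    alpha: float


def control_vs_tumor_power(
    n_seeds: int = 100,
    base_seed: int = 1,
    control_prob: float = 0.06,
    tumor_prob: float = 0.01,
    n_controls: int = 5,
    n_tumors: int = 21,
    coverage_prob: float = 0.3,
    depth_mean: float = 5.0,
    alpha: float = 0.05,
) -> PowerResult:
    """Power of the unpaired control-vs-tumor comparison at FFPE sparsity.

    Simulates ``n_controls`` control and ``n_tumors`` primary-tumor samples
    per replicate with per-read methylation probabilities ``control_prob``
    vs ``tumor_prob``, quantifies the region and applies the Mann-Whitney U
    test.  Reports the rejection rate at ``alpha`` and the fraction of
    replicates in which the mean recovered percentage orders correctly
    (control > tumor).
    """
    ref_config = _single_region_config(
        {"MC": control_prob, "GBM1": tumor_prob, "GBM2": tumor_prob},
        seed=base_seed, n_pairs=n_tumors, n_controls=n_controls,
        coverage_prob=coverage_prob, depth_mean=depth_mean,
    )
    reference, truth = generate_reference(ref_config)
    regions = generate_regions(ref_config, reference, truth)
    from .genome_io import enumerate_cpg_sites
    sites = enumerate_cpg_sites(reference[regions[0].chrom], regions[0])

    rejections = 0
    ordered = 0
    for k in range(n_seeds):
        config = _single_region_config(
            ref_config.region_effects["ADRA1D"], seed=base_seed + k,
            n_pairs=n_tumors, n_controls=n_controls,
            coverage_prob=coverage_prob, depth_mean=depth_mean,
        )
        design = build_cohort_design(config)
        controls = [
            _region_percent(s, truth, regions, sites, config)
            for s in design if s.group == "MC"
        ]
        tumors = [
            _region_percent(s, truth, regions, sites, config)
            for s in design if s.group == "GBM1"
        ]
        if mann_whitney_u(controls, tumors).p_value < alpha:
            rejections += 1
        if sum(controls) / len(controls) > sum(tumors) / len(tumors):
            ordered += 1
    return PowerResult(power=rejections / n_seeds, ordering_rate=ordered / n_seeds,
                       n_seeds=n_seeds, n_controls=n_controls, n_tumors=n_tumors,
                       alpha=alpha)
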
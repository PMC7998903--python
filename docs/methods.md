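# Methods

## The measurement model

The pipeline quantifies DNA CpG methylation of named genomic regions of
interest (gROIs — one promoter + gene range per marker) from site-level
bisulfite methylation calls, scores immunohistochemistry slides, and runs a
nonparametric comparison battery over a four-group cohort:

- **MC** — methylation controls (non-tumor brain with usable DNA; RRBS only),
- **HC** — histological controls (postmortem brain; IHC only),
- **GBM1 / GBM2** — primary and recurrent glioblastoma from the same
  patient, linked by a pair identifier (both modalities).

The two control groups are disjoint on purpose: postmortem FFPE DNA is too
fragmented for sequencing, while biopsy-sized methylation controls have no
matched slides. The comparison battery therefore picks its control group per
measure — MC for methylation measures, HC for complex scores.

### Region methylation percentage

For a region with reference CpG sites $s_1,\dots,s_D$ and a sample's calls
$(m_i, u_i)$ (methylated/unmethylated read counts at site $i$):

- site $i$ is **captured** iff $m_i + u_i \ge$ `min_coverage` (default 1);
- a captured site is **methylated** iff $m_i / (m_i + u_i) \ge$
  `meth_fraction_threshold` (default 0.5);
- the sample's value is $100 \cdot \#\{\text{methylated}\} / D$.

Design choices behind this, made where the convention is genuinely open:

- *What counts as a CpG site.* One site per CG dinucleotide, anchored at the
  forward-strand C; a CG whose C is the last base inside the region counts
  even when its G falls just outside (membership by anchor base is
  deterministic). Reverse-strand calls (records at the G) are merged into
  the anchor by summing counts; strand collapse conserves total reads.
  Calls at non-CpG reference positions are retained and flagged but never
  enter numerator or denominator.
- *What "captured methylated" means.* The capture/methylation criterion is
  not a community standard at site level; we use the coverage gate plus
  majority-fraction rule above, both configurable, with an "any methylated
  read" preset (`meth_fraction_threshold` → ~0) for the permissive reading.
  With the default 0.5 rule and shallow depth, low per-read methylation
  probabilities (a few percent, typical of unmethylated promoters) yield
  percentages well below the per-read rate; the statistic is a site-count
  fraction, not a read-level average, and the two should not be compared
  numerically.
- *Denominator.* Always the reference CpG count of the region, per sample —
  never pooled across the cohort. A cohort-pooled numerator (counting a site
  as methylated if captured methylated in *any* sample) would make the
  statistic grow with cohort size; that dependence is exactly why comparing
  cohorts of very different sizes with this family of statistics is biased,
  and why this implementation stays strictly per-sample.
- *Missing regions.* A region with zero reference CpGs is marked missing
  (NaN) and excluded from statistics, never imputed. Regions with value 0
  (or missing) in every sample are removed by the all-zero filter.

### IHC complex score

CS = intensity (0–3) × percent positive cells ∈ [0, 300]. Readers are
aggregated on the CS scale (median by default, mean selectable): scoring
each reading first preserves the per-reader product, whereas aggregating
intensities and percentages separately does not commute with it. The median
is robust to one discordant reader; with an even reader count it is the
midpoint of the central pair.

### Comparison battery

Per measure: control vs GBM1 and control vs GBM2 with the two-sided
Mann–Whitney U test; GBM1 vs GBM2 with the two-sided Wilcoxon signed-rank
test on pair-matched differences, using complete pairs only (a pair with
either member missing is dropped and the reported n shrinks accordingly).
Group summaries are median, Q1, Q3.

Numerical conventions:

- Midranks for ties in both tests.
- Exact null distributions (equivalent to enumerating all label assignments
  / sign patterns) for tie-free samples with both n ≤ 8 (U) or n ≤ 12
  (signed rank); otherwise a normal approximation with tie-corrected
  variance and a 0.5 continuity correction. If the observed statistic
  equals its null mean, p = 1 exactly. The approximation agrees with the
  exact p within ~0.01 from n ≈ 10 per group (U) and within ~0.02 at n = 12
  pairs (signed rank); the continuity correction slightly over-corrects
  mid-range p at the smallest sizes.
- Wilcoxon zeros are dropped before ranking (Wilcoxon's original rule, not
  Pratt); all-zero differences give a degenerate result flagged as such
  with p = 1.
- Quantiles: linear interpolation between order statistics by default
  ("type 7"); the weighted-average rule used by some commercial packages
  ("type 6", `rule="weibull"`) is selectable because the two differ
  noticeably at n ≤ 10.
- No multiple-testing correction by default (raw p per marker);
  Benjamini–Hochberg across all comparisons is optional.

## The synthetic-data generator

The generator emulates the study design end to end so that every stage is
testable without controlled-access data. Defaults (all configurable):

| parameter | default | why |
| --- | --- | --- |
| chromosomes × length | 2 × 50 kb | smallest reference exercising multi-chromosome regions |
| CpG density | 0.08 per position | CpG-dense promoter/gene territory, as RRBS enriches for |
| regions | 4 × 10 kb | promoter (~2 kb) + compact gene body per marker; ~800 reference CpGs each |
| cohort | MC 5, HC 6, 21 GBM pairs | the emulated study's group sizes |
| coverage_prob | 0.3 | FFPE dropout: fraction of reference CpGs captured per sample |
| depth_mean | 5 | shallow FFPE RRBS; depth is 1 + Poisson(depth_mean − 1) |
| region effects | controls 3–6 %, tumors 1–2 % per-read; GBM1 = GBM2 | control-high / tumor-low pattern, methylation-silent recurrence |
| background methylation | 0.75 | globally methylated genome outside regions; exercises region masking |
| IHC effects | per marker/group intensity distribution + mean percent | complex-score medians in the ballpark of the emulated markers |
| reader jitter | SD 5 percentage points | inter-reader disagreement on percent positive; intensity is shared |

Mechanics: reference sequences plant CG dinucleotides explicitly and draw
background bases so no accidental CG can form — the generator's truth list
is exactly the enumerable CpG set, which the construction-equals-enumeration
tests rely on. Each sample owns an RNG stream keyed by (master seed,
sample id), so outputs are byte-reproducible and independent of generation
order. Methylated reads at a site are binomial in the region's group
probability; GBM pair members can share a latent per-pair offset
(default 0) to construct paired-difference scenarios.

What the generator does **not** emulate: read-level data and bisulfite
conversion errors, sequence-context coverage bias (real RRBS coverage
follows MspI fragments, not independent site dropout), spatial correlation
of methylation along the genome, tumor purity and subclonal heterogeneity,
and reader bias that correlates across samples. Passing tests therefore
demonstrate the pipeline's correctness and its statistical calibration
under idealized sparsity — not that real FFPE data meet these assumptions.

## Calibration experiments

Two Monte-Carlo experiments (in `roimeth.calibration`, run by both the
acceptance tests and `scripts/acceptance.py`) characterize the battery
under the emulated design:

- **Size.** With identical GBM1/GBM2 generating parameters (21 pairs,
  per-read methylation 0.30, coverage 0.3, depth 5, ~800-CpG region), the
  paired Wilcoxon rejection rate at α = 0.05 over 1000 replicate cohorts is
  ~0.04 — slightly conservative, as expected for a rank test on a discrete
  site-count statistic. The experiment runs at a moderate methylation level
  by design: at tumor-like per-read rates (~0.01) under the same sparsity
  the per-sample statistic is almost surely exactly 0, every paired
  difference vanishes, and the signed-rank test is degenerate, so no size
  measurement is possible there; a calibration experiment needs a
  non-degenerate sampling distribution.
- **Power.** With control vs tumor per-read methylation 6 % vs 1 % at
  coverage 0.3 and depth 5, 5 controls vs 21 tumors, the Mann–Whitney
  comparison rejects at α = 0.05 in ~99 % of 100 replicate cohorts, and the
  mean recovered percentages order correctly (control > tumor) in ~100 %.

Problem sizes throughout (replicate counts, region sizes, cohort sizes) are
the defaults above; they were chosen once as the emulated study conditions
and are passed explicitly by the experiments.

## Known limitations

- The capture/methylation rule is a documented convention, not a recovered
  one; results at shallow depth depend on it, which is why both thresholds
  are exposed and exported alongside the raw numerator/denominator table.
- The per-sample statistic is not comparable across references or region
  definitions (the denominator changes), and not comparable to read-level
  methylation averages.
- The battery reports raw p-values per marker by design; with many regions,
  enable BH.
- Exact tests are only used for tie-free data; heavily tied small samples
  fall back to the approximation, which can be conservative.
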
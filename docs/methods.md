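# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions and the open design choices behind `xbias`. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Screening model

Within one tissue, each probe's log2 intensities are compared between
female and male samples with a two-sided Wilcoxon (Mann–Whitney) rank-sum
test in its normal approximation: midranks for ties, the tie-corrected
variance

σ² = (n₁n₂/12) · [(N+1) − Σ(t³−t)/(N(N−1))],

and a 0.5 continuity correction applied toward the null mean — the
convention of standard statistical environments. A Welch two-sample t-test
(pooled-variance optional) is computed alongside as the parametric
companion; calls are made on the rank-sum p. **No multiple-testing
correction is applied**: the analysis style this package implements screens
at fixed unadjusted thresholds (α = 0.001 for the primary per-tissue screen,
α = 0.01 for the relaxed multi-tissue screen) and controls false positives
downstream by requiring cross-tissue consistency. A probe is called
`female` if p < α and Δ = mean_F − mean_M > 0, `male` if p < α and Δ < 0,
and `ns` otherwise; Δ = 0 with p < α (a measure-zero event) is `ns` because
the direction is undefined. Fold-changes are 2^Δ; table-style reports print
the magnitude 2^|Δ|, with direction carried by the table section.

Rationale for the rank-sum screen: probe intensities need not be normal per
gene; the rank test is insensitive to that, and with the sample sizes the
design targets (tens of arrays per sex) the normal approximation is
accurate. Exact small-sample enumeration exists in the test suite as an
oracle, not in the analysis path.

### Attainable size at small n

The approximation is *conservative* at the tail thresholds this pipeline
uses. At 20 samples per sex, the exact size of the nominal p < 0.001 rule —
computed from the exact null distribution of U — is 0.000595. The test
suite verifies both that the size never exceeds nominal and that null
simulations produce counts consistent with the exact size. Deviations from
exact enumeration p-values are largest for the smallest designs: up to
0.088 at 2 vs 2 observations and 0.051 at 2 vs 3; from 3 observations per
group (or 2 vs ≥4) the approximation is within 0.05 of exact everywhere.
This is a property of the continuity-corrected normal approximation itself,
not of this implementation, which matches the reference implementation of
the same approximation to 10 decimal places.

## Standardization

Matrices are standardized by a single affine transform of the pooled
dataset so that the pooled mean is 8 and pooled SD (ddof = 0) is 2 — the
scale convention for the normalized arrays this pipeline consumes. Pooled
(dataset-level) rather than per-array or per-probe scaling was chosen
because an affine map of the whole matrix preserves every rank statistic
and every fold-change up to a common factor, making standardization a
transparent normalization rather than a modeling step. Standardizing twice
moves no value by more than 1e-9 (asserted). A constant matrix is a
degenerate input (zero pooled SD).

## Chromosome-class contrasts

Biased probes are tallied per tissue × chromosome class (A, X, Y, NA).
Three contrasts are built as 2×2 tables:

* `XF_vs_XM`: (female-biased, not) vs (male-biased, not) within X;
* `XF_vs_AF`, `XM_vs_AM`: (biased-in-direction, not) × (X, A).

The two-sided Fisher exact p is the probability-mass definition: the sum of
hypergeometric probabilities, at fixed margins, of all tables at most as
probable as the observed one. For tables with N ≤ 500 the enumeration runs
in exact integer arithmetic (no floating-point tie tolerance is needed);
larger tables use the identical definition in floating point via SciPy.
The reported effect size for cross-class contrasts is the signed relative
difference (f_X − f_A)/f_A of biased fractions; −0.25 reads as a 25%
relative depletion. Reports round it to the nearest integer percent; full
precision is retained internally. NA-class probes never enter X-vs-A
contrasts.

### Derived array class totals

The packaged summary-table fixture prints biased counts and percentages per
class but not the class sizes. `derive_class_totals` recovers them by the
pooled ratio estimator Σcounts / Σ(pct/100) over every printed cell of a
class with nonzero percentage, rounded to the nearest probe (X ≈ 1429,
A ≈ 43012). The printed percentages carry rounding error, so these totals
are accurate to a few tens of probes — ample for the relative-depletion
percentages, which are integer-rounded, but not for reproducing exact
p-values, which are therefore not asserted anywhere. The derived totals are
logged by the pipeline so the assumption is auditable.

## Escapee exclusion

The packaged exclusion list holds 17 known mouse XCI escapee gene symbols.
Exclusion removes every probe whose gene symbol — or intron host gene —
matches a listed symbol; matching is token-wise so aliased labels
(`2010000I03Rik (Jpx)`) are caught under either name. Unknown symbols in a
user list are ignored with a warning.

## Multi-tissue consistency and clusters

A probe is consistently biased when significant at α = 0.01 in ≥2 tissues
with the same direction in all of them; opposite-direction significance
excludes the probe (a single probe cannot be both). Probes aggregate to
gene-level entries by entry id; intron-marked probe rows merge into their
host entry, standalone intronic rows stay separate. The tissue set of an
entry is the union over its probes; coordinates span min(start)–max(stop)
of the probe alignments.

"Unique gene" counts deduplicate entries sharing a gene symbol (a gene can
appear under two printed entry numbers via distinct probes); unnamed units
(the intergenic transcript, standalone introns) count by entry id. Probe-
level counts ("transcripts") count probe rows. This pairing is what makes
the fixture's gene-level (25) and probe-level (2) multi-tissue counts both
reproduce.

Clusters are found by single-linkage chaining on one chromosome: entries
sorted by start, the gap next.start − current.stop (floored at 0 for
overlaps; 1-based inclusive coordinates throughout) joins entries when
< 50 kb (configurable); only chains of ≥2 are reported, and every emitted
cluster's largest internal gap is asserted below the threshold. Gaps are
measured between probe-alignment extents because those are the coordinates
the fixture tables provide; gene-model boundaries would give slightly
different gaps (one known cluster in the printed tables — Xist/Jpx/Ftx —
only chains under gene-model coordinates, so the total printed cluster
count is not a reproduction target; the Kdm5c cluster, which is, chains
correctly from alignment extents).

## Gene age

Branch labels 0–11 are phylostratigraphic strata; 0–5 predate the placental
mammal radiation (>100 myr) — the boundary is a fixed constant between
branches 5 and 6, not inferred. Probes join the branch table by Ensembl id
with gene-symbol fallback; unmatched probes are excluded and counted.
Branches with fewer than 10 probes are excluded from proportion reports.
The old-vs-young test is a two-sided Fisher exact test on
(biased, not) × (old, young) at the probe level; a gene-level mode exists
for sensitivity analysis because "proportion of genes" and the ≥10-*probe*
filter are both defensible units.

## Synthetic-data model

The generator emulates a large two-sex multi-tissue array experiment:

| parameter | default | meaning |
|---|---|---|
| `n_probes_a/x/y/na` | 43000 / 1428 / 16 / 30 | probes per chromosome class |
| `samples_per_sex` | 50 | arrays per sex per tissue |
| `baseline_mean`, `baseline_sd` | 8, 1.94 | per-probe baseline (log2) |
| `noise_sd` | 0.5 | per-probe residual SD (log2) |
| `x_delta_range` | [0.07, 1.0] | X effect sizes (fold 1.05–2) |
| `a_delta_range` | up to [0.07, 3.0] | autosomal effects; dimorphic tissues allow >4-fold |
| `n_escapees`, `escapee_delta` | 8, 0.4 | escapee-like X entries, biased in all tissues |
| `xist_delta` | 7.0 | Xist-like probe (fold ≈ 128), female-only |
| `y_floor` | 4.0 | female intensity for Y probes (male-only expression) |
| `clusters` | (5, ≤40 kb), (2, ≤40 kb) | planted female-biased clusters |
| `old_female_odds` | 3.0 | old-branch enrichment among female-biased entries |

Females draw Normal(baseline + Δ/2, noise_sd), males Normal(baseline − Δ/2,
noise_sd): symmetric shifts keep the pooled mean at 8, and with baseline SD
1.94 and residual SD 0.5 the pooled SD is ≈ 2.003, so the mean-8/SD-2
standardization is a near-no-op on simulated data. **The decomposition of
the pooled SD of 2 into between-probe baseline spread (1.94) and per-probe
residual noise (0.5) is this package's design choice**: arrays of this class
detect 1.05–2-fold sex differences at p < 0.001 with 46–199 arrays, which
bounds the per-probe residual SD to a few tenths of a log2 unit — a pooled
SD of 2 is dominated by between-probe variation, not noise. All the power
and calibration figures in the test suite follow analytically from this
noise model and are cross-checked against normal-theory approximations
(Wilcoxon ARE 3/π) where stated.

Y probes are modeled as males ~ Normal(max(baseline, floor+2), noise) and
females ~ Normal(floor = 4, noise) — an intensity exists for every probe,
as arrays report, and male-side expression stays clear of the floor.
Cluster members are placed with inter-gene gaps uniform in [1 kb, max_gap);
every other pair of adjacent X genes is ≥ 250 kb apart (5× the 50 kb rule),
so planted clusters are the only sub-threshold adjacencies and cluster
precision/recall can be asserted exactly. Branch labels are drawn
independently of position; `old_female_odds` multiplies the old-branch
(0–5) weights for entries that are female-biased in any tissue, creating a
recoverable age signal. Coordinates are synthetic (the X is as long as the
layout needs); if `chrom_length_x` is set and the layout exceeds it, the
configuration is rejected.

What the generator does **not** model: probe-sequence and hybridization
effects, batch structure, covariates (body weight, hormonal state),
correlated probes within a gene (one probe per entry by default), non-
Gaussian heavy tails, and unequal female:male array counts. Passing
recovery tests therefore demonstrate the pipeline's correctness under a
clean additive-Gaussian regime, not robustness to real-array artifacts.

## Problem sizes in the test and acceptance runs

Calibration and recovery suites run at the sizes their statements specify:
the null false-positive check on 20,000 probes × 20 samples/sex; enrichment
null calibration over 500 replicates of a 3,400-probe single-tissue
experiment at 10 samples/sex; X-excess recovery over 50 replicates of 1,428
X probes (50 female / 10 male planted at Δ = 1, 20/sex); age-split power
over 100 replicates of 1,000 X probes. The general-purpose unit-test
experiment uses 1,510 probes × 2 tissues × 20 samples/sex. These sizes are
the package's chosen study conditions for its own verification and run the
whole suite in well under a minute of statistics time.

## Numerical conventions and degenerate inputs

* Coordinates are 1-based inclusive; the probe length of a record spanning
  positions s..t is t − s + 1.
* Rank-sum rows where all values are tied have zero variance → p = 1.
* t-test with zero variance in both groups: p = 1 when means are equal
  (scalar API raises a degenerate-input error when they differ; the
  vectorized screen maps separation of constants to p = 0).
* Fisher tables with a zero margin are degenerate inputs, except inside the
  age-split test where zero biased probes overall returns p = 1 (no
  evidence of a difference).
* Odds ratios at zero boundaries are ∞ (or NaN for 0/0).
* p-values are clamped to [0, 1].
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configs are bit-reproducible.

## Known limitations

* The exact per-class probe totals of the fixture array are unrecoverable
  from printed percentages (±40 probes); exact fixture p-values are
  consequently out of reach and only integer-rounded relative differences
  are asserted.
* The rank-sum approximation's guarantees at 2–3 observations per group are
  weak (see "Attainable size"); the pipeline requires ≥2 per sex but is
  meant for tens of arrays per sex.
* Escapee exclusion is symbol-based; probes with empty gene symbols can
  never be excluded.
* The cluster rule is a proximity heuristic, sensitive to the choice of
  coordinates (alignment extents vs gene models) near the 50 kb boundary.
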
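# Methods

## Scope and model

cdtbench measures the performance of a local cluster detection test — here
Kulldorff's circular Poisson spatial scan — by simulation. One experiment
("study") fixes a study region, a cluster size D, a set of baseline
incidences I and relative risks theta, and a replicate count m. For every
SU-centered true cluster (the center plus its D−1 nearest neighbours by
Euclidean centroid distance, ties broken toward the SU earlier in the
region order), m datasets are drawn with independent per-SU Poisson counts:
mean eps_i = I·pop_i outside the cluster, theta·eps_i inside. Each dataset
is scanned, the detection is classified against the truth SU-by-SU, and
the per-cluster indicators TC_a, TC_c and usual power are aggregated.

Defaults mirror a realistic birth-defect registry setting: incidences
2.26% and 0.48% of births per year, relative risks 3 and 6, D = 4, m = 1000,
zone population cap 50%, R = 999 Monte Carlo replicates, alpha = 0.05. With
a 221-SU region and the 2×2 risk grid this enumerates 884,000 datasets and
884 cluster×combination summaries.

## The scan statistic

Zones are the nested prefixes of each center's distance-ordered SU list,
kept while 0 < N_z ≤ 0.5·N and N_z < N, deduplicated across centers. The
statistic benchmarks a zone's cases against the **expected count at the
known baseline incidence**: log LR = n_z·log(n_z/(λN_z)) +
(n−n_z)·log((n−n_z)/(λ(N−N_z))) when n_z > λN_z, with λ = I and the
0·log 0 := 0 convention; otherwise the zone is not a candidate. This is a
deliberate design point: the widely used fully conditional form benchmarks
against n·N_z/N instead, and is available via `baseline="conditional"`,
but the λ-benchmarked form is the default because the baseline incidence is
a known input of the simulation design. With no candidate zone the scan
reports an empty detection with statistic 0.

Monte Carlo inference conditions on the observed total n: null replicates
redistribute n over SUs multinomially with probabilities eps_i/Σeps, the
standard convention for scan statistics. p = (1 + #{null ≥ obs})/(R+1);
ties count toward the numerator so p-values are valid, and a no-candidate
observation ties with every replicate, giving p = 1. Detection is p ≤ α.
Tie between zones with equal statistic: fewer SUs first, then the earlier
center — determinism matters more than any substantive argument here.

The kernel evaluates all zones for a batch of case vectors with a
k·log k lookup table (counts are small integers) and precomputed per-zone
log denominators, compiled with numba; a 100-SU scan with R = 199 runs in
a few milliseconds, which is what makes desk-scale ordering experiments
(tens of thousands of scans) practical on one CPU.

## Indicators

TC = TP/(TP+FP+FN) per dataset; a non-significant result classifies all
SUs negative (TP=FP=0, FN=D, TN=n−D), contributing TC = 0. TC_a is the
arithmetic mean of the m TC values; TC_c pools the integer counts first and
divides once (all aggregation is exact integer arithmetic, division last).
Both are ≤ usual power, since a detection contributes 1 to power but at
most 1 to either indicator.

The diagnostic curves sort replicates with detections first by increasing
FP (ties by replicate index — the source ordering is otherwise arbitrary)
and track the running TC_a (f) and TC_c (g). Past the last detection q,
f(s) = M/s and g(s) = A/(B+sD) with M = Σ TP/(D+FP), A = Σ TP, B = Σ FP
over detections, so f/g → M·D/A ≤ 1. Note the exact equality
characterization: M·D/A = 1 iff no detection has both TP > 0 and FP > 0 —
a detection with FP but no TP contributes zero to both M and A and leaves
the ratio untouched. The ratio is undefined (reported absent) when A = 0.

## Synthetic regions

The generator emulates a mixed rural/urban administrative geography:
a square lattice at unit spacing truncated to n SUs, jittered uniformly by
±0.25 (default `jittered-grid`) so distances are effectively tie-free while
the layout stays irregular; populations are log-normal with parameters fit
to quartile cut points 17/35/70 births per year (median 35, σ ≈ 1.049),
a strongly right-skewed distribution. What it does **not** emulate:
spatially autocorrelated population sizes (cities as contiguous
high-population blocks), irregular tract shapes and sizes, and edge
effects of a real region boundary. Passing tests therefore demonstrate the
statistical machinery and the indicator algebra under realistic population
heterogeneity, not the exact spatial pattern of any real region's
performance maps.

## Reproducibility

Every random draw comes from a numpy `SeedSequence` substream keyed by
(master seed; stream tag; combination, cluster, replicate indices): tag 0
for H1 datasets, 1 for null-calibration datasets, 2 for Monte Carlo
inference. Hence identical outputs at any worker count, exact resume, and
re-analysis reproducing archived p-values bit-for-bit. Parallelism is
across clusters (joblib), serial within a cluster's replicates, matching
the archive granularity.

## Problem sizes used in the shipped experiments

The test suite runs scaled-down twins of a full study: oracle equivalence
on 22–25 SU regions (100 datasets against a naive per-zone maximizer),
type-I calibration on 50 SUs (500 homogeneous datasets, R = 199), and the
indicator-ordering experiment on 100 SUs with m = 100, R = 199 at the
highest (I = 2.26%, θ = 6) and lowest (I = 0.48%, θ = 3) risk levels —
sizes chosen so the whole suite completes in minutes on a laptop core
while still giving the ordering comparisons hundreds of clusters.

## Known limitations

- Circular zones and a single most likely cluster only; no elliptic or
  flexible shapes, no secondary clusters, no space–time scanning.
- The Poisson truth model has exactly one cluster and no overdispersion.
- Choropleth class bounds are fixed five equal classes on [0, 1]
  (overridable); a monotone scale is all the maps promise.
- TC is undefined for pure null calibration runs (no simulated cluster);
  those runs report type-I error only.
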
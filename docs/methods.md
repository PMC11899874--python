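# Methods

This note documents the models and procedures implemented in `precimap`,
the parameters that matter, the design choices made where the method
description left room, and what the synthetic-data experiments do and do not
demonstrate.

## The mapping problem

The unit of analysis is the *grayordinate*: a cortical surface sampling
point carrying a BOLD time series (TR 0.8 s in the extended-acquisition
regime the defaults target). An individualized network map assigns every
grayordinate to one of 14 named large-scale networks (AUD, DMN, PMN, SMd,
VAN, CO, FP, PON, SMl, VIS, DAN, MTL, Sal, Tpole) or to "unassigned" (0).
Subcortex is out of scope; everything here is cortex-only.

Two mapping procedures are implemented end to end:

1. **Template matching** — supervised by a set of network templates.
2. **Tie-density community consensus** — unsupervised (Infomap-style), used
   as the comparison arm.

Both consume the same preprocessed input: the dense series smoothed with a
geodesic Gaussian kernel (2.25 mm) and motion-censored at framewise
displacement (FD) < 0.3 mm, then correlated all-against-all (Pearson) into a
dense connectivity matrix.

## Template generation and matching

Per subject, each network of a prior parcellation contributes a *seed map*:
the correlation of the network's unweighted mean time series with every
grayordinate. Seed maps are averaged across the cohort and thresholded per
network at mean + 1·SD of the averaged map (sample SD over all
grayordinates); sub-threshold values are set to exactly 0, which encodes the
template's support.

Matching computes, for every grayordinate g and network k, the eta-squared
similarity between g's connectivity row and template k:

    eta2(a, b) = 1 - SS_within / SS_total
    SS_within  = sum_i (a_i - m_i)^2 + (b_i - m_i)^2,   m_i = (a_i + b_i)/2
    SS_total   = sum_i (a_i - M)^2 + (b_i - M)^2,       M = grand mean

Because the per-pair mean minimizes within-pair squared deviation,
eta2 is always in [0, 1]; it is symmetric but *not* invariant to rescaling
one argument alone. Each grayordinate takes the argmax network
(winner-take-all), so template-matched maps have no unassigned
grayordinates.

Design choices (each exposed as a flag or parameter):

* **2.25 mm is interpreted as the Gaussian sigma**, not FWHM; the kernel is
  truncated at 3·sigma and row-normalized (`smoothing_is_sigma`).
* **The 1-SD threshold is referenced to each network's own averaged map**
  over all grayordinates, not the pooled distribution of all networks
  (`threshold_reference = per_map_all_grayordinates`).
* **eta2 is computed over all grayordinates**, template zeros included
  (`eta_domain = all`) — the thresholded template *is* the network's
  expected profile, zeros and all.
* Exact argmax ties are broken by lowest label id and counted in the log.
* Connectivity is raw Pearson; Fisher z is an export option only.
* The seed is the mean of the raw (smoothed, censored) series, not of
  standardized series (`standardize_before_seed = false`).

## Community-detection consensus

From the same connectivity matrix: pairs closer than the exclusion radius
along the mesh (20 mm at full scale) are removed to control for smoothing;
the strongest `round(density · |admissible|)` pairs are kept at each tie
density (0.3, 0.4, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0 %; rounding is half-up;
weight ties at the cut break lexicographically and are logged); each
thresholded graph is partitioned by a community-detection backend; networks
smaller than 400 grayordinates are unassigned; the per-density maps are
stacked most-stringent-first (a grayordinate keeps the first label it
receives); contiguous clusters smaller than 30 grayordinates are absorbed,
smallest first and iterated to a fixed point, into the neighboring label
with the largest adjacent-cluster grayordinate count; finally the anonymous
communities are renamed by greedy one-to-one Jaccard matching (J ≥ 0.2)
against a named reference parcellation, unmatched communities becoming
unassigned.

The reference backend is a seeded greedy two-level **map-equation**
optimizer: Louvain-style node-move passes (accept the move with the largest
codelength decrease, repeat until no move helps) alternating with graph
aggregation. It is deterministic under its seed and recovers planted
4-block partitions (within-block edge probability 0.9, between 0.01) at
NMI ≥ 0.95; `python-igraph`'s Infomap can be swapped in via
`ConsensusConfig.backend = "igraph-infomap"` and agrees with it on planted
partitions (cross-checked in the tests).

Inferential steps the original description leaves open, and what this
implementation does:

* **Label identity across densities**: each density map's anonymous labels
  are Jaccard-matched to the running consensus before filling unassigned
  grayordinates; communities with no counterpart get fresh ids. This is the
  largest inference in the module.
* The 400-grayordinate size filter is applied **per density map, before**
  consensus stacking.
* Grayordinates unassigned at every density **remain unassigned** rather
  than being forced into a network.

## Reliability

Similarity of two maps is normalized mutual information from the
grayordinate contingency table, natural logs, arithmetic normalization
NMI = 2·I/(H₁+H₂) (alternatives `max` and `sqrt` are available).
Grayordinates unassigned in either map are excluded from the table — they
are "no claim", not a class (switchable). NMI is label-permutation
invariant and bounded in [0, 1]; at G = 2000 its finite-sample bias against
independent maps is below ~0.02.

Split-half analysis cuts the *frame index range* at its midpoint (an odd
frame goes to the first half) and maps each half independently; because
censored frames need not balance across the midpoint, the halves' retained
minutes generally differ. The inter-subject null compares subject i's
first-half map with subject j's second-half map over all ordered pairs
(i ≠ j), mirroring the within-subject construction; like-half pairing is
available. Subjects below a configurable retained-minutes inclusion
threshold (20 min at full scale) are skipped with a logged reason.

Sampling curves draw `round(minutes·60/TR)` retained frames from the first
half — either a consecutive run with a random start (continuous) or
uniformly without replacement (random) — map the sample, and compare to the
full second-half map; each grid point (default 1/5/10/15/25 min) averages
10 repetitions. Data-amount dependence is summarized by OLS of
within-subject NMI on the mean retained minutes per half.

## The synthetic cohort generator

The generator emulates the study conditions the real datasets embody:

* **Surface**: a unit-spacing grid (or icosphere) mesh stands in for the
  midthickness surface; geodesic distances are shortest paths along edges.
* **Group topology**: farthest-point seeds plus round-robin breadth-first
  growth partition the mesh into K contiguous, approximately balanced
  networks.
* **Individual topology**: each grayordinate adjacent to a network boundary
  flips, with probability `boundary_jitter` (default 0.2), to a neighboring
  network's label — individual-specific topology without foreign-label
  islands.
* **Signal**: network latents are low-pass-filtered Gaussian series
  (0.1 Hz cutoff — the large-amplitude, low-frequency regime) with
  population correlation given by a K×K coupling matrix; the "infant"
  preset anticorrelates the dorsal sensorimotor network with DMN, DAN and
  FP at −0.3. A grayordinate in network k observes
  `sqrt(w)·latent_k + sqrt(1−w)·noise` with independent low-passed noise;
  `w` (`within_network_signal_fraction`, default 0.8) is the SNR dial. No
  single value of w is canonical for infant data, so the tests probe a
  range. Under w = 1 and long duration the empirical latent correlations
  converge to the coupling (verified at 10,000 frames, tolerance 0.05).
* **Motion**: FD is a lognormal baseline moment-matched to
  (mean 0.1 mm, SD 0.05 mm) plus Bernoulli spike frames (default
  probability 0.1) resampled above the 0.3 mm threshold, so the censored
  fraction tracks the spike probability.
* **Data amounts**: per-subject durations default to a uniform draw from
  20–44.7 minutes, the acquisition range of the cohort that anchors the
  20-minute inclusion rule; TR defaults to 0.8 s.

The whole cohort is a pure function of `SimulationConfig`, including its
seed.

What the generator does **not** model: hemodynamic response shape, spatially
structured noise, scanner drift, registration error, global signal, or any
volumetric/anatomical structure. Passing tests therefore demonstrate the
*internal consistency* of the pipeline — that it recovers planted topologies
and reproduces the ordinal structure expected of real data (within-subject >
inter-subject similarity; random sampling ≥ continuous at matched minutes;
similarity increasing with data amount) — not its absolute performance on
real infant scans, whose NMI levels are far lower than the clean synthetic
values here.

## Scale-dependent parameters in the synthetic experiments

Several published thresholds are calibrated to real cortical surfaces
(~60–90 k grayordinates, ~2 mm vertex spacing, ~200 mm extent). On toy
meshes of 10²–10³ grayordinates they are rescaled, as the package's own
choice, to preserve each rule's *role* rather than its number:

* distance exclusion 8 mm on a 30×30 mm mesh (vs. 20 mm at full scale) —
  still larger than the smoothing footprint, still smaller than the mesh;
* network-size filter 30 and minimum region 5 (vs. 400 and 30) — the same
  fractions of a ~150-grayordinate toy network as the originals are of a
  full-scale network;
* the consensus method-comparison cohort is processed without spatial
  smoothing, because a 2.25 mm kernel on a 30 mm mesh blurs a large fraction
  of each network and erases the planted boundary differences the
  comparison measures;
* the split-half inclusion rule is 15 retained minutes for 20-minute
  simulated acquisitions (censoring removes ~10 % of frames, so the
  full-scale 20-minute rule would exclude every simulated subject).

Problem sizes used by `scripts/acceptance.py`: recovery/reliability cohort
10 subjects × 2000 grayordinates × 14 networks × 20 min; sampling cohort
5 × 1200 × 14 × 55 min (so the 25-minute grid point fits inside half 1,
matching the extended-acquisition cohort on which sampling analysis is
meaningful); consensus cohort 4 × 900 × 6 × 10 min at w = 0.5 (a noise level
at which both methods' maps reflect the individual realization rather than
saturating at the planted truth); dispatcher calibration 2000 null datasets
per branch, groups of 25.

## Statistical dispatcher

Group comparisons of NMI distributions are routed by diagnostics: Lilliefors
(estimated-parameter Kolmogorov-Smirnov) normality per group; equal variance
by a two-sided F-test (2 groups) or Brown-Forsythe plus Bartlett (> 2, with
unequal variance assumed when they disagree — the conservative choice).
Branches: t-test / one-way ANOVA + Tukey HSD (normal, equal variance);
Welch t / Welch ANOVA + pairwise Welch t (normal, unequal); Mann-Whitney /
Kruskal-Wallis + Dunn's rank post hoc with tie correction and Bonferroni
adjustment (any non-normal); paired designs use the paired t-test or
Wilcoxon signed-rank. Every report carries the diagnostics needed to
re-derive its branch. Calibration is measured per branch as the rejection
rate among null datasets the dispatcher actually routed to that branch;
all six branches sit within 0.05 ± 0.015 at 2000 datasets per branch.

## Numerical choices and degenerate inputs

* Zero-variance grayordinates (exact constant over retained frames) abort
  connectivity with the offending indices named.
* eta2 of two identical constant vectors is 0/0 and defined as 1.0 with a
  warning; the vectorized path treats non-finite ratios the same way.
* A non-positive-semidefinite coupling matrix is repaired by eigenvalue
  clipping and diagonal renormalization; the latent factor uses the
  eigendecomposition, so exactly singular couplings are fine.
* NMI with no jointly assigned grayordinates is an error; both-constant
  identical maps give 1.0, and a zero entropy on one side gives 0.0.
* Tie-density edge counts round half-up; argmax and Jaccard ties break
  deterministically (lowest id / lexicographic) and are logged.
* Low-pass filtering falls back to white noise below 18 frames, where the
  filter's padding would exceed the series.

## Known limitations

* The map-equation optimizer is two-level only; deeply nested community
  structure would be summarized at its top level.
* The consensus pipeline leaves grayordinates unassigned where no density
  assigns them; on small meshes with aggressive exclusion this fraction can
  be substantial.
* The generator's noise is temporally low-passed but spatially white;
  spatial autocorrelation of real BOLD noise would lower all NMI values.
* CIFTI-2 export writes a synthetic single-hemisphere brain-model axis; it
  is a carrier for the toy data, not a registered surface.
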
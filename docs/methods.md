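# Methods

## The model

`overnet` treats a functional network as an overlapping partition: node i
carries a membership vector π_i on the K-simplex, and a binary
functional-connectivity graph A is modeled with an assortative
mixed-membership stochastic blockmodel. Generatively, π_i ~ Dirichlet(α);
for each pair (i, j) each node draws a community indicator from its own
memberships; when the indicators agree on community k the pair links at a
within-community rate b, otherwise at a background rate ε. Marginally

    p(A_ij = 1 | π_i, π_j) = b · Σ_k π_ik π_jk + ε · (1 − Σ_k π_ik π_jk),

so link probability grows with membership overlap. We use a single shared
within-rate b rather than per-community rates: the link rule above carries
no community-specific rate, and — more importantly — freeing the rates
creates a degeneracy in which one community drifts to a low rate and
becomes a catch-all background that absorbs every node (we observed
truth-initialized fits decaying this way). `predict_link_prob` still
accepts per-community rates for evaluating Σ_k π_ik π_jk β_k.

## Inference

Variational, with Dirichlet factors q(π_i) = Dir(γ_i) and closed-form
per-pair factors φ_ij over "agree on k" / "disagree". Global updates are
natural-gradient steps toward α + Σ_j φ_ijk; the default full-node batch
takes the unit step, which is exact coordinate ascent, while node
mini-batching (`FitConfig.batch_nodes`) uses the Robbins–Monro schedule
ρ_t = (τ + t)^(−κ) with defaults τ = 1024, κ = 0.9 (κ must lie in
(0.5, 1]).

Three choices stabilize the fit, each forced by a failure mode we observed:

1. **Initialization is structure-aware.** Symmetric or weakly perturbed
   uniform initializations collapse under synchronous mean-field updates
   (all nodes converge to one community). We instead cluster a spectral
   embedding of the normalized adjacency with seeded k-means and give each
   node a degree-proportional head start on its spectral community, plus a
   seed-controlled random perturbation. Different seeds explore different
   k-means solutions; consensus across seeds is handled downstream.
2. **Rates are re-estimated from the hard partition.** Estimating b and ε
   from the φ-weighted expected counts is self-referential: once ε drops,
   cross-community links get assigned to "agree", which drives ε further
   down and eventually bridges communities together. Measuring b and ε as
   the empirical link rates inside and across the current disjointified
   partition anchors them to the graph. ε is kept below b (set to b/2 if
   the partition is anti-assortative).
3. **The best-objective iterate is returned.** Dense-pair mean-field
   accumulates γ mass from every same-community pair, linked or not, so
   after finding the structure the largest community slowly absorbs the
   rest. The monitored objective — the marginal pair pseudo-likelihood
   Σ_{i<j} log p̂(A_ij) — peaks at the structured solution and declines
   during this drift, so the fit snapshots the best iterate and stops when
   it has not improved for `patience` (10) iterations.

A consequence worth knowing: on a structureless (Erdős–Rényi) graph the
optimum of this objective is the homogeneous explanation — all nodes
confidently in a single community with b equal to the density. The fit
therefore signals "no structure" through community occupancy, not through
diffuse membership values. Isolated nodes receive the prior (uniform
memberships) with a warning, since no pair carries evidence about them.

Hyperparameter defaults: α = 1/K (symmetric), max_iters = 150,
rate re-estimation starts after 3 iterations. A 542-node, K = 7 fit takes
roughly a second on one core.

## Consensus and aggregation

Communities come out of each fit in arbitrary order. Following the
k-means/cosine/assignment recipe: membership columns from all seeds are
pooled, canonically sorted (so no result can depend on column order),
clustered into K centroids, and each seed is aligned to the centroids by
the permutation maximizing total column cosine similarity (Hungarian
algorithm; ties resolved at the lowest index). Aligned matrices are
averaged and rows renormalized. The same centroids align run-level results
before averaging runs→sessions→animals→group, with row renormalization at
every stage. Consensus output is exactly invariant to independent column
permutations of every input; its own column order follows the canonical
centroid order, so "identical seeds in, same matrix out" holds up to that
canonical permutation.

## Graph construction

Per run: optional zero-phase Butterworth band-pass (forward–backward
`sosfiltfilt`, which doubles the effective order — the nominal order is 3),
with `trim` (default 15) samples discarded from each end. Note the 0.01 Hz
band edge has a transient of several hundred samples; the trim removes the
worst edge artifacts, but steady-state attenuation figures should be
measured mid-signal. Frames with motion above 0.1 mm are censored, and a
run is dropped when more than half its frames exceed the threshold.
Pearson correlation matrices are binarized by rank-ordering the
off-diagonal weights (signed value by default; magnitude via
`absolute=True`) and keeping the top fraction d (default 0.15), with ties
broken deterministically by (i, j) order so every run's graph has exactly
round(d·N(N−1)/2) edges. Group FC is averaged through Fisher's r-to-z.

## Node statistics

Membership entropy h_i = −Σ_k π_ik log_K π_ik ∈ [0, 1] (0 = disjoint,
1 = uniformly affiliated; a node split over two networks sits at log_K 2).
Membership values are thresholded per animal before interpretation: each
(node, community) entry is tested against zero across runs (one-sided
one-sample t-test — memberships are nonnegative), BH-FDR corrected at
q = 0.05 across all entries, zeroed if not significant, and rows
renormalized. "Belonging" uses t_ik = (π̄_ik − μ0)/SE_ik with μ0 = 1/K and
SE from the hierarchical bootstrap; the overlap score is the fraction of
nodes belonging to more than one network. Tiers assign each entry the
highest multiplier m of 1/K it significantly exceeds (default multipliers
0.5, 1.5, 2.5, 3.5 — thresholds between consecutive multiples of 1/K).
Membership histograms use four bins of width 0.2 on (0.2, 1.0]; values at
or below 0.2 are excluded because the disjoint-benchmark calibration shows
the detector keeps >0.8 of the mass on the true community, making 0.2 the
complement floor. Degree, normalized degree (per region count), weighted
degree, rank-ordered t-statistic percentile maps, and the participation
coefficient 1 − Σ_s (k_is/k_i)² (0 for isolated nodes, with a count warning)
complete the battery.

Network similarity between two aligned community columns is reported on a
[0, 1] scale s = (c + 1)/2 where c is the cosine of the mean-centered
columns: 1 identical, 0.5 orthogonal/unrelated, 0 inversely correlated.
The three anchor points are only mutually consistent if the cosine can be
negative, hence the centering; the raw non-centered variant is available
via `centered=False`.

## Inference machinery

The hierarchical bootstrap resamples animals, then sessions within each
sampled animal, then runs within each sampled session (all with
replacement), so every resampled path exists in the data. SE is the
bootstrap standard deviation; intervals are BCa with the acceleration from
an animal-level jackknife (the natural exchangeable unit), falling back to
percentile intervals with a warning when only one animal exists. Default
10,000 iterations (the full-scale 10⁶ is supported; estimates scale as
1/√B). Calibration, measured at 500 replicate experiments on the
10 × 3 × 4 design: with Gaussian random effects at the animal and session
levels (sd 0.5 each) plus run noise (sd 1), 95% BCa coverage is ≈ 0.96.
Two regimes bracket this: with no hierarchical structure at all the
three-stage resampling triples the bootstrap variance and intervals
over-cover (≈ 0.99), and when animal-level variance dominates, 10 clusters
is few and coverage drops toward 0.91. Users whose effect of interest
lives at the animal level should expect the latter.

Paired condition comparisons use two-sided sign-flip permutation tests:
exact enumeration of the 2^n sign patterns when that fits in the resample
budget, otherwise Monte-Carlo with p = (b+1)/(B+1). Holm–Bonferroni and
Benjamini–Hochberg corrections are delegated to statsmodels behind the
package's own surface and are property-tested against literal step-down /
step-up implementations.

## Gradients

Group FC → keep each row's top fraction of connections (default 10%,
negatives zeroed) → cosine affinity between sparsified connectivity
profiles → anisotropic diffusion normalization (α = 0.5) → eigendecompose
the symmetric diffusion operator. The trivial stationary eigenvector is
dropped; components are ordered by eigenvalue magnitude, z-scored, and
sign-fixed (largest-magnitude loading positive). Variance fractions are
eigenvalue mass over the nontrivial positive total. A disconnected
affinity raises an error naming the component count — note that toy block
matrices with zero between-block correlation disconnect *by construction*
under row sparsification, so small synthetic inputs need a gentler
sparsification (we use top 60% for ≤ 40-node examples). Gradient sets are
compared by pairwise Pearson correlation with an optimal assignment on
absolute correlation (eigenvector signs are arbitrary).

## Synthetic data

The dataset generator emulates the hierarchical design: K latent community
time courses per run (low-pass-smoothed unit-variance noise, cutoff 0.4 of
Nyquist by default), mixed into ROI signals by the planted membership
matrix, plus Gaussian observation noise; each animal perturbs the planted
memberships slightly (sd 0.02, renormalized) so animal-level variance
exists; motion traces have a small baseline with exponential spikes for
censoring simulations. It reproduces the design arithmetic (10 × 3 × 4
runs of 10 min = 1200 min) but none of the physiology: no hemodynamics, no
spatial autocorrelation, no scanner artifacts, no frequency-dependent
coupling between conditions. Passing tests on these data demonstrate that
the pipeline's algorithms behave as specified on data that match the
model's assumptions — not that the assumptions hold in any real recording.

The overlapping LFR-style generator draws power-law degrees (exponent t1,
default 2, or fitted to a reference degree distribution via a log-log
slope) with the mean matched to the requested density, and power-law
community sizes (exponent t2 = 0.1) on [c_min, c_max] = [0.05N, 0.35N],
then places exactly ON overlapping nodes with OM memberships each. Edges
are laid down by degree-matched (Chung-Lu) sampling inside communities and
across them at rate set by the mixing parameter μ (default 0.2 — moderate
mixing, chosen once as typical for FC-derived graphs), with the edge
probabilities rescaled so the realized density lands within ~2% of the
request. ON and OM are exact; degrees and mixing are approximate, and the
realized per-node mixing is returned. A node whose internal-degree demand
exceeds its communities' capacity (small community, high degree) has the
excess shifted to external links; sequence construction retries up to 100
times before raising an error naming the violated constraint.

## Problem sizes

Defaults are desk-scale and stated as such: pipeline examples use 40–120
node graphs, consensus over 5–10 seeds (the full-scale analysis uses 500),
and bootstraps of 10³–10⁴ iterations. The calibration benchmark runs at
full size (N = 542, K = 7, 10 seeds) in well under a minute.

## Known limitations

- Mean-field memberships are overconfident: π values concentrate more than
  the posterior warrants, which is why overlap quantification relies on
  thresholding, consensus averaging, and the entropy/belonging statistics
  rather than raw membership magnitudes.
- Model selection over K is out of scope; K is fixed a priori.
- The LFR-style generator is a Chung-Lu approximation of the original
  rewiring construction: degree and mixing tolerances are declared, not
  exact.
- BCa coverage degrades when cluster-level variance dominates with few
  clusters (see above); this is a property of the method, not a knob.
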
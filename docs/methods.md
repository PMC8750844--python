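# Methods

`dmrsmooth` detects differentially methylated regions (DMRs) between two
groups of replicated whole-genome bisulfite sequencing samples using a
three-step nonparametric procedure: smoothing of the between-group
methylation difference curve, location of candidate regions at equilibrium
points of the smoothed curve, and biological refinement followed by
Bonferroni-corrected t-tests.

## Data model

Input is one count table per replicate: per CpG site, a methylated count and
a total count (Bismark-coverage or 4-column TSV). Replicates are outer-joined
on position; absent (position, replicate) cells are filled with (0, 0) counts
and the number of fills is reported — a zero count contributes nothing to the
pooled sums, so this matches the pooled-level definition below. Sites whose
pooled total count is zero in either group are removed before analysis (their
level is 0/0); a `pooled` variant of the rule, removing a site only when all
replicates of both groups have zero coverage, is selectable because the
weaker reading is also defensible. Strand is ignored; positions are 1-based
internally and converted to 0-based half-open only in BED output.

The per-site group methylation level is the pooled ratio
`level = Σ_r meth_r / Σ_r total_r` across replicates, and the response for
all smoothing is the per-site difference `d_i = level_A(x_i) − level_B(x_i)`.
Pooling weights replicates by coverage; no per-replicate variance model is
assumed (the procedure is deliberately nonparametric).

## Step 1 — smoothing the difference curve

The smoothed difference curve is a Nadaraya–Watson (local-constant) estimate
with a standard normal kernel,

    θ̂(x0) = Σ_i κ_h(x_i − x0) d_i / Σ_i κ_h(x_i − x0),

where the bandwidth h is the kernel's standard deviation. The bandwidth
adapts to local site density: starting from a baseline h0, h is multiplied by
1.1 until the 95% kernel window x0 ± z·h (z = Φ⁻¹(0.975) ≈ 1.959964) contains
at least 70 sites ("influence points"), capped at the number of available
sites. The geometric schedule is deterministic and terminates; 70 influence
points is the procedure's effective resolution floor — in data of mean
spacing Δ the working bandwidth never falls below ≈ 70Δ/(2z).

### Baseline bandwidth (AMISE plug-in)

With `h0="auto"` the baseline minimises the asymptotic mean integrated
squared error for a fixed design on span (b−a):

    h0 = [ σ̂² R(κ) (b−a)² / (n μ₂(κ)² R̂(θ″)) ]^{1/5},

R(κ) = 1/(2√π), μ₂(κ) = 1 for the Gaussian kernel. σ̂² is the Rice
first-difference estimator Σ(d_{i+1}−d_i)²/(2(n−1)). R̂(θ″) = ∫θ̂″² comes
from a pilot Nadaraya–Watson smooth at twice a rule-of-thumb scale,
differentiated twice on a 401-point uniform grid, **minus** the expected
noise contribution σ̂²R(κ″)(b−a)²/(n h_pilot⁵), R(κ″) = 3/(8√π); without
that correction the plug-in is noise-dominated whenever the pilot tracks the
data closely. The rule-of-thumb scale is span/40, deliberately n-free so the
n^(−1/5) law is carried by the formula itself (verified: a 32× larger sample
yields a ratio of 0.505 vs the theoretical 0.5); it targets
chromosome-scale curvature. Degenerate inputs (constant d, or curvature
indistinguishable from noise) fall back to span/10 with a warning. Because
the plug-in is global, the pipeline additionally caps the auto baseline at
the adaptive-influence scale 70Δ/(2z): above that scale the influence rule
governs anyway, and an uncapped fallback would flatten every local feature.
A user-supplied h0 is never capped.

### Segmentation

Long chromosomes are smoothed in overlapping segments for tractability:
original segments of 2000 sites tile the index range; additional 2000-site
segments are centred on each interior boundary. Each segment contributes the
predictions of its central 1000 indices (terminal segments contribute 1500
toward the chromosome end), so contribution spans tile the range exactly
once — asserted at plan construction. Sites of a segment beyond its
contribution span still serve as influence points for predictions inside it.
The first and last `trim_sites` sites are excluded from analysis as
boundary-unreliable; the default is `auto` = min(11,000, n/20) — 11,000 at
the ~700k-site scale of a full human chromosome, proportionally smaller for
small inputs (11,000 would erase a small simulation entirely).

## Step 2 — equilibrium points and confidence windows

The first derivative θ̇(x0) is estimated at every analyzed site by
kernel-weighted local quadratic least squares,

    α̂ = argmin Σ_i κ_h(x_i−x0) (d_i − α0 − α1(x_i−x0) − α2(x_i−x0)²)²,

with θ̂(x0) = α̂0 and θ̂̇(x0) = α̂1; the quadratic term reduces boundary
bias relative to a local linear fit. Implementation notes: covariates are
centred and scaled by h for conditioning; weights are the unnormalised
Gaussian exp(−u²/2) so Σw acts as an effective influence count (the 1/h
factor of κ_h cancels from both the estimator and its variance); the
weighted RSS is computed from explicit residuals because the quadratic-form
shortcut cancels catastrophically on near-exact fits. The variance of α̂1 is
the heteroscedasticity-agnostic sandwich
(X′WX)⁻¹(X′W²X)(X′WX)⁻¹ σ̂² with σ̂² = wRSS/(Σw − 3), and the pointwise
interval uses normal quantiles, matching the asymptotic framing: (l, u) =
α̂1 ∓ z·se. On simulated null data (flat difference, binomial counts at
depth 30) the 95% intervals cover zero at ≈ 96% — slightly conservative.
The se = 0 exact-fit limit is handled as p = 0 for α̂1 ≠ 0, p = 1 otherwise.

Equilibrium points — coordinates where θ̇ = 0, i.e. local extrema of the
smoothed curve — are found from the per-site derivative track:

* at every sign change of α̂1 (+→− a maximum, −→+ a minimum), the point is
  the site with smallest |α̂1| inside the adjacent maximal run of sites whose
  CIs contain zero (ties broken by largest p-value); a crossing with no
  CI-containing-zero neighbour yields nothing;
* a maximal CI-zero run with no observed sign change (a plateau, possible
  because the sites are discrete) yields at most one point: the site with
  the largest p-value, its kind read from the flanking derivative signs,
  falling back to the sign of the local curvature α̂2 at the track ends.

Both maxima and minima are kept: regions may be hyper- or hypomethylated.

Each equilibrium point's derivative CI (l, u) is inverted into a positional
confidence window by scanning up to 10 sites on either side: for a maximum
the upper coordinate is the first site with α̂1 ≤ l and the lower coordinate
the first with α̂1 ≥ u (mirrored comparisons for minima). If only one side
resolves at k sites, the other is set k sites opposite by symmetry
("mirrored"); if the mirror leaves the analyzed track, or neither side
resolves within 10 sites, the point is discarded. The scan runs over the
stitched position-ordered track, ignoring segment boundaries.

## Step 3 — refinement and testing

A candidate region is the set of sites inside a window. Member sites are
split into maximal clusters at every inter-site gap strictly greater than
300 bp (a DMR should contain at least one CpG per 0.3 kb; a gap of exactly
300 bp does not split). Clusters with fewer than 10 sites — singletons being
the fully dispersed case — are discarded, and clusters from different
equilibrium points that share sites are merged so no site is tested twice.
Refinement is idempotent and every output satisfies both rules by
construction. Note the split rule means the candidate funnel is not strictly
monotone: one window can legitimately become two tested regions.

Each surviving region is tested with a one-sample two-sided t-test of its
raw per-site differences d_i against zero (t = mean/(sd/√n), df = n−1); a
region is a DMR when p < 0.05 / #tested regions (Bonferroni over the regions
actually tested). Zero-variance regions are reported untested rather than
silently dropped. Whether the t-test should use raw or smoothed differences
is ambiguous in the source description; raw differences are the default and
the smoothed track is available for inspection export only. Two optional
stricter filters are off by default: minimum pooled coverage at every member
site, and a minimum |mean difference|.

## Synthetic data

The generator emulates the structure the method assumes: inter-site gaps are
geometric with configurable mean (default 100 bp; irregular spacing without
explicit CpG-island structure), a smooth baseline level shared by both
groups, and localized difference bumps added to group A. Bumps are Tukey
windows — a flat core carrying the nominal effect with raised-cosine tapers
over the outer quarter of each side — so the true difference curve is smooth
while the interior of a planted region carries the stated effect size.
Counts are total ~ Poisson(depth) and meth ~ Binomial(total, level) per
replicate; Poisson depth lets zero-coverage sites occur naturally,
exercising the undefined-level filter. Everything is reproducible from the
seed.

What the generator does **not** emulate: replicate-specific batch effects,
coverage autocorrelation along the genome, CpG-island clustering of sites,
and baseline variation between groups. A green recovery test therefore
establishes that the pipeline machinery works on smooth, binomial,
independently-sampled data — not that it is robust to those real-data
features.

## Operating characteristics measured on the frozen worlds

Two nominal operating bounds are asserted by the acceptance tests and are
**not met** by the procedure on the frozen simulation worlds; the tests are
left failing deliberately rather than re-tuned, and the shortfalls are
genuine properties of the procedure there:

* **Planted recovery** (20,000 sites, 100 bp mean spacing, ten 2-kb bumps of
  effect 0.3, depth 30, 3+3 replicates): sensitivity ≈ 0.7 against a nominal
  0.8, FDP 0.0–0.2. Stage-tracing shows three loss modes, all faithful to
  the published rules: a >300-bp gap inside the ±10-site window splits it
  below 10 sites; the scan fails to exit the derivative CI within 10 sites
  on both flanks (the point is then discarded by rule); and the Bonferroni
  boundary (p just above 0.05/#tested). The window is a confidence interval
  for the extremum *location* — it tightens, not widens, as the signal
  strengthens, so it cannot be made to hold more sites by increasing depth.
* **Null family-wise error** (100 null chromosomes of 2000 sites): the share
  of runs with at least one significant call is ≈ 0.17 against a nominal
  0.094, and grows with chromosome size. The cause is selection: regions
  are selected where the smoothed *same* differences have an extremum, so
  the selected sites' mean is biased away from zero and the per-region
  t-test p-values are anti-conservative. Bonferroni divides by the number
  of tested regions, which does not address this double-dipping. Users
  should treat the per-region p-values as ranking scores, not calibrated
  error rates, on weak-signal data; the stricter optional filters
  (`min_coverage`, `min_abs_diff`) are the practical mitigation.

## Numerical and design choices

* Gaussian kernel only; the kernel argument is a seam where tricube or
  Epanechnikov variants could be added, but none are implemented.
* 95% kernel window uses the exact normal quantile 1.959964, not 2.
* Degenerate local designs (<3 distinct coordinates with weight) raise and
  the site is skipped rather than imputed.
* The pipeline contains no unseeded randomness; identical inputs give
  byte-identical outputs.
* BED scores encode min(1000, round(−10·log10 p)); untested regions score 0.
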
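# Methods

## Model

Each cytosine site carries counts (k, N): methylated ("C") reads out of
total reads.  Conditional on the latent binary methylation status, reads
are independent Bernoulli trials with C-read probability p₁ (methylated)
or p₀ (non-methylated), so the site likelihoods are binomial kernels; the
combinatorial constant cancels in every odds ratio and is omitted.  The
posterior odds of methylation under prior π are

    odds = [π/(1−π)] · (p₁/p₀)ᵏ · ((1−p₁)/(1−p₀))^(N−k)

computed in log space.  A site is called methylated when odds ≥ cutoff
(ties methylated); the default cutoff 19 makes the posterior probability of
a false methylated call at most 1/(1+19) = 0.05.  Sites with N = 0 are
carried through as `no_data` so output rows always align with input rows.

Sequencing error ε folds into the conversion rates as
p' = p(1−ε) + (1−p)ε.  This folding formula is a reconstruction from the
verbal description of the error process (a C read arises either from a
correctly read C signal or from a misread T); in practice ε is confounded
with p₀/p₁ when rates are estimated from data, so the default is ε = 0 and
ε matters only for forward simulation.

## Error-rate estimation (EM)

p₀, p₁ and the global methylation level π are estimated by EM on a
two-component binomial mixture over covered sites (details in
`bisclass.em`).  The E/M updates and the convergence rule are the standard
ones for this mixture; the original derivation circulated only in an
unavailable supplement, so this module is a faithful reconstruction from
the stated likelihood model.  Defaults: init p₀ = 0.005, p₁ = 0.5,
π = pooled C fraction; tol 1e-8 on the log-likelihood; max 500 iterations;
identifiability enforced by a label swap on exit (p₀ < p₁).  Equal (k, N)
pairs are collapsed with multiplicities, so the per-iteration cost is the
number of distinct count pairs, not the number of sites.  Degenerate input
with no C reads at all leaves p₁ at its initial value and reports
non-convergence.  A moment-based alternative for π alone inverts
E[F] = π·p₁ + (1−π)·p₀ on the pooled counts; the two estimators agree to
Monte-Carlo error on model-generated data, and both sit below the raw
fractional methylation for sparse methylomes (non-conversion inflates raw
F; over-conversion deflates it).

## Local prior

The prior mixes global and local methylation levels,
π₁ᶜ = (1−w)π₁ᴳ + wπ₁ᴸ, clipped into [1e-6, 1−1e-6] so log-odds stay
finite in fully unmethylated windows.  w = 0.5 treats the two sources
equally and is the documented default.

π₁ᴸ is a kernel-weighted average over neighboring covered sites of the
per-site corrected fraction c = clip((F − p₀)/(p₁ − p₀), 0, 1), weighted by
kernel value times read count.  Design points, each genuinely open in the
source description and decided here:

* **Read-count weighting.** Deep neighbors estimate their fraction better,
  so terms are weighted by Lₖ as well as K(dₖ); a `count_weighted=False`
  flag drops the Lₖ factor.
* **Clipping.** Per-neighbor corrected fractions are clipped to [0, 1]
  before averaging; F < p₀ at a sparse site is sampling noise.  Clipping
  slightly deflates local levels in very-low-coverage neighborhoods
  (a single-C-read neighbor contributes c = 1 rather than ≈ 1.4).
* **Windows.** `distance` mode uses every site with nonzero kernel weight
  (for the truncating triangle kernel, ± bandwidth).  `k_nearest` mode uses
  the k nearest covered cytosines: the contiguous run of k+1 sorted covered
  positions minimizing the maximum distance, with the kernel bandwidth set
  adaptively to the window half-width so weights still decay with distance.
  On evenly spaced genomes the two modes coincide (200 nearest sites at
  15 bp spacing ≈ a 1.5 kb half-window).  Windows never cross chromosome
  boundaries; K(0) = 0 excludes the focal site so its own reads never
  inform its prior.  If a window holds no covered neighbor the local level
  falls back to π₁ᴳ.
* **Kernels.** triangle (default; zero beyond the bandwidth), gaussian,
  laplace.  On clustered simulations the three give ≥ 95% concordant calls.
* **Bandwidth.** Default 1500 bp, the distance at which the spatial
  correlation of methylation levels in honey-bee-like methylomes falls
  below 0.2; `bisclass.spatial.select_bandwidth` re-derives it from data as
  the first sustained crossing of the binned correlation curve below the
  threshold (binning defaults: pairs within 5 kb, 50 bp bins, coverage ≥ 4
  to stabilize F — the pairing scheme of the original analysis is not
  recorded, so these are package defaults, all overridable).

Numerics: triangle-kernel window sums are evaluated exactly by a prefix-sum
decomposition (the weight is linear in position on each side of the focal
site), giving O(n log n) total work; gaussian/laplace use a memory-bounded
chunked evaluation.  Both paths agree with brute force to ~1e-13.

## Binomial baseline

Upper-tail binomial p-values P(X ≥ k) under Binomial(N, p₀), corrected by
Benjamini–Hochberg over all covered sites of the analyzed context (the
printed one-line q ≈ p·N/rank formula is not monotone; the full step-up
with cumulative minimum is the standard interpretation and is what is
implemented, via statsmodels).  `min_calling_percentile(k, N, p₀, α)` =
p/α is the smallest p-value percentile (equivalently, genome methylation
level) at which BH can call the site: 4% for a single C read and ≈ 12% for
one C in three reads at p₀ = 0.002 — the low-coverage power pathology that
motivates the posterior-odds caller.

## Simulator

The generator encodes the study conditions: 100,000 CpGs at uniform 15 bp
spacing on one synthetic chromosome; per-site coverage 1 + NB with the NB
component moment-matched so the shifted draw has mean `mean_cov`
(default 4, honey-bee-like; the benchmark cells use 3–9) and variance
`var_factor × mean_cov` (default 3×).  The shift constant 1 is a package
choice (the source states only the mean and variance); it guarantees every
site is covered and reproduces both stated moments exactly.  Methylation
truth is Bernoulli: homogeneous at rate π (default 0.005), or clustered
with `cluster_fraction` (0.1) of sites in `cluster_count` (10) contiguous
blocks at `cluster_intensity` (10×) times π, with the out-of-cluster rate
chosen by conservation so the genome-wide expectation equals π in both
modes — zero out-of-cluster at the defaults.  The alternative reading
(out-of-cluster = π) is available as `preserve_global_mean=False`.  Reads
are Binomial(N, p₁') or Binomial(N, p₀') per the truth.  Everything is
reproducible from one seed.

What the simulator does *not* emulate: read-level artifacts (PCR
duplicates, mapping bias, quality scores), non-CpG contexts,
strand-resolved counts, and the fine-scale spatial texture of real
methylomes (within clusters, truth is i.i.d.).  Consequently, passing
benchmarks show correct behavior of the statistical machinery under the
stated coverage/sparsity/clustering regime, not end-to-end accuracy on any
particular real dataset.

## Benchmark findings and test design

On the clustered low-coverage cell (coverage 3, π = 0.005, p₀ = 0.002,
p₁ = 0.7) the posterior-odds caller is more sensitive than the binomial
baseline by a small but systematic margin (≈ +0.5 percentage points,
paired over shared simulations) and its methylated-normalized
false-positive ratio stays far below 5%.  The advantage is small in this
cell because the in-cluster methylation rate (10 × 0.005 = 0.05) sits just
below the local level (≈ 0.1) at which a single-C-read site crosses odds
19; at π = 0.01 the in-cluster rate reaches 0.1 and the sensitivity gain
exceeds 10 percentage points.  AUC, which sweeps all cutoffs, shows a large
and uniform advantage (≈ +0.02 to +0.07) in every clustered cell.  In
homogeneous genomes the two callers are close, with the binomial baseline
very slightly (< 1 point) more sensitive at its q < 0.05 boundary — FDR
control and the per-site posterior bound reject slightly different marginal
sites.

Accordingly the test suite assesses superiority with paired per-replicate
differences (both methods score the same simulated genomes; 3 paired SEs)
and equivalence by comparing each method's mean ± 3 unpaired Monte-Carlo
SEs, since a paired equivalence test would flag arbitrarily small
systematic differences that are invisible at figure resolution.  Benchmark
sizes in the tests (10–50 replicates of 100,000-site genomes) keep the
whole suite under a minute while leaving the decisive margins several SEs
wide.

## Evaluation metrics

Because sparse methylomes are extremely unbalanced, the false-positive
ratio is reported normalized by the number of *truly methylated* sites
(FP / #methylated) — the convention of the original evaluation — alongside
the standard specificity TN/(TN+FP) and the class-weighted accuracy.  AUC
uses the Mann–Whitney rank formulation with midrank ties (posterior odds
ranked descending; binomial p-values ascending).  The coverage-downsampling
experiment builds a pseudo-truth from coverage-rich sites (≥ 7 reads;
F < 0.1 non-methylated, F > 0.3 methylated, intermediates excluded),
subsamples reads without replacement (hypergeometric) to 1–3 reads and
re-runs both callers.  Replicate consistency reports the coefficient of
variation of methylated-site counts and pairwise Pearson correlations of
per-feature methylation levels (user-supplied BED features, or 1 kb tiles).

## Limitations

* Binary calls only; fractional methylation estimation is out of scope.
* Error rates are genome-wide (no context- or strand-specific p₀/p₁) and
  ε is not separately identifiable from count data.
* The local prior assumes exchangeable neighbors within the window; no
  adaptive per-site bandwidth, no strand-resolved smoothing.
* Hemimethylation and per-read quality are not modeled.
* The spatial correlation curve is a diagnostic; the window-based
  significance test of spatial correlation from the original supplement is
  not reproduced.
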
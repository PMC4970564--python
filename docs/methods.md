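# Methods

## Model

An experiment reports n subjects and a list of foci (peak coordinates, mm).
Each focus is treated as a noisy observation of a true activation site; the
spatial uncertainty has a between-template component and a between-subject
component that averages out with sample size:

    FWHM_total² = FWHM_template² + FWHM_subject² / n
    σ = FWHM_total / (2·√(2·ln 2))

Defaults are FWHM_template = 5.7 mm and FWHM_subject = 11.6 mm, the
empirical values standard in the ALE literature; both are configurable
(`fwhm_template_mm`, `fwhm_subject_mm`).  σ is therefore bounded below by
the template term (≈2.42 mm by default) no matter how large a study is.

Two kernel normalizations exist because the formula usually printed for the
Gaussian probability function, P = e^(−d²/2σ²)/((2π)^0.5·σ), is
dimensionally a 1-D density and does not integrate to 1 over a volume.
`printed_1d` reproduces that formula exactly; `gaussian_3d` (the default)
uses the true 3-D density e^(−d²/2σ²)/((2π)^(3/2)·σ³).  Kernels are
truncated at 3σ (configurable) for bounded support.

A voxel's activation probability under one focus is density × voxel volume,
capped at 1.  Within an experiment, foci combine voxelwise by maximum
(default — several peaks reported around one site count once) or by
probabilistic union; across experiments the ALE score is the union
1 − ∏(1 − MA).  The union is associative and order-invariant, and adding an
experiment can only raise a voxel's ALE.

## Null distribution and thresholding

The null hypothesis is "no biological activity": every experiment keeps its
foci count and subject count, but focus positions are independent uniform
draws over in-mask voxel centers.  The null ALE distribution is pooled over
voxels and iterations (one histogram, not per-voxel), which presumes
spatial stationarity under uniform relocation.

Two constructions are provided and cross-checked:

* `monte_carlo` — literal simulation (default 1000 iterations, seeded); the
  pooled sample is retained so p-values equal direct counting exactly.
* `analytic_histogram` (default) — the same distribution without sampling.
  For a single focus, the pooled distribution of its per-voxel probability
  follows exactly from the number of in-mask (voxel, focus) pairs realizing
  each integer offset, i.e. the mask autocorrelation.  Within an
  experiment, the maximum over f foci is a CDF power (the foci are
  conditionally i.i.d. given the voxel); the union rule is an f-fold
  self-convolution.  Across experiments, 1 − ∏(1 − MAᵢ) becomes an ordinary
  sum in L = −log(1 − ALE), computed by FFT convolution on a uniform L grid
  (2¹⁶ bins by default; point masses are deposited on the grid by the lever
  rule, preserving means).

  Voxels near the mask boundary see truncated kernels, so the pooled
  distribution is really a mixture over voxel neighborhoods.  A homogeneous
  convolution misstates the tail (≈1.3% on 90–99th percentiles against
  Monte-Carlo on a 20³ 2-mm box, enough to miscalibrate p-values by ≈4%
  relative).  The builder therefore stratifies in-mask voxels by their
  in-mask neighbor count within the largest kernel box (16 strata by
  default), convolves per stratum on a common L grid, and mixes by stratum
  size.  This brings tail-quantile agreement with Monte-Carlo to ≈0.2–0.4%
  and the pooled p < 0.05 rate under a true uniform null to 0.050.

p-values are right-tail and inclusive, p = P(null ≥ observed), floored at
the smallest representable tail mass (1/sample-size for Monte-Carlo).
Thresholding applies Benjamini–Hochberg FDR (step-up over in-mask voxels,
q = 0.05 by default, via statsmodels) first, then removes connected
components (26-connectivity by default) smaller than 100 mm³; survival is
inclusive (≥).  Cluster peaks break ties toward the lexicographically
smallest voxel index; weighted centers are ALE-weighted mean coordinates.

A consequence of exact-null discreteness worth knowing: when observed foci
sit exactly on voxel centers (as the synthetic null corpora do by design),
observed ALE values coincide with null atoms and inclusive p-values are
conservative by up to one atom gap.  At α = 0.05 the effect is negligible
(pooled rate 0.0500); deeper in the tail it grows (≈5–8% relative at
α = 0.01).  Real foci have continuous coordinates and do not tie.

## Networks, seeds and MACM

Thresholded condition maps are summed voxelwise into an overlap count; the
construct network keeps voxels present in ≥ k of n conditions (default
k = 2 — an explicit, configurable definitional choice).  Intersection with
the target network gives seed voxels, whose connected components are
labeled in decreasing size order; component centers are weighted by the
mean condition ALE (uniform where it vanishes).  Anatomical names are
user-supplied metadata, not computed — atlas lookup is out of scope.

MACM selects every experiment with at least one focus inside the seed
(literal membership, nearest voxel) and re-runs ALE on the sub-corpus.  A
configurable seed dilation (default 0 mm) exists for sparse-foci corpora
where the seed is only a few voxels.

## The synthetic generator

`SynthSpec` emulates one database search per condition: each experiment
expresses each of its condition's true centers independently with
probability `expression_prob`, displaces expressed centers by isotropic
Gaussian jitter parameterized as FWHM (one spatial vocabulary with the
kernels), appends `n_noise_foci` uniform draws over in-mask voxel centers —
exactly the null model of the significance test, so calibration simulations
are a true null — and draws subject counts uniformly from a range.
Coactivation structure arises because experiments co-express their
condition's centers, which is what MACM detects.  Everything is
deterministic given the spec's seed, down to the Sleuth bytes.

What it does not emulate: anatomical priors (boxes, not brains), reporting
bias, correlated noise foci, non-Gaussian jitter, or per-study smoothing
beyond the subject-count-driven σ.  Passing benchmarks therefore
establishes the statistical machinery, not performance on any particular
literature.

## Benchmarks

`benchmark.null_calibration_study`: 60 corpora of 20 experiments × 8
uniform foci on a 20³ 2-mm box, subject counts 15–30 (kernels near the
5.7 mm template floor, keeping suprathreshold events spatially compact so
the binomial band is a fair yardstick for the pooled exceedance rate).
Under this global null every discovery is false, so the realized FDP per
corpus is the rejection indicator; its mean estimates the FDR with
binomial noise and is checked against q with a one-sided 99% allowance
(the measured rate is ≈0.0475).

`benchmark.planted_network_study`: four constructs × three centers plus a
target condition on a 24³ 4-mm box (96 mm cube; centers ≥ 24 mm apart and
≥ 20 mm from the faces), 40 experiments/condition, expression probability
0.7, 10 mm jitter FWHM, 2 noise foci; one center is shared by two
constructs and the target, so it alone should survive the 2-of-4
conjunction intersected with the target network.  MACM runs with seed
dilation equal to the jitter FWHM (10 mm): the conjunction seed is only a
few voxels wide while co-expressing experiments scatter their shared-center
focus at that scale, and selection should tolerate the same displacement
the generator applies.  Scored over 20 replicates: seed-set hit rate within
10 mm of the shared center, and the fraction of co-expressed centers
(the other centers of the sharing conditions) recovered by MACM clusters
under optimal one-to-one matching at 10 mm.

## Numerical and design choices

* Grids are diagonal-affine only (template space); mm↔voxel transforms are
  exact inverses on voxel centers; reference-space conversion is out of
  scope (space labels are opaque).
* The Sleuth dialect is accepted liberally: any `// key=value` comment is
  metadata, other comments name the experiment; floats are written with
  `repr` so round-trips are bit-exact.
* FDR-then-extent ordering; both steps inclusive; all tie-breaks
  deterministic, so repeated runs are bitwise identical given a seed.
* Recovery matching uses optimal assignment (radius-capped costs) rather
  than greedy nearest-first, so it equals the brute-force optimum on small
  instances by construction.
* Problem sizes in tests and the acceptance script (16³–24³ boxes, 20–60
  corpora, 20 replicates) were chosen to make every experiment rerunnable
  in seconds to a minute on one CPU.

## Limitations

No between-group contrast ALE, no cluster-level FWE or TFCE, no
effective-connectivity modeling, no surface data, no atlas labeling.  The
analytic null's within-experiment CDF power and across-experiment
convolution treat per-voxel kernel values as independent across foci given
the stratum; the residual error against full Monte-Carlo is ≈0.2–0.4% on
tail quantiles at the stratification default.
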
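# alekit

Coordinate-based meta-analysis of neuroimaging foci: activation likelihood
estimation (ALE), conjunction networks across constructs, and meta-analytic
connectivity modeling (MACM).

## The problem

Most published functional-neuroimaging results are reported only as peak
activation coordinates (foci, in template-space mm) with a subject count.
Coordinate-based meta-analysis asks where such foci *converge* across many
independent experiments.  `alekit` implements the full chain used to map a
psychological construct onto a brain network and then ask what else that
network coactivates with:

1. **ALE.** Each focus is modeled as a 3-D Gaussian probability
   distribution centered on the reported coordinate, with

   FWHM² = FWHM²_template + FWHM²_subject / n,   σ = FWHM / (2√(2 ln 2)),

   so larger studies get tighter kernels (defaults 5.7 mm and 11.6 mm).
   The per-experiment modeled-activation (MA) map combines foci voxelwise,
   and the ALE score is the probabilistic union across experiments,
   ALE = 1 − ∏ᵢ(1 − MAᵢ).
2. **Significance.** ALE scores are compared with the null distribution of
   "no biological activity": the same experiments with every focus
   relocated uniformly at random inside the brain mask.  The null is
   available as a literal Monte-Carlo simulation or as an exact
   histogram convolution (stratified by mask-edge proximity); voxelwise
   right-tail p-values are corrected by Benjamini–Hochberg FDR (q = 0.05)
   and surviving components smaller than 100 mm³ are discarded.
3. **Conjunction networks.** Thresholded maps of n construct conditions
   (e.g. emotion, pain, reward, fear) are overlap-counted; voxels present
   in at least k of n (default 2 of 4) form the construct network.
4. **Seeds and MACM.** Intersecting the construct network with a target
   network (e.g. depression) yields seed regions.  Every experiment with a
   focus inside a seed is selected and meta-analyzed again: the clusters of
   that sub-corpus are the seed's coactivation network — regions inferred
   to be functionally connected to it.

Because real literature databases are proprietary and query-only, the
package ships a synthetic corpus generator that plants condition networks
(true centers, expression probability, between-study spatial jitter,
uniform noise foci) and scores how well the pipeline recovers them.

## Worked example

Simulate one "pain" literature of 40 experiments with two true centers
(expressed with probability 0.7, 10 mm FWHM between-study jitter, 2 uniform
noise foci per experiment) and meta-analyze it:

```python
import alekit as ak

grid = ak.make_box_mask((24, 24, 24), (4, 4, 4), (0, 0, 0))
spec = ak.SynthSpec(
    grid=grid,
    conditions=[ak.ConditionSpec("pain", [(44, 44, 44), (72, 20, 20)],
                                 expression_prob=0.7)],
    n_experiments_per_condition=40, jitter_fwhm_mm=10.0, n_noise_foci=2,
    n_subjects_range=(10, 30), rng_seed=7,
)
corpus, truth = ak.generate_corpus(spec)

est = ak.ALE(fdr_q=0.05, min_cluster_mm3=100).fit(corpus, grid)
print(est.result_.clusters_table().round(3).to_string(index=False))

report = ak.evaluate_recovery(est.clusters_, truth.centers_of("pain"),
                              match_radius_mm=10)
print(f"sensitivity={report.sensitivity:.2f}  "
      f"false_positives={report.n_false_positives}")
```

Output:

```
 label  n_voxels  size_mm3  peak_x  peak_y  peak_z  center_x  center_y  center_z  peak_ale
     1        31    1984.0    44.0    40.0    44.0    43.004    42.318    43.317     0.721
     2        27    1728.0    76.0    16.0    20.0    72.921    19.047    18.873     0.625
sensitivity=1.00  false_positives=0
```

Both surviving clusters peak within one voxel of a planted center; the
peak ALE of ~0.72 says that, at that voxel, the modeled probability that
at least one experiment in the corpus activates it is 72%.

The same chain is scriptable from the shell — `alekit simulate` writes a
Sleuth-format corpus, `alekit ale` thresholds one corpus, and `alekit run
--config pipeline.yaml` drives the full per-group pipeline (per-condition
ALE → 2-of-4 conjunction → target intersection → seed labeling → MACM →
two-group overlay), writing NIfTI maps, TSV cluster/seed tables and a
run manifest.

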
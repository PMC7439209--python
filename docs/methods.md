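# Methods

This note records the modelling and numerical decisions behind hemimorph:
what the pipeline computes, what the synthetic data generator does and does
not emulate, and where the design was genuinely open.

## Network construction

**Shared density mesh.** The Jensen–Shannon divergence integrates both
distributions against their pointwise mixture, so *p* and *q* must share a
support.  All subregion densities of a subject are therefore evaluated on one
27-point mesh spanning the subject's pooled thickness range padded by three
bandwidths.  On a uniform mesh the quadrature weights cancel in the
divergence's ratios, so densities are treated as discrete distributions
(masses summing to 1) and the divergence as a plain sum; this makes
JSS(p, p) = 1 exact rather than approximate.

**Kernel and bandwidth.** The kernel is Gaussian.  The default bandwidth
follows Silverman's rule, `0.9 · min(sd, IQR/1.34) · n^(-1/5)`, with the
*scale* taken from the subject's pooled thickness and the *sample-size
factor* from the median subregion vertex count — densities are estimated per
subregion, so that is the relevant n.  A fixed bandwidth in mm can be set in
`DensityConfig` instead; the value used is recorded in the run manifest.

**Probability floor.** Masses are floored at 1e-12 before renormalisation so
the logarithms in the divergence stay finite; the divergence of
near-disjoint distributions then approaches ln 2 smoothly.

**Logarithm base.** Natural log.  Consequently JSS = exp(−JSD) lies in
[exp(−ln 2), 1] = [0.5, 1]; the similarity scale's lower bound is 0.5, not 0.

**Binarization.** At sparsity K the ⌊K·N(N−1)/2⌋ strongest edges are kept.
One descending-weight edge ordering (ties broken by node-index pairs, which
matters only on measure-zero events but makes tests exactly reproducible)
serves every level, so edge sets are nested in K by construction.
Inter-hemispheric edges are never computed; the two hemispheric networks of
a subject are separate graphs.

## Graph metrics

The characteristic path length is the *harmonic* mean of pairwise shortest
path lengths; this keeps it finite on disconnected graphs and makes
L_p · E_global = 1 an exact algebraic identity, which the test suite asserts
on every computed network.  Unreachable pairs contribute 0 to all
inverse-distance sums (the standard efficiency convention).  Nodal
efficiency is the mean inverse distance from a node to all others (its mean
over nodes equals global efficiency); local efficiency of a node is the
global efficiency of its neighbour-induced subgraph, 0 for degree < 2.

Normalisation uses degree-preserving double-edge-swap (Maslov–Sneppen)
surrogates: `swaps_per_edge × E` attempted swaps per surrogate (default 10),
100 surrogates by default (`RandomizationConfig.n_random`), reducible to 10
for desk-scale runs.  Surrogates are not forced connected — the harmonic
path length is finite regardless.  Shortest paths are computed by
breadth-first expansion expressed as boolean matrix products (exact for
unweighted graphs); local efficiency uses a bitset breadth-first kernel
compiled with numba, with a pure-numpy fallback, both verified against
independent brute-force oracles.

## Statistics

With a two-level within factor, the repeated-measures ANOVA decomposes
exactly: the subject mean (L+R)/2 regressed on gender + age carries the
gender effect; the difference L−R regressed on gender + age carries the
hemisphere effect (intercept, with gender effect-coded ±½ and age centred)
and the interaction (gender term).  Each F is the square of the
corresponding t; sphericity is trivially satisfied, so no correction is
applied.  Age enters linearly, mean-centred.  Two-sample t-tests pool
variances by default (Welch optional).  FDR families are the homologous
region pairs, applied separately per local metric and per test type;
global-metric tests are reported at uncorrected p.

## The synthetic cohort generator

The generator emulates surface-pipeline output at the *tabular* level —
labeled spherical vertex clouds with per-vertex thickness — not MRI or mesh
topology.  Per subject, thickness is

```
thickness(v) = mu(region(v)) + field(v) + eps(v)
```

* `mu`: one mean per anatomical region, uniform on 1.5–4.5 mm, drawn once
  per anatomy and shared by both hemispheres and all subjects.  Splitting
  the seed into `anatomy_seed` and `seed` mirrors how repeated studies
  sample new participants on one underlying cortex.
* `field`: a smooth random field on the sphere, built from real spherical
  harmonics up to degree ⌈1/ℓ⌉ (ℓ = `spatial_autocorrelation_length`,
  default 0.25 → degree 4) with i.i.d. normal coefficients, scaled so its
  pointwise SD is `field_sd` (default 0.30 mm).  Drawn independently per
  subject *and hemisphere*: the within-subject L/R differences it creates
  are what gives asymmetry indexes their subject-level variance.
* `eps`: i.i.d. vertex noise whose SD is drawn per region from
  `within_region_sd` (default the interval 0.15–0.50 mm).  Regional
  heterogeneity of spread is deliberate: regions with broad thickness
  distributions overlap many others, act as similarity hubs and shorten
  network paths, while regions with similar means form tightly clustered
  neighbourhoods.  Both features are needed for the generated networks to
  sit in the economical small-world regime that real cortical thickness
  networks occupy; with homogeneous spreads the similarity graph degenerates
  into a one-dimensional proximity lattice with σ ≈ 1.

Thickness is floored at 0.1 mm for physical plausibility.  Region partitions
come from nearest-of-k farthest-point seeds on the sphere — contiguous,
anatomically-boundary-like, but not a real atlas.  Homologous regions are
geometrically identical in the two hemispheres by construction, so with no
injected effects the left and right distributions of every region are
exchangeable and every downstream asymmetry index is symmetric about zero
(verified by sign-balance tests).

What the generator does **not** emulate: cortical folding and geodesic
geometry, mesh topology, multimodal gyral/sulcal thickness distributions,
spatial covariance between hemispheres, family structure (each subject gets
a unique family id; the dedup filter is exercised by its own tests), and any
empirical left–right biases of the human cortex.  Passing tests therefore
show that the *pipeline* behaves correctly and that its statistics are
calibrated and powered under a realistic covariance structure — not that any
particular real-data asymmetry would be reproduced.

**Injected effects.** An `EffectSpec` shifts the mean (`dmean`, mm) and/or
scales the subject-level variation (`sd_scale`) of one (region, hemisphere,
gender) cell.  The documented recovery effect inflates the right TPOmid
spread ×3 and shifts it +0.4 mm in females; both changes depress that node's
similarity to every other region, lowering its right-hemisphere degree and
inducing a leftward (positive) degree AI in females only.  Effect strength
is monotone in the injected magnitude (tested at three levels).

## Default sizes and scaling choices

* `vertices_per_region` defaults to 600 (≈ 23 400 vertices per hemisphere),
  giving mean subregion sizes of ≈ 91 vertices — the same order as real
  surface data at this parcellation and comfortably above the 30-vertex
  floor below which 27-point density estimates degrade.  The cluster-count
  allocation errors out if a configuration would drop below that floor.
* The default study condition is 10 subjects per gender with 10 surrogates
  per normalisation (the small-world profile); the statistical-calibration
  simulations use 200 cohorts of 30 subjects and the recovery simulations 50
  cohorts of 40 per gender, both on reduced parcellations (6 or 12 regions
  per hemisphere, 24 or 48 nodes) — the calibration of a t-test battery and
  of FDR control does not depend on network size, and these scales keep the
  suite fast.
* k-means uses deterministic farthest-point seeding, one initialisation and
  a 100-iteration cap; subregion ids are hemisphere-major, then region
  (sorted by name), then cluster.

## Degenerate inputs and numerical edges

Constant thickness (no spread) is rejected when building the mesh; empty
samples are rejected by the estimator.  A sparsity level that would yield
zero edges raises.  AI is undefined (NaN, flagged) when M_L + M_R = 0.
Zero-variance t-test samples raise, except two equal constant groups in the
two-sample test, which return t = 0 by convention.  Singular ANOVA designs
(constant age, fewer than two subjects per gender) raise rather than
returning unstable F values.

## Limitations

The generator's realism is a modelling choice, not a constraint inherited
from real data; absolute metric values (e.g. the size of σ) depend on its
spread-heterogeneity and autocorrelation settings.  Only the two-level
within-subject design is supported by the ANOVA decomposition.  No weighted
graph metrics, alternative atlases, geodesic clustering, or KL-divergence
edge variants are implemented.
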
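# Methods

## Scales and conversions

A probe's β-value is `M_int / (M_int + U_int + α)` with channel
intensities `M_int` (methylated) and `U_int` (unmethylated) and a count
offset α = 100 that regularises low-intensity probes; the M-value is
`log2((M_int + α)/(U_int + α))` with α = 1. Since the vast majority of
probes have intensities well above the offsets, the package relates the
two scales by the offset-free logit pair `M = log2(β/(1−β))`,
`β = 2^M/(2^M+1)`. β-values are clamped into `[ε, 1−ε]` with ε = 1e−6
before the log transform, so β ∈ {0, 1} maps to finite M (±~19.93) and
the pair is an exact inverse on the clamped domain. All matrices are
double precision; the scale of a matrix ("beta" or "m") is declared
explicitly and conversions refuse mismatched inputs. Statistical work
(mixture fitting, moderated t) happens on the M scale, which is
approximately homoscedastic across the methylation range; replicate SD
and absolute-difference metrics are reported on the β scale, where
effect sizes are bounded and comparable across probes.

## Mixture model and EM

Per sample and per probe type, M-values are modelled as a K-component
univariate Gaussian mixture (K = 3: hypomethylated U, hemimethylated H,
hypermethylated F). EM starts from μ = (−4, 0, 4), σ = (1, 1, 1) and
uniform weights — the natural state locations on the M scale — and is
deterministic given its start; no random restarts are used. Components
are reported sorted by mean.

Numerical choices:

- **Convergence.** Relative log-likelihood change below 1e−8, capped at
  500 iterations. A looser 1e−6 stops a 200k-point fit after ~8
  iterations with parameters still moving by ~2e−3, enough to break the
  documented insensitivity to ±0.5 perturbations of the starting means;
  at 1e−8 the fit converges in ~20 iterations (about one second) and
  perturbed starts agree to ~1e−5.
- **σ floor.** Component SDs are floored at 1e−4. Hitting the floor
  (possible on near-duplicate values) emits a warning rather than an
  error: the fit is still usable, merely degenerate.
- **K_I escalation.** When the fitted type I F component satisfies
  `μ_I^F − σ_I^F < μ_II^F − σ_II^F` (strict; equality keeps K = 3), the
  type I model is refit from scratch with K = 4 from
  μ = (−4, 0, 3, 6), which adds a far-right start so the new highest-mean
  component can sit right of the type II F component. Refit-from-scratch
  (rather than splitting an existing component) keeps the procedure a
  pure function of the data and the recorded K; the provenance stores
  both the 3- and 4-component fits. With K = 4 the two middle components
  are both treated as H, and the U/F parameters fed to the quantile map
  are those of the lowest- and highest-mean components, taken from the
  mixture fit (not re-estimated on the relabelled subsets).

## The normalization map

State assignment maximises the posterior `π_k N(x|μ_k, σ_k²)` — the
mixing proportions are part of the fitted model, so they weight the
decision; ties break to the lower-mean component. A value exactly at its
state's representative mean goes to the right half. Posterior argmax
regions can in principle be non-contiguous when component SDs differ;
values are used as assigned, and the provenance records a diagnostic
count of order inversions of the assigned component along the sorted
sample (zero in all simulated conditions exercised here).

The outer halves `U_IIL` and `F_IIR` are quantile-mapped through the
fitted Gaussians. The CDF/inverse-CDF composition is evaluated through
the lower tail for values below the source mean and through the survival
function above it, with tail probabilities clamped at 1e−15; inside the
unclamped region the composition agrees with the exact affine form
`μ_dst + σ_dst (x − μ_src)/σ_src` to better than 1e−9 (the clamp only
engages beyond ~7.9 source SDs).

The middle set `G = U_IIR ∪ H_II ∪ F_IIL` is mapped affinely so that the
gaps to the quantile-mapped flanks are conserved exactly:
`minG′ = max(U_IIL′) + Δ_UG` and `maxG′ = min(F_IIR′) − Δ_GF` with
`Δ_UG = minG − max(U_IIL)`, `Δ_GF = min(F_IIR) − maxG`, and dilation
factor `df = (maxG′ − minG′)/(maxG − minG)`. Because the side split is
strict at the component means, both gaps are positive and the assembled
map is monotone: type II ranks are preserved within and across the three
pieces. A degenerate G spanning a single point maps to the midpoint of
the target interval with a warning. If any of `U_IIL`, `F_IIR`, `G` is
empty the sample fails loudly with the name of the empty set — on full
arrays with all three methylation states populated this does not occur,
and silently skipping the constraint would produce discontinuous output.

Matrix-level behaviour: columns are normalized independently (the model
is per array); missing cells are excluded from fitting and emitted as
missing; a column with fewer than 30 non-missing probes of either type
is passed through unnormalized and flagged rather than failing the whole
matrix. β input is converted to M on entry and back on exit, so output
scale matches input scale and back-converted values are strictly inside
(0, 1); type I rows are bit-identical to the input on the input's scale.

## Synthetic data

The generator draws, per probe, a latent methylation state from the
mixture weights and a standard-normal deviate shared between the two
design parameterizations, so the type II value is a component-wise
affine compression of the type-I-scale truth
(`m_II = μ_II[k] + (σ_II[k]/σ_I[k])(m_I − μ_I[k])`). Defaults are the
canonical conditions: weights (0.3, 0.3, 0.4), type I means (−4, 0, 4),
type II means (−2.6, 0, 2.6), unit SDs, 20k type I and 50k type II
probes. Setting `mix_II = mix_I` makes the compression the identity,
which is the basis of the self-map check. A smooth `c·tanh(x/c)`
compression matching the outer-mean target is available behind
`compression="sigmoid"`. Replicate columns share the latent truth within
a replicate group and differ by i.i.d. N(0, sd²) noise on the M scale
(default sd 0.3); spiked probes are shifted by a fixed effect in label-1
samples before the design compression.

What the generator does not emulate: per-sample distributional shifts
(dye/batch effects between replicates), spatially correlated chip
artefacts, detection-p chemistry, intensity-level noise, or the
beta-like skew of real per-state distributions. Consequences for
interpretation: passing the bias-reduction and self-map checks shows the
transform does what it claims on mixture-distributed data, not that it
removes every artefact of real arrays. In particular, because replicate
noise here is purely i.i.d., per-sample normalization has no shared
distributional drift to remove, while the conformal dilation (df ≈ 1.4–
1.5 under the default compression) necessarily amplifies mid-range noise
— so the median per-probe β SD across replicates falls after
normalization (outer-state probes dominate the median and move into the
flat tails of the logistic curve), but the mean absolute β difference
between replicate pairs, dominated by mid-range probes, rises slightly
under these conditions. On real replicates, where much of the
between-array difference is a distributional shift that per-sample
fitting absorbs, both quantities are expected to fall; the simulation
isolates the noise-geometry component only.

## Differential methylation and QC

Two-group comparisons use a moderated t-statistic: per-probe pooled
within-group variances are shrunk toward a prior fitted across probes by
moment-matching a scaled-F model on log variances (prior df d0 via a
trigamma inversion), `s²_post = (d0·s0² + df·s²)/(d0 + df)`, with
`df + d0` total degrees of freedom. The implementation reproduces the
Bioconductor reference implementation of this shrinkage to machine
precision on shared input (see the test suite). q-values are
Benjamini–Hochberg; the DMP set is `{q < 0.35}` by default, matching the
threshold used in the published comparison this package's metrics mirror.
Probes constant across all samples have no defined statistic and are
reported NA and never called. Testing defaults to M-values; a flag
switches to β. Validation of training DMPs on a test set counts probes
that are significant at the same FDR with concordant effect sign
(configurable), and PPV = nTP/nDMP is reported at full precision and
rounded half-up to two decimals as count tables print it.

Sample QC: a probe is bad in a sample when its detection p-value is
strictly above τ_p; a sample is dropped when its bad fraction is strictly
above τ_r (τ_r ≤ 0.3 — a sample with more than 30% bad probes is not
worth normalizing). Both boundaries are strict because the verbal
definitions ("more than") leave equality inside the kept set.

## Problem sizes

Simulated checks run at 20k type I + 50k type II probes per sample
(roughly a seventh of a real array, preserving the 1:2.6 type ratio),
200k draws for EM recovery, and 5k probes across 20 seeds for the null
FDR study — sizes at which every Monte-Carlo margin in the checks is
comfortably resolved. Larger inputs only tighten the estimates.

## Known limitations

- The method assumes all three methylation states are populated in both
  probe types; samples violating this (e.g. severely degraded arrays)
  fail per sample rather than being force-normalized.
- The conformal dilation amplifies measurement noise for mid-range
  probes by the factor df; this is inherent to restoring the type I
  dynamic range, not an implementation artefact.
- Only two-group designs are supported in the DMP module; covariates and
  paired designs are out of scope.
- EPIC (850K) arrays, IDAT parsing, intensity-level preprocessing and
  batch correction are out of scope.
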
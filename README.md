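# mgmin

Gaussian-mixture normalization of the type II probe design bias on
Illumina Infinium HumanMethylation450 (450K) arrays.

## The problem

The 450K array measures DNA methylation at ~485k CpG sites with two probe
chemistries. Type I and type II probes report the same underlying quantity
— a β-value in [0, 1], or equivalently an M-value
`M = log2(β / (1 − β))` — but type II probes show a compressed dynamic
range: their hypo- and hypermethylated peaks sit closer to zero on the M
scale than the type I peaks. Left uncorrected, this design bias inflates
technical variation and distorts any analysis that pools the two probe
types, including differential-methylation scans in EWAS.

## The method

Per sample, the M-values of each probe type are modelled as a
three-component Gaussian mixture over methylation states
(U = hypomethylated, H = hemimethylated, F = hypermethylated):

    p(M_i; θ) = Σ_k π_k · N(M_i | μ_k, σ_k²),   k ∈ {U, H, F}

fitted by EM from the canonical starting values μ = (−4, 0, 4),
σ = (1, 1, 1). Each type II probe is assigned to a state by maximum
posterior probability, and the U and F states are split at their
component means into left/right halves. Then:

1. **Quantile mapping of the outer tails.** A probe in `U_IIL` (left of
   the U mean) at value *x* has tail probability
   `p = Φ((x − μ_II^U)/σ_II^U)` and is sent to
   `q = Φ⁻¹(p; μ_I^U, σ_I^U)`, the value with the same quantile under the
   type I U component; `F_IIR` is mapped likewise with the F parameters.
   For Gaussian source and target this is exactly the affine map
   `q = μ_dst + σ_dst (x − μ_src)/σ_src`.
2. **Conformal (shift + dilation) transform of the middle.** The
   remaining probes `G = U_IIR ∪ H_II ∪ F_IIL` are mapped by
   `x ↦ minG′ + df · (x − minG)` with dilation factor
   `df = (maxG′ − minG′)/(maxG − minG)`, where the new endpoints conserve
   the observed gaps between G and the quantile-mapped flanks — keeping
   the normalized type II values continuous and rank-preserving.

Type I probes are never altered. If the fitted type I hypermethylated
component sits too far left (`μ_I^F − σ_I^F < μ_II^F − σ_II^F`), the type
I model is automatically refit with four components so the mapping target
lies right of the type II component. β input is converted to M on entry
and back on exit.

The package also ships a synthetic 450K generator with known ground truth
(mixture memberships, spiked group differences, replicate noise) and the
evaluation metrics used to judge normalization: replicate SD and mean
absolute β difference, Kolmogorov–Smirnov concordance between probe
types, deviation summaries against a gold standard, moderated-t
differential methylation with BH FDR, PPV = nTP/nDMP, and detection-p
sample QC.

## Worked example

```python
import numpy as np
from mgmin import (SimulationSpec, simulate_array, normalize_matrix,
                   distribution_distance)

spec = SimulationSpec(n_typeI=20_000, n_typeII=50_000, n_samples=1,
                      replicate_noise_sd=0.0, seed=7)
matrix, _ = simulate_array(spec)          # M-scale, type II compressed
res = normalize_matrix(matrix)

prov = res.provenance["s01"]
print("K_I =", prov.k_type1)
print("type II fit means:", np.round(prov.fit_II.means, 3))
print("type I  fit means:", np.round(prov.fit_I.means, 3))
print("dilation factor df = %.3f" % prov.conformal.df)

m1 = matrix.type_mask("I")
I   = matrix.values.to_numpy()[m1, 0]
II  = matrix.values.to_numpy()[~m1, 0]
IIn = res.matrix.values.to_numpy()[~m1, 0]
print("KS raw        = %.3f" % distribution_distance(I, II))
print("KS normalized = %.3f" % distribution_distance(I, IIn))
```

Output:

```
K_I = 3
type II fit means: [-2.712 -0.055  2.649]
type I  fit means: [-4.008  0.017  4.004]
dilation factor df = 1.494
KS raw        = 0.211
KS normalized = 0.043
```

The fits recover the simulated bias (type II outer states at ±2.6 against
type I ±4), the middle range is dilated by ~1.5× to restore the type I
span, and the distribution mismatch between probe types (KS statistic)
drops from 0.211 to 0.043.

The same pipeline is available from the shell:

```sh
mgmin simulate --output-prefix demo --seed 7
mgmin normalize --input demo_matrix.tsv --annotation demo_annotation.tsv \
                --scale m --output demo_norm.tsv --provenance demo_prov.json
mgmin evaluate --metric ks --input demo_norm.tsv \
               --annotation demo_annotation.tsv --scale m
```

## Layout

- `src/mgmin/values.py` — β/M/intensity conversions with offsets and clamps
- `src/mgmin/gmm.py` — per-sample EM mixture fits, K_I escalation rule
- `src/mgmin/normalize.py` — state assignment, quantile map, conformal transform
- `src/mgmin/synthetic.py` — ground-truth 450K simulator
- `src/mgmin/evaluate.py` — replicate/concordance/DMP/QC metrics
- `src/mgmin/io.py` — TSV/CSV matrices, annotations, Illumina manifests
- `src/mgmin/cli.py` — the `mgmin` command
- `docs/methods.md` — model details, parameter choices, limitations
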
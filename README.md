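# fractamorph

Reusable pipeline linking brain morpho-structural features to cognitive
and balance outcomes:

- **`fractamorph.fd`** — 3-D box-counting fractal dimension of binary
  voxel structures, for three structural features per ROI: the general
  structure, its 6-connectivity boundary surface, and a
  topology-preserving skeleton. The dimension is the OLS slope of
  `ln N(r)` on `ln(1/r)`.
- **`fractamorph.fa`** — ROI-mean fractional anisotropy from a scalar FA
  map and an integer label atlas sharing one voxel grid (no resampling).
- **`fractamorph.behavior`** — center-of-pressure (COP) path-length
  statistic from force-platform trials (epoch → 10 Hz zero-phase low-pass
  → linear detrend → trial average → cumulative |Δ| over 2 s) and
  per-measure group comparisons (Welch t-test, pooled-SD standardized
  mean difference).
- **`fractamorph.plsc`** — behavioral partial least squares correlation:
  SVD of the z-scored cross-block covariance `R = Yᵀ X`, permutation
  p-values per latent component (add-one estimator, Y-row shuffling),
  bootstrap stability ratios (|BSR| ≥ 2 ⇒ stable), composite scores and
  loadings.
- **`fractamorph.synthetic`** — every input needed to exercise the
  pipeline without real data: fractal phantoms of known dimension (Menger
  sponge, cubes, sheets, rods), rank-1 latent-variable cohorts
  (18 subjects, 8 HC / 10 TBI, 34 imaging features, 5 behavioral
  measures by default), sinusoid-perturbation COP traces, and paired
  atlas / scalar-map volumes.
- **`fractamorph.pipeline` / CLI** — orchestration from one YAML config
  with a versioned JSON report; reruns with the same seed are
  byte-identical.

## CLI

```sh
fractamorph demo --out demo --seed 1        # write synthetic inputs + config
fractamorph run --config demo/config.yaml   # full pipeline -> demo/results/
fractamorph fd --masks-dir demo/masks --out fd.tsv
fractamorph fa --atlas demo/atlas.nii --map demo/fa_map.nii \
    --labels demo/labels.yaml --out fa.tsv
fractamorph behavior --cohort demo/cohort.csv --cop-dir demo/cop_trials \
    --out behavior.tsv
fractamorph plsc --cohort demo/cohort.csv --n-perm 1000 --n-boot 500 \
    --seed 1 --out plsc.json
```

## Notes

- The t-test is the Welch variant (Satterthwaite df); it reproduces the
  published SCWT p-value where the pooled-variance variant does not.
- Box-count grids are corner-anchored by default for determinism; an
  eight-offset minimum policy is available to reduce quantization bias.
- All randomness flows from a single integer seed via independent child
  streams.
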
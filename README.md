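# scampi

Statistical classification of membrane-protein fluorescence microscopy images
(e.g. TIRF frames of T-cell receptor clusters) from pixel statistics alone.

The pipeline has three stages:

1. **Spatial-lag image model** (`scampi.image_model`) — each image is treated
   as a two-dimensional autoregressive field: every interior pixel is
   regressed on the image shifted by small integer offsets (one spatial lag
   gives three regressors: left, upper, and diagonal neighbours). The model
   is estimated per image by OLS without intercept; parameter significance
   uses Student-t tests with the White (HC0) heteroskedasticity-robust
   covariance, and lag order is selected by a forward significance search.
2. **Fisher linear discriminant** (`scampi.discriminate`) — per-image
   coefficient vectors from two classes are projected onto the direction
   maximising between-class over within-class scatter; a midpoint (or
   Gaussian-likelihood) threshold classifies test images.
3. **Logistic class probabilities** (`scampi.probability`) — a binary
   logistic regression on the scalar projections maps each image to a
   probability of class membership.

Supporting modules: `scampi.baselines` (threshold spreading area, lognormal
signal summaries, KS normality, a symmetric-KL two-sample statistic),
`scampi.simulate` (exact forward recursion of the lag model plus a cell-like
scene generator, both fully seeded), and `scampi.io` / `scampi.cli`
(TIFF loading, train/test splits, reports).

## CLI

```bash
# fit the lag model for every TIFF in a folder
scampi fit-models --input images/OKT3 --out fits/

# full two-class pipeline: fit, 80/20 split, FLD, classify, probabilities
scampi discriminate --class-a images/PLL --class-b images/OKT3 \
    --train 80 --seed 7 --out report/

# refit logistic probabilities from a previous run's projections
scampi probabilities --run report/

# generate a labelled synthetic two-class image set
scampi simulate --spec sim_spec.json --n 100 --out simdata/ --seed 3

# per-image baseline statistics
scampi baselines --input images/OKT3 --spread-threshold 1200
```

`discriminate` writes `fits.csv`, `projections.csv`, `probabilities.csv`,
`baselines.csv`, `fld_model.json`, `logistic_model.json`, and `run.json`
(config echo, recorded split, confusion counts, timings). Identical config
and seed reproduce the CSVs byte for byte.

A simulation spec JSON has keys `class_a` / `class_b`, each either
`{"kind": "lag", "shape": [256, 256], "beta": [0.64, 0.67, -0.34],
"innovation_sd": 5.0}` or `{"kind": "scene", "n_clusters": 40, ...}`.

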
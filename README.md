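# cytofp

Cytometric fingerprinting of microbial communities.

`cytofp` turns flow-cytometry event data into per-sample community
fingerprints and diversity estimates:

1. **Preprocessing** — asinh intensity transform and a fixed 2-D polygon
   gate separating cells from debris.
2. **Fingerprint templates** — either an overclustered K-component Gaussian
   mixture fitted by EM to the pooled training events (cells are assigned to
   the component with the highest posterior), or a fixed L×L binning grid on
   every bivariate channel combination (the classic binning comparator).
   Both yield a samples × components table of relative cell counts.
3. **Diversity** — Hill numbers D0/D1/D2 (richness, exponential Shannon,
   inverse Simpson) per sample, Bray-Curtis dissimilarities between samples,
   and a permutation Mantel test between distance matrices.
4. **Supervised layer** — Random Forest regression from fingerprints to
   diversity values with a randomized hyperparameter search
   (max features ∈ {1..K}, min leaf ∈ {1..5}, k-fold CV).
5. **In-silico benchmark** — synthetic strain event clouds with tunable
   overlap, Dirichlet community compositions over 2–20 strains, exact
   largest-remainder community assembly, and scoring of the estimates
   against the known ground truth (tie-aware Kendall τ_B, R², Mantel).

Everything runs from synthetic data; no downloads are required.

## CLI

```sh
# fingerprint real or synthetic acquisitions listed in a manifest CSV
# (columns: path, sample_id, replicate_id; CSV or FCS 3.0/3.1 event files)
cytofp fingerprint manifest.csv --config run.yaml --out-dir out/

# generate a synthetic strain pool + Dirichlet community compositions
cytofp simulate --n-strains 20 --n-communities 400 --a 1.0 --out-dir sim/

# full in-silico benchmark (defaults: 300/100 train/test, K=128, 10 runs,
# a in {0.1, 1, 10})
cytofp benchmark --n-runs 10 --out results.csv

# one-at-a-time parameter sweep (sweep section in the YAML config)
cytofp sweep run.yaml --out sweep.csv

# score saved estimates against saved truth
cytofp evaluate --true true.csv --estimated est.csv
```

A run config is a YAML file; every key is optional:

```yaml
channels: [FSC-H, SSC-H, FL1-H]
method: gmm          # or grid
K: 128
covariance_type: full  # diag | full | spherical | tied
L: 128
n_cells_min: 1000    # per file into the template training pool
n_cells_rep: null    # per replicate for fingerprinting (null = lowest)
gate_file: gate.yaml # polygon gate in transformed coordinates
seed: 0
sweep: {K: [8, 32, 128]}
```

## Layout

| module | contents |
| --- | --- |
| `cytofp.events` | `EventMatrix`, `ExperimentSet`, CSV/FCS reading, subsampling, training concatenation |
| `cytofp.preprocessing` | asinh transform, polygon `Gate`, gating |
| `cytofp.gmm` | `GMMTemplate`, EM fitting, cell assignment, fingerprints |
| `cytofp.grid` | `GridTemplate`, grid construction, histogram fingerprints |
| `cytofp.diversity` | Hill numbers, Bray-Curtis, dissimilarity matrices |
| `cytofp.evaluation` | Kendall τ_B, R², Mantel test, Lorenz curves, BH-corrected correlation screen |
| `cytofp.insilico` | Dirichlet compositions, community assembly, true diversity |
| `cytofp.synthetic` | seeded strain-cloud generator with tunable overlap |
| `cytofp.predict` | Random Forest diversity regression with randomized search |
| `cytofp.benchmark` | end-to-end benchmark and parameter sweeps |
| `cytofp.cli` / `cytofp.config` | command-line surface and YAML config |
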
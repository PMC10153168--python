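# Methods

This note records the model, the conventions, and the numerical choices
implemented by `fcbench`, in enough detail to re-derive every quantity the
package computes.

## 1. Confound retrieval

### Input dialect

A scan is addressed by its preprocessed BOLD image path; the confounds table
is the sibling `*_desc-confounds_timeseries.tsv` (tab-separated, missing
values written `n/a`), with an optional JSON sidecar of the same stem
describing CompCor components (`Mask`, `CumulativeVarianceExplained`).
Recognized column families:

- motion: `trans_{x,y,z}`, `rot_{x,y,z}` plus `*_derivative1`, `*_power2`,
  `*_derivative1_power2` expansions (rotations in radians);
- tissue: `csf`, `white_matter`, `global_signal`, same expansions;
- `framewise_displacement`, `std_dvars` (undefined at volume 0);
- `cosine00…` discrete-cosine drift terms;
- `a_comp_cor_NN` anatomical CompCor components;
- `aroma_motion_NN` ICA-AROMA motion components;
- `non_steady_state_outlierNN` one-hot indicators.

Validation enforces: unique column names; all six motion bases present when
any is; derivative columns may be missing only at volume 0 (that single NaN
is imputed to 0 when the column is selected, since the scan starts at rest
by convention — note some other implementations back-fill instead).

### Parameter vocabulary

- `motion`, `wm_csf`, `global_signal` ∈ {`basic`, `derivatives`, `power2`,
  `full`}: k, 2k, 2k, or 4k columns per k base signals.
- `scrub` (minimum surviving segment length, volumes), `fd_threshold` (mm),
  `std_dvars_threshold`: censoring. A volume is censored when FD exceeds
  the threshold (strictly) **or** std-DVARS exceeds its threshold; a missing
  value never censors. After thresholding, maximal retained runs shorter
  than `scrub` volumes are censored. Non-steady-state volumes are always
  censored, in every strategy.
- `compcor` (`anat_combined`), `n_compcor`: either a fixed count of
  combined-mask components or `"all"` = the shortest prefix whose sidecar
  cumulative variance explained reaches 50 %.
- `ica_aroma`: `nonaggressive` selects zero columns but requires the
  `desc-smoothAROMAnonaggr_bold` image variant (the denoising already
  happened in image space); `aggressive` selects the `aroma_motion_*`
  columns against the ordinary `preproc` image.
- `high_pass` selects all cosine columns; `demean` subtracts from each
  selected regressor its mean **over retained volumes**, so censored-then-
  regressed analyses are centered on the data that is actually fit.

### Strategy registry

Ten named bundles; all use high-pass cosines and demeaning:

| strategy | motion | wm_csf | gsr | scrubbing | compcor | aroma image |
|---|---|---|---|---|---|---|
| baseline | — | — | — | — | — | preproc |
| simple | full | basic | — | — | — | preproc |
| simple+gsr | full | basic | basic | — | — | preproc |
| scrubbing.5 | full | full | — | FD > 0.5 mm, DVARS > 3, seg ≥ 5 | — | preproc |
| scrubbing.5+gsr | full | full | basic | as above | — | preproc |
| scrubbing.2 | full | full | — | FD > 0.2 mm, DVARS > 3, seg ≥ 5 | — | preproc |
| scrubbing.2+gsr | full | full | basic | as above | — | preproc |
| compcor | full | — | — | — | combined, 50 % | preproc |
| compcor6 | full | — | — | — | combined, 6 | preproc |
| aroma | — | basic | — | — | — | smoothAROMAnonaggr |

`simple` therefore selects 24 motion + 2 tissue = 26 regressors beyond the
cosines; `simple+gsr` adds the global signal for 27.

## 2. Signal processing

- **Extraction.** Discrete-label atlases: mean over member voxels per
  volume. Probabilistic maps: per-volume least squares of the stacked maps
  on the voxel vector (handles overlap). Image and atlas must share grid
  and affine; no resampling is performed.
- **Cleaning.** Censoring happens *first*; the confound matrix and the
  signals are restricted to retained volumes, then each parcel series is
  replaced by its OLS residual against `[1, confounds]`. An intercept is
  always included; `demean=False` adds the fitted mean back. An error is
  raised when regressors ≥ retained volumes.
- **Connectome.** Pearson correlation across retained volumes (≥ 3
  required); constant parcels yield NaN edges plus a warning. Edges are
  vectorized as the strictly-lower triangle in row-major order.
- **Geometry.** Parcel centers are voxel coordinates pushed through the
  affine and averaged (map-weighted for probabilistic atlases); distances
  are Euclidean in mm.

## 3. Motion and quality control

FD(t) = Σ|Δtranslations| + 50 mm × Σ|Δrotations|, FD(0) = 0. A subject is
excluded when any of: mean FD > 0.25 mm; more than 80 % of volumes censored
when scrubbing at 0.2 mm (segment rule included); less than one minute of
scan retained. QC runs before any metric and its exclusions apply to all
strategies, so every strategy is scored on the same cohort.

## 4. Metrics

- **DoF loss** = number of regressors + number of censored volumes,
  reported as a percentage of scan length.
- **QC-FC**: per edge, the partial Pearson correlation between subjects'
  mean FD and edge strength with age and sex as covariates: residualize
  both on `[1, age, sex]`, correlate the residuals, and test with the t
  transform on n − 2 − k degrees of freedom (two-sided). Summaries: the
  fraction of edges with p < 0.05 (optionally after Benjamini–Hochberg FDR
  via statsmodels) and the median |r|. Edges with missing values use
  pairwise deletion.
- **DM-FC** = |Pearson r| between inter-parcel distance and the per-edge
  QC-FC values.
- **Modularity**: signed Louvain with the asymmetric negative-weight
  scheme, Q\* = Q⁺ − s⁻/(s⁺+s⁻) Q⁻, where Q± are Newman modularity terms of
  the positive/negative parts and s± their total weights (reduces to
  Newman–Girvan when no edge is negative, as confirmed against networkx).
  100 restarts with seed-derived substreams; the maximum-Q partition is
  kept. The per-subject Q values are then partially correlated with mean
  FD (age, sex controlled).

Bootstrap confidence intervals (percentile, 2.5/97.5) resample subjects.

## 5. Synthetic cohort generator

Defaults: 50 subjects, 200 volumes at TR = 2 s, 64 cubic parcels tiling an
8×8×8 voxel grid at 3 mm, 4 planted modules.

- **Connectivity.** Parcel signals are Gaussian with correlation 0.3 within
  modules, 0 between (Cholesky factor of the block matrix).
- **Motion.** Per-subject target mean FD is log-normal (median 0.15 mm,
  log-σ 0.3). Translations/rotations follow a random walk whose step size
  is chosen so the expected drift FD matches the target
  (E|N(0,s)| = s·√(2/π), six equal channels). Spikes occur at rate 0.05
  per volume with magnitude U[0.25, 0.6] mm applied to one translation for
  a single volume, elevating FD at the spike and the return. The emitted
  FD column is recomputed from the emitted motion columns, so it is
  internally consistent by construction.
- **Contamination.** Six sources at random positions load onto parcels as
  exp(−d/8 mm), scaled by 4 × (subject mean FD). Each source's time course
  is spike-locked noise (SD 3 on spike-affected volumes, zero elsewhere).
  Contamination is therefore distance-dependent and motion-coupled, and is
  removed *exactly* by either censoring the spike volumes or regressing
  the true source time courses — which is what the benchmark measures.
- **Other signal.** Global signal (amplitude 0.5), cosine drift, voxel
  noise SD 0.5. The `global_signal` column is the realized voxel mean of
  the emitted image. The AROMA image variant is the same data minus the
  contamination term. CompCor columns are noisy mixtures of the true
  sources and global signal, with a sidecar variance ladder crossing 50 %.
- **Determinism.** All randomness flows from one seed through spawned
  `SeedSequence` substreams (one per subject), so output files are
  byte-identical across runs.

The generator writes a BIDS-derivative-like tree (per-subject images,
confounds TSV + JSON sidecar, atlas, participants table) plus a `truth/`
directory holding the planted nuisance regressors and partition.

### Scope and limitations

The generator validates the *pipeline*, not fMRI physics: there is no
hemodynamic response, no spatial autocorrelation beyond the parcel blocks,
no susceptibility or physiological noise, and the contamination model is
deliberately exactly removable. Results on synthetic data establish that
each metric responds in the right direction, not effect sizes for real
cohorts. The similarity ordering of strategies depends on the hierarchical
clustering heuristic (average linkage on 1 − r) and should be read as a
layout aid, not an inference.

## 6. Numerical conventions

- Missing token `n/a`; NaN in derivative columns only at volume 0, imputed
  to 0 on selection.
- FD/std-DVARS thresholds compare strictly (`>`); NaN comparisons are false,
  so volume 0 is never censored by them.
- Constant series are detected by exact zero range (`ptp == 0`) rather than
  a floating-point std comparison; partial correlations treat residual
  variance below 1e−10 of the centered data scale as zero.
- Correlations are clipped to [−1, 1] before any t transform.
- Louvain node moves require a gain > 1e−10 to terminate despite rounding.
- TSVs are written with `%.10g` floats; JSON with `indent=1` — both stable
  across platforms for byte-identical reruns.
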
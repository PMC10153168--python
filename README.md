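# fcbench

Strategy-driven retrieval of fMRIPrep confounds and a benchmark of
resting-state fMRI denoising strategies.

## The problem

Head motion contaminates resting-state functional connectivity: it inflates
correlations between nearby brain regions and couples edge strength to how
much each subject moved. fMRIPrep outputs a large table of candidate
nuisance regressors per scan (motion parameters and their expansions, tissue
signals, CompCor components, ICA-AROMA components, cosine drift terms,
censoring indicators), but selecting a *consistent, correct* subset is
error-prone: column names vary, derivative columns carry a missing value at
the first volume, CompCor components must be read off a JSON sidecar, and
non-aggressive ICA-AROMA requires a different input image altogether.

`fcbench` provides:

1. **A confound-retrieval API** (`load_confounds`,
   `load_confounds_strategy`) that turns an fMRIPrep ≥ 1.4 derivative pair
   (BOLD image + confounds TSV/JSON) into a validated regressor matrix and a
   volume-censoring mask, via a registry of named denoising strategies
   (`baseline`, `simple`, `simple+gsr`, `scrubbing.5`, `scrubbing.5+gsr`,
   `scrubbing.2`, `scrubbing.2+gsr`, `compcor`, `compcor6`, `aroma`).
2. **A benchmark pipeline** that scores each strategy on four
   motion-sensitivity metrics: loss of temporal degrees of freedom, QC-FC
   (per-edge partial correlation of edge strength with mean framewise
   displacement, controlling age and sex), distance-dependence of QC-FC
   (DM-FC), and network modularity (signed Louvain Q) plus its correlation
   with motion.
3. **A synthetic cohort generator** that plants known block-structured
   connectivity, realistic motion traces, and spike-locked,
   distance-dependent contamination — so every metric can be validated
   against ground truth without any real data.

## Worked example

Generate a small synthetic cohort and retrieve confounds for one scan:

```python
from pathlib import Path
from fcbench import SimulationConfig, simulate_cohort, load_confounds_strategy

root = Path("cohort")
simulate_cohort(SimulationConfig(n_subjects=8, n_volumes=120, seed=5), root)

img = root / "sub-01" / "func" / "sub-01_task-rest_desc-preproc_bold.nii.gz"
selection, mask = load_confounds_strategy(img, "scrubbing.2+gsr")
print(f"regressors: {selection.n_regressors}")
print(f"by category: { {k: v for k, v in selection.counts.items() if v} }")
print(f"volumes censored: {mask.censored_count} of {mask.n_volumes}")
```

prints

```
regressors: 37
by category: {'motion': 24, 'tissue': 8, 'global': 1, 'cosine': 4}
volumes censored: 46 of 120
```

(24 motion = 6 parameters × {value, derivative, square, squared derivative};
8 tissue = WM + CSF fully expanded; 1 global signal; 4 cosine drift terms.)

Run the benchmark across strategies:

```python
import pandas as pd
from fcbench import MetricConfig, RunManifest, run_benchmark

manifest = RunManifest(
    derivatives=root,
    participants=root / "participants.tsv",
    atlases=[(root / "atlas" / "atlas-synth_dseg.nii.gz",
              root / "atlas" / "atlas-synth_labels.tsv")],
    strategies=["baseline", "simple", "simple+gsr", "scrubbing.2"],
    out_dir=Path("out"),
    metric_config=MetricConfig(louvain_runs=20),
    bootstrap=25,
    seed=0,
)
paths = run_benchmark(manifest)
metrics = pd.read_csv(paths["metrics"], sep="\t")
print(metrics.pivot_table(index="strategy", columns="metric",
                          values="value").round(3))
```

Three of the eight subjects fail motion quality control (mean FD > 0.25 mm,
more than 80 % of volumes censored at 0.2 mm, or under one minute retained);
the remaining five produce:

```
metric       dof_percent_of_scan  mean_offdiag_r  qcfc_fraction_significant   dmfc  modularity_q
strategy
baseline                   3.333           0.293                      0.062  0.083         0.129
scrubbing.2               60.000           0.085                      0.035  0.039         0.393
simple                    25.000           0.112                      0.050  0.025         0.384
simple+gsr                25.833          -0.016                      0.038  0.028         0.752
```

The planted contamination behaves like real motion artifact: the baseline
(high-pass only) strategy shows the most motion-coupled edges and the
weakest modularity, scrubbing at 0.2 mm costs the most degrees of freedom,
and global signal regression centers the connectivity distribution near
zero (`mean_offdiag_r` −0.016 versus 0.112 without GSR).

The same pipeline is available from the command line:

```bash
fcbench simulate --out cohort --seed 5 --n-subjects 8
fcbench run --derivatives cohort --participants cohort/participants.tsv \
    --atlas cohort/atlas/atlas-synth_dseg.nii.gz:cohort/atlas/atlas-synth_labels.tsv \
    --strategies baseline,simple,simple+gsr --out out
fcbench strategies   # print the registry with all parameters
```

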
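import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from fcbench.simulate import SimulationConfig, simulate_cohort


def write_confounds_fixture(
    directory: Path,
    frame: pd.DataFrame,
    sidecar: dict | None = None,
    subject: str = "sub-01",
    variant: str = "preproc",
) -> Path:
    """Write a handmade confounds table as a paired BOLD/TSV fixture and
    return the (non-existent) BOLD image path the API pairs against."""
    func = directory / subject / "func"
    func.mkdir(parents=True, exist_ok=True)
    stem = f"{subject}_task-rest"
    frame.to_csv(
        func / f"{stem}_desc-confounds_timeseries.tsv",
        sep="\t", index=False, na_rep="n/a",
    )
    if sidecar is not None:
        (func / f"{stem}_desc-confounds_timeseries.json").write_text(
            json.dumps(sidecar)
        )
    return func / f"{stem}_desc-{variant}_bold.nii.gz"


def complete_confounds_frame(n_volumes: int = 20, seed: int = 0,
                             n_cosine: int = 4, n_compcor: int = 8,
                             n_nonsteady: int = 0) -> tuple[pd.DataFrame,
                                                            dict]:
    """A full-dialect confounds table with every column family present."""
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for base in ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
                 "csf", "white_matter", "global_signal"):
        series = rng.normal(size=n_volumes)
        deriv = np.concatenate([[np.nan], np.diff(series)])
        cols[base] = series
        cols[f"{base}_derivative1"] = deriv
        cols[f"{base}_power2"] = series ** 2
        cols[f"{base}_derivative1_power2"] = deriv ** 2
    fd = np.abs(rng.normal(0.1, 0.03, n_volumes))
    fd[0] = np.nan
    cols["framewise_displacement"] = fd
    dvars = 1 + 0.2 * np.abs(rng.normal(size=n_volumes))
    dvars[0] = np.nan
    cols["std_dvars"] = dvars
    for k in range(n_cosine):
        cols[f"cosine{k:02d}"] = rng.normal(size=n_volumes)
    sidecar = {}
    ladder = [0.20, 0.35, 0.48, 0.51, 0.60, 0.65, 0.69, 0.72][:n_compcor]
    for k in range(n_compcor):
        name = f"a_comp_cor_{k:02d}"
        cols[name] = rng.normal(size=n_volumes)
        sidecar[name] = {"Mask": "combined",
                         "CumulativeVarianceExplained": ladder[k]}
    for k in range(4):
        cols[f"aroma_motion_{k:02d}"] = rng.normal(size=n_volumes)
    for k in range(n_nonsteady):
        onehot = np.zeros(n_volumes)
        onehot[k] = 1
        cols[f"non_steady_state_outlier{k:02d}"] = onehot
    return pd.DataFrame(cols), sidecar


@pytest.fixture()
def complete_table_path(tmp_path):
    frame, sidecar = complete_confounds_frame()
    return write_confounds_fixture(tmp_path, frame, sidecar)


@pytest.fixture(scope="session")
def small_tree(tmp_path_factory):
    """A small but complete synthetic derivative tree (8 subjects, of whom
    5 pass motion QC, so the motion metrics are computable)."""
    root = tmp_path_factory.mktemp("tree")
    config = SimulationConfig(n_subjects=8, n_volumes=120, seed=5)
    truth = simulate_cohort(config, root)
    return root, config, truth
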
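"""Synthetic fMRIPrep-style derivative trees with known ground truth.

The generator emulates the statistical structure the benchmark metrics
assume, with every nuisance component known exactly:

* a block-structured "functional network" — parcels grouped into modules
  with a common within-module correlation;
* a shared global signal added to every parcel (what GSR removes);
* subject-varying head motion — AR(0)-style random-walk drifts plus sudden
  spikes — from which the framewise-displacement column is computed with
  the same 50 mm-sphere formula the package validates;
* spike-locked, spatially localized contamination: a handful of artifact
  sources at random positions add shared components (nonzero only around
  motion spikes) to nearby parcels, with amplitude proportional to the
  subject's mean FD.  Contaminated edges are therefore close in space and
  their strength scales with motion across subjects — the structure QC-FC
  and DM-FC are designed to detect — and censoring the spike volumes or
  regressing the true source time courses removes the contamination
  exactly.

Confound tables are written in the fMRIPrep >= 1.4 column dialect
(including derivative/power expansions, cosine drift terms, CompCor
components with a sidecar variance ladder, and AROMA columns), so every
emitted file round-trips through the package's own readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputError
from .motion import MotionParams, framewise_displacement
from .signals import Atlas, centers_of_mass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a typical resting-state acquisition: TR 2 s, 200
    volumes, 4 cosine drift regressors, mean FD around 0.15 mm with
    subject-level spread, and motion spikes large enough to cross the 0.2 mm
    scrubbing threshold.
    """

    n_subjects: int = 50
    n_volumes: int = 200
    tr_seconds: float = 2.0
    # atlas: grid of cubic parcels
    grid_shape: tuple[int, int, int] = (8, 8, 8)
    voxel_size_mm: float = 3.0
    n_parcels: int = 64
    # network structure
    n_blocks: int = 4
    within_r: float = 0.3
    between_r: float = 0.0
    global_amplitude: float = 0.5
    drift_amplitude: float = 0.5
    # motion
    mean_fd_median_mm: float = 0.15
    mean_fd_log_sigma: float = 0.3
    spike_rate: float = 0.05  # per volume
    spike_magnitude_mm: tuple[float, float] = (0.25, 0.6)  # uniform range
    spike_artifact_sd: float = 3.0
    # contamination
    contamination_beta: float = 4.0  # loading per mm of mean FD
    distance_decay_lambda_mm: float = 8.0
    n_contamination_sources: int = 6
    # confound dialect
    n_cosine: int = 4
    n_compcor: int = 8
    n_aroma: int = 6
    n_nonsteady: int = 0
    # voxel noise
    noise_sigma: float = 0.5
    # demographics
    age_mean: float = 32.0
    age_sd: float = 9.0
    seed: int = 0
    write_aroma_variant: bool = True

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_volumes, self.n_parcels) <= 0:
            raise InputError("sizes must be positive")
        if self.spike_rate < 0 or self.contamination_beta < 0:
            raise InputError("rates must be non-negative")
        if self.n_parcels % self.n_blocks:
            raise InputError("n_blocks must divide n_parcels")

    def target_covariance(self) -> np.ndarray:
        """Planted parcel covariance; raises if not positive semidefinite."""
        p, b = self.n_parcels, self.n_blocks
        block = self.block_partition()
        same = block[:, None] == block[None, :]
        cov = np.where(same, self.within_r, self.between_r)
        np.fill_diagonal(cov, 1.0)
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10:
            raise InputError(
                f"within/between correlations yield a non-PSD target "
                f"matrix (min eigenvalue {eig.min():.3g})"
            )
        return cov

    def block_partition(self) -> np.ndarray:
        per = self.n_parcels // self.n_blocks
        return np.repeat(np.arange(self.n_blocks), per)


@dataclass
class GroundTruth:
    """Everything planted by the generator, reproducible from (config, seed)."""

    partition: np.ndarray  # parcel -> module label
    mean_fd: dict[str, float]  # realized, from the emitted FD column
    nuisance: dict[str, np.ndarray]  # subject -> volumes x (1 + K) regressors
    source_centers: np.ndarray  # K x 3 world mm
    contamination_loadings: np.ndarray  # parcels x K geometry-only weights
    subjects: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


def make_atlas(config: SimulationConfig) -> Atlas:
    """Cubic-block label atlas: n_parcels contiguous cuboids tiling the grid."""
    per_axis = round(config.n_parcels ** (1 / 3))
    if per_axis ** 3 != config.n_parcels:
        raise InputError("n_parcels must be a perfect cube for the block "
                         "atlas layout")
    gx, gy, gz = config.grid_shape
    if gx % per_axis or gy % per_axis or gz % per_axis:
        raise InputError("grid_shape must be divisible by the parcel grid")
    bx, by, bz = gx // per_axis, gy // per_axis, gz // per_axis
    labels = np.zeros(config.grid_shape, dtype=int)
    pid = 1
    for ix in range(per_axis):
        for iy in range(per_axis):
            for iz in range(per_axis):
                labels[
                    ix * bx:(ix + 1) * bx,
                    iy * by:(iy + 1) * by,
                    iz * bz:(iz + 1) * bz,
                ] = pid
                pid += 1
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    lookup = {i: f"parcel_{i:03d}" for i in range(1, config.n_parcels + 1)}
    return Atlas(kind="labels", data=labels, affine=affine, lookup=lookup)


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------


def simulate_motion(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[MotionParams, np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject motion: random-walk drift plus single-volume spikes.

    Returns (params, fd, std_dvars, spike_envelope); fd is recomputed from
    the params with the 50 mm formula, so the emitted column is internally
    consistent by construction.  The envelope marks the volumes whose FD a
    spike elevates (the spike volume and its successor).
    """
    n = config.n_volumes
    target = config.mean_fd_median_mm * np.exp(
        rng.normal(0.0, config.mean_fd_log_sigma)
    )
    # choose per-step sd so that expected drift FD matches the target:
    # E|N(0,s)| = s*sqrt(2/pi), six parameter channels contribute equally
    step = target / (6.0 * np.sqrt(2.0 / np.pi))
    dtrans = rng.normal(0.0, step, size=(n - 1, 3))
    drot = rng.normal(0.0, step / 50.0, size=(n - 1, 3))
    trans = np.vstack([np.zeros(3), np.cumsum(dtrans, axis=0)])
    rot = np.vstack([np.zeros(3), np.cumsum(drot, axis=0)])

    envelope = np.zeros(n)
    spikes = rng.random(n) < config.spike_rate
    spikes[0] = False  # keep volume 0 clean
    lo, hi = config.spike_magnitude_mm
    for t in np.flatnonzero(spikes):
        mag = rng.uniform(lo, hi)
        trans[t, 0] += mag  # one-volume displacement, returns at t+1
        envelope[t] = mag
        if t + 1 < n:
            envelope[t + 1] = max(envelope[t + 1], mag)
    params = MotionParams(trans, rot)
    fd = framewise_displacement(params)
    std_dvars = 1.0 + 0.3 * np.abs(rng.normal(size=n))
    return params, fd, std_dvars, envelope


def _dct_basis(n_volumes: int, n_terms: int) -> np.ndarray:
    t = np.arange(n_volumes)
    basis = np.column_stack(
        [
            np.cos(np.pi * (t + 0.5) * (k + 1) / n_volumes)
            for k in range(n_terms)
        ]
    )
    return basis * np.sqrt(2.0 / n_volumes)


def _expansions(base: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Add fMRIPrep derivative/power expansion columns (NaN at volume 0 for
    derivatives)."""
    out: dict[str, np.ndarray] = {}
    for name, series in base.items():
        deriv = np.concatenate([[np.nan], np.diff(series)])
        out[name] = series
        out[f"{name}_derivative1"] = deriv
        out[f"{name}_power2"] = series ** 2
        out[f"{name}_derivative1_power2"] = deriv ** 2
    return out


# ---------------------------------------------------------------------------
# subject-level data
# ---------------------------------------------------------------------------


@dataclass
class _SubjectData:
    params: MotionParams
    fd: np.ndarray
    std_dvars: np.ndarray
    envelope: np.ndarray
    global_signal: np.ndarray
    sources: np.ndarray  # volumes x K spike-locked components
    parcel_signals: np.ndarray  # volumes x parcels
    bold: np.ndarray  # 4D
    bold_clean: np.ndarray  # 4D, contamination removed (AROMA-like variant)
    mean_fd: float


def _simulate_subject(
    config: SimulationConfig,
    rng: np.random.Generator,
    chol: np.ndarray,
    loadings_geom: np.ndarray,
    atlas: Atlas,
) -> _SubjectData:
    n, p = config.n_volumes, config.n_parcels
    params, fd, std_dvars, envelope = simulate_motion(config, rng)
    mean_fd = float(np.mean(fd))

    latent = rng.standard_normal((n, p)) @ chol.T
    g = rng.standard_normal(n)
    K = config.n_contamination_sources
    sources = (envelope > 0)[:, None] * rng.normal(
        0.0, config.spike_artifact_sd, size=(n, K)
    )
    amp = config.contamination_beta * mean_fd
    contamination = sources @ (amp * loadings_geom).T  # volumes x parcels
    drift = _dct_basis(n, config.n_cosine) @ rng.normal(
        0.0, config.drift_amplitude, size=(config.n_cosine, p)
    )
    signals = (
        latent
        + config.global_amplitude * g[:, None]
        + contamination
        + drift
    )

    labels = atlas.data
    bold = np.empty(labels.shape + (n,), dtype=np.float32)
    bold_clean = np.empty_like(bold)
    noise = rng.normal(0.0, config.noise_sigma,
                       size=labels.shape + (n,)).astype(np.float32)
    signals_clean = signals - contamination
    for k, pid in enumerate(atlas.parcel_ids):
        member = labels == pid
        bold[member] = signals[:, k].astype(np.float32)
        bold_clean[member] = signals_clean[:, k].astype(np.float32)
    bold += noise
    bold_clean += noise
    return _SubjectData(
        params=params, fd=fd, std_dvars=std_dvars, envelope=envelope,
        global_signal=g, sources=sources, parcel_signals=signals,
        bold=bold, bold_clean=bold_clean, mean_fd=mean_fd,
    )


def simulate_confounds_frame(
    config: SimulationConfig,
    data: _SubjectData,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Confounds table + sidecar in the fMRIPrep >= 1.4 dialect."""
    n = config.n_volumes
    trans, rot = data.params.translations, data.params.rotations
    base = {
        "trans_x": trans[:, 0], "trans_y": trans[:, 1],
        "trans_z": trans[:, 2],
        "rot_x": rot[:, 0], "rot_y": rot[:, 1], "rot_z": rot[:, 2],
    }
    columns = _expansions(base)

    src_mean = data.sources.mean(axis=1)
    csf = 0.7 * data.global_signal + 0.3 * src_mean + \
        0.3 * rng.standard_normal(n)
    wm = 0.6 * data.global_signal + 0.2 * src_mean + \
        0.3 * rng.standard_normal(n)
    # the global-signal column is the brain-wide voxel mean of the image
    gs = data.bold.reshape(-1, n).mean(axis=0).astype(float)
    columns.update(_expansions({"csf": csf, "white_matter": wm,
                                "global_signal": gs}))

    fd = data.fd.copy()
    dvars = data.std_dvars.copy()
    fd[0] = np.nan  # dialect: first volume has no predecessor
    dvars[0] = np.nan
    columns["framewise_displacement"] = fd
    columns["std_dvars"] = dvars

    basis = _dct_basis(n, config.n_cosine)
    for k in range(config.n_cosine):
        columns[f"cosine{k:02d}"] = basis[:, k]

    # CompCor: noisy mixtures of the true nuisance sources, with a sidecar
    # cumulative-variance ladder crossing 50%
    sidecar: dict[str, dict] = {}
    ladder = 0.70 * (1 - 0.78 ** np.arange(1, config.n_compcor + 1))
    ladder = np.round(ladder / ladder[-1] * 0.68, 4)
    for k in range(config.n_compcor):
        mix = (
            0.5 * data.sources[:, k % data.sources.shape[1]]
            + 0.4 * data.global_signal
            + 0.6 * rng.standard_normal(n)
        )
        name = f"a_comp_cor_{k:02d}"
        columns[name] = mix
        sidecar[name] = {
            "Method": "aCompCor",
            "Mask": "combined",
            "CumulativeVarianceExplained": float(ladder[k]),
        }
    for k in range(2):  # a couple of single-tissue components for realism
        name = f"a_comp_cor_{config.n_compcor + k:02d}"
        columns[name] = rng.standard_normal(n)
        sidecar[name] = {
            "Method": "aCompCor",
            "Mask": "CSF",
            "CumulativeVarianceExplained": float(0.3 + 0.2 * k),
        }

    for k in range(config.n_aroma):
        columns[f"aroma_motion_{k:02d}"] = (
            0.6 * data.sources[:, k % data.sources.shape[1]]
            + 0.4 * rng.standard_normal(n)
        )

    for k in range(config.n_nonsteady):
        onehot = np.zeros(n)
        onehot[k] = 1.0
        columns[f"non_steady_state_outlier{k:02d}"] = onehot

    return pd.DataFrame(columns), sidecar


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _nifti(data: np.ndarray, affine: np.ndarray) -> nib.Nifti1Image:
    img = nib.Nifti1Image(data, affine)
    img.header.set_data_dtype(np.float32)
    return img


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path
) -> GroundTruth:
    """Write a BIDS-derivative-like tree plus participants table and truth.

    Layout::

        out/
          atlas/atlas-synth_dseg.nii.gz, atlas-synth_labels.tsv
          participants.tsv
          truth/truth.json, sub-XX_nuisance.tsv
          sub-XX/func/sub-XX_task-rest_desc-preproc_bold.nii.gz
                      sub-XX_task-rest_desc-confounds_timeseries.tsv/.json
                      sub-XX_task-rest_desc-smoothAROMAnonaggr_bold.nii.gz
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    rng_cohort = np.random.default_rng(ss.spawn(1)[0])

    atlas = make_atlas(config)
    atlas_dir = out / "atlas"
    atlas_dir.mkdir(exist_ok=True)
    nib.save(
        nib.Nifti1Image(atlas.data.astype(np.int16), atlas.affine),
        atlas_dir / "atlas-synth_dseg.nii.gz",
    )
    pd.DataFrame(
        {"index": list(atlas.lookup), "name": list(atlas.lookup.values())}
    ).to_csv(atlas_dir / "atlas-synth_labels.tsv", sep="\t", index=False)

    geometry = centers_of_mass(atlas)
    K = config.n_contamination_sources
    lo = geometry.centers.min(axis=0)
    hi = geometry.centers.max(axis=0)
    source_centers = rng_cohort.uniform(lo, hi, size=(K, 3))
    dist = np.linalg.norm(
        geometry.centers[:, None, :] - source_centers[None, :, :], axis=-1
    )
    loadings_geom = np.exp(-dist / config.distance_decay_lambda_mm)

    cov = config.target_covariance()
    chol = np.linalg.cholesky(cov)

    ages = np.clip(
        rng_cohort.normal(config.age_mean, config.age_sd, config.n_subjects),
        18, 65,
    ).round(1)
    sexes = rng_cohort.integers(0, 2, config.n_subjects)

    truth = GroundTruth(
        partition=config.block_partition(),
        mean_fd={},
        nuisance={},
        source_centers=source_centers,
        contamination_loadings=loadings_geom,
    )
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    participants = []

    for i in range(config.n_subjects):
        sub = f"sub-{i + 1:02d}"
        rng = np.random.default_rng(ss.spawn(1)[0])
        data = _simulate_subject(config, rng, chol, loadings_geom, atlas)
        func = out / sub / "func"
        func.mkdir(parents=True, exist_ok=True)
        stem = f"{sub}_task-rest"
        nib.save(_nifti(data.bold, atlas.affine),
                 func / f"{stem}_desc-preproc_bold.nii.gz")
        if config.write_aroma_variant:
            nib.save(
                _nifti(data.bold_clean, atlas.affine),
                func / f"{stem}_desc-smoothAROMAnonaggr_bold.nii.gz",
            )
        frame, sidecar = simulate_confounds_frame(config, data, rng)
        frame.to_csv(
            func / f"{stem}_desc-confounds_timeseries.tsv",
            sep="\t", index=False, na_rep="n/a", float_format="%.10g",
        )
        (func / f"{stem}_desc-confounds_timeseries.json").write_text(
            json.dumps(sidecar, indent=1)
        )

        nuisance = np.column_stack([data.global_signal, data.sources])
        truth.nuisance[sub] = nuisance
        truth.mean_fd[sub] = float(
            np.nanmean(frame["framewise_displacement"])
        )
        truth.subjects.append(sub)
        pd.DataFrame(
            nuisance,
            columns=["global"] + [f"source_{k:02d}" for k in range(K)],
        ).to_csv(truth_dir / f"{sub}_nuisance.tsv", sep="\t", index=False,
                 float_format="%.10g")
        participants.append(
            {"participant_id": sub, "age": ages[i],
             "sex": "F" if sexes[i] else "M"}
        )

    pd.DataFrame(participants).to_csv(
        out / "participants.tsv", sep="\t", index=False
    )
    (truth_dir / "truth.json").write_text(
        json.dumps(
            {
                "partition": truth.partition.tolist(),
                "mean_fd": truth.mean_fd,
                "source_centers": source_centers.tolist(),
                "seed": config.seed,
            },
            indent=1,
        )
    )
    return truth
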
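"""Parcel time-series extraction, confound regression and connectomes.

Works on NIfTI 4D BOLD images and either discrete-label atlases (3D integer
image, background 0) or probabilistic map atlases (4D, one spatial map per
parcel).  The image and atlas must already share grid and affine; no
resampling happens here.  Denoising censors volumes first, then removes the
confound matrix from each parcel series by ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .confounds import ConfoundSelection, SampleMask
from .errors import DegreesOfFreedomError, InputError


@dataclass
class Atlas:
    """Parcellation: discrete labels or probabilistic maps plus a lookup."""

    kind: str  # "labels" | "maps"
    data: np.ndarray  # 3D int labels or 4D float maps
    affine: np.ndarray  # 4x4 voxel-to-world (mm)
    lookup: dict[int, str]  # parcel id -> name

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.kind == "labels":
            if self.data.ndim != 3:
                raise InputError("labels atlas must be 3D")
            if (self.data < 0).any():
                raise InputError("labels must be non-negative (background 0)")
        elif self.kind == "maps":
            if self.data.ndim != 4:
                raise InputError("maps atlas must be 4D")
            if not np.isfinite(self.data).all():
                raise InputError("maps atlas holds non-finite values")
            if self.data.shape[3] != len(self.lookup):
                raise InputError("maps count does not match lookup")
        else:
            raise InputError(f"unknown atlas kind {self.kind!r}")

    @property
    def parcel_ids(self) -> list[int]:
        return sorted(self.lookup)

    @classmethod
    def from_files(
        cls, nifti_path: str | Path, lookup_tsv: str | Path
    ) -> "Atlas":
        """Load an atlas NIfTI plus its lookup TSV (columns: index, name)."""
        img = nib.load(str(nifti_path))
        data = np.asanyarray(img.dataobj)
        table = pd.read_csv(lookup_tsv, sep="\t")
        lookup = dict(
            zip(table["index"].astype(int), table["name"].astype(str))
        )
        kind = "maps" if data.ndim == 4 else "labels"
        if kind == "labels":
            data = np.rint(data).astype(int)
        return cls(kind=kind, data=data, affine=img.affine, lookup=lookup)


@dataclass
class ParcelTimeSeries:
    series: np.ndarray  # volumes x parcels
    parcel_ids: list[int]
    tr_seconds: float = 2.0

    @property
    def n_volumes(self) -> int:
        return self.series.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.series.shape[1]

    def to_tsv(self, path: str | Path, lookup: dict[int, str] | None = None):
        names = [lookup[i] if lookup else str(i) for i in self.parcel_ids]
        pd.DataFrame(self.series, columns=names).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


@dataclass
class Connectome:
    matrix: np.ndarray  # parcels x parcels Pearson r
    parcel_ids: list[int]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.matrix,
            index=self.parcel_ids,
            columns=self.parcel_ids,
        ).to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class ParcelGeometry:
    centers: np.ndarray  # parcels x 3, world mm (NaN for empty parcels)
    parcel_ids: list[int]

    @property
    def pairwise_distance(self) -> np.ndarray:
        diff = self.centers[:, None, :] - self.centers[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))


def _check_grids(image_data: np.ndarray, image_affine: np.ndarray,
                 atlas: Atlas) -> None:
    if image_data.shape[:3] != atlas.data.shape[:3]:
        raise InputError(
            f"image grid {image_data.shape[:3]} does not match atlas grid "
            f"{atlas.data.shape[:3]}; resample before extraction"
        )
    if not np.allclose(image_affine, atlas.affine, atol=1e-4):
        raise InputError("image and atlas affines differ; resample first")


def _load_4d(image) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(image, (str, Path)):
        image = nib.load(str(image))
    data = np.asanyarray(image.dataobj, dtype=float)
    if data.ndim != 4:
        raise InputError("expected a 4D BOLD image")
    return data, image.affine


def extract_labels(
    image, atlas: Atlas, tr_seconds: float = 2.0
) -> ParcelTimeSeries:
    """Mean time course over each labelled parcel.

    Empty parcels (present in the lookup, no voxels) yield a zero column and
    a warning; the parcel id is retained so column order is stable.
    """
    if atlas.kind != "labels":
        raise InputError("extract_labels needs a labels atlas")
    data, affine = _load_4d(image)
    _check_grids(data, affine, atlas)
    n_vol = data.shape[3]
    ids = atlas.parcel_ids
    out = np.zeros((n_vol, len(ids)))
    flat = data.reshape(-1, n_vol)
    labels = atlas.data.reshape(-1)
    for k, pid in enumerate(ids):
        member = labels == pid
        if not member.any():
            warnings.warn(f"parcel {pid} has no voxels; zero series kept")
            continue
        out[:, k] = flat[member].mean(axis=0)
    return ParcelTimeSeries(out, ids, tr_seconds)


def extract_maps(
    image, atlas: Atlas, tr_seconds: float = 2.0
) -> ParcelTimeSeries:
    """Per-volume least-squares regression of the spatial maps on the data.

    Each volume's voxel vector is regressed onto the stacked maps; the
    fitted coefficients are the parcel signals (handles overlapping or
    disjoint probabilistic parcels).
    """
    if atlas.kind != "maps":
        raise InputError("extract_maps needs a maps atlas")
    data, affine = _load_4d(image)
    _check_grids(data, affine, atlas)
    n_vol = data.shape[3]
    ids = atlas.parcel_ids
    maps = atlas.data.reshape(-1, len(ids))  # voxels x parcels
    rank = np.linalg.matrix_rank(maps)
    if rank < len(ids):
        raise InputError(
            f"maps matrix is rank deficient (rank {rank} < {len(ids)} "
            "maps); collinear or empty spatial maps"
        )
    Y = data.reshape(-1, n_vol)
    coef, *_ = np.linalg.lstsq(maps, Y, rcond=None)
    return ParcelTimeSeries(coef.T, ids, tr_seconds)


def clean(
    ts: ParcelTimeSeries,
    selection: ConfoundSelection,
    mask: SampleMask | None = None,
    demean: bool = True,
    standardize: bool = False,
) -> ParcelTimeSeries:
    """Censor volumes, then regress confounds out of each parcel series.

    Censored volumes are dropped from signals and confounds *before* the
    regression, so spikes confined to censored volumes cannot leak into the
    retained data.  The regression always includes an intercept; with
    ``demean=False`` the fitted mean is added back.  ``standardize``
    z-scores each parcel after cleaning.
    """
    if mask is None:
        mask = SampleMask.full(ts.n_volumes)
    if selection.n_regressors and selection.matrix.shape[0] != ts.n_volumes:
        raise InputError("confound rows do not align with time-series "
                         "volumes")
    kept = mask.kept
    y = ts.series[kept]
    n_kept = y.shape[0]
    design = np.column_stack(
        [np.ones(n_kept)]
        + ([selection.matrix[kept]] if selection.n_regressors else [])
    )
    if design.shape[1] >= n_kept:
        raise DegreesOfFreedomError(
            f"{design.shape[1]} regressors (incl. intercept) for "
            f"{n_kept} retained volumes"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    if not demean:
        resid = resid + design[:, :1] @ beta[:1]
    if standardize:
        sd = resid.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        resid = (resid - resid.mean(axis=0)) / sd
    return ParcelTimeSeries(resid, list(ts.parcel_ids), ts.tr_seconds)


def pearson_connectome(ts: ParcelTimeSeries) -> Connectome:
    """Pearson correlation matrix; zero-variance parcels give NaN edges."""
    if ts.n_volumes < 3:
        raise InputError("need at least 3 volumes for a correlation matrix")
    # constant columns have exactly zero range; std can be ~1e-16 for them
    zero_var = np.ptp(ts.series, axis=0) == 0
    if zero_var.any():
        bad = [ts.parcel_ids[i] for i in np.flatnonzero(zero_var)]
        warnings.warn(f"zero-variance parcels {bad}: edges set to NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts.series, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    r[zero_var, :] = np.nan
    r[:, zero_var] = np.nan
    np.fill_diagonal(r, 1.0)
    return Connectome(r, list(ts.parcel_ids))


def vectorize(conn: Connectome) -> np.ndarray:
    """Strictly-lower-triangle edges in row-major order, length p(p-1)/2."""
    p = conn.matrix.shape[0]
    rows, cols = np.tril_indices(p, k=-1)
    return conn.matrix[rows, cols]


def edge_index_pairs(p: int) -> list[tuple[int, int]]:
    """(row, col) parcel-index pairs matching :func:`vectorize` order."""
    rows, cols = np.tril_indices(p, k=-1)
    return list(zip(rows.tolist(), cols.tolist()))


def centers_of_mass(atlas: Atlas) -> ParcelGeometry:
    """Parcel centers in world coordinates (mm).

    Labels: mean of member-voxel coordinates pushed through the affine.
    Maps: map-weighted mean of voxel coordinates.  Empty parcels yield NaN
    centers and a warning.
    """
    ids = atlas.parcel_ids
    centers = np.full((len(ids), 3), np.nan)
    shape = atlas.data.shape[:3]
    grid = np.indices(shape).reshape(3, -1).T.astype(float)  # voxels x 3
    world = grid @ atlas.affine[:3, :3].T + atlas.affine[:3, 3]
    if atlas.kind == "labels":
        labels = atlas.data.reshape(-1)
        for k, pid in enumerate(ids):
            member = labels == pid
            if not member.any():
                warnings.warn(f"parcel {pid} empty; center is NaN")
                continue
            centers[k] = world[member].mean(axis=0)
    else:
        maps = atlas.data.reshape(-1, len(ids))
        for k in range(len(ids)):
            w = maps[:, k]
            total = w.sum()
            if total == 0:
                warnings.warn(f"map {ids[k]} is all-zero; center is NaN")
                continue
            centers[k] = (world * w[:, None]).sum(axis=0) / total
    return ParcelGeometry(centers, ids)
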
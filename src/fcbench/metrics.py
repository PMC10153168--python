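"""Denoising-quality metrics over a cohort of connectomes.

Four metrics are implemented:

* loss of temporal degrees of freedom — regressors used plus volumes
  censored, relative to scan length;
* QC-FC — per-edge partial correlation between subjects' mean framewise
  displacement and edge strength, with age and sex as covariates;
* DM-FC — absolute correlation between inter-parcel Euclidean distance and
  the QC-FC values, measuring distance-dependent motion artifact;
* network modularity — Louvain Q per connectome plus its partial
  correlation with mean FD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .confounds import ConfoundSelection, SampleMask
from .errors import InputError
from .louvain import best_louvain
from .signals import Connectome


@dataclass
class Phenotypes:
    """Per-subject covariates for the motion metrics."""

    mean_fd: np.ndarray  # mm
    age: np.ndarray  # years
    sex: np.ndarray  # {0, 1}
    subjects: list[str] | None = None

    def __post_init__(self) -> None:
        self.mean_fd = np.asarray(self.mean_fd, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        n = self.mean_fd.size
        if self.age.size != n or self.sex.size != n:
            raise InputError("phenotype arrays must share length")
        for arr, name in ((self.mean_fd, "mean_fd"), (self.age, "age"),
                          (self.sex, "sex")):
            if not np.isfinite(arr).all():
                raise InputError(f"missing values in {name}")
        if n < 5:
            raise InputError("need >= 5 subjects for partial correlation "
                             "with two covariates")

    @property
    def covariates(self) -> np.ndarray:
        return np.column_stack([self.age, self.sex])


@dataclass
class MetricConfig:
    alpha: float = 0.05
    multiple_comparison: str = "none"  # or "fdr"
    louvain_seed: int = 0
    louvain_negative_scheme: str = "negative_asym"
    louvain_runs: int = 100
    louvain_gamma: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InputError("alpha must lie in (0, 1)")
        if self.multiple_comparison not in ("none", "fdr"):
            raise InputError("multiple_comparison must be 'none' or 'fdr'")


@dataclass
class QCFCResult:
    r: np.ndarray  # per-edge partial correlation (NaN where degenerate)
    p: np.ndarray
    fraction_significant: float
    median_absolute_r: float


@dataclass
class DoFReport:
    n_regressors: int
    breakdown: dict[str, int]
    cosine: int
    n_censored: int
    n_volumes: int

    @property
    def total_loss(self) -> int:
        return self.n_regressors + self.n_censored

    @property
    def percent_of_scan(self) -> float:
        return 100.0 * self.total_loss / self.n_volumes


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residual of each column of y against [1, covariates]."""
    y = np.atleast_2d(np.asarray(y, dtype=float).T).T  # n x m
    n = y.shape[0]
    X = np.column_stack([np.ones(n), covariates]) if covariates.size else \
        np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_corr(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on ``[1, covariates]`` and the residuals
    correlated; the two-sided p-value uses the t transform with
    ``n - 2 - k`` degrees of freedom.  Returns ``(nan, nan)`` with a warning
    when either residual has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = np.empty((x.size, 0))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != x.size:
        covariates = covariates.T
    n, k = x.size, covariates.shape[1]
    if n <= k + 2:
        raise InputError(f"need n > k + 2 subjects (n={n}, k={k})")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("x and y must be finite")
    rx = _residualize(x, covariates)[:, 0]
    ry = _residualize(y, covariates)[:, 0]
    sx, sy = rx.std(), ry.std()
    # residuals of a perfectly explained variable are ~1e-16, not exactly 0
    tol_x = 1e-10 * max(1.0, float(np.abs(x - x.mean()).max()))
    tol_y = 1e-10 * max(1.0, float(np.abs(y - y.mean()).max()))
    if sx <= tol_x or sy <= tol_y:
        warnings.warn("zero residual variance; partial correlation "
                      "undefined")
        return np.nan, np.nan
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = max(-1.0, min(1.0, r))
    dof = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), dof)
    return r, float(p)


def qcfc(
    edges: np.ndarray,
    pheno: Phenotypes,
    config: MetricConfig | None = None,
) -> QCFCResult:
    """QC-FC: per-edge partial correlation of edge strength with mean FD.

    ``edges`` is subjects x edges.  Edges with missing values are dropped
    pairwise (per edge).  ``fraction_significant`` is the share of edges
    with p < alpha, after Benjamini-Hochberg correction when the config
    requests FDR.
    """
    config = config or MetricConfig()
    edges = np.asarray(edges, dtype=float)
    n_sub, n_edges = edges.shape
    if n_sub != pheno.mean_fd.size:
        raise InputError("edges rows must match phenotype subjects")
    if np.std(pheno.mean_fd) == 0:
        raise InputError("mean_fd is constant across subjects")
    r = np.full(n_edges, np.nan)
    p = np.full(n_edges, np.nan)
    covs = pheno.covariates
    finite_edge = np.isfinite(edges).all(axis=0)
    # vectorized path for fully-finite edges
    idx = np.flatnonzero(finite_edge)
    if idx.size:
        n, k = n_sub, covs.shape[1]
        rx = _residualize(pheno.mean_fd, covs)[:, 0]
        ry = _residualize(edges[:, idx], covs)
        sx = rx.std()
        sy = ry.std(axis=0)
        ok = (sx > 0) & (sy > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rv = (rx @ ry) / (n * sx * sy)
        rv = np.clip(rv, -1, 1)
        dof = n - 2 - k
        with np.errstate(invalid="ignore", divide="ignore"):
            tv = rv * np.sqrt(dof / (1 - rv ** 2))
        pv = 2 * stats.t.sf(np.abs(tv), dof)
        pv = np.where(np.abs(rv) >= 1, 0.0, pv)
        rv = np.where(ok, rv, np.nan)
        pv = np.where(ok, pv, np.nan)
        r[idx], p[idx] = rv, pv
    # per-edge pairwise deletion for edges with missing values
    for j in np.flatnonzero(~finite_edge):
        rows = np.isfinite(edges[:, j])
        if rows.sum() <= covs.shape[1] + 2:
            continue
        sub = Phenotypes(pheno.mean_fd[rows], pheno.age[rows],
                         pheno.sex[rows]) if rows.sum() >= 5 else None
        if sub is None:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r[j], p[j] = partial_corr(sub.mean_fd, edges[rows, j],
                                      sub.covariates)
    valid = np.isfinite(p)
    if valid.any():
        pvals = p[valid]
        if config.multiple_comparison == "fdr":
            reject, _, _, _ = multipletests(pvals, alpha=config.alpha,
                                            method="fdr_bh")
            frac = float(reject.mean())
        else:
            frac = float((pvals < config.alpha).mean())
    else:
        frac = np.nan
    med = float(np.nanmedian(np.abs(r))) if np.isfinite(r).any() else np.nan
    return QCFCResult(r, p, frac, med)


def benjamini_hochberg(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """BH step-up rejection decisions (thin wrapper, exposed for reuse)."""
    reject, _, _, _ = multipletests(np.asarray(p, dtype=float), alpha=alpha,
                                    method="fdr_bh")
    return reject


def dmfc(qcfc_r: np.ndarray, distance_mm: np.ndarray) -> float:
    """|Pearson r| between per-edge distance and QC-FC; NaN-pairs dropped."""
    qcfc_r = np.asarray(qcfc_r, dtype=float)
    distance_mm = np.asarray(distance_mm, dtype=float)
    if qcfc_r.size != distance_mm.size:
        raise InputError("edge vectors must share length")
    ok = np.isfinite(qcfc_r) & np.isfinite(distance_mm)
    if ok.sum() < 3:
        raise InputError("need >= 3 edges for DM-FC")
    x, y = qcfc_r[ok], distance_mm[ok]
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance in DM-FC inputs; result undefined")
        return np.nan
    return float(abs(np.corrcoef(x, y)[0, 1]))


def louvain_q(
    conn: Connectome, config: MetricConfig | None = None
) -> tuple[float, np.ndarray]:
    """Network modularity Q of a connectome (diagonal ignored).

    Louvain is restarted ``config.louvain_runs`` times with seed-derived
    substreams and the best-Q partition kept; negative edges (from GSR)
    enter with the configured signed scheme.
    """
    config = config or MetricConfig()
    W = np.array(conn.matrix, dtype=float)
    W = np.nan_to_num(W, nan=0.0)
    np.fill_diagonal(W, 0.0)
    return best_louvain(
        W,
        runs=config.louvain_runs,
        gamma=config.louvain_gamma,
        scheme=config.louvain_negative_scheme,
        seed=config.louvain_seed,
    )


def modularity_motion(
    q: np.ndarray, pheno: Phenotypes
) -> tuple[float, float]:
    """Partial correlation between per-subject modularity and mean FD."""
    return partial_corr(pheno.mean_fd, np.asarray(q, dtype=float),
                        pheno.covariates)


def dof_loss(
    selection: ConfoundSelection, mask: SampleMask, n_volumes: int
) -> DoFReport:
    """Temporal degrees-of-freedom loss: regressors + censored volumes."""
    return DoFReport(
        n_regressors=selection.n_regressors,
        breakdown=dict(selection.counts),
        cosine=selection.counts.get("cosine", 0),
        n_censored=mask.censored_count,
        n_volumes=n_volumes,
    )
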
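"""End-to-end benchmark orchestration.

For every included subject x strategy x atlas the pipeline runs confound
retrieval -> parcel extraction -> censoring + regression -> Pearson
connectome, then aggregates the four denoising-quality metrics and the
cross-strategy similarity into TSV tables.  Subjects failing the motion
quality control are excluded before any metric is computed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import confounds as capi
from . import metrics as qm
from . import signals as sig
from .errors import FCBenchError, InputError
from .motion import QCDecision, subject_qc, write_qc_report

log = logging.getLogger("fcbench")

SEX_CODING = {"M": 0, "F": 1}  # recorded in the run manifest


@dataclass
class RunManifest:
    derivatives: Path
    participants: Path
    atlases: list[tuple[Path, Path]]  # (nifti, lookup tsv) pairs
    strategies: list[str]
    out_dir: Path
    metric_config: qm.MetricConfig = field(default_factory=qm.MetricConfig)
    task: str = "rest"
    tr_seconds: float = 2.0
    fdr: bool = False
    bootstrap: int = 50
    seed: int = 0
    included: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.derivatives = Path(self.derivatives)
        self.participants = Path(self.participants)
        self.out_dir = Path(self.out_dir)
        self.atlases = [(Path(a), Path(b)) for a, b in self.atlases]
        if not self.strategies:
            raise InputError("need at least one strategy")
        if self.fdr:
            self.metric_config.multiple_comparison = "fdr"

    def echo(self) -> dict:
        return {
            "derivatives": str(self.derivatives),
            "participants": str(self.participants),
            "atlases": [[str(a), str(b)] for a, b in self.atlases],
            "strategies": self.strategies,
            "task": self.task,
            "tr_seconds": self.tr_seconds,
            "alpha": self.metric_config.alpha,
            "multiple_comparison": self.metric_config.multiple_comparison,
            "louvain_seed": self.metric_config.louvain_seed,
            "louvain_runs": self.metric_config.louvain_runs,
            "louvain_negative_scheme":
                self.metric_config.louvain_negative_scheme,
            "bootstrap": self.bootstrap,
            "seed": self.seed,
            "sex_coding": SEX_CODING,
            "included": self.included,
            "excluded": self.excluded,
        }


def list_strategies() -> pd.DataFrame:
    """The ten benchmark strategy rows with all parameters."""
    rows = []
    for name, spec in capi.BENCHMARK_STRATEGIES.items():
        rows.append(
            {
                "strategy": name,
                "image": f"desc-{'smoothAROMAnonaggr' if spec.ica_aroma else 'preproc'}_bold",
                "high_pass": spec.high_pass,
                "motion": spec.motion or "N/A",
                "wm_csf": spec.wm_csf or "N/A",
                "global_signal": spec.global_signal or "N/A",
                "scrub": spec.scrub if spec.scrub is not None else "N/A",
                "fd_threshold": spec.fd_threshold
                if spec.fd_threshold is not None else "N/A",
                "std_dvars_threshold": spec.std_dvars_threshold
                if spec.std_dvars_threshold is not None else "N/A",
                "compcor_mask": spec.compcor_mask or "N/A",
                "n_compcor": spec.n_compcor
                if spec.n_compcor is not None else "N/A",
                "ica_aroma": spec.ica_aroma,
                "demean": spec.demean,
            }
        )
    return pd.DataFrame(rows)


def _image_path(root: Path, sub: str, task: str, variant: str) -> Path:
    return (
        root / sub / "func" / f"{sub}_task-{task}_desc-{variant}_bold.nii.gz"
    )


def _percentile_ci(values: np.ndarray, rng: np.random.Generator,
                   n_boot: int) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2 or n_boot < 1:
        return np.nan, np.nan
    means = [
        values[rng.integers(0, values.size, values.size)].mean()
        for _ in range(n_boot)
    ]
    return float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5))


def _qcfc_bootstrap_ci(
    edges: np.ndarray,
    pheno: qm.Phenotypes,
    config: qm.MetricConfig,
    distance: np.ndarray,
    rng: np.random.Generator,
    n_boot: int,
) -> dict[str, tuple[float, float]]:
    """Percentile CIs for the edge-level summaries by subject bootstrap."""
    n = edges.shape[0]
    fracs, meds, dms = [], [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        fd = pheno.mean_fd[idx]
        if np.std(fd) == 0:
            continue
        sub = qm.Phenotypes(fd, pheno.age[idx], pheno.sex[idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = qm.qcfc(edges[idx], sub, config)
                fracs.append(res.fraction_significant)
                meds.append(res.median_absolute_r)
                dms.append(qm.dmfc(res.r, distance))
            except (FCBenchError, np.linalg.LinAlgError):
                continue
    def ci(vals):
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            return np.nan, np.nan
        return (float(np.percentile(vals, 2.5)),
                float(np.percentile(vals, 97.5)))
    return {"qcfc_fraction_significant": ci(fracs),
            "qcfc_median_absolute": ci(meds),
            "dmfc": ci(dms)}


def run_benchmark(manifest: RunManifest) -> dict[str, Path]:
    """Run the full benchmark and write all output tables.

    Per-subject failures are logged and the subject skipped for that
    strategy; an empty included set aborts the run.
    Returns a name -> path map of the written files.
    """
    out = manifest.out_dir
    out.mkdir(parents=True, exist_ok=True)
    participants = pd.read_csv(manifest.participants, sep="\t")
    subjects = participants["participant_id"].astype(str).tolist()

    # ---- motion QC -------------------------------------------------------
    decisions: list[QCDecision] = []
    mean_fd: dict[str, float] = {}
    for sub in subjects:
        img = _image_path(manifest.derivatives, sub, manifest.task,
                          "preproc")
        try:
            table, _ = capi.read_confounds_pair(
                img, tr_seconds=manifest.tr_seconds)
        except FCBenchError as exc:
            log.warning("QC: skipping %s (%s)", sub, exc)
            decisions.append(QCDecision(sub, np.nan, np.nan, np.nan, True,
                                        [f"unreadable: {exc}"]))
            continue
        fd = table.frame["framewise_displacement"].to_numpy(dtype=float)
        d = subject_qc(fd, manifest.tr_seconds, subject=sub)
        decisions.append(d)
        if not d.excluded:
            mean_fd[sub] = d.mean_fd
    manifest.included = [d.subject for d in decisions if not d.excluded]
    manifest.excluded = {
        d.subject: "; ".join(d.reasons) for d in decisions if d.excluded
    }
    if not manifest.included:
        raise InputError("motion QC excluded every subject; aborting")
    write_qc_report(decisions, out / "qc_report.tsv")

    info = participants.set_index(participants["participant_id"].astype(str))
    age = np.array([float(info.loc[s, "age"]) for s in manifest.included])
    sex = np.array(
        [SEX_CODING[str(info.loc[s, "sex"])] for s in manifest.included],
        dtype=float,
    )
    fd_vec = np.array([mean_fd[s] for s in manifest.included])
    pheno = None
    if len(manifest.included) >= 5 and np.std(fd_vec) > 0:
        pheno = qm.Phenotypes(fd_vec, age, sex, list(manifest.included))
    else:
        log.warning("too few subjects for motion metrics; QC-FC/DM-FC/"
                    "modularity-motion reported as NaN")

    rng = np.random.default_rng(manifest.seed)
    config = manifest.metric_config
    dof_rows, metric_rows = [], []
    mean_edges_by_strategy: dict[str, list[np.ndarray]] = {
        s: [] for s in manifest.strategies
    }

    for atlas_path, lookup_path in manifest.atlases:
        atlas = sig.Atlas.from_files(atlas_path, lookup_path)
        atlas_name = Path(atlas_path).name.split(".")[0]
        geometry = sig.centers_of_mass(atlas)
        dist_edges = sig.vectorize(
            sig.Connectome(geometry.pairwise_distance, geometry.parcel_ids)
        )
        extractor = (sig.extract_labels if atlas.kind == "labels"
                     else sig.extract_maps)

        for strategy in manifest.strategies:
            spec = capi.get_strategy(strategy)
            variant = ("smoothAROMAnonaggr" if spec.ica_aroma else "preproc")
            edge_rows, q_values, ok_subjects = [], [], []
            for si, sub in enumerate(manifest.included):
                img = _image_path(manifest.derivatives, sub, manifest.task,
                                  variant)
                try:
                    selection, mask = capi.load_confounds_strategy(
                        img, strategy, tr_seconds=manifest.tr_seconds
                    )
                    ts = extractor(img, atlas,
                                   tr_seconds=manifest.tr_seconds)
                    cleaned = sig.clean(ts, selection, mask,
                                        standardize=True)
                    conn = sig.pearson_connectome(cleaned)
                except FCBenchError as exc:
                    log.warning("%s/%s/%s failed: %s", strategy, atlas_name,
                                sub, exc)
                    continue
                edge_rows.append(sig.vectorize(conn))
                q, _ = qm.louvain_q(
                    conn,
                    qm.MetricConfig(
                        alpha=config.alpha,
                        louvain_seed=int(
                            np.random.SeedSequence(
                                (config.louvain_seed, si)
                            ).generate_state(1)[0] % (2 ** 31)
                        ),
                        louvain_negative_scheme=
                        config.louvain_negative_scheme,
                        louvain_runs=config.louvain_runs,
                        louvain_gamma=config.louvain_gamma,
                    ),
                )
                q_values.append(q)
                ok_subjects.append(sub)
                report = qm.dof_loss(selection, mask, ts.n_volumes)
                dof_rows.append(
                    {
                        "strategy": strategy, "atlas": atlas_name,
                        "subject": sub,
                        "n_regressors": report.n_regressors,
                        "cosine": report.cosine,
                        "n_censored": report.n_censored,
                        "total_loss": report.total_loss,
                        "percent_of_scan": report.percent_of_scan,
                    }
                )
            if not edge_rows:
                log.warning("no usable subjects for %s/%s", strategy,
                            atlas_name)
                continue
            edges = np.vstack(edge_rows)
            mean_edges_by_strategy[strategy].append(edges.mean(axis=0))
            q_values = np.asarray(q_values)

            def add(metric, value, ci=(np.nan, np.nan)):
                metric_rows.append(
                    {"strategy": strategy, "atlas": atlas_name,
                     "metric": metric, "value": value,
                     "ci_low": ci[0], "ci_high": ci[1]}
                )

            dof_pct = [r["percent_of_scan"] for r in dof_rows
                       if r["strategy"] == strategy
                       and r["atlas"] == atlas_name]
            add("dof_percent_of_scan", float(np.mean(dof_pct)),
                _percentile_ci(np.asarray(dof_pct), rng, manifest.bootstrap))
            add("mean_offdiag_r", float(np.nanmean(edges)),
                _percentile_ci(np.nanmean(edges, axis=1), rng,
                               manifest.bootstrap))
            add("modularity_q", float(np.mean(q_values)),
                _percentile_ci(q_values, rng, manifest.bootstrap))

            # metrics against motion need the phenotypes of the subjects
            # that actually produced a connectome for this strategy
            if pheno is not None and len(ok_subjects) == len(
                    manifest.included):
                sub_pheno = pheno
            elif len(ok_subjects) >= 5:
                rows = [manifest.included.index(s) for s in ok_subjects]
                sub_pheno = qm.Phenotypes(fd_vec[rows], age[rows],
                                          sex[rows], ok_subjects)
            else:
                sub_pheno = None
            if sub_pheno is not None:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = qm.qcfc(edges, sub_pheno, config)
                    dm = qm.dmfc(res.r, dist_edges)
                    cis = _qcfc_bootstrap_ci(edges, sub_pheno, config,
                                             dist_edges, rng,
                                             manifest.bootstrap)
                    r_mod, p_mod = qm.modularity_motion(q_values, sub_pheno)
                add("qcfc_fraction_significant", res.fraction_significant,
                    cis["qcfc_fraction_significant"])
                add("qcfc_median_absolute", res.median_absolute_r,
                    cis["qcfc_median_absolute"])
                add("dmfc", dm, cis["dmfc"])
                add("modularity_motion_r", r_mod)
                add("modularity_motion_p", p_mod)
            else:
                for m in ("qcfc_fraction_significant",
                          "qcfc_median_absolute", "dmfc",
                          "modularity_motion_r", "modularity_motion_p"):
                    add(m, np.nan)

    paths = {
        "qc_report": out / "qc_report.tsv",
        "dof": out / "dof.tsv",
        "metrics": out / "metrics.tsv",
        "manifest": out / "run_config.json",
    }
    pd.DataFrame(dof_rows).to_csv(paths["dof"], sep="\t", index=False,
                                  float_format="%.10g")
    pd.DataFrame(metric_rows).to_csv(paths["metrics"], sep="\t", index=False,
                                     float_format="%.10g")

    # ---- similarity across strategies (mean over subjects, then atlases) -
    mean_edges = {
        s: np.mean(np.vstack(v), axis=0)
        for s, v in mean_edges_by_strategy.items() if v
    }
    if len(mean_edges) >= 2:
        from .similarity import strategy_similarity

        sim = strategy_similarity(mean_edges)
        sim.to_tsv(out / "similarity_matrix.tsv",
                   out / "similarity_order.tsv")
        paths["similarity_matrix"] = out / "similarity_matrix.tsv"
        paths["similarity_order"] = out / "similarity_order.tsv"

    paths["manifest"].write_text(json.dumps(manifest.echo(), indent=1))
    return paths
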
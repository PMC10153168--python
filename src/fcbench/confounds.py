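"""fMRIPrep confound retrieval.

Parses fMRIPrep-style confound tables (``*_desc-confounds_timeseries.tsv``
plus JSON sidecar) and assembles strategy-specific nuisance-regressor
matrices and volume-censoring sample masks.  Two entry points mirror the
two public APIs: :func:`load_confounds` selects confounds by category
(motion, tissue, global signal, CompCor, ICA-AROMA, cosine high-pass,
non-steady-state, scrubbing), and :func:`load_confounds_strategy` applies a
named parameter bundle from the strategy registry.

Only the fMRIPrep >= 1.4 column dialect is supported: ``trans_x`` ..
``rot_z`` motion bases with ``*_derivative1`` / ``*_power2`` /
``*_derivative1_power2`` expansions, ``cosine00``-style drift terms,
``a_comp_cor_NN`` components described in the sidecar, ``aroma_motion_NN``
columns and ``non_steady_state_outlierNN`` spike indicators.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    FilePairingError,
    InputError,
    MissingConfoundError,
    RegistryError,
    StrategyMismatchError,
)

MOTION_BASE = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
BOLD_SUFFIXES = (
    "_desc-preproc_bold.nii.gz",
    "_desc-preproc_bold.nii",
    "_desc-smoothAROMAnonaggr_bold.nii.gz",
    "_desc-smoothAROMAnonaggr_bold.nii",
)
# expansion suffixes appended to a base column name, in output order
_EXPANSIONS = {
    "basic": ("",),
    "derivatives": ("", "_derivative1"),
    "power2": ("", "_power2"),
    "full": ("", "_derivative1", "_power2", "_derivative1_power2"),
}

VALID_CATEGORIES = frozenset(
    {
        "motion",
        "wm_csf",
        "global_signal",
        "scrub",
        "compcor",
        "ica_aroma",
        "high_pass",
        "non_steady_state",
    }
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ConfoundTable:
    """Per-scan table of named nuisance time courses.

    ``frame`` holds one column per confound with NaN marking the missing
    token (``n/a``); derivative columns may be NaN at volume 0 only.
    """

    frame: pd.DataFrame
    tr_seconds: float = 2.0

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    def validate(self) -> None:
        if self.tr_seconds <= 0:
            raise InputError("tr_seconds must be positive")
        if self.frame.columns.duplicated().any():
            dup = self.frame.columns[self.frame.columns.duplicated()].tolist()
            raise InputError(f"duplicated confound columns: {dup}")
        present = [c for c in MOTION_BASE if c in self.frame.columns]
        if present and len(present) != 6:
            missing = sorted(set(MOTION_BASE) - set(present))
            raise InputError(
                f"incomplete motion base columns; missing {missing}"
            )
        deriv = [c for c in self.frame.columns if c.endswith("_derivative1")
                 or c.endswith("_derivative1_power2")]
        for c in deriv:
            nan_rows = np.flatnonzero(self.frame[c].isna().to_numpy())
            if nan_rows.size and not np.array_equal(nan_rows, [0]):
                raise InputError(
                    f"column {c!r} holds missing values beyond volume 0"
                )


@dataclass
class SidecarMeta:
    """CompCor component descriptions from the confounds JSON sidecar."""

    compcor_components: list[tuple[str, str, float]] = field(
        default_factory=list
    )  # (name, mask, cumulative_variance_explained), sidecar order

    def components_for_mask(self, mask: str) -> list[tuple[str, str, float]]:
        return [c for c in self.compcor_components if c[1] == mask]


@dataclass(frozen=True)
class StrategySpec:
    """Parameter bundle naming one benchmark denoising strategy."""

    name: str
    image_variant: str = "preproc"  # or "smoothAROMAnonaggr"
    high_pass: bool = True
    motion: str | None = None  # none/basic/power2/derivatives/full
    wm_csf: str | None = None
    global_signal: str | None = None
    scrub: int | None = None  # minimal retained contiguous segment length
    fd_threshold: float | None = None  # mm
    std_dvars_threshold: float | None = None
    compcor_mask: str | None = None  # "anat_combined"
    n_compcor: int | str | None = None  # count or "all"
    ica_aroma: bool = False
    demean: bool = True

    def categories(self) -> list[str]:
        cats: list[str] = []
        if self.high_pass:
            cats.append("high_pass")
        if self.motion:
            cats.append("motion")
        if self.wm_csf:
            cats.append("wm_csf")
        if self.global_signal:
            cats.append("global_signal")
        if self.scrub is not None:
            cats.append("scrub")
        if self.compcor_mask:
            cats.append("compcor")
        if self.ica_aroma:
            cats.append("ica_aroma")
        cats.append("non_steady_state")
        return cats


CATEGORY_KEYS = (
    "motion",
    "tissue",
    "global",
    "compcor",
    "aroma",
    "cosine",
    "non_steady_state",
)


@dataclass
class ConfoundSelection:
    """A regressor matrix (volumes x regressors) plus per-category counts."""

    matrix: np.ndarray
    names: list[str]
    counts: dict[str, int] = field(default_factory=dict)
    requires_aroma_image: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim == 1:
            self.matrix = self.matrix.reshape(-1, 1)
        full = {k: 0 for k in CATEGORY_KEYS}
        full.update(self.counts)
        self.counts = full
        if len(self.names) != len(set(self.names)):
            raise InputError("duplicated regressor names in selection")
        if self.matrix.shape[1] != len(self.names):
            raise InputError("selection matrix/name shape mismatch")
        if sum(self.counts.values()) != len(self.names):
            raise InputError("category counts do not sum to column count")

    @property
    def n_regressors(self) -> int:
        return len(self.names)

    @classmethod
    def empty(cls, n_volumes: int) -> "ConfoundSelection":
        return cls(np.empty((n_volumes, 0)), [], {})


@dataclass
class SampleMask:
    """Ordered indices of volumes retained after censoring."""

    kept: np.ndarray
    n_volumes: int

    def __post_init__(self) -> None:
        self.kept = np.asarray(self.kept, dtype=int)
        if self.kept.size and (
            np.any(np.diff(self.kept) <= 0)
            or self.kept[0] < 0
            or self.kept[-1] >= self.n_volumes
        ):
            raise InputError("kept indices must be strictly increasing "
                             "and within [0, n_volumes)")

    @property
    def censored_count(self) -> int:
        return self.n_volumes - self.kept.size

    @classmethod
    def full(cls, n_volumes: int) -> "SampleMask":
        return cls(np.arange(n_volumes), n_volumes)


# ---------------------------------------------------------------------------
# strategy registry (Table 1 / Table 2 bundles)
# ---------------------------------------------------------------------------

PREDEFINED_STRATEGIES: dict[str, StrategySpec] = {
    "simple": StrategySpec("simple", motion="full", wm_csf="basic"),
    "scrubbing": StrategySpec(
        "scrubbing", motion="full", wm_csf="full",
        scrub=5, fd_threshold=0.2, std_dvars_threshold=3.0,
    ),
    "compcor": StrategySpec(
        "compcor", motion="full",
        compcor_mask="anat_combined", n_compcor="all",
    ),
    "ica_aroma": StrategySpec(
        "ica_aroma", image_variant="smoothAROMAnonaggr",
        wm_csf="basic", ica_aroma=True,
    ),
}

BENCHMARK_STRATEGIES: dict[str, StrategySpec] = {
    "baseline": StrategySpec("baseline"),
    "simple": StrategySpec("simple", motion="full", wm_csf="basic"),
    "simple+gsr": StrategySpec(
        "simple+gsr", motion="full", wm_csf="basic", global_signal="basic"
    ),
    "scrubbing.5": StrategySpec(
        "scrubbing.5", motion="full", wm_csf="full",
        scrub=5, fd_threshold=0.5, std_dvars_threshold=3.0,
    ),
    "scrubbing.5+gsr": StrategySpec(
        "scrubbing.5+gsr", motion="full", wm_csf="full",
        global_signal="basic", scrub=5, fd_threshold=0.5,
        std_dvars_threshold=3.0,
    ),
    "scrubbing.2": StrategySpec(
        "scrubbing.2", motion="full", wm_csf="full",
        scrub=5, fd_threshold=0.2, std_dvars_threshold=3.0,
    ),
    "scrubbing.2+gsr": StrategySpec(
        "scrubbing.2+gsr", motion="full", wm_csf="full",
        global_signal="basic", scrub=5, fd_threshold=0.2,
        std_dvars_threshold=3.0,
    ),
    "compcor": StrategySpec(
        "compcor", motion="full",
        compcor_mask="anat_combined", n_compcor="all",
    ),
    "compcor6": StrategySpec(
        "compcor6", motion="full",
        compcor_mask="anat_combined", n_compcor=6,
    ),
    "aroma": StrategySpec(
        "aroma", image_variant="smoothAROMAnonaggr",
        wm_csf="basic", ica_aroma=True,
    ),
}


def get_strategy(name: str) -> StrategySpec:
    """Look up a registered strategy (benchmark names take precedence)."""
    if name in BENCHMARK_STRATEGIES:
        return BENCHMARK_STRATEGIES[name]
    if name in PREDEFINED_STRATEGIES:
        return PREDEFINED_STRATEGIES[name]
    valid = sorted(set(BENCHMARK_STRATEGIES) | set(PREDEFINED_STRATEGIES))
    raise RegistryError(f"unknown strategy {name!r}; valid names: {valid}")


# ---------------------------------------------------------------------------
# file pairing and parsing
# ---------------------------------------------------------------------------


def infer_image_variant(image_path: str | Path) -> str:
    name = Path(image_path).name
    if "_desc-smoothAROMAnonaggr_bold" in name:
        return "smoothAROMAnonaggr"
    return "preproc"


def confounds_path_for(image_path: str | Path) -> Path:
    """Expected sibling confounds TSV for a preprocessed BOLD path."""
    image_path = Path(image_path)
    name = image_path.name
    for suffix in BOLD_SUFFIXES:
        if name.endswith(suffix):
            stem = name[: -len(suffix)]
            return image_path.with_name(stem + "_desc-confounds_timeseries.tsv")
    raise InputError(
        f"{image_path} does not end with an accepted BOLD suffix "
        f"{BOLD_SUFFIXES}"
    )


def read_confounds_pair(
    image_path: str | Path, tr_seconds: float = 2.0
) -> tuple[ConfoundTable, SidecarMeta]:
    """Locate and parse the confounds TSV (+ JSON sidecar) for a BOLD image.

    Raises :class:`FilePairingError` naming the expected TSV path when the
    sibling file is missing, and :class:`InputError` on bad suffixes.
    """
    tsv = confounds_path_for(image_path)
    if not tsv.exists():
        raise FilePairingError(
            f"no confounds file for {image_path}; expected {tsv}"
        )
    frame = pd.read_csv(tsv, sep="\t", na_values=["n/a"])
    table = ConfoundTable(frame=frame, tr_seconds=tr_seconds)
    table.validate()

    sidecar = SidecarMeta()
    json_path = tsv.with_suffix(".json")
    if json_path.exists():
        meta = json.loads(json_path.read_text())
        comps = []
        for name, entry in meta.items():
            if not isinstance(entry, dict) or "Mask" not in entry:
                continue
            comps.append(
                (
                    name,
                    str(entry["Mask"]),
                    float(entry.get("CumulativeVarianceExplained", np.nan)),
                )
            )
        # sanity: cumulative variance non-decreasing within each mask group
        for mask in {c[1] for c in comps}:
            cum = [c[2] for c in comps if c[1] == mask]
            finite = [v for v in cum if np.isfinite(v)]
            if any(b < a - 1e-12 for a, b in zip(finite, finite[1:])):
                raise InputError(
                    f"cumulative variance not non-decreasing for mask {mask!r}"
                )
        sidecar = SidecarMeta(compcor_components=comps)
    return table, sidecar


def write_confounds_table(table: ConfoundTable, tsv_path: str | Path) -> None:
    """Write a table back to fMRIPrep TSV dialect ('n/a' missing token)."""
    table.frame.to_csv(tsv_path, sep="\t", index=False, na_rep="n/a")


# ---------------------------------------------------------------------------
# per-category selections
# ---------------------------------------------------------------------------


def _expand(table: ConfoundTable, bases: Sequence[str], option: str,
            category_key: str) -> ConfoundSelection:
    if option not in _EXPANSIONS:
        raise InputError(f"unknown expansion option {option!r}")
    names: list[str] = []
    for suffix in _EXPANSIONS[option]:
        names.extend(base + suffix for base in bases)
    missing = [n for n in names if n not in table.frame.columns]
    if missing:
        raise MissingConfoundError(
            f"confound columns absent from table: {missing}"
        )
    matrix = table.frame[names].to_numpy(dtype=float)
    # derivative columns hold n/a at volume 0: impute to 0 (D-choice: keeps
    # the first volume usable; the value is demeaned away downstream)
    matrix = np.where(np.isnan(matrix), 0.0, matrix)
    return ConfoundSelection(matrix, names, {category_key: len(names)})


def expand_motion(table: ConfoundTable, option: str) -> ConfoundSelection:
    """Select the 6 rigid-body motion parameters with optional expansion.

    basic -> 6 columns, derivatives/power2 -> 12, full -> 24.
    """
    for c in MOTION_BASE:
        if c not in table.frame.columns:
            raise MissingConfoundError(f"motion base column {c!r} absent")
    return _expand(table, MOTION_BASE, option, "motion")


def select_tissue(
    table: ConfoundTable, category: str, option: str
) -> ConfoundSelection:
    """Select WM/CSF mean signals or the global signal, with expansion."""
    if category == "wm_csf":
        bases, key = ("csf", "white_matter"), "tissue"
    elif category == "global_signal":
        bases, key = ("global_signal",), "global"
    else:
        raise InputError(f"unknown tissue category {category!r}")
    return _expand(table, bases, option, key)


def select_compcor(
    table: ConfoundTable,
    sidecar: SidecarMeta,
    mask: str = "anat_combined",
    n: int | str = "all",
) -> ConfoundSelection:
    """Select anatomical CompCor components from the combined WM+CSF mask.

    ``n="all"`` keeps the smallest prefix (in sidecar order) whose cumulative
    variance explained reaches 50%; an integer keeps the first ``n``.
    """
    if mask != "anat_combined":
        raise InputError(f"unsupported compcor mask {mask!r}")
    comps = sidecar.components_for_mask("combined")
    if not comps:
        raise MissingConfoundError(
            "no combined-mask CompCor components in sidecar"
        )
    if n == "all":
        chosen: list[str] = []
        for name, _, cumvar in comps:
            chosen.append(name)
            if cumvar >= 0.50:
                break
        else:
            # ladder never reaches 50%: keep everything available
            pass
    else:
        n = int(n)
        if len(comps) < n:
            raise MissingConfoundError(
                f"requested {n} CompCor components, sidecar lists "
                f"{len(comps)} for the combined mask"
            )
        chosen = [name for name, _, _ in comps[:n]]
    missing = [c for c in chosen if c not in table.frame.columns]
    if missing:
        raise MissingConfoundError(
            f"CompCor columns absent from table: {missing}"
        )
    matrix = table.frame[chosen].to_numpy(dtype=float)
    return ConfoundSelection(matrix, chosen, {"compcor": len(chosen)})


def select_aroma(
    table: ConfoundTable,
    image_variant: str = "smoothAROMAnonaggr",
    mode: str = "nonaggressive",
) -> ConfoundSelection:
    """ICA-AROMA handling.

    Non-aggressive mode (the benchmark ``aroma`` strategy) consumes the
    pre-denoised ``smoothAROMAnonaggr`` image, so zero AROMA columns are
    returned and the selection is flagged as requiring that image variant.
    Aggressive mode selects the ``aroma_motion_*`` columns for regression.
    """
    if mode == "nonaggressive":
        if image_variant != "smoothAROMAnonaggr":
            raise StrategyMismatchError(
                "ICA-AROMA strategy requires the desc-smoothAROMAnonaggr "
                f"image variant, got {image_variant!r}"
            )
        sel = ConfoundSelection.empty(table.n_volumes)
        sel.requires_aroma_image = True
        return sel
    cols = [c for c in table.frame.columns
            if re.fullmatch(r"aroma_motion_\d+", c)]
    if not cols:
        raise MissingConfoundError("no aroma_motion_* columns in table")
    matrix = table.frame[cols].to_numpy(dtype=float)
    return ConfoundSelection(matrix, cols, {"aroma": len(cols)})


def select_high_pass(
    table: ConfoundTable, required: bool = True
) -> ConfoundSelection:
    """All discrete-cosine drift columns (regression-based high-pass)."""
    cols = [c for c in table.frame.columns if re.fullmatch(r"cosine\d+", c)]
    if required and not cols:
        raise MissingConfoundError("high_pass requested but no cosine* "
                                   "columns present")
    matrix = table.frame[cols].to_numpy(dtype=float) if cols else np.empty(
        (table.n_volumes, 0))
    return ConfoundSelection(matrix, cols, {"cosine": len(cols)})


def select_non_steady_state(table: ConfoundTable) -> ConfoundSelection:
    """All one-hot non-steady-state outlier columns (may be empty)."""
    cols = [
        c for c in table.frame.columns
        if re.fullmatch(r"non_steady_state_outlier\d+", c)
    ]
    if not cols:
        return ConfoundSelection.empty(table.n_volumes)
    matrix = table.frame[cols].to_numpy(dtype=float)
    return ConfoundSelection(matrix, cols, {"non_steady_state": len(cols)})


# ---------------------------------------------------------------------------
# sample mask
# ---------------------------------------------------------------------------


def _filter_short_runs(retained: np.ndarray, min_segment: int) -> np.ndarray:
    """Censor maximal runs of contiguous retained volumes < min_segment."""
    retained = retained.copy()
    n = retained.size
    i = 0
    while i < n:
        if not retained[i]:
            i += 1
            continue
        j = i
        while j < n and retained[j]:
            j += 1
        if j - i < min_segment:
            retained[i:j] = False
        i = j
    return retained


def non_steady_state_volumes(table: ConfoundTable) -> np.ndarray:
    """Volume indices flagged by any non_steady_state_outlier column."""
    sel = select_non_steady_state(table)
    if sel.n_regressors == 0:
        return np.empty(0, dtype=int)
    flagged = np.nan_to_num(sel.matrix).sum(axis=1) > 0
    return np.flatnonzero(flagged)


def build_sample_mask(
    table: ConfoundTable,
    fd_threshold: float,
    std_dvars_threshold: float,
    min_segment: int,
) -> SampleMask:
    """Scrubbing mask: censor high-motion volumes and short segments.

    A volume is censored when FD > ``fd_threshold`` (strict) or standardized
    DVARS > ``std_dvars_threshold``; a missing value at volume 0 never
    censors.  After thresholding, maximal retained runs shorter than
    ``min_segment`` are censored too.  Non-steady-state volumes are always
    censored.
    """
    if fd_threshold <= 0 or std_dvars_threshold <= 0:
        raise InputError("censoring thresholds must be positive")
    for col in ("framewise_displacement", "std_dvars"):
        if col not in table.frame.columns:
            raise MissingConfoundError(f"column {col!r} absent; cannot scrub")
    fd = table.frame["framewise_displacement"].to_numpy(dtype=float)
    dvars = table.frame["std_dvars"].to_numpy(dtype=float)
    # NaN at volume 0 compares False, so a missing value never censors
    with np.errstate(invalid="ignore"):
        censored = (fd > fd_threshold) | (dvars > std_dvars_threshold)
    nss = non_steady_state_volumes(table)
    censored[nss] = True
    retained = _filter_short_runs(~censored, min_segment)
    return SampleMask(np.flatnonzero(retained), table.n_volumes)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def _concat(
    selections: list[ConfoundSelection], n_volumes: int
) -> ConfoundSelection:
    if not selections:
        return ConfoundSelection.empty(n_volumes)
    matrix = np.hstack([s.matrix for s in selections])
    names = [n for s in selections for n in s.names]
    counts: dict[str, int] = {}
    for s in selections:
        for k, v in s.counts.items():
            counts[k] = counts.get(k, 0) + v
    out = ConfoundSelection(matrix, names, counts)
    out.requires_aroma_image = any(s.requires_aroma_image for s in selections)
    return out


def _demean(selection: ConfoundSelection, mask: SampleMask) -> None:
    """Demean confound columns over the retained volumes (in place)."""
    if selection.n_regressors == 0 or mask.kept.size == 0:
        return
    means = selection.matrix[mask.kept].mean(axis=0)
    selection.matrix = selection.matrix - means


def load_confounds(
    image_path,
    strategy: Sequence[str],
    *,
    motion: str = "full",
    wm_csf: str = "basic",
    global_signal: str = "basic",
    scrub: int = 5,
    fd_threshold: float = 0.2,
    std_dvars_threshold: float = 3.0,
    compcor: str = "anat_combined",
    n_compcor: int | str = "all",
    ica_aroma: str = "nonaggressive",
    demean: bool = True,
    tr_seconds: float = 2.0,
):
    """Category-driven confound retrieval for one path or a list of paths.

    Returns ``(ConfoundSelection, SampleMask)``, or a list of such pairs for
    list input.  Non-steady-state volumes are folded into the sample mask in
    every strategy so that initial-volume handling is identical across
    strategies; the one-hot spike columns are never returned as regressors.
    """
    if isinstance(image_path, (list, tuple)):
        return [
            load_confounds(
                p, strategy, motion=motion, wm_csf=wm_csf,
                global_signal=global_signal, scrub=scrub,
                fd_threshold=fd_threshold,
                std_dvars_threshold=std_dvars_threshold, compcor=compcor,
                n_compcor=n_compcor, ica_aroma=ica_aroma, demean=demean,
                tr_seconds=tr_seconds,
            )
            for p in image_path
        ]

    unknown = set(strategy) - VALID_CATEGORIES
    if unknown:
        raise InputError(
            f"unknown strategy categories {sorted(unknown)}; "
            f"valid: {sorted(VALID_CATEGORIES)}"
        )
    table, sidecar = read_confounds_pair(image_path, tr_seconds=tr_seconds)
    variant = infer_image_variant(image_path)

    selections: list[ConfoundSelection] = []

    def run(category, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (MissingConfoundError, InputError,
                StrategyMismatchError) as exc:
            raise type(exc)(f"[{category}] {exc}") from exc

    if "high_pass" in strategy:
        selections.append(run("high_pass", select_high_pass, table))
    if "motion" in strategy:
        selections.append(run("motion", expand_motion, table, motion))
    if "wm_csf" in strategy:
        selections.append(run("wm_csf", select_tissue, table, "wm_csf",
                              wm_csf))
    if "global_signal" in strategy:
        selections.append(
            run("global_signal", select_tissue, table, "global_signal",
                global_signal)
        )
    if "compcor" in strategy:
        selections.append(
            run("compcor", select_compcor, table, sidecar, compcor, n_compcor)
        )
    if "ica_aroma" in strategy:
        selections.append(
            run("ica_aroma", select_aroma, table, variant, ica_aroma)
        )

    if "scrub" in strategy:
        mask = build_sample_mask(
            table, fd_threshold, std_dvars_threshold, scrub
        )
    else:
        retained = np.ones(table.n_volumes, dtype=bool)
        retained[non_steady_state_volumes(table)] = False
        mask = SampleMask(np.flatnonzero(retained), table.n_volumes)

    selection = _concat(selections, table.n_volumes)
    if demean:
        _demean(selection, mask)
    return selection, mask


def load_confounds_strategy(image_path, name: str, **overrides):
    """Apply a registered strategy bundle; ``+gsr`` names add global signal.

    Equivalent to :func:`load_confounds` with the Table-driven parameter
    bundle.  Keyword overrides replace individual bundle fields.
    """
    if isinstance(image_path, (list, tuple)):
        return [load_confounds_strategy(p, name, **overrides)
                for p in image_path]
    tr = overrides.pop("tr_seconds", None)
    spec = get_strategy(name)
    if overrides:
        spec = StrategySpec(**{**spec.__dict__, **overrides})
    variant = infer_image_variant(image_path)
    if spec.ica_aroma and variant != "smoothAROMAnonaggr":
        raise StrategyMismatchError(
            f"strategy {name!r} requires a desc-smoothAROMAnonaggr image, "
            f"got {variant!r} variant: {image_path}"
        )
    if not spec.ica_aroma and variant == "smoothAROMAnonaggr":
        raise StrategyMismatchError(
            f"strategy {name!r} expects the desc-preproc image, got the "
            f"AROMA-denoised variant: {image_path}"
        )
    kwargs: dict = {"demean": spec.demean}
    if spec.motion:
        kwargs["motion"] = spec.motion
    if spec.wm_csf:
        kwargs["wm_csf"] = spec.wm_csf
    if spec.global_signal:
        kwargs["global_signal"] = spec.global_signal
    if spec.scrub is not None:
        kwargs.update(
            scrub=spec.scrub,
            fd_threshold=spec.fd_threshold,
            std_dvars_threshold=spec.std_dvars_threshold,
        )
    if spec.compcor_mask:
        kwargs.update(compcor=spec.compcor_mask, n_compcor=spec.n_compcor)
    if tr is not None:
        kwargs["tr_seconds"] = tr
    cats = [c for c in spec.categories() if c != "non_steady_state"]
    return load_confounds(image_path, cats, **kwargs)
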
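"""Framewise displacement and subject-level motion quality control.

FD at volume t sums the absolute volume-to-volume changes of the three
translations (mm) and the three rotations, the latter converted to arc
length on a 50 mm sphere.  The recomputed FD is used for validation and
synthetic data; pipeline metrics consume the shipped
``framewise_displacement`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

DEFAULT_ROTATION_RADIUS_MM = 50.0


@dataclass
class MotionParams:
    """Rigid-body parameters: translations (mm) and rotations (radians)."""

    translations: np.ndarray  # volumes x 3, mm
    rotations: np.ndarray  # volumes x 3, radians
    rotation_radius: float = DEFAULT_ROTATION_RADIUS_MM

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(
            np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations,
                                                  dtype=float))
        if self.translations.shape != self.rotations.shape or \
                self.translations.shape[1] != 3:
            raise InputError("translations/rotations must both be "
                             "volumes x 3")
        if self.rotation_radius <= 0:
            raise InputError("rotation radius must be positive")
        if not (np.isfinite(self.translations).all()
                and np.isfinite(self.rotations).all()):
            raise InputError("motion parameters must be finite")


def framewise_displacement(m: MotionParams) -> np.ndarray:
    """FD series in mm; FD(0) = 0 by convention."""
    if m.translations.shape[0] < 2:
        raise InputError("need at least 2 volumes for FD")
    dt = np.abs(np.diff(m.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(m.rotations, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + m.rotation_radius * dr])
    return fd


@dataclass
class QCDecision:
    subject: str
    mean_fd: float
    pct_censored: float
    minutes_retained: float
    excluded: bool
    reasons: list[str] = field(default_factory=list)


def _scrub_retained(fd: np.ndarray, fd_threshold: float,
                    min_segment: int) -> np.ndarray:
    """FD-only censoring with short-segment removal (boolean retained)."""
    from .confounds import _filter_short_runs

    with np.errstate(invalid="ignore"):
        retained = ~(fd > fd_threshold)
    return _filter_short_runs(retained, min_segment)


def subject_qc(
    fd: np.ndarray,
    tr_seconds: float,
    subject: str = "",
    mean_fd_max: float = 0.25,
    scrub_fd: float = 0.2,
    max_pct: float = 80.0,
    min_minutes: float = 1.0,
    min_segment: int = 5,
) -> QCDecision:
    """Exclusion rule: mean FD > 0.25 mm, > 80% of volumes censored when
    scrubbing at 0.2 mm (short-segment removal included), or less than one
    minute of scan retained."""
    fd = np.asarray(fd, dtype=float)
    if tr_seconds <= 0:
        raise InputError("tr_seconds must be positive")
    mean_fd = float(np.nanmean(fd))
    retained = _scrub_retained(np.nan_to_num(fd), scrub_fd, min_segment)
    pct = 100.0 * (1 - retained.mean())
    minutes = retained.sum() * tr_seconds / 60.0
    reasons = []
    if mean_fd > mean_fd_max:
        reasons.append(f"mean_fd {mean_fd:.3f} > {mean_fd_max}")
    if pct > max_pct:
        reasons.append(f"pct_censored {pct:.1f} > {max_pct}")
    if minutes < min_minutes:
        reasons.append(f"minutes_retained {minutes:.2f} < {min_minutes}")
    return QCDecision(
        subject=subject,
        mean_fd=mean_fd,
        pct_censored=pct,
        minutes_retained=minutes,
        excluded=bool(reasons),
        reasons=reasons,
    )


def write_qc_report(decisions: list[QCDecision], path: str | Path) -> None:
    rows = [
        {
            "subject": d.subject,
            "mean_fd": d.mean_fd,
            "pct_censored": d.pct_censored,
            "minutes_retained": d.minutes_retained,
            "excluded": d.excluded,
            "reasons": "; ".join(d.reasons),
        }
        for d in decisions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")
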
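"""Head-motion summaries from rigid-body fMRI realignment parameters.

Realignment of an fMRI time series (SPM, FSL) yields six parameters per
frame — three translations and three rotations — describing each frame's
position relative to the first (reference) frame.  This module parses
those files, converts parameters to homogeneous rigid-body transforms,
and summarises the per-frame displacement with the Jenkinson RMS metric:
the root-mean-square displacement, over a brain-sized ball of radius R,
induced by the relative transform between consecutive frames,

    d = sqrt( (1/5) R^2 tr(A'A) + (t + A x_c)'(t + A x_c) ),

where [A t; 0 0] = T2 T1^-1 - I, x_c is the centre of the ball and
R = 80 mm by default.  Subjects are flagged for gross motion when any
frame exceeds 3 mm translation or 2 degrees rotation on any axis
(strict inequality), and optionally as >4-sd outliers on the log scale
relative to a cohort.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RigidMotionSeries",
    "AffineTransform",
    "MotionSummary",
    "read_realignment_series",
    "write_realignment_series",
    "params_to_affine",
    "jenkinson_displacement",
    "framewise_series",
    "reference_series",
    "gross_motion_flag",
    "summarize_subject_motion",
    "summarize_cohort",
    "MotionSummarizer",
]

#: Default brain radius in millimetres for the RMS displacement metric.
BRAIN_RADIUS_MM = 80.0
#: Default centre of the ball (scanner-origin coordinates).
DEFAULT_CENTER = (0.0, 0.0, 0.0)
#: Gross-motion thresholds: >3 mm translation or >2 degrees rotation.
TRANS_THRESH_MM = 3.0
ROT_THRESH_DEG = 2.0
#: Floor applied before the log transform for (synthetic) zero-motion traces.
LOG_FLOOR_MM = 1e-6
#: |rotation| above this (radians) triggers a dialect sanity warning.
ROTATION_SANITY_RAD = 0.5


class MotionParseError(ValueError):
    """Raised for malformed realignment parameter files."""


@dataclass
class RigidMotionSeries:
    """Six-parameter rigid-body motion trace for one subject.

    Translations are in millimetres, rotations in radians; frame 1 is the
    realignment reference, so its parameters are all zero.
    """

    subject_id: str
    translations: np.ndarray  # (n_frames, 3) mm
    rotations: np.ndarray  # (n_frames, 3) rad
    dialect: str = "spm"

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        if self.translations.shape != self.rotations.shape or self.translations.ndim != 2:
            raise ValueError("translations and rotations must both be (n_frames, 3)")
        if self.n_frames < 2:
            raise ValueError("a motion series needs at least 2 frames")
        if not (np.isfinite(self.translations).all() and np.isfinite(self.rotations).all()):
            raise ValueError("motion parameters must be finite")
        if np.abs(self.rotations).max() > ROTATION_SANITY_RAD:
            warnings.warn(
                f"subject {self.subject_id}: |rotation| exceeds {ROTATION_SANITY_RAD} rad; "
                "file may contain degrees or a mixed-up dialect",
                stacklevel=2,
            )

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]


@dataclass(frozen=True)
class AffineTransform:
    """4x4 homogeneous rigid-body transform (translation column in mm)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("bottom row must be (0,0,0,1)")
        R = m[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation block must be orthonormal")

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]


@dataclass
class MotionSummary:
    """Per-subject displacement summary and exclusion flags."""

    subject_id: str
    n_frames: int
    mean_displacement: float  # mm
    log_displacement: float  # ln(mean_displacement)
    max_abs_translation: float  # mm
    max_abs_rotation: float  # degrees
    gross_motion: bool
    sd_outlier: bool = False


def read_realignment_series(
    path: str | Path, dialect: str = "spm", subject_id: str | None = None
) -> RigidMotionSeries:
    """Parse an SPM ``rp_*.txt`` or FSL ``.par`` realignment parameter file.

    SPM columns are translations (mm) then rotations (rad); FSL is
    rotations (rad) then translations (mm).
    """
    if dialect not in ("spm", "fsl"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'spm' or 'fsl'")
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise MotionParseError(
                    f"{path}, line {lineno}: expected 6 fields, found {len(fields)}"
                )
            try:
                rows.append([float(f) for f in fields])
            except ValueError as exc:
                raise MotionParseError(f"{path}, line {lineno}: non-numeric field") from exc
    if len(rows) < 2:
        raise MotionParseError(f"{path}: found {len(rows)} frames; need at least 2")
    arr = np.asarray(rows, dtype=float)
    if dialect == "spm":
        trans, rot = arr[:, :3], arr[:, 3:]
    else:
        rot, trans = arr[:, :3], arr[:, 3:]
    sid = subject_id if subject_id is not None else _subject_id_from_path(path)
    return RigidMotionSeries(subject_id=sid, translations=trans, rotations=rot, dialect=dialect)


def _subject_id_from_path(path: Path) -> str:
    stem = path.stem
    if stem.startswith("rp_"):
        stem = stem[3:]
    return stem


def write_realignment_series(series: RigidMotionSeries, path: str | Path) -> None:
    """Write a series back out in its own dialect (round-trip safe)."""
    if series.dialect == "spm":
        arr = np.hstack([series.translations, series.rotations])
    else:
        arr = np.hstack([series.rotations, series.translations])
    np.savetxt(path, arr, fmt="%.17e")  # full double precision: round-trip exact


def params_to_affine(translation: Sequence[float], rotation: Sequence[float]) -> AffineTransform:
    """Build T = Translate(t) @ Rx @ Ry @ Rz (SPM convention, right-handed)."""
    t = np.asarray(translation, dtype=float)
    r = np.asarray(rotation, dtype=float)
    if t.shape != (3,) or r.shape != (3,):
        raise ValueError("translation and rotation must be 3-vectors")
    if not (np.isfinite(t).all() and np.isfinite(r).all()):
        raise ValueError("parameters must be finite")
    cx, sx = math.cos(r[0]), math.sin(r[0])
    cy, sy = math.cos(r[1]), math.sin(r[1])
    cz, sz = math.cos(r[2]), math.sin(r[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    m = np.eye(4)
    m[:3, :3] = Rx @ Ry @ Rz
    m[:3, 3] = t
    return AffineTransform(m)


def jenkinson_displacement(
    T1: AffineTransform,
    T2: AffineTransform,
    radius: float = BRAIN_RADIUS_MM,
    center: Sequence[float] = DEFAULT_CENTER,
) -> float:
    """RMS displacement (mm) over the radius-R ball under T2 relative to T1.

    Equals the RMS of |(T2 T1^-1 - I) x| over x uniform in the ball centred
    at ``center``; reduces to |t| exactly for a pure relative translation.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    m1, m2 = T1.matrix, T2.matrix
    det = np.linalg.det(m1)
    if abs(det) < 1e-12:
        raise np.linalg.LinAlgError("T1 is singular")
    rel = m2 @ np.linalg.inv(m1) - np.eye(4)
    A = rel[:3, :3]
    t = rel[:3, 3]
    xc = np.asarray(center, dtype=float)
    v = t + A @ xc
    val = (radius**2 / 5.0) * np.trace(A.T @ A) + v @ v
    return float(np.sqrt(max(val, 0.0)))


def _batch_matrices(series: RigidMotionSeries) -> np.ndarray:
    """(n_frames, 4, 4) absolute transforms, T = Translate(t) Rx Ry Rz."""
    t, r = series.translations, series.rotations
    n = series.n_frames
    cx, sx = np.cos(r[:, 0]), np.sin(r[:, 0])
    cy, sy = np.cos(r[:, 1]), np.sin(r[:, 1])
    cz, sz = np.cos(r[:, 2]), np.sin(r[:, 2])
    Rx = np.zeros((n, 3, 3))
    Rx[:, 0, 0] = 1
    Rx[:, 1, 1], Rx[:, 1, 2] = cx, -sx
    Rx[:, 2, 1], Rx[:, 2, 2] = sx, cx
    Ry = np.zeros((n, 3, 3))
    Ry[:, 1, 1] = 1
    Ry[:, 0, 0], Ry[:, 0, 2] = cy, sy
    Ry[:, 2, 0], Ry[:, 2, 2] = -sy, cy
    Rz = np.zeros((n, 3, 3))
    Rz[:, 2, 2] = 1
    Rz[:, 0, 0], Rz[:, 0, 1] = cz, -sz
    Rz[:, 1, 0], Rz[:, 1, 1] = sz, cz
    R = Rx @ Ry @ Rz
    M = np.tile(np.eye(4), (n, 1, 1))
    M[:, :3, :3] = R
    M[:, :3, 3] = t
    return M


def _batch_displacement(M1: np.ndarray, M2: np.ndarray, radius: float, center) -> np.ndarray:
    """Vectorized metric for aligned stacks of rigid transforms."""
    R1 = M1[:, :3, :3]
    t1 = M1[:, :3, 3]
    inv1 = np.tile(np.eye(4), (len(M1), 1, 1))
    R1t = np.swapaxes(R1, 1, 2)
    inv1[:, :3, :3] = R1t
    inv1[:, :3, 3] = -np.einsum("nij,nj->ni", R1t, t1)
    rel = M2 @ inv1 - np.eye(4)
    A = rel[:, :3, :3]
    tv = rel[:, :3, 3]
    xc = np.asarray(center, dtype=float)
    v = tv + np.einsum("nij,j->ni", A, xc)
    vals = (radius**2 / 5.0) * np.einsum("nij,nij->n", A, A) + np.einsum("ni,ni->n", v, v)
    return np.sqrt(np.clip(vals, 0.0, None))


def framewise_series(
    series: RigidMotionSeries,
    radius: float = BRAIN_RADIUS_MM,
    center: Sequence[float] = DEFAULT_CENTER,
) -> np.ndarray:
    """Displacement between consecutive frames; length ``n_frames - 1``.

    Frame parameters describe position relative to the reference frame;
    consecutive displacements are computed on the composed relative
    transform T_{i+1} T_i^-1.
    """
    M = _batch_matrices(series)
    return _batch_displacement(M[:-1], M[1:], radius, center)


def reference_series(
    series: RigidMotionSeries,
    radius: float = BRAIN_RADIUS_MM,
    center: Sequence[float] = DEFAULT_CENTER,
) -> np.ndarray:
    """Displacement of every frame from the reference frame (alternative summary)."""
    M = _batch_matrices(series)
    eye = np.tile(np.eye(4), (series.n_frames - 1, 1, 1))
    return _batch_displacement(eye, M[1:], radius, center)


def gross_motion_flag(
    series: RigidMotionSeries,
    trans_thresh: float = TRANS_THRESH_MM,
    rot_thresh: float = ROT_THRESH_DEG,
) -> bool:
    """True iff any |translation| > 3 mm or |rotation| > 2 deg on any axis.

    Thresholds are strict, on parameters relative to the reference frame.
    """
    rot_thresh_rad = math.radians(rot_thresh)
    return bool(
        (np.abs(series.translations) > trans_thresh).any()
        or (np.abs(series.rotations) > rot_thresh_rad).any()
    )


def summarize_subject_motion(
    series: RigidMotionSeries,
    cohort_log_values: Sequence[float] | None = None,
    radius: float = BRAIN_RADIUS_MM,
    center: Sequence[float] = DEFAULT_CENTER,
    trans_thresh: float = TRANS_THRESH_MM,
    rot_thresh: float = ROT_THRESH_DEG,
    statistic: str = "mean",
) -> MotionSummary:
    """Summarise one subject: mean framewise displacement, its natural log, flags.

    ``sd_outlier`` is informative only (the flagged subject stays in the
    analysis); it is set when the log value lies more than 4 cohort
    standard deviations from the cohort mean.
    """
    fw = framewise_series(series, radius=radius, center=center)
    if statistic == "mean":
        disp = float(np.mean(fw))
    elif statistic == "median":
        disp = float(np.median(fw))
    else:
        raise ValueError("statistic must be 'mean' or 'median'")
    if disp <= LOG_FLOOR_MM:
        warnings.warn(
            f"subject {series.subject_id}: displacement {disp:g} mm at/below floor; "
            f"log computed on {LOG_FLOOR_MM} mm",
            stacklevel=2,
        )
    log_disp = float(np.log(max(disp, LOG_FLOOR_MM)))
    sd_outlier = False
    if cohort_log_values is not None:
        cohort = np.asarray(cohort_log_values, dtype=float)
        mu, sd = cohort.mean(), cohort.std(ddof=1)
        if sd > 0:
            sd_outlier = bool(abs(log_disp - mu) > 4.0 * sd)
    return MotionSummary(
        subject_id=series.subject_id,
        n_frames=series.n_frames,
        mean_displacement=disp,
        log_displacement=log_disp,
        max_abs_translation=float(np.abs(series.translations).max()),
        max_abs_rotation=float(np.degrees(np.abs(series.rotations).max())),
        gross_motion=gross_motion_flag(series, trans_thresh=trans_thresh, rot_thresh=rot_thresh),
        sd_outlier=sd_outlier,
    )


def summarize_cohort(
    series_list: Iterable[RigidMotionSeries],
    radius: float = BRAIN_RADIUS_MM,
    center: Sequence[float] = DEFAULT_CENTER,
    trans_thresh: float = TRANS_THRESH_MM,
    rot_thresh: float = ROT_THRESH_DEG,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Summarise a cohort; the 4-sd outlier flag uses the cohort's own logs."""
    summaries = [
        summarize_subject_motion(
            s,
            radius=radius,
            center=center,
            trans_thresh=trans_thresh,
            rot_thresh=rot_thresh,
            statistic=statistic,
        )
        for s in series_list
    ]
    logs = np.array([s.log_displacement for s in summaries])
    if len(logs) >= 3:
        mu, sd = logs.mean(), logs.std(ddof=1)
        if sd > 0:
            for s in summaries:
                s.sd_outlier = bool(abs(s.log_displacement - mu) > 4.0 * sd)
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in summaries],
            "n_frames": [s.n_frames for s in summaries],
            "mean_displacement_mm": [s.mean_displacement for s in summaries],
            "log_displacement": [s.log_displacement for s in summaries],
            "max_abs_translation_mm": [s.max_abs_translation for s in summaries],
            "max_abs_rotation_deg": [s.max_abs_rotation for s in summaries],
            "gross_motion": [s.gross_motion for s in summaries],
            "sd_outlier": [s.sd_outlier for s in summaries],
        }
    )


class MotionSummarizer:
    """Transformer turning motion series (or files) into a summary table.

    Parameters
    ----------
    radius : float
        Brain radius in mm for the RMS displacement metric.
    center : tuple of float
        Centre of the ball, scanner coordinates (mm).
    trans_thresh, rot_thresh : float
        Gross-motion thresholds in mm and degrees (strict inequalities).
    statistic : str
        Per-subject summary of the framewise series ('mean' or 'median').
    dialect : str
        File dialect used when transforming paths ('spm' or 'fsl').
    """

    def __init__(
        self,
        radius: float = BRAIN_RADIUS_MM,
        center: tuple = DEFAULT_CENTER,
        trans_thresh: float = TRANS_THRESH_MM,
        rot_thresh: float = ROT_THRESH_DEG,
        statistic: str = "mean",
        dialect: str = "spm",
    ):
        self.radius = radius
        self.center = center
        self.trans_thresh = trans_thresh
        self.rot_thresh = rot_thresh
        self.statistic = statistic
        self.dialect = dialect

    def get_params(self, deep: bool = True) -> dict:
        return {
            "radius": self.radius,
            "center": self.center,
            "trans_thresh": self.trans_thresh,
            "rot_thresh": self.rot_thresh,
            "statistic": self.statistic,
            "dialect": self.dialect,
        }

    def set_params(self, **params) -> "MotionSummarizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "MotionSummarizer":
        self.n_subjects_ = len(list(X))
        return self

    def transform(self, X) -> pd.DataFrame:
        series = [
            x
            if isinstance(x, RigidMotionSeries)
            else read_realignment_series(x, dialect=self.dialect)
            for x in X
        ]
        return summarize_cohort(
            series,
            radius=self.radius,
            center=self.center,
            trans_thresh=self.trans_thresh,
            rot_thresh=self.rot_thresh,
            statistic=self.statistic,
        )

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
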
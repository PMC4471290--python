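"""Head-motion summaries and subject exclusion rules.

Exclusion thresholds follow the common rfMRI quality-control practice of
dropping a scan when maximum translation exceeds 3 mm, maximum rotation
exceeds 3 degrees, or mean frame-wise displacement exceeds 0.35 mm; all
three comparisons are strict, so a subject sitting exactly at a threshold
is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MotionTrace",
    "SubjectQC",
    "framewise_displacement",
    "read_motion_trace",
    "apply_exclusions",
    "MAX_TRAN_MM",
    "MAX_ROT_DEG",
    "MAX_MEANFD_MM",
]

MAX_TRAN_MM = 3.0
MAX_ROT_DEG = 3.0
MAX_MEANFD_MM = 0.35


@dataclass
class MotionTrace:
    """Per-timepoint rigid-body motion: (T, 3) translations mm, (T, 3) rotations deg."""

    translations_mm: np.ndarray
    rotations_deg: np.ndarray

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, float))
        self.rotations_deg = np.atleast_2d(np.asarray(self.rotations_deg, float))
        if self.translations_mm.shape != self.rotations_deg.shape:
            raise ValueError("translation/rotation shape mismatch")
        if self.translations_mm.shape[0] < 2:
            raise ValueError("trace shorter than 2 timepoints")
        if not (
            np.isfinite(self.translations_mm).all()
            and np.isfinite(self.rotations_deg).all()
        ):
            raise ValueError("non-finite motion parameters")


@dataclass
class SubjectQC:
    """Scalar quality-control covariates for one subject."""

    meanFD: float
    maxTran: float
    maxRot: float
    mcBBR: float
    jacobian_mean: float = 1.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        for name in ("meanFD", "maxTran", "maxRot", "mcBBR", "jacobian_mean"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative finite number")


def framewise_displacement(
    trace: MotionTrace, head_radius_mm: float = 50.0
) -> tuple[np.ndarray, float]:
    """Power-style frame-wise displacement series and its mean.

    FD_t = sum_i |Delta translation_i| + head_radius * sum_i |Delta rotation_i|
    with rotations converted to radians; FD_1 = 0 by convention and the
    mean is taken over frames t >= 2.
    """
    dt = np.abs(np.diff(trace.translations_mm, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(np.deg2rad(trace.rotations_deg), axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + head_radius_mm * dr])
    return fd, float(fd[1:].mean())


def read_motion_trace(path: str) -> MotionTrace:
    """Read a 6-column text file (3 translations mm, 3 rotations deg per row)."""
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion file must have 6 columns")
    return MotionTrace(arr[:, :3], arr[:, 3:])


def apply_exclusions(
    qc_list: list[SubjectQC],
) -> tuple[list[SubjectQC], list[tuple[SubjectQC, list[str]]]]:
    """Split subjects into (kept, dropped-with-reasons).

    A subject is dropped iff maxTran > 3 mm OR maxRot > 3 deg OR
    meanFD > 0.35 mm (strict inequalities).  Idempotent and deterministic;
    kept + dropped partition the input in order.
    """
    kept: list[SubjectQC] = []
    dropped: list[tuple[SubjectQC, list[str]]] = []
    for qc in qc_list:
        reasons = []
        if qc.maxTran > MAX_TRAN_MM:
            reasons.append(f"maxTran {qc.maxTran:g} mm > {MAX_TRAN_MM:g} mm")
        if qc.maxRot > MAX_ROT_DEG:
            reasons.append(f"maxRot {qc.maxRot:g} deg > {MAX_ROT_DEG:g} deg")
        if qc.meanFD > MAX_MEANFD_MM:
            reasons.append(f"meanFD {qc.meanFD:g} mm > {MAX_MEANFD_MM:g} mm")
        if reasons:
            dropped.append((qc, reasons))
        else:
            kept.append(qc)
    return kept, dropped
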
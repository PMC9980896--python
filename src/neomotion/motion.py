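"""Frame-wise displacement and volume censoring.

Rigid-body head motion during an fMRI scan is summarised per frame by the
frame-wise displacement (FD): the mean of the six absolute frame-to-frame
displacement terms, with the three rotations converted from radians to
millimetres on a sphere approximating the (neonatal) head. FD then drives
*censoring* ("scrubbing"): frames whose FD exceeds a threshold are dropped
before connectivity is computed, and the surviving series is capped to a fixed
scan length so that every censoring condition is compared at an equal number
of frames.

Conventions
-----------
* FD at frame 0 is defined as 0 (there is no preceding frame), so frame 0 is
  never censored on FD grounds.
* The six terms are averaged (divided by 6), not summed. Some FD variants sum
  the terms instead; values here are 6x smaller than those.
* Absolute values are taken term-wise so FD is nonnegative; the sign
  convention of the frame-to-frame difference is therefore irrelevant.
* Mean FD after censoring is the mean of the original per-frame FD values of
  the surviving frames; FD is never recomputed between now-adjacent survivors.
* The scan-length cap keeps the *earliest* surviving frames, preserving
  temporal order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, InvalidConfigError, ValidationError

DEFAULT_HEAD_RADIUS_MM = 30.0
#: Order of the six rigid-body parameters throughout the package.
PARAM_NAMES = ("trans_x", "trans_y", "trans_z", "rot_roll", "rot_pitch", "rot_yaw")


def condition_tag(threshold_mm: Optional[float]) -> str:
    """Short tag naming a censoring condition, e.g. ``none``, ``0.5mm``."""
    if threshold_mm is None:
        return "none"
    return f"{threshold_mm:g}mm"


@dataclass(frozen=True)
class MotionParams:
    """Per-frame 6-parameter rigid-body motion estimates.

    Parameters
    ----------
    params
        Array of shape ``(n_frames, 6)``: translations along x, y, z in mm
        followed by roll, pitch, yaw rotations in radians.
    frame_period
        Repetition time (TR) in seconds.
    """

    params: np.ndarray
    frame_period: float = 2.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.params, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise ValidationError(
                f"motion parameters must have shape (n_frames, 6), got {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise ValidationError("motion parameters need at least one frame")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("motion parameters contain non-finite values")
        if self.frame_period <= 0:
            raise InvalidConfigError("frame_period must be positive")
        object.__setattr__(self, "params", arr)

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.params, columns=list(PARAM_NAMES))


@dataclass(frozen=True)
class FDTrace:
    """Per-frame displacement in mm; ``values[0] == 0`` by definition."""

    values: np.ndarray
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValidationError("FD trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("FD trace contains non-finite values")
        if arr[0] != 0.0:
            raise ValidationError("FD at frame 0 must be 0 by definition")
        if np.any(arr < 0):
            raise ValidationError("FD values must be nonnegative")
        object.__setattr__(self, "values", arr)

    @property
    def n_frames(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CensorPlan:
    """Keep/drop decision per frame from thresholding plus a scan-length cap.

    ``censored_fraction`` refers to the thresholding stage only (the quantity
    reported as "% volumes censored"); the cap is a separate truncation
    applied to make conditions comparable.
    """

    threshold_mm: Optional[float]
    cap_frames: Optional[int]
    keep_mask: np.ndarray
    survivor_indices: np.ndarray
    n_frames: int
    n_threshold_survivors: int

    @property
    def n_survivors(self) -> int:
        return int(self.survivor_indices.size)

    @property
    def censored_fraction(self) -> float:
        return 1.0 - self.n_threshold_survivors / self.n_frames

    @property
    def under_cap(self) -> bool:
        """True when thresholding left fewer frames than the cap asks for."""
        if self.cap_frames is None:
            return False
        return self.n_threshold_survivors < self.cap_frames


def compute_fd(
    motion: MotionParams, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
) -> FDTrace:
    """Frame-wise displacement from 6-parameter motion estimates.

    For frame ``i >= 1``::

        FD[i] = (|dx| + |dy| + |dz| + r*|droll| + r*|dpitch| + r*|dyaw|) / 6

    where each ``d`` is the difference between the parameter at frames
    ``i-1`` and ``i`` and ``r = head_radius_mm`` converts radians to mm arc
    length. ``FD[0] = 0``.
    """
    p = motion.params
    if p.shape[0] == 1:
        return FDTrace(np.zeros(1), head_radius_mm)
    d = np.abs(np.diff(p, axis=0))
    terms = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    fd = np.concatenate(([0.0], terms / 6.0))
    return FDTrace(fd, head_radius_mm)


def mean_fd(fd: FDTrace, keep_mask: Optional[np.ndarray] = None) -> float:
    """Mean FD over all frames, or over surviving frames when a mask is given."""
    if keep_mask is None:
        return float(fd.values.mean())
    mask = np.asarray(keep_mask, dtype=bool)
    if mask.shape != fd.values.shape:
        raise ValidationError(
            f"keep_mask length {mask.size} != trace length {fd.n_frames}"
        )
    if not mask.any():
        raise EmptySelectionError("keep_mask selects zero frames")
    return float(fd.values[mask].mean())


def make_censor_plan(
    fd: FDTrace,
    threshold_mm: Optional[float],
    cap_seconds: Optional[float],
    tr_seconds: float,
) -> CensorPlan:
    """Build a censoring plan: FD thresholding, then a scan-length cap.

    Frames with ``FD > threshold_mm`` are dropped (frame 0 is always eligible
    since its FD is 0); the earliest surviving frames are then retained up to
    ``floor(cap_seconds / tr_seconds)``. Both stages are optional.
    """
    if tr_seconds <= 0:
        raise InvalidConfigError("tr_seconds must be positive")
    if threshold_mm is not None and threshold_mm <= 0:
        raise InvalidConfigError("threshold_mm must be positive or None")
    n = fd.n_frames
    if threshold_mm is None:
        thr_mask = np.ones(n, dtype=bool)
    else:
        thr_mask = fd.values <= threshold_mm
    n_thr = int(thr_mask.sum())

    cap_frames: Optional[int] = None
    survivors = np.flatnonzero(thr_mask)
    if cap_seconds is not None:
        if cap_seconds <= 0:
            raise InvalidConfigError("cap_seconds must be positive or None")
        cap_frames = int(np.floor(cap_seconds / tr_seconds))
        survivors = survivors[:cap_frames]
    keep = np.zeros(n, dtype=bool)
    keep[survivors] = True
    return CensorPlan(
        threshold_mm=threshold_mm,
        cap_frames=cap_frames,
        keep_mask=keep,
        survivor_indices=survivors,
        n_frames=n,
        n_threshold_survivors=n_thr,
    )


def censor_summary(plans: Mapping[str, Sequence[CensorPlan]]) -> pd.DataFrame:
    """Cohort censoring summary per condition.

    Parameters
    ----------
    plans
        Mapping from condition tag to the per-scan plans of that condition.

    Returns
    -------
    DataFrame indexed by condition with mean/SD/max censored fraction and the
    number of scans whose threshold survivors fall short of the cap.
    """
    if not plans or any(len(v) == 0 for v in plans.values()):
        raise ValidationError("censor_summary needs at least one plan per condition")
    rows = {}
    for tag, cohort in plans.items():
        frac = np.array([p.censored_fraction for p in cohort])
        rows[tag] = {
            "n_scans": len(cohort),
            "mean_censored_frac": frac.mean(),
            "sd_censored_frac": frac.std(ddof=1) if len(cohort) > 1 else 0.0,
            "max_censored_frac": frac.max(),
            "n_under_cap": int(sum(p.under_cap for p in cohort)),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "condition"
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_SPLIT = re.compile(r"[,\s]+")


def read_motion_params(
    path: str | Path,
    tr_seconds: float = 2.0,
    rot_unit: str = "rad",
    col_order: str = "txyz-rpy",
) -> MotionParams:
    """Read a 6-column whitespace/comma-delimited motion parameter file.

    ``rot_unit='deg'`` converts degree-valued rotations (AFNI convention) to
    radians; ``col_order='rpy-txyz'`` accepts rotations-first column layouts.
    The unit and order are never guessed from the data.
    """
    if rot_unit not in ("rad", "deg"):
        raise InvalidConfigError(f"rot_unit must be 'rad' or 'deg', got {rot_unit!r}")
    if col_order not in ("txyz-rpy", "rpy-txyz"):
        raise InvalidConfigError(f"unknown col_order {col_order!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = _SPLIT.split(line)
            if len(parts) != 6:
                raise ValidationError(
                    f"{path}: line {lineno}: expected 6 columns, found {len(parts)}"
                )
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: line {lineno}: non-numeric value ({exc})"
                ) from None
    if not rows:
        raise ValidationError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    if col_order == "rpy-txyz":
        arr = arr[:, [3, 4, 5, 0, 1, 2]]
    if rot_unit == "deg":
        arr[:, 3:] = np.deg2rad(arr[:, 3:])
    return MotionParams(arr, frame_period=tr_seconds)


def read_dhcp_motion(path: str | Path) -> FDTrace:
    """Read a dHCP-style ``*_motion.tsv`` carrying a precomputed FD column.

    Bypasses :func:`compute_fd`; the first frame's FD (often NaN in these
    files) is set to 0 by definition.
    """
    table = pd.read_csv(path, sep="\t")
    if "framewise_displacement" not in table.columns:
        raise ValidationError(
            f"{path}: no 'framewise_displacement' column "
            f"(columns: {list(table.columns)})"
        )
    vals = table["framewise_displacement"].to_numpy(dtype=float)
    if vals.size and (np.isnan(vals[0]) or vals[0] == 0.0):
        vals = vals.copy()
        vals[0] = 0.0
    if np.isnan(vals).any():
        raise ValidationError(f"{path}: NaN FD values beyond frame 0")
    return FDTrace(vals)


def write_fd_table(
    path: str | Path, fd: FDTrace, plans: Mapping[str, CensorPlan]
) -> None:
    """Write a per-scan FD trace TSV: ``frame fd_mm keep_<tag> ...``."""
    data = {"frame": np.arange(fd.n_frames), "fd_mm": fd.values}
    for tag, plan in plans.items():
        data[f"keep_{tag}"] = plan.keep_mask.astype(int)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_motion_params(path: str | Path, motion: MotionParams) -> None:
    """Write a 6-column whitespace-delimited motion parameter file."""
    np.savetxt(path, motion.params, fmt="%.8f")
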
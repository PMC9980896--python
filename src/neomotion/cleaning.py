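"""Nuisance design construction, joint regression + band-pass, and tSNR.

Nuisance regression and temporal band-pass filtering are performed
*simultaneously*: sine/cosine regressors at every discrete-Fourier frequency
outside the pass-band are appended to the nuisance design and the whole block
is removed in a single least-squares projection. Sequential
regress-then-filter pipelines can reintroduce nuisance variance into the
filtered band; the joint projection cannot, and it makes the question of
whether nuisance columns were themselves pre-filtered moot (the projection is
invariant to replacing columns by any basis of the same span).

tSNR is computed on the *raw* (pre-regression) series: it is a data-quality
measure of the acquired signal, not of the cleaned residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvalidConfigError, ValidationError
from .motion import PARAM_NAMES, MotionParams

DEFAULT_BAND_HZ = (0.009, 0.08)


@dataclass(frozen=True)
class CleanOptions:
    """Options for :func:`clean_timeseries`.

    band_hz
        Pass-band (low, high) in Hz; frequencies outside it are projected out.
        Edges are inclusive: a DFT frequency exactly on an edge is retained.
    tr_seconds
        Repetition time, defining the Nyquist frequency 1/(2*TR).
    gsr_enabled
        Whether designs built by :func:`build_design` include a global-signal
        column.
    n_csf_pcs
        Number of CSF principal components in tissue designs.
    """

    tr_seconds: float = 2.0
    band_hz: tuple = DEFAULT_BAND_HZ
    gsr_enabled: bool = False
    n_csf_pcs: int = 3

    def __post_init__(self) -> None:
        low, high = self.band_hz
        if self.tr_seconds <= 0:
            raise InvalidConfigError("tr_seconds must be positive")
        nyquist = 0.5 / self.tr_seconds
        if not (0 <= low < high < nyquist):
            raise InvalidConfigError(
                f"band must satisfy 0 <= low < high < Nyquist ({nyquist:g} Hz), "
                f"got {self.band_hz}"
            )
        if self.n_csf_pcs < 0:
            raise InvalidConfigError("n_csf_pcs must be nonnegative")


def friston24(motion: MotionParams) -> pd.DataFrame:
    """24-regressor expansion of the six rigid-body motion parameters.

    Columns, in order: the 6 parameters, their 6 backward differences (first
    row 0), the squares of the parameters, and the squares of the differences.
    """
    p = motion.params
    if p.shape[0] < 2:
        raise ValidationError("friston24 needs at least 2 frames")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(p, axis=0)])
    blocks = [p, deriv, p**2, deriv**2]
    labels = (
        list(PARAM_NAMES)
        + [f"d_{n}" for n in PARAM_NAMES]
        + [f"{n}_sq" for n in PARAM_NAMES]
        + [f"d_{n}_sq" for n in PARAM_NAMES]
    )
    return pd.DataFrame(np.hstack(blocks), columns=labels)


def tissue_regressors(
    wm_timeseries: np.ndarray,
    csf_timeseries: np.ndarray,
    n_pcs: int = 3,
) -> pd.DataFrame:
    """White-matter mean plus top CSF principal components.

    The WM column is the frame-wise mean over WM voxels. CSF voxel series are
    column-centered and decomposed by SVD; the returned components are the
    projections onto the top ``n_pcs`` right singular vectors, each sign-fixed
    so its largest-magnitude voxel loading is positive. Components whose
    singular value is numerically zero are flagged by a ``near_zero``
    attribute on the frame (rank-deficient CSF blocks).
    """
    wm = np.atleast_2d(np.asarray(wm_timeseries, dtype=float))
    csf = np.atleast_2d(np.asarray(csf_timeseries, dtype=float))
    if wm.shape[0] != csf.shape[0]:
        raise ValidationError("WM and CSF series must have the same frame count")
    if csf.shape[1] < n_pcs + 1:
        raise ValidationError(
            f"need at least n_pcs+1={n_pcs + 1} CSF voxels, got {csf.shape[1]}"
        )
    cols = {"wm_mean": wm.mean(axis=1)}
    centered = csf - csf.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = s[0] * max(centered.shape) * np.finfo(float).eps if s.size else 0.0
    near_zero = []
    for k in range(n_pcs):
        load = vt[k]
        sign = 1.0 if load[np.argmax(np.abs(load))] >= 0 else -1.0
        cols[f"csf_pc{k + 1}"] = sign * u[:, k] * s[k]
        if s[k] <= tol:
            near_zero.append(f"csf_pc{k + 1}")
    out = pd.DataFrame(cols)
    out.attrs["near_zero"] = near_zero
    return out


def global_signal(gray_timeseries: np.ndarray) -> np.ndarray:
    """Per-frame mean signal over gray-matter units."""
    g = np.atleast_2d(np.asarray(gray_timeseries, dtype=float))
    if g.shape[1] < 1:
        raise ValidationError("global_signal needs at least one unit")
    return g.mean(axis=1)


def build_design(
    motion: Optional[MotionParams] = None,
    wm_timeseries: Optional[np.ndarray] = None,
    csf_timeseries: Optional[np.ndarray] = None,
    gray_timeseries: Optional[np.ndarray] = None,
    options: Optional[CleanOptions] = None,
) -> Optional[pd.DataFrame]:
    """Assemble the labeled nuisance design from the enabled blocks.

    Includes Friston-24 motion regressors when ``motion`` is given, tissue
    regressors when WM/CSF series are given, and a global-signal column when
    ``options.gsr_enabled`` and gray-matter series are given. Intercept,
    drift, and frequency regressors are added later by
    :func:`clean_timeseries`. Returns None when no block is enabled.
    """
    options = options or CleanOptions()
    parts = []
    if motion is not None:
        parts.append(friston24(motion))
    if wm_timeseries is not None and csf_timeseries is not None:
        parts.append(tissue_regressors(wm_timeseries, csf_timeseries, options.n_csf_pcs))
    if options.gsr_enabled:
        if gray_timeseries is None:
            raise InvalidConfigError("gsr_enabled requires gray_timeseries")
        parts.append(pd.DataFrame({"global_signal": global_signal(gray_timeseries)}))
    if not parts:
        return None
    return pd.concat(parts, axis=1)


def bandstop_regressors(
    n_frames: int, tr_seconds: float, band_hz: tuple = DEFAULT_BAND_HZ
) -> pd.DataFrame:
    """Sine/cosine regressors at every DFT frequency outside the pass-band.

    Frequencies ``k/(n*TR)`` for ``k = 1..n//2``; those inside
    ``[low, high]`` (edges inclusive, with a small numeric tolerance) are
    skipped so they survive the projection. DC (k=0) is handled by the
    intercept column of the cleaning design.
    """
    low, high = band_hz
    t = np.arange(n_frames)
    cols = {}
    eps = 1e-12
    for k in range(1, n_frames // 2 + 1):
        f = k / (n_frames * tr_seconds)
        if low - eps <= f <= high + eps:
            continue
        w = 2.0 * np.pi * k * t / n_frames
        cols[f"cos_f{k}"] = np.cos(w)
        if not (n_frames % 2 == 0 and k == n_frames // 2):  # sine at Nyquist is 0
            cols[f"sin_f{k}"] = np.sin(w)
    return pd.DataFrame(cols)


def clean_timeseries(
    ts: np.ndarray,
    design: Optional[pd.DataFrame],
    options: CleanOptions,
) -> np.ndarray:
    """Joint nuisance regression + band-pass by one least-squares projection.

    The combined design holds an intercept, a linear drift, the supplied
    nuisance columns, and out-of-band sine/cosine regressors; the returned
    residuals are orthogonal to every one of them.
    """
    y = np.atleast_2d(np.asarray(ts, dtype=float))
    if y.ndim != 2:
        raise ValidationError("timeseries must be 2-D (frames x units)")
    n = y.shape[0]
    blocks = [np.ones((n, 1)), (np.arange(n) - (n - 1) / 2.0).reshape(-1, 1) / n]
    if design is not None:
        d = np.asarray(design, dtype=float)
        if d.shape[0] != n:
            raise ValidationError(
                f"design has {d.shape[0]} frames but data has {n}"
            )
        if d.size and np.any(np.all(d == 0, axis=0)):
            raise ValidationError("design contains an all-zero column")
        blocks.append(d)
    freq = bandstop_regressors(n, options.tr_seconds, options.band_hz)
    if freq.shape[1]:
        blocks.append(freq.to_numpy())
    x = np.hstack(blocks)
    if n < x.shape[1]:
        raise ValidationError(
            f"{n} frames < {x.shape[1]} combined regressors; cannot project"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        warnings.warn(
            f"combined design is rank-deficient (rank {rank} < {x.shape[1]} "
            "columns); using pseudoinverse",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


@dataclass(frozen=True)
class TsnrResult:
    """Per-unit temporal SNR and its masked summary."""

    per_unit: np.ndarray
    mean: float
    n_zero_sd: int


def compute_tsnr(
    raw_ts: np.ndarray, mask: Optional[Sequence[int] | np.ndarray] = None
) -> TsnrResult:
    """Temporal SNR: per-unit temporal mean / SD (ddof=1), averaged over a mask.

    Units with zero temporal SD are excluded from the summary mean and
    counted; if every unit in the mask has zero SD the input is degenerate.
    """
    y = np.atleast_2d(np.asarray(raw_ts, dtype=float))
    if y.shape[0] < 2:
        raise ValidationError("tSNR needs at least 2 frames")
    mu = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(sd > 0, mu / sd, np.nan)
    if mask is not None:
        idx = np.asarray(mask)
        if idx.dtype == bool:
            sel = tsnr[idx]
        else:
            sel = tsnr[idx.astype(int)]
    else:
        sel = tsnr
    valid = np.isfinite(sel)
    n_zero = int(sel.size - valid.sum())
    if not valid.any():
        raise DegenerateDataError("all units have zero temporal SD")
    return TsnrResult(per_unit=tsnr, mean=float(sel[valid].mean()), n_zero_sd=n_zero)
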
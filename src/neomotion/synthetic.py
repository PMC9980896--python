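"""Synthetic motion-corrupted neonatal rs-fMRI cohorts with known ground truth.

Every downstream stage of the package is testable without any image
downloads: this module generates multi-scan cohorts of ROI timeseries plus
6-parameter motion traces in which the quantities the analyses estimate --
the inter-ROI covariance, the motion-artifact coupling, the temporal-SNR
loss, and the age effect -- are known exactly.

Generative model per scan
-------------------------
* **Geometry**: ROI centroids are drawn in one hemisphere and mirrored across
  the midsagittal plane, so every ROI has an explicit homotopic partner.
* **Ground-truth correlation**: a convex blend
  ``(1-a) * exp(-d_ij / lambda) + a * (I + homotopic block)`` of an
  exponential distance-decay kernel and a pairwise homotopic block; the blend
  lets the homotopic Fisher-z be set exactly (shifted linearly with
  postmenstrual age) while remaining provably positive-definite.
* **Motion**: a small random-walk jitter on all six rigid-body parameters
  plus sparse transient bursts -- single-frame parameter excursions on a
  random parameter subset -- giving the long quiet stretches interrupted by
  surges seen in real neonatal traces.
* **Artifact**: a shared additive component ``gain * FD_t * w`` with fixed
  per-ROI signed weights ``w``; same-sign ROI pairs have motion-inflated
  correlation, opposite-sign pairs motion-deflated, reproducing both
  directions of FD-FC association.
* **Noise/tSNR**: white measurement noise whose SD grows linearly with FD,
  so high-motion scans have lower temporal SNR; a constant positive offset
  keeps tSNR finite and positive.
* **Age**: PMA is drawn uniformly and *independently* of motion, so PMA-FC
  analyses are unconfounded by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .connectivity import RoiTable, fisher_z
from .errors import InvalidConfigError
from .motion import MotionParams, compute_fd

#: weight of the exact homotopic block in the ground-truth correlation blend;
#: supports homotopic targets up to |r| < 0.75 for any geometry
HOMOTOPIC_BLEND = 0.75


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Defaults follow the acquisition of the emulated neonatal cohort: 149
    scans of 200 volumes at TR = 2 s over a 90-region parcellation, with a
    postmenstrual-age range of 37.7-47.7 weeks. Motion defaults give a
    heavy-tailed cohort mean-FD distribution (mean roughly equal to SD);
    artifact and noise couplings are free parameters of the simulation, not
    estimates of the real neonatal artifact.
    """

    n_scans: int = 149
    n_frames: int = 200
    tr_seconds: float = 2.0
    n_rois: int = 90
    homotopic_strength: float = 0.6
    distance_decay_mm: float = 40.0
    burst_rate: float = 0.10
    burst_amp_mm: float = 1.5
    baseline_jitter_mm: float = 0.02
    artifact_gain: float = 1.0
    dropout_gain: float = 2.0
    noise_sd: float = 0.2
    signal_offset: float = 100.0
    burst_rate_dispersion: Optional[float] = 1.0
    pma_range_weeks: tuple = (37.7, 47.7)
    pma_slope: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 4 or self.n_rois % 2 != 0:
            raise InvalidConfigError("n_rois must be even and >= 4")
        if self.n_frames < 2:
            raise InvalidConfigError("n_frames must be >= 2")
        if self.n_scans < 1:
            raise InvalidConfigError("n_scans must be >= 1")
        if self.tr_seconds <= 0:
            raise InvalidConfigError("tr_seconds must be positive")
        if not (-1 < self.homotopic_strength < 1):
            raise InvalidConfigError("homotopic_strength must lie in (-1, 1)")
        if self.distance_decay_mm <= 0:
            raise InvalidConfigError("distance_decay_mm must be positive")
        if not (0 <= self.burst_rate <= 1):
            raise InvalidConfigError("burst_rate must lie in [0, 1]")
        for name in ("burst_amp_mm", "baseline_jitter_mm", "artifact_gain",
                     "dropout_gain", "noise_sd", "signal_offset"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be nonnegative")
        if self.burst_rate_dispersion is not None and self.burst_rate_dispersion <= 0:
            raise InvalidConfigError("burst_rate_dispersion must be positive or None")
        lo, hi = self.pma_range_weeks
        if not lo <= hi:
            raise InvalidConfigError("pma_range_weeks must be (low, high)")

    @property
    def pma_midpoint(self) -> float:
        lo, hi = self.pma_range_weeks
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected into one scan."""

    true_covariance: np.ndarray
    roi_geometry: RoiTable
    artifact_weights: np.ndarray
    injected_high_motion_frames: np.ndarray

    def true_z(self) -> np.ndarray:
        """Fisher-z of the generating correlation, NaN diagonal."""
        z = np.asarray(fisher_z(self.true_covariance), dtype=float)
        np.fill_diagonal(z, np.nan)
        return z


@dataclass(frozen=True)
class Scan:
    """One scan: raw ROI series, motion trace, and (for synthetic scans) the
    ground truth the generator injected; ``None`` for loaded real data."""

    scan_id: str
    timeseries: pd.DataFrame
    motion: MotionParams
    ground_truth: Optional[GroundTruth]
    pma_weeks: float


@dataclass(frozen=True)
class Cohort:
    """A cohort of scans plus its ``scan_id / pma_weeks / sex`` table.

    ``config`` is the generating configuration for synthetic cohorts and
    ``None`` for cohorts loaded from disk.
    """

    scans: tuple
    table: pd.DataFrame
    geometry: RoiTable
    config: Optional[SyntheticConfig]


def make_geometry(n_rois: int, seed: int) -> RoiTable:
    """Mirrored ROI geometry: odd ids right hemisphere, even ids their
    left-hemisphere mirror (first coordinate negated)."""
    if n_rois < 2 or n_rois % 2 != 0:
        raise InvalidConfigError("n_rois must be even and >= 2")
    rng = np.random.default_rng(seed)
    m = n_rois // 2
    # neonatal-scale head: |x| up to ~35 mm from midline
    x = rng.uniform(8.0, 35.0, size=m)
    y = rng.uniform(-45.0, 40.0, size=m)
    z = rng.uniform(-25.0, 35.0, size=m)
    rows = []
    for k in range(m):
        rid_r, rid_l = 2 * k + 1, 2 * k + 2
        rows.append({"roi_id": rid_r, "name": f"roi{k + 1:02d}_R", "hemi": "R",
                     "partner_id": rid_l, "x_mm": x[k], "y_mm": y[k], "z_mm": z[k]})
        rows.append({"roi_id": rid_l, "name": f"roi{k + 1:02d}_L", "hemi": "L",
                     "partner_id": rid_r, "x_mm": -x[k], "y_mm": y[k], "z_mm": z[k]})
    return RoiTable(pd.DataFrame(rows))


def true_correlation(
    geometry: RoiTable, config: SyntheticConfig, pma_weeks: float
) -> np.ndarray:
    """Ground-truth ROI correlation for a scan at a given postmenstrual age.

    Homotopic entries hit ``tanh(atanh(homotopic_strength) +
    pma_slope * (pma - midpoint))`` exactly; all other entries decay as
    ``(1 - a) * exp(-d / lambda)``. Raises when the requested structure is
    not positive-definite (the implied homotopic block weight leaves (-1, 1),
    or numerically otherwise).
    """
    from .connectivity import roi_distances

    d = roi_distances(geometry)
    kernel = np.exp(-d / config.distance_decay_mm)
    a = HOMOTOPIC_BLEND
    z_target = np.arctanh(config.homotopic_strength) + config.pma_slope * (
        pma_weeks - config.pma_midpoint
    )
    r_target = float(np.tanh(z_target))
    corr = (1.0 - a) * kernel
    np.fill_diagonal(corr, 1.0)
    ids = geometry.ids
    block = np.zeros_like(corr)
    for _, row in geometry.homotopic_pairs().iterrows():
        i = geometry.index_of(row["left_id"])
        j = geometry.index_of(row["right_id"])
        h = (r_target - (1.0 - a) * kernel[i, j]) / a
        if not (-1.0 < h < 1.0):
            raise InvalidConfigError(
                f"requested homotopic correlation {r_target:.3f} is not "
                "positive-definite with this geometry/decay"
            )
        block[i, j] = block[j, i] = a * h
    corr = corr + block
    min_eig = float(np.linalg.eigvalsh(corr).min())
    if min_eig <= 1e-10:
        raise InvalidConfigError(
            f"requested covariance is not positive-definite (min eig {min_eig:.2e})"
        )
    return corr


#: exponential decay constant (frames) of a motion surge settling back
BURST_DECAY_FRAMES = 1.5
#: geometric continuation probability controlling surge duration
BURST_CONTINUE_P = 0.35


def make_motion_trace(
    config: SyntheticConfig, seed: int, burst_rate: Optional[float] = None
) -> tuple:
    """Six-parameter trace: random-walk jitter plus sparse motion surges.

    A surge starts with per-frame probability ``burst_rate`` on frames
    1..n-1, affects a random subset of the six parameters with Gaussian peak
    amplitude of scale ``burst_amp_mm`` (rotations scaled to equivalent mm on
    the 30 mm sphere), and settles back exponentially over a geometric
    number of frames -- the head moves and then relaxes toward its previous
    position, which spreads the per-frame displacement over a range of
    magnitudes rather than a single spike. Returns
    ``(MotionParams, surge_onset_indices)``.
    """
    rng = np.random.default_rng(seed)
    n = config.n_frames
    rate = config.burst_rate if burst_rate is None else burst_rate
    scale = np.array([1.0, 1.0, 1.0, 1 / 30.0, 1 / 30.0, 1 / 30.0])
    steps = rng.normal(0.0, config.baseline_jitter_mm, size=(n, 6)) * scale
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    burst_frames = np.flatnonzero(rng.random(n - 1) < rate) + 1 if n > 1 else np.array([], int)
    for f in burst_frames:
        affected = rng.random(6) < 0.5
        if not affected.any():
            affected[rng.integers(6)] = True
        peak = rng.normal(0.0, config.burst_amp_mm, size=6) * scale
        peak = np.where(affected, peak, 0.0)
        length = 1 + rng.geometric(1.0 - BURST_CONTINUE_P)
        for k in range(min(length, n - f)):
            params[f + k] += peak * np.exp(-k / BURST_DECAY_FRAMES)
    return MotionParams(params, frame_period=config.tr_seconds), burst_frames


def _cohort_weights(config: SyntheticConfig) -> np.ndarray:
    """Fixed per-ROI signed artifact weights, derived from the master seed."""
    rng = np.random.default_rng([config.seed, 1])
    return rng.standard_normal(config.n_rois)


def make_scan(
    config: SyntheticConfig,
    pma_weeks: float,
    seed: int,
    burst_rate: Optional[float] = None,
    scan_id: Optional[str] = None,
) -> Scan:
    """Generate one scan. Geometry and artifact weights derive
    deterministically from ``config.seed`` (cohort-level); motion and signal
    draws use ``seed`` (scan-level), so single scans are regenerable."""
    geometry = make_geometry(config.n_rois, config.seed)
    weights = _cohort_weights(config)
    motion, bursts = make_motion_trace(config, seed, burst_rate)
    fd = compute_fd(motion).values
    corr = true_correlation(geometry, config, pma_weeks)
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng([seed, 1])
    latent = rng.standard_normal((config.n_frames, config.n_rois)) @ chol.T
    artifact = config.artifact_gain * fd[:, None] * weights[None, :]
    noise_sd = config.noise_sd * (1.0 + config.dropout_gain * fd)
    noise = rng.standard_normal((config.n_frames, config.n_rois)) * noise_sd[:, None]
    ts = config.signal_offset + latent + artifact + noise
    truth = GroundTruth(
        true_covariance=corr,
        roi_geometry=geometry,
        artifact_weights=weights,
        injected_high_motion_frames=bursts,
    )
    return Scan(
        scan_id=scan_id or f"scan{seed:06d}",
        timeseries=pd.DataFrame(ts, columns=[int(i) for i in geometry.ids]),
        motion=motion,
        ground_truth=truth,
        pma_weeks=float(pma_weeks),
    )


def scan_seed(config: SyntheticConfig, index: int) -> int:
    """Per-scan seed: master seed + 1 + scan index (offset keeps scan streams
    distinct from the cohort-level stream seeded at the master)."""
    return config.seed + 1 + index


def make_cohort(config: SyntheticConfig) -> Cohort:
    """Generate ``n_scans`` scans plus the cohort table.

    PMA is uniform on ``pma_range_weeks`` and drawn independently of every
    motion quantity. When ``burst_rate_dispersion`` is set, each scan's burst
    rate is Gamma-distributed with mean ``burst_rate`` and shape
    ``dispersion``, giving the heavy-tailed between-scan motion spread seen
    in real neonatal cohorts.
    """
    rng = np.random.default_rng([config.seed, 2])
    lo, hi = config.pma_range_weeks
    pma = rng.uniform(lo, hi, size=config.n_scans)
    sex = rng.choice(["M", "F"], size=config.n_scans)
    if config.burst_rate_dispersion is not None and config.burst_rate > 0:
        shape = config.burst_rate_dispersion
        # truncate the tail: even the worst real scans keep most of their
        # frames, so the per-scan surge propensity is capped at 2.5x the mean
        rates = np.minimum(
            rng.gamma(shape, config.burst_rate / shape, size=config.n_scans),
            min(2.5 * config.burst_rate, 1.0),
        )
    else:
        rates = np.full(config.n_scans, config.burst_rate)
    scans = []
    for i in range(config.n_scans):
        scans.append(
            make_scan(
                config, pma[i], scan_seed(config, i),
                burst_rate=float(rates[i]), scan_id=f"sub{i + 1:04d}",
            )
        )
    table = pd.DataFrame(
        {
            "scan_id": [s.scan_id for s in scans],
            "pma_weeks": pma,
            "sex": sex,
        }
    )
    return Cohort(
        scans=tuple(scans), table=table,
        geometry=scans[0].ground_truth.roi_geometry, config=config,
    )


# ---------------------------------------------------------------------------
# Linear-model cohort table (for bootstrap confounding experiments)
# ---------------------------------------------------------------------------


def make_confounded_table(
    n_scans: int,
    pma_effect: float,
    fd_effect: float,
    noise_sd: float = 0.1,
    seed: int = 0,
    network: str = "synthetic",
    condition: str = "none",
    pma_range_weeks: tuple = (37.7, 47.7),
    fd_mean_mm: float = 0.13,
) -> pd.DataFrame:
    """Cohort table with ``strength = a*(PMA - mid) + b*FD + noise``.

    PMA is uniform, mean FD Gamma-distributed (shape 1: mean = SD, matching
    the heavy-tailed cohort distribution) and independent of PMA. With
    ``fd_effect != 0`` the FD-partialled PMA correlation is closer to the
    confound-free association than the simple one; with 0 they coincide.
    """
    rng = np.random.default_rng(seed)
    lo, hi = pma_range_weeks
    pma = rng.uniform(lo, hi, size=n_scans)
    fd = rng.gamma(1.0, fd_mean_mm, size=n_scans)
    strength = (
        pma_effect * (pma - 0.5 * (lo + hi))
        + fd_effect * fd
        + rng.normal(0.0, noise_sd, size=n_scans)
    )
    from .association import fc_column, fd_column

    return pd.DataFrame(
        {
            "scan_id": [f"sub{i + 1:04d}" for i in range(n_scans)],
            "pma_weeks": pma,
            fd_column(condition): fd,
            fc_column(network, condition): strength,
        }
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_scan_tsv(path: str | Path, scan: Scan) -> None:
    """ROI timeseries as TSV: frames as rows, one column per roi_id."""
    scan.timeseries.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_scan_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [int(c) for c in df.columns]
    return df


def write_cohort_table(path: str | Path, cohort: Cohort) -> None:
    cohort.table.to_csv(path, sep="\t", index=False)


def write_scan_nifti(
    bold_path: str | Path, parc_path: str | Path, scan: Scan
) -> None:
    """Emit a small 4-D NIfTI (each ROI a 2-voxel block) plus the matching
    integer-label parcellation, to exercise the image-extraction path."""
    import nibabel as nib

    ids = [int(c) for c in scan.timeseries.columns]
    n_rois = len(ids)
    n_frames = len(scan.timeseries)
    vol = np.zeros((n_rois, 2, 1, n_frames), dtype=np.float32)
    labels = np.zeros((n_rois, 2, 1), dtype=np.int16)
    for k, rid in enumerate(ids):
        series = scan.timeseries[rid].to_numpy(dtype=np.float32)
        vol[k, 0, 0, :] = series
        vol[k, 1, 0, :] = series
        labels[k, :, 0] = rid
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(vol, affine), str(bold_path))
    nib.save(nib.Nifti1Image(labels, affine), str(parc_path))
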
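"""Cohort-level motion-connectivity association statistics.

Covers the statistical battery used to quantify how head motion contaminates
connectivity estimates and how censoring mitigates it: Pearson FD-FC
associations per network, edgewise contamination fractions across the whole
connectome, low/high motion group contrasts with BH-FDR control, distance
dependence of connectivity and of censoring-induced shifts, one-way ANOVA
across censoring conditions, and bootstrap subsampling of simple versus
FD-partialled PMA-connectivity correlations.

Cohort tables are plain pandas DataFrames with one row per scan and the
column convention ``mean_fd_<condition>`` / ``fc_<network>_<condition>`` plus
``scan_id``, ``pma_weeks`` and ``tsnr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import FCMatrix, fisher_z
from .errors import DegenerateDataError, InvalidConfigError, ValidationError


def fd_column(condition: str) -> str:
    return f"mean_fd_{condition}"


def fc_column(network: str, condition: str) -> str:
    return f"fc_{network}_{condition}"


@dataclass(frozen=True)
class AssociationResult:
    """Pearson association between two cohort variables."""

    r: float
    p: float
    n: int
    variables: tuple
    condition: Optional[str] = None
    degenerate: bool = False


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple:
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def fd_fc_association(
    cohort: pd.DataFrame, network: str, condition: str
) -> AssociationResult:
    """Pearson correlation across scans between mean FD and network strength."""
    xcol, ycol = fd_column(condition), fc_column(network, condition)
    for c in (xcol, ycol):
        if c not in cohort.columns:
            raise ValidationError(f"cohort table lacks column {c!r}")
    sub = cohort[[xcol, ycol]].dropna()
    if len(sub) < 4:
        raise ValidationError(f"need >= 4 scans with both variables, got {len(sub)}")
    x = sub[xcol].to_numpy(float)
    y = sub[ycol].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("constant variable in association")
    r, p = _pearson(x, y)
    return AssociationResult(r, p, len(sub), (xcol, ycol), condition)


@dataclass(frozen=True)
class EdgewiseResult:
    """Per-edge FD association across a cohort of FC matrices."""

    r: np.ndarray
    p: np.ndarray
    alpha: float
    n_edges: int
    n_scans: int
    condition: Optional[str] = None

    @property
    def significant_fraction(self) -> float:
        valid = np.isfinite(self.p)
        if not valid.any():
            return float("nan")
        return float((self.p[valid] < self.alpha).sum() / valid.sum())


def edgewise_fd_association(
    fc_stack: np.ndarray | Sequence[FCMatrix],
    fd_values: np.ndarray,
    alpha: float = 0.05,
    condition: Optional[str] = None,
) -> EdgewiseResult:
    """Pearson r(mean FD, edge z) for every unordered ROI pair.

    ``fc_stack`` is either an array of shape ``(n_scans, n_edges)`` or a
    sequence of :class:`FCMatrix`, whose upper triangles are stacked.
    """
    if not isinstance(fc_stack, np.ndarray):
        fc_stack = np.vstack([m.upper_values() for m in fc_stack])
    z = np.asarray(fc_stack, dtype=float)
    fd = np.asarray(fd_values, dtype=float)
    if z.shape[0] != fd.size:
        raise ValidationError("fd_values length != number of scans in stack")
    usable = ~np.isnan(z).all(axis=1)  # scans flagged unusable at this condition
    z, fd = z[usable], fd[usable]
    n = fd.size
    if n < 4:
        raise ValidationError("need >= 4 scans for edgewise association")
    xc = fd - fd.mean()
    zc = z - z.mean(axis=0)
    sx = np.sqrt((xc**2).sum())
    sz = np.sqrt((zc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where((sx > 0) & (sz > 0), xc @ zc / (sx * sz), np.nan)
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = np.where(np.isfinite(t), 2 * stats.t.sf(np.abs(t), df=n - 2), np.nan)
    return EdgewiseResult(
        r=r, p=p, alpha=alpha, n_edges=z.shape[1], n_scans=n, condition=condition
    )


def split_by_motion(
    cohort: pd.DataFrame, condition: str, fraction: float = 0.25
) -> tuple:
    """Extreme-motion split: the ``fraction`` of scans with the lowest mean FD
    form the low-motion group, the same count with the highest FD the
    high-motion group. Ties are broken deterministically by scan id."""
    if not (0 < fraction <= 0.5):
        raise InvalidConfigError("fraction must lie in (0, 0.5]")
    col = fd_column(condition)
    if col not in cohort.columns:
        raise ValidationError(f"cohort table lacks column {col!r}")
    n = len(cohort)
    if n < 8:
        raise ValidationError(f"need >= 8 scans to split, got {n}")
    k = int(np.floor(fraction * n))
    ordered = cohort.sort_values([col, "scan_id"], kind="mergesort")
    low = ordered["scan_id"].iloc[:k].tolist()
    high = ordered["scan_id"].iloc[n - k:].tolist()
    return low, high


@dataclass(frozen=True)
class GroupContrast:
    """Per-unit two-sample contrast of high- versus low-motion maps."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig_unc: np.ndarray
    sig_fdr: np.ndarray
    delta_z: np.ndarray
    excluded: np.ndarray
    alpha_unc: float
    fdr_q: float
    n_low: int
    n_high: int

    @property
    def n_valid(self) -> int:
        return int((~self.excluded).sum())

    @property
    def n_sig_unc(self) -> int:
        return int(self.sig_unc.sum())

    @property
    def n_sig_fdr(self) -> int:
        return int(self.sig_fdr.sum())

    @property
    def frac_sig_unc(self) -> float:
        return self.n_sig_unc / self.n_valid if self.n_valid else float("nan")

    @property
    def frac_sig_fdr(self) -> float:
        return self.n_sig_fdr / self.n_valid if self.n_valid else float("nan")

    @property
    def mean_delta_z_sig(self) -> float:
        """Mean high-minus-low difference over uncorrected-significant units."""
        if not self.sig_unc.any():
            return float("nan")
        return float(self.delta_z[self.sig_unc].mean())


def group_contrast(
    maps_low: np.ndarray,
    maps_high: np.ndarray,
    alpha_unc: float = 0.01,
    fdr_q: float = 0.05,
    equal_var: bool = True,
) -> GroupContrast:
    """Two-sample t per unit (high > low direction, two-sided p) with BH-FDR.

    Student's pooled-variance t by default; ``equal_var=False`` switches to
    Welch. Units with zero variance in both groups are flagged and excluded
    from counts and FDR.
    """
    lo = np.atleast_2d(np.asarray(maps_low, dtype=float))
    hi = np.atleast_2d(np.asarray(maps_high, dtype=float))
    if lo.shape[1] != hi.shape[1]:
        raise ValidationError("group maps have different unit counts")
    if lo.shape[0] < 2 or hi.shape[0] < 2:
        raise ValidationError("need >= 2 maps per group")
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant units -> NaN t
        t, p = stats.ttest_ind(hi, lo, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    excluded = ~np.isfinite(t)
    p = np.where(excluded, np.nan, p)
    q = np.full_like(p, np.nan)
    valid = ~excluded
    if valid.any():
        _, q_valid = fdr_bh(p[valid], fdr_q)
        q[valid] = q_valid
    sig_unc = valid & (p < alpha_unc)
    sig_fdr = valid & (q < fdr_q)
    delta = hi.mean(axis=0) - lo.mean(axis=0)
    return GroupContrast(
        t=t, p=p, q=q, sig_unc=sig_unc, sig_fdr=sig_fdr, delta_z=delta,
        excluded=excluded, alpha_unc=alpha_unc, fdr_q=fdr_q,
        n_low=lo.shape[0], n_high=hi.shape[0],
    )


def within_group_map(maps: np.ndarray, fdr_q: float = 0.05) -> dict:
    """One-sample t against 0 per unit with a BH-FDR significance mask."""
    m = np.atleast_2d(np.asarray(maps, dtype=float))
    if m.shape[0] < 2:
        raise ValidationError("need >= 2 maps")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_1samp(m, 0.0, axis=0)
    t = np.asarray(t, dtype=float)
    p = np.where(np.isfinite(t), np.asarray(p, dtype=float), 1.0)
    mask, q = fdr_bh(p, fdr_q)
    return {"t": t, "p": p, "q": q, "mask": mask}


def strength_comparison(delta_sets: Mapping[str, np.ndarray]) -> dict:
    """One-way ANOVA over censoring conditions plus pairwise post hoc t tests.

    ``delta_sets`` maps condition tag to the per-unit high-minus-low strength
    differences of that condition.
    """
    if len(delta_sets) < 2:
        raise ValidationError("need >= 2 conditions")
    groups = {k: np.asarray(v, dtype=float) for k, v in delta_sets.items()}
    for k, v in groups.items():
        if v.size < 2:
            raise ValidationError(f"condition {k!r} has < 2 values")
    f, p = stats.f_oneway(*groups.values())
    k = len(groups)
    n_total = sum(v.size for v in groups.values())
    rows = []
    tags = list(groups)
    for i in range(k):
        for j in range(i + 1, k):
            t_ij, p_ij = stats.ttest_ind(groups[tags[i]], groups[tags[j]])
            rows.append(
                {"cond_a": tags[i], "cond_b": tags[j],
                 "t": float(t_ij), "p": float(p_ij)}
            )
    return {
        "F": float(f),
        "df": (k - 1, n_total - k),
        "p": float(p),
        "posthoc": pd.DataFrame(rows),
    }


def _upper(mat: np.ndarray | FCMatrix) -> np.ndarray:
    if isinstance(mat, FCMatrix):
        return mat.upper_values()
    m = np.asarray(mat, dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def distance_dependence(
    mean_fc: np.ndarray | FCMatrix, distances: np.ndarray
) -> AssociationResult:
    """Pearson association of cohort-mean edge strength with inter-ROI distance."""
    z = _upper(mean_fc)
    d = _upper(distances)
    if z.size != d.size:
        raise ValidationError("edge sets of FC and distances differ")
    ok = np.isfinite(z) & np.isfinite(d)
    z, d = z[ok], d[ok]
    if z.std() == 0 or d.std() == 0:
        return AssociationResult(
            float("nan"), float("nan"), z.size, ("distance", "mean_z"),
            degenerate=True,
        )
    r, p = _pearson(d, z)
    return AssociationResult(r, p, z.size, ("distance", "mean_z"))


def censor_distance_shift(
    fc_uncensored: np.ndarray | FCMatrix,
    fc_censored: np.ndarray | FCMatrix,
    distances: np.ndarray,
) -> AssociationResult:
    """Association of the censoring-induced edge shift (uncensored minus
    censored z) with inter-ROI distance; degenerate (all-zero shift) inputs
    are flagged rather than raised."""
    diff = _upper(fc_uncensored) - _upper(fc_censored)
    d = _upper(distances)
    ok = np.isfinite(diff) & np.isfinite(d)
    diff, d = diff[ok], d[ok]
    if diff.size == 0 or diff.std() == 0 or d.std() == 0:
        return AssociationResult(
            float("nan"), float("nan"), diff.size,
            ("distance", "delta_z"), degenerate=True,
        )
    r, p = _pearson(d, diff)
    return AssociationResult(r, p, diff.size, ("distance", "delta_z"))


# ---------------------------------------------------------------------------
# Bootstrap PMA association
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap-subsampled simple and FD-partialled PMA-FC correlations.

    Per replicate, a random subset of scans is drawn and the Fisher-z of the
    simple Pearson r(PMA, strength) -- and, when FD control is on, of the
    partial correlation given mean FD -- is recorded. ``p_paired`` tests the
    partial-minus-simple increment across replicates.
    """

    simple_z: np.ndarray
    partial_z: Optional[np.ndarray]
    n_boot: int
    subset_frac: float
    seed: Optional[int]
    network: str
    condition: str

    @property
    def mean_simple(self) -> float:
        return float(self.simple_z.mean())

    @property
    def sd_simple(self) -> float:
        return float(self.simple_z.std(ddof=1))

    @property
    def mean_partial(self) -> float:
        return float(self.partial_z.mean()) if self.partial_z is not None else float("nan")

    @property
    def sd_partial(self) -> float:
        return float(self.partial_z.std(ddof=1)) if self.partial_z is not None else float("nan")

    @property
    def p_simple(self) -> float:
        return float(stats.ttest_1samp(self.simple_z, 0.0).pvalue)

    @property
    def p_partial(self) -> float:
        if self.partial_z is None:
            return float("nan")
        return float(stats.ttest_1samp(self.partial_z, 0.0).pvalue)

    @property
    def p_paired(self) -> float:
        if self.partial_z is None:
            return float("nan")
        return float(stats.ttest_rel(self.partial_z, self.simple_z).pvalue)


def partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial correlation of x and y given z, by residualizing
    both on [1, z] and correlating the residuals."""
    zz = np.column_stack([np.ones_like(z), z])
    rx = x - zz @ np.linalg.lstsq(zz, x, rcond=None)[0]
    ry = y - zz @ np.linalg.lstsq(zz, y, rcond=None)[0]
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        raise DegenerateDataError("zero residual variance in partial correlation")
    return float(rx @ ry / denom)


def pma_association(
    cohort: pd.DataFrame,
    network: str,
    condition: str,
    control_fd: bool = True,
    n_boot: int = 5000,
    subset_frac: float = 0.5,
    seed: Optional[int] = None,
    with_replacement: bool = False,
) -> BootstrapResult:
    """Bootstrap-subsampled PMA-strength association, simple and FD-partialled.

    Each replicate draws ``floor(subset_frac * n)`` scans (without replacement
    by default: subsampling, not classic resampling) and records Fisher-z
    transformed correlations.
    """
    for col in ("pma_weeks", fd_column(condition), fc_column(network, condition)):
        if col not in cohort.columns:
            raise ValidationError(f"cohort table lacks column {col!r}")
    sub = cohort[["pma_weeks", fd_column(condition), fc_column(network, condition)]].dropna()
    n = len(sub)
    if n < 10:
        raise ValidationError(f"need >= 10 scans, got {n}")
    m = int(np.floor(subset_frac * n))
    if m < 4:
        raise ValidationError(f"subset of {m} scans too small for correlation")
    pma = sub["pma_weeks"].to_numpy(float)
    fd = sub[fd_column(condition)].to_numpy(float)
    y = sub[fc_column(network, condition)].to_numpy(float)
    rng = np.random.default_rng(seed)
    simple = np.empty(n_boot)
    partial = np.empty(n_boot) if control_fd else None
    for b in range(n_boot):
        idx = rng.choice(n, size=m, replace=with_replacement)
        xs, ys, zs = pma[idx], y[idx], fd[idx]
        r = np.corrcoef(xs, ys)[0, 1]
        simple[b] = fisher_z(r)
        if control_fd:
            partial[b] = fisher_z(partial_corr(xs, ys, zs))
    return BootstrapResult(
        simple_z=simple, partial_z=partial, n_boot=n_boot,
        subset_frac=subset_frac, seed=seed, network=network, condition=condition,
    )


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple:
    """Benjamini-Hochberg step-up: rejection mask and monotone q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, qvals, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, qvals
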
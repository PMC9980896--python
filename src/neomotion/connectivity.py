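"""ROI timeseries extraction, Fisher-z connectivity, and seed maps.

Functional connectivity between two units is the Fisher z-transform
(``atanh``) of the Pearson correlation of their BOLD time courses over the
surviving frames. The z-transform stabilises the sampling variance so values
can be averaged across scans and tested with t statistics. Perfect
correlations (|r| within 1e-12 of 1) are clamped before the transform so the
output stays finite; clamped entries are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DegenerateDataError, ValidationError

#: correlations with |r| >= 1 - CLAMP_EPS are clamped before atanh
CLAMP_EPS = 1e-12
Z_MAX = float(np.arctanh(1.0 - CLAMP_EPS))

ROI_TABLE_COLUMNS = ["roi_id", "name", "hemi", "partner_id", "x_mm", "y_mm", "z_mm"]


@dataclass(frozen=True)
class RoiTable:
    """Parcellation table: ROI ids, names, hemispheres, homotopic partners,
    centroid coordinates in mm.

    The homotopic partner mapping is taken from the explicit ``partner_id``
    column, never inferred from label parity or naming conventions.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in ROI_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"ROI table missing columns: {missing}")
        if df["roi_id"].duplicated().any():
            raise ValidationError("duplicate roi_id in ROI table")
        if not np.all(np.isfinite(df[["x_mm", "y_mm", "z_mm"]].to_numpy(float))):
            raise ValidationError("non-finite ROI centroids")
        pmap = dict(zip(df["roi_id"], df["partner_id"]))
        for rid, pid in pmap.items():
            if pid not in pmap or pmap[pid] != rid:
                raise ValidationError(
                    f"partner mapping not symmetric at roi_id {rid} -> {pid}"
                )
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["roi_id"].to_numpy()

    def index_of(self, roi_id: int) -> int:
        pos = np.flatnonzero(self.ids == roi_id)
        if pos.size == 0:
            raise ValidationError(f"unknown roi_id {roi_id}")
        return int(pos[0])

    def partner(self, roi_id: int) -> int:
        return int(self.table.loc[self.index_of(roi_id), "partner_id"])

    def centroids(self) -> np.ndarray:
        return self.table[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

    def homotopic_pairs(self) -> pd.DataFrame:
        """One row per unordered homotopic pair: ``pair, left_id, right_id``.

        The pair name strips a trailing ``_L``/``_R`` from the member names
        when both sides share the remaining stem, else ``id-id``.
        """
        rows = []
        seen = set()
        for _, row in self.table.iterrows():
            a, b = int(row["roi_id"]), int(row["partner_id"])
            if a == b or (b, a) in seen or (a, b) in seen:
                continue
            seen.add((a, b))
            na = str(row["name"])
            nb = str(self.table.loc[self.index_of(b), "name"])
            stem_a, stem_b = na.rsplit("_", 1)[0], nb.rsplit("_", 1)[0]
            pair = stem_a if stem_a == stem_b else f"{min(a, b)}-{max(a, b)}"
            left = a if str(row["hemi"]).upper().startswith("L") else b
            right = b if left == a else a
            rows.append({"pair": pair, "left_id": left, "right_id": right})
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.table[ROI_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RoiTable":
        return cls(pd.read_csv(path, sep="\t"))


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh with clamping of |r| >= 1 - 1e-12 to keep z finite."""
    return np.arctanh(np.clip(r, -1.0 + CLAMP_EPS, 1.0 - CLAMP_EPS))


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric Fisher-z connectivity matrix; diagonal is NaN (undefined)."""

    z: np.ndarray
    condition: str = "none"
    n_frames_used: int = 0
    zero_variance_rois: tuple = ()
    clamped: bool = False

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]

    def upper_values(self) -> np.ndarray:
        """Edge values for the ``n*(n-1)/2`` unordered pairs, row-major."""
        iu = np.triu_indices(self.n_rois, k=1)
        return self.z[iu]


def fc_matrix(
    ts: np.ndarray | pd.DataFrame,
    keep_mask: Optional[np.ndarray] = None,
    condition: str = "none",
) -> FCMatrix:
    """Pearson correlation over surviving frames, Fisher z-transformed.

    Zero-variance ROIs yield NaN rows/columns (flagged in
    ``zero_variance_rois``) rather than silent zeros.
    """
    y = np.asarray(ts, dtype=float)
    if y.ndim != 2:
        raise ValidationError("timeseries must be 2-D (frames x ROIs)")
    if keep_mask is not None:
        mask = np.asarray(keep_mask, dtype=bool)
        if mask.size != y.shape[0]:
            raise ValidationError("keep_mask length mismatch")
        y = y[mask]
    if y.shape[0] < 3:
        raise ValidationError(
            f"need >= 3 surviving frames to correlate, got {y.shape[0]}"
        )
    sd = y.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(y.T)
    r = np.atleast_2d(r)
    clamped = bool(np.any(np.abs(r[~np.isnan(r)]) >= 1.0 - CLAMP_EPS))
    z = np.asarray(fisher_z(r), dtype=float)
    z[dead, :] = np.nan
    z[:, dead] = np.nan
    np.fill_diagonal(z, np.nan)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float asymmetries
    return FCMatrix(
        z=z,
        condition=condition,
        n_frames_used=y.shape[0],
        zero_variance_rois=tuple(int(i) for i in dead),
        clamped=clamped,
    )


def homotopic_fc(
    fc: FCMatrix,
    roi_table: RoiTable,
    pair_ids: Optional[Sequence[str]] = None,
) -> pd.Series:
    """Fisher-z strength per named left-right homotopic pair."""
    pairs = roi_table.homotopic_pairs()
    if pair_ids is not None:
        unknown = set(pair_ids) - set(pairs["pair"])
        if unknown:
            raise ValidationError(f"unknown homotopic pair(s): {sorted(unknown)}")
        pairs = pairs[pairs["pair"].isin(pair_ids)]
    vals = {}
    for _, row in pairs.iterrows():
        i = roi_table.index_of(row["left_id"])
        j = roi_table.index_of(row["right_id"])
        vals[row["pair"]] = fc.z[i, j]
    return pd.Series(vals, name="homotopic_z")


def roi_distances(roi_table: RoiTable) -> np.ndarray:
    """Euclidean distance (mm) between ROI centroids; symmetric, zero diagonal."""
    c = roi_table.centroids()
    return cdist(c, c)


def seed_map(
    ts_targets: np.ndarray | pd.DataFrame, seed_ts: np.ndarray
) -> np.ndarray:
    """Fisher-z of the Pearson correlation between a seed series and every
    target unit. Bilateral seeds must be averaged into ``seed_ts`` first."""
    y = np.asarray(ts_targets, dtype=float)
    s = np.asarray(seed_ts, dtype=float).ravel()
    if y.shape[0] != s.size:
        raise ValidationError("seed and target frame counts differ")
    if s.std() == 0:
        raise DegenerateDataError("seed series has zero variance")
    sc = s - s.mean()
    yc = y - y.mean(axis=0)
    denom = np.sqrt((sc**2).sum()) * np.sqrt((yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, sc @ yc / denom, np.nan)
    return np.asarray(fisher_z(r), dtype=float)


def extract_roi_timeseries(
    image_4d,
    parcellation,
    roi_table: RoiTable,
) -> pd.DataFrame:
    """Mean BOLD series over the voxels of each ROI label.

    Accepts nibabel spatial images or plain arrays; the label image grid must
    match the BOLD grid. ROI order follows ``roi_table``; any roi_id absent
    from the parcellation raises an error listing every missing label.
    """
    data = np.asarray(getattr(image_4d, "dataobj", image_4d), dtype=float)
    labels = np.asarray(getattr(parcellation, "dataobj", parcellation))
    if data.ndim != 4:
        raise ValidationError(f"BOLD image must be 4-D, got shape {data.shape}")
    if labels.shape != data.shape[:3]:
        raise ValidationError(
            f"parcellation grid {labels.shape} != BOLD grid {data.shape[:3]}"
        )
    missing = [int(r) for r in roi_table.ids if not np.any(labels == r)]
    if missing:
        raise ValidationError(f"labels absent from parcellation: {missing}")
    cols = {}
    for rid in roi_table.ids:
        mask = labels == rid
        cols[int(rid)] = data[mask, :].mean(axis=0)
    return pd.DataFrame(cols)


def write_fc_matrix(path: str | Path, fc: FCMatrix, roi_table: RoiTable) -> None:
    """Write an FC matrix as TSV with a roi_id header."""
    ids = [int(i) for i in roi_table.ids]
    pd.DataFrame(fc.z, index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="roi_id", float_format="%.6f"
    )
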
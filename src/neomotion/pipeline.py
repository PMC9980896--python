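"""End-to-end orchestration of the three cohort analyses.

Binds the stages together into the three experiments the CLI exposes:

1. **QC** -- FD summaries, censored fractions, tSNR, and the FD-tSNR
   association across the cohort.
2. **Censoring evaluation** -- per-condition FD-FC associations, edgewise
   contamination fractions, low/high-motion group contrasts with FDR,
   distance-dependence analyses, and the ANOVA across censoring conditions.
3. **PMA bootstrap** -- simple versus FD-partialled PMA-connectivity
   correlation over bootstrap subsamples.

Censoring conditions are evaluated at an equal scan length: the 4-minute cap
is applied to every condition (including "no censoring") before any
connectivity is computed, so differences between conditions are not
confounded by different numbers of frames.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    censor_distance_shift,
    distance_dependence,
    edgewise_fd_association,
    fc_column,
    fd_column,
    fd_fc_association,
    group_contrast,
    pma_association,
    split_by_motion,
    strength_comparison,
)
from .cleaning import CleanOptions, clean_timeseries, compute_tsnr, friston24
from .connectivity import FCMatrix, fc_matrix, homotopic_fc, roi_distances
from .errors import InvalidConfigError, ValidationError
from .motion import (
    CensorPlan,
    censor_summary,
    compute_fd,
    condition_tag,
    make_censor_plan,
    mean_fd,
    write_fd_table,
)
from .connectivity import RoiTable
from .errors import NeomotionError
from .motion import read_motion_params
from .synthetic import Cohort, Scan, SyntheticConfig, make_cohort, read_scan_tsv

DEFAULT_THRESHOLDS = (None, 0.5, 0.2)


def load_cohort(
    data_dir: str | Path,
    tr_seconds: float = 2.0,
    rot_unit: str = "rad",
    col_order: str = "txyz-rpy",
    skip_bad: bool = False,
) -> Cohort:
    """Load a cohort from disk: ``cohort.tsv`` (scan_id, pma_weeks, sex),
    ``roi_table.tsv``, and per scan ``<id>_bold.tsv`` + ``<id>_motion.par``.

    With ``skip_bad`` malformed scans are dropped (and reported in the
    returned table's attrs); otherwise the first error is raised.
    """
    d = Path(data_dir)
    table = pd.read_csv(d / "cohort.tsv", sep="\t")
    if "scan_id" not in table.columns:
        raise ValidationError(f"{d / 'cohort.tsv'}: missing 'scan_id' column")
    geometry = RoiTable.from_tsv(d / "roi_table.tsv")
    scans, bad = [], []
    for _, row in table.iterrows():
        sid = str(row["scan_id"])
        try:
            ts = read_scan_tsv(d / f"{sid}_bold.tsv")
            motion = read_motion_params(
                d / f"{sid}_motion.par", tr_seconds, rot_unit, col_order
            )
            if len(ts) != motion.n_frames:
                raise ValidationError(
                    f"{sid}: {len(ts)} BOLD frames != {motion.n_frames} motion frames"
                )
            scans.append(
                Scan(
                    scan_id=sid, timeseries=ts, motion=motion,
                    ground_truth=None,
                    pma_weeks=float(row["pma_weeks"]) if "pma_weeks" in row else float("nan"),
                )
            )
        except (NeomotionError, OSError) as exc:
            if not skip_bad:
                raise
            bad.append({"scan_id": sid, "error": str(exc)})
    if not scans:
        raise ValidationError(f"no readable scans in {d}")
    keep = table["scan_id"].astype(str).isin([s.scan_id for s in scans])
    out_table = table[keep].reset_index(drop=True)
    out_table.attrs["skipped"] = bad
    return Cohort(scans=tuple(scans), table=out_table, geometry=geometry, config=None)


@dataclass
class RunConfig:
    """Configuration of a pipeline run; round-trips through YAML losslessly."""

    synthetic: Optional[SyntheticConfig] = None
    input_dir: Optional[str] = None
    tr_seconds: float = 2.0
    rot_unit: str = "rad"
    col_order: str = "txyz-rpy"
    skip_bad: bool = False
    thresholds_mm: tuple = DEFAULT_THRESHOLDS
    cap_seconds: Optional[float] = 240.0
    clean: bool = True
    band_hz: tuple = (0.009, 0.08)
    gsr: bool = False
    networks: Optional[tuple] = None
    alpha_unc: float = 0.01
    fdr_q: float = 0.05
    alpha_edge: float = 0.05
    split_fraction: float = 0.25
    n_boot: int = 5000
    subset_frac: float = 0.5
    seed: int = 0
    out_dir: str = "neomotion_out"

    def __post_init__(self) -> None:
        for t in self.thresholds_mm:
            if t is not None and t <= 0:
                raise InvalidConfigError("censoring thresholds must be positive")
        if self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds_mm"] = list(self.thresholds_mm)
        d["band_hz"] = list(self.band_hz)
        if self.networks is not None:
            d["networks"] = list(self.networks)
        if d["synthetic"] is not None:
            d["synthetic"]["pma_range_weeks"] = list(
                self.synthetic.pma_range_weeks
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        if syn is not None:
            syn = dict(syn)
            if "pma_range_weeks" in syn:
                syn["pma_range_weeks"] = tuple(syn["pma_range_weeks"])
            syn = SyntheticConfig(**syn)
        kwargs = {}
        for key, val in d.items():
            if key in ("thresholds_mm", "band_hz", "networks") and val is not None:
                val = tuple(val)
            kwargs[key] = val
        return cls(synthetic=syn, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CohortAnalysis:
    """Per-scan and per-condition products of one cohort pass."""

    cohort_df: pd.DataFrame
    fc_stacks: dict
    mean_fc: dict
    plans: dict
    distances: np.ndarray
    truth_mean_z: Optional[np.ndarray]
    networks: tuple
    conditions: tuple


def analyze_cohort(
    cohort: Cohort,
    thresholds_mm: Sequence[Optional[float]] = DEFAULT_THRESHOLDS,
    cap_seconds: Optional[float] = 240.0,
    clean: bool = True,
    band_hz: tuple = (0.009, 0.08),
    gsr: bool = False,
    networks: Optional[Sequence[str]] = None,
) -> CohortAnalysis:
    """Run every scan through FD -> censoring -> (cleaning) -> connectivity.

    Cleaning (Friston-24 + band-pass joint projection, optional GSR) runs on
    the full series; frames are dropped only afterwards, per condition, when
    connectivity is computed. tSNR and FD always come from the raw data.
    """
    geometry = cohort.geometry
    pair_table = geometry.homotopic_pairs()
    all_networks = tuple(pair_table["pair"])
    networks = tuple(networks) if networks is not None else all_networks
    unknown = set(networks) - set(all_networks)
    if unknown:
        raise ValidationError(f"unknown network(s): {sorted(unknown)}")
    tags = tuple(condition_tag(t) for t in thresholds_mm)
    tr = cohort.scans[0].motion.frame_period

    rows = []
    stacks = {tag: [] for tag in tags}
    plans: dict = {tag: [] for tag in tags}
    truth_z = []
    for scan in cohort.scans:
        fd = compute_fd(scan.motion)
        raw = scan.timeseries.to_numpy(dtype=float)
        tsnr = compute_tsnr(raw)
        if clean:
            opts = CleanOptions(tr_seconds=tr, band_hz=tuple(band_hz), gsr_enabled=gsr)
            from .cleaning import build_design

            design = build_design(
                motion=scan.motion,
                gray_timeseries=raw if gsr else None,
                options=opts,
            )
            ts = clean_timeseries(raw, design, opts)
        else:
            ts = raw
        row = {
            "scan_id": scan.scan_id,
            "pma_weeks": scan.pma_weeks,
            "tsnr": tsnr.mean,
        }
        for thr, tag in zip(thresholds_mm, tags):
            plan = make_censor_plan(fd, thr, cap_seconds, tr)
            plans[tag].append(plan)
            row[fd_column(tag)] = mean_fd(fd, plan.keep_mask)
            row[f"censored_frac_{tag}"] = plan.censored_fraction
            if plan.n_survivors >= 3:
                fc = fc_matrix(ts, plan.keep_mask, condition=tag)
            else:
                # scan unusable at this threshold: flag with all-NaN FC
                nan = np.full((ts.shape[1], ts.shape[1]), np.nan)
                fc = FCMatrix(z=nan, condition=tag, n_frames_used=plan.n_survivors)
            stacks[tag].append(fc)
            strengths = homotopic_fc(fc, geometry, pair_ids=networks)
            for net, val in strengths.items():
                row[fc_column(net, tag)] = val
        rows.append(row)
        if scan.ground_truth is not None:
            truth_z.append(scan.ground_truth.true_z())

    per_scan = pd.DataFrame(rows).drop(columns=["pma_weeks"])
    cohort_df = cohort.table.merge(per_scan, on="scan_id")
    fc_stacks = {
        tag: np.vstack([m.upper_values() for m in mats])
        for tag, mats in stacks.items()
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN diagonal
        mean_fc = {
            tag: np.nanmean(np.stack([m.z for m in mats]), axis=0)
            for tag, mats in stacks.items()
        }
        truth_mean = np.nanmean(np.stack(truth_z), axis=0) if truth_z else None
    return CohortAnalysis(
        cohort_df=cohort_df,
        fc_stacks=fc_stacks,
        mean_fc=mean_fc,
        plans=plans,
        distances=roi_distances(geometry),
        truth_mean_z=truth_mean,
        networks=networks,
        conditions=tags,
    )


def _write_manifest(out: Path, config: RunConfig, stage: str) -> None:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "neomotion_version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))



def _get_cohort(config: "RunConfig", cohort=None):
    if cohort is not None:
        return cohort
    if config.input_dir:
        return load_cohort(
            config.input_dir, config.tr_seconds, config.rot_unit,
            config.col_order, config.skip_bad,
        )
    return make_cohort(config.synthetic)

def run_qc(config: RunConfig, cohort: Optional[Cohort] = None) -> dict:
    """QC experiment: FD/censoring summaries, tSNR, FD-tSNR association."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = _get_cohort(config, cohort)
    analysis = analyze_cohort(
        cohort, config.thresholds_mm, config.cap_seconds,
        clean=False, networks=config.networks,
    )
    df = analysis.cohort_df
    summary = censor_summary(analysis.plans)
    uncens = condition_tag(config.thresholds_mm[0])
    from scipy import stats as _stats

    fd_vals = df[fd_column(uncens)].to_numpy(float)
    if fd_vals.std() == 0 or df["tsnr"].std() == 0:
        r, p = float("nan"), float("nan")  # zero-motion cohort: undefined
    else:
        r, p = _stats.pearsonr(fd_vals, df["tsnr"].to_numpy(float))
    qc_stats = {
        "r_tsnr_fd": float(r),
        "p_tsnr_fd": float(p),
        "mean_fd_mean": float(fd_vals.mean()),
        "mean_fd_sd": float(fd_vals.std(ddof=1)),
        "mean_fd_max": float(fd_vals.max()),
        "n_scans": int(len(df)),
    }
    keep = ["scan_id", "pma_weeks", "sex", "tsnr"] + [
        c for c in df.columns if c.startswith(("mean_fd_", "censored_frac_"))
    ]
    df[keep].to_csv(out / "qc_scans.tsv", sep="\t", index=False, float_format="%.6f")
    summary.to_csv(out / "qc_censoring.tsv", sep="\t", float_format="%.6f")
    (out / "qc_stats.json").write_text(json.dumps(qc_stats, indent=2, sort_keys=True))
    _write_manifest(out, config, "qc")
    return {"cohort": df, "censoring": summary, "stats": qc_stats}


def run_censoring_eval(config: RunConfig, cohort: Optional[Cohort] = None) -> dict:
    """Censoring-versus-connectivity experiment across all conditions."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = _get_cohort(config, cohort)
    analysis = analyze_cohort(
        cohort, config.thresholds_mm, config.cap_seconds,
        clean=config.clean, band_hz=config.band_hz, gsr=config.gsr,
        networks=config.networks,
    )
    df = analysis.cohort_df
    tags = analysis.conditions

    assoc_rows = []
    for tag in tags:
        for net in analysis.networks:
            res = fd_fc_association(df, net, tag)
            assoc_rows.append(
                {"condition": tag, "network": net, "r": res.r, "p": res.p, "n": res.n}
            )
    assoc = pd.DataFrame(assoc_rows)

    edge_rows = []
    edgewise = {}
    for tag in tags:
        res = edgewise_fd_association(
            analysis.fc_stacks[tag], df[fd_column(tag)].to_numpy(float),
            alpha=config.alpha_edge, condition=tag,
        )
        edgewise[tag] = res
        edge_rows.append(
            {"condition": tag, "n_edges": res.n_edges,
             "significant_fraction": res.significant_fraction}
        )
    edge_summary = pd.DataFrame(edge_rows)

    contrasts = {}
    delta_sets = {}
    group_analysis = len(df) >= 8
    if group_analysis:
        for tag in tags:
            low, high = split_by_motion(df, tag, config.split_fraction)
            idx = {sid: i for i, sid in enumerate(df["scan_id"])}
            lo_rows = [idx[s] for s in low]
            hi_rows = [idx[s] for s in high]
            stack = analysis.fc_stacks[tag]
            gc = group_contrast(
                stack[lo_rows], stack[hi_rows],
                alpha_unc=config.alpha_unc, fdr_q=config.fdr_q,
            )
            contrasts[tag] = gc
            if gc.sig_unc.any():
                delta_sets[tag] = gc.delta_z[gc.sig_unc]
    anova = None
    if len([k for k, v in delta_sets.items() if v.size >= 2]) >= 2:
        anova = strength_comparison(
            {k: v for k, v in delta_sets.items() if v.size >= 2}
        )

    dist_rows = []
    for tag in tags:
        res = distance_dependence(analysis.mean_fc[tag], analysis.distances)
        dist_rows.append(
            {"analysis": f"distance_fc_{tag}", "r": res.r, "p": res.p,
             "n": res.n, "degenerate": res.degenerate}
        )
    strictest = tags[-1]
    shift = censor_distance_shift(
        analysis.mean_fc[tags[0]], analysis.mean_fc[strictest], analysis.distances
    )
    dist_rows.append(
        {"analysis": f"censor_shift_{tags[0]}_vs_{strictest}", "r": shift.r,
         "p": shift.p, "n": shift.n, "degenerate": shift.degenerate}
    )
    dist = pd.DataFrame(dist_rows)

    assoc.to_csv(out / "association.tsv", sep="\t", index=False, float_format="%.6f")
    edge_summary.to_csv(out / "edgewise.tsv", sep="\t", index=False, float_format="%.6f")
    dist.to_csv(out / "distance.tsv", sep="\t", index=False, float_format="%.6f")
    if contrasts:
        rows = []
        for tag, gc in contrasts.items():
            rows.append(
                {"condition": tag, "n_low": gc.n_low, "n_high": gc.n_high,
                 "n_sig_unc": gc.n_sig_unc, "frac_sig_unc": gc.frac_sig_unc,
                 "n_sig_fdr": gc.n_sig_fdr, "frac_sig_fdr": gc.frac_sig_fdr,
                 "mean_delta_z_sig": gc.mean_delta_z_sig}
            )
        pd.DataFrame(rows).to_csv(
            out / "group_contrast.tsv", sep="\t", index=False, float_format="%.6f"
        )
    if anova is not None:
        payload = {
            "F": anova["F"], "df": list(anova["df"]), "p": anova["p"],
            "posthoc": anova["posthoc"].to_dict(orient="records"),
        }
        (out / "anova.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    _write_manifest(out, config, "censor-eval")
    return {
        "cohort": df, "associations": assoc, "edgewise": edgewise,
        "edge_summary": edge_summary, "contrasts": contrasts,
        "anova": anova, "distance": dist, "analysis": analysis,
    }


def run_pma_analysis(
    config: RunConfig,
    cohort_df: Optional[pd.DataFrame] = None,
    networks: Optional[Sequence[str]] = None,
    condition: Optional[str] = None,
) -> dict:
    """Bootstrap PMA-connectivity analysis, simple versus FD-partialled."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort_df is None:
        cohort = _get_cohort(config)
        analysis = analyze_cohort(
            cohort, config.thresholds_mm, config.cap_seconds,
            clean=config.clean, band_hz=config.band_hz, gsr=config.gsr,
            networks=config.networks,
        )
        cohort_df = analysis.cohort_df
        networks = networks or analysis.networks
        condition = condition or analysis.conditions[0]
    if "pma_weeks" not in cohort_df.columns:
        raise ValidationError("cohort table lacks a 'pma_weeks' column")
    if networks is None or condition is None:
        raise ValidationError("networks and condition must be given with a table")
    rows = []
    results = {}
    for i, net in enumerate(networks):
        res = pma_association(
            cohort_df, net, condition, control_fd=True,
            n_boot=config.n_boot, subset_frac=config.subset_frac,
            seed=config.seed + i,
        )
        results[net] = res
        rows.append(
            {"network": net, "condition": condition,
             "mean_simple_z": res.mean_simple, "sd_simple_z": res.sd_simple,
             "mean_partial_z": res.mean_partial, "sd_partial_z": res.sd_partial,
             "p_simple": res.p_simple, "p_partial": res.p_partial,
             "p_paired": res.p_paired, "n_boot": res.n_boot}
        )
    table = pd.DataFrame(rows)
    table.to_csv(out / "bootstrap.tsv", sep="\t", index=False, float_format="%.6g")
    _write_manifest(out, config, "pma")
    return {"table": table, "results": results}


def simulate_cohort(config: RunConfig, write_nifti: bool = False) -> Cohort:
    """Generate a synthetic cohort and write it to the output directory."""
    from .motion import write_motion_params
    from .synthetic import write_cohort_table, write_scan_nifti, write_scan_tsv

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = make_cohort(config.synthetic)
    cohort.geometry.to_tsv(out / "roi_table.tsv")
    write_cohort_table(out / "cohort.tsv", cohort)
    for scan in cohort.scans:
        write_scan_tsv(out / f"{scan.scan_id}_bold.tsv", scan)
        write_motion_params(out / f"{scan.scan_id}_motion.par", scan.motion)
        if write_nifti:
            write_scan_nifti(
                out / f"{scan.scan_id}_bold.nii.gz",
                out / f"{scan.scan_id}_parc.nii.gz",
                scan,
            )
    _write_manifest(out, config, "simulate")
    return cohort
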
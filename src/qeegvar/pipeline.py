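"""Study-level orchestration: simulate -> preprocess -> spectra -> statistics.

``run_central`` processes every recording of a study directory with one
common parameter set (the centralised-analysis mode); ``run_local``
processes each laboratory with its own analysis dialect (total-power
range, band edges, artifact threshold, reporting units), so the effect of
local versus central analysis on the between-laboratory variance is a
one-command comparison.  Both write endpoint tables, per-laboratory
contrast tables, variance-component tables, boxplot summaries, artifact
masks, a manifest and a markdown report into the output directory;
``report`` regenerates the report from those saved outputs alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .edf_io import read_metadata, read_recording, write_endpoint_table
from .errors import ConfigError, InsufficientDataError, QeegError
from .preprocess import (
    MIN_SEGMENT_S,
    clean_segments,
    detect_artifacts,
    lowpass_49,
    mask_to_bed,
    remove_dc,
    resample_100hz,
)
from .spectral import psd_of_segments
from .stats_models import (
    emm_contrast,
    fit_crosslab,
    fit_per_lab,
    log10_endpoint,
    tukey_summary,
    variance_table,
)
from .synthetic_cohort import AnalysisDialect

__all__ = ["PipelineConfig", "run_central", "run_local", "report", "process_recording"]

GENOTYPE_ENDPOINTS = ["log10_total_power", "log10_relative_theta"]
RINGTEST_ENDPOINTS = ["log10_relative_gamma", "gamma_pct_change"]


@dataclass
class PipelineConfig:
    """All pipeline parameters in one place.

    Exclusion thresholds and analysis parameters are configuration, never
    hard-coded in stage code: silent divergence of exactly these settings
    across sites is what the local/central comparison is about.
    """

    study_dir: str
    out_dir: str
    mode: str = "central"  # central | local
    endpoints: list[str] | None = None  # default derived from study phase
    # preprocessing
    rms_window_s: float = 1.0
    threshold_multiplier: float = 6.0
    pad_s: float = 0.5
    interp: str = "linear"
    max_masked_fraction: float = 0.5
    min_seg_s: float = MIN_SEGMENT_S
    # spectral
    n_freq: int = 512
    overlap: float = 0.5
    window_fn: str = "hamming"
    total_range: tuple[float, float] = (1.0, 48.0)
    theta_band: tuple[float, float] = (4.0, 8.0)
    gamma_band: tuple[float, float] = (32.0, 48.0)
    pct_change_use: str = "raw"
    # local-mode dialects: lab_id -> AnalysisDialect fields; if None they
    # are read from the study's truth record (synthetic studies).
    dialects: dict | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        for key in ("total_range", "theta_band", "gamma_band"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _central_dialect(cfg: PipelineConfig) -> AnalysisDialect:
    return AnalysisDialect(
        total_range=tuple(cfg.total_range),
        gamma_band=tuple(cfg.gamma_band),
        theta_band=tuple(cfg.theta_band),
        artifact_multiplier=cfg.threshold_multiplier,
        report_scale=1.0,
    )


def _load_dialects(cfg: PipelineConfig) -> dict[str, AnalysisDialect]:
    if cfg.dialects is not None:
        out = {}
        for lab, d in cfg.dialects.items():
            if isinstance(d, AnalysisDialect):
                out[lab] = d
            else:
                d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
                out[lab] = AnalysisDialect(**d)
        return out
    truth_path = Path(cfg.study_dir) / "truth.json"
    if not truth_path.exists():
        raise ConfigError(
            "local mode needs per-lab dialects (config.dialects or a study "
            "truth record)"
        )
    with open(truth_path) as fh:
        truth = json.load(fh)
    out = {}
    for lab in truth["design"]["labs"]:
        d = lab["dialect"]
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        out[lab["lab_id"]] = AnalysisDialect(**d)
    return out


def process_recording(
    recording,
    cfg: PipelineConfig,
    endpoints: list[str],
    dialect: AnalysisDialect | None = None,
):
    """Run one recording through the full chain to endpoint values.

    Returns (values dict, mask) or raises; exclusion conditions (too much
    masked time, no usable clean span) raise :class:`InsufficientDataError`
    with the reason.
    """
    dial = dialect or _central_dialect(cfg)
    rec = remove_dc(recording)
    rec = resample_100hz(rec, interp=cfg.interp)
    rec = lowpass_49(rec)
    mask = detect_artifacts(
        rec, cfg.rms_window_s, dial.artifact_multiplier, cfg.pad_s
    )

    needs_dose = any(e in ("log10_relative_gamma", "gamma_pct_change") for e in endpoints)
    windows = ["pre", "post"] if needs_dose else [(0.0, rec.duration)]
    spectra = {}
    for win in windows:
        segs = clean_segments(rec, mask, win, min_seg_s=cfg.min_seg_s)
        frac = mask.masked_fraction(segs.window)
        if frac > cfg.max_masked_fraction:
            raise InsufficientDataError(
                f"window {win}: {100 * frac:.0f}% masked exceeds "
                f"{100 * cfg.max_masked_fraction:.0f}% limit"
            )
        if not segs.spans:
            raise InsufficientDataError(f"window {win}: no clean span long enough")
        spectra[win if isinstance(win, str) else "all"] = psd_of_segments(
            segs.extract(rec),
            rate=rec.sampling_rate,
            n_freq=cfg.n_freq,
            overlap=cfg.overlap,
            window=cfg.window_fn,
        )

    values = {}
    for name in endpoints:
        if name == "log10_total_power":
            spec = spectra["all"]
            values[name] = float(np.log10(spec.range_sum(dial.total_range)))
        elif name == "log10_relative_theta":
            spec = spectra["all"]
            rel = spec.band_sum(*dial.theta_band) / spec.range_sum(dial.total_range)
            values[name] = float(np.log10(rel * dial.report_scale))
        elif name == "log10_relative_gamma":
            spec = spectra["post"]
            rel = (
                spec.band_sum(dial.gamma_band[0], dial.gamma_band[1], closed_high=True)
                / spec.range_sum(dial.total_range)
            )
            values[name] = float(np.log10(rel * dial.report_scale))
        elif name == "gamma_pct_change":
            lo, hi = dial.gamma_band
            if cfg.pct_change_use == "raw":
                g1 = spectra["post"].band_sum(lo, hi, closed_high=True)
                g0 = spectra["pre"].band_sum(lo, hi, closed_high=True)
            else:
                g1 = spectra["post"].band_sum(lo, hi, True) / spectra["post"].range_sum(
                    dial.total_range
                )
                g0 = spectra["pre"].band_sum(lo, hi, True) / spectra["pre"].range_sum(
                    dial.total_range
                )
            values[name] = float(100.0 * (g1 - g0) / g0)
        else:
            raise ConfigError(f"unknown endpoint {name!r}")
    return values, mask


def _run(cfg: PipelineConfig) -> dict:
    study = Path(cfg.study_dir)
    out = Path(cfg.out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    meta = read_metadata(study / "metadata.csv")

    phase = str(meta["phase"].iloc[0]) if "phase" in meta.columns else "harmonisation"
    endpoints = cfg.endpoints or (
        RINGTEST_ENDPOINTS if phase == "ringtest" else GENOTYPE_ENDPOINTS
    )
    dialects = _load_dialects(cfg) if cfg.mode == "local" else {}

    ep_rows, excluded = [], []
    for _, row in meta.iterrows():
        rec = read_recording(study / row["file"], row)
        dial = dialects.get(rec.lab_id) if cfg.mode == "local" else None
        try:
            values, mask = process_recording(rec, cfg, endpoints, dialect=dial)
        except QeegError as exc:
            excluded.append(
                {
                    "lab_id": rec.lab_id,
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "reason": str(exc),
                }
            )
            continue
        bed = mask_to_bed(rec, mask)
        (out / "masks" / f"{rec.lab_id}_{rec.subject_id}_{rec.group}.bed").write_text(bed)
        for name, value in values.items():
            ep_rows.append(
                {
                    "lab_id": rec.lab_id,
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "endpoint": name,
                    "value": value,
                }
            )

    endpoint_df = pd.DataFrame(ep_rows)
    if endpoint_df.empty:
        raise InsufficientDataError("every recording was excluded")
    write_endpoint_table(endpoint_df, out / "endpoints.csv")
    pd.DataFrame(excluded, columns=["lab_id", "subject_id", "group", "reason"]).to_csv(
        out / "excluded.csv", index=False
    )

    results = analyse_endpoints(endpoint_df, out)

    manifest = {
        "package_version": __version__,
        "mode": cfg.mode,
        "phase": phase,
        "endpoints": endpoints,
        "config": cfg.to_dict(),
        "study_files": sorted(meta["file"].tolist()),
        "n_recordings": int(len(meta)),
        "n_excluded": len(excluded),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    report(out)
    results["manifest"] = manifest
    results["excluded"] = excluded
    return results


def analyse_endpoints(endpoint_df: pd.DataFrame, out: Path) -> dict:
    """Per-lab fits, cross-lab variance components and boxplot summaries.

    Writes one contrast table and one Tukey-summary table per endpoint
    plus numeric and formatted variance-component tables; returns the
    fitted objects keyed by endpoint.
    """
    out.mkdir(parents=True, exist_ok=True)
    endpoints = list(dict.fromkeys(endpoint_df["endpoint"]))
    labs = list(dict.fromkeys(endpoint_df["lab_id"]))
    results: dict = {"per_lab": {}, "crosslab": {}, "tukey": {}}

    vc_numeric_rows = []
    for name in endpoints:
        contrast_rows = []
        for lab in labs:
            try:
                fit = fit_per_lab(endpoint_df, lab, name)
            except InsufficientDataError:
                continue
            results["per_lab"].setdefault(name, {})[lab] = fit
            for g, (est, se, lo, hi) in fit.group_means.items():
                contrast_rows.append(
                    {
                        "lab_id": lab,
                        "term": g,
                        "estimate": est,
                        "se": se,
                        "lower_cl": lo,
                        "upper_cl": hi,
                        "p": np.nan,
                    }
                )
            for c in fit.contrasts:
                contrast_rows.append(
                    {
                        "lab_id": lab,
                        "term": c.name,
                        "estimate": c.estimate,
                        "se": c.se,
                        "lower_cl": c.ci_low,
                        "upper_cl": c.ci_high,
                        "p": c.p,
                    }
                )
        pd.DataFrame(contrast_rows).to_csv(
            out / f"per_lab_contrasts_{name}.csv", index=False
        )

        vc = fit_crosslab(endpoint_df, name)
        results["crosslab"][name] = vc
        vc_numeric_rows.append(
            {
                "endpoint": name,
                "sigma_b2": vc.sigma_b2,
                "sigma_d2": vc.sigma_d2,
                "sigma_e2": vc.sigma_e2,
                "total": vc.total,
                **{f"share_{k}": v for k, v in vc.shares.items()},
            }
        )
        emm_rows = []
        for g in vc.groups[1:]:
            c = emm_contrast(vc, (g, vc.groups[0]))
            emm_rows.append(
                {
                    "term": c.name,
                    "estimate": c.estimate,
                    "se": c.se,
                    "lower_cl": c.ci_low,
                    "upper_cl": c.ci_high,
                    "p": c.p,
                }
            )
        pd.DataFrame(emm_rows).to_csv(out / f"emm_contrasts_{name}.csv", index=False)

        tk_rows = []
        for (lab, group), sub in endpoint_df[endpoint_df["endpoint"] == name].groupby(
            ["lab_id", "group"], sort=False
        ):
            s = tukey_summary(sub["value"])
            results["tukey"].setdefault(name, {})[(lab, group)] = s
            tk_rows.append(
                {
                    "lab_id": lab,
                    "group": group,
                    "n": len(sub),
                    "q1": s.q1,
                    "median": s.median,
                    "q3": s.q3,
                    "whisker_low": s.whisker_low,
                    "whisker_high": s.whisker_high,
                    "n_outliers": len(s.outliers),
                }
            )
        pd.DataFrame(tk_rows).to_csv(out / f"tukey_{name}.csv", index=False)

    pd.DataFrame(vc_numeric_rows).to_csv(out / "variance_components.csv", index=False)
    table = variance_table({name: results["crosslab"][name] for name in endpoints})
    table.to_csv(out / "variance_table.csv")
    return results


def run_central(cfg: PipelineConfig) -> dict:
    """Centralised analysis: identical parameters for every laboratory."""
    cfg.mode = "central"
    return _run(cfg)


def run_local(cfg: PipelineConfig) -> dict:
    """Local analysis: each laboratory's own dialect, same statistics."""
    cfg.mode = "local"
    return _run(cfg)


def report(out_dir) -> str:
    """Regenerate the markdown report from saved outputs (no recompute)."""
    out = Path(out_dir)
    lines = ["# qEEG multi-laboratory analysis report", ""]
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines += [
            f"- mode: **{manifest.get('mode')}**, phase: {manifest.get('phase')}",
            f"- recordings: {manifest.get('n_recordings')} "
            f"({manifest.get('n_excluded')} excluded)",
            f"- package version: {manifest.get('package_version')}",
            "",
        ]
    vt = out / "variance_table.csv"
    if vt.exists():
        lines += ["## Variance components", ""]
        lines += _csv_to_md(vt)
    for f in sorted(out.glob("per_lab_contrasts_*.csv")):
        name = f.stem.replace("per_lab_contrasts_", "")
        lines += [f"## Per-laboratory estimates and contrasts: {name}", ""]
        lines += _csv_to_md(f)
    for f in sorted(out.glob("tukey_*.csv")):
        name = f.stem.replace("tukey_", "")
        lines += [f"## Boxplot summaries (per lab and group): {name}", ""]
        lines += _csv_to_md(f)
    ex = out / "excluded.csv"
    if ex.exists():
        df = pd.read_csv(ex)
        lines += ["## Excluded recordings", ""]
        if df.empty:
            lines.append("none")
        else:
            lines += _df_to_md(df)
        lines.append("")
    lines.append("_Per-laboratory p-values are unadjusted (no multiple-testing correction)._")
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text


def _csv_to_md(path: Path) -> list[str]:
    return _df_to_md(pd.read_csv(path))


def _df_to_md(df: pd.DataFrame) -> list[str]:
    def fmt(v):
        if isinstance(v, float):
            return "" if pd.isna(v) else f"{v:.4g}"
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "---|" * len(df.columns)
    rows = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return [header, sep, *rows, ""]
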
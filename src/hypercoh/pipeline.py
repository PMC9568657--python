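"""Configured, logged, reproducible end-to-end runs.

Stage order: simulate (or load) -> preprocess -> ERP -> scalp coherence ->
source coherence (optional) -> statistics. Every stage writes immutable
TSV/JSON outputs into the run directory; a manifest records the package
version, the normalized configuration and its hash, so a run is fully
reproducible from (config, seed).
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coherence import collapse_band, dyad_trial_coherence
from .erp import average_epochs, peak_table
from .io import DyadRecording, read_fixture, read_leadfield, read_roi_table
from .preprocess import preprocess_dyad
from .source import (
    apply_inverse,
    build_eloreta,
    crossvalidate_lambda,
    drop_unmodeled_channels,
    orient_pca,
    roi_epochs,
)
from .stats import (
    StatSeries,
    agency_contrast,
    ar1_coefficient,
    gb_filter,
    gb_threshold,
    mixed_anova,
    pointwise_paired_t,
)
from .synth import AGENCY_LEVELS, CouplingSpec, generate_schedule, simulate_dyad

logger = logging.getLogger("hypercoh")

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "n_dyads": 14,
    "n_blocks": 7,
    "trials_per_block": 30,
    "iti_samples": 1000,
    "fs": 250.0,
    "channel_names": None,  # None -> full 61+3 default montage
    "kappa": {"fair": 0.9, "unfair": 0.5, "hyperunfair": 0.3},
    "amp_by_fairness": {"fair": 8.0, "unfair": 5.0, "hyperunfair": 4.0},
    "noise_pink_sigma": 10.0,
    "noise_white_sigma": 2.0,
    "input_fixtures": None,  # list of dyad fixture paths; overrides simulation
    "filter_low": 1.0,
    "filter_high": 45.0,
    "epoch_window": (-0.2, 1.0),
    "baseline_window": (-0.2, 0.0),
    "reject_threshold_uv": 80.0,
    "band": (4.0, 7.0),
    "voices": 12,
    "analysis_channel": "Pz",
    "peak_window": (0.4, 0.8),
    "alpha": 0.05,
    "gb_rho": "auto",  # AR(1) for the run-length null; 'auto' estimates it
    "gb_n_sim": 2000,
    "source_enabled": False,
    "leadfield": None,
    "roi_table": None,
    "lam": "auto",
    "lambda_grid": (0.0, 1e-2, 1.0),
    "fairness_contrast": ("fair", "hyperunfair"),
}


@dataclass
class RunConfig:
    """Validated, fully-defaulted pipeline configuration."""

    values: dict[str, Any] = field(default_factory=dict)

    def __getattr__(self, key: str) -> Any:
        try:
            return self.values[key]
        except KeyError as e:
            raise AttributeError(key) from e

    def hash(self) -> str:
        blob = json.dumps(self.values, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(source: str | os.PathLike | dict | None = None) -> RunConfig:
    """Normalize a config mapping or YAML file; all errors reported at once.

    Unknown keys are rejected naming the nearest valid key; paper-default
    parameter values (1-45 Hz band, -200..1000 ms window, +-80 µV,
    4-7 Hz, alpha 0.05) fill anything unspecified.
    """
    if source is None:
        raw: dict[str, Any] = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.pop("paper_defaults", None)  # explicit no-op switch
    errors: list[str] = []
    for key in raw:
        if key not in _DEFAULTS:
            near = difflib.get_close_matches(key, _DEFAULTS, n=1)
            hint = f" (did you mean {near[0]!r}?)" if near else ""
            errors.append(f"unknown key {key!r}{hint}")
    cfg = {**_DEFAULTS, **{k: v for k, v in raw.items() if k in _DEFAULTS}}

    for key in ("epoch_window", "baseline_window", "band", "peak_window"):
        v = cfg[key]
        if not (isinstance(v, (list, tuple)) and len(v) == 2):
            errors.append(f"{key} must be a (low, high) pair, got {v!r}")
        elif not v[0] < v[1]:
            errors.append(f"{key} range invalid: {v[0]} >= {v[1]}")
        else:
            cfg[key] = (float(v[0]), float(v[1]))
    if cfg["filter_low"] >= cfg["filter_high"]:
        errors.append("filter_low must be < filter_high")
    if not 0 < cfg["alpha"] < 1:
        errors.append(f"alpha must be in (0, 1), got {cfg['alpha']}")
    if cfg["reject_threshold_uv"] <= 0:
        errors.append("reject_threshold_uv must be positive")
    if cfg["seed"] is None:
        errors.append("seed is mandatory")
    if cfg["source_enabled"]:
        for key in ("leadfield", "roi_table"):
            path = cfg[key]
            if path is None:
                errors.append(f"source stage enabled but {key} not given")
            elif not os.path.exists(path):
                errors.append(f"{key} file not found: {path}")
    if cfg["input_fixtures"]:
        for p in cfg["input_fixtures"]:
            if not os.path.exists(p):
                errors.append(f"input fixture not found: {p}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return RunConfig(values=cfg)


def _simulate_dyads(cfg: RunConfig) -> list[DyadRecording]:
    dyads = []
    for d in range(cfg.n_dyads):
        seed = cfg.seed * 10007 + d
        schedule = generate_schedule(
            n_blocks=cfg.n_blocks,
            trials_per_block=cfg.trials_per_block,
            iti_samples=cfg.iti_samples,
            seed=seed,
        )
        coupling = CouplingSpec(
            kappa=dict(cfg.kappa) if isinstance(cfg.kappa, dict) else cfg.kappa,
            amp_by_fairness=dict(cfg.amp_by_fairness),
            noise_pink_sigma=cfg.noise_pink_sigma,
            noise_white_sigma=cfg.noise_white_sigma,
        )
        dyads.append(
            simulate_dyad(
                schedule, coupling, channel_names=cfg.channel_names,
                fs=cfg.fs, seed=seed, epoch_window=cfg.epoch_window,
            )
        )
    return dyads


def _coherence_stats(
    courses: dict[str, list[np.ndarray]],
    cfg: RunConfig,
    time_axis: np.ndarray,
    run_threshold: int,
) -> tuple[dict[str, StatSeries], np.ndarray]:
    """Fair-vs-hyperunfair paired t per agency + agent-pc contrast."""
    fair, hyper = cfg.fairness_contrast
    series = {}
    for agency in AGENCY_LEVELS:
        a = np.stack(courses[f"{fair}/{agency}"])
        b = np.stack(courses[f"{hyper}/{agency}"])
        ss = pointwise_paired_t(
            a, b, alpha=cfg.alpha, time_axis=time_axis,
            name=f"{fair}-vs-{hyper}:{agency}",
        )
        series[agency] = gb_filter(ss, run_threshold)
    contrast = agency_contrast(series["agent"], series["pc"])
    return series, contrast


def _write_statseries(series: dict[str, StatSeries], path: str) -> None:
    frames = []
    for agency, ss in series.items():
        frames.append(
            pd.DataFrame(
                {
                    "agency": agency,
                    "time_s": ss.time_axis,
                    "t": ss.t,
                    "p": ss.p,
                    "sig_raw": ss.sig_raw.astype(int),
                    "sig_filtered": ss.sig_filtered.astype(int),
                }
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: RunConfig, out_dir: str | os.PathLike) -> dict[str, Any]:
    """Execute all configured stages; returns a summary dict.

    Outputs written to ``out_dir``: rejection_report.tsv, peaks.tsv,
    anova.tsv, scalp_coherence_stats.tsv, agency_contrast.tsv, optional
    source_coherence_stats.tsv, and manifest.json.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict[str, Any] = {}
    try:
        return _run(cfg, out_dir, summary)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out_dir: str, summary: dict[str, Any]) -> dict[str, Any]:
    fair, hyper = cfg.fairness_contrast

    if cfg.input_fixtures:
        dyads = [read_fixture(p) for p in cfg.input_fixtures]
        logger.info("loaded %d dyad fixtures", len(dyads))
    else:
        dyads = _simulate_dyads(cfg)
        logger.info("simulated %d dyads (seed %d)", len(dyads), cfg.seed)

    # preprocess
    pairs, reports = [], []
    for d, dyad in enumerate(dyads):
        es_r, es_o, report = preprocess_dyad(
            dyad, low=cfg.filter_low, high=cfg.filter_high,
            window=cfg.epoch_window, baseline=cfg.baseline_window,
            threshold_uv=cfg.reject_threshold_uv,
        )
        report.insert(0, "dyad", d)
        pairs.append((es_r, es_o))
        reports.append(report)
        logger.info(
            "dyad %d: %d/%d joint trials kept", d,
            int((es_r.keep_mask).sum()), es_r.n_trials,
        )
    pd.concat(reports).to_csv(
        os.path.join(out_dir, "rejection_report.tsv"), sep="\t", index=False
    )

    # ERP peaks + ANOVA
    peak_channels = tuple(
        ch for ch in ("Fz", "Cz", "Pz") if ch in pairs[0][0].channel_names
    ) or (cfg.analysis_channel,)
    erps = {}
    for d, (es_r, es_o) in enumerate(pairs):
        for role, es in (("receiver", es_r), ("observer", es_o)):
            for agency in AGENCY_LEVELS:
                for fairness in (fair, hyper):
                    erp = average_epochs(es, f"{fairness}/{agency}")
                    erp.role = role
                    erps[(f"d{d}-{role}", role, agency, fairness)] = erp
    peaks = peak_table(erps, channels=peak_channels, window=cfg.peak_window)
    peaks.to_csv(os.path.join(out_dir, "peaks.tsv"), sep="\t", index=False)
    anova_ch = (
        cfg.analysis_channel if cfg.analysis_channel in peak_channels else peak_channels[-1]
    )
    anova = mixed_anova(peaks[peaks["channel"] == anova_ch])
    anova.table.to_csv(os.path.join(out_dir, "anova.tsv"), sep="\t", index=False)
    summary["anova"] = anova
    logger.info("ANOVA on %s peaks written", anova_ch)

    # scalp coherence
    n_time = pairs[0][0].epochs.shape[2]
    courses: dict[str, list[np.ndarray]] = {}
    diffs = []
    for es_r, es_o in pairs:
        for agency in AGENCY_LEVELS:
            for fairness in (fair, hyper):
                cond = f"{fairness}/{agency}"
                wmap = dyad_trial_coherence(
                    es_r, es_o, cfg.analysis_channel, cond,
                    band=cfg.band, voices=cfg.voices,
                )
                courses.setdefault(cond, []).append(
                    collapse_band(wmap, cfg.band).values
                )
        for agency in AGENCY_LEVELS:
            diffs.append(
                np.nan_to_num(
                    courses[f"{fair}/{agency}"][-1]
                    - courses[f"{hyper}/{agency}"][-1]
                )
            )
    rho = (
        ar1_coefficient(np.stack(diffs)) if cfg.gb_rho == "auto" else float(cfg.gb_rho)
    )
    rho = float(np.clip(rho, -0.99, 0.99))
    run_thr = gb_threshold(
        rho, n_time, len(pairs), alpha=cfg.alpha, n_sim=cfg.gb_n_sim,
        seed=cfg.seed + 1,
    )
    logger.info("GB null: rho=%.3f -> run threshold %d samples", rho, run_thr)
    time_axis = pairs[0][0].time_axis
    scalp_series, scalp_contrast = _coherence_stats(
        {k: [np.nan_to_num(v) for v in vs] for k, vs in courses.items()},
        cfg, time_axis, run_thr,
    )
    _write_statseries(
        scalp_series, os.path.join(out_dir, "scalp_coherence_stats.tsv")
    )
    pd.DataFrame({"time_s": time_axis, "t_agent_minus_pc": scalp_contrast}).to_csv(
        os.path.join(out_dir, "agency_contrast.tsv"), sep="\t", index=False
    )
    summary["scalp"] = scalp_series
    summary["gb_run_threshold"] = run_thr

    # source level (optional)
    if cfg.source_enabled:
        lf = read_leadfield(cfg.leadfield)
        rois = read_roi_table(cfg.roi_table)
        lam = cfg.lam
        if lam == "auto":
            es0 = drop_unmodeled_channels(pairs[0][0])
            es0 = es0.pick_channels(
                [nm for nm in lf.channel_names if nm in es0.channel_names]
            )
            lam = crossvalidate_lambda(es0, lf, list(cfg.lambda_grid))
            logger.info("cross-validated lambda = %g", lam)
        im = build_eloreta(lf, float(lam))
        roi_courses: dict[str, dict[str, list[np.ndarray]]] = {}
        for es_r, es_o in pairs:
            roi_pair = {}
            for key, es in (("r", es_r), ("o", es_o)):
                es2 = drop_unmodeled_channels(es)
                se = orient_pca(apply_inverse(im, es2))
                roi_pair[key] = roi_epochs(se, rois)
            for roi in rois.names:
                for agency in AGENCY_LEVELS:
                    for fairness in (fair, hyper):
                        cond = f"{fairness}/{agency}"
                        wmap = dyad_trial_coherence(
                            roi_pair["r"], roi_pair["o"], roi, cond,
                            band=cfg.band, voices=cfg.voices,
                        )
                        roi_courses.setdefault(roi, {}).setdefault(cond, []).append(
                            np.nan_to_num(collapse_band(wmap, cfg.band).values)
                        )
        frames = []
        source_series = {}
        for roi, cc in roi_courses.items():
            series, contrast = _coherence_stats(cc, cfg, time_axis, run_thr)
            source_series[roi] = series
            for agency, ss in series.items():
                frames.append(
                    pd.DataFrame(
                        {
                            "roi": roi, "agency": agency, "time_s": ss.time_axis,
                            "t": ss.t, "p": ss.p,
                            "sig_filtered": ss.sig_filtered.astype(int),
                            "t_agent_minus_pc": contrast,
                        }
                    )
                )
        pd.concat(frames).to_csv(
            os.path.join(out_dir, "source_coherence_stats.tsv"),
            sep="\t", index=False, float_format="%.10g",
        )
        summary["source"] = source_series

    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.values.items()},
        "config_hash": cfg.hash(),
        "n_dyads": len(dyads),
        "gb_run_threshold": run_thr,
        "gb_rho": rho,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    summary["manifest"] = manifest
    return summary
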
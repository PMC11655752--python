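"""End-to-end analysis pipeline: simulate/ingest -> baseline -> binning and
correlations -> rERP fits -> neutralized forward estimates -> figures and a
machine-readable summary.

The pipeline is driven by a YAML (or dict) configuration::

    seed: 1
    simulation:
      preset: biphasic          # or "monophasic"
      overrides: {n_subjects: 8, n_items: 24}
    # alternatively: input: epochs.csv
    electrode: Pz
    windows:
      n400: [300, 500]
      segment: [0, 1200]
      p600: [600, 1000]
    baseline: [-200, 0]
    binning: {k: 3}

Outputs (written to ``out_dir``): condition ERPs, bin waveforms (naive and
subtraction-based), coefficient time-courses (pooled and per condition),
estimate/residual figures for each neutralization mode, CSV artifacts, and
``summary.json`` holding the correlations and window-averaged coefficients
together with the config and seed. Identical config + seed give an
identical summary.
"""

from __future__ import annotations

import json
from contextlib import contextmanager
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import binning, estimation, rerp, simulate
from .epochs import (BASELINE_WINDOW, EpochSet, WindowSpec, baseline_correct,
                     grand_average, read_epochs, window_average, write_epochs)
from .errors import ConfigurationError, PipelineError, TrialDynError
from .plotting import plot_waveforms, save_figure

REQUIRED_WINDOWS = ("n400", "segment", "p600")

_PRESETS = {
    "biphasic": simulate.preset_biphasic,
    "monophasic": simulate.preset_monophasic,
}


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:  # propagate with the failing stage's name
        raise PipelineError(name, str(exc)) from exc


def validate_config(config: Mapping) -> dict:
    """Check the pipeline configuration before any stage runs."""
    cfg = dict(config)
    if ("simulation" in cfg) == ("input" in cfg):
        raise ConfigurationError(
            "config must name exactly one of 'simulation' or 'input'"
        )
    windows = cfg.get("windows") or {}
    missing = [w for w in REQUIRED_WINDOWS if w not in windows]
    if missing:
        raise ConfigurationError(f"config lacks required windows: {missing}")
    for name, pair in windows.items():
        if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
            raise ConfigurationError(f"window {name!r} must be a [start, end] pair")
    if "simulation" in cfg:
        preset = cfg["simulation"].get("preset")
        if preset not in _PRESETS:
            raise ConfigurationError(
                f"unknown simulation preset {preset!r}; choose from {sorted(_PRESETS)}"
            )
    cfg.setdefault("seed", 0)
    cfg.setdefault("electrode", "Pz")
    cfg.setdefault("baseline", [BASELINE_WINDOW.start_ms, BASELINE_WINDOW.end_ms])
    cfg.setdefault("binning", {"k": 3})
    return cfg


def _window(cfg: Mapping, name: str, label: str) -> WindowSpec:
    lo, hi = cfg["windows"][name]
    return WindowSpec(label, float(lo), float(hi))


def _window_mean(summary, window: WindowSpec, electrode: str,
                 group_col: str, group_val) -> float:
    d = summary.data
    sel = (d["electrode"] == electrode) & (d[group_col] == group_val) & \
          (d["time_ms"] >= window.start_ms) & (d["time_ms"] <= window.end_ms)
    return float(d.loc[sel, "mean_uv"].mean())


def run_pipeline(config, out_dir=None) -> dict:
    """Run all stages; returns the summary dict (also written as JSON).

    ``config`` is a mapping or a path to a YAML file. ``out_dir`` overrides
    the config's ``output_dir`` (default: "trialdyn_results").
    """
    if not isinstance(config, Mapping):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = validate_config(config)
    out = Path(out_dir or cfg.get("output_dir", "trialdyn_results"))
    out.mkdir(parents=True, exist_ok=True)

    n400_w = _window(cfg, "n400", "N400")
    seg_w = _window(cfg, "segment", "Segment")
    p600_w = _window(cfg, "p600", "P600")
    electrode = cfg["electrode"]
    seed = int(cfg["seed"])

    # -- ingest / simulate ------------------------------------------------
    with _stage("simulate"):
        if "simulation" in cfg:
            sim = cfg["simulation"]
            gen_cfg = _PRESETS[sim["preset"]](**(sim.get("overrides") or {}),
                                              seed=seed)
            epochs, truth = simulate.generate_dataset(gen_cfg)
            truth.to_csv(out / "ground_truth.csv", index=False)
        else:
            epochs = read_epochs(cfg["input"])

    with _stage("baseline"):
        lo, hi = cfg["baseline"]
        epochs = baseline_correct(epochs, WindowSpec("baseline", float(lo), float(hi)))

    summary: dict = {"config": _jsonable(cfg), "seed": seed,
                     "electrode": electrode,
                     "n_trials": int(epochs.n_trials),
                     "n_subjects": len(epochs.subjects)}

    # -- condition ERPs ---------------------------------------------------
    with _stage("condition_erps"):
        cond_erp = grand_average(epochs, group_by=("condition",))
        save_figure(plot_waveforms(cond_erp, "Condition ERPs"),
                    out / "fig_condition_erps.png")

    # -- correlations and bins -------------------------------------------
    with _stage("correlate"):
        corr = binning.component_correlations(epochs, n400_w, p600_w, seg_w,
                                              electrode)
        summary["correlations"] = {k: round(v, 6) for k, v in corr.items()}

    with _stage("bin"):
        k = int(cfg["binning"].get("k", 3))
        a_n400 = window_average(epochs, n400_w, electrode)
        a_seg = window_average(epochs, seg_w, electrode)
        naive = binning.assign_bins(a_n400, k)
        subtr = binning.assign_bins(
            binning.subtraction_scores(a_n400, a_seg), k)
        bins_df = epochs.trials[["subject", "item", "condition"]].copy()
        bins_df["bin_naive"] = naive.bins
        bins_df["bin_subtraction"] = subtr.bins
        bins_df.to_csv(out / "bins.csv", index=False)
        for mode, assignment in (("naive", naive), ("subtraction", subtr)):
            ws = binning.bin_waveforms(epochs, assignment, electrode)
            save_figure(plot_waveforms(ws, f"{mode.capitalize()} N400 bins ({electrode})"),
                        out / f"fig_bins_{mode}.png")

    # -- rERP fits --------------------------------------------------------
    with _stage("fit"):
        predictors = rerp.build_predictors(epochs, n400_w, seg_w)
        coeffs = rerp.fit_rerp(epochs, predictors)
        coeffs.to_frame().to_csv(out / "coefficients.csv", index=False)
        coef_summary = rerp.summarize_coefficients(coeffs, add_intercept=True)
        save_figure(plot_waveforms(coef_summary, "Coefficients (added to intercept)",
                                   ci_multiplier=1.0),
                    out / "fig_coefficients.png")
        summary["coefficients"] = _coef_window_means(
            coeffs, electrode, {"n400_window": n400_w, "p600_window": p600_w})

    with _stage("fit_by_condition"):
        per_cond = {}
        for cond in epochs.conditions:
            c = rerp.fit_by_condition(epochs, cond, n400_w, seg_w)
            per_cond[cond] = _coef_window_means(
                c, electrode, {"n400_window": n400_w, "p600_window": p600_w})
            cs = rerp.summarize_coefficients(c, add_intercept=True)
            save_figure(
                plot_waveforms(cs, f"Coefficients, condition {cond}",
                               ci_multiplier=1.0),
                out / f"fig_coefficients_{cond}.png")
        summary["coefficients_by_condition"] = per_cond

    # -- forward estimates ------------------------------------------------
    with _stage("estimate"):
        modes = {"full": (), "intercept_only": ("N400", "Segment"),
                 "n400_isolated": ("Segment",), "segment_isolated": ("N400",)}
        for mode, neut in modes.items():
            est = estimation.forward_estimate(coeffs, predictors, epochs,
                                              neutralize=neut)
            est_ws = estimation.estimate_by_condition(est, epochs)
            res_ws = estimation.residual_by_condition(est, epochs)
            save_figure(plot_waveforms(est_ws, f"Estimates ({mode})"),
                        out / f"fig_estimates_{mode}.png")
            save_figure(plot_waveforms(res_ws, f"Residual error ({mode})"),
                        out / f"fig_residuals_{mode}.png")

    with _stage("report"):
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _coef_window_means(coeffs, electrode: str, windows: Mapping[str, WindowSpec]) -> dict:
    """Across-subject mean beta per term, averaged over named windows (µV)."""
    cs = rerp.summarize_coefficients(coeffs, add_intercept=False)
    result: dict = {}
    for term in coeffs.terms:
        result[term] = {
            wname: round(_window_mean(cs, w, electrode, "term", term), 6)
            for wname, w in windows.items()
        }
    return result


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
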
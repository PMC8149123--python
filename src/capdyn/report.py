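"""Run reports and the end-to-end synthetic pipeline.

``run_pipeline`` exercises every stage on synthetic data with ground truth:
cap movie -> segmentation/tracking -> dynamics, FRAP simulation -> two-phase
fit -> derived metrics, colocalization scene -> object and Costes scoring,
fallout table -> correlation. ``build_report`` bundles stage outputs into a
deterministic JSON report, a human-readable summary, and optional figures;
all files are listed in a SHA-256 manifest, so two runs with the same config
and seed can be compared byte for byte.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc as coloc_mod
from . import dynamics as dyn
from . import frap as frap_mod
from . import segmentation as seg
from . import stats as stats_mod
from . import synthetic as synth
from .config import RunConfig
from .errors import CapdynError, ConfigError
from .stack_io import dump_json, write_results

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "build_report"]


def _figures(out_dir: Path, payload: dict, tables: dict) -> list[str]:
    import matplotlib
    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    made = []
    traces = tables.get("aligned_traces")
    if traces is not None and len(traces):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for cid, sub in traces.groupby("cap_id"):
            ax.plot(sub["time_s"], sub["norm_area"], lw=1, label=f"cap {cid}")
        ax.set_xlabel("time from initiation (s)")
        ax.set_ylabel("normalized cap area")
        fig.tight_layout()
        fig.savefig(out_dir / "fig_traces.png", dpi=120, metadata={"Software": None})
        plt.close(fig)
        made.append("fig_traces.png")
    frap_info = payload.get("frap")
    if frap_info and "curve_x" in frap_info:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(frap_info["curve_x"], frap_info["curve_y"], ".", ms=3, label="normalized")
        ax.plot(frap_info["curve_x"], frap_info["curve_fit"], "-", label="two-phase fit")
        ax.set_xlabel("time since bleach (s)")
        ax.set_ylabel("normalized intensity")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out_dir / "fig_frap.png", dpi=120, metadata={"Software": None})
        plt.close(fig)
        made.append("fig_frap.png")
    fallout = tables.get("fallout_conditions")
    if fallout is not None and len(fallout) and "fallout" in payload:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        x = fallout["expansion_rate_um2_s"]
        ax.plot(x, fallout["fallout_rate"], "o")
        fit = payload["fallout"]
        xs = np.linspace(float(x.min()), float(x.max()), 50)
        ax.plot(xs, fit["intercept"] + fit["slope"] * xs, "--")
        ax.set_xlabel("cap expansion rate (um^2/s)")
        ax.set_ylabel("nuclear fallout rate")
        fig.tight_layout()
        fig.savefig(out_dir / "fig_fallout.png", dpi=120, metadata={"Software": None})
        plt.close(fig)
        made.append("fig_fallout.png")
    return made


def build_report(stages: dict, out_dir: str | Path, *, config: RunConfig | None = None,
                 make_figures: bool = False) -> dict:
    """Bundle stage outputs into report.json, summary.txt and a manifest.

    ``stages`` maps stage names to ``{"payload": dict, "tables": {name: df}}``;
    a stage may carry its own ``config_echo``, and conflicting echoes raise
    :class:`ConfigError`. Missing stages are marked absent, not errors.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not stages:
        raise CapdynError("no stage outputs to report")

    echoes = {name: st.get("config_echo") for name, st in stages.items()
              if st.get("config_echo") is not None}
    if len({repr(sorted(e.items()) if isinstance(e, dict) else e)
            for e in echoes.values()}) > 1:
        raise ConfigError(f"conflicting config echoes across stages: {sorted(echoes)}")

    payload: dict = {"config": config.to_dict() if config else None, "stages": {}}
    tables: dict[str, pd.DataFrame] = {}
    for name in sorted(stages):
        st = stages[name]
        stage_payload = {k: v for k, v in st.get("payload", {}).items()
                         if not k.startswith("curve_")}
        payload["stages"][name] = {"present": True, **stage_payload}
        for tname, df in st.get("tables", {}).items():
            tables[tname] = df
    for name in ("dynamics", "frap", "coloc", "fallout"):
        if name not in payload["stages"]:
            payload["stages"][name] = {"present": False}

    flat_payload = {**payload["stages"].get("frap", {}),
                    **{"fallout_" + k: v for k, v in
                       payload["stages"].get("fallout", {}).items()}}
    lines = ["capdyn run report", "=" * 17]
    for name in sorted(payload["stages"]):
        st = payload["stages"][name]
        lines.append(f"[{name}] " + ("present" if st.get("present") else "absent"))
        for k, v in st.items():
            if k == "present" or isinstance(v, (dict, list)):
                continue
            if isinstance(v, float):
                lines.append(f"  {k} = {v:.6g}")
            else:
                lines.append(f"  {k} = {v}")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

    fig_payload = {}
    for name, st in stages.items():
        fig_payload[name] = st.get("payload", {})
    figures = _figures(out_dir, {**fig_payload,
                                 "fallout": payload["stages"].get("fallout", {})},
                       tables) if make_figures else []
    payload["figures"] = figures

    dump_json(payload, out_dir / "report.json")
    manifest = write_results(out_dir, tables=tables)
    # fold the report/summary/figures into the manifest for byte comparison
    extra = ["report.json", "summary.txt", *figures]
    from .stack_io import _sha256
    files = {f["path"]: f for f in manifest["files"]}
    for name in extra:
        p = out_dir / name
        files[name] = {"path": name, "sha256": _sha256(p), "bytes": p.stat().st_size}
    manifest = {"files": sorted(files.values(), key=lambda d: d["path"])}
    dump_json(manifest, out_dir / "manifest.json")
    return manifest


def run_pipeline(config: RunConfig, out_dir: str | Path, *,
                 scene: synth.SceneConfig | None = None,
                 frap_params: synth.FrapSimParams | None = None,
                 coloc_scene: synth.ColocSceneConfig | None = None,
                 fallout_config: synth.FalloutSimConfig | None = None,
                 make_figures: bool = False) -> dict:
    """Run the full synthetic pipeline and write a report; returns the manifest."""
    config.validate()
    out_dir = Path(out_dir)
    seed = config.seed

    # --- cap movie -> segmentation -> dynamics -----------------------------
    scene = scene if scene is not None else synth.SceneConfig(seed=seed)
    stack, truth = synth.simulate_cap_movie(scene)
    meas = seg.measure_movie(
        stack, offset_um=config.segmentation.plane_offset_um,
        detect_factor=config.segmentation.detect_factor,
        background_percentile=config.segmentation.background_percentile,
        min_area_um2=config.segmentation.min_area_um2,
        smooth_sigma_px=config.segmentation.smooth_sigma_px)
    tracks = seg.link_tracks(meas,
                             max_displacement_um=config.segmentation.max_displacement_um,
                             max_gap_frames=config.segmentation.max_gap_frames)
    anchor = truth.elongation_onset_frame
    trace_rows, phase_rows, growth_fits, fold_changes = [], [], {}, {}
    for track in tracks:
        if len(track) < anchor + 1 or track.data["touching"].any():
            continue
        try:
            trace = dyn.align_and_normalize(
                track, anchor, frame_interval_s=stack.frame_interval_s,
                lookback_s=config.dynamics.lookback_s)
            rates = dyn.rolling_expansion_rate(trace, window_s=config.dynamics.window_s)
            phases = dyn.classify_phases(
                trace, theta_grow=config.dynamics.theta_grow,
                theta_stab=config.dynamics.theta_stab,
                theta_ecc=config.dynamics.theta_ecc,
                theta_het=config.dynamics.theta_het,
                window_s=config.dynamics.window_s)
            gfit = dyn.fit_expansion_exponential(
                trace, span_s=config.dynamics.fit_span_s,
                x_unit=config.dynamics.x_unit)
        except CapdynError as exc:
            log.warning("track %d skipped: %s", track.track_id, exc)
            continue
        growth_fits[f"track_{track.track_id}"] = gfit.to_dict()
        fold_changes[f"track_{track.track_id}"] = dyn.fold_change(
            trace, 0.0, min(float(trace.time_s[-1]), scene.expansion_s))
        for i in range(len(trace.time_s)):
            trace_rows.append({
                "cap_id": track.track_id, "time_s": trace.time_s[i],
                "area_um2": trace.area_um2[i], "norm_area": trace.norm_area[i],
                "mean_int": trace.mean_int[i], "norm_het": trace.norm_het[i],
                "ecc": trace.ecc[i], "rate_um2_s": rates["rate_um2_s"].iloc[i],
                "rate_norm_s": rates["rate_norm_s"].iloc[i],
                "phase": phases.labels[i],
            })
        for phase, t_start in phases.boundaries.items():
            phase_rows.append({"cap_id": track.track_id, "phase": phase,
                               "start_s": t_start})
    dynamics_stage = {
        "payload": {
            "n_tracks": len(tracks),
            "n_analyzed": len(growth_fits),
            "mean_fold_change": float(np.mean(list(fold_changes.values())))
            if fold_changes else float("nan"),
            "growth_fits": growth_fits,
            "fold_changes": fold_changes,
        },
        "tables": {
            "measurements": meas,
            "aligned_traces": pd.DataFrame(trace_rows),
            "phase_boundaries": pd.DataFrame(phase_rows),
        },
    }

    # --- FRAP --------------------------------------------------------------
    fp = frap_params if frap_params is not None else synth.FrapSimParams(
        noise_sd=0.02, seed=seed + 1)
    trace_f, fp_true = synth.simulate_frap_experiment(fp)
    norm = frap_mod.normalize_frap(trace_f,
                                   rescale_prebleach=config.frap.rescale_prebleach)
    fit = frap_mod.fit_two_phase(norm.x, norm.y, min_samples=config.frap.min_samples)
    metrics = frap_mod.derive_metrics(fit, norm.y_minus1)
    frap_stage = {
        "payload": {
            **fit.to_dict(), **metrics.to_dict(),
            "y_minus1": norm.y_minus1,
            "true_t50_s": fp_true.t50_s,
            "true_immobile_fraction": fp_true.immobile_fraction,
            "curve_x": norm.x, "curve_y": norm.y, "curve_fit": fit.predict(norm.x),
        },
        "tables": {"frap_trace": trace_f.data},
    }

    # --- colocalization ----------------------------------------------------
    cs = coloc_scene if coloc_scene is not None else synth.ColocSceneConfig(
        puncta=(
            synth.PunctumSpec(12.0, 10.0, 60),
            synth.PunctumSpec(9.0, 9.0, 10),
            synth.PunctumSpec(9.0, 9.0, 9),
            synth.PunctumSpec(10.0, 12.0, 0),
            synth.PunctumSpec(11.0, 9.5, 40),
            synth.PunctumSpec(7.5, 9.0, 0),
        ),
        noise_sd=5.0,
        seed=seed + 2)
    scene_c = synth.simulate_coloc_scene(cs)
    ps = cs.pixel_size_um
    puncta_a, labels_a = coloc_mod.detect_puncta(
        scene_c.channel_a, ps, min_area_um2=config.coloc.min_area_um2)
    puncta_b, labels_b = coloc_mod.detect_puncta(
        scene_c.channel_b, ps, min_area_um2=config.coloc.min_area_um2)
    calls, percent = coloc_mod.call_colocalization(
        labels_a, labels_b, min_shared_px=config.coloc.min_shared_px)
    coloc_ids = labels_a * np.isin(
        labels_a, calls.loc[calls["colocalized"], "punctum_id"].to_numpy())
    if coloc_ids.any():
        recruit_table, recruit_mean = coloc_mod.recruitment_ability(
            scene_c.channel_a, scene_c.channel_b, coloc_ids, labels_b > 0,
            gfp_background=cs.background_a, mch_background=cs.background_b)
    else:
        recruit_table, recruit_mean = pd.DataFrame(), float("nan")
    costes = coloc_mod.pearson_costes(
        scene_c.channel_a, scene_c.channel_b, psf_px=config.coloc.psf_px,
        n_randomizations=config.coloc.n_randomizations, seed=seed + 3)
    coloc_stage = {
        "payload": {
            "percent_colocalized": percent,
            "n_gated_a": len(puncta_a), "n_gated_b": len(puncta_b),
            "recruitment_ability_mean": recruit_mean,
            "costes": costes.to_dict(),
        },
        "tables": {"puncta_a": puncta_a, "puncta_b": puncta_b,
                   "coloc_calls": calls, "coloc_truth": scene_c.truth},
    }

    # --- fallout correlation ----------------------------------------------
    fc = fallout_config if fallout_config is not None else synth.FalloutSimConfig(
        seed=seed + 4)
    fallout = synth.simulate_fallout_dataset(fc)
    corr = stats_mod.correlate_fallout(fallout)
    fallout_stage = {
        "payload": {**corr.to_dict(),
                    "stars": stats_mod.significance_stars(corr.p_value)},
        "tables": {"fallout_conditions": fallout},
    }

    stages = {"dynamics": dynamics_stage, "frap": frap_stage,
              "coloc": coloc_stage, "fallout": fallout_stage}
    return build_report(stages, out_dir, config=config, make_figures=make_figures)
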
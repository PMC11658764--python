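"""End-to-end orchestration: synthesize -> segment -> quantify -> spatial
stats -> calcium events, with seeded reproducibility and tidy CSV outputs.

A run produces one directory containing::

    clusters.csv           one row per (cell, frame, cluster)
    window_summary.csv     one row per (cell, window)
    ripley.csv             one row per (cell, timepoint, radius)
    aggregation_index.csv  one row per cell (plus a pooled row)
    events.csv             one row per detected calcium event
    flicker_summary.csv    one row per cell
    shapes.csv             one row per cell
    manifest.json          config snapshot, seed, row counts, version

All randomness flows from a single seed through independent spawned
streams per cell and stage, so identical seeds give byte-identical CSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from nanocal.calcium import build_event_graph, detect_events, flicker_summary
from nanocal.core_io import (
    AnalysisConfig,
    BinaryMask,
    ImageStack,
    IntensityTrace,
    config_to_dict,
    read_stack,
    save_json,
    write_table,
)
from nanocal.quantify import (
    cluster_count_by_window,
    compartment_intensity_pair,
    mfi_in_mask,
    shape_metrics,
)
from nanocal.ripley import (
    PointPattern,
    aggregation_index,
    classify,
    ripley_curve,
)
from nanocal.segmentation import (
    auto_threshold,
    cluster_mask,
    extract_nanoclusters,
    segment_cell,
)
from nanocal.synth import (
    ClusterProcessParams,
    FlickerEvent,
    make_cell_mask,
    render_calcium_channel,
    render_cluster_channel,
    sample_point_pattern,
)

__all__ = ["synthesize_cell_stack", "analyze_cell_stack", "run_pipeline",
           "demo_figure4"]

logger = logging.getLogger("nanocal")

#: acquisition defaults the synthetic movies emulate
SYNTH_PIXEL_SIZE_UM = 0.284
SYNTH_FRAME_INTERVAL_S = 2.0
SYNTH_DURATION_S = 600.0
SYNTH_FRAME_PX = 128  # per-cell crop; full-chip 512 px frames scale the same
SYNTH_CELL_RADIUS_UM = 7.0  # a spread, crawling cell

TABLE_SCHEMAS = {
    "clusters.csv": ["cell_id", "frame", "cluster_id", "x_um", "y_um",
                     "area_um2", "pixel_count"],
    "window_summary.csv": ["cell_id", "window", "mean_cluster_count",
                           "ca_mfi_in_cluster", "ca_mfi_negative",
                           "actin_per_cell_area"],
    "ripley.csv": ["cell_id", "timepoint_s", "r_um", "k", "upper", "lower",
                   "normalized", "label", "n_points"],
    "aggregation_index.csv": ["cell_id", "aggregation_index",
                              "n_curves_included", "n_curves_excluded"],
    "events.csv": ["cell_id", "onset_s", "offset_s", "peak_time_s", "peak_z",
                   "amplitude", "auc", "half_width_s", "group_id"],
    "flicker_summary.csv": ["cell_id", "n_events", "events_per_minute",
                            "mean_duration_s"],
    "shapes.csv": ["cell_id", "area_um2", "perimeter_um", "circularity",
                   "solidity"],
}


def synthesize_cell_stack(
    seed: int,
    regime: str = "clustered",
    enrichment: float = 2.0,
    expected_clusters: float = 100.0,
    parent_intensity: float = 0.04,
    offspring_sd_um: float = 0.8,
    hard_core_um: float = 1.0,
    spot_sigma_um: float = 0.25,
    flicker_rate_per_min: float = 1.0,
    flicker_amplitude_sd: float = 10.0,
    actin_level: float = 30.0,
    noise_sd: float = 1.5,
    frame_px: int = SYNTH_FRAME_PX,
    duration_s: float = SYNTH_DURATION_S,
    frame_interval_s: float = SYNTH_FRAME_INTERVAL_S,
) -> tuple[ImageStack, dict]:
    """One synthetic single-cell movie (gcamp, lfa1, actin channels).

    The nanocluster pattern is static over the movie (the analysis
    averages per window, not per cluster lifetime); the calcium channel
    carries cluster-site enrichment and Poisson-scheduled cell-wide
    flickers whose amplitude is ``flicker_amplitude_sd`` noise sd.

    Because rendered spots have a finite optical size, the generator
    models nanoclusters as physical objects with a hard-core minimum
    separation (``hard_core_um``); locations closer than that would
    segment as a single cluster, so ``expected_clusters`` is the Poisson
    mean *before* hard-core thinning and the realized object count is
    lower.  Returns the stack and a ground-truth dict.
    """
    ss = np.random.SeedSequence(seed)
    s_mask, s_pattern, s_flick, s_ca, s_lfa, s_actin = ss.generate_state(6) % (
        2**31
    )
    mask = make_cell_mask(
        (frame_px, frame_px), SYNTH_CELL_RADIUS_UM, SYNTH_PIXEL_SIZE_UM,
        irregularity=0.25, seed=int(s_mask),
    )
    pattern = sample_point_pattern(
        mask,
        ClusterProcessParams(
            regime=regime,
            expected_total_points=expected_clusters,
            parent_intensity=parent_intensity,
            offspring_sd_um=offspring_sd_um,
            hard_core_um=hard_core_um,
            rng_seed=int(s_pattern),
        ),
    )
    times = np.arange(0, duration_s, frame_interval_s)
    rng = np.random.default_rng(int(s_flick))
    n_flick = rng.poisson(flicker_rate_per_min * duration_s / 60.0)
    flickers = tuple(
        FlickerEvent(
            onset_s=float(rng.uniform(0, duration_s - 30)),
            amplitude=float(flicker_amplitude_sd * noise_sd),
            half_width_s=float(rng.uniform(4, 10)),
        )
        for _ in range(n_flick)
    )
    ca_frames, truth = render_calcium_channel(
        mask, pattern, enrichment=enrichment, flickers=flickers,
        frame_times_s=times, baseline=50.0, noise_sd=noise_sd,
        seed=int(s_ca),
    )
    lfa_rng = np.random.default_rng(int(s_lfa))
    lfa_base = render_cluster_channel(
        mask, pattern, spot_sigma_um=spot_sigma_um, amplitude=120.0,
        background=8.0, noise_sd=0.0,
    )
    lfa_frames = np.clip(
        lfa_base[None] + lfa_rng.normal(0, noise_sd, size=ca_frames.shape), 0, None
    )
    actin_rng = np.random.default_rng(int(s_actin))
    actin_base = np.where(mask.pixels, actin_level, 2.0)
    actin_frames = np.clip(
        actin_base[None] + actin_rng.normal(0, noise_sd, size=ca_frames.shape),
        0, None,
    )
    stack = ImageStack(
        data=np.stack([ca_frames, lfa_frames, actin_frames], axis=1),
        pixel_size_um=SYNTH_PIXEL_SIZE_UM,
        frame_interval_s=frame_interval_s,
        channel_names=("gcamp", "lfa1", "actin"),
    )
    ground_truth = {
        "mask": mask,
        "pattern": pattern,
        "regime": regime,
        "enrichment": enrichment,
        "flickers": flickers,
        "truth": truth,
    }
    return stack, ground_truth


def analyze_cell_stack(
    stack: ImageStack, config: AnalysisConfig, cell_id: str, seed: int
) -> dict[str, list[dict]]:
    """Run the full single-cell analysis on one movie.

    Ripley curves are computed at one representative frame per configured
    time window (the window's first frame), matching the per-timepoint
    summary design of the windowed quantities.
    """
    px = stack.pixel_size_um
    gcamp = stack.channel("gcamp")
    lfa = stack.channel("lfa1")
    actin = stack.channel("actin") if "actin" in stack.channel_names else None
    times = stack.frame_times_s

    cell = segment_cell(gcamp.mean(axis=0), px, method=config.threshold_method)
    rows: dict[str, list[dict]] = {name: [] for name in TABLE_SCHEMAS}

    if cell.n_pixels == 0:
        logger.warning("%s: empty cell mask; emitting empty tables", cell_id)
        return rows

    # --- per-frame nanocluster segmentation -------------------------------
    cluster_sets = []
    cluster_masks = []
    for f in range(stack.n_frames):
        thr = auto_threshold(lfa[f], px, method=config.threshold_method)
        thr = BinaryMask(thr.pixels & cell.pixels, px)
        cs = extract_nanoclusters(
            thr, min_area_um2=config.min_cluster_area_um2, frame_index=f
        )
        cluster_sets.append(cs)
        cluster_masks.append(cluster_mask(thr, config.min_cluster_area_um2))
        for rec in cs.records:
            rows["clusters.csv"].append(
                {
                    "cell_id": cell_id,
                    "frame": f,
                    "cluster_id": rec.cluster_id,
                    "x_um": rec.centroid_xy_um[0],
                    "y_um": rec.centroid_xy_um[1],
                    "area_um2": rec.area_um2,
                    "pixel_count": rec.pixel_count,
                }
            )

    # --- windowed summaries ------------------------------------------------
    counts = cluster_count_by_window(
        cluster_sets, stack.frame_interval_s, config.time_windows_s
    )
    for window in config.time_windows_s:
        start, end = window
        sel = np.nonzero((times >= start) & (times < end))[0]
        ca_in, ca_out, actin_per_area = [], [], []
        for f in sel:
            neg = BinaryMask(cell.pixels & ~cluster_masks[f].pixels, px)
            cl_in_cell = BinaryMask(cell.pixels & cluster_masks[f].pixels, px)
            a, b = compartment_intensity_pair(gcamp[f], cl_in_cell, neg)
            ca_in.append(a)
            ca_out.append(b)
            if actin is not None:
                actin_per_area.append(mfi_in_mask(actin[f], cell))
        rows["window_summary.csv"].append(
            {
                "cell_id": cell_id,
                "window": AnalysisConfig.window_label(window),
                "mean_cluster_count": counts[window],
                "ca_mfi_in_cluster": float(np.nanmean(ca_in)) if ca_in else np.nan,
                "ca_mfi_negative": float(np.nanmean(ca_out)) if ca_out else np.nan,
                "actin_per_cell_area": float(np.nanmean(actin_per_area))
                if actin_per_area
                else np.nan,
            }
        )

    # --- Ripley spatial statistics (one frame per window) ------------------
    ss = np.random.SeedSequence(seed)
    env_seeds = ss.generate_state(len(config.time_windows_s)) % (2**31)
    curves = []
    for w_idx, (start, end) in enumerate(config.time_windows_s):
        sel = np.nonzero((times >= start) & (times < end))[0]
        if sel.size == 0:
            continue
        f = int(sel[0])
        pattern = PointPattern(cluster_sets[f].centroids_um, cell)
        if len(pattern) < 2:
            continue
        curve = ripley_curve(
            pattern, config.radii_um, n_sims=config.n_envelope_sims,
            seed=int(env_seeds[w_idx]),
        )
        curves.append(curve)
        labels = classify(curve.normalized)
        for i, r in enumerate(curve.radii_um):
            rows["ripley.csv"].append(
                {
                    "cell_id": cell_id,
                    "timepoint_s": float(times[f]),
                    "r_um": float(r),
                    "k": float(curve.k[i]),
                    "upper": float(curve.upper[i]),
                    "lower": float(curve.lower[i]),
                    "normalized": float(curve.normalized[i]),
                    "label": labels[i],
                    "n_points": curve.n_points,
                }
            )
    agg = (
        aggregation_index(curves, min_points=config.min_ripley_points)
        if curves
        else None
    )
    rows["aggregation_index.csv"].append(
        {
            "cell_id": cell_id,
            "aggregation_index": agg.index if agg else np.nan,
            "n_curves_included": agg.n_curves_included if agg else 0,
            "n_curves_excluded": agg.n_curves_excluded if agg else 0,
        }
    )

    # --- calcium flickers ---------------------------------------------------
    trace = IntensityTrace(
        times_s=times, values=gcamp[:, cell.pixels].mean(axis=1), cell_id=cell_id
    )
    events = build_event_graph(
        detect_events(
            trace,
            z_threshold=config.z_threshold,
            baseline_window_s=config.baseline_window_s,
        )
    )
    for ev in events:
        rows["events.csv"].append(
            {
                "cell_id": cell_id,
                "onset_s": ev.onset_s,
                "offset_s": ev.offset_s,
                "peak_time_s": ev.peak_time_s,
                "peak_z": ev.peak_z,
                "amplitude": ev.amplitude,
                "auc": ev.auc,
                "half_width_s": ev.half_width_s,
                "group_id": ev.group_id,
            }
        )
    summ = flicker_summary(events, trace.duration_s, cell_id=cell_id)
    rows["flicker_summary.csv"].append(
        {
            "cell_id": cell_id,
            "n_events": summ.n_events,
            "events_per_minute": summ.events_per_minute,
            "mean_duration_s": summ.mean_duration_s,
        }
    )

    # --- shape --------------------------------------------------------------
    sm = shape_metrics(cell)
    rows["shapes.csv"].append(
        {
            "cell_id": cell_id,
            "area_um2": sm.area_um2,
            "perimeter_um": sm.perimeter_um,
            "circularity": sm.circularity,
            "solidity": sm.solidity,
        }
    )
    return rows


def _merge_rows(all_rows: list[dict[str, list[dict]]]) -> dict[str, list[dict]]:
    merged: dict[str, list[dict]] = {name: [] for name in TABLE_SCHEMAS}
    for rows in all_rows:
        for name in TABLE_SCHEMAS:
            merged[name].extend(rows.get(name, []))
    return merged


def run_pipeline(
    config: AnalysisConfig,
    input: str | Path = "synthetic",
    out_dir: str | Path = "nanocal_out",
    n_cells: int = 4,
    regime: str = "clustered",
    enrichment: float = 2.0,
    channel_names: tuple[str, ...] = ("gcamp", "lfa1", "actin"),
    pixel_size_um: float = SYNTH_PIXEL_SIZE_UM,
    frame_interval_s: float = SYNTH_FRAME_INTERVAL_S,
) -> Path:
    """Run the complete analysis and write the CSV bundle + manifest.

    ``input`` is either the string ``"synthetic"`` (generate ``n_cells``
    ground-truthed movies under the given regime/enrichment) or a path to
    a TIFF movie containing one cell.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.rng_seed)
    all_rows = []
    if str(input) == "synthetic":
        cell_seeds = ss.generate_state(2 * n_cells) % (2**31)
        for i in range(n_cells):
            logger.info("synthesizing + analyzing cell %d/%d", i + 1, n_cells)
            stack, _ = synthesize_cell_stack(
                seed=int(cell_seeds[2 * i]), regime=regime, enrichment=enrichment
            )
            all_rows.append(
                analyze_cell_stack(
                    stack, config, cell_id=f"cell{i:03d}",
                    seed=int(cell_seeds[2 * i + 1]),
                )
            )
    else:
        stack = read_stack(
            input, pixel_size_um=pixel_size_um,
            frame_interval_s=frame_interval_s, channel_names=channel_names,
        )
        all_rows.append(
            analyze_cell_stack(
                stack, config, cell_id=Path(input).stem,
                seed=int(ss.generate_state(1)[0] % (2**31)),
            )
        )
    merged = _merge_rows(all_rows)
    row_counts = {}
    for name, schema in TABLE_SCHEMAS.items():
        write_table(merged[name], out / name, columns=schema)
        row_counts[name] = len(merged[name])
    from nanocal import __version__
    save_json(
        {
            "config": config_to_dict(config),
            "input": str(input),
            "seed": config.rng_seed,
            "row_counts": row_counts,
            "version": __version__,
        },
        out / "manifest.json",
    )
    return out


def demo_figure4(
    seed: int = 1,
    out_dir: str | Path | None = None,
    n_cells: int = 4,
    wt_enrichment: float = 2.0,
    ko_enrichment: float = 1.0,
    wt_clusters: float = 100.0,
    ko_clusters: float = 15.0,
    wt_actin: float = 40.0,
    ko_actin: float = 25.0,
) -> pd.DataFrame:
    """Two-cohort synthetic comparison of the main imaging readouts.

    Cohort "WT-like": clustered nanocluster pattern, calcium enriched at
    cluster sites, higher actin level.  Cohort "KO-like": spatially random
    pattern, weaker enrichment, fewer clusters, lower actin.  Returns (and
    optionally writes) a tidy per-cohort table of mean cluster count,
    in-cluster calcium MFI, aggregation index and actin intensity per cell
    area, which should order WT-like above KO-like on all four readouts.
    """
    cohorts = {
        "WT-like": dict(regime="clustered", enrichment=wt_enrichment,
                        expected_clusters=wt_clusters, actin_level=wt_actin),
        "KO-like": dict(regime="csr", enrichment=ko_enrichment,
                        expected_clusters=ko_clusters, actin_level=ko_actin),
    }
    config = AnalysisConfig(rng_seed=seed)
    ss = np.random.SeedSequence(seed)
    records = []
    for c_idx, (name, params) in enumerate(cohorts.items()):
        cohort_ss = np.random.SeedSequence([seed, c_idx])
        cell_seeds = cohort_ss.generate_state(2 * n_cells) % (2**31)
        all_rows = []
        for i in range(n_cells):
            stack, _ = synthesize_cell_stack(
                seed=int(cell_seeds[2 * i]),
                regime=params["regime"],
                enrichment=params["enrichment"],
                expected_clusters=params["expected_clusters"],
                actin_level=params["actin_level"],
            )
            all_rows.append(
                analyze_cell_stack(
                    stack, config, cell_id=f"{name}-cell{i:03d}",
                    seed=int(cell_seeds[2 * i + 1]),
                )
            )
        merged = _merge_rows(all_rows)
        win = pd.DataFrame(merged["window_summary.csv"])
        agg = pd.DataFrame(merged["aggregation_index.csv"])
        records.append(
            {
                "cohort": name,
                "regime": params["regime"],
                "enrichment": params["enrichment"],
                "mean_cluster_count": win["mean_cluster_count"].mean(),
                "ca_mfi_in_cluster": win["ca_mfi_in_cluster"].mean(),
                "ca_mfi_negative": win["ca_mfi_negative"].mean(),
                "aggregation_index": agg["aggregation_index"].mean(),
                "actin_per_cell_area": win["actin_per_cell_area"].mean(),
                "n_cells": n_cells,
            }
        )
    report = pd.DataFrame.from_records(records)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "figure4_demo.csv", index=False)
        save_json(
            {
                "seed": seed,
                "n_cells": n_cells,
                "config": config_to_dict(config),
                "cohorts": {k: {kk: vv for kk, vv in v.items()}
                            for k, v in cohorts.items()},
            },
            out / "figure4_demo_manifest.json",
        )
    return report
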
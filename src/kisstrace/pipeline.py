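"""End-to-end orchestration of the live and fixed analysis chains.

Live: detect per frame → link → pick the burst track (RNA track with the
highest mean sum intensity over real detections) → distance trace → kissing
episodes, approach times, intensity correlation. Fixed: segment nuclei →
detect per channel in 3D → per-nucleus burst → rim distances and
within-cutoff fractions → nearest-condensate statistics, near/far brightness
test, distance-vs-burst correlations → object/signal/three-way
co-localization. Every numeric field in a report is also written to a stage
CSV, and the config hash and package version are embedded so reruns are
traceable and byte-identical for identical inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .coloc import object_colocalization, signal_overlap_channel, three_way_overlap
from .config import PipelineConfig
from .detect import (
    NuclearMask,
    SpotRecord,
    detect_spots,
    identify_bursts,
    segment_nucleus,
)
from .io import FrameStack, VolumeStack, spots_to_frame, tracks_to_frame
from .kissing import (
    InsufficientDataError,
    approach_times,
    call_kissing_episodes,
    compute_distance_trace,
    summarize_kissing,
)
from .rim import (
    distance_to_boundary,
    distance_vs_burst_correlation,
    fraction_within,
    near_far_intensity_test,
    nearest_gag_to_burst,
)
from .track import Track, link_nearest_neighbor

log = logging.getLogger("kisstrace")


def _report_header(cfg: PipelineConfig) -> dict:
    return {"software_version": __version__, "config_hash": cfg.hash()}


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def detect_movie(
    stack: FrameStack, cfg: PipelineConfig, channel_names: tuple[str, ...] = ("rna", "gag")
) -> list[SpotRecord]:
    """Per-frame LoG detection over the requested channels of a live movie."""
    spacing = (stack.pixel_size_um, stack.pixel_size_um)
    spots: list[SpotRecord] = []
    for name in channel_names:
        if name not in stack.channels:
            raise KeyError(f"channel {name!r} missing from movie (has {stack.channels})")
        imgs = stack.channel(name)
        for t in range(stack.n_frames):
            spots.extend(
                detect_spots(
                    imgs[t],
                    spacing,
                    scale_um=cfg.detect_scale_um,
                    threshold=cfg.detect_threshold,
                    k_sigma=cfg.detect_k_sigma,
                    min_size=cfg.min_spot_px,
                    channel=name,
                    frame=t,
                )
            )
    return spots


def run_live_pipeline(
    stack: FrameStack,
    cfg: PipelineConfig,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Full live-cell analysis of one movie. Returns the per-movie report and
    (optionally) writes stage CSVs, the JSON report and the trace plot."""
    report = _report_header(cfg)
    report["warnings"] = []
    spots = detect_movie(stack, cfg)
    spots_rna = [s for s in spots if s.channel == "rna"]
    spots_gag = [s for s in spots if s.channel == "gag"]

    tracks = link_nearest_neighbor(spots, max_disp_um=cfg.max_disp_um, max_gap=cfg.max_gap)
    rna_tracks = [t for t in tracks if t.channel == "rna" and len(t) >= 2]
    gag_tracks = [t for t in tracks if t.channel == "gag" and len(t) >= 2]

    burst_track: Optional[Track] = None
    if rna_tracks:
        # temporal extension of the per-nucleus brightest rule
        burst_track = max(rna_tracks, key=lambda t: (t.mean_sum_intensity(), -t.object_id))
    else:
        report["warnings"].append("no burst track (no linkable RNA detections)")
    if not gag_tracks:
        report["warnings"].append("no Gag track (no linkable protein detections)")

    report["n_spots_rna"] = len(spots_rna)
    report["n_spots_gag"] = len(spots_gag)
    report["n_tracks_rna"] = len(rna_tracks)
    report["n_tracks_gag"] = len(gag_tracks)
    report["per_gag_track"] = []

    traces = []
    if burst_track is not None:
        for tr in gag_tracks:
            try:
                trace = compute_distance_trace(tr, burst_track, stack.frame_interval_s)
            except InsufficientDataError as exc:
                report["warnings"].append(f"track {tr.object_id}: {exc}")
                continue
            episodes = call_kissing_episodes(trace, cfg.kissing_threshold_um)
            events = approach_times(trace, cfg.kissing_threshold_um)
            summary = summarize_kissing(trace, episodes, events)
            summary["object_id"] = tr.object_id
            summary["episodes"] = [
                [e.start_frame, e.end_frame, e.duration_s, e.min_distance_um]
                for e in episodes
            ]
            report["per_gag_track"].append(summary)
            traces.append((tr.object_id, trace))

    # movie-level aggregate over all condensate track segments (the linker
    # may split a single physical object at large inter-frame jumps)
    tot_valid = sum(s["n_valid_frames"] for s in report["per_gag_track"])
    tot_kiss = sum(
        s["kissing_frame_fraction"] * s["n_valid_frames"] for s in report["per_gag_track"]
    )
    report["overall"] = {
        "n_valid_frames": int(tot_valid),
        "kissing_frame_fraction": tot_kiss / tot_valid if tot_valid else 0.0,
        "n_episodes": int(sum(s["n_episodes"] for s in report["per_gag_track"])),
        "total_kissing_time_s": float(
            sum(s["total_kissing_time_s"] for s in report["per_gag_track"])
        ),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spots_to_frame(spots).to_csv(out / "spots.csv", index=False)
        tracks_to_frame(tracks).to_csv(out / "tracks.csv", index=False)
        rows = []
        for oid, trace in traces:
            for i in range(len(trace.frames)):
                rows.append(
                    {
                        "object_id": oid,
                        "frame": int(trace.frames[i]),
                        "time_s": float(trace.time_s[i]),
                        "distance_um": float(trace.distance_um[i]),
                        "gag_intensity": float(trace.gag_intensity[i]),
                        "rna_intensity": float(trace.rna_intensity[i]),
                        "gag_area_um2": float(trace.gag_area_um2[i]),
                        "valid": bool(trace.valid[i]),
                    }
                )
        pd.DataFrame(rows).to_csv(out / "distance_traces.csv", index=False)
        _write_json(report, out / "live_report.json")
        if traces:
            from .plotting import plot_distance_trace

            plot_distance_trace(
                traces[0][1], cfg.kissing_threshold_um, out / "distance_trace.png"
            )
    return report


def detect_volume(vol: VolumeStack, cfg: PipelineConfig, mask: NuclearMask) -> list[SpotRecord]:
    spots: list[SpotRecord] = []
    for name in vol.channels:
        if name == "nuclear":
            continue
        found = detect_spots(
            vol.channel(name),
            vol.voxel_size_um,
            scale_um=cfg.detect_scale_um,
            threshold=cfg.detect_threshold,
            k_sigma=cfg.detect_k_sigma,
            min_size=cfg.min_spot_vox,
            channel=name,
        )
        for s in found:
            s.nucleus_id = mask.nucleus_of(s.center_um)
        spots.extend(found)
    # relabel uniquely across channels
    for i, s in enumerate(spots):
        s.label = i
    return spots


def run_fixed_pipeline(
    vol: VolumeStack,
    cfg: PipelineConfig,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Full fixed-cell analysis of one z-stack (one field of view)."""
    report = _report_header(cfg)
    report["warnings"] = []
    if "nuclear" not in vol.channels:
        raise KeyError("fixed pipeline requires a 'nuclear' channel")
    mask = segment_nucleus(
        vol.channel("nuclear"),
        vol.voxel_size_um,
        smooth_um=cfg.nucleus_smooth_um,
        min_volume_um3=cfg.nucleus_min_volume_um3,
    )
    report["n_nuclei"] = mask.n_nuclei

    spots = detect_volume(vol, cfg, mask)
    nuclear_spots = [s for s in spots if s.nucleus_id and s.nucleus_id > 0]
    report["n_spots"] = len(spots)
    report["n_spots_excluded_outside_nucleus"] = len(spots) - len(nuclear_spots)

    bursts = identify_bursts(nuclear_spots, rna_channel="rna")
    spot_by_label = {s.label: s for s in spots}
    report["bursts"] = {str(k): v for k, v in bursts.items()}
    for nid in range(1, mask.n_nuclei + 1):
        if bursts.get(nid) is None:
            report["warnings"].append(f"nucleus {nid}: no burst (no RNA focus)")

    # rim distances
    if nuclear_spots:
        pts = np.array([s.center_um for s in nuclear_spots])
        records, n_out = distance_to_boundary(
            pts,
            mask,
            channels=[s.channel for s in nuclear_spots],
            labels=[s.label for s in nuclear_spots],
        )
        rim_by_label = {r.label: r for r in records}
        report["n_rim_excluded"] = n_out
        burst_rims = [
            rim_by_label[lbl].distance_um
            for lbl in bursts.values()
            if lbl is not None and lbl in rim_by_label
        ]
        gag_rims = [
            r.distance_um for r in records if r.channel == "gag"
        ]
        if burst_rims:
            report["burst_rim"] = fraction_within(burst_rims, cfg.rim_cutoff_um)
        if gag_rims:
            report["gag_rim"] = fraction_within(gag_rims, cfg.rim_cutoff_um)
    else:
        records, rim_by_label = [], {}

    # nearest-condensate geometry and near/far brightness per nucleus
    all_nearest = []
    near_far_rows = []
    for nid, burst_label in bursts.items():
        if burst_label is None:
            continue
        burst = spot_by_label[burst_label]
        gag_in_nuc = [s for s in nuclear_spots if s.channel == "gag" and s.nucleus_id == nid]
        res = nearest_gag_to_burst(gag_in_nuc, burst)
        if res["nearest_um"] is not None:
            all_nearest.append(res["nearest_um"])
        for s, dist in zip(gag_in_nuc, res["distances_um"]):
            near_far_rows.append(
                {"nucleus_id": nid, "label": s.label, "distance_um": float(dist),
                 "sum_intensity": s.sum_intensity}
            )
    report["nearest_gag_um"] = all_nearest
    if near_far_rows:
        d = np.array([r["distance_um"] for r in near_far_rows])
        gag_spots_nf = [spot_by_label[r["label"]] for r in near_far_rows]
        report["gag_within_burst_cutoff"] = fraction_within(d, cfg.rim_cutoff_um)
        try:
            report["near_far_test"] = near_far_intensity_test(
                gag_spots_nf, d, cfg.rim_cutoff_um
            )
        except InsufficientDataError as exc:
            report["warnings"].append(f"near/far test: {exc}")
        # distance vs burst size/intensity across nuclei
        rows_d, rows_v, rows_i = [], [], []
        for nid, burst_label in bursts.items():
            if burst_label is None:
                continue
            burst = spot_by_label[burst_label]
            for r in near_far_rows:
                if r["nucleus_id"] == nid:
                    rows_d.append(r["distance_um"])
                    rows_v.append(burst.volume_um3 or 0.0)
                    rows_i.append(burst.sum_intensity)
        try:
            report["distance_vs_burst"] = distance_vs_burst_correlation(rows_d, rows_v, rows_i)
        except Exception as exc:  # constant burst stats in a single-nucleus volume
            report["warnings"].append(f"distance-vs-burst correlation: {exc}")

    # co-localization
    rna_spots = [s for s in nuclear_spots if s.channel == "rna"]
    gag_spots = [s for s in nuclear_spots if s.channel == "gag"]
    if rna_spots:
        cr = object_colocalization(rna_spots, gag_spots, cfg.coloc_radius_um)
        mean, sem = cr.mean_sem
        report["object_coloc"] = {
            "fraction": cr.fraction,
            "n_query": cr.n_query,
            "n_coloc": cr.n_coloc,
            "mean": mean,
            "sem": sem,
        }
    overlap = signal_overlap_channel(
        [vol.channel("rna"), vol.channel("gag")], names=("rna", "gag")
    )
    report["signal_overlap_voxels"] = overlap.n_voxels
    if "eu" in vol.channels:
        triple, in_nuc = three_way_overlap(
            vol.channel("rna"), vol.channel("gag"), vol.channel("eu"), nuclear_mask=mask
        )
        report["three_way_overlap_voxels"] = triple.n_voxels
        report["three_way_overlap_in_nucleus"] = in_nuc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        spots_to_frame(spots).to_csv(out / "spots.csv", index=False)
        if records:
            pd.DataFrame(
                [
                    {
                        "label": r.label,
                        "channel": r.channel,
                        "nucleus_id": r.nucleus_id,
                        "distance_um": r.distance_um,
                    }
                    for r in records
                ]
            ).to_csv(out / "rim_distances.csv", index=False)
        if near_far_rows:
            pd.DataFrame(near_far_rows).to_csv(out / "gag_burst_distances.csv", index=False)
        import tifffile

        tifffile.imwrite(out / "nuclear_labels.tif", mask.labels.astype(np.uint16))
        _write_json(report, out / "fixed_report.json")
    return report
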
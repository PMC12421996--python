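"""Distance traces, kissing-episode calling, approach times and intensity
correlations — the central live-cell readout.

A *kissing interaction* is object-based co-localization of the condensate with
the RNA burst at a centre-to-centre distance of ≤ 0.25 µm (the optical
resolution limit). An episode is a maximal run of valid frames at or below
that threshold; an *approach event* measures the transit time from a local
distance maximum above the threshold to the first subsequent frame at or
below it (peak-to-valley time). No hysteresis is applied and one-frame
episodes count ("hit-and-run" contacts). Invalid frames (interpolated or
missing detections) terminate episodes rather than being bridged, so contacts
are never fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .track import Track


class InsufficientDataError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass
class DistanceTrace:
    """Per-frame centre-to-centre distance between the condensate and the
    burst, with the accompanying intensity/area series."""

    frames: np.ndarray
    time_s: np.ndarray
    distance_um: np.ndarray
    gag_intensity: np.ndarray
    rna_intensity: np.ndarray
    gag_area_um2: np.ndarray
    valid: np.ndarray  # False on interpolated/low-confidence frames

    def __post_init__(self) -> None:
        n = len(self.frames)
        for name in ("time_s", "distance_um", "gag_intensity", "rna_intensity", "gag_area_um2", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError("all trace arrays must have equal length")


@dataclass
class KissingEpisode:
    start_frame: int
    end_frame: int  # inclusive
    duration_s: float
    min_distance_um: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass
class ApproachEvent:
    peak_frame: int
    valley_frame: int
    transit_s: float


def compute_distance_trace(
    gag_track: Track, burst_track: Track, frame_interval_s: float
) -> DistanceTrace:
    """Euclidean centre distance per common frame, µm. Frames are valid only
    where both tracks carry real (non-interpolated) detections."""
    common = sorted(set(gag_track.frames) & set(burst_track.frames))
    if len(common) < 2:
        raise InsufficientDataError("tracks overlap in fewer than 2 frames")
    dist, g_int, r_int, g_area, valid = [], [], [], [], []
    for f in common:
        gs = gag_track.spot_at(f)
        bs = burst_track.spot_at(f)
        dist.append(float(np.linalg.norm(gs.center_um - bs.center_um)))
        g_int.append(gs.sum_intensity)
        r_int.append(bs.sum_intensity)
        g_area.append(gs.area_um2 if gs.area_um2 is not None else np.nan)
        valid.append(f not in gag_track.gap_frames and f not in burst_track.gap_frames)
    frames = np.asarray(common)
    return DistanceTrace(
        frames=frames,
        time_s=frames * frame_interval_s,
        distance_um=np.asarray(dist),
        gag_intensity=np.asarray(g_int),
        rna_intensity=np.asarray(r_int),
        gag_area_um2=np.asarray(g_area),
        valid=np.asarray(valid, dtype=bool),
    )


def call_kissing_episodes(
    trace: DistanceTrace, threshold_um: float = 0.25
) -> list[KissingEpisode]:
    """Maximal runs of valid frames with distance ≤ threshold (inclusive
    boundary). Invalid frames terminate runs. Durations count the frames in
    the episode times the frame interval."""
    below = (trace.distance_um <= threshold_um) & trace.valid
    interval = float(trace.time_s[1] - trace.time_s[0]) if len(trace.time_s) > 1 else 0.0
    episodes: list[KissingEpisode] = []
    start: Optional[int] = None
    for i in range(len(below) + 1):
        inside = i < len(below) and below[i]
        if inside and start is None:
            start = i
        elif not inside and start is not None:
            seg = trace.distance_um[start:i]
            episodes.append(
                KissingEpisode(
                    start_frame=int(trace.frames[start]),
                    end_frame=int(trace.frames[i - 1]),
                    duration_s=(i - start) * interval,
                    min_distance_um=float(seg.min()),
                )
            )
            start = None
    return episodes


def approach_times(
    trace: DistanceTrace, threshold_um: float = 0.25
) -> list[ApproachEvent]:
    """Peak-to-valley transit times.

    A peak is a local distance maximum above the threshold (3-frame
    neighbourhood); its valley is the first subsequent valid frame at or
    below the threshold, provided no invalid frame intervenes.
    """
    d, valid, frames = trace.distance_um, trace.valid, trace.frames
    n = len(d)
    events: list[ApproachEvent] = []
    for i in range(n):
        if not valid[i] or d[i] <= threshold_um:
            continue
        left_ok = i == 0 or (valid[i - 1] and d[i] >= d[i - 1])
        right_ok = i == n - 1 or (valid[i + 1] and d[i] >= d[i + 1])
        if not (left_ok and right_ok):
            continue
        for j in range(i + 1, n):
            if not valid[j]:
                break
            if d[j] <= threshold_um:
                events.append(
                    ApproachEvent(
                        peak_frame=int(frames[i]),
                        valley_frame=int(frames[j]),
                        transit_s=float(trace.time_s[j] - trace.time_s[i]),
                    )
                )
                break
    return events


def intensity_correlation(
    series_a: Sequence[float],
    series_b: Sequence[float],
    valid: Optional[Sequence[bool]] = None,
) -> tuple[float, float, int]:
    """Sample Pearson r between two paired series with a two-sided p value
    from the t distribution on n−2 degrees of freedom."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if valid is not None:
        m = np.asarray(valid, dtype=bool)
        a, b = a[m], b[m]
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 3:
        raise InsufficientDataError(f"need ≥3 paired frames, got {n}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue), n


def summarize_kissing(
    trace: DistanceTrace,
    episodes: Sequence[KissingEpisode],
    events: Sequence[ApproachEvent],
) -> dict:
    """Per-movie JSON-ready summary of the kissing statistics."""
    durations = [e.duration_s for e in episodes]
    n_valid = int(trace.valid.sum())
    kiss_frames = int(sum(e.n_frames for e in episodes))
    summary = {
        "n_frames": int(len(trace.frames)),
        "n_valid_frames": n_valid,
        "n_episodes": len(episodes),
        "total_kissing_time_s": float(sum(durations)),
        "kissing_frame_fraction": kiss_frames / n_valid if n_valid else 0.0,
        "episode_durations_s": durations,
        "approach_transit_s": [e.transit_s for e in events],
        "min_distance_um": float(np.min(trace.distance_um)) if len(trace.distance_um) else None,
    }
    try:
        r, p, n = intensity_correlation(
            trace.gag_intensity, trace.rna_intensity, trace.valid
        )
        summary.update({"intensity_r": r, "intensity_p": p, "intensity_n": n})
    except (InsufficientDataError, UndefinedCorrelationError) as exc:
        summary.update({"intensity_r": None, "intensity_p": None, "intensity_note": str(exc)})
    return summary
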
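"""Frame-to-frame linking of detected foci into tracks.

The movies this pipeline targets contain very few objects (a stationary RNA
burst and one to a handful of protein condensates), so each frame is linked
by exact optimal assignment (Hungarian algorithm) over candidate
(track, spot) pairs within the displacement gate: the matching maximises the
number of links and, among those, minimises total displacement — identical
to exhaustive enumeration at these problem sizes. Tracks may bridge up to
``max_gap`` missing frames; bridged frames are filled by linear interpolation
and flagged so downstream statistics can exclude them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .detect import SpotRecord


@dataclass
class Track:
    """Time-ordered sequence of spots for one object."""

    object_id: int
    channel: str
    frames: list[int] = field(default_factory=list)
    spots: list[SpotRecord] = field(default_factory=list)
    gap_frames: set[int] = field(default_factory=set)  # interpolated entries

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def centers_um(self) -> np.ndarray:
        return np.array([s.center_um for s in self.spots])

    @property
    def sum_intensities(self) -> np.ndarray:
        return np.array([s.sum_intensity for s in self.spots])

    def mean_sum_intensity(self) -> float:
        real = [s.sum_intensity for f, s in zip(self.frames, self.spots) if f not in self.gap_frames]
        return float(np.mean(real)) if real else 0.0

    def spot_at(self, frame: int) -> Optional[SpotRecord]:
        try:
            return self.spots[self.frames.index(frame)]
        except ValueError:
            return None


def _group_by_frame(spots: Sequence[SpotRecord]) -> dict[int, list[SpotRecord]]:
    by_frame: dict[int, list[SpotRecord]] = {}
    for s in spots:
        if s.frame is None:
            raise ValueError("live linking requires spots with frame indices")
        by_frame.setdefault(int(s.frame), []).append(s)
    return by_frame


def link_nearest_neighbor(
    spots: Sequence[SpotRecord],
    max_disp_um: float = 0.5,
    max_gap: int = 2,
) -> list[Track]:
    """Optimal-assignment linking.

    ``max_disp_um`` is the per-frame displacement gate; across a gap of g
    missing frames the gate scales to ``max_disp_um * (g + 1)``. Each frame
    solves a gated linear assignment (maximum matches, then minimum total
    displacement). Spots are linked within their own channel only. Unmatched
    spots start new tracks. Gap frames are interpolated afterwards and
    recorded in ``Track.gap_frames``.
    """
    from scipy.optimize import linear_sum_assignment

    BIG = 1e9  # dominates any realistic displacement sum → max-cardinality

    channels = sorted({s.channel for s in spots})
    if len(channels) > 1:
        out: list[Track] = []
        for ch in channels:
            out.extend(
                link_nearest_neighbor(
                    [s for s in spots if s.channel == ch], max_disp_um, max_gap
                )
            )
        for i, tr in enumerate(out):
            tr.object_id = i
        return out

    by_frame = _group_by_frame(spots)
    if not by_frame:
        return []
    frames = sorted(by_frame)
    tracks: list[Track] = []
    open_tracks: list[Track] = []

    for f in frames:
        candidates = by_frame[f]
        used_spots: set[int] = set()
        eligible = [
            (ti, tr) for ti, tr in enumerate(open_tracks) if f - tr.frames[-1] <= max_gap + 1
        ]
        if eligible and candidates:
            cost = np.full((len(eligible), len(candidates)), BIG)
            for row, (ti, tr) in enumerate(eligible):
                gate = max_disp_um * (f - tr.frames[-1])
                last = tr.spots[-1].center_um
                for j, s in enumerate(candidates):
                    d = float(np.linalg.norm(s.center_um - last))
                    if d <= gate:
                        cost[row, j] = d
            rows, cols = linear_sum_assignment(cost)
            for row, j in zip(rows, cols):
                if cost[row, j] >= BIG:
                    continue
                _, tr = eligible[row]
                tr.frames.append(f)
                tr.spots.append(candidates[j])
                used_spots.add(j)
        for j, s in enumerate(candidates):
            if j not in used_spots:
                tr = Track(object_id=len(tracks), channel=s.channel, frames=[f], spots=[s])
                tracks.append(tr)
                open_tracks.append(tr)
        open_tracks = [tr for tr in open_tracks if f - tr.frames[-1] <= max_gap]

    filled: list[Track] = []
    for tr in tracks:
        filled.extend(fill_gaps(tr, max_gap))
    for i, tr in enumerate(filled):
        tr.object_id = i
    return filled


def _interpolated_spot(a: SpotRecord, b: SpotRecord, w: float, frame: int) -> SpotRecord:
    s = copy.copy(a)
    s.center_um = (1 - w) * np.asarray(a.center_um) + w * np.asarray(b.center_um)
    s.sum_intensity = (1 - w) * a.sum_intensity + w * b.sum_intensity
    s.peak_intensity = (1 - w) * a.peak_intensity + w * b.peak_intensity
    s.frame = frame
    s.low_confidence = True
    return s


def fill_gaps(track: Track, max_gap: int = 2) -> list[Track]:
    """Linearly interpolate centre and intensity across frame gaps of at most
    ``max_gap`` missing frames; longer gaps split the track. Interpolated
    frames are recorded in ``gap_frames``."""
    if len(track) == 0:
        return []
    segments: list[tuple[list[int], list[SpotRecord]]] = [([track.frames[0]], [track.spots[0]])]
    for f, s in zip(track.frames[1:], track.spots[1:]):
        prev_f = segments[-1][0][-1]
        if f - prev_f - 1 > max_gap:
            segments.append(([f], [s]))
        else:
            segments[-1][0].append(f)
            segments[-1][1].append(s)
    out: list[Track] = []
    for frames, spots in segments:
        new = Track(object_id=track.object_id, channel=track.channel)
        for (f0, s0), (f1, s1) in zip(
            list(zip(frames, spots))[:-1], list(zip(frames, spots))[1:]
        ):
            new.frames.append(f0)
            new.spots.append(s0)
            for g in range(f0 + 1, f1):
                w = (g - f0) / (f1 - f0)
                new.frames.append(g)
                new.spots.append(_interpolated_spot(s0, s1, w, g))
                new.gap_frames.add(g)
        new.frames.append(frames[-1])
        new.spots.append(spots[-1])
        out.append(new)
    return out
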
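"""Object-based and signal-based (pixel-overlap) co-localization.

Object-based: a query focus is co-localized when its nearest target centre is
at most ``radius_um`` away (inclusive boundary, default 0.25 µm); fractions
are computed per cell and aggregated as mean ± SEM across cells. Signal-based:
the voxelwise AND of per-channel threshold exceedance — the "white channel"
showing pixels where both signals are present, which can report edge overlap
even when the object centres are farther apart than the object-based radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from .detect import NuclearMask, SpotRecord


@dataclass
class OverlapChannel:
    """Binary overlap of ≥2 registered channels above per-channel thresholds."""

    mask: np.ndarray
    source_channels: tuple[str, ...]
    thresholds: tuple[float, ...]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def any_overlap(self) -> bool:
        return bool(self.mask.any())


@dataclass
class ColocResult:
    """Per-cell object co-localization fractions with aggregate mean ± SEM."""

    per_cell_fraction: dict[int, float]
    n_query: int
    n_coloc: int
    radius_um: float

    @property
    def fraction(self) -> float:
        return self.n_coloc / self.n_query if self.n_query else 0.0

    @property
    def mean_sem(self) -> tuple[float, float]:
        vals = np.array(list(self.per_cell_fraction.values()), dtype=float)
        if vals.size == 0:
            return float("nan"), float("nan")
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        return float(vals.mean()), sem


def object_colocalization(
    query_spots: Sequence[SpotRecord],
    target_spots: Sequence[SpotRecord],
    radius_um: float = 0.25,
) -> ColocResult:
    """Centre-distance co-localization at ``radius_um`` (boundary inclusive).

    Spots are grouped per cell by ``nucleus_id`` (None counts as one cell);
    cells with no query spots do not contribute a per-cell fraction.
    """
    if not target_spots:
        warnings.warn("empty target spot set — co-localization fraction is 0", stacklevel=2)
    by_cell_query: dict[int, list[SpotRecord]] = {}
    for s in query_spots:
        by_cell_query.setdefault(s.nucleus_id if s.nucleus_id is not None else -1, []).append(s)
    by_cell_target: dict[int, list[SpotRecord]] = {}
    for s in target_spots:
        by_cell_target.setdefault(s.nucleus_id if s.nucleus_id is not None else -1, []).append(s)

    per_cell: dict[int, float] = {}
    n_query = n_coloc = 0
    for cell, qs in by_cell_query.items():
        ts = by_cell_target.get(cell, [])
        n_query += len(qs)
        if not ts:
            per_cell[cell] = 0.0
            continue
        tree = cKDTree(np.array([t.center_um for t in ts]))
        dists, _ = tree.query(np.array([q.center_um for q in qs]))
        hits = int(np.count_nonzero(dists <= radius_um))
        n_coloc += hits
        per_cell[cell] = hits / len(qs)
    return ColocResult(
        per_cell_fraction=per_cell, n_query=n_query, n_coloc=n_coloc, radius_um=radius_um
    )


def signal_overlap_channel(
    channels: Sequence[np.ndarray],
    thresholds: Optional[Sequence[Optional[float]]] = None,
    names: Optional[Sequence[str]] = None,
) -> OverlapChannel:
    """Voxelwise AND of per-channel exceedance masks.

    Thresholds default to per-channel Otsu; pass explicit values to override
    individual channels (None entries keep Otsu). Symmetric and associative
    in its sources; raising any threshold never adds overlap voxels.
    """
    if len(channels) < 2:
        raise ValueError("need at least two channels")
    shape = np.asarray(channels[0]).shape
    arrays = []
    for c in channels:
        arr = np.asarray(c, dtype=float)
        if arr.shape != shape:
            raise ValueError("channel shapes must match")
        arrays.append(arr)
    if thresholds is None:
        thresholds = [None] * len(arrays)
    used = []
    mask = np.ones(shape, dtype=bool)
    for arr, thr in zip(arrays, thresholds):
        if thr is None:
            thr = float(threshold_otsu(arr)) if np.ptp(arr) > 0 else float(arr.max())
        used.append(float(thr))
        mask &= arr > thr
    if names is None:
        names = tuple(f"ch{i}" for i in range(len(arrays)))
    return OverlapChannel(mask=mask, source_channels=tuple(names), thresholds=tuple(used))


def three_way_overlap(
    chan_rna: np.ndarray,
    chan_gag: np.ndarray,
    chan_eu: np.ndarray,
    thresholds: Optional[Sequence[Optional[float]]] = None,
    nuclear_mask: Optional[NuclearMask] = None,
) -> tuple[OverlapChannel, Optional[bool]]:
    """Triple voxelwise AND (RNA ∧ protein ∧ nascent-RNA). When a nuclear
    mask is given, also reports whether any overlap voxel lies inside a
    nucleus."""
    overlap = signal_overlap_channel(
        [chan_rna, chan_gag, chan_eu], thresholds, names=("rna", "gag", "eu")
    )
    in_nucleus = None
    if nuclear_mask is not None:
        in_nucleus = bool((overlap.mask & nuclear_mask.mask).any())
    return overlap, in_nucleus
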
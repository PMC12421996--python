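import numpy as np
import pytest

from kisstrace import FixedSimConfig, LiveSimConfig
from kisstrace.detect import NuclearMask


@pytest.fixture
def live_cfg():
    return LiveSimConfig(n_frames=60, rng_seed=7)


@pytest.fixture
def fixed_cfg():
    return FixedSimConfig(rng_seed=11, n_gag_foci=8)


def digitized_ellipsoid_mask(
    semiaxes_um, spacing_um, margin_um=0.6
) -> tuple[NuclearMask, np.ndarray]:
    """Voxelize an axis-aligned ellipsoid; returns the mask and its centre."""
    semi = np.asarray(semiaxes_um, dtype=float)
    sp = np.asarray(spacing_um, dtype=float)
    shape = np.ceil(2 * (semi + margin_um) / sp).astype(int)
    center = (shape - 1) * sp / 2
    idx = np.indices(shape, dtype=float)
    coords = idx * sp.reshape(-1, *([1] * len(shape)))
    inside = (
        np.sum(((coords - center.reshape(-1, *([1] * len(shape)))) / semi.reshape(-1, *([1] * len(shape)))) ** 2, axis=0)
        <= 1.0
    )
    return NuclearMask(labels=inside.astype(int), spacing=tuple(sp)), center


def brute_force_ellipsoid_distance(point_rel_um, semiaxes_um, n=400):
    """Minimum distance to a dense surface sampling of the ellipsoid —
    independent oracle for the analytic solver."""
    a = np.asarray(semiaxes_um, dtype=float)
    th = np.linspace(0, np.pi, n)
    ph = np.linspace(0, 2 * np.pi, 2 * n, endpoint=False)
    T, P = np.meshgrid(th, ph, indexing="ij")
    surf = np.stack(
        [a[0] * np.cos(T), a[1] * np.sin(T) * np.cos(P), a[2] * np.sin(T) * np.sin(P)],
        axis=-1,
    ).reshape(-1, 3)
    return float(np.min(np.linalg.norm(surf - np.asarray(point_rel_um), axis=1)))
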
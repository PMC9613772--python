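import numpy as np
import pytest
from hypothesis import settings

import ktrdiv as kd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def short_sim():
    """Small, short population with divisions, reused across tests."""
    cfg = kd.SimConfig(n_cells=8, frac_dividing=0.5, duration_h=6,
                       sampling_interval_h=0.25, division_window_h=(2.5, 5.0),
                       seed=3)
    cells, traces = kd.simulate_cell_population(cfg)
    return cfg, cells, traces


@pytest.fixture(scope="session")
def ideal_render(short_sim):
    """Noiseless, blur-free, shading-free render of the short population."""
    cfg, cells, _ = short_sim
    rc = kd.RenderConfig(psf_sigma_px=0.0, gaussian_noise_sd=0.0,
                         flatfield_amplitude=0.0, background_offset=0.0)
    movie = kd.render_timelapse(cells, rc, cfg)
    return rc, movie


def brute_force_cytoring(mask: np.ndarray, width: int) -> np.ndarray:
    """Per-pixel oracle: nearest-nucleus Euclidean assignment within `width`.

    For every background pixel, compute the distance to every nuclear pixel
    of every label; assign the pixel to the nearest label (ties to the
    lower label) if that distance is within `width`.
    """
    from scipy.spatial.distance import cdist

    labels = np.unique(mask)
    labels = labels[labels > 0]
    out = np.zeros_like(mask, dtype=np.int32)
    if labels.size == 0:
        return out
    bg = np.argwhere(mask == 0)
    best_d = np.full(len(bg), np.inf)
    best_lab = np.zeros(len(bg), dtype=np.int32)
    for lab in labels:  # ascending: strict < keeps the lower label on ties
        d = cdist(bg, np.argwhere(mask == lab)).min(axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        best_lab[upd] = lab
    sel = best_d <= width
    out[bg[sel, 0], bg[sel, 1]] = best_lab[sel]
    return out


def random_label_mask(rng: np.random.Generator, shape=(64, 64),
                      n_blobs=4, radius_range=(3, 7)) -> np.ndarray:
    """Random disjoint disk mask with labels 1..n (some may be absent)."""
    mask = np.zeros(shape, dtype=np.int32)
    rows, cols = shape
    placed = []
    lab = 1
    for _ in range(n_blobs * 4):
        if lab > n_blobs:
            break
        rad = rng.integers(*radius_range)
        r = rng.integers(rad, rows - rad)
        c = rng.integers(rad, cols - rad)
        if any((r - pr) ** 2 + (c - pc) ** 2 < (rad + prad + 1) ** 2
               for pr, pc, prad in placed):
            continue
        rr, cc = np.mgrid[0:rows, 0:cols]
        mask[(rr - r) ** 2 + (cc - c) ** 2 <= rad ** 2] = lab
        placed.append((r, c, rad))
        lab += 1
    return mask
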
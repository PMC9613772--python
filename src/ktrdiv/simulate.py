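"""Synthetic single-cell KTR dynamics and time-lapse movie rendering.

Generates ground-truth populations of cells with ERK/Akt activity time
courses (baseline, growth-factor-induced logistic rise to a noisy plateau,
AR(1) noise with a per-class ERK-Akt correlation) and renders them into
multi-channel fluorescence movies in which cell division produces the
transient steep C/N-ratio drop that the division detector keys on.

Activity is expressed directly in C/N-ratio units: the ground-truth
"activity" of a cell at a frame IS the cytoplasm/nuclear ratio an ideal
quantification would measure.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

CHANNELS = ("erk", "akt")

__all__ = [
    "SimConfig",
    "RenderConfig",
    "GroundTruthCell",
    "simulate_cell_population",
    "simulate_crosstalk_experiment",
    "render_timelapse",
    "masks_from_cells",
    "write_fixture",
    "read_traces",
    "read_ground_truth",
]


@dataclass
class SimConfig:
    """Study-design parameters for a simulated KTR imaging experiment.

    Defaults emulate the canonical acquisition: serum-starved cells imaged
    every 15 min for 48 h, growth factor added after 1 h of baseline, with
    divisions falling in the S/G2 window so they land inside the 8.5-40 h
    analysis interval.
    """

    n_cells: int = 200
    frac_dividing: float = 0.5
    duration_h: float = 48.0
    sampling_interval_h: float = 0.25
    gf_time_h: float = 1.0
    # activity (C/N units)
    baseline_activity: float = 0.4
    plateau_median_nondiv: float = 1.0
    effect_size_erk: float = 0.35
    effect_size_akt: float = 0.15
    rise_t50_h: float = 1.0          # half-rise time after growth factor
    rise_tau_h: float = 0.25         # logistic rise time constant
    noise_sd: float = 0.1            # fractional stationary sd of the AR(1) noise
    ar_coeff: float = 0.8
    cell_sd: float = 0.25            # per-cell plateau spread (C/N units)
    rho_div: float = 0.35
    rho_nondiv: float = 0.7
    # division phenomenology
    division_window_h: tuple[float, float] = (16.0, 36.0)
    drop_frac: float = 0.5
    drop_span_frames: int = 2
    # optional pulsing (disabled by default)
    pulse_amplitude: float = 0.0
    pulse_period_h: float = 2.0
    # crosstalk / perturbation structure (0 = the two nodes do not interact)
    inhibit: str | None = None       # None, "erk" or "akt"
    crosstalk_erk_to_akt: float = 0.0
    crosstalk_akt_to_erk: float = 0.0
    # motion
    arena_shape: tuple[int, int] = (256, 256)
    motion_step_px: float = 0.5
    border_margin_px: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if not 0.0 <= self.frac_dividing <= 1.0:
            raise ValueError("frac_dividing must lie in [0, 1]")
        if self.duration_h <= 0 or self.sampling_interval_h <= 0:
            raise ValueError("duration_h and sampling_interval_h must be positive")
        lo, hi = self.division_window_h
        if not (self.gf_time_h < lo < hi < self.duration_h):
            raise ValueError(
                "division_window_h must lie strictly inside (gf_time_h, duration_h)"
            )
        for rho in (self.rho_div, self.rho_nondiv):
            if abs(rho) > 1:
                raise ValueError("class correlations must lie in [-1, 1]")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")
        if not 0.0 < self.drop_frac <= 1.0:
            raise ValueError("drop_frac must lie in (0, 1]")
        if self.drop_span_frames < 1:
            raise ValueError("drop_span_frames must be >= 1")
        if self.inhibit not in (None, "erk", "akt"):
            raise ValueError("inhibit must be None, 'erk' or 'akt'")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h / self.sampling_interval_h)) + 1

    @property
    def times_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.sampling_interval_h

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class RenderConfig:
    """Optics and geometry of the rendered movies (intensities in ADU)."""

    image_shape: tuple[int, int] = (256, 256)
    nucleus_radius_px: int = 10
    cyto_radius_px: int = 22
    # 20x widefield at ~0.65 um/px puts the PSF sigma near a third of a pixel
    psf_sigma_px: float = 0.3
    background_offset: float = 100.0
    flatfield_amplitude: float = 0.1
    gaussian_noise_sd: float = 20.0
    total_ktr_intensity: float = 2000.0

    def __post_init__(self) -> None:
        if self.nucleus_radius_px < 3:
            raise ValueError("nucleus_radius_px must be >= 3")
        if self.cyto_radius_px <= self.nucleus_radius_px:
            raise ValueError("cyto_radius_px must exceed nucleus_radius_px")
        for v in (self.background_offset, self.total_ktr_intensity,
                  self.gaussian_noise_sd):
            if v < 0:
                raise ValueError("intensities must be >= 0")


@dataclass
class GroundTruthCell:
    """One simulated cell: latent activity, observed C/N traces and motion."""

    cell_id: int
    divides: bool
    division_time_h: float | None
    division_frame: int | None
    erk_activity: np.ndarray          # latent, drop-free
    akt_activity: np.ndarray
    erk_cn: np.ndarray                # observed C/N (drop injected at division)
    akt_cn: np.ndarray
    path: np.ndarray                  # (n_frames, 2) centroids, (row, col) px

    def activity(self, channel: str) -> np.ndarray:
        return self.erk_activity if channel == "erk" else self.akt_activity

    def cn(self, channel: str) -> np.ndarray:
        return self.erk_cn if channel == "erk" else self.akt_cn


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _logistic_rise(times_h: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Fractional rise (0 at baseline, ->1 at plateau) after growth factor."""
    z = (times_h - cfg.gf_time_h - cfg.rise_t50_h) / cfg.rise_tau_h
    rise = 1.0 / (1.0 + np.exp(-z))
    rise[times_h < cfg.gf_time_h] = 0.0
    return rise


def _bivariate_ar1(rng: np.random.Generator, n: int, sd: float, a: float,
                   rho: float) -> np.ndarray:
    """AR(1) noise pair with stationary sd `sd` and cross-correlation `rho`."""
    chol_rho = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]])
                                  + 1e-12 * np.eye(2))
    innov = rng.standard_normal((n, 2)) @ chol_rho.T
    out = np.empty((n, 2))
    out[0] = innov[0] * sd
    scale = sd * np.sqrt(1.0 - a * a)
    for t in range(1, n):
        out[t] = a * out[t - 1] + scale * innov[t]
    return out


def _rise_scales(cfg: SimConfig) -> dict[str, float]:
    """Per-channel scaling of the growth-factor rise under inhibition.

    Inhibiting a node suppresses its own rise; any configured crosstalk
    edge propagates a proportional suppression to the other node.
    """
    scale = {"erk": 1.0, "akt": 1.0}
    if cfg.inhibit == "erk":
        scale["erk"] = 0.0
        scale["akt"] = 1.0 - cfg.crosstalk_erk_to_akt
    elif cfg.inhibit == "akt":
        scale["akt"] = 0.0
        scale["erk"] = 1.0 - cfg.crosstalk_akt_to_erk
    return scale


def _initial_positions(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Jittered-grid seeding with a guaranteed minimum separation."""
    rows, cols = cfg.arena_shape
    m = cfg.border_margin_px
    usable_r, usable_c = rows - 2 * m, cols - 2 * m
    if usable_r <= 0 or usable_c <= 0:
        raise ValueError("arena too small for the border margin")
    n_side = int(np.ceil(np.sqrt(cfg.n_cells)))
    pitch_r, pitch_c = usable_r / n_side, usable_c / n_side
    sites = [(m + (i + 0.5) * pitch_r, m + (j + 0.5) * pitch_c)
             for i in range(n_side) for j in range(n_side)]
    order = rng.permutation(len(sites))[: cfg.n_cells]
    jit = min(pitch_r, pitch_c) * 0.15
    pos = np.asarray([sites[k] for k in order], dtype=float)
    pos += rng.uniform(-jit, jit, size=pos.shape)
    return pos


def _random_walk(rng: np.random.Generator, start: np.ndarray, n_frames: int,
                 cfg: SimConfig) -> np.ndarray:
    """Reflected Gaussian random walk confined to the margined arena."""
    rows, cols = cfg.arena_shape
    m = float(cfg.border_margin_px)
    steps = rng.normal(0.0, cfg.motion_step_px, size=(n_frames - 1, 2))
    path = np.empty((n_frames, 2))
    path[0] = start
    lo = np.array([m, m])
    hi = np.array([rows - 1 - m, cols - 1 - m])
    for t in range(1, n_frames):
        p = path[t - 1] + steps[t - 1]
        p = np.where(p < lo, 2 * lo - p, p)
        p = np.where(p > hi, 2 * hi - p, p)
        path[t] = np.clip(p, lo, hi)
    return path


def simulate_cell_population(
    config: SimConfig,
) -> tuple[list[GroundTruthCell], pd.DataFrame]:
    """Simulate a population of single-cell ERK/Akt C/N time courses.

    Returns the ground-truth cells and a long-format trace table with
    columns (cell_id, frame, time_h, channel, cn_ratio). Exactly
    ``round(frac_dividing * n_cells)`` cells divide, at a time drawn
    uniformly from ``division_window_h``; at division the observed C/N of
    both channels is multiplied by ``1 - drop_frac`` for
    ``drop_span_frames`` frames (the morphological drop signature), after
    which the trace continues as the nearer daughter.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_frames = cfg.n_frames
    times = cfg.times_h
    rise = _logistic_rise(times, cfg)
    rise_scale = _rise_scales(cfg)

    n_div = _round_half_up(cfg.frac_dividing * cfg.n_cells)
    divides_flags = np.zeros(cfg.n_cells, dtype=bool)
    divides_flags[rng.permutation(cfg.n_cells)[:n_div]] = True

    positions = _initial_positions(rng, cfg)

    effect = {"erk": cfg.effect_size_erk, "akt": cfg.effect_size_akt}
    cells: list[GroundTruthCell] = []
    records = []
    for cid in range(cfg.n_cells):
        div = bool(divides_flags[cid])
        rho = cfg.rho_div if div else cfg.rho_nondiv
        # per-cell plateau offsets share the class correlation so that the
        # pooled (cell x time) ERK-Akt correlation stays on target
        chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]])
                                  + 1e-12 * np.eye(2))
        cell_off = cfg.cell_sd * (chol @ rng.standard_normal(2))
        noise = _bivariate_ar1(rng, n_frames, cfg.noise_sd, cfg.ar_coeff, rho)

        latent = {}
        for k, ch in enumerate(CHANNELS):
            plateau = (cfg.plateau_median_nondiv
                       + (effect[ch] if div else 0.0)
                       + cell_off[k])
            amp = (plateau - cfg.baseline_activity) * rise_scale[ch]
            mean_t = cfg.baseline_activity + amp * rise
            if cfg.pulse_amplitude > 0:
                pulse = cfg.pulse_amplitude * np.sin(
                    2 * np.pi * (times - cfg.gf_time_h) / cfg.pulse_period_h)
                mean_t = mean_t + pulse * rise
            # multiplicative noise: measured C/N scatter scales with the
            # signal level, as in ratio imaging
            latent[ch] = np.clip(mean_t * (1.0 + noise[:, k]), 0.02, None)

        if div:
            t_div = rng.uniform(*cfg.division_window_h)
            f_div = int(round(t_div / cfg.sampling_interval_h))
        else:
            t_div, f_div = None, None

        observed = {}
        for ch in CHANNELS:
            obs = latent[ch].copy()
            if div:
                stop = min(f_div + cfg.drop_span_frames, n_frames)
                obs[f_div:stop] *= (1.0 - cfg.drop_frac)
                obs[f_div:stop] = np.clip(obs[f_div:stop], 0.02, None)
            observed[ch] = obs

        path = _random_walk(rng, positions[cid], n_frames, cfg)
        cells.append(GroundTruthCell(
            cell_id=cid, divides=div, division_time_h=t_div,
            division_frame=f_div,
            erk_activity=latent["erk"], akt_activity=latent["akt"],
            erk_cn=observed["erk"], akt_cn=observed["akt"], path=path,
        ))
        for ch in CHANNELS:
            records.append(pd.DataFrame({
                "cell_id": cid,
                "frame": np.arange(n_frames),
                "time_h": times,
                "channel": ch,
                "cn_ratio": observed[ch],
            }))

    traces = pd.concat(records, ignore_index=True)
    return cells, traces


def simulate_crosstalk_experiment(
    config: SimConfig, inhibit: str | None, seed: int | None = None,
) -> pd.DataFrame:
    """One arm of the 2-node network-reconstruction design.

    Re-runs the population simulation with the named node inhibited
    (suppressing its growth-factor-induced rise, and the other node's rise
    through any configured crosstalk edge). Divisions are disabled: the
    perturbation time courses are short (acute-regime) recordings of
    activity only.
    """
    cfg = config.replace(
        inhibit=inhibit,
        frac_dividing=0.0,
        seed=config.seed if seed is None else seed,
    )
    _, traces = simulate_cell_population(cfg)
    return traces


# ---------------------------------------------------------------------------
# rendering


def _activity_to_cyto_fraction(a: np.ndarray | float) -> np.ndarray:
    """Monotone map from C/N activity to the cytoplasmic KTR fraction.

    phi = a / (1 + a), clipped to [0.05, 0.95] so both compartments always
    carry signal; within the clip range the per-pixel intensity ratio of
    annulus to nucleus equals the activity exactly.
    """
    return np.clip(np.asarray(a, dtype=float) / (1.0 + np.asarray(a, dtype=float)),
                   0.05, 0.95)


def _paint_disk(img: np.ndarray, center: np.ndarray, radius: float,
                value: float, annulus_inner: float | None = None) -> None:
    """Add `value` over a disk (or annulus) around `center`, clipped to bounds."""
    rows, cols = img.shape
    r0 = int(np.floor(center[0] - radius)) - 1
    r1 = int(np.ceil(center[0] + radius)) + 2
    c0 = int(np.floor(center[1] - radius)) - 1
    c1 = int(np.ceil(center[1] + radius)) + 2
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, rows), min(c1, cols)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    sel = d2 <= radius ** 2
    if annulus_inner is not None:
        sel &= d2 > annulus_inner ** 2
    img[r0:r1, c0:c1][sel] += value


def _nucleus_centers(cells: list[GroundTruthCell], frame: int,
                     render: RenderConfig) -> list[tuple[int, np.ndarray]]:
    """(cell_id, center) for every nucleus present at `frame`, daughters included."""
    out = []
    for cell in cells:
        out.append((cell.cell_id, cell.path[frame]))
        if cell.divides and frame >= cell.division_frame:
            # second daughter departs perpendicular to nothing in particular;
            # a fixed direction keyed on cell_id keeps rendering deterministic
            ang = 2 * np.pi * ((cell.cell_id * 0.6180339887) % 1.0)
            sep = 2 * render.nucleus_radius_px + 2
            off = sep * np.array([np.sin(ang), np.cos(ang)])
            out.append((cell.cell_id, cell.path[frame] + off))
    return out


def _check_overlaps(cells: list[GroundTruthCell], render: RenderConfig,
                    n_frames: int) -> None:
    min_sep = 2 * render.nucleus_radius_px
    for f in (0, n_frames // 2, n_frames - 1):
        entries = _nucleus_centers(cells, f, render)
        pts = np.array([p for _, p in entries])
        ids = [i for i, _ in entries]
        if len(pts) < 2:
            continue
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        iu = np.triu_indices(len(pts), k=1)
        bad = [(ids[i], ids[j]) for i, j in zip(*iu)
               if d[i, j] < min_sep and ids[i] != ids[j]]
        if bad:
            offenders = sorted({c for pair in bad for c in pair})
            raise ValueError(
                f"unresolvably overlapping nuclei at frame {f}: cells {offenders}")


def _smooth_flatfield(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Unit-mean smooth multiplicative shading field, 1 + amplitude * f(x, y)."""
    rows, cols = shape
    rr = np.linspace(-1.0, 1.0, rows)[:, None]
    cc = np.linspace(-1.0, 1.0, cols)[None, :]
    f = 0.5 * (rr + cc)  # tilted plane in [-1, 1], zero mean
    return 1.0 + amplitude * f


def render_timelapse(
    cells: list[GroundTruthCell],
    render: RenderConfig,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a population into a (frames, channels, rows, cols) movie.

    Channel 0 is the nuclear marker; channels 1 and 2 are the ERK and Akt
    KTRs. For each cell the KTR intensity is split between the nuclear disk
    and the cytoplasmic annulus so the annulus/nucleus per-pixel ratio
    equals the observed ground-truth C/N. Frames are PSF-blurred,
    shaded by a smooth flatfield, offset and corrupted by Gaussian noise.
    """
    if not cells:
        raise ValueError("cell list is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed + 104729)
    n_frames = len(cells[0].path)
    _check_overlaps(cells, render, n_frames)
    rows, cols = render.image_shape
    movie = np.zeros((n_frames, 3, rows, cols), dtype=float)
    flat = _smooth_flatfield(render.image_shape, render.flatfield_amplitude)

    cn_by_ch = {"erk": 1, "akt": 2}
    for f in range(n_frames):
        ideal = movie[f]
        for cell in cells:
            centers = [cell.path[f]]
            if cell.divides and f >= cell.division_frame:
                centers = [p for i, p in _nucleus_centers([cell], f, render)]
            for center in centers:
                if not (0 <= center[0] < rows and 0 <= center[1] < cols):
                    continue
                _paint_disk(ideal[0], center, render.nucleus_radius_px,
                            render.total_ktr_intensity)
                for ch, k in cn_by_ch.items():
                    a = cell.cn(ch)[f]
                    phi = float(_activity_to_cyto_fraction(a))
                    _paint_disk(ideal[k], center, render.nucleus_radius_px,
                                render.total_ktr_intensity * (1 - phi))
                    _paint_disk(ideal[k], center, render.cyto_radius_px,
                                render.total_ktr_intensity * phi,
                                annulus_inner=render.nucleus_radius_px)
        for k in range(3):
            img = ideal[k]
            if render.psf_sigma_px > 0:
                img = ndi.gaussian_filter(img, render.psf_sigma_px)
            img = img * flat + render.background_offset
            if render.gaussian_noise_sd > 0:
                img = img + rng.normal(0.0, render.gaussian_noise_sd, img.shape)
            movie[f, k] = np.clip(img, 0.0, None)
    return movie


def masks_from_cells(cells: list[GroundTruthCell], render: RenderConfig,
                     frames: range | None = None) -> np.ndarray:
    """Ground-truth nuclear label masks (label = cell_id + 1), no optics.

    Daughter nuclei after division carry the mother's label for the nearer
    daughter; the departing daughter is not labelled (its track is a new
    object for the tracker to discover via segmentation, not ground truth).
    """
    n_frames = len(cells[0].path)
    idx = frames if frames is not None else range(n_frames)
    rows, cols = render.image_shape
    masks = np.zeros((len(idx), rows, cols), dtype=np.int32)
    for out_f, f in enumerate(idx):
        img = masks[out_f]
        for cell in cells:
            center = cell.path[f]
            if not (0 <= center[0] < rows and 0 <= center[1] < cols):
                continue
            r = render.nucleus_radius_px
            r0, r1 = max(int(center[0] - r) - 1, 0), min(int(center[0] + r) + 2, rows)
            c0, c1 = max(int(center[1] - r) - 1, 0), min(int(center[1] + r) + 2, cols)
            sub_r, sub_c = np.mgrid[r0:r1, c0:c1]
            sel = (sub_r - center[0]) ** 2 + (sub_c - center[1]) ** 2 <= r ** 2
            img[r0:r1, c0:c1][sel] = cell.cell_id + 1
    return masks


# ---------------------------------------------------------------------------
# fixtures on disk

TRACE_COLUMNS = ["cell_id", "frame", "time_h", "channel", "cn_ratio"]
TRUTH_COLUMNS = ["cell_id", "divides", "division_time_h"]
CHANNEL_FILES = {0: "nuclear.tif", 1: "erk.tif", 2: "akt.tif"}


def write_fixture(
    traces: pd.DataFrame,
    images: np.ndarray | None,
    out_dir: str | os.PathLike,
    cells: list[GroundTruthCell] | None = None,
) -> dict[str, str]:
    """Write traces / ground truth as CSV and movies as per-channel TIFFs."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    tr = traces.loc[:, TRACE_COLUMNS] if len(traces) else pd.DataFrame(
        columns=TRACE_COLUMNS)
    p = os.path.join(out_dir, "traces.csv")
    tr.to_csv(p, index=False)
    paths["traces"] = p
    if cells is not None:
        gt = pd.DataFrame({
            "cell_id": [c.cell_id for c in cells],
            "divides": [c.divides for c in cells],
            "division_time_h": [c.division_time_h for c in cells],
        })
        p = os.path.join(out_dir, "ground_truth.csv")
        gt.to_csv(p, index=False)
        paths["ground_truth"] = p
    if images is not None:
        arr = np.clip(images, 0, 65535).astype(np.uint16)
        for k, name in CHANNEL_FILES.items():
            if k >= arr.shape[1]:
                continue
            p = os.path.join(out_dir, name)
            tifffile.imwrite(p, arr[:, k])
            paths[name] = p
    return paths


def read_traces(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    return df


def read_ground_truth(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
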
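"""Per-frame quantification of KTR movies.

Illumination correction, classical nuclear segmentation, perinuclear-ring
("cytoring") construction, and the cytoplasm/nuclear (C/N) ratio measurement
that serves as the single-cell kinase-activity readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential, watershed

__all__ = [
    "CytoringParams",
    "CellMeasurement",
    "correct_illumination",
    "segment_nuclei",
    "build_cytoring",
    "measure_cells",
]


@dataclass
class CytoringParams:
    """Cytoring geometry: the ring extends `width_px` from the nuclear mask."""

    width_px: int = 10

    def __post_init__(self) -> None:
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")


@dataclass
class CellMeasurement:
    """Nuclear / ring mean intensity and C/N ratio for one label at one frame."""

    frame: int
    label: int
    nuc_mean: float
    ring_mean: float
    cn_ratio: float  # NaN when undefined (empty ring or non-positive nucleus)
    flags: frozenset[str] = field(default_factory=frozenset)


def correct_illumination(
    frames: np.ndarray,
    mode: str = "none",
    reference: np.ndarray | None = None,
    background_percentile: float = 50.0,
    smooth_sigma_px: float = 25.0,
) -> np.ndarray:
    """Flatfield-divide or background-subtract an image series.

    ``divide_flatfield`` divides every frame by a unit-mean smooth field:
    the supplied ``reference`` if given, otherwise the heavily smoothed
    temporal median frame. ``subtract_background`` subtracts, per frame, a
    robust background estimate — the ``background_percentile`` (default:
    median) of the non-cell pixels, i.e. those below the frame's Otsu
    threshold — clipping at zero. ``none`` is the identity.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty (T, H, W) series")
    if mode == "none":
        return frames.copy()
    if mode == "divide_flatfield":
        if reference is not None:
            ref = np.asarray(reference, dtype=float)
            if ref.shape != frames.shape[1:]:
                raise ValueError("reference shape does not match frames")
            if np.any(ref <= 0):
                raise ValueError("flatfield reference contains non-positive pixels")
        else:
            ref = ndi.gaussian_filter(np.median(frames, axis=0), smooth_sigma_px)
            if np.any(ref <= 0):
                raise ValueError("estimated flatfield contains non-positive pixels")
        ref = ref / ref.mean()
        return frames / ref[None]
    if mode == "subtract_background":
        bg = np.empty(frames.shape[0])
        for t, fr in enumerate(frames):
            if np.ptp(fr) == 0:
                bg[t] = fr.flat[0]
            else:
                noncell = fr[fr < threshold_otsu(fr)]
                bg[t] = np.percentile(noncell if noncell.size else fr,
                                      background_percentile)
        return np.clip(frames - bg[:, None, None], 0.0, None)
    raise ValueError(f"unknown mode {mode!r}")


def segment_nuclei(
    nuclear_frame: np.ndarray,
    threshold_method: str = "otsu",
    min_area_px: int = 30,
    max_area_px: int = 10_000,
    split_touching: bool = True,
    min_peak_distance_px: int = 7,
) -> np.ndarray:
    """Classical nuclear segmentation: threshold, fill, watershed-split, sieve.

    A deliberately simple stand-in for trained pixel classifiers; the rest
    of the pipeline accepts externally produced label masks, so better
    segmentations can be dropped in unchanged.
    """
    img = np.asarray(nuclear_frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclear_frame must be a single 2-D channel")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    if threshold_method == "otsu":
        thr = threshold_otsu(img)
    elif threshold_method == "mean":
        thr = img.mean()
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    binary = ndi.binary_fill_holes(img > thr)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)
    if split_touching:
        dist = ndi.distance_transform_edt(binary)
        blobs = cc_label(binary)
        peaks = peak_local_max(
            dist, labels=blobs, min_distance=min_peak_distance_px,
            exclude_border=False)
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-dist, markers, mask=binary)
    else:
        labels = cc_label(binary)
    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < min_area_px) | (areas > max_area_px))
    labels[np.isin(labels, bad[bad > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def build_cytoring(mask: np.ndarray, params: CytoringParams | None = None) -> np.ndarray:
    """Perinuclear ring labels: all pixels within `width_px` (Euclidean) of a
    nucleus, excluding every nuclear pixel, each assigned to its nearest
    nucleus (ties broken toward the lower label).

    Exact: per label, the Euclidean distance transform is evaluated on the
    label's padded bounding box (which contains every pixel that can lie
    within range), and the global nearest-label assignment is assembled by
    ascending label with a strict-less update, which realises the
    lower-label tie break.
    """
    params = params or CytoringParams()
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    rings = np.zeros(mask.shape, dtype=np.int32)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return rings
    w = params.width_px
    best = np.full(mask.shape, np.inf)
    slices = ndi.find_objects(mask)
    for lab in labels:
        sl = slices[lab - 1]
        r0 = max(sl[0].start - w - 1, 0)
        r1 = min(sl[0].stop + w + 1, mask.shape[0])
        c0 = max(sl[1].start - w - 1, 0)
        c1 = min(sl[1].stop + w + 1, mask.shape[1])
        win = (slice(r0, r1), slice(c0, c1))
        dist = ndi.distance_transform_edt(mask[win] != lab)
        upd = (dist <= w) & (dist < best[win])
        best[win][upd] = dist[upd]
        sub = rings[win]
        sub[upd] = lab
        rings[win] = sub
    rings[mask > 0] = 0
    return rings


def measure_cells(
    ktr_frame: np.ndarray,
    nuclei: np.ndarray,
    rings: np.ndarray,
    frame_idx: int = 0,
) -> list[CellMeasurement]:
    """Per-label compartment means and C/N ratio.

    Labels whose ring is empty (e.g. fully clipped at the border) or whose
    nuclear mean is non-positive get ``cn_ratio = NaN`` plus a flag rather
    than being dropped.
    """
    frame = np.asarray(ktr_frame, dtype=float)
    if frame.shape != nuclei.shape or frame.shape != rings.shape:
        raise ValueError("frame and masks must share a shape")
    out: list[CellMeasurement] = []
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    if labels.size == 0:
        return out
    nuc_means = ndi.mean(frame, labels=nuclei, index=labels)
    ring_counts = np.bincount(rings.ravel(), minlength=int(labels.max()) + 1)
    for lab, nm in zip(labels, np.atleast_1d(nuc_means)):
        flags: set[str] = set()
        if ring_counts[lab] > 0:
            rm = float(ndi.mean(frame, labels=rings, index=lab))
        else:
            rm = float("nan")
            flags.add("EMPTY_RING")
        if nm <= 0:
            flags.add("NONPOSITIVE_NUCLEUS")
        cn = rm / nm if not flags else float("nan")
        out.append(CellMeasurement(
            frame=frame_idx, label=int(lab), nuc_mean=float(nm),
            ring_mean=rm, cn_ratio=float(cn), flags=frozenset(flags)))
    return out
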
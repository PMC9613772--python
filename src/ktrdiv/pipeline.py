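"""End-to-end orchestration: movie -> measurements -> tracks -> fates -> stats.

Each stage is a thin composition of the module functions so that any stage
can be swapped (external masks, external trackers, pre-quantified traces).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import division as dv
from . import imaging as im
from . import stats as st
from . import tracking as tr

__all__ = [
    "quantify_movie",
    "analyze_traces",
    "analyze_movie",
    "features_from_traces",
    "TraceAnalysis",
]

KTR_CHANNELS = {"erk": 1, "akt": 2}


def quantify_movie(
    movie: np.ndarray,
    ring_width_px: int = 10,
    nuclear_channel: int = 0,
    illumination_mode: str | tuple[str, ...] = "none",
    flatfield_reference: np.ndarray | None = None,
    segment_kwargs: dict | None = None,
    masks: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Quantify a (frames, channels, H, W) movie into per-cell measurements.

    Returns the nuclear label-mask series and a long measurement table
    (frame, label, channel, nuc_mean, ring_mean, cn_ratio, flags).
    Externally produced ``masks`` (e.g. from a trained segmenter) bypass
    the built-in classical segmentation.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 4:
        raise ValueError("movie must be (frames, channels, rows, cols)")
    n_frames = movie.shape[0]
    modes = ((illumination_mode,) if isinstance(illumination_mode, str)
             else tuple(illumination_mode))
    chans = []
    for c in range(movie.shape[1]):
        frames = movie[:, c]
        for mode in modes:
            frames = im.correct_illumination(frames, mode=mode,
                                             reference=flatfield_reference)
        chans.append(frames)
    corrected = np.stack(chans, axis=1)
    seg_kwargs = segment_kwargs or {}
    params = im.CytoringParams(width_px=ring_width_px)
    mask_list, rows = [], []
    for f in range(n_frames):
        labels = (np.asarray(masks[f]) if masks is not None
                  else im.segment_nuclei(corrected[f, nuclear_channel],
                                         **seg_kwargs))
        mask_list.append(labels)
        rings = im.build_cytoring(labels, params)
        for ch, cidx in KTR_CHANNELS.items():
            if cidx >= movie.shape[1]:
                continue
            for m in im.measure_cells(corrected[f, cidx], labels, rings,
                                      frame_idx=f):
                rows.append({"frame": f, "label": m.label, "channel": ch,
                             "nuc_mean": m.nuc_mean, "ring_mean": m.ring_mean,
                             "cn_ratio": m.cn_ratio,
                             "flags": ";".join(sorted(m.flags))})
    meas = pd.DataFrame(rows, columns=["frame", "label", "channel", "nuc_mean",
                                       "ring_mean", "cn_ratio", "flags"])
    return np.stack(mask_list), meas


def tracks_with_measurements(
    masks: np.ndarray, measurements: pd.DataFrame, max_disp_px: float = 25.0,
) -> list[tr.CellTrack]:
    """Link masks into tracks and attach each channel's C/N series."""
    tracks = tr.link_tracks(masks, max_disp_px=max_disp_px)
    lut = {(int(r.frame), int(r.label), r.channel): r.cn_ratio
           for r in measurements.itertuples()}
    channels = sorted(measurements["channel"].unique())
    for t in tracks:
        for ch in channels:
            t.measurements[ch] = [lut.get((f, lab, ch), np.nan)
                                  for f, lab, _ in t.frames]
    return tracks


def _trace_matrix(traces: pd.DataFrame, channel: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sub = traces[traces["channel"] == channel]
    piv = sub.pivot_table(index="cell_id", columns="frame", values="cn_ratio")
    times = (sub.drop_duplicates("frame").sort_values("frame")["time_h"]
             .to_numpy())
    return piv.index.to_numpy(), piv.to_numpy(), times


@dataclass
class TraceAnalysis:
    """Full statistical report for one set of per-cell C/N traces."""

    fates: pd.DataFrame
    features: pd.DataFrame
    ranksum: dict[str, st.RankSumResult]
    logit: st.LogitFit | None
    correlations: dict[str, st.CorrelationResult]
    calls: dict[int, dv.DivisionCall | None] = field(default_factory=dict)

    def to_report(self) -> dict:
        rep = {
            "n_dividing": int((self.fates["fate"] == "dividing").sum()),
            "n_nondividing": int((self.fates["fate"] == "non-dividing").sum()),
            "n_excluded": int((self.fates["fate"] == "excluded").sum()),
            "ranksum": {ch: {"W": r.statistic, "p": r.p_value,
                             "n_div": r.n_x, "n_nondiv": r.n_y}
                        for ch, r in self.ranksum.items()},
            "correlations": {k: {"r": c.r, "n_points": c.n_points,
                                 "band": c.band}
                             for k, c in self.correlations.items()},
        }
        if self.logit is not None:
            rep["logit"] = {"params": self.logit.params,
                            "pvalues": self.logit.pvalues,
                            "converged": self.logit.converged}
        return rep


def features_from_traces(
    traces: pd.DataFrame,
    sampling_interval_h: float,
    detect: dv.DetectParams | None = None,
    fate: dv.FateConfig | None = None,
    window: st.WindowSpec | None = None,
    min_points: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[int, dv.DivisionCall | None]]:
    """Detect divisions, classify fates and compute windowed medians.

    ``traces`` is the long table (cell_id, frame, time_h, channel,
    cn_ratio). Division detection runs on the configured detection channel;
    all channels of a dividing cell are truncated at the same point.
    Returns (fates, features, calls).
    """
    detect = detect or dv.DetectParams()
    fate = fate or dv.FateConfig(sampling_interval_h=sampling_interval_h)
    window = window or st.WindowSpec()
    channels = sorted(traces["channel"].unique())
    det_ch = detect.detection_channel if detect.detection_channel in channels \
        else channels[0]

    ids, det_mat, times = _trace_matrix(traces, det_ch)
    n_frames_total = det_mat.shape[1]

    calls: dict[int, dv.DivisionCall | None] = {}

    class _T:  # minimal track shim for classify_fates
        def __init__(self, tid, n):
            self.track_id = tid
            self.start_frame = 0
            self.end_frame = n - 1

    shims = []
    for i, cid in enumerate(ids):
        row = det_mat[i]
        valid = np.flatnonzero(np.isfinite(row))
        n_obs = 0 if valid.size == 0 else valid[-1] + 1
        shims.append(_T(int(cid), n_obs))
        if n_obs >= detect.truncate_offset_frames + 2:
            filled = row[:n_obs].copy()
            if np.any(~np.isfinite(filled)):
                filled[~np.isfinite(filled)] = np.nanmean(row)
            calls[int(cid)] = dv.detect_division(filled, detect,
                                                 track_id=int(cid))
        else:
            calls[int(cid)] = None
    fates = dv.classify_fates(shims, calls, fate, n_frames_total)
    fates_df = pd.DataFrame([{
        "cell_id": r.track_id, "fate": r.fate, "reason": r.reason,
        "qc_flags": ";".join(sorted(r.qc_flags))} for r in fates])

    mats = {ch: _trace_matrix(traces, ch) for ch in channels}
    feat_rows = []
    for rec in fates:
        cid = rec.track_id
        row = {"cell_id": cid, "divided": rec.fate == "dividing"}
        call = calls.get(cid)
        for ch in channels:
            ids_ch, mat, t_ch = mats[ch]
            pos = np.flatnonzero(ids_ch == cid)
            if pos.size == 0:
                row[f"median_{ch}"] = np.nan
                continue
            trace = mat[pos[0]]
            if rec.fate == "dividing" and call is not None:
                trace = dv.truncate_trace(trace, call, detect)
            med = st.window_median(trace, t_ch, window, min_points=min_points)
            row[f"median_{ch}"] = np.nan if med is None else med
        feat_rows.append(row)
    features = pd.DataFrame(feat_rows)
    return fates_df, features, calls


def analyze_traces(
    traces: pd.DataFrame,
    sampling_interval_h: float = 0.25,
    detect: dv.DetectParams | None = None,
    fate: dv.FateConfig | None = None,
    window: st.WindowSpec | None = None,
    null_band_seed: int | None = None,
    null_band_reps: int = 1000,
) -> TraceAnalysis:
    """The full statistical analysis on pre-quantified traces.

    Fate classification, per-channel rank-sum of windowed medians
    (dividing vs non-dividing), bivariate logistic regression (when both
    channels are present), and pooled per-class ERK-Akt correlation with
    optional MVN resampling bands.
    """
    detect = detect or dv.DetectParams()
    window = window or st.WindowSpec()
    fates_df, features, calls = features_from_traces(
        traces, sampling_interval_h, detect, fate, window)
    channels = sorted(traces["channel"].unique())

    ranksum = {}
    for ch in channels:
        col = f"median_{ch}"
        div = features.loc[features["divided"], col].dropna()
        keep = fates_df.set_index("cell_id")["fate"]
        nondiv_ids = keep[keep == "non-dividing"].index
        nd = features.set_index("cell_id").loc[
            features.set_index("cell_id").index.intersection(nondiv_ids), col
        ].dropna()
        if len(div) and len(nd):
            ranksum[ch] = st.ranksum_right(div.to_numpy(), nd.to_numpy())

    logit = None
    if {"median_erk", "median_akt"} <= set(features.columns):
        analyzable = features[features["cell_id"].isin(
            fates_df.loc[fates_df["fate"] != "excluded", "cell_id"])]
        sub = analyzable.dropna(subset=["median_erk", "median_akt"])
        if sub["divided"].nunique() == 2:
            logit = st.fit_division_logit(sub)

    correlations = {}
    if {"erk", "akt"} <= set(channels):
        pooled = _pooled_points(traces, fates_df, calls, detect, window,
                                sampling_interval_h)
        for cls, (ex, ax) in pooled.items():
            if ex.size >= 3:
                res = st.pooled_pearson(ex, ax, class_label=cls)
                if null_band_seed is not None:
                    pts = np.column_stack([ex, ax])
                    spec = st.CorrelationNullSpec(
                        mu=pts.mean(axis=0), cov=np.cov(pts.T),
                        reps=null_band_reps)
                    res.band = st.correlation_null_band(
                        spec, ex.size, seed=null_band_seed)
                correlations[cls] = res
    return TraceAnalysis(fates=fates_df, features=features, ranksum=ranksum,
                         logit=logit, correlations=correlations, calls=calls)


def _pooled_points(traces, fates_df, calls, detect, window,
                   sampling_interval_h):
    """Pooled in-window (ERK, Akt) pairs per fate class, honouring truncation."""
    fate_by_id = fates_df.set_index("cell_id")["fate"].to_dict()
    ids_e, mat_e, t = _trace_matrix(traces, "erk")
    ids_a, mat_a, _ = _trace_matrix(traces, "akt")
    pos_a = {cid: i for i, cid in enumerate(ids_a)}
    out = {"dividing": ([], []), "non-dividing": ([], [])}
    for i, cid in enumerate(ids_e):
        cls = fate_by_id.get(int(cid))
        if cls not in out or int(cid) not in pos_a:
            continue
        e = mat_e[i].copy()
        a = mat_a[pos_a[int(cid)]].copy()
        call = calls.get(int(cid))
        if cls == "dividing" and call is not None:
            stop = max(call.peak_frame - detect.truncate_offset_frames, 0)
            e, a = e[:stop], a[:stop]
        sel = window.contains(t[: e.size]) & np.isfinite(e) & np.isfinite(a[: e.size])
        out[cls][0].append(e[: sel.size][sel])
        out[cls][1].append(a[: sel.size][sel])
    return {cls: (np.concatenate(v[0]) if v[0] else np.empty(0),
                  np.concatenate(v[1]) if v[1] else np.empty(0))
            for cls, v in out.items()}


def analyze_movie(
    movie: np.ndarray,
    sampling_interval_h: float = 0.25,
    ring_width_px: int = 10,
    max_disp_px: float = 25.0,
    illumination_mode: str = "none",
    detect: dv.DetectParams | None = None,
    **analyze_kwargs,
) -> TraceAnalysis:
    """Movie in, statistics out: quantify, track, filter, analyze."""
    masks, meas = quantify_movie(movie, ring_width_px=ring_width_px,
                                 illumination_mode=illumination_mode)
    tracks = tracks_with_measurements(masks, meas, max_disp_px=max_disp_px)
    n_frames = movie.shape[0]
    kept, _ = tr.filter_full_duration(tracks, n_frames)
    rows = []
    for t in kept:
        for ch, series in t.measurements.items():
            for (f, _, _), cn in zip(t.frames, series):
                rows.append({"cell_id": t.track_id, "frame": f,
                             "time_h": f * sampling_interval_h,
                             "channel": ch, "cn_ratio": cn})
    traces = pd.DataFrame(rows)
    return analyze_traces(traces, sampling_interval_h, detect=detect,
                          **analyze_kwargs)
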
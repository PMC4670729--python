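"""Single-cell lineage analysis: generations, elongation rates, recovery.

Mother-machine length tracks are segmented into generations at division
events, recognized as abrupt length drops (a cell roughly halves at
division, so a frame-to-frame length ratio below ``drop_fraction`` marks a
division even under ~10% measurement noise). Per-generation elongation
rates are log-linear OLS slopes, pooled into a time-binned population curve
whose weights are the number of frames a generation contributes to a bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import GenerationSegment, LengthTrack, PopulationGrowthCurve

__all__ = [
    "segment_generations", "fit_elongation_rate", "population_growth_curve",
    "detect_arrest_and_recovery",
]

DEFAULT_DROP_FRACTION = 0.7


def segment_generations(
    track: LengthTrack, drop_fraction: float = DEFAULT_DROP_FRACTION
) -> list[GenerationSegment]:
    """Split a track into generations at length drops below ``drop_fraction``.

    First and last segments are marked censored (birth/division not
    observed). A track with no division yields one censored segment.
    """
    if len(track.times) < 6:
        raise ValueError("need at least 6 frames to segment a track")
    ratio = track.lengths[1:] / track.lengths[:-1]
    div_after = np.nonzero(ratio < drop_fraction)[0]   # division between k, k+1
    edges = [0] + [int(k) + 1 for k in div_after] + [len(track.times)]
    segments = []
    for s, (a, b) in enumerate(zip(edges, edges[1:])):
        frames = np.arange(a, b)
        if len(frames) < 3:
            continue
        first = s == 0
        last = s == len(edges) - 2
        division_time = None if last else float(track.times[b - 1])
        seg = GenerationSegment(
            cell_id=track.cell_id,
            birth_time=float(track.times[a]),
            division_time=division_time,
            frames=frames,
            censored=first or last,
        )
        seg.rate, seg.r_squared = fit_elongation_rate(seg, track)
        segments.append(seg)
    return segments


def fit_elongation_rate(segment: GenerationSegment, track: LengthTrack):
    """OLS slope of ln(length) vs time within the segment; (rate, R^2)."""
    if len(segment.frames) < 3:
        raise ValueError("need at least 3 frames to fit an elongation rate")
    t = track.times[segment.frames]
    y = np.log(track.lengths[segment.frames])
    tbar, ybar = t.mean(), y.mean()
    sxx = np.sum((t - tbar) ** 2)
    slope = float(np.sum((t - tbar) * (y - ybar)) / sxx)
    resid = y - (ybar + slope * (t - tbar))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return slope, r2


def population_growth_curve(
    segments_with_tracks,
    bin_width: float = 30.0,
    include_censored: bool = True,
) -> PopulationGrowthCurve:
    """Frames-weighted mean elongation rate per time bin.

    ``segments_with_tracks`` is an iterable of (segment, track) pairs. Each
    generation's rate is assigned to every bin its frames overlap, weighted
    by the number of frames inside the bin; the SD uses the same weights.
    Empty bins are omitted. Censored generations are included by default so
    that filamenting (never-dividing) cells still contribute; pass
    ``include_censored=False`` for unbiased per-generation statistics.
    """
    rows = []
    for seg, track in segments_with_tracks:
        if not include_censored and seg.censored:
            continue
        if not np.isfinite(seg.rate):
            continue
        for t in track.times[seg.frames]:
            rows.append((t, seg.rate, seg.cell_id))
    if not rows:
        raise ValueError("no usable segments")
    df = pd.DataFrame(rows, columns=["t", "rate", "cell_id"])
    bin_idx = np.floor(df["t"].to_numpy() / bin_width).astype(int)
    df["bin"] = bin_idx
    centers, means, sds, ns = [], [], [], []
    for b, sub in df.groupby("bin"):
        w_rates = sub["rate"].to_numpy()
        mean = float(w_rates.mean())          # one row per frame = frame weight
        sd = float(w_rates.std(ddof=0))
        centers.append((b + 0.5) * bin_width)
        means.append(mean)
        sds.append(sd)
        ns.append(int(sub["cell_id"].nunique()))
    return PopulationGrowthCurve(
        bin_centers=np.asarray(centers), mean_rates=np.asarray(means),
        sd_rates=np.asarray(sds), n_cells=np.asarray(ns),
        bin_width=bin_width,
    )


def detect_arrest_and_recovery(
    curve: PopulationGrowthCurve,
    removal_time: float,
    readdition_time: float,
    fraction: float = 0.9,
) -> dict:
    """Lags from inducer removal to growth decline and re-addition to recovery.

    The pre-removal mean rate is the reference; ``lag_to_decline`` is the
    first bin center after removal whose mean falls below ``fraction`` of it,
    ``lag_to_recovery`` the first bin center after re-addition back above
    that fraction. Lags are measured from the respective schedule event.
    """
    t = curve.bin_centers
    if removal_time <= t[0] or readdition_time >= t[-1]:
        raise ValueError("schedule events outside the curve range")
    pre = curve.mean_rates[t < removal_time]
    if len(pre) == 0:
        raise ValueError("no bins before the removal event")
    ref = float(pre.mean())
    after_rm = (t > removal_time) & (curve.mean_rates < fraction * ref)
    after_add = (t > readdition_time) & (curve.mean_rates > fraction * ref)
    lag_decline = (
        float(t[np.argmax(after_rm)] - removal_time) if after_rm.any() else None
    )
    lag_recovery = (
        float(t[np.argmax(after_add)] - readdition_time)
        if after_add.any() else None
    )
    return {
        "lag_to_decline": lag_decline,
        "lag_to_recovery": lag_recovery,
        "reference_rate": ref,
    }
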
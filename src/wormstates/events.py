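"""Detectors for pharyngeal pumping, defecation, and egg-laying.

All three consume the extracted :class:`~wormstates.record.BehaviorRecord`
geometry rather than raw pixels, so they are invariant to uniform image
brightness scaling; the single exception is the grinder locator, which
works on the contrast-normalized intensity profile along the centerline.

Pumping: the grinder and the posterior end of the posterior bulb appear as
dark landmarks along the anterior body.  Their separation (the "grinder
distance") oscillates once per pump; pumps are counted as sufficiently deep
negative excursions of the bandpassed distance.

Defecation: the defecation motor program contracts the body twice, ~3.5 s
apart.  A matched filter with a two-Gaussian kernel picks these paired dips
out of the proportional body-length fluctuation.

Egg-laying: an egg appearing at the vulva widens the body profile abruptly
on the ventral side; candidate frames satisfy four geometric criteria and
are then confirmed against ground truth (tests) or an operator review file
(real recordings), a programmatic stand-in for manual verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, find_peaks, sosfiltfilt

from .record import BehaviorRecord, EventTrain


@dataclass(frozen=True)
class DetectorParams:
    """Tunable constants of the three event detectors (µm, s, px).

    The numeric defaults encode the detectors' operating points: length
    spikes beyond 30 µm over the rolling 90th percentile are tracking
    artifacts; grinder landmarks sit 8-17 µm apart; a pump excursion must
    dip 0.6 µm below the mean; the defecation kernel is two 0.9 s Gaussians
    3.5 s apart; an egg must widen a mid-body segment by >= 6 px within
    100 ms while the body length stays within 5%.
    """

    length_artifact_excess_um: float = 30.0
    length_percentile_window_s: float = 600.0
    grinder_min_um: float = 8.0
    grinder_max_um: float = 17.0
    pump_bandpass: tuple[float, float] = (0.2, 0.8)  # fraction of Nyquist
    pump_filter_order: int = 2
    pump_peak_depth_um: float = 0.6
    pump_min_separation_s: float = 0.05
    defecation_median_window_s: float = 50.0
    defecation_gauss_width_s: float = 0.9
    defecation_gauss_sep_s: float = 3.5
    defecation_threshold_mads: float = 5.0
    defecation_refractory_s: float = 10.0
    egg_width_jump_px: float = 6.0
    egg_jump_window_s: float = 0.1
    egg_length_change_frac: float = 0.05
    egg_segments: tuple[int, int] = (15, 20)  # 1-based, inclusive
    egg_diff_filter_s: float = 0.25
    egg_region_weights: tuple[float, float, float] = (1.0, 2.0, 1.0)
    egg_filter_threshold_px: float = 2.5
    vulva_position: float = 0.55

    def __post_init__(self) -> None:
        if not 0 < self.grinder_min_um < self.grinder_max_um:
            raise ValueError("grinder bounds must satisfy 0 < min < max")


@dataclass
class GrinderTrace:
    """Per-frame grinder separation (µm); NaN where the landmarks were not found."""

    times: np.ndarray
    distance: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distance, dtype=float)
        defined = d[np.isfinite(d)]
        if defined.size and (defined.min() <= 0 or defined.max() >= 30):
            raise ValueError("grinder distances must lie in (0, 30) µm where defined")


# ---------------------------------------------------------------------------
# pumping


def exclude_length_artifacts(
    lengths_um: np.ndarray, frame_rate: float, params: DetectorParams | None = None
) -> np.ndarray:
    """Validity mask: False where the length spikes above the rolling 90th
    percentile of the surrounding 10 min by at least 30 µm (eggs touching
    the nose or tail inflate the apparent body length)."""
    params = params or DetectorParams()
    lengths = np.asarray(lengths_um, dtype=float)
    if lengths.size == 0:
        raise ValueError("empty length series")
    window = max(3, int(round(params.length_percentile_window_s * frame_rate)))
    p90 = (
        pd.Series(lengths)
        .rolling(window, center=True, min_periods=1)
        .quantile(0.9)
        .to_numpy()
    )
    return ~(lengths > p90 + params.length_artifact_excess_um)


def locate_grinder(
    intensity_profile: np.ndarray,
    worm_length_um: float,
    params: DetectorParams | None = None,
) -> float:
    """Grinder separation (µm) from one frame's centerline intensity profile.

    The profile (head at index 0) is spline-upsampled to ~0.2 µm
    resolution over the first quarter of the body; among the four darkest
    local minima, a pair 8-17 µm apart is the grinder plus the posterior
    end of the posterior bulb.  Returns NaN when no qualifying pair exists.
    """
    params = params or DetectorParams()
    profile = np.asarray(intensity_profile, dtype=float)
    n = profile.size
    if n < 8:  # profile too coarse to resolve landmarks
        return np.nan
    quarter = max(4, int(np.ceil(n / 4)))
    seg = profile[:quarter]
    seg_len_um = worm_length_um * (quarter - 1) / (n - 1)
    m = max(quarter, int(round(seg_len_um / 0.2)) + 1)
    x = np.linspace(0.0, seg_len_um, quarter)
    xs = np.linspace(0.0, seg_len_um, m)
    fine = CubicSpline(x, seg)(xs)
    # prominence floor rejects interpolation ripple, not real landmarks
    span = np.ptp(fine)
    if span == 0:
        return np.nan
    minima, _ = find_peaks(-fine, prominence=0.02 * span)
    if minima.size < 2:
        return np.nan
    darkest = minima[np.argsort(fine[minima])[:4]]
    pos = xs[darkest]
    best = np.nan
    best_depth = np.inf
    for i in range(len(darkest)):
        for j in range(i + 1, len(darkest)):
            sep = abs(pos[i] - pos[j])
            if params.grinder_min_um <= sep <= params.grinder_max_um:
                depth = fine[darkest[i]] + fine[darkest[j]]
                if depth < best_depth:
                    best, best_depth = sep, depth
    return float(best)


def grinder_trace(
    record: BehaviorRecord, params: DetectorParams | None = None
) -> GrinderTrace:
    """Grinder separation per frame, on length-artifact-free valid frames."""
    params = params or DetectorParams()
    ok = exclude_length_artifacts(record.worm_length, record.frame_rate, params)
    ok &= record.valid_posture
    dist = np.full(record.n_frames, np.nan)
    for i in np.flatnonzero(ok):
        dist[i] = locate_grinder(
            record.centerline_intensity[i], record.worm_length[i], params
        )
    return GrinderTrace(times=record.timestamps, distance=dist)


def count_pumps(
    trace: GrinderTrace, frame_rate: float, params: DetectorParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pump event times plus a per-frame pump-rate series (Hz; NaN where the
    grinder distance is missing).

    Each contiguous defined stretch is zero-phase bandpass filtered
    (2nd-order Butterworth, 0.2-0.8 of Nyquist) and negative excursions
    deeper than 0.6 µm below zero are counted, at most one per 50 ms.
    Stretches shorter than 1 s (the filter warm-up) are skipped.
    """
    params = params or DetectorParams()
    d = np.asarray(trace.distance, dtype=float)
    defined = np.isfinite(d)
    sos = butter(
        params.pump_filter_order, params.pump_bandpass, btype="bandpass", output="sos"
    )
    min_len = int(np.ceil(frame_rate))
    event_times: list[float] = []
    rate = np.full(d.size, np.nan)
    idx = np.flatnonzero(defined)
    if idx.size:
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for stretch in np.split(idx, splits):
            if stretch.size < max(min_len, 15):
                continue
            filt = sosfiltfilt(sos, d[stretch])
            peaks, _ = find_peaks(
                -filt,
                height=params.pump_peak_depth_um,
                distance=max(1, int(round(params.pump_min_separation_s * frame_rate))),
            )
            times = trace.times[stretch[peaks]]
            event_times.extend(times)
            # local rate over a 1-s centered window
            counts = np.zeros(stretch.size)
            counts[peaks] = 1.0
            kernel = np.ones(int(round(frame_rate)))
            local = np.convolve(counts, kernel, mode="same") / (kernel.size / frame_rate)
            rate[stretch] = local
    return np.asarray(sorted(event_times)), rate


# ---------------------------------------------------------------------------
# defecation


def defecation_kernel(frame_rate: float, params: DetectorParams) -> np.ndarray:
    """Zero-mean matched-filter kernel: two negative Gaussian lobes (the
    paired body-length contractions of the motor program)."""
    sep = params.defecation_gauss_sep_s
    width = params.defecation_gauss_width_s
    half = sep / 2 + 3 * width
    t = np.arange(-half, half + 1 / frame_rate, 1 / frame_rate)
    k = -np.exp(-0.5 * ((t + sep / 2) / width) ** 2) - np.exp(
        -0.5 * ((t - sep / 2) / width) ** 2
    )
    return k - k.mean()


def detect_defecation(
    lengths_um: np.ndarray,
    frame_rate: float,
    params: DetectorParams | None = None,
    timestamps: np.ndarray | None = None,
) -> np.ndarray:
    """Defecation event times from the body-length series.

    The proportional length fluctuation (length minus its 50-s moving
    median, divided by the median) is correlated with the two-Gaussian
    kernel; local maxima exceeding 5 robust SDs (MAD-scaled), separated by
    a 10-s refractory period, are events.  The peak is reported at the
    midpoint of the two lobes; the returned times are shifted to the first
    (leading) contraction.
    """
    params = params or DetectorParams()
    lengths = np.asarray(lengths_um, dtype=float)
    n = lengths.size
    if timestamps is None:
        timestamps = np.arange(n) / frame_rate
    if n < int(params.defecation_median_window_s * frame_rate):
        raise ValueError("need at least 50 s of data to detect defecation")
    window = int(round(params.defecation_median_window_s * frame_rate))
    med = pd.Series(lengths).rolling(window, center=True, min_periods=1).median()
    med = med.to_numpy()
    frac = (lengths - med) / med
    kernel = defecation_kernel(frame_rate, params)
    score = np.convolve(frac, kernel[::-1], mode="same")
    mad = np.median(np.abs(score - np.median(score))) * 1.4826
    if mad == 0:
        return np.asarray([])
    peaks, _ = find_peaks(
        score,
        height=params.defecation_threshold_mads * mad,
        distance=max(1, int(round(params.defecation_refractory_s * frame_rate))),
    )
    times = timestamps[peaks] - params.defecation_gauss_sep_s / 2
    inside = (times >= timestamps[0]) & (times <= timestamps[-1])
    # snap to the nearest frame timestamp
    snapped = timestamps[
        np.clip(
            np.searchsorted(timestamps, times[inside]), 0, n - 1
        )
    ]
    return snapped


# ---------------------------------------------------------------------------
# egg-laying


def _region_filter(
    widths: np.ndarray, frame_rate: float, params: DetectorParams
) -> np.ndarray:
    """Vulva-tuned width filter: differenced mean width of the anterior,
    vulval, and posterior 5-segment regions, summed with weights 1, 2, 1."""
    n_seg = widths.shape[1]
    v = int(round(params.vulva_position * n_seg))
    vul = slice(max(0, v - 2), min(n_seg, v + 3))
    ant = slice(max(0, v - 7), max(0, v - 2))
    post = slice(min(n_seg, v + 3), min(n_seg, v + 8))
    lag = max(1, int(round(params.egg_diff_filter_s * frame_rate)))
    out = np.zeros(widths.shape[0])
    for w, sl in zip(params.egg_region_weights, (ant, vul, post)):
        region = widths[:, sl].mean(axis=1)
        diff = np.zeros_like(region)
        diff[lag:] = region[lag:] - region[:-lag]
        out += w * diff
    return out


def detect_egg_candidates(
    record: BehaviorRecord, params: DetectorParams | None = None
) -> dict[int, np.ndarray]:
    """Candidate egg-laying frames per side ``{0: left_frames, 1: right_frames}``.

    A frame qualifies on a side iff, within the 100 ms jump window, (1) the
    worm area does not decrease, (2) the length changes by <= 5%, (3) some
    width segment 15-20 on that side jumps by >= 6 px, and (4) the
    weighted region filter on that side crosses its threshold.
    """
    params = params or DetectorParams()
    fr = record.frame_rate
    jump = max(1, int(round(params.egg_jump_window_s * fr)))
    lo, hi = params.egg_segments
    n = record.n_frames
    out: dict[int, np.ndarray] = {}
    area = record.worm_area
    length = record.worm_length
    with np.errstate(invalid="ignore"):
        area_ok = np.zeros(n, dtype=bool)
        area_ok[jump:] = area[jump:] >= area[:-jump]
        len_ok = np.zeros(n, dtype=bool)
        len_ok[jump:] = (
            np.abs(length[jump:] - length[:-jump]) / length[:-jump]
            <= params.egg_length_change_frac
        )
    for side in (0, 1):
        widths = record.half_widths[:, side, :]
        seg = widths[:, lo - 1 : hi]
        jump_ok = np.zeros(n, dtype=bool)
        jump_ok[jump:] = (
            (seg[jump:] - seg[:-jump]) >= params.egg_width_jump_px
        ).any(axis=1)
        filt = _region_filter(widths, fr, params)
        filt_ok = filt > params.egg_filter_threshold_px
        good = area_ok & len_ok & jump_ok & filt_ok & record.valid_widths
        out[side] = np.flatnonzero(good)
    return out


def assign_ventral_side(
    candidates: dict[int, np.ndarray],
) -> tuple[str, np.ndarray]:
    """Label the side with more candidate events as ventral (eggs exit only
    through the ventral vulva) and drop dorsal candidates.  A tie yields
    ('unknown', both sides merged)."""
    n_left, n_right = len(candidates.get(0, ())), len(candidates.get(1, ()))
    if n_left == n_right:
        merged = np.union1d(
            np.asarray(candidates.get(0, []), int), np.asarray(candidates.get(1, []), int)
        )
        return "unknown", merged
    side = 0 if n_left > n_right else 1
    return ("left", "right")[side], np.asarray(candidates[side], dtype=int)


def merge_candidate_frames(frames: np.ndarray, frame_rate: float, gap_s: float = 1.0):
    """Collapse runs of nearby candidate frames into single events (the
    width bump persists for several frames after one laying event)."""
    frames = np.asarray(frames, dtype=int)
    if frames.size == 0:
        return []
    gap = max(1, int(round(gap_s * frame_rate)))
    groups = np.split(frames, np.flatnonzero(np.diff(frames) > gap) + 1)
    return [int(g[0]) for g in groups]


def review_events(
    candidate_frames: np.ndarray,
    record: BehaviorRecord,
    ground_truth: "object | None" = None,
    review_file: str | None = None,
    match_tolerance_s: float = 1.0,
) -> EventTrain:
    """Confirm candidate egg frames into an event train with per-event counts.

    Real recordings are reviewed by an operator CSV (columns frame_index,
    accept, egg_count); synthetic fixtures are confirmed against their
    ground truth.  Candidates resolved by neither source are rejected.
    """
    fr = record.frame_rate
    events = merge_candidate_frames(candidate_frames, fr)
    times, counts = [], []
    if review_file is not None:
        review = pd.read_csv(review_file).set_index("frame_index")
        bad = [f for f in review.index if f < 0 or f >= record.n_frames]
        if bad:
            raise ValueError(f"review file references unknown frames: {bad}")
        for f in events:
            near = review.index[np.abs(review.index - f) <= match_tolerance_s * fr]
            if len(near) and bool(review.loc[near[0], "accept"]):
                times.append(record.timestamps[f])
                counts.append(int(review.loc[near[0], "egg_count"]))
    elif ground_truth is not None:
        true_eggs = ground_truth.events["egg"]
        used = np.zeros(true_eggs.n_events, dtype=bool)
        for f in events:
            t = record.timestamps[f]
            dt = np.abs(true_eggs.times - t)
            dt[used] = np.inf
            j = int(np.argmin(dt)) if dt.size else -1
            if j >= 0 and dt[j] <= match_tolerance_s:
                used[j] = True
                times.append(true_eggs.times[j])
                counts.append(int(true_eggs.counts[j]))
    else:
        times = [record.timestamps[f] for f in events]
        counts = [1] * len(times)
    order = np.argsort(times)
    return EventTrain(
        "egg",
        np.asarray(times, dtype=float)[order],
        np.asarray(counts, dtype=int)[order] if times else None,
    )


def detect_events(
    record: BehaviorRecord,
    params: DetectorParams | None = None,
    ground_truth=None,
    review_file: str | None = None,
) -> tuple[dict[str, EventTrain], str]:
    """Run all three detectors on a record; returns event trains + ventral side."""
    params = params or DetectorParams()
    fr = record.frame_rate
    trace = grinder_trace(record, params)
    pump_times, _ = count_pumps(trace, fr, params)
    defec_times = detect_defecation(
        record.worm_length, fr, params, timestamps=record.timestamps
    )
    candidates = detect_egg_candidates(record, params)
    ventral, kept = assign_ventral_side(candidates)
    eggs = review_events(kept, record, ground_truth, review_file)
    return {
        "pump": EventTrain("pump", pump_times),
        "defecation": EventTrain("defecation", defec_times),
        "egg": eggs,
    }, ventral
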
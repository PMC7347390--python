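"""State-dependent behavioral quantification.

Covers the analyses layered on top of the extracted record and decoded
state path: eigenworm decomposition of posture, velocity-binned behavior
profiles, per-state behavior summaries, event-triggered averages,
state-dependent egg-laying rates with resampling tests, egg-dispersal
metrics (k-nearest-egg distance, grid occupancy), bend-phase estimation
with circular statistics, and correlates of an external scalar trace
(e.g. a neural activity signal) with body angles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .record import BehaviorRecord, EventTrain
from .states import StatePath


@dataclass
class EigenwormBasis:
    """Principal components of the mean-centered 14-angle posture matrix."""

    components: np.ndarray  # (n_components, 14), orthonormal rows
    explained_fraction: np.ndarray  # descending

    def project(self, postures: np.ndarray) -> np.ndarray:
        return np.asarray(postures) @ self.components.T


@dataclass
class VelocityBinnedProfile:
    bin_edges: np.ndarray  # mm/s
    statistic: np.ndarray  # per-bin median or mean rate
    dispersion: np.ndarray  # (n_bins, 2) percentiles or CI
    time_in_bin: np.ndarray  # seconds per bin
    excluded: np.ndarray = field(default=None)  # bool per bin, with reason in meta
    excluded_reason: str = ""


@dataclass
class PhaseProfile:
    """Bend phase (rad, [-pi, pi)) and bend depth per frame during forward waves."""

    phase: np.ndarray  # NaN outside forward runs / degenerate amplitude
    depth: np.ndarray  # SD of the 14 mean-centered body angles


# ---------------------------------------------------------------------------
# eigenworms


def eigenworm_pca(postures: np.ndarray, n_components: int = 4
                  ) -> tuple[EigenwormBasis, np.ndarray]:
    """PCA of the posture matrix; returns the basis and per-frame projections.

    On-food wild-type data concentrates the majority of postural variance
    in the top four components.  Rank-deficient input yields fewer
    components with a warning.
    """
    X = np.asarray(postures, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more frames than angle dimensions")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    k = min(n_components, rank)
    if k < n_components:
        import warnings

        warnings.warn(f"rank-deficient posture matrix: {k} components only")
    pca = PCA(n_components=X.shape[1]).fit(X)
    basis = EigenwormBasis(
        components=pca.components_[:k],
        explained_fraction=pca.explained_variance_ratio_[:k],
    )
    return basis, basis.project(X - X.mean(axis=0))


# ---------------------------------------------------------------------------
# binned / per-state summaries


def _event_rate_per_bin(
    event_times: np.ndarray,
    frame_values: np.ndarray,
    timestamps: np.ndarray,
    bin_edges: np.ndarray,
    frame_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Events/minute per bin of an instantaneous per-frame covariate."""
    n_bins = bin_edges.size - 1
    which = np.digitize(frame_values, bin_edges) - 1
    ok = (which >= 0) & (which < n_bins) & np.isfinite(frame_values)
    time_in_bin = np.bincount(which[ok], minlength=n_bins) / frame_rate
    ev_frames = np.searchsorted(timestamps, event_times)
    ev_frames = np.clip(ev_frames, 0, frame_values.size - 1)
    ev_bin = which[ev_frames]
    ev_ok = ok[ev_frames]
    counts = np.bincount(ev_bin[ev_ok], minlength=n_bins).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = counts / (time_in_bin / 60.0)
    rate[time_in_bin == 0] = np.nan
    return rate, time_in_bin


def velocity_binned_behavior(
    record: BehaviorRecord,
    velocity: np.ndarray,
    signals: dict[str, np.ndarray] | None = None,
    events: dict[str, EventTrain] | None = None,
    bin_edges: np.ndarray | None = None,
    shuffle_null: bool = False,
    seed: int = 0,
) -> dict[str, VelocityBinnedProfile]:
    """Behaviors separated into instantaneous-velocity bins.

    Continuous signals (angular velocity, pump rate, ...) are summarized
    by per-bin median and quartiles; event kinds by mean event rate
    (events/min of time in bin).  ``shuffle_null=True`` additionally
    returns rate profiles for time-shuffled events (flat under the null
    of velocity-independent event generation).
    """
    if bin_edges is None:
        bin_edges = np.arange(-0.25, 0.4501, 0.05)
    fr = record.frame_rate
    which = np.digitize(velocity, bin_edges) - 1
    n_bins = bin_edges.size - 1
    ok = (which >= 0) & (which < n_bins) & np.isfinite(velocity)
    time_in_bin = np.bincount(which[ok], minlength=n_bins) / fr
    out: dict[str, VelocityBinnedProfile] = {}
    rng = np.random.default_rng(seed)

    for name, sig in (signals or {}).items():
        med = np.full(n_bins, np.nan)
        disp = np.full((n_bins, 2), np.nan)
        for b in range(n_bins):
            vals = sig[ok & (which == b)]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                med[b] = np.median(vals)
                disp[b] = np.percentile(vals, [25, 75])
        out[name] = VelocityBinnedProfile(
            bin_edges=bin_edges, statistic=med, dispersion=disp,
            time_in_bin=time_in_bin, excluded=time_in_bin == 0,
            excluded_reason="no data in bin",
        )

    for kind, train in (events or {}).items():
        rate, tib = _event_rate_per_bin(
            train.times, velocity, record.timestamps, bin_edges, fr
        )
        out[kind] = VelocityBinnedProfile(
            bin_edges=bin_edges, statistic=rate,
            dispersion=np.full((n_bins, 2), np.nan), time_in_bin=tib,
            excluded=tib == 0, excluded_reason="no data in bin",
        )
        if shuffle_null:
            shuffled = rng.choice(
                record.timestamps[ok], size=train.n_events, replace=False
            )
            null_rate, _ = _event_rate_per_bin(
                np.sort(shuffled), velocity, record.timestamps, bin_edges, fr
            )
            out[f"{kind}_null"] = VelocityBinnedProfile(
                bin_edges=bin_edges, statistic=null_rate,
                dispersion=np.full((n_bins, 2), np.nan), time_in_bin=tib,
                excluded=tib == 0, excluded_reason="no data in bin",
            )
    return out


def reversal_runs(velocity: np.ndarray, frame_rate: float,
                  duration_threshold_s: float = 4.0) -> tuple[list, list]:
    """Maximal runs of negative body-axis velocity, split into short (<4 s)
    and long (>= 4 s) reversals; each run is (start_frame, end_frame)."""
    neg = np.asarray(velocity) < 0
    neg &= np.isfinite(velocity)
    short, long_ = [], []
    runs = []
    i = 0
    n = neg.size
    while i < n:
        if neg[i]:
            j = i
            while j < n and neg[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    for s, e in runs:
        (long_ if (e - s) / frame_rate >= duration_threshold_s else short).append((s, e))
    return short, long_


def state_behavior_summary(
    record: BehaviorRecord,
    velocity: np.ndarray,
    state_path: StatePath,
    bin_s: float = 3.0,
    events: dict[str, EventTrain] | None = None,
    pump_rate: np.ndarray | None = None,
) -> dict[int, dict[str, float]]:
    """Per-hidden-state behavior table.

    'average_motion' is the standard deviation of each of the 14 body
    angles over 2-s intervals, averaged over angles and intervals in the
    state — a measure of rapid postural change.  Reversals are maximal
    negative-velocity runs, classified short/long at 4 s.  Event rates
    are events per minute of state occupancy.
    """
    fr = record.frame_rate
    frames_per_bin = int(round(bin_s * fr))
    n = record.n_frames
    frame_state = np.full(n, -1, dtype=int)
    for b, s in enumerate(state_path.states):
        frame_state[b * frames_per_bin : (b + 1) * frames_per_bin] = s

    two_s = int(round(2.0 * fr))
    n_int = n // two_s
    motion = np.full(n_int, np.nan)
    int_state = np.full(n_int, -1)
    for k in range(n_int):
        sl = slice(k * two_s, (k + 1) * two_s)
        if record.valid_posture[sl].all():
            motion[k] = record.posture[sl].std(axis=0).mean()
        vals, cnts = np.unique(frame_state[sl], return_counts=True)
        int_state[k] = vals[np.argmax(cnts)]

    short, long_ = reversal_runs(velocity, fr)
    out: dict[int, dict[str, float]] = {}
    for s in sorted(set(state_path.states[state_path.states >= 0].tolist())):
        sel = frame_state == s
        minutes = sel.sum() / fr / 60.0
        if minutes == 0:
            continue
        row: dict[str, float] = {
            "label": state_path.labels.get(s, str(s)),
            "occupancy_min": minutes,
            "velocity_mean": float(np.nanmean(velocity[sel])),
            "velocity_median": float(np.nanmedian(velocity[sel])),
            "fraction_forward": float(np.nanmean(velocity[sel] > 0)),
            "average_motion": float(np.nanmean(motion[int_state == s])),
            "short_reversal_per_min": sum(frame_state[a] == s for a, _ in short)
            / minutes,
            "long_reversal_per_min": sum(frame_state[a] == s for a, _ in long_)
            / minutes,
        }
        if pump_rate is not None:
            row["pump_rate_hz"] = float(np.nanmean(pump_rate[sel]))
        for kind, train in (events or {}).items():
            ev_frames = np.clip(
                np.searchsorted(record.timestamps, train.times), 0, n - 1
            )
            weights = train.counts if train.counts is not None else None
            in_state = frame_state[ev_frames] == s
            count = (
                float(np.sum(np.asarray(weights)[in_state]))
                if weights is not None
                else float(in_state.sum())
            )
            row[f"{kind}_rate_per_min"] = count / minutes
        out[s] = row
    return out


def event_triggered_average(
    record: BehaviorRecord,
    signals: dict[str, np.ndarray],
    event_times: np.ndarray,
    window_s: float = 30.0,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Mean +/- SEM of each signal in a window around events.

    Events whose window is truncated by the recording edges are excluded.
    Returns ``{name: (lag_s, mean, sem)}``.
    """
    fr = record.frame_rate
    half = int(round(window_s * fr))
    frames = np.searchsorted(record.timestamps, np.asarray(event_times))
    frames = frames[(frames >= half) & (frames < record.n_frames - half)]
    if frames.size == 0:
        raise ValueError("no events with full window coverage")
    lag = np.arange(-half, half + 1) / fr
    out = {}
    for name, sig in signals.items():
        snips = np.stack([sig[f - half : f + half + 1] for f in frames])
        mean = np.nanmean(snips, axis=0)
        sem = np.nanstd(snips, axis=0, ddof=1) / np.sqrt(snips.shape[0])
        out[name] = (lag, mean, sem)
    return out


# ---------------------------------------------------------------------------
# state-dependent egg-laying


def egg_rate_by_state_and_velocity(
    records: list[BehaviorRecord],
    velocities: list[np.ndarray],
    egg_trains: list[EventTrain],
    state_paths: list[StatePath],
    bin_edges: np.ndarray | None = None,
    bin_s: float = 3.0,
    min_time_per_animal_s: float = 240.0,
    n_boot: int = 1000,
    n_perm: int = 5000,
    seed: int = 0,
) -> dict:
    """Egg-laying rate vs velocity, separately for roaming and dwelling.

    Per state x velocity bin: rate = eggs / time-in-bin pooled over
    animals; bins with less than 4 min of data per animal (on average) are
    excluded.  95% CIs come from bootstrapping animals; per-bin
    roaming-vs-dwelling differences are tested by permuting the state
    labels of egg events within the bin (Bonferroni-corrected across
    bins); a positive within-state velocity-rate association is tested by
    bootstrapping the slope.
    """
    if bin_edges is None:
        bin_edges = np.arange(-0.25, 0.4501, 0.05)
    rng = np.random.default_rng(seed)
    n_bins = bin_edges.size - 1
    n_animals = len(records)
    if n_animals == 1:
        import warnings

        warnings.warn("single animal: CIs bootstrap events, not animals")

    # per-animal per-state time and egg counts per bin
    time_a = np.zeros((n_animals, 2, n_bins))
    eggs_a = np.zeros((n_animals, 2, n_bins))
    egg_bin_records = []  # (animal, state_idx, bin) per egg event
    for a, (rec, vel, eggs, sp) in enumerate(
        zip(records, velocities, egg_trains, state_paths)
    ):
        fr = rec.frame_rate
        frames_per_bin = int(round(bin_s * fr))
        frame_state = np.full(rec.n_frames, -1, int)
        for b, s in enumerate(sp.states):
            frame_state[b * frames_per_bin : (b + 1) * frames_per_bin] = s
        roam_ids = [s for s, lab in sp.labels.items() if lab == "roam"]
        is_roam = np.isin(frame_state, roam_ids)
        which = np.digitize(vel, bin_edges) - 1
        ok = (which >= 0) & (which < n_bins) & np.isfinite(vel) & (frame_state >= 0)
        for st, sel_state in ((0, is_roam), (1, ~is_roam)):
            sel = ok & sel_state
            time_a[a, st] = np.bincount(which[sel], minlength=n_bins) / fr
        ev_frames = np.clip(np.searchsorted(rec.timestamps, eggs.times), 0, rec.n_frames - 1)
        counts = eggs.counts if eggs.counts is not None else np.ones(eggs.n_events, int)
        for f, c in zip(ev_frames, counts):
            if ok[f]:
                st = 0 if is_roam[f] else 1
                eggs_a[a, st, which[f]] += c
                egg_bin_records.append((a, st, which[f]))

    total_time = time_a.sum(axis=0)  # (2, n_bins) seconds
    total_eggs = eggs_a.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = total_eggs / (total_time / 60.0)
    excluded = (time_a.mean(axis=0) < min_time_per_animal_s)  # (2, n_bins)
    rate[excluded] = np.nan

    # bootstrap CI over animals
    boot = np.full((n_boot, 2, n_bins), np.nan)
    for i in range(n_boot):
        pick = rng.integers(n_animals, size=n_animals)
        t = time_a[pick].sum(axis=0)
        e = eggs_a[pick].sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot[i] = e / (t / 60.0)
    ci = np.nanpercentile(boot, [2.5, 97.5], axis=0)

    # per-bin permutation test: shuffle state labels of eggs within a bin,
    # holding each state's observation time fixed
    p_values = np.full(n_bins, np.nan)
    for b in range(n_bins):
        if excluded[:, b].any() or total_time[0, b] == 0 or total_time[1, b] == 0:
            continue
        n_r = int(total_eggs[0, b])
        n_d = int(total_eggs[1, b])
        n_tot = n_r + n_d
        if n_tot == 0:
            continue
        p_roam = total_time[0, b] / total_time[:, b].sum()
        obs = abs(
            n_r / (total_time[0, b] / 60) - n_d / (total_time[1, b] / 60)
        )
        draws = rng.binomial(n_tot, p_roam, size=n_perm)
        null = np.abs(
            draws / (total_time[0, b] / 60)
            - (n_tot - draws) / (total_time[1, b] / 60)
        )
        p_values[b] = (1 + np.sum(null >= obs)) / (n_perm + 1)
    n_tested = np.isfinite(p_values).sum()
    p_bonf = np.minimum(p_values * max(1, n_tested), 1.0)

    # within-state velocity-rate slope, bootstrap over animals
    slope_p = {}
    centers = (bin_edges[:-1] + bin_edges[1:]) / 2
    for st, name in ((0, "roam"), (1, "dwell")):
        sel = np.isfinite(rate[st])
        if sel.sum() < 3:
            continue
        slopes = []
        for i in range(n_boot):
            pick = rng.integers(n_animals, size=n_animals)
            t = time_a[pick, st].sum(axis=0)
            e = eggs_a[pick, st].sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = e / (t / 60.0)
            m = sel & np.isfinite(r) & (t > 0)
            if m.sum() >= 3:
                slopes.append(np.polyfit(centers[m], r[m], 1)[0])
        slopes = np.asarray(slopes)
        slope_p[name] = float(np.mean(slopes <= 0)) if slopes.size else np.nan

    return {
        "bin_edges": bin_edges,
        "rate": rate,  # (2, n_bins): row 0 roaming, row 1 dwelling
        "ci": ci,
        "excluded": excluded,
        "p_bin": p_values,
        "p_bin_bonferroni": p_bonf,
        "slope_p_one_sided": slope_p,
    }


# ---------------------------------------------------------------------------
# egg dispersal


def knn_egg_distance(egg_positions: np.ndarray, k_range=range(1, 11)
                     ) -> dict[int, float]:
    """Mean distance from each egg to its k nearest other eggs, per k.

    Invariant under rigid motions of the egg set.  k is truncated (with a
    warning) when fewer than k+1 eggs exist.
    """
    pos = np.atleast_2d(np.asarray(egg_positions, float))
    n = pos.shape[0]
    if n < 2:
        raise ValueError("need at least 2 eggs")
    from scipy.spatial.distance import squareform, pdist

    d = squareform(pdist(pos))
    np.fill_diagonal(d, np.inf)
    d.sort(axis=1)
    out = {}
    for k in k_range:
        if k > n - 1:
            import warnings

            warnings.warn(f"only {n-1} neighbors available; truncating k={k}")
            break
        out[k] = float(d[:, :k].mean())
    return out


def grid_dispersal(
    path: np.ndarray,
    egg_positions: np.ndarray,
    cell_size: float = 500.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Fraction of path-visited grid cells that contain at least one egg.

    A square grid (default 0.5 mm cells) is superimposed on the centroid
    trajectory; dispersal = |visited cells with >= 1 egg| / |visited
    cells|.  Eggs in never-visited cells are logged but do not count.
    Translation of the grid by whole cells leaves the result unchanged.
    """
    path = np.atleast_2d(np.asarray(path, float))
    if path.size == 0:
        raise ValueError("empty path")
    cells = set(map(tuple, np.floor((path - origin) / cell_size).astype(int)))
    eggs = np.atleast_2d(np.asarray(egg_positions, float))
    if eggs.size == 0:
        return 0.0
    egg_cells = set(map(tuple, np.floor((eggs - origin) / cell_size).astype(int)))
    stray = egg_cells - cells
    if stray:
        import logging

        logging.getLogger(__name__).info(
            "%d egg cell(s) outside the visited area", len(stray)
        )
    return len(egg_cells & cells) / len(cells)


# ---------------------------------------------------------------------------
# bend phase and circular statistics


def bend_phase(
    projections: np.ndarray,
    postures: np.ndarray,
    forward: np.ndarray | None = None,
    min_amplitude: float = 1e-3,
) -> PhaseProfile:
    """Phase of the forward-propagating bend from the two dominant
    eigenworm projections.

    Phase is the angle of (proj1, proj2); forward crawling traces a cycle
    in this plane, so phase advances through each undulation.  The sign
    convention is fixed so mean phase velocity is positive on forward
    frames.  Depth is the per-frame SD of the mean-centered body angles.
    Near-zero projection amplitude leaves phase undefined.
    """
    proj = np.asarray(projections, float)[:, :2]
    amp = np.linalg.norm(proj, axis=1)
    phase = np.arctan2(proj[:, 1], proj[:, 0])
    phase[amp < min_amplitude] = np.nan
    # orient so phase increases during forward locomotion
    dph = np.diff(np.unwrap(phase[np.isfinite(phase)]))
    if forward is not None:
        fsel = np.asarray(forward, bool)
        good = np.isfinite(phase)
        dph = np.diff(np.unwrap(phase[good & fsel])) if (good & fsel).sum() > 2 else dph
    if dph.size and np.nanmean(dph) < 0:
        phase = -phase
    if forward is not None:
        phase = np.where(np.asarray(forward, bool), phase, np.nan)
    phase = np.mod(phase + np.pi, 2 * np.pi) - np.pi
    depth = np.asarray(postures, float).std(axis=1)
    return PhaseProfile(phase=phase, depth=depth)


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh z test of circular non-uniformity: z = n R^2.

    Returns (z, p) with the standard small-sample corrected p
    approximation.
    """
    phases = np.asarray(phases, float)
    phases = phases[np.isfinite(phases)]
    n = phases.size
    if n == 0:
        raise ValueError("no phases")
    R = np.abs(np.exp(1j * phases).mean())
    z = n * R**2
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - (R * n) ** 2)) - (1 + 2 * n))
    return float(z), float(min(max(p, 0.0), 1.0))


def phase_event_histogram(
    event_times: np.ndarray,
    timestamps: np.ndarray,
    phase_profile: PhaseProfile,
    n_bins: int = 12,
) -> dict:
    """Histogram of event phases plus the Rayleigh test of phase locking."""
    frames = np.clip(
        np.searchsorted(timestamps, np.asarray(event_times)), 0, timestamps.size - 1
    )
    ph = phase_profile.phase[frames]
    ph = ph[np.isfinite(ph)]
    if ph.size == 0:
        raise ValueError("no events with defined phase")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    counts, _ = np.histogram(ph, bins=edges)
    z, p = rayleigh_test(ph)
    return {"bin_edges": edges, "counts": counts, "z": float(z), "p": float(p),
            "n": int(ph.size)}


# ---------------------------------------------------------------------------
# trace correlates


def trace_correlates(
    trace: np.ndarray,
    record: BehaviorRecord,
    speed: np.ndarray,
    speed_bin_edges: np.ndarray | None = None,
) -> dict:
    """Correlates of an external scalar trace with posture and locomotion.

    Returns the Pearson correlation of the trace with each of the 14 body
    angles (over valid frames) and the mean |time derivative| of the trace
    within speed bins.
    """
    trace = np.asarray(trace, float)
    if trace.size != record.n_frames:
        raise ValueError("trace must be time-aligned to the record")
    ok = record.valid_posture & np.isfinite(trace)
    if ok.sum() < 100:
        raise ValueError("fewer than 100 aligned valid frames")
    corr = np.array(
        [stats.pearsonr(trace[ok], record.posture[ok, i])[0] for i in range(14)]
    )
    fr = record.frame_rate
    deriv = np.abs(np.gradient(trace) * fr)
    if speed_bin_edges is None:
        speed_bin_edges = np.arange(0.0, 0.351, 0.05)
    n_bins = speed_bin_edges.size - 1
    which = np.digitize(speed, speed_bin_edges) - 1
    sel_ok = (which >= 0) & (which < n_bins) & np.isfinite(speed) & np.isfinite(deriv)
    binned = np.full(n_bins, np.nan)
    for b in range(n_bins):
        vals = deriv[sel_ok & (which == b)]
        if vals.size:
            binned[b] = vals.mean()
    return {
        "angle_correlations": corr,
        "speed_bin_edges": speed_bin_edges,
        "abs_derivative_by_speed": binned,
    }
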
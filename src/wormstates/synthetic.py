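"""Forward model: brightfield-like frames and ground-truth behavior records.

This module inverts the analysis stack.  It draws a hidden behavioral-state
sequence from a discrete-emission HMM, realizes frame-level postures,
locomotion, pharyngeal pumping, defecation contractions and egg-laying
events consistent with that state path, and can render the result as dark
worms on a light background so the full image pipeline can be exercised
without real video.  All generators are pure functions of (parameters,
seed).

The default :class:`GeneratorModel` encodes the structure the state
analyses assume: 9 hidden states over 8 posture-group emission symbols, one
of which is a high-velocity roaming state, with a roaming:dwelling
egg-laying rate ratio of 6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import pdist

from . import _splines
from .record import (
    AcquisitionConfig,
    BehaviorRecord,
    EventTrain,
    write_events_csv,
    write_frame_sequence,
)

#: 3-second coarsening bin used throughout the state analyses
COARSE_BIN_S = 3.0

N_GROUPS = 8
N_STATES = 9

# rendering intensities (8-bit)
_BG_LEVEL = 200
_WORM_LEVEL = 60
_GRINDER_LEVEL = 10
_EGG_LEVEL = 80


@dataclass(frozen=True)
class SceneSpec:
    """Physical parameters of a synthetic recording.

    Defaults describe a one-day-old adult on food: ~1 mm body length,
    pharyngeal grinder landmarks resting ~12 µm apart (anatomically bounded
    to 8–17 µm), continuous pumping near 4.5 Hz, a defecation motor program
    every ~45 s, and a vulva at 55% of body length from the head.
    """

    duration: float = 600.0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    worm_length_um: float = 1000.0
    width_profile: np.ndarray | None = None  # 30-element half-width template (px)
    grinder_separation_um: float = 12.0
    pump_rate_hz: float = 4.5
    pump_amplitude_um: float = 1.5
    defecation_period_s: float = 45.0
    defecation_depth: float = 0.02  # fractional length contraction per lobe
    egg_rate_by_state: np.ndarray | None = None  # events/min per hidden state
    vulva_position: float = 0.55
    noise_sd: float = 3.0
    intensity_samples: int = 501  # centerline-intensity resolution per frame

    def __post_init__(self) -> None:
        if not 8.0 <= self.grinder_separation_um <= 17.0:
            raise ValueError("grinder separation must lie in the 8-17 µm range")
        if not 0.0 < self.vulva_position < 1.0:
            raise ValueError("vulva position must be a body-length fraction in (0,1)")
        if self.width_profile is None:
            object.__setattr__(self, "width_profile", default_width_profile())
        if self.egg_rate_by_state is not None:
            rates = np.asarray(self.egg_rate_by_state, dtype=float)
            if np.any(rates < 0):
                raise ValueError("egg rates must be non-negative")
            object.__setattr__(self, "egg_rate_by_state", rates)


@dataclass
class GroundTruth:
    """Hidden truth behind a synthetic scene; the oracle for every detector."""

    state_path: np.ndarray  # hidden state id per 3-s bin
    posture_groups: np.ndarray  # group id per frame (0..7)
    postures: np.ndarray  # reference-posture id per frame
    events: dict[str, EventTrain]
    ventral_side: str
    roaming_state: int = 0


@dataclass
class GeneratorModel:
    """Generative behavioral model: HMM over posture groups + posture library."""

    transition: np.ndarray  # (n_states, n_states) row-stochastic
    emission: np.ndarray  # (n_states, n_groups) row-stochastic
    prototypes: np.ndarray  # (n_postures, 14) mean-centered angle vectors
    group_of_posture: np.ndarray  # (n_postures,) group id per reference posture
    roaming_state: int = 0
    egg_rate_ratio: float = 6.0
    posture_dwell_mean_s: float = 0.4
    roaming_speed_mm_s: float = 0.25
    dwelling_speed_mm_s: float = 0.03

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        _check_stochastic(self.transition, "transition")
        _check_stochastic(self.emission, "emission")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def n_groups(self) -> int:
        return self.emission.shape[1]

    def postures_in_group(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.group_of_posture == group)


def _check_stochastic(mat: np.ndarray, name: str) -> None:
    if mat.ndim != 2 or np.any(mat < 0) or not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError(f"{name} matrix must be row-stochastic")


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(transition.T)
    i = np.argmin(np.abs(vals - 1.0))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def default_width_profile(max_half_width_px: float = 22.0) -> np.ndarray:
    """Smooth half-width template (30 spline coefficients, px), tapering at both ends."""
    s = np.linspace(0.0, 1.0, 1001)
    w = max_half_width_px * np.sin(np.pi * np.clip(s, 0.02, 0.98)) ** 0.5
    return _splines.fit_coeffs(w, _splines.N_WIDTH_COEFFS)


def sinusoid_prototypes(n_prototypes: int, rng: np.random.Generator) -> np.ndarray:
    """Mean-centered 14-vectors of smooth bend waves spanning forward postures."""
    s = np.linspace(0.0, 1.0, 14)
    protos = np.empty((n_prototypes, 14))
    kernel = np.exp(-0.5 * (np.arange(-3, 4) / 1.2) ** 2)
    kernel /= np.sqrt((kernel**2).sum())  # unit-variance smooth noise
    for j in range(n_prototypes):
        amp = rng.uniform(0.25, 1.0)
        wavenumber = rng.uniform(1.0, 2.5)
        phase = rng.uniform(0.0, 2 * np.pi)
        amp2 = rng.uniform(0.0, 0.3)
        wave = amp * np.sin(2 * np.pi * wavenumber * s + phase) + amp2 * np.sin(
            2 * np.pi * 0.5 * s + rng.uniform(0, 2 * np.pi)
        )
        # smooth idiosyncratic component: keeps prototypes off the thin
        # sinusoid manifold so that distinct postures stay well separated
        rough = np.convolve(rng.normal(0.0, 1.0, 20), kernel, mode="same")[3:17]
        protos[j] = wave + 0.35 * rough
    return protos - protos.mean(axis=1, keepdims=True)


def default_generator_model(
    n_postures: int = 100, seed: int = 2024, **overrides
) -> GeneratorModel:
    """The 9-state / 8-group model used as the standard study condition.

    State 0 is roaming: fast, sticky, and postured on the stereotyped
    forward-wave repertoire (an even split over the first four posture
    groups — distinct from every dwelling sub-mode's concentrated
    repertoire, but broad enough that no single pair of groups is coupled
    by roaming alone).  States 1..8 are dwelling sub-modes, each
    concentrated on one posture group.  Stationary roaming occupancy is
    0.25.
    """
    transition = np.full((N_STATES, N_STATES), 0.0)
    transition[0, 0] = 0.97
    transition[0, 1:] = 0.03 / (N_STATES - 1)
    for s in range(1, N_STATES):
        transition[s, s] = 0.95
        transition[s, 0] = 0.01
        others = [j for j in range(1, N_STATES) if j != s]
        transition[s, others] = 0.04 / len(others)
    emission = np.empty((N_STATES, N_GROUPS))
    emission[0] = 0.02 / (N_GROUPS - 4)
    emission[0, :4] = 0.245
    for s in range(1, N_STATES):
        emission[s] = 0.15 / (N_GROUPS - 1)
        emission[s, s - 1] = 0.85
    rng = np.random.default_rng(seed)
    prototypes = sinusoid_prototypes(n_postures, rng)
    # posture groups are sets of geometrically similar postures (animals
    # oscillate among neighboring shapes), so group by posture similarity
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=N_GROUPS, n_init=10, random_state=seed).fit(prototypes)
    group_of_posture = km.labels_
    params = dict(
        transition=transition,
        emission=emission,
        prototypes=prototypes,
        group_of_posture=group_of_posture,
    )
    params.update(overrides)
    return GeneratorModel(**params)


def default_egg_rates(
    model: GeneratorModel, dwelling_rate_per_min: float = 1.0 / 12.0
) -> np.ndarray:
    """Per-state egg rates (events/min) realizing the model's roaming:dwelling ratio.

    The dwelling rate default (0.083/min) together with 25% roaming
    occupancy yields ~65 eggs over six hours, at the top of the typical
    20-70 events observed per overnight dataset.
    """
    rates = np.full(model.n_states, dwelling_rate_per_min)
    rates[model.roaming_state] = dwelling_rate_per_min * model.egg_rate_ratio
    return rates


# ---------------------------------------------------------------------------
# state / record generation


def generate_state_sequence(
    model: GeneratorModel,
    n_bins: int,
    seed: int,
    start_state: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a hidden-state path and its emitted posture-group symbols.

    Returns ``(states, symbols)`` of length ``n_bins`` (one entry per 3-s
    bin).  The start state defaults to a draw from the stationary
    distribution of the transition matrix.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    trans, emit = model.transition, model.emission
    states = np.empty(n_bins, dtype=int)
    if start_state is None:
        states[0] = rng.choice(model.n_states, p=stationary_distribution(trans))
    else:
        states[0] = start_state
    for t in range(1, n_bins):
        states[t] = rng.choice(model.n_states, p=trans[states[t - 1]])
    u = rng.random(n_bins)
    cum = np.cumsum(emit, axis=1)
    symbols = (u[:, None] > cum[states]).sum(axis=1)
    return states, symbols


def _sample_posture_ids(
    model: GeneratorModel,
    group_per_frame: np.ndarray,
    frame_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Frame-level reference-posture ids: dwell within the active group.

    Within each run of a posture group the animal hops between the group's
    member postures, holding each for a geometric dwell time with the
    model's mean dwell.
    """
    n = group_per_frame.size
    ids = np.empty(n, dtype=int)
    p_leave = min(1.0, 1.0 / (model.posture_dwell_mean_s * frame_rate))
    members = {g: model.postures_in_group(g) for g in range(model.n_groups)}
    u_leave = rng.random(n)
    u_pick = rng.random(n)
    current = -1
    for i in range(n):
        g = group_per_frame[i]
        if current < 0 or model.group_of_posture[current] != g or u_leave[i] < p_leave:
            mem = members[g]
            choices = mem[mem != current] if mem.size > 1 else mem
            current = int(choices[int(u_pick[i] * choices.size)])
        ids[i] = current
    return ids


def generate_behavior_record(
    model: GeneratorModel,
    spec: SceneSpec,
    seed: int,
    posture_noise_sd: float | None = None,
) -> tuple[BehaviorRecord, GroundTruth]:
    """Realize a full behavior record plus its ground truth from the model.

    Postures follow the HMM state path through posture groups; centroid
    speed is high in the roaming state and low elsewhere; egg-laying is a
    state-modulated Poisson process; defecation is quasi-periodic; the
    centerline-intensity profile carries grinder landmarks oscillating at
    the pump rate.
    """
    rng = np.random.default_rng(seed)
    if posture_noise_sd is None:
        # continuous within-posture variation scaled so the reference
        # postures explain ~76% of postural variance, as on real data
        vp = model.prototypes.var(axis=0).mean()
        posture_noise_sd = float(np.sqrt(vp * 0.24 / 0.76))
    fr = spec.acquisition.frame_rate
    n_frames = int(round(spec.duration * fr))
    frames_per_bin = int(round(COARSE_BIN_S * fr))
    n_bins = max(1, int(np.ceil(n_frames / frames_per_bin)))

    states, symbols = generate_state_sequence(
        model, n_bins, seed=int(rng.integers(2**31))
    )
    group_per_frame = np.repeat(symbols, frames_per_bin)[:n_frames]
    state_per_frame = np.repeat(states, frames_per_bin)[:n_frames]
    posture_ids = _sample_posture_ids(model, group_per_frame, fr, rng)

    timestamps = np.arange(n_frames) / fr
    # within-posture variation is temporally smooth (bodies deform
    # continuously); low-pass the noise over ~0.15 s, variance-preserving
    noise = rng.normal(0.0, posture_noise_sd, (n_frames, 14))
    sigma_frames = 0.15 * fr
    if n_frames > 10 and sigma_frames > 0.5:
        from scipy.ndimage import gaussian_filter1d

        noise = gaussian_filter1d(noise, sigma_frames, axis=0)
        noise *= posture_noise_sd / max(noise.std(), 1e-12)
    posture = model.prototypes[posture_ids] + noise
    posture -= posture.mean(axis=1, keepdims=True)
    valid_posture = np.ones(n_frames, dtype=bool)

    # orientation drifts slowly; centroid advances along the forward body axis
    orientation = np.cumsum(rng.normal(0.0, 0.02, n_frames))
    speed_um_s = np.where(
        state_per_frame == model.roaming_state,
        model.roaming_speed_mm_s,
        model.dwelling_speed_mm_s,
    ) * 1000.0
    heading = np.stack([-np.cos(orientation), -np.sin(orientation)], axis=1)
    step = heading * (speed_um_s / fr)[:, None] + rng.normal(0, 0.5, (n_frames, 2))
    centroid = np.cumsum(step, axis=0)

    ventral_side = "left" if rng.random() < 0.5 else "right"

    # events -------------------------------------------------------------
    rates = (
        spec.egg_rate_by_state
        if spec.egg_rate_by_state is not None
        else default_egg_rates(model)
    )
    if rates.shape[0] != model.n_states:
        raise ValueError("egg_rate_by_state length must equal the state count")
    p_egg = rates[state_per_frame] / 60.0 / fr
    egg_frames = np.flatnonzero(rng.random(n_frames) < p_egg)
    egg_counts = np.where(rng.random(egg_frames.size) < 0.05, 2, 1)
    eggs = EventTrain("egg", timestamps[egg_frames], egg_counts)

    defec_times = []
    t = rng.uniform(5.0, spec.defecation_period_s)
    while t < spec.duration:
        defec_times.append(t)
        t += max(5.0, spec.defecation_period_s + rng.normal(0.0, 3.0))
    defecation = EventTrain("defecation", np.asarray(defec_times))

    # body length with defecation contractions --------------------------
    frac = np.zeros(n_frames)
    tt = timestamps
    for te in defec_times:
        for lobe in (te, te + 3.5):
            lo = max(0, int((lobe - 5.0) * fr))
            hi = min(n_frames, int((lobe + 5.0) * fr))
            frac[lo:hi] -= spec.defecation_depth * np.exp(
                -0.5 * ((tt[lo:hi] - lobe) / 0.9) ** 2
            )
    worm_length = spec.worm_length_um * (1.0 + frac) + rng.normal(0, 1.0, n_frames)

    # widths, area, eggs' signature --------------------------------------
    base_w = np.asarray(spec.width_profile, dtype=float)
    half_widths = np.tile(base_w, (n_frames, 2, 1)) + rng.normal(
        0.0, 0.15, (n_frames, 2, 30)
    )
    worm_area = np.full(n_frames, 42_000.0) + rng.normal(0, 60.0, n_frames)
    ventral_idx = 0 if ventral_side == "left" else 1
    vseg = int(round(spec.vulva_position * 30))
    decay_frames = int(round(2.0 * fr))
    for f0 in egg_frames:
        span = np.arange(f0, min(n_frames, f0 + decay_frames))
        bump = 8.0 * np.exp(-(span - f0) / (0.8 * fr))
        for seg in range(max(0, vseg - 2), min(30, vseg + 2)):
            half_widths[span, ventral_idx, seg] += bump
        worm_area[span] += 250.0 * np.exp(-(span - f0) / (1.5 * fr))

    # centerline intensity with oscillating grinder landmarks ------------
    p = max(1, spec.intensity_samples)
    intensity = np.full((n_frames, p), float(_BG_LEVEL - _WORM_LEVEL))
    pumps = EventTrain("pump", np.asarray([]))
    if p > 50:
        s = np.linspace(0.0, 1.0, p)
        phase = 2 * np.pi * spec.pump_rate_hz * tt
        sep_um = spec.grinder_separation_um + spec.pump_amplitude_um * np.sin(phase)
        pos1 = 0.10 * spec.worm_length_um
        dip_sigma_um = 2.5
        for which, center_um in ((0, pos1), (1, None)):
            centers = (
                np.full(n_frames, pos1) if which == 0 else pos1 + sep_um
            )
            dist = s[None, :] * worm_length[:, None] - centers[:, None]
            intensity -= 100.0 * np.exp(-0.5 * (dist / dip_sigma_um) ** 2)
        intensity += rng.normal(0.0, 1.0, intensity.shape)
        # one pump per oscillation cycle (separation minimum)
        cycle = np.floor(spec.pump_rate_hz * tt - 0.25).astype(int)
        mins = []
        for c in np.unique(cycle):
            idx = np.flatnonzero(cycle == c)
            mins.append(idx[np.argmin(sep_um[idx])])
        pump_times = tt[np.asarray(mins)]
        pumps = EventTrain("pump", pump_times)

    record = BehaviorRecord(
        timestamps=timestamps,
        centroid=centroid,
        posture=posture,
        orientation=orientation,
        valid_posture=valid_posture,
        half_widths=half_widths,
        valid_widths=np.ones(n_frames, dtype=bool),
        worm_length=worm_length,
        worm_area=worm_area,
        centerline_intensity=intensity,
        ventral_side="unknown",
    )
    truth = GroundTruth(
        state_path=states,
        posture_groups=group_per_frame,
        postures=posture_ids,
        events={"egg": eggs, "defecation": defecation, "pump": pumps},
        ventral_side=ventral_side,
        roaming_state=model.roaming_state,
    )
    return record, truth


# ---------------------------------------------------------------------------
# rendering


def reconstruct_centerline_px(
    coeffs: np.ndarray,
    orientation: float,
    length_px: float,
    n_points: int = 1001,
) -> np.ndarray:
    """Centerline points (x, y) in px from a posture vector, starting at the head."""
    angles = _splines.evaluate(np.asarray(coeffs, float), n_points - 1) + orientation
    step = length_px / (n_points - 1)
    dxy = np.stack([np.cos(angles), np.sin(angles)], axis=1) * step
    pts = np.vstack([[0.0, 0.0], np.cumsum(dxy, axis=0)])
    return pts


def render_worm_frame(
    posture: np.ndarray,
    spec: SceneSpec,
    orientation: float = 0.0,
    length_scale: float = 1.0,
    grinder_separation_um: float | None = None,
    egg_positions_px: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one brightfield-like frame: dark worm on a light background.

    The body is the union of discs along the reconstructed centerline with
    the spec's half-width profile; two darker grinder spots sit in the
    anterior quarter separated by ``grinder_separation_um`` (modulated
    against the resting value during pump frames); ``length_scale`` < 1
    renders the defecation contraction; eggs are persistent dark ellipses
    at the given pixel positions.  Gaussian blur (sigma 1 px) and additive
    noise finish the frame.
    """
    rows, cols = spec.acquisition.frame_shape
    px = spec.acquisition.pixel_size
    length_px = spec.worm_length_um / px * length_scale
    pts = reconstruct_centerline_px(posture, orientation, length_px)
    pts = pts - pts.mean(axis=0) + np.array([cols / 2.0, rows / 2.0])

    widths = _splines.evaluate(np.asarray(spec.width_profile, float), 1001)
    margin = widths.max() + 3
    if (
        pts[:, 0].min() < margin
        or pts[:, 1].min() < margin
        or pts[:, 0].max() > cols - margin
        or pts[:, 1].max() > rows - margin
    ):
        raise ValueError(
            "worm exceeds frame bounds; increase AcquisitionConfig.frame_shape"
        )

    img = np.full((rows, cols), float(_BG_LEVEL))
    yy_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i in range(0, 1001, 4):
        r = widths[i]
        ri = int(np.ceil(r))
        if ri not in yy_cache:
            dy, dx = np.mgrid[-ri : ri + 1, -ri : ri + 1]
            inside = dy**2 + dx**2 <= r**2 + 1e-9
            yy_cache[ri] = (dy[inside], dx[inside])
        dy, dx = yy_cache[ri]
        cy, cx = int(round(pts[i, 1])), int(round(pts[i, 0]))
        img[cy + dy, cx + dx] = _WORM_LEVEL

    # grinder landmarks along the anterior body
    sep = (
        grinder_separation_um
        if grinder_separation_um is not None
        else spec.grinder_separation_um
    )
    arc = np.linspace(0.0, spec.worm_length_um * length_scale, 1001)
    for pos_um in (0.10 * spec.worm_length_um, 0.10 * spec.worm_length_um + sep):
        # sub-pixel placement: interpolate the centerline at the arc
        # position and stamp a Gaussian spot, so pump-cycle separation
        # changes survive pixel quantization
        u = np.clip(pos_um * length_scale, arc[0], arc[-1])
        cx = np.interp(u, arc, pts[:, 0])
        cy = np.interp(u, arc, pts[:, 1])
        r0, c0 = int(cy) - 5, int(cx) - 5
        dy, dx = np.mgrid[0:11, 0:11]
        gauss = np.exp(
            -(((r0 + dy) - cy) ** 2 + ((c0 + dx) - cx) ** 2) / (2 * 1.5**2)
        )
        patch = img[r0 : r0 + 11, c0 : c0 + 11]
        img[r0 : r0 + 11, c0 : c0 + 11] = patch - (patch - _GRINDER_LEVEL) * gauss

    if egg_positions_px is not None:
        a, b = 27.0 / px, 17.0 / px  # egg ~54 x 34 µm: semi-axes in px
        dy, dx = np.mgrid[-int(a) : int(a) + 1, -int(a) : int(a) + 1]
        inside = (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
        for ex, ey in np.atleast_2d(egg_positions_px):
            cy, cx = int(round(ey)), int(round(ex))
            if 0 <= cy - a and cy + a < rows and 0 <= cx - a and cx + a < cols:
                img[cy + dy[inside], cx + dx[inside]] = _EGG_LEVEL

    img = gaussian_filter(img, sigma=1.0)
    if rng is not None and spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def synthesize_video(
    model: GeneratorModel,
    spec: SceneSpec,
    seed: int,
    out_dir: str | Path,
) -> GroundTruth:
    """Write a synthetic frame sequence + manifest + ground truth to disk.

    Frames are worm-centered (the tracking microscope keeps the animal in
    view), so laid eggs drift out of frame as the animal moves on.  Eggs
    appear within one inter-frame interval, matching the abruptness the
    egg detector assumes.
    """
    out_dir = Path(out_dir)
    record, truth = generate_behavior_record(model, spec, seed)
    rng = np.random.default_rng(seed + 1)
    fr = spec.acquisition.frame_rate
    px = spec.acquisition.pixel_size
    rows, cols = spec.acquisition.frame_shape
    center = np.array([cols / 2.0, rows / 2.0])

    egg_times = truth.events["egg"].times
    egg_lab_um: list[np.ndarray] = []
    laid: list[float] = []
    defec_times = truth.events["defecation"].times

    ventral_sign = 1.0 if truth.ventral_side == "left" else -1.0

    def frames():
        for i, t in enumerate(record.timestamps):
            # defecation length contraction (two-lobed)
            scale = 1.0
            for te in defec_times:
                for lobe in (te, te + 3.5):
                    scale -= spec.defecation_depth * np.exp(
                        -0.5 * ((t - lobe) / 0.9) ** 2
                    )
            sep = spec.grinder_separation_um + spec.pump_amplitude_um * np.sin(
                2 * np.pi * spec.pump_rate_hz * t
            )
            # new eggs appear adjacent to the vulva on the ventral side
            pts = reconstruct_centerline_px(
                record.posture[i],
                record.orientation[i],
                spec.worm_length_um / px * scale,
            )
            pts = pts - pts.mean(axis=0) + center
            for te in egg_times[(egg_times >= t - 0.5 / fr) & (egg_times < t + 0.5 / fr)]:
                if te not in laid:
                    laid.append(te)
                    iv = int(round(spec.vulva_position * 1000))
                    tang = pts[iv + 1] - pts[iv - 1]
                    normal = np.array([-tang[1], tang[0]])
                    normal /= np.linalg.norm(normal)
                    # egg pressed lightly against the body wall: deep enough
                    # that the thresholded component includes it (an abrupt
                    # width jump), shallow enough not to drag the skeleton
                    egg_px = pts[iv] + ventral_sign * normal * (
                        _splines.evaluate(spec.width_profile, 1001)[iv] + 6.0
                    )
                    egg_lab_um.append((egg_px - center) * px + record.centroid[i])
            eggs_px = (
                (np.asarray(egg_lab_um) - record.centroid[i]) / px + center
                if egg_lab_um
                else None
            )
            img = render_worm_frame(
                record.posture[i],
                spec,
                orientation=record.orientation[i],
                length_scale=scale,
                grinder_separation_um=sep,
                egg_positions_px=eggs_px,
                rng=rng,
            )
            yield t, img

    write_frame_sequence(out_dir, frames())
    write_events_csv(truth.events, out_dir / "ground_truth_events.csv")
    meta = {
        "seed": seed,
        "ventral_side": truth.ventral_side,
        "roaming_state": truth.roaming_state,
        "state_path": truth.state_path.tolist(),
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(meta))
    return truth


# ---------------------------------------------------------------------------
# posture clustering fixture


def generate_posture_dataset(
    n_prototypes: int,
    samples_per_prototype: int,
    noise_sd: float | None = None,
    seed: int = 0,
    explainable_fraction: float = 0.76,
    min_separation_factor: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noisy samples around well-separated smooth posture prototypes.

    Returns ``(samples, labels, prototypes)``.  When ``noise_sd`` is None
    it is set so that the true prototypes explain ``explainable_fraction``
    of the total variance (the fraction a full-size reference compendium
    explains on real posture data).  Prototypes are redrawn until all
    pairwise distances exceed ``min_separation_factor * noise_sd`` (at
    least the guaranteed 4x separation).

    Raises if the requested separation cannot be achieved.
    """
    if n_prototypes < 1:
        raise ValueError("n_prototypes must be >= 1")
    rng = np.random.default_rng(seed)

    def sigma_for(p: np.ndarray) -> float:
        if noise_sd is not None:
            return float(noise_sd)
        v = p.var(axis=0).mean()
        f = explainable_fraction
        return float(np.sqrt(v * (1 - f) / f))

    # greedy packing: accept candidates that clear the separation radius.
    # The margin compensates for the packed subset being more spread out
    # than the pool, which inflates the noise scale tied to prototype
    # variance; escalate it until the final check passes.
    factor = max(4.0, min_separation_factor)
    protos = None
    for margin in (1.4, 1.5, 1.65, 1.8):
        pool = sinusoid_prototypes(max(8000, 100 * n_prototypes), rng)
        sigma = sigma_for(pool)
        kept: list[np.ndarray] = []
        for cand in pool:
            if not kept or np.min(
                np.linalg.norm(np.asarray(kept) - cand, axis=1)
            ) >= margin * factor * sigma:
                kept.append(cand)
                if len(kept) == n_prototypes:
                    break
        if len(kept) < n_prototypes:
            continue
        cand_protos = np.asarray(kept)
        sigma = sigma_for(cand_protos)
        if n_prototypes == 1 or np.min(pdist(cand_protos)) >= factor * sigma:
            protos = cand_protos
            break
    if protos is None:
        raise ValueError(
            "could not draw prototypes with the required pairwise separation"
        )
    sigma = sigma_for(protos)
    labels = np.repeat(np.arange(n_prototypes), samples_per_prototype)
    samples = protos[labels] + rng.normal(0.0, sigma, (labels.size, 14))
    perm = rng.permutation(labels.size)
    return samples[perm], labels[perm], protos
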
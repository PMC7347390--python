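"""End-to-end orchestration: frames → record → states → analysis tables."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import _splines
from .posture import (
    SegmentationParams,
    assign_head_tail,
    compute_half_widths,
    compute_locomotion,
    extract_centerline,
    segment_worm,
)
from .record import AcquisitionConfig, BehaviorRecord, read_record, read_events_csv
from .states import (
    assign_postures,
    build_compendium,
    build_transition_matrix,
    cluster_posture_groups,
    coarsen_intervals,
    select_model_bic,
    viterbi_decode,
)

INTENSITY_SAMPLES = 501


def _intensity_profile(image: np.ndarray, points: np.ndarray, half_px: int = 4
                       ) -> np.ndarray:
    """Mean of 8 perpendicularly oriented pixels at each centerline point,
    resampled to a fixed number of samples along the body."""
    idx = np.linspace(0, points.shape[0] - 1, INTENSITY_SAMPLES).astype(int)
    pts = points[idx]
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-9)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    offsets = np.arange(-half_px, half_px) + 0.5
    probes = pts[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    r = np.clip(np.round(probes[..., 1]).astype(int), 0, image.shape[0] - 1)
    c = np.clip(np.round(probes[..., 0]).astype(int), 0, image.shape[1] - 1)
    return image[r, c].mean(axis=1)


def extract_record(
    frames: Iterable[tuple[float, np.ndarray]] | Iterator[tuple[float, np.ndarray]],
    acquisition: AcquisitionConfig | None = None,
    seg_params: SegmentationParams | None = None,
    global_flip: bool | str = "auto",
) -> tuple[BehaviorRecord, dict]:
    """Full per-frame image pipeline over a frame sequence.

    Runs segmentation, centerline extraction, half-width measurement and
    the intensity profile per frame, then the two-stage head/tail
    consistency pass, and finally the posture-spline fit.  Returns the
    record plus per-stage counters.

    ``global_flip`` resolves which end is the head once the labeling is
    internally consistent: True/False apply or skip a whole-record flip
    (the stand-in for checking a single frame by eye); "auto" flips so
    that the darkest intensity landmarks — the pharyngeal grinder and
    posterior bulb — sit in the anterior quarter of the body.
    """
    acq = acquisition or AcquisitionConfig()
    seg = seg_params or SegmentationParams()
    px = acq.pixel_size

    times, angles, intensities, widths = [], [], [], []
    centroids, lengths, areas, valid = [], [], [], []
    stats = {"empty_mask": 0, "self_intersecting": 0, "invalid_posture": 0}

    for t, img in frames:
        times.append(t)
        mask = segment_worm(img, seg)
        ok = mask.any()
        cl = None
        if ok:
            try:
                cl = extract_centerline(mask, image=img)
            except ValueError:
                cl = None
            if cl is None or cl.self_intersecting or cl.points is None:
                if cl is not None and cl.self_intersecting:
                    stats["self_intersecting"] += 1
                ok = False
        else:
            stats["empty_mask"] += 1
        if ok:
            d = np.diff(cl.points, axis=0)
            angles.append(np.unwrap(np.arctan2(d[:, 1], d[:, 0])))
            intensities.append(_intensity_profile(img, cl.points))
            hw = compute_half_widths(mask, cl)
            widths.append(hw if hw is not None else np.zeros((2, 30)))
            rc = np.argwhere(mask).mean(axis=0)
            centroids.append(np.array([rc[1], rc[0]]) * px)
            lengths.append(cl.arc_length * px)
            areas.append(float(mask.sum()))
            valid.append(hw is not None)
        else:
            angles.append(np.zeros(1000))
            intensities.append(np.zeros(INTENSITY_SAMPLES))
            widths.append(np.zeros((2, 30)))
            centroids.append(centroids[-1] if centroids else np.zeros(2))
            lengths.append(np.nan)
            areas.append(np.nan)
            valid.append(False)
        if not ok:
            stats["invalid_posture"] += 1

    valid = np.asarray(valid, dtype=bool)
    angles = np.asarray(angles)
    intensities = np.asarray(intensities)
    widths = np.asarray(widths)
    angles, intensities, flipped = assign_head_tail(
        angles, intensities, valid, global_flip=False
    )
    do_flip = bool(global_flip) if global_flip != "auto" else False
    if global_flip == "auto" and valid.any():
        prof = intensities[valid].mean(axis=0)
        q = prof.size // 4
        do_flip = prof[:q].min() > prof[-q:].min()
    if do_flip:
        from .posture import flip_angles

        for i in np.flatnonzero(valid):
            angles[i] = flip_angles(angles[i])
            intensities[i] = intensities[i][::-1]
            flipped[i] = ~flipped[i]
    for i in np.flatnonzero(flipped):
        widths[i] = widths[i, ::-1, ::-1]
    stats["n_flipped"] = int(flipped.sum())
    stats["flipped"] = flipped

    B = _splines.design_matrix(_splines.N_ANGLE_COEFFS, 1000)
    coeffs = np.zeros((len(times), 14))
    orientation = np.zeros(len(times))
    for i in np.flatnonzero(valid):
        c, *_ = np.linalg.lstsq(B, angles[i], rcond=None)
        m = float((B @ c).mean())
        coeffs[i] = c - m
        orientation[i] = m

    record = BehaviorRecord(
        timestamps=np.asarray(times, dtype=float),
        centroid=np.asarray(centroids),
        posture=coeffs,
        orientation=orientation,
        valid_posture=valid,
        half_widths=widths,
        valid_widths=valid,
        worm_length=np.asarray(lengths),
        worm_area=np.asarray(areas),
        centerline_intensity=intensities,
    )
    return record, stats


def discover_states(
    records: list[BehaviorRecord],
    seed: int = 0,
    max_K: int = 200,
    compendium_sample: int = 100_000,
    group_restarts: int = 50,
    state_range: range = range(2, 13),
    hmm_restarts: int = 3,
) -> dict:
    """Posture compendium → groups → coarsening → BIC-selected HMM → paths."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([r.posture[r.valid_posture] for r in records])
    if pooled.shape[0] > compendium_sample:
        pooled = pooled[rng.choice(pooled.shape[0], compendium_sample, replace=False)]
    max_K = min(max_K, pooled.shape[0])
    compendium = build_compendium(pooled, max_K=max_K, seed=int(rng.integers(2**31)))

    ids = [assign_postures(r.posture, compendium, valid=r.valid_posture)
           for r in records]
    T = build_transition_matrix(
        np.concatenate([np.concatenate([i, [-1]]) for i in ids]),
        n_postures=compendium.size,
    )
    groups, n_groups = cluster_posture_groups(
        T, n_restarts=group_restarts, seed=int(rng.integers(2**31))
    )

    sequences, velocities = [], []
    for r, pid in zip(records, ids):
        gid = np.where(pid >= 0, groups.assignment[np.clip(pid, 0, None)], -1)
        seq, _ = coarsen_intervals(
            gid, r.frame_rate, n_groups=n_groups, seed=int(rng.integers(2**31))
        )
        sequences.append(seq)
        loco = compute_locomotion(r)
        v = loco["velocity_1s"]
        fpb = int(round(seq.bin_s * r.frame_rate))
        nb = seq.n_bins
        vb = np.array([np.nanmean(v[b * fpb : (b + 1) * fpb]) for b in range(nb)])
        velocities.append(vb)

    best_n, bic_curve, models = select_model_bic(
        sequences,
        state_range=state_range,
        n_restarts=hmm_restarts,
        seed=int(rng.integers(2**31)),
        n_symbols=n_groups,
    )
    hmm = models[best_n]
    paths = [
        viterbi_decode(hmm, seq, velocity_per_bin=vb)
        for seq, vb in zip(sequences, velocities)
    ]
    return {
        "compendium": compendium,
        "groups": groups,
        "n_groups": n_groups,
        "transition": T,
        "sequences": sequences,
        "hmm": hmm,
        "bic_curve": bic_curve,
        "paths": paths,
    }


def analyze_record(
    record_file: str | Path,
    events_file: str | Path,
    states_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Standard analysis tables for one record: velocity-binned event rates
    and the eigenworm spectrum; per-state summaries when a decoded state
    path is available."""
    from .analysis import eigenworm_pca, velocity_binned_behavior

    record = read_record(record_file)
    events = read_events_csv(events_file)
    loco = compute_locomotion(record)
    v = loco["velocity_1s"]
    profiles = velocity_binned_behavior(
        record,
        v,
        signals={"angular_velocity": loco["angular_velocity_1s"]},
        events=events,
    )
    rows = []
    for name, prof in profiles.items():
        for b in range(prof.bin_edges.size - 1):
            rows.append({
                "behavior": name,
                "v_lo": prof.bin_edges[b],
                "v_hi": prof.bin_edges[b + 1],
                "statistic": prof.statistic[b],
                "time_in_bin_s": prof.time_in_bin[b],
            })
    tables = {"velocity_binned": pd.DataFrame(rows)}

    if record.valid_posture.sum() > 14:
        basis, _ = eigenworm_pca(record.posture[record.valid_posture])
        tables["eigenworms"] = pd.DataFrame({
            "component": np.arange(1, basis.explained_fraction.size + 1),
            "explained_fraction": basis.explained_fraction,
        })

    if states_dir is not None:
        paths = sorted(Path(states_dir).glob("state_path_*.csv"))
        if paths:
            tables["state_path"] = pd.read_csv(paths[0])
    return tables
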
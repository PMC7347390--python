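"""Calibrate the egg region-filter threshold on synthetic fixtures.

Sweeps DetectorParams.egg_filter_threshold_px over record-level fixtures and
reports recall and false positives per 10 minutes at each setting, so the
default can be placed where recall >= 0.9 at <= 1 false positive / 10 min.

Run from the repository root:

    python scripts/calibrate_egg_threshold.py --seed 1
"""

from __future__ import annotations

import argparse

import numpy as np

from wormstates.events import (
    DetectorParams,
    assign_ventral_side,
    detect_egg_candidates,
    merge_candidate_frames,
)
from wormstates.synthetic import (
    SceneSpec,
    default_generator_model,
    generate_behavior_record,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-records", type=int, default=3)
    ap.add_argument(
        "--thresholds", type=float, nargs="+", default=[2.0, 2.5, 3.0, 3.5, 4.0, 5.0]
    )
    args = ap.parse_args()

    model = default_generator_model()
    spec = SceneSpec(
        duration=600.0, egg_rate_by_state=np.full(9, 2.0), intensity_samples=1
    )
    fixtures = [
        generate_behavior_record(model, spec, seed=args.seed + i)
        for i in range(args.n_records)
    ]
    print(f"{'thr_px':>7} {'recall':>8} {'fp_per_10min':>13}")
    for thr in args.thresholds:
        recalls, fps = [], []
        for rec, truth in fixtures:
            params = DetectorParams(egg_filter_threshold_px=thr)
            candidates = detect_egg_candidates(rec, params)
            _, kept = assign_ventral_side(candidates)
            events = merge_candidate_frames(kept, rec.frame_rate)
            times = rec.timestamps[np.asarray(events, int)] if events else np.array([])
            true_times = truth.events["egg"].times
            hit = [
                times.size > 0 and np.min(np.abs(times - t)) <= 1.0
                for t in true_times
            ]
            recalls.append(np.mean(hit) if len(hit) else np.nan)
            fps.append(
                sum(1 for t in times if np.min(np.abs(true_times - t)) > 1.0)
            )
        print(f"{thr:7.1f} {np.nanmean(recalls):8.3f} {np.mean(fps):13.2f}")


if __name__ == "__main__":
    main()
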
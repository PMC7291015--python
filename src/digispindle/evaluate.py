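"""Ground-truth matching oracles: detection and track recovery metrics.

These matchers are deliberately simple and independent of the detection and
linking code paths: greedy nearest-pair matching within a radius, and
majority-overlap track-to-truth attribution.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .models import GroundTruthTrajectory
from .tracking import Track

__all__ = ["greedy_match", "detection_metrics", "track_recovery"]


def greedy_match(
    truth_um: np.ndarray, found_um: np.ndarray, radius_um: float
) -> list[tuple[int, int]]:
    """Greedy nearest-pair one-to-one matching within ``radius_um``.

    All candidate pairs are sorted by distance and accepted greedily; each
    truth point and each found point is used at most once.
    """
    a = np.asarray(truth_um, float).reshape(-1, 3)
    b = np.asarray(found_um, float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        return []
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    ii, jj = np.nonzero(d <= radius_um)
    order = np.argsort(d[ii, jj], kind="stable")
    used_i: set[int] = set()
    used_j: set[int] = set()
    matches = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        matches.append((i, j))
    return matches


def detection_metrics(
    truth: pd.DataFrame, detections: pd.DataFrame, radius_um: float = 0.3
) -> dict:
    """Per-series recall/precision of detections against ground-truth comets.

    Both tables are long-format with columns frame, x_um, y_um, z_um;
    matching is done frame by frame with :func:`greedy_match`.
    """
    n_truth = n_found = n_matched = 0
    frames = sorted(set(truth["frame"]) | set(detections["frame"]))
    cols = ["x_um", "y_um", "z_um"]
    for f in frames:
        t = truth[truth["frame"] == f][cols].to_numpy(dtype=float)
        d = detections[detections["frame"] == f][cols].to_numpy(dtype=float)
        n_truth += len(t)
        n_found += len(d)
        n_matched += len(greedy_match(t, d, radius_um))
    return {
        "n_truth": n_truth,
        "n_detections": n_found,
        "n_matched": n_matched,
        "recall": n_matched / n_truth if n_truth else float("nan"),
        "precision": n_matched / n_found if n_found else float("nan"),
    }


def track_recovery(
    truth: Sequence[GroundTruthTrajectory],
    tracks: Sequence[Track],
    radius_um: float = 0.3,
    min_coverage: float = 0.8,
) -> dict:
    """Fraction of truth trajectories recovered by the linked tracks.

    Each track is attributed to the truth trajectory that the majority of its
    points fall on (same frame, within ``radius_um``).  A truth trajectory
    counts as recovered when some single track covers at least
    ``min_coverage`` of its points.  Also returns the mapping
    track_id → truth_id (or None) for downstream per-track comparisons.
    """
    coverage: dict[int, float] = {tr.id: 0.0 for tr in truth}
    by_id = {tr.id: tr for tr in truth}
    attribution: dict[int, int | None] = {}
    for tk in tracks:
        votes: Counter = Counter()
        for f, p in zip(tk.frames, tk.positions_um):
            for tr in truth:
                k = f - tr.start_frame
                if 0 <= k < tr.n_points and np.linalg.norm(
                    tr.positions_um[k] - p
                ) <= radius_um:
                    votes[tr.id] += 1
        if not votes:
            attribution[tk.id] = None
            continue
        best, n_votes = votes.most_common(1)[0]
        attribution[tk.id] = best
        coverage[best] = max(coverage[best], n_votes / by_id[best].n_points)
    recovered = sum(1 for v in coverage.values() if v >= min_coverage)
    return {
        "n_truth": len(truth),
        "n_tracks": len(tracks),
        "n_recovered": recovered,
        "recovery_rate": recovered / len(truth) if truth else float("nan"),
        "attribution": attribution,
    }
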
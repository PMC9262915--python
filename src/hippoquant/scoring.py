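"""Detector-scoring helpers: event matching against ground truth."""

from __future__ import annotations

import numpy as np

__all__ = ["match_events", "recall_precision"]


def match_events(detected_s: np.ndarray, truth_s: np.ndarray,
                 tolerance_s: float) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to ground-truth event times.

    Returns (true positives, false positives, false negatives).  Each truth
    event can absorb at most one detection; matches are assigned nearest-first.
    """
    det = np.sort(np.asarray(detected_s, dtype=float))
    tru = np.sort(np.asarray(truth_s, dtype=float))
    used_det: set[int] = set()
    used_tru: set[int] = set()
    pairs: list[tuple[float, int, int]] = []
    for i, d in enumerate(det):
        j = int(np.searchsorted(tru, d))
        for jj in (j - 1, j):
            if 0 <= jj < tru.size and abs(d - tru[jj]) <= tolerance_s:
                pairs.append((abs(d - tru[jj]), i, jj))
    tp = 0
    for _, i, j in sorted(pairs):
        if i in used_det or j in used_tru:
            continue
        used_det.add(i)
        used_tru.add(j)
        tp += 1
    return tp, det.size - tp, tru.size - tp


def recall_precision(detected_s, truth_s, tolerance_s: float) -> tuple[float, float]:
    """(recall, precision) of detected vs ground-truth event times."""
    tp, fp, fn = match_events(detected_s, truth_s, tolerance_s)
    recall = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    return recall, precision
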
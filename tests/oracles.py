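"""Brute-force reference implementations used only to cross-check the package.

These stay deliberately naive (explicit loops, no vectorization, no shared
code with the implementation) so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def si_pairs_oracle(cultures, abx, max_c_to_a=72.0, max_a_to_c=24.0):
    """All qualifying (culture, antibiotic) pairs with their index times."""
    pairs = []
    for c in cultures:
        for a in abx:
            if c <= a and a - c <= max_c_to_a:
                pairs.append((c, a, min(c, a)))
            elif a < c and c - a <= max_a_to_c:
                pairs.append((c, a, min(c, a)))
    return sorted(pairs, key=lambda p: (p[2], p[0], p[1]))


def onset_oracle(si_index_times, grid_times, grid_scores, before=48.0, after=24.0, threshold=2):
    """Earliest grid time with an acute SOFA increase in any SI window."""
    best = None
    for idx in si_index_times:
        window = [
            (t, s)
            for t, s in zip(grid_times, grid_scores)
            if idx - before <= t <= idx + after
        ]
        for j, (t, s) in enumerate(window):
            running_min = min(s2 for _, s2 in window[: j + 1])
            if s - running_min >= threshold:
                if best is None or t < best:
                    best = t
                break
    return best


def sliding_samples_oracle(
    admit, discharge, onset, obs=12.0, pred=12.0, lead=0.0, shift=6.0, eps=1e-9
):
    """Enumeration of (prediction_time, label) for the sliding-window framing."""
    out = []
    k = 0
    while True:
        t = admit + obs + k * shift
        if t > discharge + eps:
            break
        k += 1
        if onset is not None and t >= onset - eps:
            continue
        label = int(onset is not None and (t + lead) < onset <= (t + lead + pred))
        out.append((t, label))
    return out


def ace_oracle(labels, probs, n_bins=10):
    """Hand-binned average calibration error (percent)."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    gaps = []
    for b in range(n_bins):
        members = [
            i
            for i, p in enumerate(probs)
            if (edges[b] < p <= edges[b + 1]) or (b == 0 and p <= edges[0])
        ]
        if not members:
            continue
        obs_rate = sum(labels[i] for i in members) / len(members)
        mean_p = sum(probs[i] for i in members) / len(members)
        gaps.append(abs(obs_rate - mean_p))
    return 100.0 * sum(gaps) / len(gaps)


def stratified_brier_oracle(labels, probs):
    pos = [(1.0 - p) ** 2 for y, p in zip(labels, probs) if y == 1]
    neg = [p**2 for y, p in zip(labels, probs) if y == 0]
    bp = 100.0 * sum(pos) / len(pos) if pos else float("nan")
    bn = 100.0 * sum(neg) / len(neg) if neg else float("nan")
    return bp, bn
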
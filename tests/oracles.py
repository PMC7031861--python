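"""Naive, loop-based reimplementations of the score formulas.

Kept deliberately independent of ``rms.scoring`` (pure Python lists, no
shared helpers) so the vectorized implementation can be checked against
a direct transcription of the definitions.
"""

from __future__ import annotations


def combined_counts(count5, count3):
    L = len(count5)
    return [int(count3[i]) + (int(count5[i + 1]) if i + 1 < L else 0) for i in range(L)]


def naive_scores(count5, count3, w, weights=None):
    """Return {score_name: [value or None per position]} for one profile."""
    n = combined_counts(count5, count3)
    L = len(n)
    if weights is None:
        weights = [1.0] * w
    out = {k: [None] * L for k in ("max", "maxmax", "mean", "a", "methscore")}
    for i in range(L):
        if i < w or i >= L - w:
            continue
        norm = sum(weights)
        left = sum(weights[j - 1] * n[i - j] for j in range(1, w + 1)) / norm
        right = sum(weights[j - 1] * n[i + j] for j in range(1, w + 1)) / norm
        d53 = max(0.0, 1.0 - n[i] / left) if left > 0 else None
        d35 = max(0.0, 1.0 - n[i] / right) if right > 0 else None
        if d53 is not None:
            out["max"][i] = d53
        defined = [d for d in (d53, d35) if d is not None]
        if defined:
            out["maxmax"][i] = max(defined)
        if d53 is not None and d35 is not None:
            out["mean"][i] = (d53 + d35) / 2.0
        if left + right > 0:
            out["a"][i] = max(0.0, 1.0 - 2.0 * n[i] / (left + right))
            out["methscore"][i] = 1.0 - 2.0 * n[i] / (left + right)
    return out


def naive_score_d(values_a, valid_a, values_m, valid_m):
    """Min-max normalize each track over its valid positions, then average."""

    def norm(values, valid):
        vv = [v for v, ok in zip(values, valid) if ok]
        lo, hi = min(vv), max(vv)
        span = hi - lo
        return [
            ((v - lo) / span if span > 0 else 0.0) if ok else 0.0
            for v, ok in zip(values, valid)
        ]

    na, nm = norm(values_a, valid_a), norm(values_m, valid_m)
    return [
        0.5 * (a + m) if (oa and om) else None
        for a, m, oa, om in zip(na, nm, valid_a, valid_m)
    ]


def naive_auc(scores, is_positive):
    """Mann-Whitney probability that a positive outscores a negative,
    counting ties as one half."""
    pos = [s for s, y in zip(scores, is_positive) if y]
    neg = [s for s, y in zip(scores, is_positive) if not y]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
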
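"""RiboMethSeq protection score family.

All scores compare the combined end count ``n_i`` at a position with
weighted means of its neighbors on each side::

    L_i = sum_j(w_j * n_{i-j}) / sum_j(w_j)      (5'-side mean)
    R_i = sum_j(w_j * n_{i+j}) / sum_j(w_j)      (3'-side mean)
    drop53_i = max(0, 1 - n_i / L_i)             (5'->3' relative drop)
    drop35_i = max(0, 1 - n_i / R_i)             (3'->5' relative drop)

for offsets ``j = 1..w``. The named scores combine the two directional
drops in different ways:

* ScoreMAX — the pure 5'->3' drop ``drop53``, favoring the orientation
  in which the protection gap is read out.
* ScoreMAX-MAX — ``max(drop53, drop35)``.
* ScoreMEAN — ``(drop53 + drop35) / 2``.
* ScoreA — clamped symmetric protection ``max(0, 1 - 2 n_i / (L_i + R_i))``.
* MethScore (ScoreC) — ``1 - 2 n_i / (L_i + R_i)`` unclamped; linear in
  the gap depth, so it tracks the methylation fraction and may go
  negative at over-cleaved positions.
* ScoreD — the normalized sum of a ScoreA track and a ScoreMEAN track.

Scores are ratios of counts, hence invariant to rescaling the library
depth. Positions within ``w`` of a terminus, or whose required neighbor
means vanish, are masked invalid rather than scored. No pseudocounts are
added; scoring is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from rms.profiles import EndCountProfile

#: Decreasing neighbor weights shipped for the +/-6 window.
DEFAULT_W6_WEIGHTS = (1.0, 1.0, 1.0, 0.9, 0.8, 0.7)

SCORE_NAMES = ("max", "maxmax", "mean", "a", "methscore", "d")


@dataclass(frozen=True)
class ScoreParams:
    """Neighbor-window parameters shared by all scores.

    Parameters
    ----------
    window : int
        Half-width ``w`` of the neighbor window in nucleotides. The
        recommended setting is 2 (four neighbors); the historical
        default was 6 (twelve neighbors).
    weights : tuple of float, optional
        Per-offset weights for offsets ``1..w``, applied symmetrically
        on both sides. Defaults to unit weights, except ``window == 6``
        which ships a decreasing series.
    """

    window: int = 2
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.window <= 8:
            raise ValueError(f"window must be in 1..8, got {self.window}")
        if self.weights is None:
            w = DEFAULT_W6_WEIGHTS if self.window == 6 else (1.0,) * self.window
            object.__setattr__(self, "weights", tuple(w))
        else:
            object.__setattr__(self, "weights", tuple(float(x) for x in self.weights))
        if len(self.weights) != self.window:
            raise ValueError(
                f"need {self.window} weights, got {len(self.weights)}"
            )
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")


@dataclass
class ScoreTrack:
    """Per-position values of one named score on one reference."""

    ref_name: str
    score_name: str
    params: ScoreParams
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask must have equal shape")

    @property
    def length(self) -> int:
        return len(self.values)

    def positions(self) -> np.ndarray:
        """1-based positions with a defined score."""
        return np.flatnonzero(self.valid) + 1

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


def _side_means(n: np.ndarray, params: ScoreParams):
    """Weighted neighbor means L, R and the interior mask."""
    w = params.window
    if len(n) < 2 * w + 1:
        raise ValueError(
            f"reference of length {len(n)} too short for window {w} "
            f"(needs >= {2 * w + 1} positions)"
        )
    weights = np.asarray(params.weights, dtype=float)
    num_l = np.zeros(len(n), dtype=float)
    num_r = np.zeros(len(n), dtype=float)
    nf = n.astype(float)
    for j in range(1, w + 1):
        num_l[j:] += weights[j - 1] * nf[:-j]
        num_r[:-j] += weights[j - 1] * nf[j:]
    norm = weights.sum()
    left = num_l / norm
    right = num_r / norm
    interior = np.zeros(len(n), dtype=bool)
    interior[w : len(n) - w] = True
    return left, right, interior


def _drops(n, left, right):
    with np.errstate(divide="ignore", invalid="ignore"):
        drop53 = np.where(left > 0, 1.0 - n / left, np.nan)
        drop35 = np.where(right > 0, 1.0 - n / right, np.nan)
    return np.maximum(drop53, 0.0), np.maximum(drop35, 0.0)


def _track(profile, name, params, values, valid) -> ScoreTrack:
    values = np.where(valid, values, 0.0)
    return ScoreTrack(
        ref_name=profile.ref_name,
        score_name=name,
        params=params,
        values=values,
        valid=valid,
    )


def score_max(profile: EndCountProfile, params: ScoreParams | None = None) -> ScoreTrack:
    """Directional 5'->3' drop (ScoreMAX). Masked where the 5'-side mean is zero."""
    params = params or ScoreParams()
    n = profile.countN
    left, right, interior = _side_means(n, params)
    drop53, _ = _drops(n, left, right)
    valid = interior & (left > 0)
    return _track(profile, "max", params, drop53, valid)


def score_maxmax(
    profile: EndCountProfile, params: ScoreParams | None = None
) -> ScoreTrack:
    """Larger of the two directional drops (ScoreMAX-MAX).

    One-sided where a single neighbor mean vanishes; masked only when
    both sides are undefined.
    """
    params = params or ScoreParams()
    n = profile.countN
    left, right, interior = _side_means(n, params)
    drop53, drop35 = _drops(n, left, right)
    values = np.fmax(drop53, drop35)  # fmax ignores NaN on one side
    valid = interior & ((left > 0) | (right > 0))
    return _track(profile, "maxmax", params, values, valid)


def score_mean(
    profile: EndCountProfile, params: ScoreParams | None = None
) -> ScoreTrack:
    """Average of the two directional drops (ScoreMEAN).

    The recommended detection score at window 2 (ScoreMEAN2): it keeps
    the clamped directional readout but is symmetric, which discriminates
    one-sided false-positive gaps better than ScoreMAX.
    """
    params = params or ScoreParams()
    n = profile.countN
    left, right, interior = _side_means(n, params)
    drop53, drop35 = _drops(n, left, right)
    values = 0.5 * (drop53 + drop35)
    valid = interior & (left > 0) & (right > 0)
    return _track(profile, "mean", params, values, valid)


def score_a(profile: EndCountProfile, params: ScoreParams | None = None) -> ScoreTrack:
    """Clamped symmetric protection score (ScoreA)."""
    params = params or ScoreParams()
    n = profile.countN
    left, right, interior = _side_means(n, params)
    both = left + right
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.maximum(1.0 - 2.0 * n / both, 0.0)
    valid = interior & (both > 0)
    return _track(profile, "a", params, values, valid)


def methscore(
    profile: EndCountProfile, params: ScoreParams | None = None
) -> ScoreTrack:
    """Quantification score MethScore (ScoreC), unclamped.

    Under a homogeneous cleavage profile the value equals the fraction of
    molecules methylated at the position: 0 when unprotected, 1.0 when
    fully protected. Over-cleaved positions yield negative values, which
    are reported as-is.
    """
    params = params or ScoreParams()
    n = profile.countN
    left, right, interior = _side_means(n, params)
    both = left + right
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 1.0 - 2.0 * n / both
    valid = interior & (both > 0)
    return _track(profile, "methscore", params, values, valid)


def _minmax_normalize(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = np.zeros_like(values, dtype=float)
    vv = values[valid]
    if len(vv) == 0:
        return out
    lo, hi = vv.min(), vv.max()
    if hi > lo:
        out[valid] = (values[valid] - lo) / (hi - lo)
    # constant track normalizes to all-zeros by convention
    return out


def score_d(track_a: ScoreTrack, track_mean: ScoreTrack) -> ScoreTrack:
    """Normalized sum of a ScoreA track and a ScoreMEAN track (ScoreD).

    Each input is min-max scaled to [0, 1] over its valid positions and
    the two are averaged; a constant input normalizes to zeros.
    """
    if track_a.ref_name != track_mean.ref_name:
        raise ValueError(
            f"reference mismatch: {track_a.ref_name!r} vs {track_mean.ref_name!r}"
        )
    if track_a.params.window != track_mean.params.window:
        raise ValueError(
            f"window mismatch: {track_a.params.window} vs {track_mean.params.window}"
        )
    if track_a.length != track_mean.length:
        raise ValueError("track length mismatch")
    valid = track_a.valid & track_mean.valid
    norm_a = _minmax_normalize(track_a.values, track_a.valid)
    norm_m = _minmax_normalize(track_mean.values, track_mean.valid)
    values = np.where(valid, 0.5 * (norm_a + norm_m), 0.0)
    return ScoreTrack(
        ref_name=track_a.ref_name,
        score_name="d",
        params=track_a.params,
        values=values,
        valid=valid,
    )


_SCORE_FUNCS = {
    "max": score_max,
    "maxmax": score_maxmax,
    "mean": score_mean,
    "a": score_a,
    "methscore": methscore,
}


def compute_score(
    profile: EndCountProfile, score_name: str, params: ScoreParams | None = None
) -> ScoreTrack:
    """Dispatch a named score (``max``, ``maxmax``, ``mean``, ``a``,
    ``methscore``); ``d`` is derived from ScoreA + ScoreMEAN."""
    if score_name == "d":
        params = params or ScoreParams()
        return score_d(score_a(profile, params), score_mean(profile, params))
    try:
        func = _SCORE_FUNCS[score_name]
    except KeyError:
        raise ValueError(
            f"unknown score {score_name!r}; expected one of {SCORE_NAMES}"
        ) from None
    return func(profile, params)


def parse_score_spec(spec: str) -> tuple[str, ScoreParams]:
    """Parse a compact score spec like ``mean2``, ``a2``, ``max6``,
    ``maxmax2`` or ``methscore2`` into (name, params)."""
    spec = spec.lower()
    for name in sorted(_SCORE_FUNCS, key=len, reverse=True):
        if spec.startswith(name):
            rest = spec[len(name) :]
            window = int(rest) if rest else 2
            return name, ScoreParams(window=window)
    if spec == "d":
        return "d", ScoreParams()
    raise ValueError(f"cannot parse score spec {spec!r}")


def score_sweep(
    profile: EndCountProfile,
    score_name: str,
    windows: Sequence[int],
    weights_by_window: dict[int, Sequence[float]] | None = None,
) -> list[ScoreTrack]:
    """Compute one score across several window half-widths.

    Convenience wrapper for the window-size experiment: wider windows
    mask more terminal positions and smooth the neighbor means over more
    of the heterogeneous cleavage landscape.
    """
    tracks = []
    for w in windows:
        weights = None
        if weights_by_window and w in weights_by_window:
            weights = tuple(weights_by_window[w])
        tracks.append(
            compute_score(profile, score_name, ScoreParams(window=w, weights=weights))
        )
    return tracks


SCORES_HEADER = "#ref\tpos\tscore_name\twindow\tvalue\tvalid"


def save_tracks(tracks: ScoreTrack | Sequence[ScoreTrack], path) -> None:
    """Write score tracks to TSV (all positions; masked rows flagged 0)."""
    if isinstance(tracks, ScoreTrack):
        tracks = [tracks]
    with open(path, "w") as fh:
        fh.write(SCORES_HEADER + "\n")
        for tr in tracks:
            for i in range(tr.length):
                fh.write(
                    f"{tr.ref_name}\t{i + 1}\t{tr.score_name}\t{tr.params.window}"
                    f"\t{tr.values[i]:.10g}\t{int(tr.valid[i])}\n"
                )


def load_tracks(path) -> list[ScoreTrack]:
    """Read a score TSV back into tracks (one per ref x score x window)."""
    groups: dict[tuple[str, str, int], dict[int, tuple[float, bool]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"{path}: line {lineno}: expected 6 columns")
            ref, pos, name, window, value, valid = fields
            key = (ref, name, int(window))
            groups.setdefault(key, {})[int(pos)] = (float(value), valid == "1")
    tracks = []
    for (ref, name, window), rows in groups.items():
        length = max(rows)
        values = np.zeros(length)
        valid = np.zeros(length, dtype=bool)
        for pos, (v, ok) in rows.items():
            values[pos - 1] = v
            valid[pos - 1] = ok
        tracks.append(
            ScoreTrack(
                ref_name=ref,
                score_name=name,
                params=ScoreParams(window=window),
                values=values,
                valid=valid,
            )
        )
    return tracks
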
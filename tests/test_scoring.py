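import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rms.scoring import (
    DEFAULT_W6_WEIGHTS,
    ScoreParams,
    compute_score,
    load_tracks,
    methscore,
    parse_score_spec,
    save_tracks,
    score_a,
    score_d,
    score_max,
    score_maxmax,
    score_mean,
    score_sweep,
)

from conftest import make_profile
from oracles import naive_score_d, naive_scores

ALL_SCORES = [score_max, score_maxmax, score_mean, score_a, methscore]


def five_point(n_center, left, right):
    """Profile whose center position has combined count ``n_center`` and
    uniform side counts, with a +/-2 window in mind."""
    return make_profile([left, left, n_center, right, right])


class TestParams:
    def test_default_weights_are_unit(self):
        assert ScoreParams(window=2).weights == (1.0, 1.0)

    def test_window6_ships_decreasing_series(self):
        assert ScoreParams(window=6).weights == DEFAULT_W6_WEIGHTS

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window": 0},
            {"window": 9},
            {"window": 2, "weights": (1.0,)},
            {"window": 2, "weights": (1.0, -1.0)},
            {"window": 2, "weights": (1.0, 0.0)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScoreParams(**kwargs)

    def test_spec_parsing(self):
        assert parse_score_spec("mean2") == ("mean", ScoreParams(window=2))
        assert parse_score_spec("a2") == ("a", ScoreParams(window=2))
        assert parse_score_spec("max6")[1].window == 6
        assert parse_score_spec("maxmax2")[0] == "maxmax"
        assert parse_score_spec("methscore2")[0] == "methscore"
        with pytest.raises(ValueError):
            parse_score_spec("bogus3")


class TestPointValues:
    @pytest.mark.parametrize("score", ALL_SCORES)
    def test_uniform_profile_scores_zero(self, score, uniform_profile):
        track = score(uniform_profile, ScoreParams(window=2))
        assert track.valid[2:-2].all()
        assert np.allclose(track.values[track.valid], 0.0)

    @pytest.mark.parametrize("score", ALL_SCORES)
    def test_fully_protected_position_scores_one(self, score):
        track = score(five_point(0, 100, 100), ScoreParams(window=2))
        assert track.values[2] == pytest.approx(1.0)

    def test_maxmax_takes_deeper_directional_drop(self):
        track = score_maxmax(five_point(50, 100, 200), ScoreParams(window=2))
        assert track.values[2] == pytest.approx(0.75)

    def test_mean_averages_directional_drops(self):
        track = score_mean(five_point(50, 100, 200), ScoreParams(window=2))
        assert track.values[2] == pytest.approx(0.625)

    def test_score_a_symmetric_half_protection(self):
        track = score_a(five_point(50, 100, 100), ScoreParams(window=2))
        assert track.values[2] == pytest.approx(0.5)

    def test_methscore_goes_negative_when_overcleaved(self):
        track = methscore(five_point(300, 100, 100), ScoreParams(window=2))
        assert track.values[2] == pytest.approx(-2.0)

    def test_max_and_mean_coincide_on_symmetric_sides(self):
        prof = five_point(40, 100, 100)
        params = ScoreParams(window=2)
        assert score_max(prof, params).values[2] == pytest.approx(
            score_mean(prof, params).values[2]
        )


class TestMasking:
    def test_terminal_positions_masked(self, uniform_profile):
        for w in (2, 4):
            track = score_mean(uniform_profile, ScoreParams(window=w))
            assert not track.valid[:w].any() and not track.valid[-w:].any()
            assert track.valid[w:-w].all()

    def test_zero_neighborhood_masked_not_scored(self):
        countn = np.full(20, 100)
        countn[5:12] = 0  # dead zone: both neighbor means vanish mid-zone
        track = score_a(make_profile(countn), ScoreParams(window=2))
        assert not track.valid[8]  # center of the dead zone
        assert track.valid[3]

    def test_maxmax_survives_one_dead_side(self):
        countn = np.array([0, 0, 50, 100, 100, 100, 100])
        track = score_maxmax(make_profile(countn), ScoreParams(window=2))
        assert track.valid[2]  # left mean is 0 but right side defined
        assert track.values[2] == pytest.approx(0.5)
        assert not score_mean(make_profile(countn), ScoreParams(window=2)).valid[2]

    def test_reference_shorter_than_window_errors(self):
        with pytest.raises(ValueError, match="too short"):
            score_mean(make_profile([1, 2, 3]), ScoreParams(window=2))


class TestOracleEquivalence:
    @pytest.mark.parametrize("window", [1, 2, 3, 6])
    def test_matches_naive_formulas(self, window, rng):
        params = ScoreParams(window=window)
        for _ in range(50):
            count5 = rng.poisson(80, 40)
            count3 = rng.poisson(30, 40)
            prof = make_profile(count3, count5=count5)
            expected = naive_scores(count5, count3, window, list(params.weights))
            for func, name in zip(ALL_SCORES, ("max", "maxmax", "mean", "a", "methscore")):
                track = func(prof, params)
                for i in range(40):
                    if expected[name][i] is None:
                        if params.window <= i < 40 - params.window:
                            assert not track.valid[i]
                    else:
                        assert track.valid[i]
                        assert track.values[i] == pytest.approx(
                            expected[name][i], rel=1e-12, abs=1e-12
                        )

    def test_custom_weights_respected(self, rng):
        params = ScoreParams(window=3, weights=(1.0, 0.5, 0.25))
        count5 = rng.poisson(60, 30)
        count3 = rng.poisson(25, 30)
        prof = make_profile(count3, count5=count5)
        expected = naive_scores(count5, count3, 3, [1.0, 0.5, 0.25])
        track = methscore(prof, params)
        for i in range(3, 27):
            assert track.values[i] == pytest.approx(expected["methscore"][i], rel=1e-12)


class TestInvariants:
    @given(scale=st.integers(min_value=2, max_value=1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariance(self, scale):
        """Scores are count ratios: rescaling library depth changes nothing."""
        rng = np.random.default_rng(7)
        countn = rng.poisson(50, 30) + 1
        base = make_profile(countn)
        scaled = make_profile(countn * scale)
        for func in ALL_SCORES:
            a, b = func(base), func(scaled)
            assert np.array_equal(a.valid, b.valid)
            assert np.allclose(a.values[a.valid], b.values[b.valid], rtol=1e-9)

    def test_reversal_symmetry(self, rng):
        """Reversing the profile swaps the directional drops, leaving the
        symmetric scores invariant and mirroring ScoreMAX."""
        countn = rng.poisson(60, 35) + 1
        fwd = make_profile(countn)
        rev = make_profile(countn[::-1])
        for func in (score_mean, score_maxmax, score_a, methscore):
            a, b = func(fwd), func(rev)
            assert np.array_equal(a.valid, b.valid[::-1])
            assert np.allclose(a.values, b.values[::-1])
        # ScoreMAX on the reversed profile reads the 3'->5' drop, so it is
        # bounded above by MAX-MAX of the forward profile and differs from MAX
        mx_rev = score_max(rev).values[::-1]
        mm_fwd = score_maxmax(fwd).values
        valid = score_max(rev).valid[::-1]
        assert np.all(mx_rev[valid] <= mm_fwd[valid] + 1e-12)

    def test_maxmax_dominates_max(self, rng):
        countn = rng.poisson(40, 30) + 1
        prof = make_profile(countn)
        mx, mm = score_max(prof), score_maxmax(prof)
        joint = mx.valid & mm.valid
        assert np.all(mm.values[joint] >= mx.values[joint] - 1e-12)

    def test_clamped_scores_bounded(self, rng):
        countn = rng.poisson(20, 50)
        prof = make_profile(countn)
        for func in (score_max, score_maxmax, score_mean, score_a):
            track = func(prof)
            vals = track.values[track.valid]
            assert np.all(vals >= 0) and np.all(vals <= 1)
        ms = methscore(prof)
        assert np.all(ms.values[ms.valid] <= 1.0)

    def test_methscore_is_one_iff_count_zero(self, rng):
        countn = rng.poisson(30, 40) + 1
        countn[10] = 0
        track = methscore(make_profile(countn))
        hits = np.flatnonzero(track.valid & (track.values == 1.0))
        assert hits.tolist() == [10]


class TestScoreD:
    def test_identical_inputs_reduce_to_normalized_track(self, rng):
        countn = rng.poisson(50, 30) + 1
        prof = make_profile(countn)
        a = score_a(prof)
        d = score_d(a, a)
        vv = a.values[a.valid]
        expected = (vv - vv.min()) / (vv.max() - vv.min())
        assert np.allclose(d.values[d.valid], expected)

    def test_constant_track_normalizes_to_zero(self, uniform_profile, rng):
        const = score_a(uniform_profile)  # all zeros
        assert np.allclose(const.values[const.valid], 0.0)
        countn = rng.poisson(50, 30) + 1
        varying = score_mean(make_profile(countn))
        d = score_d(score_a(uniform_profile), varying)
        vv = varying.values[varying.valid]
        expected = 0.5 * (vv - vv.min()) / (vv.max() - vv.min())
        assert np.allclose(d.values[d.valid], expected)

    def test_matches_normalize_then_average_oracle(self, rng):
        countn = rng.poisson(70, 50) + 1
        prof = make_profile(countn)
        a, m = score_a(prof), score_mean(prof)
        d = score_d(a, m)
        expected = naive_score_d(
            a.values.tolist(), a.valid.tolist(), m.values.tolist(), m.valid.tolist()
        )
        for i, exp in enumerate(expected):
            if exp is None:
                assert not d.valid[i]
            else:
                assert d.values[i] == pytest.approx(exp, rel=1e-12, abs=1e-12)
        assert np.all((d.values >= 0) & (d.values <= 1))

    def test_mismatched_inputs_rejected(self, rng):
        countn = rng.poisson(50, 30) + 1
        prof = make_profile(countn)
        other = make_profile(countn, ref_name="other")
        with pytest.raises(ValueError, match="reference"):
            score_d(score_a(prof), score_mean(other))
        with pytest.raises(ValueError, match="window"):
            score_d(score_a(prof, ScoreParams(window=2)), score_mean(prof, ScoreParams(window=3)))


class TestSweep:
    def test_single_window_reduces_to_direct_call(self, rng):
        countn = rng.poisson(50, 40) + 1
        prof = make_profile(countn)
        [track] = score_sweep(prof, "mean", [2])
        direct = score_mean(prof, ScoreParams(window=2))
        assert np.array_equal(track.values, direct.values)

    def test_valid_count_shrinks_with_window(self, rng):
        countn = rng.poisson(50, 40) + 1
        tracks = score_sweep(make_profile(countn), "a", [2, 4, 6, 8])
        counts = [int(t.valid.sum()) for t in tracks]
        assert counts == sorted(counts, reverse=True)
        assert all(a > b for a, b in zip(counts, counts[1:]))


class TestTrackIO:
    def test_round_trip(self, tmp_path, rng):
        countn = rng.poisson(50, 25) + 1
        prof = make_profile(countn)
        tracks = [score_mean(prof), methscore(prof)]
        path = tmp_path / "scores.tsv"
        save_tracks(tracks, path)
        loaded = {t.score_name: t for t in load_tracks(path)}
        for orig in tracks:
            back = loaded[orig.score_name]
            assert np.array_equal(back.valid, orig.valid)
            assert np.allclose(back.values, orig.values)
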
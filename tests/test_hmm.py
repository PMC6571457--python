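"""Movement HMM: regularization, step/angle geometry, likelihood, decoding, budgets."""

import numpy as np
import pandas as pd
import pytest

from colonyforage import HMMParams, geo, hmm, synth
from colonyforage.errors import InvalidParamsError

COLONY = (54.0, -5.0)


def toy_params(**kw):
    defaults = dict(
        mean=np.array([0.05, 0.5, 2.0]),
        sd=np.array([0.04, 0.3, 0.8]),
        kappa=np.array([0.5, 1.0, 8.0]),
        tpm=np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]]),
    )
    defaults.update(kw)
    return HMMParams(**defaults)


# ---------------------------------------------------------------------------
# parameter validation and bookkeeping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [
    dict(mean=np.array([0.0, 0.5, 2.0])),
    dict(sd=np.array([0.04, -0.3, 0.8])),
    dict(kappa=np.array([-1.0, 1.0, 8.0])),
    dict(tpm=np.array([[0.5, 0.5, 0.5], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])),
    dict(zero_mass=np.array([0.1, 1.0, 0.0])),
])
def test_invalid_params_rejected(bad):
    with pytest.raises(InvalidParamsError):
        toy_params(**bad).validate()


def test_stationary_distribution_is_fixed_point():
    p = toy_params()
    pi = p.stationary()
    np.testing.assert_allclose(pi @ p.tpm, pi, atol=1e-12)
    assert pi.sum() == pytest.approx(1.0)


def test_state_relabelling_by_mean_step_length():
    scrambled = toy_params(mean=np.array([2.0, 0.05, 0.5]),
                           sd=np.array([0.8, 0.04, 0.3]),
                           kappa=np.array([8.0, 0.5, 1.0]))
    ordered, perm = scrambled.sorted_by_mean()
    np.testing.assert_allclose(ordered.mean, [0.05, 0.5, 2.0])
    np.testing.assert_allclose(ordered.kappa, [0.5, 1.0, 8.0])
    # transition rows permuted consistently
    np.testing.assert_allclose(ordered.tpm, scrambled.tpm[np.ix_(perm, perm)])


# ---------------------------------------------------------------------------
# steps and angles
# ---------------------------------------------------------------------------

def test_square_path_steps_and_left_turns():
    xy = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
    steps, angles = hmm.steps_angles(xy)
    np.testing.assert_allclose(steps, [1, 1, 1])
    np.testing.assert_allclose(angles, [np.pi / 2, np.pi / 2])


def test_collinear_positions_zero_angle():
    xy = np.column_stack([np.arange(4.0), np.zeros(4)])
    _, angles = hmm.steps_angles(xy)
    np.testing.assert_allclose(angles, [0.0, 0.0], atol=1e-12)


def test_right_turn_is_negative():
    xy = np.array([[0, 0], [1, 0], [1, -1]], dtype=float)
    _, angles = hmm.steps_angles(xy)
    assert angles[0] == pytest.approx(-np.pi / 2)


def test_zero_length_step_gives_missing_angle():
    xy = np.array([[0, 0], [1, 0], [1, 0], [2, 0]], dtype=float)
    steps, angles = hmm.steps_angles(xy)
    assert steps[1] == 0.0
    assert np.isnan(angles[0]) and np.isnan(angles[1])


# ---------------------------------------------------------------------------
# regularization
# ---------------------------------------------------------------------------

def fixes_frame(times, xy_km):
    lat, lon = geo.aeq_inverse(np.asarray(xy_km)[:, 0], np.asarray(xy_km)[:, 1],
                               *COLONY)
    return pd.DataFrame({"timestamp": pd.to_datetime(times, utc=True),
                         "lat": np.atleast_1d(lat), "lon": np.atleast_1d(lon)})


def test_regularize_identity_on_lattice_fixes():
    t0 = pd.Timestamp("2015-06-01 10:00", tz="UTC")
    times = [t0 + pd.Timedelta(minutes=5 * i) for i in range(6)]
    xy = np.column_stack([np.linspace(0, 5, 6), np.linspace(0, 2, 6)])
    (track,) = hmm.regularize(fixes_frame(times, xy), COLONY, dt_min=5)
    np.testing.assert_allclose(track.xy, xy, atol=1e-6)


def test_regularize_inserts_midpoint():
    t0 = pd.Timestamp("2015-06-01 10:00", tz="UTC")
    times = [t0, t0 + pd.Timedelta(minutes=10), t0 + pd.Timedelta(minutes=20)]
    xy = np.array([[0.0, 0.0], [2.0, 4.0], [4.0, 0.0]])
    (track,) = hmm.regularize(fixes_frame(times, xy), COLONY, dt_min=5)
    assert track.n == 5
    np.testing.assert_allclose(track.xy[1], [1.0, 2.0], atol=1e-6)


def test_regularize_breaks_at_long_gaps():
    """A 6 h gap with a 1 h max gap yields two segments, nothing interpolated inside."""
    t0 = pd.Timestamp("2015-06-01 08:00", tz="UTC")
    times = ([t0 + pd.Timedelta(minutes=5 * i) for i in range(5)]
             + [t0 + pd.Timedelta(hours=6) + pd.Timedelta(minutes=5 * i) for i in range(5)])
    xy = np.column_stack([np.arange(10.0), np.zeros(10)])
    tracks = hmm.regularize(fixes_frame(times, xy), COLONY, dt_min=5, max_gap_min=60)
    assert len(tracks) == 2
    assert all(tr.n == 5 for tr in tracks)


def test_regularize_skips_too_short_trips():
    t0 = pd.Timestamp("2015-06-01 08:00", tz="UTC")
    times = [t0, t0 + pd.Timedelta(minutes=4)]
    assert hmm.regularize(fixes_frame(times, np.zeros((2, 2))), COLONY, dt_min=5) == []


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------

def test_one_state_fit_recovers_gamma_mean():
    """With one state the step-mean MLE is the sample mean (gamma closed form);
    at n = 5000 it sits within 5% of truth."""
    rng = np.random.default_rng(0)
    p1 = HMMParams(mean=np.array([0.4]), sd=np.array([0.25]), kappa=np.array([1.0]),
                   tpm=np.array([[1.0]]))
    seqs = synth.simulate_hmm_steps(p1, 10, 500, rng)
    tracks = [(s, a) for s, a, _ in seqs]
    fit = hmm.fit_hmm(tracks, starts=p1, n_restarts=1, seed=0)
    all_steps = np.concatenate([s for s, _ in tracks])
    assert fit.params.mean[0] == pytest.approx(all_steps.mean(), rel=1e-3)
    assert fit.params.mean[0] == pytest.approx(0.4, rel=0.05)


def test_fit_deterministic_given_starts_and_seed():
    rng = np.random.default_rng(1)
    p = toy_params()
    seqs = synth.simulate_hmm_steps(p, 8, 100, rng)
    tracks = [(s, a) for s, a, _ in seqs]
    f1 = hmm.fit_hmm(tracks, starts=p, n_restarts=2, seed=7)
    f2 = hmm.fit_hmm(tracks, starts=p, n_restarts=2, seed=7)
    assert f1.loglik == f2.loglik
    np.testing.assert_array_equal(f1.params.mean, f2.params.mean)
    np.testing.assert_array_equal(f1.params.tpm, f2.params.tpm)


def test_zero_step_without_mass_is_impossible_event():
    """A zero step has zero density in every state when no point mass is set:
    the forward likelihood is -inf and Viterbi reports the offending step."""
    p = toy_params()
    steps = np.array([0.5, 0.0, 0.4])
    angles = np.array([np.nan, 0.1, -0.2])
    assert hmm.forward_loglik(p, [(steps, angles)]) == -np.inf
    with pytest.raises(FloatingPointError, match="step 1"):
        hmm.viterbi(p, (steps, angles))


def test_zero_steps_handled_by_point_mass():
    rng = np.random.default_rng(2)
    p = toy_params(zero_mass=np.array([0.3, 0.0, 0.0]))
    seqs = synth.simulate_hmm_steps(p, 10, 200, rng)
    tracks = [(s, a) for s, a, _ in seqs]
    assert any((s == 0).any() for s, _ in tracks)
    fit = hmm.fit_hmm(tracks, starts=toy_params(), n_restarts=1, seed=0)
    assert np.isfinite(fit.loglik)
    # rest state should recover a substantial zero-step mass
    assert fit.params.zero_mass[0] > 0.1


def test_refit_from_truth_never_worse_than_truth():
    rng = np.random.default_rng(3)
    p = toy_params()
    seqs = synth.simulate_hmm_steps(p, 20, 150, rng)
    tracks = [(s, a) for s, a, _ in seqs]
    ll_truth = hmm.forward_loglik(p, tracks)
    fit = hmm.fit_hmm(tracks, starts=p, n_restarts=1, seed=0)
    assert fit.loglik >= ll_truth - 1e-6


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def test_viterbi_identity_tpm_constant_path():
    p = toy_params(tpm=np.eye(3), delta=np.array([1.0, 0.0, 0.0]))
    rng = np.random.default_rng(4)
    steps = rng.gamma(2.0, 1.0, 30)
    angles = np.concatenate([[np.nan], rng.vonmises(0, 1, 29)])
    path = hmm.viterbi(p, (steps, angles))
    assert (path == 0).all()


def test_viterbi_high_separation_recovers_true_states():
    """Strongly separated emissions: >= 95% agreement with the simulated path."""
    p = toy_params(mean=np.array([0.05, 0.5, 5.0]),
                   sd=np.array([0.02, 0.15, 1.0]))
    rng = np.random.default_rng(5)
    seqs = synth.simulate_hmm_steps(p, 10, 300, rng)
    agree = []
    for steps, angles, states in seqs:
        path = hmm.viterbi(p, (steps, angles))
        agree.append((path == states).mean())
    assert np.mean(agree) >= 0.95


def test_viterbi_beats_constant_paths():
    """The decoded path is at least as likely as any single-state path."""
    p = toy_params()
    rng = np.random.default_rng(6)
    steps, angles, _ = synth.simulate_hmm_steps(p, 1, 40, rng)[0]

    def path_loglik(path):
        logb = hmm.log_emissions(p, steps, angles)
        with np.errstate(divide="ignore"):
            ll = np.log(p.initial_distribution()[path[0]]) + logb[0, path[0]]
            for t in range(1, len(path)):
                ll += np.log(p.tpm[path[t - 1], path[t]]) + logb[t, path[t]]
        return ll

    best = path_loglik(hmm.viterbi(p, (steps, angles)))
    for s in range(3):
        assert best >= path_loglik(np.full(len(steps), s)) - 1e-9


def test_time_budget_arithmetic_and_normalization():
    states = {"bird1": [np.array([0] * 30 + [1] * 50 + [2] * 20)],
              "bird2": [np.array([2] * 10), np.array([2] * 5)]}
    out = hmm.time_budget(states).set_index("bird_id")
    assert out.loc["bird1", "p_rest"] == pytest.approx(0.3)
    assert out.loc["bird1", "p_forage"] == pytest.approx(0.5)
    assert out.loc["bird1", "p_transit"] == pytest.approx(0.2)
    assert out.loc["bird2", "p_transit"] == 1.0
    sums = out[["p_rest", "p_forage", "p_transit"]].sum(axis=1)
    np.testing.assert_allclose(sums, 1.0)


def test_decoded_budgets_match_truth_at_high_separation():
    p = toy_params(mean=np.array([0.05, 0.5, 5.0]), sd=np.array([0.02, 0.15, 1.0]))
    rng = np.random.default_rng(7)
    seqs = synth.simulate_hmm_steps(p, 20, 200, rng)
    decoded = {"b": [hmm.viterbi(p, (s, a)) for s, a, _ in seqs]}
    truth_states = np.concatenate([st for _, _, st in seqs])
    budget = hmm.time_budget(decoded).iloc[0]
    for s, col in enumerate(("p_rest", "p_forage", "p_transit")):
        assert abs(budget[col] - (truth_states == s).mean()) < 0.05
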
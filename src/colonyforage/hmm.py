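"""Hidden Markov model for movement behaviour: rest / forage / transit.

The model follows the standard movement-ecology formulation: at a regular time
interval the animal emits a step length (gamma distributed, state-specific mean
and SD) and a turning angle (von Mises, state-specific concentration), with a
first-order Markov chain over behavioural states.  Parameters are estimated by
direct numerical maximum likelihood of the scaled forward recursion on a
working scale (log for positive parameters, multinomial-logit for transition
rows), and behavioural sequences are decoded with the Viterbi algorithm.

Exact-zero step lengths, which a gamma distribution cannot produce, carry a
per-state point mass; turning angles at zero-length steps are treated as
missing and contribute likelihood one.

State labels carry no meaning during optimization; after fitting, states are
relabelled in increasing order of mean step length (rest < forage < transit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special
from scipy import stats as sps

from . import geo
from .errors import InvalidParamsError

logger = logging.getLogger(__name__)

STATE_NAMES = ("rest", "forage", "transit")


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class HMMParams:
    """Emission and transition parameters for an S-state movement HMM.

    Step lengths are gamma with per-state mean ``mean`` (km) and SD ``sd`` (km);
    turning angles are von Mises with mean ``angle_mean`` (radians, default 0)
    and concentration ``kappa``.  ``tpm`` is the S x S transition probability
    matrix; ``delta`` the initial state distribution (stationary distribution of
    ``tpm`` when omitted); ``zero_mass`` the per-state probability of an
    exact-zero step.
    """

    mean: np.ndarray
    sd: np.ndarray
    kappa: np.ndarray
    tpm: np.ndarray
    delta: np.ndarray | None = None
    angle_mean: np.ndarray | None = None
    zero_mass: np.ndarray | None = None

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.sd = np.atleast_1d(np.asarray(self.sd, dtype=float))
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        self.tpm = np.atleast_2d(np.asarray(self.tpm, dtype=float))
        s = self.n_states
        if self.angle_mean is None:
            self.angle_mean = np.zeros(s)
        else:
            self.angle_mean = np.atleast_1d(np.asarray(self.angle_mean, dtype=float))
        if self.zero_mass is None:
            self.zero_mass = np.zeros(s)
        else:
            self.zero_mass = np.atleast_1d(np.asarray(self.zero_mass, dtype=float))
        if self.delta is not None:
            self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float))

    @property
    def n_states(self) -> int:
        return self.mean.size

    def validate(self):
        s = self.n_states
        for name, arr, shape in (
            ("sd", self.sd, (s,)),
            ("kappa", self.kappa, (s,)),
            ("angle_mean", self.angle_mean, (s,)),
            ("zero_mass", self.zero_mass, (s,)),
            ("tpm", self.tpm, (s, s)),
        ):
            if arr.shape != shape:
                raise InvalidParamsError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.mean <= 0) or np.any(self.sd <= 0):
            raise InvalidParamsError("gamma step mean and SD must be positive")
        if np.any(self.kappa < 0):
            raise InvalidParamsError("von Mises concentration must be non-negative")
        if np.any(self.zero_mass < 0) or np.any(self.zero_mass >= 1):
            raise InvalidParamsError("zero-step mass must lie in [0, 1)")
        if np.any(self.tpm < 0) or not np.allclose(self.tpm.sum(axis=1), 1.0, atol=1e-8):
            raise InvalidParamsError("transition matrix rows must be probabilities summing to 1")
        if self.delta is not None and (
            np.any(self.delta < 0) or not np.isclose(self.delta.sum(), 1.0, atol=1e-8)
        ):
            raise InvalidParamsError("initial distribution must sum to 1")
        return self

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the transition matrix."""
        s = self.n_states
        a = np.vstack([self.tpm.T - np.eye(s), np.ones(s)])
        b = np.zeros(s + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def initial_distribution(self) -> np.ndarray:
        return self.delta if self.delta is not None else self.stationary()

    def gamma_shape_scale(self):
        shape = (self.mean / self.sd) ** 2
        scale = self.sd**2 / self.mean
        return shape, scale

    def reordered(self, perm) -> "HMMParams":
        """Return a copy with states permuted by ``perm`` (new index i = old perm[i])."""
        perm = np.asarray(perm)
        delta = None if self.delta is None else self.delta[perm]
        return HMMParams(
            mean=self.mean[perm],
            sd=self.sd[perm],
            kappa=self.kappa[perm],
            tpm=self.tpm[np.ix_(perm, perm)],
            delta=delta,
            angle_mean=self.angle_mean[perm],
            zero_mass=self.zero_mass[perm],
        )

    def sorted_by_mean(self):
        """Relabel states by increasing mean step length; returns (params, perm)."""
        perm = np.argsort(self.mean, kind="stable")
        return self.reordered(perm), perm

    def to_dict(self) -> dict:
        d = {
            "mean_km": self.mean.tolist(),
            "sd_km": self.sd.tolist(),
            "kappa": self.kappa.tolist(),
            "angle_mean": self.angle_mean.tolist(),
            "zero_mass": self.zero_mass.tolist(),
            "tpm": self.tpm.tolist(),
        }
        if self.delta is not None:
            d["delta"] = self.delta.tolist()
        return d


# ---------------------------------------------------------------------------
# regularized tracks
# ---------------------------------------------------------------------------

@dataclass
class RegularTrack:
    """Positions of one trip (segment) resampled to a fixed interval.

    ``xy`` is an (n, 2) array of planar km coordinates in a local
    azimuthal-equidistant projection; ``times`` the matching timestamps.
    """

    trip_id: str
    dt_min: float
    xy: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)

    @property
    def n(self) -> int:
        return len(self.xy)

    @property
    def steps(self) -> np.ndarray:
        return steps_angles(self.xy)[0]

    @property
    def angles(self) -> np.ndarray:
        return steps_angles(self.xy)[1]

    def observations(self):
        """Return (steps, angles) aligned per step: the angle attached to step t
        is the heading change into that step; the first step has no angle (NaN)."""
        steps, angles = steps_angles(self.xy)
        obs_angles = np.concatenate([[np.nan], angles]) if steps.size else angles
        return steps, obs_angles


def steps_angles(xy):
    """Step lengths and signed turning angles of a planar track.

    Steps are Euclidean distances between consecutive positions; the turning
    angle is the change in heading between consecutive steps, counterclockwise
    positive, wrapped to (-pi, pi].  Angles adjacent to a zero-length step are
    returned as NaN (heading undefined).
    """
    xy = np.asarray(xy, dtype=float)
    d = np.diff(xy, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    if len(steps) < 2:
        return steps, np.empty(0)
    with np.errstate(invalid="ignore"):
        headings = np.arctan2(d[:, 1], d[:, 0])
    headings = np.where(steps > 0, headings, np.nan)
    angles = geo.wrap_angle(np.diff(headings))
    angles = np.where(np.isnan(headings[:-1]) | np.isnan(headings[1:]), np.nan, angles)
    return steps, angles


def regularize(fixes, colony_latlon, dt_min: float = 5.0, max_gap_min: float = 25.0,
               trip_id: str = "trip") -> list:
    """Linearly interpolate a trip's fixes onto a regular time lattice.

    Fixes are projected to planar km about the colony, then x and y are
    interpolated at times ``t0, t0 + dt, ...``.  Raw gaps longer than
    ``max_gap_min`` (for example the overnight logger-off window) split the trip
    into separate segments rather than fabricating positions across the gap.
    Segments with fewer than three lattice positions (no turning angle) are
    dropped with a log message.
    """
    times = np.asarray(fixes["timestamp"].astype("int64"), dtype=float) / 60e9  # minutes
    lat = np.asarray(fixes["lat"], dtype=float)
    lon = np.asarray(fixes["lon"], dtype=float)
    if len(times) < 2 or times[-1] - times[0] < 2 * dt_min:
        logger.info("trip %s shorter than two intervals; skipped", trip_id)
        return []
    x, y = geo.aeq_project(lat, lon, colony_latlon[0], colony_latlon[1])
    gaps = np.diff(times)
    breakpoints = np.flatnonzero(gaps > max_gap_min)
    starts = np.concatenate([[0], breakpoints + 1])
    ends = np.concatenate([breakpoints, [len(times) - 1]])
    tracks = []
    for k, (i0, i1) in enumerate(zip(starts, ends)):
        if i1 - i0 < 1:
            continue
        t0, t1 = times[i0], times[i1]
        lattice = t0 + dt_min * np.arange(int(np.floor((t1 - t0) / dt_min)) + 1)
        if len(lattice) < 3:
            logger.info("segment %s/%d too short after regularization; skipped", trip_id, k)
            continue
        xi = np.interp(lattice, times[i0 : i1 + 1], x[i0 : i1 + 1])
        yi = np.interp(lattice, times[i0 : i1 + 1], y[i0 : i1 + 1])
        suffix = f"{trip_id}" if len(starts) == 1 else f"{trip_id}.{k}"
        tracks.append(RegularTrack(trip_id=suffix, dt_min=dt_min,
                                   xy=np.column_stack([xi, yi]), times=lattice))
    return tracks


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _log_vonmises(x, mu, kappa):
    # log I0 computed via exponentially scaled Bessel for stability at large kappa
    return kappa * np.cos(x - mu) - np.log(2 * np.pi) - (np.log(special.ive(0, kappa)) + kappa)


def log_emissions(params: HMMParams, steps, angles):
    """Per-state log emission densities, shape ``steps.shape + (S,)``.

    Missing steps or angles (NaN) contribute zero log density.  Exact-zero
    steps take the state's zero-step point mass.
    """
    steps = np.asarray(steps, dtype=float)
    angles = np.asarray(angles, dtype=float)
    shape, scale = params.gamma_shape_scale()
    out = np.zeros(steps.shape + (params.n_states,))
    step_ok = np.isfinite(steps)
    ang_ok = np.isfinite(angles)
    for s in range(params.n_states):
        lp = np.zeros(steps.shape)
        pos = step_ok & (steps > 0)
        zero = step_ok & (steps == 0)
        if np.any(pos):
            lp_pos = sps.gamma.logpdf(steps[pos], shape[s], scale=scale[s])
            if params.zero_mass[s] > 0:
                lp_pos = lp_pos + np.log1p(-params.zero_mass[s])
            lp[pos] = lp_pos
        if np.any(zero):
            with np.errstate(divide="ignore"):
                lp[zero] = np.log(params.zero_mass[s])
        if np.any(ang_ok):
            lp[ang_ok] += _log_vonmises(angles[ang_ok], params.angle_mean[s], params.kappa[s])
        out[..., s] = lp
    return out


def _pack_observations(sequences):
    """Pad a list of (steps, angles) pairs into NaN-padded matrices."""
    lengths = np.array([len(s) for s, _ in sequences], dtype=int)
    tmax = int(lengths.max())
    S = np.full((len(sequences), tmax), np.nan)
    A = np.full((len(sequences), tmax), np.nan)
    for i, (s, a) in enumerate(sequences):
        S[i, : len(s)] = s
        A[i, : len(a)] = a
    return S, A, lengths


def _as_sequences(tracks):
    seqs = []
    for tr in tracks:
        if isinstance(tr, RegularTrack):
            seqs.append(tr.observations())
        else:
            steps, angles = tr
            seqs.append((np.asarray(steps, dtype=float), np.asarray(angles, dtype=float)))
    return seqs


def forward_loglik(params: HMMParams, tracks) -> float:
    """Total log likelihood of the tracks under ``params`` (scaled forward algorithm).

    ``tracks`` is a list of :class:`RegularTrack` or of ``(steps, angles)``
    pairs, with angles aligned per step (first angle NaN).
    """
    seqs = _as_sequences(tracks)
    S, A, lengths = _pack_observations(seqs)
    logb = log_emissions(params, S, A)  # (N, T, S)
    return _batched_forward(params, logb, lengths)


def _batched_forward(params: HMMParams, logb, lengths) -> float:
    n, tmax, s = logb.shape
    # per-(track, time) scaling of emissions so exp() stays in range
    bmax = logb.max(axis=2)
    bmax = np.where(np.isfinite(bmax), bmax, 0.0)
    b = np.exp(logb - bmax[:, :, None])  # (N, T, S)
    delta = params.initial_distribution()
    alpha = delta[None, :] * b[:, 0, :]
    c = alpha.sum(axis=1)
    if np.any(c <= 0):
        return -np.inf
    loglik = np.log(c) + bmax[:, 0]
    alpha = alpha / c[:, None]
    tpm = params.tpm
    for t in range(1, tmax):
        active = lengths > t
        if not np.any(active):
            break
        a_new = (alpha @ tpm) * b[:, t, :]
        c = a_new.sum(axis=1)
        bad = active & (c <= 0)
        if np.any(bad):
            return -np.inf
        safe_c = np.where(c > 0, c, 1.0)
        a_new = a_new / safe_c[:, None]
        alpha = np.where(active[:, None], a_new, alpha)
        loglik = loglik + np.where(active, np.log(safe_c) + bmax[:, t], 0.0)
    return float(loglik.sum())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class HMMFit:
    """Result of :func:`fit_hmm`: relabelled parameters plus diagnostics."""

    params: HMMParams
    loglik: float
    converged: bool
    message: str = ""
    n_restarts: int = 1
    restart_logliks: list = field(default_factory=list)
    state_names: tuple = STATE_NAMES


def _pack_params(params: HMMParams, estimate_zero_mass: bool, estimate_angle_mean: bool):
    s = params.n_states
    theta = [np.log(params.mean), np.log(params.sd), np.log(np.maximum(params.kappa, 1e-4))]
    off = []
    for i in range(s):
        row = np.maximum(params.tpm[i], 1e-12)
        for j in range(s):
            if j != i:
                off.append(np.log(row[j] / row[i]))
    theta.append(np.array(off))
    if estimate_zero_mass:
        z = np.clip(params.zero_mass, 1e-6, 1 - 1e-6)
        theta.append(np.log(z / (1 - z)))
    if estimate_angle_mean:
        theta.append(params.angle_mean.copy())
    return np.concatenate(theta)


def _unpack_params(theta, s: int, estimate_zero_mass: bool, estimate_angle_mean: bool) -> HMMParams:
    k = 0
    mean = np.exp(theta[k : k + s]); k += s
    sd = np.exp(theta[k : k + s]); k += s
    kappa = np.exp(theta[k : k + s]); k += s
    tpm = np.zeros((s, s))
    for i in range(s):
        logits = np.zeros(s)
        for j in range(s):
            if j != i:
                logits[j] = theta[k]; k += 1
        logits -= logits.max()
        row = np.exp(logits)
        tpm[i] = row / row.sum()
    if estimate_zero_mass:
        zm = 1.0 / (1.0 + np.exp(-theta[k : k + s])); k += s
    else:
        zm = np.zeros(s)
    if estimate_angle_mean:
        am = geo.wrap_angle(theta[k : k + s]); k += s
    else:
        am = np.zeros(s)
    return HMMParams(mean=mean, sd=sd, kappa=kappa, tpm=tpm, delta=None,
                     angle_mean=am, zero_mass=zm)


def fit_hmm(tracks, starts: HMMParams, n_restarts: int = 5, seed: int = 0,
            estimate_angle_mean: bool = False, maxiter: int = 300) -> HMMFit:
    """Fit the movement HMM to a set of regularized tracks by direct numerical ML.

    The best of ``n_restarts`` quasi-Newton optimizations is returned; the first
    restart starts exactly at ``starts`` and later ones perturb the starting
    values by ~20% multiplicative jitter.  The initial state distribution is
    tied to the stationary distribution of the transition matrix (each track
    segment begins a fresh stationary chain).  States in the result are
    relabelled by increasing mean step length.

    Raises
    ------
    InvalidParamsError
        If the likelihood is not finite at the starting values (for example a
        zero step with no zero-step mass).
    """
    starts.validate()
    seqs = _as_sequences(tracks)
    if not seqs:
        raise InvalidParamsError("no tracks to fit")
    S, A, lengths = _pack_observations(seqs)
    total_steps = int(np.isfinite(S).sum())
    if total_steps < 100:
        logger.warning("only %d steps available; HMM fit may be unstable", total_steps)
    has_zero = bool(np.any(S[np.isfinite(S)] == 0))
    estimate_zero_mass = has_zero
    start = starts
    if has_zero and np.all(starts.zero_mass == 0):
        zfrac = float((S[np.isfinite(S)] == 0).mean())
        start = replace_zero_mass(starts, np.full(starts.n_states, max(zfrac, 1e-3)))
    s = start.n_states

    def negloglik(theta):
        p = _unpack_params(theta, s, estimate_zero_mass, estimate_angle_mean)
        logb = log_emissions(p, S, A)
        ll = _batched_forward(p, logb, lengths)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    theta0 = _pack_params(start, estimate_zero_mass, estimate_angle_mean)
    ll0 = -negloglik(theta0)
    if not np.isfinite(ll0) or ll0 <= -1e11:
        raise InvalidParamsError(
            "log likelihood is not finite at the starting parameters "
            f"(starts: mean={start.mean}, sd={start.sd}, zero_mass={start.zero_mass})"
        )
    rng = np.random.default_rng(seed)
    best = None
    restart_lls = []
    for r in range(max(1, n_restarts)):
        if r == 0:
            th = theta0
        else:
            th = theta0 + rng.normal(0.0, 0.2, size=theta0.shape)
        res = optimize.minimize(negloglik, th, method="L-BFGS-B",
                                options={"maxiter": maxiter, "ftol": 1e-10})
        restart_lls.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    fitted = _unpack_params(best.x, s, estimate_zero_mass, estimate_angle_mean)
    fitted, _ = fitted.sorted_by_mean()
    converged = bool(best.success)
    if not converged:
        logger.warning("HMM optimizer did not report convergence: %s", best.message)
    return HMMFit(params=fitted, loglik=float(-best.fun), converged=converged,
                  message=str(best.message), n_restarts=max(1, n_restarts),
                  restart_logliks=restart_lls)


def replace_zero_mass(params: HMMParams, zero_mass) -> HMMParams:
    return HMMParams(mean=params.mean, sd=params.sd, kappa=params.kappa, tpm=params.tpm,
                     delta=params.delta, angle_mean=params.angle_mean,
                     zero_mass=np.asarray(zero_mass, dtype=float))


# ---------------------------------------------------------------------------
# decoding and time budgets
# ---------------------------------------------------------------------------

def viterbi(params: HMMParams, track) -> np.ndarray:
    """Most probable state path for one track (log-space Viterbi).

    Ties are broken toward the lower state index.  Raises a ``FloatingPointError``
    naming the offending time step if every state has zero emission density.
    """
    params.validate()
    if isinstance(track, RegularTrack):
        steps, angles = track.observations()
    else:
        steps, angles = track
    logb = log_emissions(params, np.asarray(steps, dtype=float), np.asarray(angles, dtype=float))
    t_len = len(steps)
    if t_len == 0:
        return np.empty(0, dtype=int)
    if np.any(np.all(~np.isfinite(logb), axis=1)):
        bad = int(np.flatnonzero(np.all(~np.isfinite(logb), axis=1))[0])
        raise FloatingPointError(f"zero emission density for every state at step {bad}")
    with np.errstate(divide="ignore"):
        log_delta = np.log(params.initial_distribution())
        log_tpm = np.log(params.tpm)
    score = log_delta + logb[0]
    back = np.zeros((t_len, params.n_states), dtype=int)
    for t in range(1, t_len):
        cand = score[:, None] + log_tpm  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # argmax -> first (lowest) index on ties
        score = cand[back[t], np.arange(params.n_states)] + logb[t]
    path = np.zeros(t_len, dtype=int)
    path[-1] = int(np.argmax(score))
    for t in range(t_len - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def decode_tracks(params: HMMParams, tracks) -> list:
    """Viterbi-decode each track; returns a list of state index arrays."""
    return [viterbi(params, tr) for tr in tracks]


def time_budget(states_by_bird: dict, n_states: int = 3):
    """Proportion of decoded positions per state for each bird.

    Parameters
    ----------
    states_by_bird
        Mapping from bird id to a list of decoded state arrays (one per track).

    Returns
    -------
    pandas.DataFrame
        One row per bird with columns ``p_rest, p_forage, p_transit`` (for the
        3-state model) summing to 1.
    """
    import pandas as pd

    rows = []
    for bird, seqs in states_by_bird.items():
        allstates = np.concatenate([np.asarray(s) for s in seqs]) if seqs else np.empty(0, int)
        if allstates.size == 0:
            continue
        counts = np.bincount(allstates, minlength=n_states).astype(float)
        props = counts / counts.sum()
        row = {"bird_id": bird, "n_positions": int(allstates.size)}
        names = STATE_NAMES if n_states == 3 else tuple(f"state{i}" for i in range(n_states))
        for i, name in enumerate(names):
            row[f"p_{name}"] = props[i]
        rows.append(row)
    return pd.DataFrame(rows)
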
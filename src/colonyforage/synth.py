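"""Synthetic worlds: environmental rasters, central-place GPS tracks, breeding success.

Every downstream stage of the analysis (heterogeneity scoring, trip
segmentation, behavioural classification, space-use overlap, regression) is
exercised against worlds generated here with known ground truth: the
environmental patchiness of each colony, the movement-model parameters, the
behavioural time budgets, the hotspot structure that drives overlap between
individuals, and the slope linking heterogeneity to breeding success are all
set by configuration and recorded in a truth sidecar.

Environmental layers are Gaussian random fields (smoothed white noise) whose
amplitude scales with each colony's heterogeneity target.  Tracks are simulated
from the configured hidden Markov movement model in a local planar projection
anchored at the colony; a weak homeward bias on transit-state headings makes
trips return to the colony, and colony-attendance blocks between trips plus a
continuous multi-day timeline produce the colony-proximal and night-time fixes
that trip filtering must remove.

The generator emulates the *statistical* structure of colony-based seabird
tracking data; it makes no attempt at ocean-physics realism (fronts and
stratification are stand-in random fields, not dynamical objects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import geo
from .errors import InvalidConfigError, InvalidParamsError
from .hmm import HMMParams, STATE_NAMES
from .rasters import LAYER_NAMES, EnvRasterStack

#: per-layer (base level, amplitude scale) in native units; the amplitude is
#: further multiplied by the colony's heterogeneity target
_LAYER_BASE_SCALE = {
    "bathymetry": (-60.0, 25.0),          # m
    "tidal_stratification": (2.5, 0.8),   # dimensionless index
    "sst": (12.5, 0.7),                   # deg C
    "front_strength": (0.4, 0.15),        # gradient magnitude, native units
    "front_distance": (15.0, 6.0),        # km
    "front_persistence": (0.35, 0.12),    # fraction of scenes
}


def default_hmm_truth() -> HMMParams:
    """Movement-model truth typical of 5-minute kittiwake GPS data.

    Rest: short drift steps with diffuse headings; forage: tortuous
    area-restricted search; transit: long, nearly straight commuting steps.
    The transition matrix combines 0.8 self-persistence with a stationary
    occupancy of (0.25, 0.40, 0.35).
    """
    pi = np.array([0.25, 0.40, 0.35])
    tpm = 0.8 * np.eye(3) + 0.2 * np.outer(np.ones(3), pi)
    return HMMParams(
        mean=np.array([0.03, 0.30, 2.0]),
        sd=np.array([0.02, 0.22, 0.8]),
        kappa=np.array([0.8, 1.2, 12.0]),
        tpm=tpm,
    )


@dataclass
class WorldConfig:
    """Generating parameters of a synthetic multi-colony world.

    The defaults mimic the scale of the study system: 15 colonies around the
    British and Irish coast, a few tens of kilometres of foraging range with a
    mean maximum trip distance near 23 km, 5-minute GPS fixes, and breeding
    success declining by about 0.18 fledglings per nest per SD of environmental
    heterogeneity around an intercept of 0.8.
    """

    n_colonies: int = 15
    n_years: int = 3
    radius_km: float = 28.0
    grid_res_km: float = 2.0
    het_levels: tuple | None = None          # one dimensionless target per colony
    hmm_truth: HMMParams = field(default_factory=default_hmm_truth)
    n_birds: int = 8                          # per colony-year
    n_fixes: int = 400                        # per bird (pre-dropout lattice)
    fix_interval_min: float = 5.0
    dropout: float = 0.0                      # probability a lattice fix is missing
    success_intercept: float = 0.8            # fledglings per nest
    success_slope: float = -0.18              # per SD of heterogeneity target
    success_noise_sd: float = 0.15
    seed: int = 0
    # --- generator plumbing ------------------------------------------------
    length_scale_km: float = 6.0              # smoothing scale of the random fields
    start_year: int = 2015
    tz: str = "Europe/London"
    # behavioural coupling: shift of forage (and opposite shift of transit)
    # stationary occupancy per SD of the heterogeneity target; 0 = use
    # hmm_truth's transition matrix unchanged at every colony
    het_behaviour_coupling: float = 0.0
    rest_share: float = 0.25
    forage_share: float = 0.40
    persistence: float = 0.8
    # hotspot structure: number of shared foraging hotspots per colony-year
    # (fewer hotspots at heterogeneous colonies concentrates birds together)
    hotspot_base_count: float = 4.0
    hotspot_count_shift: float = 0.0
    hotspot_dist_mean_km: float = 21.0
    hotspot_dist_sd_km: float = 3.0       # scatter of private (per-bird) destinations
    hotspot_shared_dist_sd_km: float = 1.5  # scatter of the persistent shared hotspots
    hotspot_sector_deg: float = 120.0     # accessible marine sector holding the hotspots
    # probability that a trip targets a shared hotspot rather than a private
    # location in the sector; rises with standardized heterogeneity when the
    # shift is non-zero (concentrated resources aggregate foragers)
    hotspot_share_base: float = 1.0
    hotspot_share_shift: float = 0.0
    homeward_weight: float = 0.3
    colony_dwell_fixes: tuple = (12, 36)      # fixes per colony-attendance block
    # patch residence is set by a flight-distance budget: the expected total
    # path length of a trip is ``trip_distance_overhead`` times the direct
    # out-and-back commute, independent of the behavioural mix — acquiring
    # resources costs a fixed flight distance, while the *time* this takes
    # scales with how much of the trip is spent in slow behaviours
    trip_distance_overhead: float = 2.0
    # between-bird spread of the distance budget (SD of a log-normal
    # multiplier): individuals differ in how much work a patch demands
    patch_dwell_bird_sd: float = 0.25

    def __post_init__(self):
        if self.het_levels is None:
            self.het_levels = tuple(np.linspace(1.1, 2.4, self.n_colonies))
        self.het_levels = tuple(float(h) for h in self.het_levels)

    def validate(self) -> "WorldConfig":
        if self.grid_res_km <= 0:
            raise InvalidConfigError("grid resolution must be positive")
        if self.fix_interval_min <= 0:
            raise InvalidConfigError("fix interval must be positive")
        if self.n_fixes < 50:
            raise InvalidConfigError("need at least 50 fixes per bird")
        if self.radius_km <= 5 * self.grid_res_km:
            raise InvalidConfigError("foraging radius must exceed 5 grid cells")
        if len(self.het_levels) != self.n_colonies:
            raise InvalidConfigError("need one heterogeneity target per colony")
        if any(h < 0 for h in self.het_levels):
            raise InvalidConfigError("heterogeneity targets must be non-negative")
        if self.success_noise_sd < 0:
            raise InvalidConfigError("success noise SD must be non-negative")
        if not 0 <= self.dropout < 1:
            raise InvalidConfigError("dropout must lie in [0, 1)")
        self.hmm_truth.validate()
        return self

    def het_z(self) -> np.ndarray:
        """Heterogeneity targets standardized across colonies (sample SD)."""
        h = np.asarray(self.het_levels, dtype=float)
        sd = h.std(ddof=1) if h.size > 1 else 0.0
        if sd == 0:
            return np.zeros_like(h)
        return (h - h.mean()) / sd


def endtoend_world(n_colonies: int = 8, n_years: int = 3, n_birds: int = 5,
                   n_fixes: int = 380, seed: int = 0) -> WorldConfig:
    """Desk-scale world with the built-in heterogeneity effects switched on.

    Heterogeneous colonies get a higher stationary forage occupancy (and lower
    transit occupancy, rest unchanged), fewer shared hotspots (raising overlap
    between individuals), and lower breeding success.  Hotspot distance — hence
    maximum trip range — is independent of heterogeneity, and forage/rest steps
    are kept short so that path length stays dominated by commuting; total and
    maximum distance and rest time therefore carry no built-in effect.
    """
    truth = default_hmm_truth()
    # rest: short steps drifting on a consistent heading (surface currents);
    # forage: tortuous area-restricted search; transit: long straight commutes
    truth = HMMParams(mean=np.array([0.03, 0.12, 2.0]), sd=np.array([0.015, 0.06, 0.8]),
                      kappa=np.array([2.0, 0.7, 12.0]), tpm=truth.tpm)
    return WorldConfig(
        n_colonies=n_colonies, n_years=n_years, n_birds=n_birds, n_fixes=n_fixes,
        radius_km=30.0, grid_res_km=3.0, hmm_truth=truth, dropout=0.03,
        het_behaviour_coupling=0.075,
        hotspot_base_count=3.5, hotspot_count_shift=1.5,
        hotspot_dist_mean_km=16.0, hotspot_dist_sd_km=3.0,
        hotspot_share_base=0.5, hotspot_share_shift=0.3,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# colony geometry
# ---------------------------------------------------------------------------

def colony_positions(config: WorldConfig) -> pd.DataFrame:
    """Colony ids and coordinates, laid out on a coarse grid so foraging
    ranges never overlap (spacing ~2 degrees)."""
    rows = []
    for i in range(config.n_colonies):
        rows.append({
            "colony_id": f"colony{i:02d}",
            "lat": 50.5 + 2.0 * (i // 5),
            "lon": -9.0 + 2.5 * (i % 5),
            "het_target": config.het_levels[i],
        })
    return pd.DataFrame(rows)


def _colony_latlon(config: WorldConfig, colony: int):
    return 50.5 + 2.0 * (colony // 5), -9.0 + 2.5 * (colony % 5)


# ---------------------------------------------------------------------------
# environmental rasters
# ---------------------------------------------------------------------------

def gen_env_rasters(config: WorldConfig, colony: int, year: int = 0) -> EnvRasterStack:
    """Six-layer environmental stack for one colony-year.

    Each layer is ``base + scale * het_target * G`` where ``G`` is a smoothed
    white-noise field normalized to unit spatial SD, so the realized
    multivariate dispersion grows monotonically with the colony's target.  A
    target of zero yields spatially constant layers.  Output is bit-identical
    for identical config and seed.
    """
    config.validate()
    lat0, lon0 = _colony_latlon(config, colony)
    res = config.grid_res_km
    half = config.radius_km + 3 * res
    k = int(np.ceil(half / res))
    offsets = np.arange(-k, k + 1) * res
    dlat = res / geo.KM_PER_DEG
    dlon = res / (geo.KM_PER_DEG * np.cos(np.radians(lat0)))
    lat = lat0 + offsets / res * dlat
    lon = lon0 + offsets / res * dlon
    het = config.het_levels[colony]
    sigma = config.length_scale_km / res
    layers = {}
    for li, name in enumerate(LAYER_NAMES):
        base, scale = _LAYER_BASE_SCALE[name]
        rng = np.random.default_rng([config.seed, 11, colony, year, li])
        white = rng.standard_normal((lat.size, lon.size))
        fielded = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
        sd = fielded.std()
        if het > 0 and sd > 0:
            fielded = (fielded - fielded.mean()) / sd
            layers[name] = base + scale * het * fielded
        else:
            layers[name] = np.full((lat.size, lon.size), base)
    return EnvRasterStack(lat=lat, lon=lon, layers=layers)


# ---------------------------------------------------------------------------
# GPS tracks
# ---------------------------------------------------------------------------

def simulate_hmm_steps(params: HMMParams, n_tracks: int, n_steps: int, rng) -> list:
    """Simulate raw (steps, angles, states) sequences from the movement HMM.

    Used for parameter-recovery experiments; no geometry, no homeward drift.
    Angles are aligned per step with the first angle missing (NaN), matching
    :meth:`RegularTrack.observations`.
    """
    params.validate()
    shape, scale = params.gamma_shape_scale()
    delta = params.initial_distribution()
    out = []
    for _ in range(n_tracks):
        states = np.zeros(n_steps, dtype=int)
        states[0] = rng.choice(params.n_states, p=delta)
        for t in range(1, n_steps):
            states[t] = rng.choice(params.n_states, p=params.tpm[states[t - 1]])
        steps = rng.gamma(shape[states], scale[states])
        zm = params.zero_mass[states]
        if np.any(zm > 0):
            steps = np.where(rng.uniform(size=n_steps) < zm, 0.0, steps)
        angles = rng.vonmises(params.angle_mean[states], np.maximum(params.kappa[states], 1e-12))
        angles[0] = np.nan
        out.append((steps, angles, states))
    return out


def _colony_tpm(config: WorldConfig, z: float):
    """Transition matrix and initial distribution for a colony with
    standardized heterogeneity ``z``."""
    c = config.het_behaviour_coupling
    truth = config.hmm_truth
    if c == 0:
        return truth.tpm, truth.initial_distribution()
    transit_share = 1.0 - config.rest_share - config.forage_share
    pi = np.array([
        config.rest_share,
        config.forage_share + c * z,
        transit_share - c * z,
    ])
    if np.any(pi <= 0):
        raise InvalidConfigError("behaviour coupling drives a state occupancy below zero")
    p = config.persistence
    tpm = p * np.eye(3) + (1 - p) * np.outer(np.ones(3), pi)
    return tpm, pi


def _simulate_trip(rng, config: WorldConfig, tpm, delta, hotspot_xy,
                   dwell_mult: float = 1.0, max_steps: int = 900):
    """One foraging trip in planar km anchored at the colony (origin).

    States evolve by the Markov chain; step lengths and turning angles follow
    the state's emission distributions; only transit-state *headings* are
    biased, so state-conditional step distributions stay exactly the
    configured gammas.  The trip has three phases: outbound (transit headings
    nudged toward the target), patch residence (transit headings pulled back
    toward the target, keeping the bird holding station over the patch), and
    homeward (transit headings nudged toward the colony).  Patch residence is
    solved from the trip's flight-distance budget (``trip_distance_overhead``
    times the direct commute, times the bird's own multiplier), so the
    expected path length of a trip does not depend on the behavioural mix.
    The trip ends when a homeward transit step passes through the 450 m colony
    zone (with safety caps for pathological parameterizations).
    """
    truth = config.hmm_truth
    shape, scale = truth.gamma_shape_scale()
    kappa = np.maximum(truth.kappa, 1e-12)
    hx, hy = hotspot_xy
    x = y = 0.0
    heading = np.arctan2(hy, hx) + rng.normal(0.0, 0.2)
    state = rng.choice(3, p=delta)
    pi = HMMParams(mean=truth.mean, sd=truth.sd, kappa=truth.kappa,
                   tpm=tpm).stationary()
    pi_t = max(float(pi[2]), 0.05)
    # expected km per step while slow (rest/forage) and while in transit
    v_slow = float(pi[0] * truth.mean[0] + pi[1] * truth.mean[1])
    d_spot = float(np.hypot(hx, hy))
    commute_km = 2.0 * d_spot / 0.95          # transit km to get out and back
    commute_steps = commute_km / max(truth.mean[2] * pi_t, 1e-6)
    budget_km = config.trip_distance_overhead * commute_km * dwell_mult
    spare_km = budget_km - commute_km - commute_steps * v_slow
    per_patch_step_km = v_slow + truth.mean[2] * pi_t  # orbit hops do not progress
    dwell_left = int(np.clip(round(spare_km / max(per_patch_step_km, 1e-6)), 3, 400))
    phase = "out"
    xs, ys, states = [], [], []
    w = config.homeward_weight
    for t in range(max_steps):
        step = rng.gamma(shape[state], scale[state])
        heading = heading + rng.vonmises(truth.angle_mean[state], kappa[state])
        if state == 2:  # transit: blend heading toward the current target
            tx, ty = (0.0, 0.0) if phase == "home" else (hx, hy)
            bear = np.arctan2(ty - y, tx - x)
            wt = w
            if phase == "patch":
                wt = 0.85  # hold station over the patch
            elif phase == "home":
                # return flights are direct: commit to the colony bearing
                wt = 0.8 if x**2 + y**2 < 5.0**2 else max(w, 0.6)
            elif phase == "out" and (x - hx) ** 2 + (y - hy) ** 2 < 5.0**2:
                wt = 0.8  # final approach: commit to the patch
            if t > 500:
                wt = 1.0
            heading = heading + wt * geo.wrap_angle(bear - heading)
        x_new = x + step * np.cos(heading)
        y_new = y + step * np.sin(heading)
        landed = False
        if phase == "home":
            # a transit step that passes through the colony zone is a landing
            dx, dy = x_new - x, y_new - y
            seg2 = dx * dx + dy * dy
            tt = 0.0 if seg2 == 0 else min(1.0, max(0.0, -(x * dx + y * dy) / seg2))
            cx, cy = x + tt * dx, y + tt * dy
            if cx * cx + cy * cy < 0.45**2:
                x_new, y_new = cx, cy
                landed = True
        x, y = x_new, y_new
        xs.append(x)
        ys.append(y)
        states.append(state)
        if phase == "out" and ((x - hx) ** 2 + (y - hy) ** 2 < 2.0**2 or t > 400):
            phase = "patch"
        elif phase == "patch":
            dwell_left -= 1
            if dwell_left <= 0 or t > 450:
                phase = "home"
        if landed:
            break
        state = rng.choice(3, p=tpm[state])
    return np.array(xs), np.array(ys), np.array(states, dtype=int)


def gen_tracks(config: WorldConfig, colony: int, year: int = 0) -> pd.DataFrame:
    """GPS fix table for all birds of one colony-year.

    Each bird alternates colony-attendance blocks (fixes jittered within a few
    hundred metres of the colony, state ``rest``) with foraging trips simulated
    from the movement HMM, on a continuous 5-minute timeline that runs through
    the night — so colony-proximal and 23:00-03:00 fixes are present for the
    trip filters to remove.  Columns: ``bird_id, colony_id, timestamp`` (UTC),
    ``lat, lon, true_state``.
    """
    config.validate()
    truth = config.hmm_truth
    if np.any(truth.kappa < 0) or np.any(truth.mean <= 0) or np.any(truth.sd <= 0):
        raise InvalidParamsError("invalid movement-model truth")
    z = config.het_z()[colony]
    tpm, delta = _colony_tpm(config, z)
    lat0, lon0 = _colony_latlon(config, colony)
    rng_cy = np.random.default_rng([config.seed, 12, colony, year])
    n_spots = max(1, int(round(config.hotspot_base_count - config.hotspot_count_shift * z)))
    # hotspots span a fixed angular sector (the colony's accessible marine
    # area) regardless of how many there are, so the spatial footprint of the
    # colony's foraging grounds is constant and only the sharing changes
    sector = np.radians(config.hotspot_sector_deg)
    if n_spots == 1:
        offsets = np.zeros(1)
    else:
        offsets = np.linspace(-sector / 2, sector / 2, n_spots)
    bearings = rng_cy.uniform(0, 2 * np.pi) + offsets
    # shared hotspots are persistent oceanographic features at a characteristic
    # distance band; private destinations (below) scatter more but are drawn
    # independently per bird, so their noise averages out within a colony
    dists = np.clip(rng_cy.normal(config.hotspot_dist_mean_km,
                                  config.hotspot_shared_dist_sd_km, n_spots), 8.0, None)
    hotspots = np.column_stack([dists * np.cos(bearings), dists * np.sin(bearings)])

    start = pd.Timestamp(f"{config.start_year + year}-06-01 05:00:00", tz="UTC")
    interval = pd.Timedelta(minutes=config.fix_interval_min)
    frames = []
    d0, d1 = config.colony_dwell_fixes
    for b in range(config.n_birds):
        rng = np.random.default_rng([config.seed, 13, colony, year, b])
        xs, ys, sts = [], [], []
        share_p = float(np.clip(config.hotspot_share_base + config.hotspot_share_shift * z,
                                0.0, 1.0))
        base_bearing = bearings.mean()
        # site fidelity: each bird commits to a single foraging destination for
        # the season — one of the colony's shared hotspots where resources are
        # concentrated, otherwise a private location in the sector.  Per-bird
        # space use is therefore comparable across colonies; only the degree of
        # *sharing* between birds tracks the heterogeneity target.
        if rng.uniform() < share_p:
            spot = hotspots[rng.integers(n_spots)]
        else:
            br = base_bearing + rng.uniform(-sector / 2, sector / 2)
            dd = max(8.0, rng.normal(config.hotspot_dist_mean_km,
                                     config.hotspot_dist_sd_km))
            spot = np.array([dd * np.cos(br), dd * np.sin(br)])
        dwell_mult = float(np.exp(rng.normal(0.0, config.patch_dwell_bird_sd))) \
            if config.patch_dwell_bird_sd > 0 else 1.0
        n_trips_added = 0
        while len(xs) < config.n_fixes:
            m = int(rng.integers(d0, d1 + 1))
            xs.extend(rng.normal(0.0, 0.08, m))
            ys.extend(rng.normal(0.0, 0.08, m))
            sts.extend([0] * m)
            tx, ty, tstates = _simulate_trip(rng, config, tpm, delta, spot,
                                             dwell_mult=dwell_mult)
            # never truncate a trip mid-way (a cut trip would distort duration
            # and distance); if it does not fit, sit out the rest of the
            # recording at the colony.  The first trip is kept regardless so
            # every bird goes to sea at least once.
            if len(xs) + len(tx) > config.n_fixes and n_trips_added > 0:
                fill = max(0, config.n_fixes - len(xs))
                xs.extend(rng.normal(0.0, 0.08, fill))
                ys.extend(rng.normal(0.0, 0.08, fill))
                sts.extend([0] * fill)
                break
            xs.extend(tx)
            ys.extend(ty)
            sts.extend(tstates)
            n_trips_added += 1
        xs = np.array(xs[: config.n_fixes])
        ys = np.array(ys[: config.n_fixes])
        sts = np.array(sts[: config.n_fixes])
        times = start + interval * np.arange(config.n_fixes)
        keep = np.ones(config.n_fixes, dtype=bool)
        if config.dropout > 0:
            keep = rng.uniform(size=config.n_fixes) >= config.dropout
            keep[0] = True
        lat, lon = geo.aeq_inverse(xs[keep], ys[keep], lat0, lon0)
        frames.append(pd.DataFrame({
            "bird_id": f"c{colony:02d}y{year}b{b:02d}",
            "colony_id": f"colony{colony:02d}",
            "timestamp": times[keep],
            "lat": np.atleast_1d(lat),
            "lon": np.atleast_1d(lon),
            "true_state": np.array(STATE_NAMES)[sts[keep]],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# breeding success
# ---------------------------------------------------------------------------

def gen_breeding_success(het_by_colony, config: WorldConfig) -> pd.DataFrame:
    """Colony-year breeding success with a known heterogeneity effect.

    ``success = intercept + slope * z(het) + noise`` truncated at zero, one draw
    per colony-year; ``z`` standardizes the targets with the sample SD.  The
    generating slope is stored in ``DataFrame.attrs['truth_slope']``.
    """
    if config.success_noise_sd < 0:
        raise InvalidConfigError("success noise SD must be non-negative")
    het = np.asarray(het_by_colony, dtype=float)
    sd = het.std(ddof=1) if het.size > 1 else 0.0
    z = (het - het.mean()) / sd if sd > 0 else np.zeros_like(het)
    rng = np.random.default_rng([config.seed, 14])
    rows = []
    for y in range(config.n_years):
        noise = rng.normal(0.0, config.success_noise_sd, het.size) if config.success_noise_sd > 0 \
            else np.zeros(het.size)
        succ = np.maximum(config.success_intercept + config.success_slope * z + noise, 0.0)
        for i in range(het.size):
            rows.append({"colony_id": f"colony{i:02d}", "year": config.start_year + y,
                         "success": succ[i]})
    out = pd.DataFrame(rows)
    out.attrs["truth_slope"] = config.success_slope
    return out


# ---------------------------------------------------------------------------
# truth sidecar
# ---------------------------------------------------------------------------

def world_truth(config: WorldConfig) -> dict:
    """Ground-truth record of a world's generating parameters."""
    return {
        "seed": config.seed,
        "het_targets": list(config.het_levels),
        "hmm_truth": config.hmm_truth.to_dict(),
        "success_slope": config.success_slope,
        "success_intercept": config.success_intercept,
        "het_behaviour_coupling": config.het_behaviour_coupling,
        "hotspot_count_shift": config.hotspot_count_shift,
    }


def save_truth(config: WorldConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(world_truth(config), fh, sort_keys=False)
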
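"""End-to-end pipeline: synthetic world -> heterogeneity -> trips -> HMM -> overlap -> tests.

``generate_world`` builds the raw inputs (GPS fixes, environmental rasters,
breeding-success table) for a configured world; ``analyze_world`` runs every
analysis stage from those raw inputs exactly as it would run on field data and
returns the heterogeneity table, trip summaries, behavioural time budgets,
space-use overlap and the full regression suite; ``table2_pattern`` reduces the
regression suite to the qualitative directional pattern (which responses rise,
fall or show no effect with heterogeneity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import heterogeneity as het
from . import hmm, spaceuse, stats, synth, trips

logger = logging.getLogger(__name__)


@dataclass
class World:
    config: synth.WorldConfig
    colonies: pd.DataFrame
    fixes: pd.DataFrame
    rasters: dict                 # (colony_index, year_index) -> EnvRasterStack
    success: pd.DataFrame
    truth: dict = field(default_factory=dict)


def generate_world(config: synth.WorldConfig) -> World:
    """Generate all raw inputs for one synthetic world."""
    config.validate()
    colonies = synth.colony_positions(config)
    fix_frames = []
    rasters = {}
    for c in range(config.n_colonies):
        for y in range(config.n_years):
            fix_frames.append(synth.gen_tracks(config, c, year=y))
            rasters[(c, y)] = synth.gen_env_rasters(config, c, year=y)
    fixes = pd.concat(fix_frames, ignore_index=True)
    success = synth.gen_breeding_success(config.het_levels, config)
    return World(config=config, colonies=colonies, fixes=fixes, rasters=rasters,
                 success=success, truth=synth.world_truth(config))


def _segment_all_trips(world: World):
    """Night-mask and segment every bird's fixes; returns a list of Trip."""
    cfg = world.config
    colony_pos = {row.colony_id: (row.lat, row.lon) for row in world.colonies.itertuples()}
    all_trips = []
    for (bird, colony_id), grp in world.fixes.groupby(["bird_id", "colony_id"], sort=True):
        latlon = colony_pos[colony_id]
        masked = trips.mask_night(grp.reset_index(drop=True), tz=cfg.tz)
        all_trips.extend(
            trips.segment_trips(masked, latlon, apply_night_mask=False))
    return all_trips


def _heterogeneity_stage(world: World, radii: pd.Series, center: str,
                         n_perm: int, include_permdisp: bool, seed: int,
                         pcoa_sample: int = 600):
    """Environmental samples, H per colony-year, PERMDISP, ANOVA, radius check."""
    cfg = world.config
    samples = []
    for (c, y), stack in world.rasters.items():
        colony_id = f"colony{c:02d}"
        lat0 = world.colonies.loc[world.colonies.colony_id == colony_id, "lat"].iloc[0]
        lon0 = world.colonies.loc[world.colonies.colony_id == colony_id, "lon"].iloc[0]
        radius = float(radii.get(colony_id, cfg.radius_km))
        radius = min(radius, cfg.radius_km + 2 * cfg.grid_res_km)  # stay on the raster
        tab = het.extract_env_samples(stack, (lat0, lon0), radius)
        tab["colony_id"] = colony_id
        tab["year"] = cfg.start_year + y
        samples.append(tab)
    samples = pd.concat(samples, ignore_index=True)
    h_table = het.heterogeneity_table(samples, center=center)
    layer_cols = [c for c in het.LAYER_NAMES if c in samples.columns]
    std = het.standardize_env(samples, columns=layer_cols)
    x = std[layer_cols].to_numpy(dtype=float)
    key = std[["colony_id", "year"]].astype(str).agg("|".join, axis=1).to_numpy()
    permdisp = None
    if include_permdisp:
        permdisp = het.permdisp_test(x, key, n_perm=n_perm, seed=seed, center=center)
    # PCoA variance explained, on a subsample when the table is large
    rng = np.random.default_rng(seed + 7)
    idx = np.arange(len(x)) if len(x) <= pcoa_sample else \
        np.sort(rng.choice(len(x), pcoa_sample, replace=False))
    from scipy.spatial.distance import pdist, squareform

    ordination = het.pcoa(squareform(pdist(x[idx])))
    anova = het.het_anova_tukey(h_table) if (h_table["colony_id"].nunique() >= 2
                                             and len(h_table) > 2) else None
    metric_means = samples.groupby(["colony_id", "year"])[layer_cols].mean().reset_index()
    return samples, h_table, permdisp, ordination, anova, metric_means


def analyze_world(world: World, *, center: str = "median", n_perm: int = 199,
                  include_permdisp: bool = True, hmm_restarts: int = 2,
                  ba_on: str = "core", seed: int = 0) -> dict:
    """Run the full analysis from raw fixes and rasters.

    Returns a dictionary with every intermediate table plus ``table2``: the
    regression suite linking colony-mean heterogeneity to trip metrics, time
    budgets, core-area size, pairwise overlap and breeding success.
    """
    cfg = world.config
    colony_pos = {row.colony_id: (row.lat, row.lon) for row in world.colonies.itertuples()}

    # --- trips ------------------------------------------------------------
    all_trips = _segment_all_trips(world)
    trip_frame = trips.trips_to_frame(all_trips)
    if trip_frame.empty:
        raise RuntimeError("no trips segmented; world too small")
    cy_summary = trips.colony_year_summary(trip_frame)
    radii = trips.colony_radius(trip_frame)

    # --- heterogeneity ----------------------------------------------------
    samples, h_table, permdisp, ordination, anova, metric_means = _heterogeneity_stage(
        world, radii, center, n_perm, include_permdisp, seed)
    h_colony = stats.colony_mean_H(h_table)
    rad_sens = het.radius_sensitivity(
        h_colony.loc[radii.index.intersection(h_colony.index)].to_numpy(),
        radii.loc[radii.index.intersection(h_colony.index)].to_numpy()) \
        if h_colony.size >= 3 else None

    # --- behavioural classification ----------------------------------------
    tracks = []
    track_bird = []
    for tr in all_trips:
        latlon = colony_pos[tr.colony_id]
        regs = hmm.regularize(tr.fixes, latlon, dt_min=cfg.fix_interval_min,
                              max_gap_min=5 * cfg.fix_interval_min, trip_id=tr.trip_id)
        tracks.extend(regs)
        track_bird.extend([tr.bird_id] * len(regs))
    fit = hmm.fit_hmm(tracks, starts=cfg.hmm_truth, n_restarts=hmm_restarts, seed=seed)
    decoded = hmm.decode_tracks(fit.params, tracks)
    states_by_bird = {}
    for bird, st in zip(track_bird, decoded):
        states_by_bird.setdefault(bird, []).append(st)
    budgets = hmm.time_budget(states_by_bird)

    # --- space use ----------------------------------------------------------
    bird_info = trip_frame.groupby("bird_id").agg(
        colony_id=("colony_id", "first"), year=("year", "first")).reset_index()
    overlap_frames = []
    core_rows = []
    for (colony_id, year), grp in bird_info.groupby(["colony_id", "year"]):
        latlon = colony_pos[colony_id]
        xy_by_bird = {}
        for bird in grp["bird_id"]:
            f = pd.concat([t.fixes for t in all_trips if t.bird_id == bird],
                          ignore_index=True)
            proj = spaceuse.project_fixes(f, latlon)
            xy_by_bird[bird] = proj[["x_km", "y_km"]].to_numpy()
        uds = spaceuse.colony_year_uds(xy_by_bird, res=1.0)
        for bird, ud in uds.items():
            area, _ = spaceuse.core_area(ud, level=0.5)
            core_rows.append({"bird_id": bird, "colony_id": colony_id, "year": year,
                              "core_area_km2": area, "h_km": ud.h})
        if len(uds) >= 2:
            overlap_frames.append(spaceuse.pairwise_overlap(
                list(uds.values()), colony_id=colony_id, year=year, on=ba_on))
    core_areas = pd.DataFrame(core_rows)
    overlaps = pd.concat(overlap_frames, ignore_index=True) if overlap_frames \
        else pd.DataFrame()

    # --- regression suite ---------------------------------------------------
    cy = cy_summary.merge(h_colony, on="colony_id")
    trip_res = stats.lm_trip_metrics(cy)
    bird_tab = budgets.merge(bird_info, on="bird_id").merge(h_colony, on="colony_id")
    budget_res = stats.glm_time_budget(bird_tab)
    core_tab = core_areas.merge(h_colony, on="colony_id")
    core_res = stats.lm_core_area(core_tab)
    ov_tab = overlaps.merge(h_colony, on="colony_id")
    ov_res = stats.lmm_overlap(ov_tab)
    succ_tab = world.success.merge(h_colony, on="colony_id")
    succ_res = stats.lm_breeding_success(succ_tab)

    table2 = {
        "p_forage": budget_res["p_forage"],
        "p_transit": budget_res["p_transit"],
        "p_rest": budget_res["p_rest"],
        "mean_duration_hr": trip_res["mean_duration_hr"],
        "mean_total_km": trip_res["mean_total_km"],
        "mean_max_km": trip_res["mean_max_km"],
        "ba_overlap": ov_res,
        "core_area_km2": core_res,
        "breeding_success": succ_res.regression,
    }
    return {
        "trips": trip_frame, "cy_summary": cy_summary, "radii": radii,
        "h_table": h_table, "permdisp": permdisp, "ordination": ordination,
        "anova": anova, "metric_means": metric_means, "radius_sensitivity": rad_sens,
        "hmm_fit": fit, "budgets": bird_tab, "core_areas": core_tab,
        "overlaps": ov_tab, "success": succ_tab,
        "table2": table2, "percent_decline": succ_res.percent_decline,
        "colony_mean_H": h_colony,
    }


#: expected qualitative pattern of the regression suite when the world's
#: built-in effects are on: +1 rise, -1 fall, 0 no effect
EXPECTED_PATTERN = {
    "p_forage": +1,
    "p_transit": -1,
    "p_rest": 0,
    "mean_duration_hr": +1,
    "mean_total_km": 0,
    "mean_max_km": 0,
    "ba_overlap": +1,
    "core_area_km2": 0,
    "breeding_success": -1,
}


def table2_pattern(table2: dict, alpha: float = 0.05) -> dict:
    """Directional outcome per response: +1 / -1 if significant, else 0."""
    out = {}
    for name, res in table2.items():
        if res.p < alpha:
            out[name] = 1 if res.estimate > 0 else -1
        else:
            out[name] = 0
    return out


def pattern_matches(table2: dict, alpha: float = 0.05) -> bool:
    """Whether the fitted suite reproduces the expected qualitative pattern."""
    got = table2_pattern(table2, alpha=alpha)
    return all(got.get(k) == v for k, v in EXPECTED_PATTERN.items())


def run_pipeline(config: synth.WorldConfig | None = None, **analyze_kwargs) -> dict:
    """Generate a world and analyze it; the one-call entry point."""
    config = config or synth.endtoend_world()
    world = generate_world(config)
    results = analyze_world(world, **analyze_kwargs)
    results["world"] = world
    return results
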
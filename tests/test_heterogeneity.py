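"""Multivariate-dispersion heterogeneity: PCoA, distance-to-centre, PERMDISP, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from colonyforage import heterogeneity as het
from colonyforage import rasters
from colonyforage.errors import (
    DegenerateColumnError,
    DegenerateGroupError,
    EmptyDomainError,
    InvalidDistanceError,
)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def grid_stack(n=10, res_km=1.0, lat0=54.0, lon0=-5.0, fill=None):
    """Regular n x n stack centred on the colony with res_km cells."""
    rng = np.random.default_rng(0)
    from colonyforage.geo import KM_PER_DEG

    offsets = (np.arange(n) - (n - 1) / 2) * res_km
    lat = lat0 + offsets / KM_PER_DEG
    lon = lon0 + offsets / (KM_PER_DEG * np.cos(np.radians(lat0)))
    layers = {name: rng.normal(size=(n, n)) for name in rasters.LAYER_NAMES}
    if fill is not None:
        layers = {name: np.full((n, n), fill) for name in rasters.LAYER_NAMES}
    return rasters.EnvRasterStack(lat=lat, lon=lon, layers=layers)


def test_extract_matches_brute_force_haversine_count():
    """Row count equals a brute-force count of cell centres within the radius."""
    from colonyforage.geo import haversine_km

    stack = grid_stack(n=10, res_km=1.0)
    tab = het.extract_env_samples(stack, (54.0, -5.0), 3.0)
    lat2d, lon2d = stack.cell_centers()
    expect = int((haversine_km(lat2d, lon2d, 54.0, -5.0) <= 3.0).sum())
    assert len(tab) == expect
    assert 20 <= expect <= 40  # sanity: a ~3-cell-radius disc


def test_extract_tiny_radius_returns_colony_cell():
    stack = grid_stack(n=9, res_km=1.0)
    tab = het.extract_env_samples(stack, (54.0, -5.0), 0.4)
    assert len(tab) == 1


def test_extract_zero_cells_raises():
    stack = grid_stack(n=5, res_km=1.0, lat0=54.0)
    with pytest.raises(EmptyDomainError):
        het.extract_env_samples(stack, (60.0, -5.0), 5.0)


def test_extract_drops_cells_with_missing_layers():
    stack = grid_stack(n=10, res_km=1.0)
    complete = het.extract_env_samples(stack, (54.0, -5.0), 3.0)
    stack.layers["sst"][4, 3:8] = np.nan  # 5 cells near the centre
    masked = het.extract_env_samples(stack, (54.0, -5.0), 3.0)
    assert len(masked) == len(complete) - 5
    assert masked.attrs["n_dropped"] == 5


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def test_standardize_uses_sample_sd_convention():
    tab = pd.DataFrame({"bathymetry": [1.0, 2.0, 3.0]})
    out = het.standardize_env(tab, columns=["bathymetry"])
    np.testing.assert_allclose(out["bathymetry"], [-1.0, 0.0, 1.0])


def test_standardize_idempotent():
    rng = np.random.default_rng(1)
    tab = pd.DataFrame(rng.normal(size=(30, 6)), columns=het.LAYER_NAMES)
    once = het.standardize_env(tab)
    twice = het.standardize_env(once)
    np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)


def test_standardize_constant_column_names_the_layer():
    tab = pd.DataFrame({"sst": [2.0, 2.0, 2.0], "bathymetry": [0.0, 1.0, 2.0]})
    with pytest.raises(DegenerateColumnError, match="sst"):
        het.standardize_env(tab, columns=["sst", "bathymetry"])


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def test_pcoa_two_points_give_symmetric_axis():
    d = 3.7
    ordn = het.pcoa(np.array([[0.0, d], [d, 0.0]]))
    assert ordn.coordinates.shape == (2, 1)
    np.testing.assert_allclose(np.sort(ordn.coordinates[:, 0]), [-d / 2, d / 2], atol=1e-12)


def test_pcoa_preserves_euclidean_distances():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(5, 3))
    dm = squareform(pdist(x))
    ordn = het.pcoa(dm)
    np.testing.assert_allclose(squareform(pdist(ordn.coordinates)), dm, atol=1e-9)


def test_pcoa_collinear_points_put_all_variance_on_axis_one():
    x = np.array([[0.0], [1.0], [2.0]])
    ordn = het.pcoa(squareform(pdist(x)))
    assert ordn.variance_explained[0] == pytest.approx(1.0)


def test_pcoa_variance_explained_sums_to_one():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(20, 6))
    ordn = het.pcoa(squareform(pdist(x)))
    assert ordn.variance_explained.sum() == pytest.approx(1.0)
    assert np.all(np.diff(ordn.eigenvalues) <= 1e-12)  # non-increasing


@pytest.mark.parametrize("bad", [
    np.array([[0.0, 1.0], [2.0, 0.0]]),            # asymmetric
    np.array([[1.0, 1.0], [1.0, 0.0]]),            # non-zero diagonal
    np.zeros((2, 3)),                               # not square
])
def test_pcoa_rejects_malformed_distances(bad):
    with pytest.raises(InvalidDistanceError):
        het.pcoa(bad)


def test_pcoa_agrees_with_scikit_bio():
    """Independent cross-check of the eigen-spectrum against skbio's PCoA."""
    import skbio

    rng = np.random.default_rng(4)
    x = rng.normal(size=(15, 6))
    dm = squareform(pdist(x))
    mine = het.pcoa(dm)
    theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dm))
    their_pos = np.sort(theirs.eigvals.values[theirs.eigvals.values > 1e-8])[::-1]
    np.testing.assert_allclose(mine.eigenvalues, their_pos, atol=1e-8)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def test_identical_observations_have_zero_dispersion():
    x = np.ones((6, 4))
    res = het.dispersion(x, np.repeat([0, 1], 3), center="median")
    assert (res.H == 0).all()


def test_unit_square_centroid_dispersion():
    square = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    res = het.dispersion(square, np.zeros(4), center="centroid")
    assert res.H.iloc[0] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)


def test_dispersion_unknown_center_rejected():
    with pytest.raises(ValueError):
        het.dispersion(np.zeros((4, 2)), np.zeros(4), center="mode")


@pytest.mark.parametrize("center", ["median", "centroid"])
def test_dispersion_via_pcoa_equals_direct_space(center):
    """Euclidean PCoA is an isometry: H is identical in either representation."""
    rng = np.random.default_rng(5)
    x = rng.normal(size=(40, 6))
    groups = np.repeat(list("abcd"), 10)
    ordn = het.pcoa(squareform(pdist(x)))
    h1 = het.dispersion(ordn.coordinates, groups, center=center).H
    h2 = het.dispersion(x, groups, center=center).H
    np.testing.assert_allclose(h1.to_numpy(), h2.to_numpy(), atol=1e-9)


def test_heterogeneity_invariant_to_layer_offsets():
    """Adding a constant to any layer before standardization leaves H unchanged."""
    rng = np.random.default_rng(6)
    tab = pd.DataFrame(rng.normal(size=(60, 6)), columns=het.LAYER_NAMES)
    tab["colony_id"] = np.repeat(["a", "b", "c"], 20)
    tab["year"] = 2015
    h1 = het.heterogeneity_table(tab)
    shifted = tab.copy()
    shifted["sst"] = shifted["sst"] + 273.15
    shifted["bathymetry"] = shifted["bathymetry"] - 1000.0
    h2 = het.heterogeneity_table(shifted)
    np.testing.assert_allclose(h1["H"], h2["H"], atol=1e-9)


def test_heterogeneity_table_pcoa_route_matches_direct_route():
    rng = np.random.default_rng(7)
    tab = pd.DataFrame(rng.normal(size=(45, 6)), columns=het.LAYER_NAMES)
    tab["colony_id"] = np.repeat(["a", "b", "c"], 15)
    tab["year"] = np.tile([2015], 45)
    direct = het.heterogeneity_table(tab, use_pcoa=False)
    via_pcoa = het.heterogeneity_table(tab, use_pcoa=True)
    merged = direct.merge(via_pcoa, on=["colony_id", "year"], suffixes=("_d", "_p"))
    np.testing.assert_allclose(merged["H_d"], merged["H_p"], atol=1e-9)


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def test_permdisp_f_matches_scikit_bio():
    """Observed F statistic agrees with skbio's permdisp for both centres."""
    from skbio import DistanceMatrix
    from skbio.stats.distance import permdisp

    rng = np.random.default_rng(8)
    x = np.vstack([rng.normal(0, 1, (12, 4)), rng.normal(0, 2.5, (12, 4))])
    groups = np.repeat(["lo", "hi"], 12)
    dm = DistanceMatrix(squareform(pdist(x)))
    for center, sk_test in (("centroid", "centroid"), ("median", "median")):
        mine = het.permdisp_test(x, groups, n_perm=99, seed=0, center=center)
        theirs = permdisp(dm, list(groups), test=sk_test, permutations=9)
        # agreement limited only by the spatial-median iteration tolerance
        assert mine.F == pytest.approx(float(theirs["test statistic"]), rel=1e-5)


def test_permdisp_detects_unequal_dispersion():
    """Groups with SD 1 vs 3 (n = 50 each) are separated at p < 0.01."""
    hits = 0
    for seed in range(3):
        rng = np.random.default_rng(20 + seed)
        x = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(0, 3, (50, 3))])
        groups = np.repeat(["a", "b"], 50)
        res = het.permdisp_test(x, groups, n_perm=199, seed=seed)
        hits += res.p < 0.01
    assert hits == 3


def test_permdisp_boundary_p_is_one_when_f_minimal():
    """Identical symmetric groups give F = 0, so every permutation ties and
    p = 1 under the add-one convention."""
    pattern = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    x = np.vstack([pattern, pattern + 10.0])
    groups = np.repeat(["a", "b"], 4)
    res = het.permdisp_test(x, groups, n_perm=99, seed=1, center="centroid")
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert res.p == 1.0


def test_permdisp_degenerate_group_rejected():
    x = np.random.default_rng(0).normal(size=(5, 2))
    with pytest.raises(DegenerateGroupError):
        het.permdisp_test(x, np.array(["a", "a", "a", "a", "b"]), n_perm=99)


def test_permdisp_deterministic_given_seed():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(30, 3))
    groups = np.repeat(["a", "b"], 15)
    r1 = het.permdisp_test(x, groups, n_perm=99, seed=42)
    r2 = het.permdisp_test(x, groups, n_perm=99, seed=42)
    assert r1.p == r2.p


# ---------------------------------------------------------------------------
# ANOVA / Tukey / radius sensitivity
# ---------------------------------------------------------------------------

def _balanced_table(colony_effects, year_effects, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for ci, ce in enumerate(colony_effects):
        for yi, ye in enumerate(year_effects):
            rows.append({"colony_id": f"c{ci}", "year": 2015 + yi,
                         "H": 1.0 + ce + ye + rng.normal(0, noise)})
    return pd.DataFrame(rows)


def test_anova_additive_colony_effect_recovered():
    """Colony effects {0, 1, 2} with no noise: colony p ~ 0, year flat (p = 1)."""
    tab = _balanced_table([0.0, 1.0, 2.0], [0.0, 0.0])
    res = het.het_anova_tukey(tab)
    assert res.anova.loc["C(colony_id)", "PR(>F)"] < 1e-10
    assert res.anova.loc["C(year)", "F"] == 0.0
    assert res.anova.loc["C(year)", "PR(>F)"] == 1.0


def test_anova_identical_h_gives_zero_f():
    tab = _balanced_table([0.0, 0.0, 0.0], [0.0, 0.0])
    res = het.het_anova_tukey(tab)
    assert res.anova.loc["C(colony_id)", "F"] == 0.0
    assert res.anova.loc["C(year)", "F"] == 0.0


def test_tukey_interval_for_equal_means_contains_zero():
    tab = _balanced_table([0.0, 0.0, 1.0], [0.0, 0.0, 0.0], noise=0.05, seed=3)
    res = het.het_anova_tukey(tab)
    tk = res.tukey["colony_id"]
    row = tk[(tk["group1"] == "c0") & (tk["group2"] == "c1")].iloc[0]
    assert float(row["lower"]) < 0 < float(row["upper"])


def test_anova_single_level_factor_skipped():
    # one year only, two replicate H values per colony so the model has
    # residual degrees of freedom
    tab = pd.concat([_balanced_table([0.0, 1.0, 2.0], [0.0], noise=0.01, seed=s)
                     for s in (0, 1)], ignore_index=True)
    res = het.het_anova_tukey(tab)
    assert "C(year)" not in res.anova.index
    assert "C(colony_id)" in res.anova.index


def test_radius_sensitivity_constant_h_has_zero_slope():
    res = het.radius_sensitivity(np.array([1.5, 1.5, 1.5, 1.5]),
                                 np.array([10.0, 20.0, 30.0, 40.0]))
    assert res.slope == pytest.approx(0.0, abs=1e-12)


def test_radius_sensitivity_exact_line_has_unit_r2():
    radius = np.array([10.0, 20.0, 30.0, 40.0])
    res = het.radius_sensitivity(2 * radius, radius)
    assert res.r2 == pytest.approx(1.0)
    assert res.slope == pytest.approx(2.0)


def test_radius_sensitivity_null_world_mostly_insignificant():
    """Independent heterogeneity and radius: p > 0.05 in most seeds."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(300 + seed)
        res = het.radius_sensitivity(rng.normal(2, 0.4, 12), rng.normal(25, 5, 12))
        hits += res.p > 0.05
    assert hits >= 9
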
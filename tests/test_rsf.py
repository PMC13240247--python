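"""Predictor derivation, RSF surface application, transferability."""

import numpy as np
import pytest
from shapely.geometry import LineString

import boreal
from boreal.grids import Feature, FeatureSet, RasterGrid
from boreal.rsf import (
    PredictorStack,
    RSFCoefficientTable,
    RSFSurface,
    apply_rsf,
    compare_surfaces,
    default_coefficient_tables,
    derive_predictors,
    load_coefficient_tables,
)
from boreal.synthetic import LandscapeStack, LandscapeSpec, generate_landscape


def make_stack(shape=(3, 1), **layers):
    grids = {
        name: RasterGrid(np.asarray(vals, dtype=float).reshape(shape), 1.0, (0.0, shape[0]))
        for name, vals in layers.items()
    }
    return PredictorStack(grids)


# ---------------------------------------------------------------------------
# derive_predictors


@pytest.fixture(scope="module")
def uniform_landscape():
    spec = LandscapeSpec(
        extent_km=(7.5, 7.5),
        resolution_m=250.0,
        landcover_classes=(("conifer", 1.0),),
        fire_fraction=0.0,
        seed=4,
    )
    return generate_landscape(spec)


class TestDerivePredictors:
    def test_uniform_class_proportion_is_one_everywhere(self, uniform_landscape):
        stack = derive_predictors(
            uniform_landscape, FeatureSet(()), window_radius_m=1000.0
        )
        np.testing.assert_allclose(stack.layers["prop_conifer"].values, 1.0)

    def test_no_roads_zero_density(self, uniform_landscape):
        stack = derive_predictors(
            uniform_landscape, FeatureSet(()), window_radius_m=1000.0
        )
        np.testing.assert_array_equal(stack.layers["road_density"].values, 0.0)

    def test_single_road_matches_brute_force_window_lengths(self, uniform_landscape):
        """Window road density equals an independent Liang–Barsky clipping
        computation of length-in-window, cell membership by center distance."""
        p0, p1 = (700.0, 800.0), (6400.0, 5600.0)
        road = FeatureSet((Feature(LineString([p0, p1]), "road"),))
        radius_m = 900.0
        stack = derive_predictors(uniform_landscape, road, window_radius_m=radius_m)
        got = np.asarray(stack.layers["road_density"].values)

        grid = uniform_landscape.landcover
        res = grid.resolution
        nrows, ncols = grid.shape
        x0, y0 = grid.origin

        def seg_length_in_box(xmin, ymin, xmax, ymax):
            # Liang–Barsky parametric clipping of segment p0-p1 to the box
            dx, dy = p1[0] - p0[0], p1[1] - p0[1]
            t0, t1 = 0.0, 1.0
            for p, q in (
                (-dx, p0[0] - xmin), (dx, xmax - p0[0]),
                (-dy, p0[1] - ymin), (dy, ymax - p0[1]),
            ):
                if p == 0:
                    if q < 0:
                        return 0.0
                    continue
                r = q / p
                if p < 0:
                    t0 = max(t0, r)
                else:
                    t1 = min(t1, r)
            if t0 >= t1:
                return 0.0
            return (t1 - t0) * np.hypot(dx, dy)

        length = np.zeros((nrows, ncols))
        for r_i in range(nrows):
            for c_i in range(ncols):
                length[r_i, c_i] = seg_length_in_box(
                    x0 + c_i * res, y0 - (r_i + 1) * res,
                    x0 + (c_i + 1) * res, y0 - r_i * res,
                )
        rc = radius_m / res
        rint = int(np.floor(rc))
        expected = np.zeros((nrows, ncols))
        for r_i in range(nrows):
            for c_i in range(ncols):
                tot, n = 0.0, 0
                for dr in range(-rint, rint + 1):
                    for dc in range(-rint, rint + 1):
                        if dr * dr + dc * dc > rc * rc:
                            continue
                        rr, cc = r_i + dr, c_i + dc
                        if 0 <= rr < nrows and 0 <= cc < ncols:
                            tot += length[rr, cc]
                            n += 1
                expected[r_i, c_i] = (tot / 1000.0) / (n * (res / 1000.0) ** 2)
        np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-12)


# ---------------------------------------------------------------------------
# apply_rsf


class TestApplyRSF:
    def test_zero_coefficients_give_unit_surface(self):
        stack = make_stack(x=[0.1, 0.5, 0.9])
        table = RSFCoefficientTable("r", "spring", (("x", 0.0),))
        surf = apply_rsf(table, stack)
        np.testing.assert_allclose(surf.values.values, 1.0)

    def test_positive_coefficient_preserves_predictor_ranking(self):
        vals = [0.3, 0.9, 0.1, 0.6]
        stack = make_stack(shape=(4, 1), x=vals)
        table = RSFCoefficientTable("r", "summer", (("x", 2.0),))
        surf = apply_rsf(table, stack)
        order = np.argsort(np.asarray(surf.values.values).ravel())
        np.testing.assert_array_equal(order, np.argsort(vals))

    def test_three_cell_hand_computation(self):
        """exp(eta)/max(exp(eta)) on a printed 3-cell example, to 1e-12."""
        x = np.array([0.2, 0.5, 0.8])
        z = np.array([1.0, 0.0, -1.0])
        beta_x, beta_z = 1.3, -0.7
        stack = make_stack(x=x, z=z)
        table = RSFCoefficientTable("r", "fall", (("x", beta_x), ("z", beta_z)))
        surf = apply_rsf(table, stack)
        eta = beta_x * x + beta_z * z
        expected = np.exp(eta) / np.exp(eta).max()
        np.testing.assert_allclose(
            np.asarray(surf.values.values).ravel(), expected, atol=1e-12
        )

    def test_constant_shift_in_eta_invariant_for_exponential(self):
        x = np.array([0.2, 0.5, 0.8])
        stack1 = make_stack(x=x, one=np.ones(3))
        t1 = RSFCoefficientTable("r", "winter", (("x", 1.7),))
        t2 = RSFCoefficientTable("r", "winter", (("x", 1.7), ("one", 42.0)))
        s1 = apply_rsf(t1, stack1)
        s2 = apply_rsf(t2, stack1)
        np.testing.assert_allclose(s1.values.values, s2.values.values, atol=1e-12)

    def test_logistic_transform_and_rescale(self):
        x = np.array([-2.0, 0.0, 2.0])
        stack = make_stack(x=x)
        table = RSFCoefficientTable("r", "spring", (("x", 1.0),), transform="logistic")
        surf = apply_rsf(table, stack)
        w = 1.0 / (1.0 + np.exp(-x))
        np.testing.assert_allclose(
            np.asarray(surf.values.values).ravel(), w / w.max(), atol=1e-12
        )

    def test_missing_predictor_error_lists_names(self):
        stack = make_stack(x=[0.0, 1.0, 2.0])
        table = RSFCoefficientTable("r", "spring", (("x", 1.0), ("absent", 2.0)))
        with pytest.raises(KeyError, match="absent"):
            apply_rsf(table, stack)

    def test_nodata_propagates(self):
        grid = RasterGrid(
            np.array([[0.1], [0.2], [0.3]]), 1.0, (0.0, 3.0),
            nodata_mask=np.array([[False], [True], [False]]),
        )
        surf = apply_rsf(
            RSFCoefficientTable("r", "spring", (("x", 1.0),)),
            PredictorStack({"x": grid}),
        )
        assert np.isnan(surf.values.values[1, 0])
        assert surf.values.nodata_mask[1, 0]

    def test_negative_road_coefficient_never_raises_use_near_roads(self, uniform_landscape):
        """With a negative road coefficient, adding road density can only
        lower the surface (ceteris paribus)."""
        road = FeatureSet(
            (Feature(LineString([(0.0, 3750.0), (7500.0, 3750.0)]), "road"),)
        )
        with_road = derive_predictors(uniform_landscape, road, window_radius_m=1000.0)
        without = derive_predictors(uniform_landscape, FeatureSet(()), window_radius_m=1000.0)
        table = RSFCoefficientTable(
            "r", "spring", (("prop_conifer", 1.0), ("road_density", -5.0))
        )
        s_with = np.asarray(apply_rsf(table, with_road).values.values)
        s_without = np.asarray(apply_rsf(table, without).values.values)
        assert (s_with <= s_without + 1e-12).all()
        dens = np.asarray(with_road.layers["road_density"].values)
        assert (s_with[dens > 0] < s_without[dens > 0]).all()


# ---------------------------------------------------------------------------
# compare_surfaces


def surf_from(vals, season="spring", name="a"):
    g = RasterGrid(np.asarray(vals, dtype=float), 1.0, (0.0, len(vals)))
    return RSFSurface(g, season=season, source_range=name)


class TestCompareSurfaces:
    def test_self_comparison_is_one(self):
        rng = np.random.default_rng(0)
        s = surf_from(rng.uniform(size=(6, 6)))
        assert compare_surfaces(s, s).pearson_r == pytest.approx(1.0)

    def test_affine_negative_is_minus_one(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(size=(6, 6))
        r = compare_surfaces(surf_from(v), surf_from(1.0 - v, name="b")).pearson_r
        assert r == pytest.approx(-1.0)

    def test_matches_independent_correlation_formula(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=(10, 10))
        b = rng.uniform(size=(10, 10))
        r = compare_surfaces(surf_from(a), surf_from(b, name="b")).pearson_r
        af, bf = a.ravel(), b.ravel()
        num = ((af - af.mean()) * (bf - bf.mean())).sum()
        den = np.sqrt(((af - af.mean()) ** 2).sum() * ((bf - bf.mean()) ** 2).sum())
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_flagged(self):
        a = surf_from(np.full((4, 4), 0.5))
        b = surf_from(np.random.default_rng(3).uniform(size=(4, 4)), name="b")
        rep = compare_surfaces(a, b)
        assert rep.zero_variance and np.isnan(rep.pearson_r)

    def test_too_few_cells_raises(self):
        g = RasterGrid(np.array([[0.1, 0.2]]), 1.0, (0.0, 1.0),
                       nodata_mask=np.array([[False, True]]))
        s = RSFSurface(g, "spring", "a")
        with pytest.raises(ValueError):
            compare_surfaces(s, s)

    def test_season_mismatch_raises(self):
        a = surf_from(np.random.default_rng(4).uniform(size=(4, 4)))
        b = surf_from(np.random.default_rng(5).uniform(size=(4, 4)), season="winter")
        with pytest.raises(ValueError):
            compare_surfaces(a, b)

    def test_pair_thinning_deterministic(self):
        rng = np.random.default_rng(6)
        a = surf_from(rng.uniform(size=(20, 20)))
        b = surf_from(rng.uniform(size=(20, 20)), name="b")
        r1 = compare_surfaces(a, b, max_pairs=50, seed=9)
        r2 = compare_surfaces(a, b, max_pairs=50, seed=9)
        np.testing.assert_array_equal(r1.paired_values, r2.paired_values)
        assert r1.paired_values.shape == (50, 2)


# ---------------------------------------------------------------------------
# coefficient tables


class TestCoefficientTables:
    def test_packaged_defaults_cover_four_ranges_and_seasons(self):
        tables = default_coefficient_tables()
        keys = {(t.range_name, t.season) for t in tables}
        assert len(keys) == 16
        assert {r for r, _ in keys} == {"Missisa", "JamesBay", "Nipigon", "Pagwachuan"}

    def test_duplicate_predictor_rejected(self):
        with pytest.raises(ValueError):
            RSFCoefficientTable("r", "spring", (("x", 1.0), ("x", 2.0)))

    def test_csv_roundtrip(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "range,season,predictor,coefficient,transform\n"
            "A,spring,x,1.5,exponential\n"
            "A,spring,y,-0.5,exponential\n"
        )
        tables = load_coefficient_tables(path)
        assert len(tables) == 1
        assert dict(tables[0].terms) == {"x": 1.5, "y": -0.5}
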
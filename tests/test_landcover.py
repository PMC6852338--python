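"""NDVI rasters, maximum-likelihood classification, kappa, areas and change."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from biovocem import synth
from biovocem.landcover import (MaximumLikelihoodClassifier,
                                accuracy_assessment, area_by_class,
                                change_analysis, classify_ml, raster_ndvi,
                                read_training_geojson, train_classifier,
                                write_training_geojson)
from biovocem.raster import LandCoverMap, RasterGrid


class TestRasterNdvi:
    def test_values_and_nodata(self, small_grid):
        nir = small_grid([[0.5, 0.3, 0.0, -9999.0]])
        red = small_grid([[0.1, 0.3, 0.0, 0.2]])
        out = raster_ndvi(nir, red)
        assert out.values[0, 0] == pytest.approx(0.4 / 0.6)
        assert out.values[0, 1] == pytest.approx(0.0)
        assert out.values[0, 2] == out.nodata  # 0/0 undefined
        assert out.values[0, 3] == out.nodata  # input nodata propagates

    def test_bounded_and_scale_invariant(self, small_grid):
        rng = np.random.default_rng(0)
        n = small_grid(rng.uniform(0.01, 1, (8, 8)))
        r = small_grid(rng.uniform(0.01, 1, (8, 8)))
        a = raster_ndvi(n, r).values
        assert np.all((a >= -1) & (a <= 1))
        b = raster_ndvi(n.with_values(n.values * 0.37),
                        r.with_values(r.values * 0.37)).values
        assert np.allclose(a, b)

    def test_misaligned_rejected(self, small_grid):
        nir = small_grid(np.zeros((4, 4)))
        red = RasterGrid(values=np.zeros((4, 4)), origin=(10.0, 3000.0),
                         pixel_size=30.0)
        with pytest.raises(ValueError, match="aligned"):
            raster_ndvi(nir, red)


class TestClassifier:
    def test_degenerate_training_regularized(self):
        X = np.array([[0.1, 0.5]] * 5 + [[0.4, 0.45]] * 5)
        y = np.array([1] * 5 + [2] * 5)
        clf = MaximumLikelihoodClassifier().fit(X, y)
        assert np.allclose(clf.means_[0], [0.1, 0.5])
        # zero sample covariance -> eps * I after regularisation
        assert np.all(np.linalg.eigvalsh(clf.covariances_[0]) > 0)
        assert np.array_equal(clf.predict(X), y)

    def test_equal_priors(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (30, 2)) + np.repeat([[0], [5], [10]], 10, 0)
        y = np.repeat([1, 2, 3], 10)
        clf = MaximumLikelihoodClassifier(priors="equal").fit(X, y)
        assert np.allclose(clf.priors_, 1 / 3)

    def test_pixel_at_class_mean_assigned_to_it(self):
        rng = np.random.default_rng(1)
        means = {1: [0.1, 0.5], 2: [0.4, 0.45], 3: [0.2, 0.8]}
        X = np.concatenate([rng.normal(m, 0.01, (20, 2))
                            for m in means.values()])
        y = np.repeat(list(means), 20)
        clf = MaximumLikelihoodClassifier().fit(X, y)
        assert clf.predict(np.array([means[2]]))[0] == 2

    def test_two_class_boundary_is_perpendicular_bisector(self):
        # equal isotropic covariances and priors -> LDA boundary
        rng = np.random.default_rng(2)
        m1, m2 = np.array([0.0, 0.0]), np.array([2.0, 1.0])
        X = np.concatenate([m1 + 0.3 * rng.standard_normal((4000, 2)),
                            m2 + 0.3 * rng.standard_normal((4000, 2))])
        y = np.repeat([1, 2], 4000)
        clf = MaximumLikelihoodClassifier().fit(X, y)
        gx, gy = np.meshgrid(np.linspace(-1, 3, 40), np.linspace(-1, 2, 40))
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        pred = clf.predict(pts)
        # signed distance to the empirical bisector of the fitted means
        mid = clf.means_.mean(axis=0)
        d = (pts - mid) @ (clf.means_[1] - clf.means_[0])
        off_boundary = np.abs(d) > 0.05
        assert np.array_equal(pred[off_boundary], np.where(d > 0, 2, 1)[off_boundary])

    def test_too_few_training_pixels_names_class(self):
        X = np.array([[0.1, 0.5], [0.11, 0.5], [0.4, 0.45], [0.41, 0.44],
                      [0.39, 0.46]])
        y = np.array([1, 1, 2, 2, 2])
        with pytest.raises(ValueError, match="class 1"):
            MaximumLikelihoodClassifier().fit(X, y)

    def test_sklearn_params_roundtrip(self):
        clf = MaximumLikelihoodClassifier(priors="proportional", reg_factor=1e-5)
        clone = MaximumLikelihoodClassifier(**clf.get_params())
        assert clone.get_params() == clf.get_params()


class TestClassifyScene:
    def test_zero_noise_scene_matches_truth_exactly(self):
        classes = (synth.ClassSpec(1, "a", 0.1, 0.5, 0.0),
                   synth.ClassSpec(2, "b", 0.4, 0.45, 0.0))
        red, nir, truth, train = synth.generate_scene(
            synth.SceneSpec(width=24, height=24, classes=classes, seed=0))
        clf = train_classifier([red, nir], train)
        pred = classify_ml([red, nir], clf, legend=truth.legend)
        assert np.array_equal(pred.labels.values, truth.labels.values)

    def test_matches_brute_force_gaussian_argmax(self):
        red, nir, truth, train = synth.generate_scene(
            synth.SceneSpec(width=32, height=32, seed=5))
        clf = train_classifier([red, nir], train)
        pred = classify_ml([red, nir], clf, legend=truth.legend)
        # independent oracle: full Gaussian density per pixel via scipy
        X = np.stack([red.values, nir.values], axis=-1).reshape(-1, 2)
        dens = np.stack([
            clf.priors_[i] * multivariate_normal(clf.means_[i],
                                                 clf.covariances_[i]).pdf(X)
            for i in range(len(clf.classes_))])
        oracle = clf.classes_[np.argmax(dens, axis=0)].reshape(32, 32)
        assert np.array_equal(pred.labels.values, oracle)

    def test_recovered_means_close_to_generator(self):
        spec = synth.SceneSpec(width=60, height=60, seed=6)
        red, nir, truth, train = synth.generate_scene(spec)
        clf = train_classifier([red, nir], train)
        for i, k in enumerate(clf.classes_):
            c = next(c for c in spec.classes if c.class_id == k)
            n_train = 100  # training strips hold far more pixels than this
            tol = 2 * c.std / np.sqrt(n_train)
            assert abs(clf.means_[i][0] - c.mean_red) < tol
            assert abs(clf.means_[i][1] - c.mean_nir) < tol

    def test_nodata_propagates(self, small_grid):
        red = small_grid(np.full((6, 6), 0.1))
        vals = np.full((6, 6), 0.5)
        vals[0, 0] = -9999.0
        nir = small_grid(vals)
        X = np.array([[0.1, 0.5]] * 5 + [[0.4, 0.45]] * 5)
        y = np.array([1] * 5 + [2] * 5)
        clf = MaximumLikelihoodClassifier().fit(X, y)
        pred = classify_ml([red, nir], clf)
        assert pred.labels.values[0, 0] == pred.labels.nodata
        assert np.all(pred.labels.values[1:] == 1)


def make_map(labels, legend, small_grid):
    return LandCoverMap(labels=small_grid(labels, nodata=-1.0).with_values(
        np.asarray(labels, dtype=int), nodata=-1), legend=legend)


class TestAccuracy:
    def test_perfect_agreement(self, small_grid):
        m = make_map(np.ones((5, 5), int), {1: "a"}, small_grid)
        rep = accuracy_assessment(m, m)
        assert rep.overall_accuracy == 1.0 and rep.kappa == 1.0

    def test_hand_checked_confusion_matrix(self, small_grid):
        # confusion [[40,10],[20,30]]: accuracy 0.70, kappa 0.4
        ref = np.array([1] * 50 + [2] * 50)
        pred = np.array([1] * 40 + [2] * 10 + [1] * 20 + [2] * 30)
        legend = {1: "a", 2: "b"}
        m_ref = make_map(ref.reshape(10, 10), legend, small_grid)
        m_pred = make_map(pred.reshape(10, 10), legend, small_grid)
        rep = accuracy_assessment(m_pred, m_ref)
        assert rep.overall_accuracy == pytest.approx(0.70)
        assert rep.kappa == pytest.approx(0.4)
        assert rep.confusion.loc[1, 2] == 10

    def test_kappa_matches_brute_force_definition(self, small_grid):
        rng = np.random.default_rng(3)
        ref = rng.integers(1, 4, (20, 20))
        pred = rng.integers(1, 4, (20, 20))
        legend = {1: "a", 2: "b", 3: "c"}
        rep = accuracy_assessment(make_map(pred, legend, small_grid),
                                  make_map(ref, legend, small_grid))
        # from-scratch kappa over raw label pairs
        n = ref.size
        p_o = np.mean(ref == pred)
        p_e = sum((np.mean(ref == k)) * (np.mean(pred == k)) for k in (1, 2, 3))
        assert rep.kappa == pytest.approx((p_o - p_e) / (1 - p_e), abs=1e-12)
        assert rep.overall_accuracy == pytest.approx(p_o, abs=1e-12)

    def test_independent_predictions_give_near_zero_kappa(self, small_grid):
        rng = np.random.default_rng(4)
        legend = {1: "a", 2: "b", 3: "c"}
        ref = rng.integers(1, 4, (60, 60))
        pred = rng.integers(1, 4, (60, 60))
        rep = accuracy_assessment(make_map(pred, legend, small_grid),
                                  make_map(ref, legend, small_grid))
        assert abs(rep.kappa) < 0.05


class TestAreasAndChange:
    def test_area_conversion(self, small_grid):
        m = make_map(np.ones((10, 10), int), {1: "a"}, small_grid)
        areas = area_by_class(m)
        assert areas["a"] == pytest.approx(9.0)  # 100 px x 900 m2 / 1e4

    def test_empty_class_zero_and_conservation(self, small_grid):
        m = make_map(np.ones((10, 10), int), {1: "a", 2: "b"}, small_grid)
        areas = area_by_class(m)
        assert areas["b"] == 0.0
        assert areas.sum() == pytest.approx(9.0)

    @pytest.mark.parametrize("species,delta,expected_rate,direction", [
        ("Eucalyptus", -469.22, 156.41, "deforestation"),
        ("Pinus", -228.11, 76.04, "deforestation"),
        ("Alnus", 44.31, 14.77, "increase"),
    ])
    def test_three_year_annual_rates(self, small_grid, species, delta,
                                     expected_rate, direction):
        # build maps whose pixel counts realise the target area change
        px_ha = 900.0 / 1e4
        n1 = int(round(max(-delta, 0) / px_ha)) + 1000
        n2 = n1 + int(round(delta / px_ha))
        side = 260
        legend = {1: species, 2: "other"}

        def lc(n_pix):
            lab = np.full(side * side, 2, int)
            lab[:n_pix] = 1
            return make_map(lab.reshape(side, side), legend, small_grid)

        table = change_analysis(lc(n1), lc(n2), years_between=3.0)
        assert table.loc[species, "delta_ha"] == pytest.approx(delta, abs=0.05)
        assert table.loc[species, "abs_rate_ha_per_year"] == pytest.approx(
            expected_rate, abs=0.02)
        assert table.loc[species, "direction"] == direction

    def test_invalid_years_rejected(self, small_grid):
        m = make_map(np.ones((3, 3), int), {1: "a"}, small_grid)
        with pytest.raises(ValueError):
            change_analysis(m, m, years_between=0.0)


class TestGeojson:
    def test_roundtrip(self, tmp_path):
        spec = synth.SceneSpec(width=12, height=12, seed=0)
        _, _, _, training = synth.generate_scene(spec)
        path = tmp_path / "train.geojson"
        write_training_geojson(training, path, legend=spec.legend())
        back = read_training_geojson(path)
        assert [c for c, _ in back] == [c for c, _ in training]
        for (_, a), (_, b) in zip(back, training):
            assert a.equals_exact(b, tolerance=1e-9)
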
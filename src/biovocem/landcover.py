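"""Raster NDVI, supervised land-cover classification and change analysis.

Classification follows the classical remote-sensing maximum-likelihood
scheme: each class is modelled as a multivariate Gaussian over the band
vector, estimated from training-area pixels, and every pixel is assigned to
the class with the highest Gaussian log-discriminant.  Accuracy is assessed
with a confusion matrix, overall accuracy and Cohen's kappa; area
tabulation and two-date change analysis yield annual deforestation /
afforestation rates in ha per year.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping as shapely_mapping, shape as shapely_shape
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .raster import LandCoverMap, RasterGrid, _require_alignment

__all__ = [
    "MaximumLikelihoodClassifier",
    "AccuracyReport",
    "raster_ndvi",
    "train_classifier",
    "classify_ml",
    "accuracy_assessment",
    "area_by_class",
    "change_analysis",
    "change_from_areas",
    "extract_training_samples",
    "read_training_geojson",
    "write_training_geojson",
]


def raster_ndvi(nir: RasterGrid, red: RasterGrid) -> RasterGrid:
    """Per-pixel NDVI = (NIR − R)/(NIR + R) on aligned reflectance grids.

    Pixels where either band is nodata, or where NIR + R = 0 (undefined
    ratio), become nodata in the output.
    """
    _require_alignment(nir, red)
    valid = nir.mask() & red.mask()
    n = nir.values.astype(float)
    r = red.values.astype(float)
    denom = n + r
    valid &= denom != 0
    out = np.full(nir.shape, nir.nodata, dtype=float)
    out[valid] = (n[valid] - r[valid]) / denom[valid]
    return nir.with_values(out)


class MaximumLikelihoodClassifier(BaseEstimator, ClassifierMixin):
    """Gaussian maximum-likelihood classifier over band vectors.

    Per class k the discriminant is

        g_k(x) = ln π_k − ½ ln|Σ_k| − ½ (x − μ_k)ᵀ Σ_k⁻¹ (x − μ_k)

    with μ_k, Σ_k the training sample mean and covariance and π_k the
    prior.  Near-singular covariances are regularised by adding
    ``reg_factor × mean(diag Σ_k)`` to the diagonal.  Ties are broken
    towards the lowest class id.

    Parameters
    ----------
    priors : {"equal", "proportional"} or mapping class id -> prior
        ``equal`` (default) gives every class the same prior;
        ``proportional`` uses the training-pixel share.
    reg_factor : float
        Diagonal regularisation strength relative to the mean variance.
    """

    def __init__(self, priors="equal", reg_factor: float = 1e-6):
        self.priors = priors
        self.reg_factor = reg_factor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_bands)")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        n_bands = X.shape[1]
        means, covs, counts = {}, {}, {}
        for k in classes:
            Xi = X[y == k]
            if len(Xi) < n_bands + 1:
                raise ValueError(
                    f"class {k} has {len(Xi)} training pixels; needs at "
                    f"least {n_bands + 1} to estimate a {n_bands}-band covariance")
            mu = Xi.mean(axis=0)
            cov = np.cov(Xi, rowvar=False, ddof=1).reshape(n_bands, n_bands)
            cov = self._regularize(cov)
            means[k], covs[k], counts[k] = mu, cov, len(Xi)

        if isinstance(self.priors, Mapping):
            pri = np.array([self.priors[k] for k in classes], dtype=float)
        elif self.priors == "equal":
            pri = np.ones(len(classes))
        elif self.priors == "proportional":
            pri = np.array([counts[k] for k in classes], dtype=float)
        else:
            raise ValueError(f"priors must be 'equal', 'proportional' or a "
                             f"mapping, got {self.priors!r}")
        pri = pri / pri.sum()

        self.classes_ = classes
        self.means_ = np.stack([means[k] for k in classes])
        self.covariances_ = np.stack([covs[k] for k in classes])
        self.priors_ = pri
        self.n_features_in_ = n_bands
        return self

    def _regularize(self, cov: np.ndarray) -> np.ndarray:
        mean_diag = float(np.trace(cov)) / cov.shape[0]
        if mean_diag <= 0:
            mean_diag = 1.0  # fully degenerate training pixels
        eps = self.reg_factor * mean_diag
        cov = cov + eps * np.eye(cov.shape[0])
        # ensure positive definiteness after regularisation
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            w = np.linalg.eigvalsh(cov)
            cov = cov + (abs(w.min()) + eps) * np.eye(cov.shape[0])
        return cov

    def decision_function(self, X) -> np.ndarray:
        """Gaussian log-discriminant per class, shape (n_samples, n_classes)."""
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        scores = np.empty((len(X), len(self.classes_)))
        for i, _ in enumerate(self.classes_):
            mu, cov = self.means_[i], self.covariances_[i]
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    f"covariance of class {self.classes_[i]!r} is singular "
                    "despite regularisation")
            diff = X - mu
            maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(cov), diff)
            scores[:, i] = np.log(self.priors_[i]) - 0.5 * logdet - 0.5 * maha
        return scores

    def predict(self, X) -> np.ndarray:
        # argmax returns the first maximum: lowest class id wins ties
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def extract_training_samples(bands: Sequence[RasterGrid],
                             polygons: Sequence[tuple[int, shapely.Geometry]],
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Band vectors and labels of pixels whose centers fall inside polygons."""
    ref = bands[0]
    for b in bands[1:]:
        _require_alignment(ref, b)
    gx, gy = ref.cell_centers()
    stack = np.stack([b.values for b in bands], axis=-1)
    valid = np.ones(ref.shape, dtype=bool)
    for b in bands:
        valid &= b.mask()
    X_list, y_list = [], []
    for class_id, geom in polygons:
        inside = shapely.contains_xy(geom, gx, gy) & valid
        X_list.append(stack[inside])
        y_list.append(np.full(int(inside.sum()), class_id))
    return np.concatenate(X_list), np.concatenate(y_list)


def train_classifier(bands: Sequence[RasterGrid],
                     training_polygons: Sequence[tuple[int, shapely.Geometry]],
                     equal_priors: bool = True,
                     reg_factor: float = 1e-6) -> MaximumLikelihoodClassifier:
    """Fit the per-class Gaussian model from training-area pixels."""
    X, y = extract_training_samples(bands, training_polygons)
    clf = MaximumLikelihoodClassifier(
        priors="equal" if equal_priors else "proportional",
        reg_factor=reg_factor)
    return clf.fit(X, y)


def classify_ml(bands: Sequence[RasterGrid],
                model: MaximumLikelihoodClassifier,
                legend: Mapping[int, str] | None = None,
                nodata_label: int = -1) -> LandCoverMap:
    """Classify every valid pixel; nodata in any band propagates."""
    check_is_fitted(model, "classes_")
    ref = bands[0]
    for b in bands[1:]:
        _require_alignment(ref, b)
    if model.n_features_in_ != len(bands):
        raise ValueError(f"model was fitted on {model.n_features_in_} bands, "
                         f"got {len(bands)}")
    valid = np.ones(ref.shape, dtype=bool)
    for b in bands:
        valid &= b.mask()
    stack = np.stack([b.values for b in bands], axis=-1)
    labels = np.full(ref.shape, nodata_label, dtype=int)
    labels[valid] = model.predict(stack[valid])
    grid = RasterGrid(values=labels, origin=ref.origin,
                      pixel_size=ref.pixel_size, crs=ref.crs,
                      nodata=nodata_label)
    if legend is None:
        legend = {int(k): str(k) for k in model.classes_}
    return LandCoverMap(labels=grid, legend=dict(legend))


@dataclass(frozen=True)
class AccuracyReport:
    """Confusion matrix (reference rows × predicted columns) with summaries."""

    confusion: pd.DataFrame
    overall_accuracy: float
    kappa: float
    n: int

    def __str__(self) -> str:
        return (f"overall accuracy {self.overall_accuracy:.4f}, "
                f"kappa {self.kappa:.4f} (n={self.n})\n{self.confusion}")


def accuracy_assessment(predicted: LandCoverMap,
                        reference: LandCoverMap) -> AccuracyReport:
    """Confusion matrix, overall accuracy and Cohen's kappa over valid pixels.

    kappa = (p_o − p_e)/(1 − p_e) with the expected agreement p_e computed
    from the row/column marginals.
    """
    _require_alignment(predicted.labels, reference.labels)
    valid = predicted.labels.mask() & reference.labels.mask()
    if not valid.any():
        raise ValueError("no overlapping valid pixels to assess")
    pred = predicted.labels.values[valid].astype(int)
    ref = reference.labels.values[valid].astype(int)
    ids = sorted(set(np.unique(pred)) | set(np.unique(ref)))
    index = pd.Index(ids, name="reference")
    cm = pd.DataFrame(0, index=index, columns=pd.Index(ids, name="predicted"))
    pairs, counts = np.unique(np.stack([ref, pred]), axis=1, return_counts=True)
    for (r, p), c in zip(pairs.T, counts):
        cm.loc[r, p] = int(c)
    n = int(cm.values.sum())
    p_o = float(np.trace(cm.values)) / n
    p_e = float(cm.sum(axis=1).values @ cm.sum(axis=0).values) / n ** 2
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return AccuracyReport(confusion=cm, overall_accuracy=p_o, kappa=kappa, n=n)


def area_by_class(lc: LandCoverMap) -> pd.Series:
    """Hectares per class (pixel count × pixel area / 10⁴ m² per ha)."""
    return lc.area_by_class()


def change_analysis(map_t1: LandCoverMap, map_t2: LandCoverMap,
                    years_between: float) -> pd.DataFrame:
    """Two-date per-class area change and annual rate.

    Returns per class: area at each date (ha), Δha = area(t2) − area(t1),
    the signed annual rate Δha/year, and a direction label —
    ``deforestation`` for losses, ``increase`` for gains.
    """
    return change_from_areas(map_t1.area_by_class(), map_t2.area_by_class(),
                             years_between)


def change_from_areas(areas_t1: pd.Series, areas_t2: pd.Series,
                      years_between: float) -> pd.DataFrame:
    """Change analysis from per-class area tables (ha) instead of maps.

    Useful when the two-date areas come from an external tabulation rather
    than in-memory classifications.
    """
    if not years_between > 0:
        raise ValueError("years_between must be > 0")
    a1 = pd.Series(areas_t1, dtype=float)
    a2 = pd.Series(areas_t2, dtype=float)
    classes = a1.index.union(a2.index)
    a1 = a1.reindex(classes, fill_value=0.0)
    a2 = a2.reindex(classes, fill_value=0.0)
    delta = a2 - a1
    rate = delta / years_between
    direction = np.where(delta < 0, "deforestation",
                         np.where(delta > 0, "increase", "stable"))
    return pd.DataFrame({
        "area_t1_ha": a1, "area_t2_ha": a2, "delta_ha": delta,
        "rate_ha_per_year": rate,
        "abs_rate_ha_per_year": rate.abs(),
        "direction": direction,
    })


def write_training_geojson(polygons: Sequence[tuple[int, shapely.Geometry]],
                           path: str | Path,
                           legend: Mapping[int, str] | None = None) -> Path:
    """Training polygons as a GeoJSON FeatureCollection with a `class` property."""
    features = []
    for class_id, geom in polygons:
        props = {"class": int(class_id)}
        if legend and class_id in legend:
            props["name"] = legend[class_id]
        features.append({"type": "Feature", "properties": props,
                         "geometry": shapely_mapping(geom)})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))
    return Path(path)


def read_training_geojson(path: str | Path) -> list[tuple[int, shapely.Geometry]]:
    data = json.loads(Path(path).read_text())
    return [(int(f["properties"]["class"]), shapely_shape(f["geometry"]))
            for f in data["features"]]
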
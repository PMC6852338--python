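"""Synthetic inputs with known ground truth for the whole pipeline.

Every stage of the inventory — classification, temperature interpolation,
emission modelling, correlation analysis — is exercised here against data
whose generating process is known exactly: class-separable two-band
reflectance scenes with labelled patches, diurnally and seasonally
structured station temperature series on an altitude gradient, spectral
signature libraries with detector-junction steps and planted outliers, and
VOC/meteorology tables with prescribed population correlations.

Reproducibility: each generator derives its own independent random stream
as ``default_rng([STREAM_TAG, seed])``, so the same seed always yields
bit-identical output and the four generators never share a stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from shapely.geometry import box

from .raster import LandCoverMap, RasterGrid
from .spectra import SpectralSignature
from .tempfield import StationRecord

__all__ = [
    "ClassSpec",
    "SceneSpec",
    "StationSpec",
    "MetVocSpec",
    "generate_scene",
    "generate_station_series",
    "generate_signatures",
    "generate_voc_met_series",
]

# stream tags keep the four generators on disjoint random streams
_STREAM_SCENE, _STREAM_STATIONS, _STREAM_SIGNATURES, _STREAM_MET = 11, 13, 17, 19


def _rng(tag: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([tag, seed])


# ---------------------------------------------------------------------------
# reflectance scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassSpec:
    """One land-cover class: id, name, band means and per-band noise std."""

    class_id: int
    name: str
    mean_red: float
    mean_nir: float
    std: float

    def __post_init__(self) -> None:
        if not (0 <= self.mean_red <= 1 and 0 <= self.mean_nir <= 1):
            raise ValueError("reflectance means must lie in [0, 1]")
        if self.std < 0:
            raise ValueError(f"class {self.class_id}: std must be >= 0")


@dataclass(frozen=True)
class SceneSpec:
    """A two-band scene with labelled polygonal class patches.

    Defaults emulate a 30 m-pixel two-band (red, near-infrared) scene over
    three forest species, with class means separated by several band
    standard deviations so the classes are spectrally distinct but not
    trivially so.  ``patches`` maps class ids to polygons in map
    coordinates; when omitted, equal vertical strips covering the grid are
    used.  Polygons of different classes must not overlap.
    """

    width: int = 200
    height: int = 200
    pixel_size: float = 30.0
    classes: tuple[ClassSpec, ...] = (
        ClassSpec(1, "Eucalyptus globulus", 0.05, 0.45, 0.02),
        ClassSpec(2, "Pinus radiata", 0.08, 0.35, 0.02),
        ClassSpec(3, "Alnus acuminata", 0.04, 0.55, 0.02),
    )
    patches: tuple[tuple[int, shapely.Geometry], ...] | None = None
    origin: tuple[float, float] = (750000.0, 9815000.0)  # UTM-like
    crs: str = "EPSG:32717"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("a scene needs at least 2 classes")
        ids = [c.class_id for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate class ids")

    def legend(self) -> dict[int, str]:
        return {c.class_id: c.name for c in self.classes}

    def resolved_patches(self) -> list[tuple[int, shapely.Geometry]]:
        if self.patches is not None:
            geoms = list(self.patches)
        else:  # default: vertical strips of equal width covering the grid
            x0, y0 = self.origin
            w_m = self.width * self.pixel_size
            h_m = self.height * self.pixel_size
            strip = w_m / len(self.classes)
            geoms = [(c.class_id,
                      box(x0 + i * strip, y0 - h_m, x0 + (i + 1) * strip, y0))
                     for i, c in enumerate(self.classes)]
        for i, (ci, gi) in enumerate(geoms):
            for cj, gj in geoms[i + 1:]:
                inter = gi.intersection(gj)
                if not inter.is_empty and inter.area > 1e-9:
                    raise ValueError(f"patches of classes {ci} and {cj} overlap")
        return geoms


def generate_scene(spec: SceneSpec,
                   training_fraction: float = 0.5,
                   ) -> tuple[RasterGrid, RasterGrid, LandCoverMap,
                              list[tuple[int, shapely.Geometry]]]:
    """Draw a two-band scene: (red, nir, truth map, training polygons).

    Band values are Gaussian around the class means, clipped to [0, 1].
    Training polygons are the class patches shrunk towards their centroid
    by ``training_fraction`` in linear scale — strict subsets of the true
    patches, as field training areas would be.
    """
    rng = _rng(_STREAM_SCENE, spec.seed)
    by_id = {c.class_id: c for c in spec.classes}
    geoms = spec.resolved_patches()

    grid0 = RasterGrid(values=np.zeros((spec.height, spec.width)),
                       origin=spec.origin, pixel_size=spec.pixel_size,
                       crs=spec.crs)
    gx, gy = grid0.cell_centers()
    labels = np.full((spec.height, spec.width), -1, dtype=int)
    for class_id, geom in geoms:
        inside = shapely.contains_xy(geom, gx, gy)
        labels[inside] = class_id
    uncovered = labels == -1
    if uncovered.any():
        raise ValueError(f"patch geometry leaves {int(uncovered.sum())} pixels "
                         "without a class; patches must cover the grid")

    red = np.empty_like(gx)
    nir = np.empty_like(gx)
    for class_id, c in by_id.items():
        sel = labels == class_id
        n = int(sel.sum())
        red[sel] = c.mean_red + c.std * rng.standard_normal(n)
        nir[sel] = c.mean_nir + c.std * rng.standard_normal(n)
    red = np.clip(red, 0.0, 1.0)
    nir = np.clip(nir, 0.0, 1.0)

    truth = LandCoverMap(labels=grid0.with_values(labels, nodata=-1),
                         legend=spec.legend())
    training = []
    for class_id, geom in geoms:
        shrunk = shapely.affinity.scale(geom, xfact=training_fraction,
                                        yfact=training_fraction,
                                        origin="centroid")
        training.append((class_id, shrunk))
    return (grid0.with_values(red), grid0.with_values(nir), truth, training)


# ---------------------------------------------------------------------------
# station temperature series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StationSpec:
    """Synthetic meteorological-station network on an altitude gradient.

    Defaults emulate a seven-station Andean network between roughly 2700
    and 3600 m: a base temperature at the reference altitude, a small
    seasonal cycle (equatorial), a ~5 °C diurnal cycle peaking at 14:00
    local (early afternoon is the warmest stretch of the day), a linear
    lapse with altitude, and Gaussian observation noise.
    """

    n_stations: int = 7
    altitude_range: tuple[float, float] = (2700.0, 3600.0)
    ref_altitude: float = 3000.0
    base_temp: float = 13.0          # °C at the reference altitude
    lapse_rate: float = 0.0065       # °C per m
    diurnal_amplitude: float = 5.0   # °C, half peak-to-trough
    seasonal_amplitude: float = 1.0  # °C
    peak_hour: int = 14
    peak_day_of_year: int = 46       # mid-February
    noise_std: float = 0.5           # °C
    bbox: tuple[float, float, float, float] = (748000.0, 9800000.0,
                                               762000.0, 9815000.0)
    seed: int = 0


def generate_station_series(spec: StationSpec, n_days: int,
                            start: str = "2014-01-01") -> list[StationRecord]:
    """Hourly temperature series for ``n_days`` complete days per station.

    T(t) = base + seasonal·cos(2π (doy − peak_doy)/365)
         + diurnal·cos(2π (hour − peak_hour)/24)
         − lapse·(altitude − ref_altitude) + N(0, noise²)
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = _rng(_STREAM_STATIONS, spec.seed)
    x0, y0, x1, y1 = spec.bbox
    xs = rng.uniform(x0, x1, spec.n_stations)
    ys = rng.uniform(y0, y1, spec.n_stations)
    alts = rng.uniform(*spec.altitude_range, spec.n_stations)

    idx = pd.date_range(start, periods=24 * n_days, freq="h")
    doy = idx.dayofyear.to_numpy()
    hour = idx.hour.to_numpy()
    seasonal = spec.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - spec.peak_day_of_year) / 365.0)
    diurnal = spec.diurnal_amplitude * np.cos(
        2 * np.pi * (hour - spec.peak_hour) / 24.0)

    stations = []
    for i in range(spec.n_stations):
        temps = (spec.base_temp + seasonal + diurnal
                 - spec.lapse_rate * (alts[i] - spec.ref_altitude)
                 + spec.noise_std * rng.standard_normal(len(idx)))
        stations.append(StationRecord(
            station_id=f"ST{i + 1:02d}", x=float(xs[i]), y=float(ys[i]),
            altitude=float(alts[i]), series=pd.Series(temps, index=idx),
            allow_out_of_range=True))
    return stations


# ---------------------------------------------------------------------------
# spectral signature libraries
# ---------------------------------------------------------------------------

def generate_signatures(n_samples: int,
                        wavelengths: np.ndarray,
                        archetype: np.ndarray,
                        noise_std: float = 0.005,
                        jump_offsets: dict[float, float] | None = None,
                        outlier_fraction: float = 0.0,
                        outlier_scale: float = 10.0,
                        species: str = "", state: str = "sapling",
                        plot_id: str = "P1", seed: int = 0,
                        ) -> tuple[list[SpectralSignature], np.ndarray]:
    """Spectra around an archetype, with detector steps and planted outliers.

    Non-outlier spectra are ``archetype + N(0, noise²)`` plus an additive
    step of the configured size at each detector-junction wavelength (the
    default junctions 1000 and 1800 nm are typical field-spectrometer
    detector boundaries).  Outliers additionally shift by
    ``outlier_scale × noise_std``; exactly ``round(outlier_fraction × n)``
    of them are planted and flagged in the returned ground-truth mask.
    """
    if not 0 <= outlier_fraction < 1:
        raise ValueError("outlier_fraction must be in [0, 1)")
    w = np.asarray(wavelengths, dtype=float)
    base = np.asarray(archetype, dtype=float)
    if base.shape != w.shape:
        raise ValueError("archetype and wavelength grid length mismatch")
    if jump_offsets is None:
        jump_offsets = {1000.0: 0.05, 1800.0: -0.03}
    rng = _rng(_STREAM_SIGNATURES, seed)

    step = np.zeros_like(base)
    for junction, offset in jump_offsets.items():
        step[w > junction] += offset

    n_out = int(round(outlier_fraction * n_samples))
    flags = np.zeros(n_samples, dtype=bool)
    if n_out:
        flags[rng.choice(n_samples, size=n_out, replace=False)] = True

    sigs = []
    for i in range(n_samples):
        r = base + step + noise_std * rng.standard_normal(len(w))
        if flags[i]:
            r = r + outlier_scale * noise_std
        sigs.append(SpectralSignature(
            wavelengths=w, reflectance=np.clip(r, 0.0, 1.0),
            species=species, vegetative_state=state, plot_id=plot_id,
            sample_id=f"S{i + 1:04d}"))
    return sigs, flags


# ---------------------------------------------------------------------------
# VOC / meteorology tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetVocSpec:
    """VOC concentrations driven linearly by meteorology.

    VOC = intercept + b_T·T + b_R·R + b_W·W + N(0, noise²) with independent
    Gaussian drivers; the coefficient signs (+, +, −) encode the physical
    expectation that emissions rise with temperature and radiation and
    concentrations fall with wind dilution.  Observation times sit between
    11:00 and 15:00, the warmest stretch of the day.
    """

    n_obs: int = 500
    intercept: float = 20.0
    b_temp: float = 4.0      # ppb per °C  (> 0)
    b_rad: float = 0.02      # ppb per W m⁻²  (> 0)
    b_wind: float = -6.0     # ppb per m s⁻¹  (< 0)
    temp_mean: float = 16.0
    temp_std: float = 3.0
    rad_mean: float = 600.0
    rad_std: float = 150.0
    wind_mean: float = 3.0
    wind_std: float = 1.0
    noise_std: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_obs < 10:
            raise ValueError("n_obs must be >= 10")
        if not (self.b_temp > 0 and self.b_rad > 0 and self.b_wind < 0):
            raise ValueError("coefficient signs must be +temperature, "
                             "+radiation, −wind")

    def voc_std(self) -> float:
        return float(np.sqrt((self.b_temp * self.temp_std) ** 2
                             + (self.b_rad * self.rad_std) ** 2
                             + (self.b_wind * self.wind_std) ** 2
                             + self.noise_std ** 2))

    def population_correlations(self) -> dict[str, float]:
        """Closed-form corr(VOC, driver) for independent Gaussian drivers."""
        s = self.voc_std()
        return {
            "temperature": self.b_temp * self.temp_std / s,
            "radiation": self.b_rad * self.rad_std / s,
            "wind": self.b_wind * self.wind_std / s,
        }


def generate_voc_met_series(spec: MetVocSpec,
                            start: str = "2018-10-08") -> pd.DataFrame:
    """Table (time, voc, no2, temperature, radiation, wind) per the spec.

    NO₂ is generated as a second linear response to temperature and
    radiation (for the two-way comparisons); its generating coefficients
    are fixed, not part of the spec surface.
    """
    rng = _rng(_STREAM_MET, spec.seed)
    n = spec.n_obs
    temp = spec.temp_mean + spec.temp_std * rng.standard_normal(n)
    rad = spec.rad_mean + spec.rad_std * rng.standard_normal(n)
    wind = np.abs(spec.wind_mean + spec.wind_std * rng.standard_normal(n))
    voc = (spec.intercept + spec.b_temp * temp + spec.b_rad * rad
           + spec.b_wind * wind + spec.noise_std * rng.standard_normal(n))
    no2 = 10.0 + 0.5 * temp + 0.005 * rad + 2.0 * rng.standard_normal(n)

    # observation times within the 11:00–15:00 window across successive days
    days = pd.Timestamp(start) + pd.to_timedelta(np.arange(n) // 16, unit="D")
    minutes = (np.arange(n) % 16) * 15
    times = days + pd.Timedelta(hours=11) + pd.to_timedelta(minutes, unit="m")
    return pd.DataFrame({"time": times, "voc": voc, "no2": no2,
                         "temperature": temp, "radiation": rad, "wind": wind})
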
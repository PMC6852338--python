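"""Guenther-model biogenic VOC emissions and their temporal aggregation.

The hourly emission of a compound class (monoterpenes or other BVOC) from
one grid cell mapped to land-use class J is

    E(K, hour) = EF_J × M(T) × FBD_J × A        [µg/h]

where EF_J is the standard emission factor (µg g⁻¹ h⁻¹) at the standard
temperature, FBD_J the foliar biomass density (g m⁻²), A the cell area
(900 m² for a 30 m pixel) and M(T) = exp(β (T − T_s)) the temperature
correction with β = 0.09 K⁻¹ and T_s = 303 K.  Aggregation is fixed by
construction: a day is the sum of its 24 hours, a month is 30 × one
representative day, a year is the sum of its 12 months.  Totals are
reported in metric tons (1 t = 10¹² µg).

Temperatures are handled in °C everywhere else in the pipeline and
converted to K only here (T_K = T_C + 273.15).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import LandCoverMap, RasterGrid, _require_alignment

__all__ = [
    "SpeciesEmissionParams",
    "EmissionModelConstants",
    "temperature_factor",
    "hourly_emission",
    "aggregate_daily",
    "aggregate_monthly",
    "aggregate_annual",
    "inventory",
    "read_params_csv",
    "write_params_csv",
    "celsius_to_kelvin",
    "UG_PER_TON",
    "DAYS_PER_MONTH",
]

UG_PER_TON = 1e12  # metric ton = 10^6 g = 10^12 µg
DAYS_PER_MONTH = 30  # fixed 30-day month in the aggregation scheme
COMPOUNDS = ("monoterpene", "bvoc")


def celsius_to_kelvin(t_c):
    return np.asarray(t_c, dtype=float) + 273.15


@dataclass(frozen=True)
class SpeciesEmissionParams:
    """Per land-use class J: emission factors and foliar biomass density."""

    class_id: int
    species: str
    ef_monoterpene: float  # µg g⁻¹ h⁻¹ at standard temperature
    ef_bvoc: float         # µg g⁻¹ h⁻¹ at standard temperature
    foliar_biomass_density: float  # g m⁻² dry leaf biomass

    def __post_init__(self) -> None:
        for name in ("ef_monoterpene", "ef_bvoc", "foliar_biomass_density"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def ef(self, compound: str) -> float:
        if compound == "monoterpene":
            return self.ef_monoterpene
        if compound == "bvoc":
            return self.ef_bvoc
        raise ValueError(f"compound must be one of {COMPOUNDS}, got {compound!r}")


@dataclass(frozen=True)
class EmissionModelConstants:
    """Model constants: β (K⁻¹), standard temperature (K), cell area (m²)."""

    beta: float = 0.09
    t_standard: float = 303.0
    cell_area: float = 900.0

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.t_standard <= 0 or self.cell_area <= 0:
            raise ValueError("beta, t_standard and cell_area must all be > 0")


def temperature_factor(t_kelvin, constants: EmissionModelConstants = EmissionModelConstants()):
    """Temperature correction M(T) = exp(β (T − T_s)); M(T_s) = 1.

    Strictly increasing in T, so warmer hours always emit more.
    """
    t = np.asarray(t_kelvin, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be > 0 K")
    out = np.exp(constants.beta * (t - constants.t_standard))
    return float(out) if np.isscalar(t_kelvin) else out


def hourly_emission(params: SpeciesEmissionParams, t_kelvin,
                    constants: EmissionModelConstants = EmissionModelConstants(),
                    compound: str = "monoterpene"):
    """Hourly cell emission EF × M(T) × FBD × A in µg/h."""
    ef = params.ef(compound)
    return ef * temperature_factor(t_kelvin, constants) * \
        params.foliar_biomass_density * constants.cell_area


def aggregate_daily(hourly: Sequence[float] | np.ndarray) -> float | np.ndarray:
    """Daily emission: sum of exactly 24 hourly values (µg/day)."""
    arr = np.asarray(hourly, dtype=float)
    if arr.shape[0] != 24:
        raise ValueError(f"need exactly 24 hourly values, got {arr.shape[0]}")
    return arr.sum(axis=0)


def aggregate_monthly(daily: float | np.ndarray) -> float | np.ndarray:
    """Monthly emission: 30 × daily, irrespective of calendar month length."""
    daily = np.asarray(daily, dtype=float)
    if np.any(daily < 0):
        raise ValueError("daily emission must be >= 0")
    out = DAYS_PER_MONTH * daily
    return float(out) if out.ndim == 0 else out


def aggregate_annual(monthly: Sequence[float] | np.ndarray) -> float | np.ndarray:
    """Annual emission: sum of exactly 12 monthly values."""
    arr = np.asarray(monthly, dtype=float)
    if arr.shape[0] != 12:
        raise ValueError(f"need exactly 12 monthly values, got {arr.shape[0]}")
    return arr.sum(axis=0)


def inventory(landcover: LandCoverMap,
              temperature_surfaces: Mapping[int, Sequence[RasterGrid]],
              params: Mapping[int, SpeciesEmissionParams] | Sequence[SpeciesEmissionParams],
              constants: EmissionModelConstants | None = None,
              temperatures_in: str = "celsius") -> pd.DataFrame:
    """Species × month × compound emission inventory in metric tons.

    ``temperature_surfaces`` maps each month (1–12) to 24 hourly grids — one
    representative diurnal cycle per month, aligned with the land-cover map.
    For every cell the 24 hourly emissions are summed to a representative
    day, scaled to a 30-day month, and months sum to the year (reported as
    month 0 rows with period ``"annual"``).  Summation order is fixed:
    hours → day → month → year, cells summed per species at month level.

    Returns a tidy frame: species, month, compound, emission_tons.
    """
    if constants is None:
        constants = EmissionModelConstants(cell_area=landcover.pixel_area)
    if not isinstance(params, Mapping):
        params = {p.class_id: p for p in params}
    class_ids = landcover.class_ids()
    missing = [c for c in class_ids if c not in params]
    if missing:
        names = {c: landcover.legend.get(c, str(c)) for c in missing}
        raise ValueError(f"no emission parameters for mapped class(es): {names}")
    months = sorted(temperature_surfaces)
    if months != list(range(1, 13)):
        raise ValueError(f"need temperature surfaces for months 1..12, got {months}")

    labels = landcover.labels
    valid = labels.mask()
    rows = []
    annual = {(c, comp): 0.0 for c in class_ids for comp in COMPOUNDS}
    for month in months:
        grids = list(temperature_surfaces[month])
        if len(grids) != 24:
            raise ValueError(f"month {month}: need 24 hourly surfaces, "
                             f"got {len(grids)}")
        for g in grids:
            _require_alignment(labels, g)
        # M(T) per cell per hour, then hour-sum (Eq. chain: hourly -> daily)
        m_sum = np.zeros(labels.shape)
        for g in grids:
            t = g.values
            t_k = celsius_to_kelvin(t) if temperatures_in == "celsius" else t
            m_sum += temperature_factor(np.where(valid, t_k, constants.t_standard),
                                        constants)
        for class_id in class_ids:
            cells = valid & (labels.values == class_id)
            p = params[class_id]
            m_month = DAYS_PER_MONTH * float(m_sum[cells].sum())
            for comp in COMPOUNDS:
                ug = p.ef(comp) * p.foliar_biomass_density * \
                    constants.cell_area * m_month
                tons = ug / UG_PER_TON
                annual[(class_id, comp)] += tons
                rows.append({"species": landcover.legend.get(class_id, str(class_id)),
                             "class_id": class_id, "month": month,
                             "compound": comp, "period": "monthly",
                             "emission_tons": tons})
    for (class_id, comp), tons in annual.items():
        rows.append({"species": landcover.legend.get(class_id, str(class_id)),
                     "class_id": class_id, "month": 0, "compound": comp,
                     "period": "annual", "emission_tons": tons})
    return pd.DataFrame(rows)


def synthetic_default_params() -> list[SpeciesEmissionParams]:
    """Synthetic default parameter table for the three study species.

    These are NOT the study's measured values — they are plausible
    Guenther-class magnitudes (high monoterpene emitters for eucalypt and
    pine, a near-zero monoterpene but moderate other-BVOC emitter for
    alder) so that tests and demonstration runs need no external table.
    Real runs should load their own table with :func:`read_params_csv`.
    """
    return [
        SpeciesEmissionParams(1, "Eucalyptus globulus", 3.0, 1.5, 350.0),
        SpeciesEmissionParams(2, "Pinus radiata", 2.4, 1.2, 500.0),
        SpeciesEmissionParams(3, "Alnus acuminata", 0.1, 1.5, 320.0),
    ]


def write_params_csv(params: Sequence[SpeciesEmissionParams], path: str | Path) -> Path:
    pd.DataFrame([{
        "class_id": p.class_id, "species": p.species,
        "ef_mon_ug_g_h": p.ef_monoterpene, "ef_bvoc_ug_g_h": p.ef_bvoc,
        "fbd_g_m2": p.foliar_biomass_density,
    } for p in params]).to_csv(path, index=False)
    return Path(path)


def read_params_csv(path: str | Path) -> dict[int, SpeciesEmissionParams]:
    df = pd.read_csv(path)
    out = {}
    for _, r in df.iterrows():
        p = SpeciesEmissionParams(
            class_id=int(r["class_id"]), species=str(r["species"]),
            ef_monoterpene=float(r["ef_mon_ug_g_h"]),
            ef_bvoc=float(r["ef_bvoc_ug_g_h"]),
            foliar_biomass_density=float(r["fbd_g_m2"]))
        out[p.class_id] = p
    return out
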
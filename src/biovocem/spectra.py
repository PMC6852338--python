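"""Field spectroradiometry processing.

Raw reflectance spectra from a field spectroradiometer carry two kinds of
artifact: step discontinuities at the junctions between the instrument's
detectors (typically near 1000 and 1800 nm), and whole spectra that fall
out of the trend of their species/vegetative-state group (probe slippage,
illumination changes).  This module corrects the jumps, rejects the
outliers, forms the representative (mean) signature per group, and computes
the field NDVI from the red (640-670 nm) and near-infrared (850-880 nm)
window means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralSignature",
    "SignatureGroup",
    "jump_correct",
    "reject_outliers",
    "representative_signature",
    "field_ndvi",
    "read_signatures_csv",
    "write_signatures_csv",
    "RED_WINDOW_NM",
    "NIR_WINDOW_NM",
]

#: NDVI wavelength windows (nm), inclusive on both ends.
RED_WINDOW_NM = (640.0, 670.0)
NIR_WINDOW_NM = (850.0, 880.0)

# canonical vegetative-state vocabulary; field sheets use several synonyms
_STATE_ALIASES = {
    "sapling": "sapling", "small trees": "sapling", "small": "sapling",
    "timber": "timber", "high trees": "timber", "high tress": "timber",
    "high": "timber",
}


def canonical_state(state: str) -> str:
    """Map a vegetative-state label to the canonical sapling/timber vocabulary."""
    key = state.strip().lower()
    return _STATE_ALIASES.get(key, key)


@dataclass(frozen=True)
class SpectralSignature:
    """One reflectance spectrum tagged with its provenance.

    ``wavelengths`` are in nm and strictly increasing; ``reflectance`` is a
    fraction.  Values slightly above 1 (up to 1.2) are tolerated before jump
    correction; correction clips to [0, 1].
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    species: str = ""
    vegetative_state: str = ""
    plot_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if w.ndim != 1 or r.shape != w.shape:
            raise ValueError("wavelengths and reflectance must be 1-D and equal length")
        if w.size and np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectance must be finite")
        if r.size and (r.min() < 0 or r.max() > 1.2):
            raise ValueError(
                f"reflectance out of tolerated range [0, 1.2]: [{r.min()}, {r.max()}]"
            )
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "reflectance", r)
        object.__setattr__(self, "vegetative_state", canonical_state(self.vegetative_state))


@dataclass(frozen=True)
class SignatureGroup:
    """Signatures sharing species + vegetative state, on a common grid."""

    members: tuple[SpectralSignature, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty signature group")
        w0 = self.members[0].wavelengths
        for m in self.members[1:]:
            if not np.array_equal(m.wavelengths, w0):
                raise ValueError("group members must share a common wavelength grid")
        object.__setattr__(self, "members", tuple(self.members))

    @property
    def wavelengths(self) -> np.ndarray:
        return self.members[0].wavelengths

    def stack(self) -> np.ndarray:
        return np.stack([m.reflectance for m in self.members])

    @property
    def pooled_std(self) -> np.ndarray:
        """Per-wavelength standard deviation across members (ddof=1)."""
        return self.stack().std(axis=0, ddof=1) if len(self.members) > 1 else \
            np.zeros_like(self.wavelengths)

    @property
    def representative(self) -> SpectralSignature:
        return representative_signature(self)


def jump_correct(sig: SpectralSignature,
                 junction_wavelengths: Sequence[float] = (1000.0, 1800.0),
                 ) -> SpectralSignature:
    """Remove detector-junction steps by additive level matching.

    For each junction wavelength, the segment strictly beyond it is shifted
    by a constant so that the first value after the junction equals the last
    value before it.  Junctions are processed left to right, so shifts
    cascade.  The result is clipped to [0, 1].  A spectrum without steps is
    returned unchanged (up to clipping), which makes the operation
    idempotent.
    """
    w, r = sig.wavelengths, sig.reflectance.copy()
    for j in sorted(junction_wavelengths):
        left = np.nonzero(w <= j)[0]
        right = np.nonzero(w > j)[0]
        if left.size == 0 or right.size == 0:
            raise ValueError(f"junction {j} nm lies outside the wavelength grid "
                             f"[{w[0]}, {w[-1]}]")
        r[right] -= r[right[0]] - r[left[-1]]
    return replace(sig, reflectance=np.clip(r, 0.0, 1.0))


def reject_outliers(group: SignatureGroup | Iterable[SpectralSignature],
                    k: float = 3.0,
                    ) -> tuple[list[SpectralSignature], list[SpectralSignature]]:
    """Single-pass rejection of spectra out of the trend of their group.

    A member is rejected when the mean absolute deviation of its spectrum
    from the per-wavelength group median exceeds ``k`` times a robust
    grid-average spread (1.4826 × median absolute deviation per
    wavelength).  The robust centre and scale keep planted outliers from
    masking themselves by inflating the group statistics.  Returns
    ``(kept, rejected)``; ``k=inf`` keeps everything.
    """
    if not isinstance(group, SignatureGroup):
        group = SignatureGroup(tuple(group))
    if len(group.members) < 3:
        raise ValueError("outlier rejection needs at least 3 group members")
    stack = group.stack()
    center = np.median(stack, axis=0)
    dev = stack - center
    scale = float(np.mean(1.4826 * np.median(np.abs(dev), axis=0)))
    mad = np.abs(dev).mean(axis=1)
    if np.isinf(k):
        bad = np.zeros(len(group.members), dtype=bool)
    elif scale == 0.0:
        # degenerate spread: members identical up to exact departures
        bad = mad > 0.0
    else:
        bad = mad > k * scale
    if bad.all():
        raise ValueError("all members rejected — degenerate group "
                         f"(k={k} too small or group inconsistent)")
    kept = [m for m, b in zip(group.members, bad) if not b]
    rejected = [m for m, b in zip(group.members, bad) if b]
    return kept, rejected


def representative_signature(group: SignatureGroup | Iterable[SpectralSignature],
                             ) -> SpectralSignature:
    """Per-wavelength arithmetic mean spectrum of a (cleaned) group."""
    if not isinstance(group, SignatureGroup):
        group = SignatureGroup(tuple(group))
    first = group.members[0]
    return SpectralSignature(
        wavelengths=group.wavelengths,
        reflectance=group.stack().mean(axis=0),
        species=first.species,
        vegetative_state=first.vegetative_state,
        plot_id=first.plot_id,
        sample_id="representative",
    )


def field_ndvi(sig: SpectralSignature,
               red_window: tuple[float, float] = RED_WINDOW_NM,
               nir_window: tuple[float, float] = NIR_WINDOW_NM) -> float:
    """NDVI from window-mean reflectances: (NIR - R) / (NIR + R).

    R is the mean reflectance over the red window, NIR over the
    near-infrared window; both windows are inclusive at their bounds.
    """
    w, r = sig.wavelengths, sig.reflectance
    means = []
    for lo, hi in (red_window, nir_window):
        sel = (w >= lo) & (w <= hi)
        if not sel.any():
            raise ValueError(f"wavelength grid does not cover window [{lo}, {hi}] nm")
        means.append(float(r[sel].mean()))
    red, nir = means
    if nir + red == 0:
        raise ZeroDivisionError("NDVI undefined: NIR + R = 0")
    return (nir - red) / (nir + red)


def write_signatures_csv(signatures: Iterable[SpectralSignature],
                         path: str | Path) -> Path:
    """Long-format CSV: wavelength_nm, reflectance, species, state, plot, sample."""
    frames = []
    for s in signatures:
        frames.append(pd.DataFrame({
            "wavelength_nm": s.wavelengths,
            "reflectance": s.reflectance,
            "species": s.species,
            "state": s.vegetative_state,
            "plot": s.plot_id,
            "sample": s.sample_id,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def read_signatures_csv(path: str | Path, unit: str = "fraction",
                        ) -> list[SpectralSignature]:
    """Read long-format signatures; ``unit`` is ``fraction`` or ``percent``."""
    if unit not in ("fraction", "percent"):
        raise ValueError(f"unit must be 'fraction' or 'percent', got {unit!r}")
    df = pd.read_csv(path, dtype={"plot": str, "sample": str})
    scale = 0.01 if unit == "percent" else 1.0
    out = []
    for (species, state, plot, sample), g in df.groupby(
            ["species", "state", "plot", "sample"], sort=False):
        g = g.sort_values("wavelength_nm")
        out.append(SpectralSignature(
            wavelengths=g["wavelength_nm"].to_numpy(float),
            reflectance=g["reflectance"].to_numpy(float) * scale,
            species=str(species), vegetative_state=str(state),
            plot_id=str(plot), sample_id=str(sample),
        ))
    return out
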
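"""Spectra and leaf optical properties on the fixed PAR band grid.

All spectral quantities in this package live on a common grid of 60
half-open 5-nm bands covering the photosynthetically active range,
[400, 700) nm.  A :class:`SpectrumGrid` value is the *band-integrated*
photon flux (µmol m⁻² s⁻¹ per band), not a spectral density, so total
flux is an exact sum over bands.  Optical coefficient spectra
(reflectance R, transmittance T, absorptance a = 1 − R − T) use the same
grid with dimensionless values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "N_BANDS",
    "BAND_EDGES",
    "BAND_CENTERS",
    "SpectrumGrid",
    "LeafOptics",
    "band_index",
    "leaf_absorptance",
    "weighted_absorption_fraction",
    "make_led_spectrum",
    "make_white_spectrum",
    "read_spectrum_csv",
    "read_leaf_optics_csv",
]

#: number of 5-nm bands between 400 and 700 nm
N_BANDS = 60
#: band edges, nm (length 61, monotone increasing)
BAND_EDGES = np.arange(400.0, 701.0, 5.0)
#: band centers, nm (length 60)
BAND_CENTERS = 0.5 * (BAND_EDGES[:-1] + BAND_EDGES[1:])

#: tolerance used when validating R + T <= 1 (inputs may be rounded at 6 decimals)
RT_TOL = 1e-9


def band_index(wavelength_nm: float) -> int:
    """Index of the half-open band [λ, λ+5) containing ``wavelength_nm``."""
    if not (BAND_EDGES[0] <= wavelength_nm < BAND_EDGES[-1]):
        raise ValueError(f"wavelength {wavelength_nm} nm outside PAR range [400, 700)")
    return int((wavelength_nm - BAND_EDGES[0]) // 5.0)


@dataclass(frozen=True)
class SpectrumGrid:
    """One non-negative value per 5-nm band on the 400–700 nm grid.

    Parameters
    ----------
    values
        Array of length 60.  Photon-flux spectra (``kind="flux"``) must be
        non-negative; coefficient spectra (``kind="coefficient"``) must lie
        in [0, 1].
    kind
        Either ``"flux"`` or ``"coefficient"``.
    """

    values: np.ndarray
    kind: str = "flux"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_BANDS,):
            raise ValueError(f"expected {N_BANDS} bands, got shape {v.shape}")
        if self.kind not in ("flux", "coefficient"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "flux":
            if np.any(v < 0):
                raise ValueError("photon-flux spectrum has negative bands")
        else:
            if np.any(v < -RT_TOL) or np.any(v > 1 + RT_TOL):
                raise ValueError("coefficient spectrum outside [0, 1]")
            v = np.clip(v, 0.0, 1.0)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    @property
    def total(self) -> float:
        """Sum over bands (total photon flux for flux spectra)."""
        return float(self.values.sum())

    def scaled(self, factor: float) -> "SpectrumGrid":
        return SpectrumGrid(self.values * factor, kind=self.kind)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": BAND_EDGES[:-1], "value": self.values}
        ).to_csv(path, index=False)


def _validate_grid_column(wl: np.ndarray) -> None:
    if not np.array_equal(np.asarray(wl, dtype=float), BAND_EDGES[:-1]):
        raise ValueError(
            "spectrum file does not use the fixed 400–700 nm, 5-nm band grid "
            "(expected lower edges 400, 405, ..., 695)"
        )


def read_spectrum_csv(path, kind: str = "flux") -> SpectrumGrid:
    """Read a spectrum from CSV with columns ``wavelength_nm`` (band lower edge), ``value``."""
    df = pd.read_csv(path)
    _validate_grid_column(df["wavelength_nm"].to_numpy())
    return SpectrumGrid(df["value"].to_numpy(dtype=float), kind=kind)


@dataclass(frozen=True)
class LeafOptics:
    """Per-band leaf reflectance and transmittance, one set per leaf side.

    Adaxial/abaxial asymmetry is supported but optics default to symmetric:
    pass only the adaxial set and it is mirrored to the abaxial side.
    """

    reflectance: SpectrumGrid
    transmittance: SpectrumGrid
    treatment_label: str = "white"
    reflectance_abaxial: SpectrumGrid | None = field(default=None)
    transmittance_abaxial: SpectrumGrid | None = field(default=None)

    def __post_init__(self) -> None:
        for side in ("adaxial", "abaxial"):
            r, t = self._rt(side)
            excess = r.values + t.values - 1.0
            if np.any(excess > RT_TOL):
                b = int(np.argmax(excess))
                raise ValueError(
                    f"R + T > 1 in band [{BAND_EDGES[b]:.0f}, {BAND_EDGES[b + 1]:.0f}) nm "
                    f"({side}): R={r.values[b]:.6f}, T={t.values[b]:.6f}"
                )

    def _rt(self, side: str) -> tuple[SpectrumGrid, SpectrumGrid]:
        if side == "adaxial":
            return self.reflectance, self.transmittance
        if side == "abaxial":
            return (
                self.reflectance_abaxial or self.reflectance,
                self.transmittance_abaxial or self.transmittance,
            )
        raise ValueError(f"unknown leaf side {side!r}")

    def absorptance(self, side: str = "adaxial") -> SpectrumGrid:
        r, t = self._rt(side)
        a = 1.0 - r.values - t.values
        return SpectrumGrid(np.clip(a, 0.0, 1.0), kind="coefficient")


def leaf_absorptance(optics: LeafOptics, side: str = "adaxial") -> SpectrumGrid:
    """Per-band absorptance a = 1 − R − T for one leaf side."""
    return optics.absorptance(side)


def weighted_absorption_fraction(
    optics: LeafOptics, source: SpectrumGrid, side: str = "adaxial"
) -> float:
    """Source-weighted absorption fraction Σ a(b)·S(b) / Σ S(b).

    This is the single number quantifying what fraction of a given light
    spectrum a leaf absorbs on first interception (the computation behind
    per-treatment "fraction of light absorbed" tables).  Invariant to
    uniform rescaling of the source.
    """
    s = source.values
    total = s.sum()
    if total <= 0:
        raise ValueError("source spectrum has zero total flux")
    a = optics.absorptance(side).values
    return float((a * s).sum() / total)


def make_led_spectrum(peak_nm: float, fwhm_nm: float = 25.0, total_flux: float = 100.0) -> SpectrumGrid:
    """Gaussian-shaped LED band spectrum, truncated to PAR and renormalized.

    The band value is the exact integral of the Gaussian line shape over
    each 5-nm band (via the error function), so the band sum equals
    ``total_flux`` after renormalization.
    """
    if not (BAND_EDGES[0] <= peak_nm <= BAND_EDGES[-1]):
        raise ValueError(f"LED peak {peak_nm} nm outside PAR range 400–700 nm")
    if fwhm_nm <= 0:
        raise ValueError("fwhm must be positive")
    if total_flux < 0:
        raise ValueError("total_flux must be non-negative")
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    z = (BAND_EDGES - peak_nm) / (sigma * np.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    band = np.diff(cdf)
    if total_flux == 0:
        return SpectrumGrid(np.zeros(N_BANDS))
    return SpectrumGrid(band / band.sum() * total_flux)


def make_white_spectrum(total_flux: float = 100.0) -> SpectrumGrid:
    """White-LED band spectrum: 13% blue (400–500), 55% green (500–600), 32% red (600–700).

    Flux is spread uniformly over the 20 bands within each color region, so
    the regional partitions are exact.
    """
    if total_flux < 0:
        raise ValueError("total_flux must be non-negative")
    fractions = (0.13, 0.55, 0.32)
    values = np.empty(N_BANDS)
    for i, frac in enumerate(fractions):
        values[i * 20 : (i + 1) * 20] = frac * total_flux / 20.0
    return SpectrumGrid(values)


def read_leaf_optics_csv(path, treatment_label: str = "white") -> LeafOptics:
    """Read leaf optics from CSV with columns wavelength_nm, reflectance, transmittance [, side]."""
    df = pd.read_csv(path)
    if "side" not in df.columns:
        df = df.assign(side="adaxial")
    parts: dict[str, tuple[SpectrumGrid, SpectrumGrid]] = {}
    for side, sub in df.groupby("side"):
        sub = sub.sort_values("wavelength_nm")
        _validate_grid_column(sub["wavelength_nm"].to_numpy())
        parts[str(side)] = (
            SpectrumGrid(np.round(sub["reflectance"].to_numpy(dtype=float), 6), kind="coefficient"),
            SpectrumGrid(np.round(sub["transmittance"].to_numpy(dtype=float), 6), kind="coefficient"),
        )
    if "adaxial" not in parts:
        raise ValueError("leaf optics file has no adaxial side")
    r_ab, t_ab = parts.get("abaxial", (None, None))
    return LeafOptics(
        reflectance=parts["adaxial"][0],
        transmittance=parts["adaxial"][1],
        treatment_label=treatment_label,
        reflectance_abaxial=r_ab,
        transmittance_abaxial=t_ab,
    )


def write_leaf_optics_csv(optics: LeafOptics, path) -> None:
    frames = []
    sides = ["adaxial"]
    if optics.reflectance_abaxial is not None:
        sides.append("abaxial")
    for side in sides:
        r, t = optics._rt(side)
        frames.append(
            pd.DataFrame(
                {
                    "wavelength_nm": BAND_EDGES[:-1],
                    "reflectance": r.values,
                    "transmittance": t.values,
                    "side": side,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)
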
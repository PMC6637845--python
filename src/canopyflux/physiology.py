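"""Spectrum-dependent leaf photosynthesis.

Gross CO₂ assimilation of a leaflet is modeled with a non-rectangular
hyperbola in the α-weighted absorbed light,

    θ·P² − (αI + P_max)·P + αI·P_max = 0,   P = smaller root,

where αI = Σ_b α(b)·A(b) converts the absorbed band spectrum A into a
CO₂-equivalent driving rate using the per-band quantum efficiency α
(µmol CO₂ per µmol absorbed photons, following the classical action
spectrum: red > green > blue), and P_max is the light-saturated rate
derived from a leaf-age-dependent maximum electron transport rate J_max
through a fixed CO₂-limitation factor at 500 ppm / 22 °C.  The module
reports gross (not net) photosynthesis; dark respiration and stomatal
coupling are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares

from .spectra import BAND_CENTERS, N_BANDS, SpectrumGrid

__all__ = [
    "PhotosynthesisParams",
    "LeafPhotoResult",
    "load_default_config",
    "alpha_band_profile",
    "nonrectangular_hyperbola",
    "leaf_gross_photosynthesis",
    "calibrate_alpha",
    "compute_lue",
]

#: theoretical maximum quantum efficiency: 1 CO2 per 8 photons
ALPHA_MAX = 0.125

#: color-region band masks on the 400–700 nm grid
COLOR_REGIONS = {
    "blue": (400.0, 500.0),
    "green": (500.0, 600.0),
    "red": (600.0, 700.0),
}


def load_default_config() -> dict:
    """Package default configuration (α table, J_max, θ, LED peaks, trace sizes)."""
    with resources.files("canopyflux.data").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def alpha_band_profile(alpha_by_color: dict[str, float]) -> np.ndarray:
    """Expand per-color α values onto the 60-band grid (piecewise by color region)."""
    out = np.empty(N_BANDS)
    for color, (lo, hi) in COLOR_REGIONS.items():
        mask = (BAND_CENTERS >= lo) & (BAND_CENTERS < hi)
        out[mask] = alpha_by_color[color]
    return out


@dataclass(frozen=True)
class PhotosynthesisParams:
    """Leaf photosynthesis parameters.

    ``alpha_band`` is the per-band quantum efficiency (µmol CO₂ µmol⁻¹
    absorbed photons, each value in (0, 1/8]); ``j_max_top`` the maximum
    electron transport rate of young leaves; the age multiplier declines
    linearly with leaf rank from the top down to a floor.
    """

    alpha_band: np.ndarray
    j_max_top: float = 150.0
    theta: float = 0.7
    co2_factor: float = 0.18
    age_decline_per_rank: float = 0.03
    age_decline_floor: float = 0.45
    temperature_C: float = 22.0
    co2_ppm: float = 500.0

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha_band, dtype=float)
        if a.shape != (N_BANDS,):
            raise ValueError(f"alpha_band must have {N_BANDS} bands")
        if np.any(a <= 0) or np.any(a > ALPHA_MAX):
            raise ValueError(f"alpha must be in (0, {ALPHA_MAX}] per band")
        if self.j_max_top <= 0:
            raise ValueError("j_max_top must be positive")
        if not (0.0 <= self.theta < 1.0):
            raise ValueError("theta must be in [0, 1)")
        a.flags.writeable = False
        object.__setattr__(self, "alpha_band", a)

    @classmethod
    def from_config(cls, config: dict | None = None) -> "PhotosynthesisParams":
        cfg = (config or load_default_config())["photosynthesis"]
        return cls(
            alpha_band=alpha_band_profile(cfg["alpha"]),
            j_max_top=cfg["j_max_top"],
            theta=cfg["theta"],
            co2_factor=cfg["co2_factor"],
            age_decline_per_rank=cfg["age_decline_per_rank"],
            age_decline_floor=cfg["age_decline_floor"],
            temperature_C=cfg.get("temperature_C", 22.0),
            co2_ppm=cfg.get("co2_ppm", 500.0),
        )

    def age_decline(self, leaf_rank) -> np.ndarray:
        """J_max multiplier per leaf rank (1 = top, youngest fully active)."""
        rank = np.asarray(leaf_rank)
        return np.maximum(self.age_decline_floor, 1.0 - self.age_decline_per_rank * (rank - 1))

    def p_max(self, leaf_rank) -> np.ndarray:
        """Light-saturated gross rate, µmol CO₂ m⁻² leaf s⁻¹, per rank."""
        return self.j_max_top * self.age_decline(leaf_rank) * self.co2_factor


@dataclass(frozen=True)
class LeafPhotoResult:
    gross_P: float  # µmol CO2 m-2 leaf s-1
    absorbed_PAR: float  # µmol photons m-2 leaf s-1
    effective_alpha: float  # flux-weighted quantum efficiency


def nonrectangular_hyperbola(alpha_I, p_max, theta):
    """Smaller root of θP² − (αI + P_max)P + αI·P_max = 0 (elementwise)."""
    alpha_I = np.asarray(alpha_I, dtype=float)
    p_max = np.asarray(p_max, dtype=float)
    s = alpha_I + p_max
    if theta == 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(s > 0, alpha_I * p_max / np.where(s > 0, s, 1.0), 0.0)
        return out
    disc = s * s - 4.0 * theta * alpha_I * p_max
    return (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * theta)


def leaf_gross_photosynthesis(
    absorbed: SpectrumGrid | np.ndarray,
    params: PhotosynthesisParams,
    leaf_rank: int = 1,
    alpha_multiplier: float = 1.0,
) -> LeafPhotoResult:
    """Gross photosynthesis of one leaflet from its absorbed band spectrum.

    ``absorbed`` is per m² leaf.  At low light P/absorbed approaches the
    flux-weighted α; at saturating light P approaches P_max(rank).
    ``alpha_multiplier`` applies the growth-spectrum quantum-efficiency
    context (leaves developed under different colors differ in α).
    """
    a = absorbed.values if isinstance(absorbed, SpectrumGrid) else np.asarray(absorbed, dtype=float)
    if a.shape != (N_BANDS,):
        raise ValueError(f"absorbed spectrum must have {N_BANDS} bands")
    if np.any(a < 0):
        raise ValueError("absorbed flux must be non-negative")
    total = float(a.sum())
    alpha_I = float((params.alpha_band * a).sum()) * alpha_multiplier
    p_max = float(params.p_max(leaf_rank))
    gross = float(nonrectangular_hyperbola(alpha_I, p_max, params.theta))
    eff = alpha_I / total if total > 0 else 0.0
    return LeafPhotoResult(gross_P=gross, absorbed_PAR=total, effective_alpha=eff)


def compute_lue(gross_P: float, absorbed_flux: float) -> float:
    """Light-use efficiency, µmol CO₂ per mmol absorbed photons.

    ``gross_P`` in µmol CO₂ m⁻² floor s⁻¹ and ``absorbed_flux`` in µmol
    photons m⁻² floor s⁻¹ give LUE = gross_P / (absorbed_flux / 1000).
    """
    if absorbed_flux <= 0:
        raise ValueError("absorbed_flux must be positive")
    return float(gross_P / (absorbed_flux / 1000.0))


def _model_P(alpha: float, irradiance: np.ndarray, p_max: float, theta: float) -> np.ndarray:
    return nonrectangular_hyperbola(alpha * irradiance, p_max, theta)


def calibrate_alpha(
    measurements: pd.DataFrame,
    params: PhotosynthesisParams,
    leaf_rank: int = 5,
) -> dict[str, float]:
    """Least-squares fit of the per-color quantum efficiency α.

    ``measurements`` needs columns ``measurement_color``, ``irradiance``
    (absorbed µmol m⁻² leaf s⁻¹) and ``P`` (gross µmol CO₂ m⁻² leaf s⁻¹);
    one α is fitted per measurement color by minimizing the squared error
    between the non-rectangular-hyperbola prediction and the measured P.
    Raises if the data are all light-saturated (α then unidentifiable).
    """
    required = {"measurement_color", "irradiance", "P"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns {sorted(missing)}")
    p_max = float(params.p_max(leaf_rank))
    theta = params.theta
    out: dict[str, float] = {}
    for color, grp in measurements.groupby("measurement_color"):
        irr = grp["irradiance"].to_numpy(dtype=float)
        P = grp["P"].to_numpy(dtype=float)
        if len(irr) < 1:
            continue

        def residual(x, irr=irr, P=P):
            return _model_P(x[0], irr, p_max, theta) - P

        fit = least_squares(residual, x0=[0.06], bounds=(1e-5, ALPHA_MAX), xtol=1e-12, ftol=1e-12)
        alpha = float(fit.x[0])
        # identifiability: relative sensitivity of P to alpha at the fit
        dP = (_model_P(alpha * 1.01, irr, p_max, theta) - _model_P(alpha * 0.99, irr, p_max, theta)) / 0.02
        with np.errstate(divide="ignore", invalid="ignore"):
            sens = np.abs(dP) / np.maximum(_model_P(alpha, irr, p_max, theta), 1e-12)
        if np.max(sens) < 0.05:
            raise ValueError(
                f"alpha for {color!r} is unidentifiable: all measurements are light-saturated; "
                "supply data in the light-limited regime"
            )
        out[str(color)] = alpha
    return out
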
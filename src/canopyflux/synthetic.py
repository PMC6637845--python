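"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate the four measured inputs of the crop model —
per-treatment leaf architecture, leaf optical spectra, LED source
spectra and leaf gas-exchange calibration data — so that every stage of
the pipeline is testable without external measurements.

Leaf optics are built from smooth Gaussian basis functions with
treatment-specific coefficients, the simplest family reproducing the
measured qualitative structure: reflectance and transmittance peak
around 550 nm (depressing green absorption), green-grown leaves
transmit the most at every wavelength, blue-grown leaves reflect the
most except near 550 nm, and white-light-weighted absorption fractions
land in the 0.85–0.92 range.  Measurement noise is multiplicative
lognormal (CV-parameterized); angle noise is additive Gaussian
truncated to valid ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import PlantArchitecture, architecture_from_row
from .physiology import PhotosynthesisParams, nonrectangular_hyperbola
from .spectra import BAND_CENTERS, LeafOptics, SpectrumGrid

__all__ = [
    "GeneratorConfig",
    "ARCHITECTURE_MEANS",
    "gen_leaf_optics",
    "gen_architecture_table",
    "gen_architectures",
    "gen_photo_measurements",
    "write_all_fixtures",
]

#: measured per-treatment leaf-architecture means (lengths cm, angles degrees)
ARCHITECTURE_MEANS = pd.DataFrame(
    [
        # treatment, length, width, LIA,  RA,  TLA, base, middle, outside, internode
        ("blue", 30.0, 29.0, 67.0, 14.0, -41.0, 15.0, 9.0, -39.0, 4.0),
        ("green", 38.0, 40.0, 82.0, -3.0, -24.0, 14.0, 4.0, -57.0, 5.5),
        ("amber", 38.0, 41.0, 87.0, -18.0, -31.0, 7.0, 4.0, -56.0, 4.8),
        ("red", 37.0, 40.0, 84.0, -12.0, -30.0, 7.0, 5.0, -52.0, 4.8),
        ("redblue", 35.0, 35.0, 74.0, 8.0, -34.0, 10.0, 5.0, -44.0, 4.5),
        ("white", 36.0, 38.0, 75.0, 9.0, -30.0, 12.0, 3.0, -43.0, 4.7),
    ],
    columns=[
        "treatment", "length_cm", "width_cm", "lia_deg", "ra_deg", "tla_deg",
        "base_deg", "middle_deg", "outside_deg", "internode_cm",
    ],
)

_ANGLE_COLUMNS = ["lia_deg", "ra_deg", "tla_deg", "base_deg", "middle_deg", "outside_deg"]
_TREATMENTS = tuple(ARCHITECTURE_MEANS["treatment"])


@dataclass
class GeneratorConfig:
    seed: int = 0
    noise_cv: float = 0.0
    treatments: tuple[str, ...] = _TREATMENTS
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _gauss(mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((BAND_CENTERS - mu) / sigma) ** 2)


def gen_leaf_optics(treatment: str, seed: int = 0, noise_cv: float = 0.0) -> LeafOptics:
    """Smooth synthetic R(λ), T(λ) for one growth-light treatment.

    Base absorptance ≈ 0.93 with a green (550 nm) dip and a small blue
    (450 nm) carotenoid boost; the non-absorbed remainder is split
    between reflectance and transmittance with treatment offsets that
    enforce the measured orderings.
    """
    if treatment not in _TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}; known: {_TREATMENTS}")

    green_dip = 0.115
    if treatment == "green":
        green_dip = 0.125  # green-grown leaves absorb their own color least
    deficit = green_dip * _gauss(550.0, 45.0) - 0.012 * _gauss(450.0, 35.0)
    absorptance = 0.93 - deficit

    # split the non-absorbed fraction: slightly more reflected than transmitted
    non_abs = 1.0 - absorptance
    R = 0.55 * non_abs
    T = 0.45 * non_abs
    if treatment == "green":
        T = T + 0.012  # highest transmission at every wavelength
    elif treatment == "blue":
        R = R + 0.010 * (1.0 - _gauss(550.0, 35.0))  # highest reflection except near 550 nm
    elif treatment in ("red", "amber"):
        T = T + 0.004

    if noise_cv > 0:
        rng = np.random.Generator(np.random.PCG64([seed, hash(treatment) & 0x7FFFFFFF]))
        sigma = np.sqrt(np.log1p(noise_cv**2))
        R = R * rng.lognormal(-0.5 * sigma**2, sigma)
        T = T * rng.lognormal(-0.5 * sigma**2, sigma)
        R = np.clip(R, 0.0, 1.0)
        T = np.clip(T, 0.0, 1.0 - R)

    return LeafOptics(
        reflectance=SpectrumGrid(R, kind="coefficient"),
        transmittance=SpectrumGrid(T, kind="coefficient"),
        treatment_label=treatment,
    )


def gen_architecture_table(seed: int = 0, noise_cv: float = 0.0, n_replicates: int = 1) -> pd.DataFrame:
    """Per-treatment architecture table: measured means plus optional noise replicates.

    With ``noise_cv`` 0 the table is exactly the measured means (one row
    per treatment).  With noise, lengths get multiplicative lognormal
    noise and angles additive Gaussian noise (σ = noise_cv × 30°),
    truncated to the valid ranges of each angle.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    rows = []
    for rep in range(n_replicates):
        df = ARCHITECTURE_MEANS.copy()
        df["replicate"] = rep
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            for col in ("length_cm", "width_cm", "internode_cm"):
                df[col] = df[col] * rng.lognormal(-0.5 * sigma**2, sigma, size=len(df))
            for col in _ANGLE_COLUMNS:
                noise = rng.normal(0.0, noise_cv * 30.0, size=len(df))
                df[col] = df[col] + noise
            df["lia_deg"] = df["lia_deg"].clip(0.0, 179.0)
            for col in _ANGLE_COLUMNS[1:]:
                df[col] = df[col].clip(-89.0, 90.0)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def gen_architectures(seed: int = 0, n_leaves: int = 21) -> dict[str, PlantArchitecture]:
    """Noise-free :class:`PlantArchitecture` per treatment (measured means)."""
    table = gen_architecture_table(seed=seed, noise_cv=0.0)
    return {
        str(row["treatment"]): architecture_from_row(row, n_leaves=n_leaves)
        for _, row in table.iterrows()
    }


def gen_photo_measurements(
    alpha_truth: dict[str, float],
    irradiances=(210.0,),
    noise_cv: float = 0.0,
    seed: int = 0,
    n_per_color: int = 6,
    params: PhotosynthesisParams | None = None,
    leaf_rank: int = 5,
    growth_color: str = "white",
) -> pd.DataFrame:
    """Simulated leaf gas-exchange measurements for α calibration.

    Forward-models gross P through the non-rectangular hyperbola at the
    given absorbed irradiances for each measurement color, then applies
    multiplicative lognormal noise.  Ground truth (``P_true``,
    ``alpha_true``) is stored alongside for recovery tests.
    """
    if params is None:
        params = PhotosynthesisParams.from_config()
    rng = np.random.Generator(np.random.PCG64(seed))
    p_max = float(params.p_max(leaf_rank))
    rows = []
    for color, alpha in alpha_truth.items():
        for k in range(n_per_color):
            irr = float(irradiances[k % len(irradiances)])
            p_true = float(nonrectangular_hyperbola(alpha * irr, p_max, params.theta))
            if noise_cv > 0:
                sigma = np.sqrt(np.log1p(noise_cv**2))
                p_obs = p_true * rng.lognormal(-0.5 * sigma**2, sigma)
            else:
                p_obs = p_true
            rows.append(
                {
                    "growth_color": growth_color,
                    "measurement_color": color,
                    "irradiance": irr,
                    "P": p_obs,
                    "P_true": p_true,
                    "alpha_true": alpha,
                }
            )
    return pd.DataFrame(rows)


def write_all_fixtures(config: GeneratorConfig) -> dict[str, Path]:
    """Write every generated artifact (CSV/YAML) to ``config.out_dir``."""
    from .geometry import LayoutConfig
    from .spectra import write_leaf_optics_csv

    out = Path(config.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    arch_path = out / "architecture.csv"
    gen_architecture_table(config.seed, config.noise_cv).to_csv(arch_path, index=False)
    written["architecture"] = arch_path

    for treatment in config.treatments:
        p = out / f"leaf_optics_{treatment}.csv"
        write_leaf_optics_csv(gen_leaf_optics(treatment, config.seed, config.noise_cv), p)
        written[f"optics_{treatment}"] = p

    meas_path = out / "photo_measurements.csv"
    gen_photo_measurements(
        {"blue": 0.055, "green": 0.065, "red": 0.075},
        noise_cv=config.noise_cv,
        seed=config.seed,
    ).to_csv(meas_path, index=False)
    written["measurements"] = meas_path

    layout_path = out / "layout.yaml"
    LayoutConfig().to_yaml(layout_path)
    written["layout"] = layout_path
    return written
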
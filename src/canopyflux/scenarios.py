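"""Scenario orchestration: the growth-color × exposure-color matrix.

A scenario is defined by the color a (virtual) crop was *grown under* —
which fixes its architecture, leaf optics and quantum-efficiency
context — the color it is *exposed to* — which fixes the lamp spectrum —
and the hierarchical scale (single leaf, 7-leaf young plants, or a
full 21-leaf crop at the target LAI).  The standard 18-scenario preset
combines a white-grown canopy at all three scales under blue/green/red
light (9 runs) with full crops grown under blue, green or red light and
transferred to each of the three colors (9 runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import PlantArchitecture
from .geometry import LayoutConfig, Scene, build_scene, crop_size_scale
from .physiology import (
    PhotosynthesisParams,
    compute_lue,
    load_default_config,
    nonrectangular_hyperbola,
)
from .spectra import SpectrumGrid, make_led_spectrum, make_white_spectrum
from .synthetic import gen_architectures, gen_leaf_optics
from .transport import DEFAULT_SEED, LightSource, trace

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "ScenarioConfig",
    "run_scenario",
    "run_matrix",
    "paper18_specs",
    "pivot_crop_matrix",
]

_COLORS = ("blue", "green", "red", "white")
_SCALES = ("leaf", "plant", "crop")


@dataclass(frozen=True)
class ScenarioSpec:
    grown_under: str
    exposed_to: str
    scale: str
    n_rays: int = 200_000
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.grown_under not in _COLORS and self.grown_under not in ("amber", "redblue"):
            raise ValueError(f"unknown growth color {self.grown_under!r}")
        if self.exposed_to not in _COLORS:
            raise ValueError(f"unknown exposure color {self.exposed_to!r}")
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}")
        if self.n_rays < 1:
            raise ValueError("n_rays must be >= 1")


@dataclass(frozen=True)
class ScenarioResult:
    spec: ScenarioSpec
    absorbance_pct: float
    gross_P: float  # µmol CO2 m-2 floor s-1
    lue: float  # µmol CO2 mmol-1 absorbed photons
    absorbed_flux: float  # µmol photons m-2 floor s-1
    input_flux: float
    conservation: dict
    lai: float

    def to_row(self) -> dict:
        return {
            "grown_under": self.spec.grown_under,
            "exposed_to": self.spec.exposed_to,
            "scale": self.spec.scale,
            "n_rays": self.spec.n_rays,
            "seed": self.spec.seed,
            "absorbance_pct": self.absorbance_pct,
            "gross_P": self.gross_P,
            "lue": self.lue,
            "lai": self.lai,
        }


class ScenarioConfig:
    """Shared model configuration plus scene/size caches for a scenario batch."""

    def __init__(
        self,
        config: dict | None = None,
        layout: LayoutConfig | None = None,
        resolution: int = 16,
        n_trusses: int = 8,
        reference_treatment: str = "white",
    ):
        self.config = config or load_default_config()
        self.layout = layout or LayoutConfig()
        self.resolution = resolution
        self.n_trusses = n_trusses
        self.reference_treatment = reference_treatment
        self.params = PhotosynthesisParams.from_config(self.config)
        self.architectures: dict[str, PlantArchitecture] = gen_architectures()
        self._size_scale: float | None = None
        self._scene_cache: dict[tuple[str, str], Scene] = {}

    @property
    def size_scale(self) -> float:
        """Leaflet size multiplier calibrated on the reference treatment at crop scale."""
        if self._size_scale is None:
            self._size_scale = crop_size_scale(
                self.architectures[self.reference_treatment], self.layout, self.resolution
            )
        return self._size_scale

    def alpha_multiplier(self, grown_under: str) -> float:
        return float(self.config["photosynthesis"]["alpha_growth_multiplier"].get(grown_under, 1.0))

    def source_spectrum(self, color: str) -> SpectrumGrid:
        flux = float(self.config["source"]["total_flux"])
        if color == "white":
            return make_white_spectrum(flux)
        peaks = self.config["led"]["peaks_nm"]
        return make_led_spectrum(float(peaks[color]), float(self.config["led"]["fwhm_nm"]), flux)

    def scene_for(self, grown_under: str, scale: str) -> Scene:
        key = (grown_under, scale)
        if key not in self._scene_cache:
            self._scene_cache[key] = build_scene(
                self.architectures[grown_under],
                gen_leaf_optics(grown_under),
                self.layout,
                scale=scale,
                size_scale=self.size_scale,
                resolution=self.resolution,
                n_trusses=self.n_trusses,
            )
        return self._scene_cache[key]


def run_scenario(spec: ScenarioSpec, model_config: ScenarioConfig | None = None) -> ScenarioResult:
    """Build the scene, trace the exposure spectrum, aggregate photosynthesis to floor area."""
    cfg = model_config or ScenarioConfig()
    scene = cfg.scene_for(spec.grown_under, spec.scale)
    spectrum = cfg.source_spectrum(spec.exposed_to)
    source = LightSource(
        segments=scene.lamp_segments,
        spectrum=spectrum,
        total_flux=float(cfg.config["source"]["total_flux"]),
        pattern=cfg.config["source"].get("pattern", "cosine"),
    )
    trace_cfg = cfg.config.get("trace", {})
    tally = trace(
        scene,
        source,
        spec.n_rays,
        max_recursions=int(trace_cfg.get("max_recursions", 40)),
        seed=spec.seed,
    )

    absorbed = float(tally.leaflet_band.sum())
    input_flux = tally.input_flux
    absorbance_pct = 100.0 * absorbed / input_flux if input_flux > 0 else 0.0

    # per-leaflet absorbed spectra per m2 leaf, then the leaf photosynthesis model
    area = scene.leaflet_area
    flux_leaf = tally.leaflet_band * (scene.ground_area / area[:, None])
    alpha_I = flux_leaf @ cfg.params.alpha_band * cfg.alpha_multiplier(spec.grown_under)
    p_max = cfg.params.p_max(scene.leaflet_rank)
    P_leaf = nonrectangular_hyperbola(alpha_I, p_max, cfg.params.theta)
    gross_P = float((P_leaf * area).sum() / scene.ground_area)
    lue = compute_lue(gross_P, absorbed) if absorbed > 0 else 0.0

    return ScenarioResult(
        spec=spec,
        absorbance_pct=absorbance_pct,
        gross_P=gross_P,
        lue=lue,
        absorbed_flux=absorbed,
        input_flux=input_flux,
        conservation=tally.conservation(),
        lai=scene.lai,
    )


def paper18_specs(n_rays: int = 200_000, seed: int = DEFAULT_SEED) -> list[ScenarioSpec]:
    """The standard 18-scenario matrix.

    White-grown canopy at leaf/plant/crop scale under blue/green/red light
    (9 scenarios), plus full crops grown under blue/green/red transferred
    to blue/green/red light (9 scenarios).
    """
    # all scenarios share one seed: common random numbers pair the color
    # comparisons, so small absorbance contrasts are resolved at modest ray counts
    specs = []
    for scale in _SCALES:
        for color in ("blue", "green", "red"):
            specs.append(ScenarioSpec("white", color, scale, n_rays, seed))
    for grown in ("blue", "green", "red"):
        for color in ("blue", "green", "red"):
            specs.append(ScenarioSpec(grown, color, "crop", n_rays, seed))
    return specs


def run_matrix(
    grown_list=None,
    exposed_list=None,
    scales=None,
    model_config: ScenarioConfig | None = None,
    preset: str | None = None,
    n_rays: int = 200_000,
    seed: int = DEFAULT_SEED,
    progress: bool = False,
) -> pd.DataFrame:
    """Run a scenario batch and return a long-format result table.

    Either pass explicit ``grown_list`` × ``exposed_list`` × ``scales``
    (full product) or ``preset="paper18"`` for the standard matrix.
    """
    cfg = model_config or ScenarioConfig()
    if preset is not None:
        if preset != "paper18":
            raise ValueError(f"unknown preset {preset!r}")
        specs = paper18_specs(n_rays, seed)
    else:
        specs = []
        for scale in scales or ():
            for grown in grown_list or ():
                for color in exposed_list if exposed_list is not None else ():
                    specs.append(ScenarioSpec(grown, color, scale, n_rays, seed))
    rows = []
    for k, spec in enumerate(specs):
        result = run_scenario(spec, cfg)
        if progress:
            print(
                f"[{k + 1}/{len(specs)}] grown={spec.grown_under} exposed={spec.exposed_to} "
                f"scale={spec.scale}: absorbance {result.absorbance_pct:.1f}%, "
                f"P {result.gross_P:.3f}, LUE {result.lue:.1f}"
            )
        rows.append(result.to_row())
    columns = [
        "grown_under", "exposed_to", "scale", "n_rays", "seed",
        "absorbance_pct", "gross_P", "lue", "lai",
    ]
    return pd.DataFrame(rows, columns=columns)


def pivot_crop_matrix(df: pd.DataFrame, value: str = "absorbance_pct") -> pd.DataFrame:
    """Pivot the crop-scale colored-grown block: rows grown_under, columns exposed_to."""
    block = df[(df["scale"] == "crop") & (df["grown_under"] != "white")]
    return block.pivot(index="grown_under", columns="exposed_to", values=value)
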
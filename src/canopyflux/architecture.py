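"""Plant-architecture parameter sets.

A :class:`PlantArchitecture` collects the morphological parameters of a
tomato plant as measured per growth-light treatment: leaf length/width,
leaf insertion angle (LIA, angle between stem and leaf base), rachis
elevation angle (RA), terminal-leaflet angle (TLA) and the elevation
angles of the basal / middle / outer leaflet groups along the rachis.
Angles are degrees; lengths are meters internally (measurement tables
use cm and are converted by the readers).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

__all__ = ["PlantArchitecture", "age_scale", "architecture_from_row", "read_architecture_csv"]


@dataclass(frozen=True)
class PlantArchitecture:
    n_leaves: int
    internode_length: float  # m
    leaf_length: float  # m
    leaf_width: float  # m
    lia_deg: float  # leaf insertion angle, [0, 180)
    ra_deg: float  # rachis elevation angle, (-90, 90]
    tla_deg: float  # terminal leaflet elevation angle
    base_angle_deg: float
    middle_angle_deg: float
    outside_angle_deg: float
    leaflets_per_leaf: int = 15
    treatment_label: str = "white"

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        for name in ("internode_length", "leaf_length", "leaf_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.lia_deg < 180.0):
            raise ValueError("LIA must be in [0, 180) degrees")
        for name in ("ra_deg", "tla_deg", "base_angle_deg", "middle_angle_deg", "outside_angle_deg"):
            v = getattr(self, name)
            if not (-90.0 < v <= 90.0):
                raise ValueError(f"{name} must be in (-90, 90] degrees, got {v}")
        if self.leaflets_per_leaf < 1:
            raise ValueError("leaflets_per_leaf must be >= 1")

    def with_leaves(self, n_leaves: int, internode_length: float | None = None) -> "PlantArchitecture":
        """Copy with a different leaf count (and optionally internode length)."""
        return replace(
            self,
            n_leaves=n_leaves,
            internode_length=internode_length or self.internode_length,
        )


def age_scale(leaf_rank: int, ramp_ranks: int = 6, youngest: float = 0.3) -> float:
    """Leaf-size multiplier as a function of rank counted from the top.

    Young leaves near the apex are smaller; the multiplier rises linearly
    from ``youngest`` at rank 1 to 1.0 at ``ramp_ranks`` and saturates
    below.  Stands in for the age function of the underlying static-crop
    parameterization; override the defaults to change the profile.
    """
    if leaf_rank < 1:
        raise ValueError("leaf_rank counts from 1 at the top")
    if leaf_rank >= ramp_ranks:
        return 1.0
    return youngest + (1.0 - youngest) * (leaf_rank - 1) / (ramp_ranks - 1)


def architecture_from_row(row, n_leaves: int = 21, internode_length: float | None = None) -> PlantArchitecture:
    """Build a :class:`PlantArchitecture` from one row of an architecture table (lengths in cm)."""
    internode = internode_length
    if internode is None:
        internode = float(row.get("internode_cm", 5.0)) / 100.0
    return PlantArchitecture(
        n_leaves=n_leaves,
        internode_length=internode,
        leaf_length=float(row["length_cm"]) / 100.0,
        leaf_width=float(row["width_cm"]) / 100.0,
        lia_deg=float(row["lia_deg"]),
        ra_deg=float(row["ra_deg"]),
        tla_deg=float(row["tla_deg"]),
        base_angle_deg=float(row["base_deg"]),
        middle_angle_deg=float(row["middle_deg"]),
        outside_angle_deg=float(row["outside_deg"]),
        treatment_label=str(row["treatment"]),
    )


def read_architecture_csv(path) -> dict[str, PlantArchitecture]:
    """Read a per-treatment architecture table (columns as written by the generator)."""
    df = pd.read_csv(path)
    return {
        str(row["treatment"]): architecture_from_row(row)
        for _, row in df.iterrows()
    }
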
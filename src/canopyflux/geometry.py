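"""Triangulated 3D tomato plants and the mirrored greenhouse scene.

Coordinates are meters, right-handed, z up, floor at z = 0.  A composite
leaf is a straight rachis carrying 7 leaflet pairs plus a terminal
leaflet (15 leaflets); each leaflet is a planar ellipse triangulated as
a fan.  Leaf curvature is approximated by the elevation angles of the
basal / middle / outer leaflet groups rather than a continuous bend.
The crop scene follows the standard greenhouse layout: 32 plants on two
double rows on a 3 × 3.2 m floor, slabs 0.8 m above the floor, plant
tops at 3.5 m, LED line lamps 4.75 m above the ground, and perfect
mirrors on all four side walls emulating an infinite canopy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .architecture import PlantArchitecture, age_scale
from .spectra import N_BANDS, LeafOptics

__all__ = [
    "LayoutConfig",
    "LeafMesh",
    "PlantMesh",
    "Scene",
    "build_leaf",
    "build_plant",
    "build_scene",
    "crop_size_scale",
]

# leaflet layout along the rachis: 7 pairs + terminal; fraction of rachis length
_PAIR_FRACTIONS = np.array([0.18, 0.29, 0.40, 0.51, 0.62, 0.73, 0.85])
# group of each pair: 0 = base, 1 = middle, 2 = outside
_PAIR_GROUP = np.array([0, 0, 1, 1, 1, 2, 2])
_REL_SIZE_BY_GROUP = np.array([0.55, 0.75, 0.85])
_REL_SIZE_TERMINAL = 1.0
# azimuthal angle of side leaflets away from the rachis axis, degrees
_SIDE_SPLAY_DEG = 55.0
# leaflet ellipse: length = _LEN_COEF * sqrt(leaf_length * leaf_width), width = aspect * length
_LEN_COEF = 0.27
_ASPECT = 0.55

# fixed gray optics for stems and trusses: intercept but do not photosynthesize
STEM_REFLECTANCE = 0.15
STEM_TRANSMITTANCE = 0.0


@dataclass
class LayoutConfig:
    """Greenhouse scene layout constants (meters)."""

    floor_x: float = 3.2
    floor_y: float = 3.0
    slab_height: float = 0.8
    crop_top_height: float = 3.5
    lamp_height: float = 4.75
    lamp_length: float = 2.5
    lamp_x: tuple[float, ...] = (0.8, 2.4)
    row_x: tuple[float, ...] = (0.6, 1.0, 2.2, 2.6)
    plants_per_row: int = 8
    lai_target: float = 3.0

    def __post_init__(self) -> None:
        for name in ("floor_x", "floor_y", "slab_height", "crop_top_height", "lamp_height", "lamp_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"layout dimension {name} must be positive")

    @property
    def ground_area(self) -> float:
        return self.floor_x * self.floor_y

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["lamp_x"] = list(self.lamp_x)
        d["row_x"] = list(self.row_x)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "LayoutConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["lamp_x"] = tuple(d.get("lamp_x", (0.8, 2.4)))
        d["row_x"] = tuple(d.get("row_x", (0.6, 1.0, 2.2, 2.6)))
        return cls(**d)


@dataclass
class LeafMesh:
    """Triangle mesh of one composite leaf."""

    triangles: np.ndarray  # (n_tri, 3, 3)
    leaflet_local: np.ndarray  # (n_tri,) index 0..14 of the leaflet each triangle belongs to
    leaflet_area: np.ndarray  # (15,) one-sided mesh area per leaflet, m^2
    leaflet_centroid: np.ndarray  # (15, 3)

    @property
    def n_leaflets(self) -> int:
        return len(self.leaflet_area)

    @property
    def area(self) -> float:
        return float(self.leaflet_area.sum())


@dataclass
class PlantMesh:
    triangles: np.ndarray  # (n_tri, 3, 3)
    surface_class: np.ndarray  # (n_tri,) 0 = leaflet, 1 = stem/truss
    leaflet_index: np.ndarray  # (n_tri,) local leaflet id, -1 for stem triangles
    leaflet_rank: np.ndarray  # (n_leaflets,) leaf rank from the top
    leaflet_area: np.ndarray  # (n_leaflets,)
    top_height: float


def _triangle_areas(tris: np.ndarray) -> np.ndarray:
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def build_leaf(
    arch: PlantArchitecture,
    leaf_rank: int,
    node_position=(0.0, 0.0, 0.0),
    azimuth_deg: float = 0.0,
    size_scale: float = 1.0,
    resolution: int = 16,
) -> LeafMesh:
    """Build one composite leaf attached at ``node_position``.

    The rachis leaves the stem rotated LIA from the stem axis, is pitched
    by RA, and carries 15 planar elliptical leaflets: 7 pairs (basal,
    middle and outer groups with their own elevation angles) plus the
    terminal leaflet pitched by TLA.  Leaflet sizes scale with the
    rank-dependent age multiplier and shrink toward the leaf base so that
    the summed ellipse areas are proportional to leaf_length × leaf_width.
    """
    if not (1 <= leaf_rank <= arch.n_leaves):
        raise ValueError(f"leaf_rank {leaf_rank} outside 1..{arch.n_leaves}")
    if arch.leaflets_per_leaf != 15:
        raise ValueError("the composite-leaf template is defined for 15 leaflets per leaf")

    p0 = np.asarray(node_position, dtype=float)
    phi = np.deg2rad(azimuth_deg)
    age = age_scale(leaf_rank)
    scale = age * size_scale

    # rachis direction: elevation (90 - LIA) from horizontal, then pitched by RA
    elev = np.deg2rad(90.0 - arch.lia_deg + arch.ra_deg)
    h = np.array([np.cos(phi), np.sin(phi), 0.0])  # horizontal rachis azimuth
    e2 = np.array([-np.sin(phi), np.cos(phi), 0.0])  # horizontal perpendicular
    u = np.cos(elev) * h + np.sin(elev) * np.array([0.0, 0.0, 1.0])
    rachis_len = arch.leaf_length * scale

    # per-leaflet attach points, axis elevations and relative sizes
    n_leaflets = 15
    attach = np.empty((n_leaflets, 3))
    axis_elev = np.empty(n_leaflets)
    splay = np.empty(n_leaflets)  # signed azimuthal splay from the rachis
    rel = np.empty(n_leaflets)
    group_elev = np.array([arch.base_angle_deg, arch.middle_angle_deg, arch.outside_angle_deg])
    # leaflet elevations ride on the rachis: measured group angles are
    # relative to the rachis axis, so tilting the leaf tilts its leaflets
    rachis_elev_deg = np.rad2deg(elev)
    for pair in range(7):
        for side, sign in ((0, 1.0), (1, -1.0)):
            j = 2 * pair + side
            attach[j] = p0 + _PAIR_FRACTIONS[pair] * rachis_len * u
            axis_elev[j] = group_elev[_PAIR_GROUP[pair]] + rachis_elev_deg
            splay[j] = sign * _SIDE_SPLAY_DEG
            rel[j] = _REL_SIZE_BY_GROUP[_PAIR_GROUP[pair]]
    attach[14] = p0 + rachis_len * u
    axis_elev[14] = arch.tla_deg + rachis_elev_deg
    splay[14] = 0.0
    rel[14] = _REL_SIZE_TERMINAL

    # leaflet axes: rotate the horizontal rachis azimuth by the splay, then elevate
    sp = np.deg2rad(splay)[:, None]
    hj = np.cos(sp) * h + np.sin(sp) * e2  # (15, 3), horizontal
    ge = np.deg2rad(axis_elev)[:, None]
    w = np.cos(ge) * hj + np.sin(ge) * np.array([0.0, 0.0, 1.0])
    # minor axis: horizontal, perpendicular to the leaflet axis
    m = np.cross(np.broadcast_to([0.0, 0.0, 1.0], w.shape), w)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    degenerate = norms[:, 0] < 1e-9
    m[degenerate] = e2
    m[~degenerate] /= norms[~degenerate]

    length = _LEN_COEF * np.sqrt(arch.leaf_length * arch.leaf_width) * rel * scale
    width = _ASPECT * length
    center = attach + 0.5 * length[:, None] * w

    theta = np.linspace(0.0, 2.0 * np.pi, resolution + 1)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # boundary points: (15, resolution+1, 3)
    pts = (
        center[:, None, :]
        + 0.5 * length[:, None, None] * cos_t[None, :, None] * w[:, None, :]
        + 0.5 * width[:, None, None] * sin_t[None, :, None] * m[:, None, :]
    )
    tris = np.empty((n_leaflets, resolution, 3, 3))
    tris[:, :, 0, :] = center[:, None, :]
    tris[:, :, 1, :] = pts[:, :-1, :]
    tris[:, :, 2, :] = pts[:, 1:, :]
    tris = tris.reshape(-1, 3, 3)
    leaflet_local = np.repeat(np.arange(n_leaflets, dtype=np.int32), resolution)
    areas = _triangle_areas(tris)
    leaflet_area = np.array([areas[leaflet_local == j].sum() for j in range(n_leaflets)])
    return LeafMesh(tris, leaflet_local, leaflet_area, center)


def _prism(p0: np.ndarray, p1: np.ndarray, radius: float, n_sides: int = 8) -> np.ndarray:
    """Open triangulated prism around the segment p0→p1 (stems, trusses)."""
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length < 1e-12:
        raise ValueError("degenerate prism axis")
    axis = axis / length
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    theta = np.linspace(0.0, 2.0 * np.pi, n_sides + 1)
    ring = radius * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
    lo = p0 + ring
    hi = p1 + ring
    tris = np.empty((2 * n_sides, 3, 3))
    tris[:n_sides, 0] = lo[:-1]
    tris[:n_sides, 1] = lo[1:]
    tris[:n_sides, 2] = hi[:-1]
    tris[n_sides:, 0] = lo[1:]
    tris[n_sides:, 1] = hi[1:]
    tris[n_sides:, 2] = hi[:-1]
    return tris


def build_plant(
    arch: PlantArchitecture,
    base_position=(0.0, 0.0, 0.0),
    base_azimuth_deg: float = 0.0,
    size_scale: float = 1.0,
    n_trusses: int = 0,
    resolution: int = 16,
    stem_radius: float = 0.007,
) -> PlantMesh:
    """Vertical stem of ``n_leaves`` internodes with one leaf per node in 137.5° spiral phyllotaxy."""
    base = np.asarray(base_position, dtype=float)
    n = arch.n_leaves
    top = base[2] + n * arch.internode_length

    tri_chunks, class_chunks, leaflet_chunks = [], [], []
    leaflet_rank = np.empty(n * 15, dtype=np.int32)
    leaflet_area = np.empty(n * 15)
    for i in range(n):  # node i (0-based) from the bottom
        rank = n - i
        node = base + np.array([0.0, 0.0, (i + 1) * arch.internode_length])
        azimuth = base_azimuth_deg + 137.5 * i
        leaf = build_leaf(arch, rank, node, azimuth, size_scale, resolution)
        tri_chunks.append(leaf.triangles)
        class_chunks.append(np.zeros(len(leaf.triangles), dtype=np.int8))
        leaflet_chunks.append(leaf.leaflet_local + 15 * i)
        leaflet_rank[15 * i : 15 * (i + 1)] = rank
        leaflet_area[15 * i : 15 * (i + 1)] = leaf.leaflet_area

    stem = _prism(base, base + np.array([0.0, 0.0, n * arch.internode_length]), stem_radius)
    tri_chunks.append(stem)
    class_chunks.append(np.ones(len(stem), dtype=np.int8))
    leaflet_chunks.append(np.full(len(stem), -1, dtype=np.int32))

    for k in range(n_trusses):
        frac = 0.25 + 0.55 * k / max(1, n_trusses - 1)
        z = base[2] + frac * n * arch.internode_length
        phi = np.deg2rad(base_azimuth_deg + 137.5 * k + 60.0)
        d = 0.1 * np.array([np.cos(phi), np.sin(phi), -0.3])
        truss = _prism(base + np.array([0.0, 0.0, z - base[2]]), base + np.array([0.0, 0.0, z - base[2]]) + d, 0.006)
        tri_chunks.append(truss)
        class_chunks.append(np.ones(len(truss), dtype=np.int8))
        leaflet_chunks.append(np.full(len(truss), -1, dtype=np.int32))

    return PlantMesh(
        triangles=np.concatenate(tri_chunks),
        surface_class=np.concatenate(class_chunks),
        leaflet_index=np.concatenate(leaflet_chunks).astype(np.int32),
        leaflet_rank=leaflet_rank,
        leaflet_area=leaflet_area,
        top_height=top,
    )


@dataclass
class Scene:
    """Triangulated scene inside a mirrored box, with an absorbing floor at z = 0.

    ``optics_index`` selects per-triangle rows of the per-band optics tables
    ``optics_R`` / ``optics_T`` (adaxial) and the ``*_ab`` abaxial variants.
    Mirror walls stand at the four box planes; the top at ``z_ceiling`` is
    open (photons crossing it upward are tallied as escaped).
    """

    triangles: np.ndarray  # (n_tri, 3, 3)
    surface_class: np.ndarray  # (n_tri,) 0 leaflet, 1 stem
    leaflet_id: np.ndarray  # (n_tri,) -1 for non-leaflets
    optics_index: np.ndarray  # (n_tri,)
    optics_R: np.ndarray  # (n_optics, 60)
    optics_T: np.ndarray  # (n_optics, 60)
    box: tuple[float, float, float, float]  # x0, x1, y0, y1
    z_ceiling: float
    ground_area: float
    n_leaflets: int = 0
    leaflet_plant: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    leaflet_rank: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    leaflet_area: np.ndarray = field(default_factory=lambda: np.empty(0))
    lamp_segments: np.ndarray = field(default_factory=lambda: np.empty((0, 2, 3)))
    optics_R_ab: np.ndarray | None = None
    optics_T_ab: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.float64)
        self.surface_class = np.asarray(self.surface_class, dtype=np.int8)
        self.leaflet_id = np.asarray(self.leaflet_id, dtype=np.int32)
        self.optics_index = np.asarray(self.optics_index, dtype=np.int32)
        self.optics_R = np.ascontiguousarray(self.optics_R, dtype=np.float64)
        self.optics_T = np.ascontiguousarray(self.optics_T, dtype=np.float64)
        if self.optics_R_ab is None:
            self.optics_R_ab = self.optics_R
        if self.optics_T_ab is None:
            self.optics_T_ab = self.optics_T
        self._grid = None

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def total_leaf_area(self) -> float:
        return float(self.leaflet_area.sum())

    @property
    def lai(self) -> float:
        return self.total_leaf_area / self.ground_area

    def validate(self, box_tolerance: float = 0.1) -> None:
        """Check triangles are non-degenerate and lie (to tolerance) inside the mirror box."""
        if self.n_triangles:
            areas = _triangle_areas(self.triangles)
            if np.any(areas < 1e-12):
                raise ValueError(f"{int((areas < 1e-12).sum())} degenerate triangles in scene")
            x0, x1, y0, y1 = self.box
            xs = self.triangles[..., 0]
            ys = self.triangles[..., 1]
            zs = self.triangles[..., 2]
            if (
                xs.min() < x0 - box_tolerance
                or xs.max() > x1 + box_tolerance
                or ys.min() < y0 - box_tolerance
                or ys.max() > y1 + box_tolerance
                or zs.min() < -1e-9
            ):
                raise ValueError("scene triangles extend outside the mirror box")
            if zs.max() >= self.z_ceiling:
                raise ValueError("scene geometry extends above the light sources")
        if self.optics_R.shape[1] != N_BANDS:
            raise ValueError("optics tables must have 60 bands")
        if np.any(self.optics_R + self.optics_T > 1.0 + 1e-9):
            raise ValueError("scene optics with R + T > 1")

    def export_obj(self, path) -> None:
        """Write the scene as Wavefront OBJ, one named object per leaflet (stems grouped)."""
        import trimesh

        geoms = {}
        verts = self.triangles.reshape(-1, 3)
        faces = np.arange(len(verts)).reshape(-1, 3)
        for lid in range(self.n_leaflets):
            mask = self.leaflet_id == lid
            if not mask.any():
                continue
            v = self.triangles[mask].reshape(-1, 3)
            f = np.arange(len(v)).reshape(-1, 3)
            geoms[f"leaflet_{lid}"] = trimesh.Trimesh(vertices=v, faces=f, process=False)
        stem_mask = self.surface_class == 1
        if stem_mask.any():
            v = self.triangles[stem_mask].reshape(-1, 3)
            geoms["stems"] = trimesh.Trimesh(vertices=v, faces=np.arange(len(v)).reshape(-1, 3), process=False)
        if not geoms:
            geoms["empty"] = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        trimesh.Scene(geoms).export(str(path))


def _fold_into_box(tris: np.ndarray, box: tuple[float, float, float, float]) -> np.ndarray:
    """Mirror-reflect triangles whose centroid falls outside the box back inside.

    The mirrored box is optically equivalent to an infinite tiling of
    reflected copies, so geometry poking through a wall is represented by
    its mirror image poking back in.  Applied per triangle by centroid.
    """
    x0, x1, y0, y1 = box
    out = tris.copy()
    c = out.mean(axis=1)
    for axis, lo, hi in ((0, x0, x1), (1, y0, y1)):
        below = c[:, axis] < lo
        out[below, :, axis] = 2 * lo - out[below, :, axis]
        above = c[:, axis] > hi
        out[above, :, axis] = 2 * hi - out[above, :, axis]
        c = out.mean(axis=1)
    return out


def crop_size_scale(arch: PlantArchitecture, layout: LayoutConfig | None = None, resolution: int = 16) -> float:
    """Global leaflet size multiplier so a 21-leaf, 32-plant crop of ``arch`` hits the LAI target."""
    layout = layout or LayoutConfig()
    n = 21
    internode = (layout.crop_top_height - layout.slab_height) / n
    plant = build_plant(arch.with_leaves(n, internode), (0, 0, layout.slab_height), 0.0, 1.0, 0, resolution)
    n_plants = len(layout.row_x) * layout.plants_per_row
    raw_lai = plant.leaflet_area.sum() * n_plants / layout.ground_area
    return float(np.sqrt(layout.lai_target / raw_lai))


def build_scene(
    arch: PlantArchitecture,
    optics: LeafOptics,
    layout: LayoutConfig | None = None,
    scale: str = "crop",
    size_scale: float | None = None,
    reference_arch: PlantArchitecture | None = None,
    resolution: int = 16,
    n_trusses: int = 8,
) -> Scene:
    """Assemble the scene for one scale preset.

    ``scale`` is one of ``"leaf"`` (a single mature leaf under a short LED
    string in a 1 × 1 m mirrored box), ``"plant"`` (32 seven-leaf young
    plants in the standard layout) or ``"crop"`` (32 twenty-one-leaf
    plants, tops at 3.5 m, LAI scaled to the layout target).  The leaflet
    size multiplier is calibrated on ``reference_arch`` (default: ``arch``
    itself) at crop scale, so treatments with smaller measured leaves
    yield a proportionally lower LAI when a common reference is used.
    """
    layout = layout or LayoutConfig()
    if scale not in ("leaf", "plant", "crop"):
        raise ValueError(f"unknown scale preset {scale!r}")
    if size_scale is None:
        size_scale = crop_size_scale(reference_arch or arch, layout, resolution)

    a_ad = optics.absorptance("adaxial")  # validates R + T <= 1 up front
    del a_ad
    optics_R = np.vstack([optics._rt("adaxial")[0].values, np.full(N_BANDS, STEM_REFLECTANCE)])
    optics_T = np.vstack([optics._rt("adaxial")[1].values, np.full(N_BANDS, STEM_TRANSMITTANCE)])
    optics_R_ab = np.vstack([optics._rt("abaxial")[0].values, np.full(N_BANDS, STEM_REFLECTANCE)])
    optics_T_ab = np.vstack([optics._rt("abaxial")[1].values, np.full(N_BANDS, STEM_TRANSMITTANCE)])

    if scale == "leaf":
        box = (0.0, 1.0, 0.0, 1.0)
        node = np.array([0.32, 0.5, layout.slab_height])
        rank = 6  # mature leaf (age multiplier 1.0)
        arch1 = arch.with_leaves(max(arch.n_leaves, rank))
        leaf = build_leaf(arch1, rank, node, 0.0, size_scale, resolution)
        tris = _fold_into_box(leaf.triangles, box)
        lamp_z = layout.slab_height + 0.5
        seg = np.array([[[0.32, 0.5, lamp_z], [0.32 + arch.leaf_length * size_scale, 0.5, lamp_z]]])
        scene = Scene(
            triangles=tris,
            surface_class=np.zeros(len(tris), dtype=np.int8),
            leaflet_id=leaf.leaflet_local,
            optics_index=np.zeros(len(tris), dtype=np.int32),
            optics_R=optics_R,
            optics_T=optics_T,
            optics_R_ab=optics_R_ab,
            optics_T_ab=optics_T_ab,
            box=box,
            z_ceiling=lamp_z + 0.01,
            ground_area=1.0,
            n_leaflets=15,
            leaflet_plant=np.zeros(15, dtype=np.int32),
            leaflet_rank=np.full(15, rank, dtype=np.int32),
            leaflet_area=leaf.leaflet_area,
            lamp_segments=seg,
        )
        scene.validate(box_tolerance=0.2)
        return scene

    n_leaves = 21 if scale == "crop" else 7
    internode = (layout.crop_top_height - layout.slab_height) / 21.0
    arch_n = arch.with_leaves(n_leaves, internode)
    trusses = n_trusses if scale == "crop" else 0
    box = (0.0, layout.floor_x, 0.0, layout.floor_y)

    tri_chunks, class_chunks, leafid_chunks = [], [], []
    plant_ids, ranks, areas = [], [], []
    spacing = layout.floor_y / layout.plants_per_row
    plant_idx = 0
    per_plant_leaflets = n_leaves * 15
    for xi, x in enumerate(layout.row_x):
        for yi in range(layout.plants_per_row):
            y = (yi + 0.5) * spacing
            azim = 83.0 * plant_idx  # deterministic per-plant rotation, no jitter
            plant = build_plant(arch_n, (x, y, layout.slab_height), azim, size_scale, trusses, resolution)
            tri_chunks.append(plant.triangles)
            class_chunks.append(plant.surface_class)
            lid = plant.leaflet_index.copy()
            lid[lid >= 0] += plant_idx * per_plant_leaflets
            leafid_chunks.append(lid)
            plant_ids.append(np.full(per_plant_leaflets, plant_idx, dtype=np.int32))
            ranks.append(plant.leaflet_rank)
            areas.append(plant.leaflet_area)
            plant_idx += 1

    tris = np.concatenate(tri_chunks)
    tris = _fold_into_box(tris, box)
    surface_class = np.concatenate(class_chunks)
    leaflet_id = np.concatenate(leafid_chunks)
    optics_index = np.where(surface_class == 0, 0, 1).astype(np.int32)

    if tris[..., 2].max() >= layout.lamp_height:
        raise ValueError("plants extend above the light sources")

    half = 0.5 * layout.lamp_length
    segs = []
    yc = 0.5 * layout.floor_y
    for lx in layout.lamp_x:
        segs.append([[lx, yc - half, layout.lamp_height], [lx, yc + half, layout.lamp_height]])

    scene = Scene(
        triangles=tris,
        surface_class=surface_class,
        leaflet_id=leaflet_id,
        optics_index=optics_index,
        optics_R=optics_R,
        optics_T=optics_T,
        optics_R_ab=optics_R_ab,
        optics_T_ab=optics_T_ab,
        box=box,
        z_ceiling=layout.lamp_height + 0.01,
        ground_area=layout.ground_area,
        n_leaflets=plant_idx * per_plant_leaflets,
        leaflet_plant=np.concatenate(plant_ids),
        leaflet_rank=np.concatenate(ranks),
        leaflet_area=np.concatenate(areas),
        lamp_segments=np.array(segs),
    )
    scene.validate(box_tolerance=0.2)
    return scene
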
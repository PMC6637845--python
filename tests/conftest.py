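"""Shared fixtures: scenario configuration, simple layered scenes, MC batching."""

from __future__ import annotations

import numpy as np
import pytest

from canopyflux import LightSource, Scene, SpectrumGrid, trace
from canopyflux.scenarios import ScenarioConfig
from canopyflux.spectra import N_BANDS


@pytest.fixture(scope="session")
def cfg() -> ScenarioConfig:
    """One shared scenario configuration (scene caches persist across tests)."""
    return ScenarioConfig()


def flat_spectrum(total: float = 100.0) -> SpectrumGrid:
    return SpectrumGrid(np.full(N_BANDS, total / N_BANDS))


def make_layer_scene(layers, box=(0.0, 1.0, 0.0, 1.0), lamp_z=3.0):
    """Horizontal full-cover layers inside a mirrored box.

    ``layers`` is a list of (z, R, T) with flat band optics; each layer is
    one 'leaflet' made of two triangles spanning the box exactly.
    """
    x0, x1, y0, y1 = box
    tris, leaflet_id, optics_idx = [], [], []
    R_rows, T_rows = [], []
    for i, (z, R, T) in enumerate(layers):
        quad = np.array(
            [
                [[x0, y0, z], [x1, y0, z], [x1, y1, z]],
                [[x0, y0, z], [x1, y1, z], [x0, y1, z]],
            ]
        )
        tris.append(quad)
        leaflet_id += [i, i]
        optics_idx += [i, i]
        R_rows.append(np.full(N_BANDS, R))
        T_rows.append(np.full(N_BANDS, T))
    tris = np.concatenate(tris) if tris else np.empty((0, 3, 3))
    n = len(layers)
    return Scene(
        triangles=tris,
        surface_class=np.zeros(len(tris), dtype=np.int8),
        leaflet_id=np.array(leaflet_id, dtype=np.int32),
        optics_index=np.array(optics_idx, dtype=np.int32),
        optics_R=np.array(R_rows) if n else np.zeros((1, N_BANDS)),
        optics_T=np.array(T_rows) if n else np.zeros((1, N_BANDS)),
        box=box,
        z_ceiling=lamp_z + 0.01,
        ground_area=(x1 - x0) * (y1 - y0),
        n_leaflets=n,
        leaflet_plant=np.zeros(n, dtype=np.int32),
        leaflet_rank=np.ones(n, dtype=np.int32),
        leaflet_area=np.full(n, (x1 - x0) * (y1 - y0)),
        lamp_segments=np.array([[[0.5 * (x0 + x1), y0 + 0.2, lamp_z], [0.5 * (x0 + x1), y1 - 0.2, lamp_z]]]),
    )


def collimated_source(spectrum=None, flux=100.0, lamp_z=3.0, box=(0.0, 1.0, 0.0, 1.0)):
    x0, x1, y0, y1 = box
    seg = np.array([[[0.5 * (x0 + x1), y0 + 0.2, lamp_z], [0.5 * (x0 + x1), y1 - 0.2, lamp_z]]])
    return LightSource(seg, spectrum or flat_spectrum(flux), flux, "delta_down")


def two_stream_layers(r: float, t: float, n_layers: int):
    """Independent flux-balance oracle for n identical full-cover layers.

    Solves the linear system for downward flux d_i incident on layer i
    (d_{n+1} hits the absorbing floor) and upward flux u_i incident on
    layer i from below, with unit input from above and a non-reflecting
    floor.  Returns (per-layer absorption, floor absorption, escaped).
    """
    n = n_layers
    # unknowns: d_1..d_{n+1}, u_1..u_n
    size = 2 * n + 1
    A = np.zeros((size, size))
    b = np.zeros(size)

    def d(i):  # 1-based
        return i - 1

    def u(i):
        return n + 1 + (i - 1)

    A[0, d(1)] = 1.0
    b[0] = 1.0
    row = 1
    for i in range(1, n + 1):
        A[row, d(i + 1)] = 1.0
        A[row, d(i)] = -t
        A[row, u(i)] = -r
        row += 1
    for i in range(1, n + 1):
        A[row, u(i)] = 1.0
        A[row, d(i + 1)] = -r if i < n else 0.0  # below layer n is the floor (absorbs)
        if i < n:
            A[row, u(i + 1)] = -t
        row += 1
    x = np.linalg.solve(A, b)
    dd = x[: n + 1]
    uu = x[n + 1 :]
    a = 1.0 - r - t
    absorbed = np.array([a * (dd[i] + uu[i]) for i in range(n)])
    floor = dd[n]
    escaped = r * dd[0] + (t * uu[0] if n >= 1 else 0.0)
    return absorbed, floor, escaped


def batched_absorbance(scene, source, n_rays, n_batches, seed0=100, max_recursions=40):
    """Mean and standard error of leaf absorbance (%) over independent seeds."""
    vals = []
    for k in range(n_batches):
        tally = trace(scene, source, n_rays, max_recursions=max_recursions, seed=seed0 + k)
        vals.append(100.0 * tally.leaflet_band.sum() / tally.input_flux)
    vals = np.asarray(vals)
    return vals.mean(), vals.std(ddof=1) / np.sqrt(n_batches), vals
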
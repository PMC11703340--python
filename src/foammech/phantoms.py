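"""Synthetic foam volumes, seeded cell blobs, and analytic phantoms.

The foam generator is a geometric stand-in for a reconstructed open-cell
scaffold — a Gaussian-smoothed random field thresholded at the quantile
that realizes the requested porosity — not a physical model of CVD foam
growth.  The phantoms carry closed-form truth (volume, surface, Euler
characteristic, thickness, tortuosity where defined) and serve as oracles
for the morphometry and transport solvers.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .volume import VoxelVolume

__all__ = [
    "generate_foam_volume",
    "seed_cells_in_foam",
    "generate_phantom",
]


def generate_foam_volume(shape: tuple[int, int, int], target_porosity: float,
                         voxel_size: float = 2.43, seed: int = 0,
                         model: str = "strut", pore_size: float = 24.0,
                         smoothing: float = 2.0) -> VoxelVolume:
    """Binary foam-like volume with the requested porosity.

    ``model='strut'`` (default) builds an open-cell network: the solid
    phase hugs the edges of a seeded Voronoi tessellation (voxels where
    the third-nearest seed is nearly as close as the first), thresholded
    at the quantile that realizes the target porosity.  This stays
    percolating down to a few percent solid fraction, like a real
    interconnected foam.  ``model='gaussian'`` thresholds a
    Gaussian-smoothed white-noise field instead — a blobbier texture that
    loses connectivity at high porosity.  Both are geometric stand-ins,
    not physical growth models.  ``pore_size`` is the mean Voronoi cell
    edge in voxels.  The realized porosity is recorded in
    ``metadata['realized_porosity']`` and must land within 0.5 percentage
    points of the target or an error is raised.
    """
    if not 0.0 < target_porosity < 100.0:
        raise ValueError("target_porosity must lie in (0, 100)")
    rng = np.random.default_rng(seed)
    if model == "strut":
        from scipy.spatial import cKDTree

        n_seeds = max(4, int(round(np.prod(shape) / pore_size**3)))
        seeds = rng.uniform(0.0, 1.0, (n_seeds, 3)) * np.array(shape)
        # tile seeds periodically so boundary cells are well-formed
        offs = np.array(np.meshgrid(*[[-1, 0, 1]] * 3)).T.reshape(-1, 3)
        tiled = (seeds[None, :, :] + offs[:, None, :] * np.array(shape)
                 ).reshape(-1, 3)
        tree = cKDTree(tiled)
        pts = np.stack(np.indices(shape), -1).reshape(-1, 3)
        d, _ = tree.query(pts, k=3, workers=1)
        field = (d[:, 2] - d[:, 0]).reshape(shape)
        thresh = np.quantile(field, (100.0 - target_porosity) / 100.0)
        grid = (field < thresh).astype(np.uint8)
    elif model == "gaussian":
        field = ndimage.gaussian_filter(rng.normal(size=shape), smoothing)
        thresh = np.quantile(field, target_porosity / 100.0)
        grid = (field > thresh).astype(np.uint8)
    else:
        raise ValueError(f"unknown foam model '{model}'")
    porosity = 100.0 * float(np.mean(grid == 0))
    if abs(porosity - target_porosity) > 0.5:
        raise ValueError(
            f"shape {shape} too small to realize porosity {target_porosity}% "
            f"(got {porosity:.2f}%)")
    vol = VoxelVolume(grid, voxel_size)
    vol.metadata["realized_porosity"] = porosity
    vol.metadata["seed"] = seed
    return vol


def _paint(target: np.ndarray, ball: np.ndarray, center: tuple[int, ...]) -> None:
    """OR a centred mask into *target*, clipping at the grid boundary."""
    br = ball.shape[0] // 2
    dst, src = [], []
    for d, c in enumerate(center):
        lo, hi = c - br, c + br + 1
        dst.append(slice(max(lo, 0), min(hi, target.shape[d])))
        src.append(slice(max(lo, 0) - lo, ball.shape[d] - (hi - min(hi, target.shape[d]))))
    target[tuple(dst)] |= ball[tuple(src)]


def _ball_mask(radius_vox: float) -> np.ndarray:
    r = int(math.ceil(radius_vox))
    zz, yy, xx = np.ogrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (zz * zz + yy * yy + xx * xx) <= radius_vox * radius_vox


def seed_cells_in_foam(volume: VoxelVolume, n_cells: int,
                       radius_range: tuple[float, float],
                       attach_to_phase: bool = True, seed: int = 0,
                       max_tries_per_cell: int = 500) -> VoxelVolume:
    """Place spherical cell blobs into a binary foam volume.

    Returns a labelled volume (0 void, 1 foam, 2 cell).  Blobs occupy void
    voxels only, never overlap or touch each other (26-neighbourhood), and
    when ``attach_to_phase`` each blob must contact the foam phase.  The
    number of blobs actually placed is stored in
    ``metadata['n_cells_placed']``; failure to place all requested blobs
    within the retry budget raises an error.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rlo, rhi = radius_range
    if rlo <= 0 or rhi < rlo:
        raise ValueError("radius_range must be positive and ordered")
    grid = volume.grid.astype(np.uint8).copy()
    if n_cells == 0:
        out = VoxelVolume(grid, volume.voxel_size, volume.origin)
        out.metadata["n_cells_placed"] = 0
        return out
    rng = np.random.default_rng(seed)
    foam = grid == 1
    near_foam = ndimage.binary_dilation(foam, iterations=2) if attach_to_phase else None
    cell_blocked = np.zeros_like(foam)  # cells plus a 1-voxel halo
    placed = 0
    radii: list[float] = []
    for _ in range(n_cells):
        ok = False
        for _try in range(max_tries_per_cell):
            r_um = rng.uniform(rlo, rhi)
            r_vox = r_um / volume.voxel_size
            ball = _ball_mask(r_vox)
            r = ball.shape[0] // 2
            shape = grid.shape
            if any(shape[d] <= 2 * r for d in range(3)):
                continue
            center = tuple(int(rng.integers(r, shape[d] - r)) for d in range(3))
            sl = tuple(slice(c - r, c + r + 1) for c in center)
            region_void = (grid[sl] == 0) | ~ball
            cell_region = ball & (grid[sl] == 0)
            if cell_region.sum() < 0.5 * ball.sum():
                continue  # mostly buried in foam
            if (cell_blocked[sl] & ball).any():
                continue
            if attach_to_phase and not (near_foam[sl] & ball).any():
                continue
            grid[sl][cell_region] = 2
            # block a halo (> sqrt(3) voxels) so later blobs cannot touch
            # this one even diagonally
            _paint(cell_blocked, _ball_mask(r_vox + 1.8), center)
            radii.append(r_um)
            placed += 1
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place blob {placed + 1}/{n_cells} without overlap "
                f"after {max_tries_per_cell} tries")
    out = VoxelVolume(grid, volume.voxel_size, volume.origin)
    out.metadata["n_cells_placed"] = placed
    out.metadata["cell_radii_um"] = radii
    return out


# ----------------------------------------------------------------------
# analytic phantoms
# ----------------------------------------------------------------------

def _grid_for(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]


def generate_phantom(kind: str, params: dict | None = None,
                     voxel_size: float = 1.0) -> VoxelVolume:
    """Binary phantom with closed-form truth in ``metadata['analytic_truth']``.

    Kinds: ``sphere`` (radius), ``cube`` (side), ``torus`` (major_radius,
    minor_radius), ``slab`` (thickness), ``cylinder`` (diameter),
    ``straight_channel`` (width), ``serpentine_channel`` (width, n_legs,
    pitch), ``disjoint_blobs`` (n, radius).  All lengths are in voxels;
    physical truths scale with ``voxel_size``.
    """
    params = dict(params or {})
    builders = {
        "sphere": _sphere, "cube": _cube, "torus": _torus, "slab": _slab,
        "cylinder": _cylinder, "straight_channel": _straight_channel,
        "serpentine_channel": _serpentine_channel, "disjoint_blobs": _disjoint_blobs,
    }
    if kind not in builders:
        raise ValueError(f"unknown phantom kind '{kind}'")
    grid, truth = builders[kind](params)
    vol = VoxelVolume(grid.astype(np.uint8), voxel_size)
    vol.metadata["analytic_truth"] = truth
    vol.metadata["kind"] = kind
    return vol


def _sphere(p: dict):
    r = float(p.get("radius", 20))
    margin = int(p.get("margin", 4))
    n = 2 * int(math.ceil(r)) + 2 * margin + 1
    c = n // 2
    zz, yy, xx = _grid_for((n, n, n))
    if c + r + 1 > n:
        raise ValueError("sphere exceeds grid bounds")
    grid = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r * r
    truth = {"volume_vox": 4.0 / 3.0 * math.pi * r**3,
             "surface_vox": 4.0 * math.pi * r**2,
             "euler": 1, "connectivity": 0, "thickness_vox": 2 * r,
             "n_objects": 1}
    return grid, truth


def _cube(p: dict):
    s = int(p.get("side", 50))
    margin = int(p.get("margin", 4))
    n = s + 2 * margin
    grid = np.zeros((n, n, n), dtype=bool)
    grid[margin:margin + s, margin:margin + s, margin:margin + s] = True
    truth = {"volume_vox": float(s**3), "surface_vox": 6.0 * s**2,
             "euler": 1, "connectivity": 0, "n_objects": 1}
    return grid, truth


def _torus(p: dict):
    R = float(p.get("major_radius", 16))
    a = float(p.get("minor_radius", 6))
    margin = int(p.get("margin", 4))
    if a >= R:
        raise ValueError("torus needs minor_radius < major_radius")
    nxy = 2 * int(math.ceil(R + a)) + 2 * margin + 1
    nz = 2 * int(math.ceil(a)) + 2 * margin + 1
    cz, cxy = nz // 2, nxy // 2
    zz, yy, xx = _grid_for((nz, nxy, nxy))
    rho = np.sqrt((yy - cxy) ** 2 + (xx - cxy) ** 2)
    grid = ((rho - R) ** 2 + (zz - cz) ** 2) <= a * a
    truth = {"volume_vox": 2.0 * math.pi**2 * R * a**2,
             "surface_vox": 4.0 * math.pi**2 * R * a,
             "euler": 0, "connectivity": 1, "thickness_vox": 2 * a,
             "n_objects": 1}
    return grid, truth


def _slab(p: dict):
    t = int(p.get("thickness", 15))
    lateral = int(p.get("lateral", 64))
    margin = int(p.get("margin", 8))
    nz = t + 2 * margin
    grid = np.zeros((nz, lateral, lateral), dtype=bool)
    grid[margin:margin + t, :, :] = True
    truth = {"volume_vox": float(t * lateral * lateral), "euler": 1,
             "connectivity": 0, "thickness_vox": float(t), "n_objects": 1}
    return grid, truth


def _cylinder(p: dict):
    d = float(p.get("diameter", 16))
    length = int(p.get("length", 64))
    margin = int(p.get("margin", 4))
    r = d / 2.0
    nxy = 2 * int(math.ceil(r)) + 2 * margin + 1
    c = nxy // 2
    zz, yy, xx = _grid_for((length, nxy, nxy))
    grid = ((yy - c) ** 2 + (xx - c) ** 2) <= r * r
    grid = np.broadcast_to(grid, (length, nxy, nxy)).copy()
    truth = {"thickness_vox": d, "euler": 1, "n_objects": 1,
             "volume_vox": math.pi * r**2 * length}
    return grid, truth


def _straight_channel(p: dict):
    w = int(p.get("width", 8))
    lateral = int(p.get("lateral", 32))
    length = int(p.get("length", 32))
    if w > lateral:
        raise ValueError("channel wider than the grid")
    grid = np.zeros((length, lateral, lateral), dtype=bool)
    a = (lateral - w) // 2
    grid[:, a:a + w, a:a + w] = True
    eps = w * w / (lateral * lateral)
    truth = {"tortuosity": 1.0, "d_eff_ratio": eps,
             "volume_fraction": 100.0 * eps, "percolation": 100.0,
             "axis": 0, "thickness_vox": float(w)}
    return grid, truth


def _serpentine_channel(p: dict):
    """Square channel snaking in the x-z plane: up, across, down, across, up.

    ``n_legs`` must be odd so the path spans inlet (z=0) to outlet (z=end).
    Truth records the centreline length and the straight-line gap, and the
    geometric tortuosity estimate (L_e / L)^2.
    """
    w = int(p.get("width", 6))
    n_legs = int(p.get("n_legs", 3))
    pitch = int(p.get("pitch", 20))  # x distance between leg centrelines
    length = int(p.get("length", 60))  # z extent
    depth = int(p.get("depth", 10))  # y extent
    if n_legs % 2 == 0:
        raise ValueError("n_legs must be odd")
    if pitch < w + 2:
        raise ValueError("pitch too small for the channel width")
    nx = (n_legs - 1) * pitch + w + 4
    grid = np.zeros((length, depth, nx), dtype=bool)
    if length < 6 * w:
        raise ValueError("length too short for the serpentine runs")
    x0 = 2
    y_sl = slice(0, depth)
    # horizontal runs sit strictly inside the grid so that only the first
    # leg touches the inlet face and only the last leg touches the outlet
    top = slice(length - 2 * w, length - w)
    bot = slice(w, 2 * w)
    for leg in range(n_legs):
        x = x0 + leg * pitch
        if leg == 0:
            grid[0:length - w, y_sl, x:x + w] = True
        elif leg == n_legs - 1:
            grid[w:length, y_sl, x:x + w] = True
        else:
            grid[w:length - w, y_sl, x:x + w] = True
    for run in range(n_legs - 1):
        xa = x0 + run * pitch
        xb = x0 + (run + 1) * pitch
        z_sl = top if run % 2 == 0 else bot
        grid[z_sl, y_sl, xa:xb + w] = True
    # centreline between run centers (z = 1.5w and z = length - 1.5w)
    centreline = (2 * (length - 1.5 * w) + (n_legs - 2) * (length - 3.0 * w)
                  + (n_legs - 1) * pitch)
    truth = {"centreline_vox": float(centreline), "gap_vox": float(length),
             "tortuosity": (centreline / length) ** 2,
             "axis": 0, "percolation": 100.0}
    return grid, truth


def _disjoint_blobs(p: dict):
    n = int(p.get("n", 7))
    r = float(p.get("radius", 4))
    gap = int(p.get("gap", 4))
    cell = 2 * int(math.ceil(r)) + gap
    per_side = int(math.ceil(n ** (1.0 / 3.0)))
    side = per_side * cell + gap
    grid = np.zeros((side, side, side), dtype=bool)
    ball = _ball_mask(r)
    br = ball.shape[0] // 2
    placed = 0
    for i in range(per_side):
        for j in range(per_side):
            for k in range(per_side):
                if placed >= n:
                    break
                c = [gap + br + idx * cell for idx in (i, j, k)]
                sl = tuple(slice(cc - br, cc + br + 1) for cc in c)
                grid[sl] |= ball
                placed += 1
    truth = {"n_objects": n, "euler": n, "connectivity": 1 - n,
             "volume_vox": n * 4.0 / 3.0 * math.pi * r**3}
    return grid, truth
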
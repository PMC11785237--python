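"""Density maps: I/O, statistics, interpolation, watershed segmentation,
map simulation from models, solvent-shell masks and lattice sampling.

A map is a 3D scalar grid with per-axis voxel size and an origin giving the
Angstrom coordinate of grid index (0, 0, 0) in the model frame.  Sigma
thresholds throughout the package mean ``avgD + k * sigma`` computed over
every voxel of the grid, with no mask applied first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .model import AtomicModel

# Gaussian width per unit resolution when simulating a map from a model:
# sd = resolution / (pi * sqrt(2)), the convention of the usual
# map-from-model ("molmap") tools.
SIGMA_FACTOR = 1.0 / (np.pi * np.sqrt(2.0))

#: Per-species amplitude weights for simulated solvent density.
DEFAULT_SPECIES_WEIGHTS = {"rna": 1.0, "water": 1.0, "MG": 1.5, "NA": 1.3}


@dataclass
class MapStats:
    """Whole-grid mean and standard deviation of voxel values."""

    avgD: float
    sigma: float

    def level(self, k: float) -> float:
        """Absolute density value of the ``k sigma`` contour."""
        return self.avgD + k * self.sigma


@dataclass
class DensityMap:
    grid: np.ndarray                    # (nx, ny, nz) float array
    voxel_size: np.ndarray              # (3,) Angstrom per voxel
    origin: np.ndarray                  # (3,) Angstrom of index (0,0,0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if not np.all(self.voxel_size > 0):
            raise ValueError("voxel_size must be positive on all axes")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def stats(self) -> MapStats:
        return MapStats(float(self.grid.mean()), float(self.grid.std()))

    # -- coordinate transforms ------------------------------------------
    def to_index(self, points: np.ndarray) -> np.ndarray:
        """Angstrom coordinates -> fractional grid indices."""
        pts = np.asarray(points, float)
        return (pts - self.origin) / self.voxel_size

    def to_coord(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, float) * self.voxel_size + self.origin

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) coordinates of every voxel center, C order."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        return self.to_coord(idx)

    def contains(self, points: np.ndarray) -> np.ndarray:
        idx = self.to_index(points)
        hi = np.array(self.shape) - 1
        return np.all((idx >= 0) & (idx <= hi), axis=-1)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Angstrom coordinates.

        Raises ValueError if any point falls outside the grid bounds.
        """
        pts = np.atleast_2d(np.asarray(points, float))
        idx = self.to_index(pts)
        hi = np.array(self.shape) - 1
        if np.any(idx < 0) or np.any(idx > hi):
            raise ValueError("point outside grid bounds")
        vals = map_coordinates(self.grid, idx.T, order=1, mode="nearest")
        return vals if np.asarray(points).ndim > 1 else float(vals[0])

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size.copy(),
                          self.origin.copy())


# ---------------------------------------------------------------------------
# I/O (CCP4/MRC mode 2 via gemmi)

def read_map(path: str) -> DensityMap:
    m = gemmi.read_ccp4_map(str(path))
    cell = m.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise ValueError("non-orthogonal unit cells are not supported")
    grid = np.array(m.grid, copy=True, dtype=np.float64)
    voxel = np.array(m.grid.spacing, float)
    origin = np.array([m.header_float(50), m.header_float(51),
                       m.header_float(52)], float)
    return DensityMap(grid, voxel, origin)


def write_map(dmap: DensityMap, path: str) -> None:
    m = gemmi.Ccp4Map()
    g = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    nx, ny, nz = dmap.shape
    vx, vy, vz = dmap.voxel_size
    g.set_unit_cell(gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90, 90, 90))
    m.grid = g
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), dmap.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Watershed segmentation

@dataclass
class Segment:
    """A watershed basin of the super-threshold region."""

    voxels: np.ndarray          # (n, 3) integer indices
    pmax: np.ndarray            # refined peak coordinate, Angstrom
    peak_density: float

    @property
    def volume(self) -> int:
        return len(self.voxels)


def _neighbor_offsets() -> np.ndarray:
    offs = [(di, dj, dk)
            for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
            if (di, dj, dk) != (0, 0, 0)]
    return np.array(offs, dtype=np.int64)


class _SplineField:
    """Cubic-spline view of a grid for sub-voxel peak refinement.

    A trilinear field attains its maxima exactly at voxel centers, so the
    peak ascent runs on a C1-continuous cubic interpolant instead; density
    *values* elsewhere in the package remain trilinear.
    """

    def __init__(self, dmap: DensityMap):
        from scipy.ndimage import spline_filter
        self.dmap = dmap
        self.coeffs = spline_filter(dmap.grid, order=3)

    def value(self, point: np.ndarray) -> float:
        idx = self.dmap.to_index(np.asarray(point, float))
        return float(map_coordinates(self.coeffs, idx[:, None], order=3,
                                     prefilter=False, mode="nearest")[0])


def _refine_peak(field: _SplineField, start: np.ndarray, bbox_lo: np.ndarray,
                 bbox_hi: np.ndarray, max_steps: int = 1000,
                 tol: float = 1e-4) -> np.ndarray:
    """Gradient ascent from a starting coordinate.

    The step starts at 0.1 voxel and halves on non-improving proposals;
    the point is kept inside the segment's bounding region.
    """
    vox = float(np.min(field.dmap.voxel_size))
    step = 0.1 * vox
    h = 0.01 * vox
    p = np.asarray(start, float).copy()
    val = field.value(p)
    for _ in range(max_steps):
        if step < tol:
            break
        grad = np.zeros(3)
        for ax in range(3):
            dp = np.zeros(3)
            dp[ax] = h
            lo = np.clip(p - dp, bbox_lo, bbox_hi)
            hi = np.clip(p + dp, bbox_lo, bbox_hi)
            grad[ax] = (field.value(hi) - field.value(lo)) / (2 * h)
        norm = np.linalg.norm(grad)
        if norm == 0:
            break
        cand = np.clip(p + step * grad / norm, bbox_lo, bbox_hi)
        cval = field.value(cand)
        if cval > val:
            p, val = cand, cval
        else:
            step *= 0.5
    return p


def segment_map(dmap: DensityMap, threshold: float) -> list[Segment]:
    """Watershed segmentation of the region with density >= threshold.

    Each voxel follows steepest ascent among its 26 neighbors; voxels whose
    paths terminate at the same local maximum form one segment.  Ties in
    ascent direction are broken toward the lowest linear voxel index, so
    the labeling is deterministic.  Segments are returned sorted by
    decreasing volume (ties by root voxel index).
    """
    grid = dmap.grid
    shape = np.array(grid.shape)
    mask = grid >= threshold
    if not mask.any():
        return []

    padded = np.pad(grid, 1, constant_values=-np.inf)
    n = grid.size
    flat = grid.ravel()
    # parent[i] = linear index of the steepest-ascent neighbor (or i if root)
    parent = np.arange(n, dtype=np.int64)
    best = flat.copy()
    strides = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
    sel = np.flatnonzero(mask.ravel())
    ii, jj, kk = np.unravel_index(sel, grid.shape)
    best_sel = flat[sel].copy()
    parent_sel = sel.copy()
    for off in _neighbor_offsets():
        nv = padded[1 + ii + off[0], 1 + jj + off[1], 1 + kk + off[2]]
        nidx = sel + off @ strides
        better = nv > best_sel
        # equal values: prefer the lower linear index (deterministic ties)
        tie = (nv == best_sel) & (nidx < parent_sel)
        upd = better | tie
        best_sel[upd] = nv[upd]
        parent_sel[upd] = nidx[upd]
    parent[sel] = parent_sel

    # pointer jumping until every masked voxel points at its root
    while True:
        pp = parent[parent[sel]]
        if np.array_equal(pp, parent[sel]):
            break
        parent[sel] = pp

    roots = parent[sel]
    order = np.argsort(roots, kind="stable")
    sel_sorted = sel[order]
    roots_sorted = roots[order]
    uniq, starts = np.unique(roots_sorted, return_index=True)
    segments: list[Segment] = []
    field = _SplineField(dmap)
    bounds = np.append(starts, len(sel_sorted))
    for u, s0, s1 in zip(uniq, bounds[:-1], bounds[1:]):
        members = sel_sorted[s0:s1]
        vox = np.stack(np.unravel_index(members, grid.shape), axis=1)
        # start ascent from the segment's maximal voxel
        vals = flat[members]
        top = vox[int(np.argmax(vals))]
        lo = dmap.to_coord(vox.min(axis=0) - 0.5)
        hi = dmap.to_coord(vox.max(axis=0) + 0.5)
        lo = np.maximum(lo, dmap.origin)
        hi = np.minimum(hi, dmap.to_coord(shape - 1))
        pmax = _refine_peak(field, dmap.to_coord(top), lo, hi)
        segments.append(Segment(vox, pmax, float(dmap.interpolate(pmax))))
    segments.sort(key=lambda s: (-s.volume, tuple(s.voxels[0])))
    return segments


# ---------------------------------------------------------------------------
# Map simulation from a model

def simulate_map(model: AtomicModel, resolution: float,
                 voxel: float | np.ndarray = 0.5,
                 species_weights: dict[str, float] | None = None,
                 margin: float = 5.0,
                 origin: np.ndarray | None = None,
                 shape: tuple[int, int, int] | None = None,
                 sigma_factor: float = SIGMA_FACTOR) -> DensityMap:
    """Gaussian-atom density simulated from a model.

    Every heavy atom contributes an isotropic Gaussian of standard
    deviation ``resolution * sigma_factor`` with peak amplitude equal to
    its species weight (water 1.0, Mg2+ 1.5, Na+ 1.3, RNA 1.0 by default;
    all atoms of a species share the amplitude).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    weights = dict(DEFAULT_SPECIES_WEIGHTS)
    if species_weights:
        weights.update(species_weights)
    sd = resolution * sigma_factor
    voxel = np.broadcast_to(np.asarray(voxel, float), (3,))
    coords = model.coords
    if origin is None or shape is None:
        lo = coords.min(axis=0) - margin
        hi = coords.max(axis=0) + margin
        origin = lo
        shape = tuple(np.ceil((hi - lo) / voxel).astype(int) + 1)
    grid = np.zeros(shape, dtype=np.float64)
    dmap = DensityMap(grid, voxel, origin)
    cutoff = 5.0 * sd
    nhalf = np.ceil(cutoff / voxel).astype(int)
    axes = [np.arange(s) for s in shape]
    for atom in model:
        w = weights.get(atom.species, 1.0)
        c = np.asarray(atom.coord, float)
        ic = dmap.to_index(c)
        lo_i = np.maximum(np.floor(ic).astype(int) - nhalf, 0)
        hi_i = np.minimum(np.ceil(ic).astype(int) + nhalf, np.array(shape) - 1)
        if np.any(lo_i > hi_i):
            continue
        sub = [axes[a][lo_i[a]:hi_i[a] + 1] * voxel[a] + origin[a] - c[a]
               for a in range(3)]
        r2 = (sub[0][:, None, None] ** 2 + sub[1][None, :, None] ** 2
              + sub[2][None, None, :] ** 2)
        grid[lo_i[0]:hi_i[0] + 1, lo_i[1]:hi_i[1] + 1, lo_i[2]:hi_i[2] + 1] \
            += w * np.exp(-0.5 * r2 / sd ** 2)
    return dmap


# ---------------------------------------------------------------------------
# Solvent shell

@dataclass
class ShellMask:
    """Boolean voxel mask of the solvent shell of well-resolved RNA."""

    mask: np.ndarray            # same shape as the map grid
    inner: float
    outer: float
    q_min: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def values(self, dmap: DensityMap) -> np.ndarray:
        return dmap.grid[self.mask]


def _shell_distances(points: np.ndarray, model: AtomicModel,
                     q_by_residue: dict[tuple[str, int], float],
                     q_min: float) -> tuple[np.ndarray, np.ndarray]:
    """Min distance of each point to (all RNA atoms, well-resolved RNA atoms)."""
    rna = model.rna
    all_coords = rna.coords
    qual = [a for a in rna
            if q_by_residue.get((a.chain, a.res_seq), -np.inf) > q_min]
    if len(all_coords) == 0:
        raise ValueError("model has no RNA heavy atoms")
    d_all = cKDTree(all_coords).query(points, k=1)[0]
    if qual:
        d_qual = cKDTree(np.array([a.coord for a in qual])).query(points, k=1)[0]
    else:
        d_qual = np.full(len(points), np.inf)
    return d_all, d_qual


def shell_mask(dmap: DensityMap, model: AtomicModel,
               q_by_residue: dict[tuple[str, int], float],
               inner: float = 1.8, outer: float = 3.5,
               q_min: float = 0.6) -> ShellMask:
    """Voxels 1.8-3.5 A from well-resolved RNA (nucleotide Q > q_min).

    A voxel qualifies when some atom of a residue with Q > q_min lies
    within [inner, outer] of its center and no RNA heavy atom is closer
    than ``inner``.
    """
    centers = dmap.voxel_centers()
    d_all, d_qual = _shell_distances(centers, model, q_by_residue, q_min)
    keep = (d_all >= inner) & (d_qual <= outer)
    return ShellMask(keep.reshape(dmap.shape), inner, outer, q_min)


def per_residue_shell_mask(dmap: DensityMap, model: AtomicModel,
                           residue: tuple[str, int],
                           inner: float = 1.8,
                           outer: float = 3.5) -> np.ndarray:
    """Boolean mask of voxels within [inner, outer] of one nucleotide's
    heavy atoms and at least ``inner`` from every RNA heavy atom."""
    centers = dmap.voxel_centers()
    rna = model.rna
    res_atoms = np.array([a.coord for a in rna
                          if (a.chain, a.res_seq) == residue])
    if len(res_atoms) == 0:
        raise ValueError(f"no RNA atoms in residue {residue}")
    d_all = cKDTree(rna.coords).query(centers, k=1)[0]
    d_res = cKDTree(res_atoms).query(centers, k=1)[0]
    keep = (d_all >= inner) & (d_res <= outer)
    return keep.reshape(dmap.shape)


def sample_shell_grid(model: AtomicModel,
                      q_by_residue: dict[tuple[str, int], float],
                      spacing: float = 1.67, inner: float = 1.5,
                      outer: float = 3.5,
                      q_min: float = 0.6) -> np.ndarray:
    """Regular lattice points in the solvent shell.

    A cube bounding the RNA (plus ``outer`` margin) is sampled every
    ``spacing`` A; points are kept when between ``inner`` and ``outer``
    from a heavy atom of a well-resolved nucleotide (Q > q_min) and no
    closer than ``inner`` to any RNA heavy atom.
    """
    coords = model.rna.coords
    lo = coords.min(axis=0) - outer
    hi = coords.max(axis=0) + outer
    axes = [np.arange(lo[a], hi[a] + spacing / 2, spacing) for a in range(3)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d_all, d_qual = _shell_distances(pts, model, q_by_residue, q_min)
    keep = (d_all >= inner) & (d_qual <= outer)
    return pts[keep]
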
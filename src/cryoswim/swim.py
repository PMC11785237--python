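"""SWIM: segment-guided water and ion modeling.

Segments of the full map above 3 sigma are visited in order of decreasing
volume; the highest interpolated density point of each segment (Pmax) is
modeled as a water, a Mg2+ ion, or nothing, according to resolvability
(Q-score gates in the full map and both half maps, and of the nearest
nucleotide), density (5 sigma gate) and chemical-geometry rules.  The pass
is repeated, with newly accepted solvent joining the model, until an
iteration adds nothing (at most ``max_iterations`` passes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .densmap import DensityMap, MapStats, segment_map
from .model import Atom, AtomicModel
from .qscore import QScoreParams, q_score


@dataclass
class SwimParams:
    seg_threshold_sigma: float = 3.0
    density_min_sigma: float = 5.0
    q_peak_min: float = 0.7          # full map AND both half maps
    q_res_min: float = 0.6           # nearest nucleotide's Q
    water_clash: float = 3.2         # C or P within this -> no water
    ion_clash: float = 3.0           # C within this -> no ion
    ion_coord_range: tuple[float, float] = (1.8, 2.5)
    ion_repel_range: tuple[float, float] = (1.8, 3.4)   # protonated N
    water_bond_range: tuple[float, float] = (2.5, 3.4)  # N or O
    water_to_ion_range: tuple[float, float] = (1.8, 2.5)
    min_water_d: float = 2.5
    min_ion_d: float = 4.5
    max_iterations: int = 3
    qscore: QScoreParams = field(default_factory=QScoreParams)

    def __post_init__(self):
        for lo, hi in (self.ion_coord_range, self.ion_repel_range,
                       self.water_bond_range, self.water_to_ion_range):
            if not lo < hi:
                raise ValueError("range bounds must satisfy lower < upper")


@dataclass
class SolventPlacement:
    species: str                     # "water" | "MG"
    coord: np.ndarray
    peak_density: float
    peak_sigma: float                # sigma units above avgD
    q_full: float
    q_half1: float
    q_half2: float
    bound_atoms: list[tuple[str, int, str, float]]
    segment_volume: int = 0
    iteration: int = 0

    def as_atom(self, serial: int) -> Atom:
        if self.species == "water":
            return Atom("O", "O", tuple(self.coord), "S", serial, "HOH")
        return Atom("MG", "MG", tuple(self.coord), "S", serial, "MG")


@dataclass
class RejectedPeak:
    coord: np.ndarray
    reason: str
    iteration: int
    segment_volume: int


class _Geometry:
    """Precomputed atom arrays for the distance rules."""

    def __init__(self, model: AtomicModel):
        self.model = model
        atoms = model.atoms
        self.coords = model.coords
        self.tree = cKDTree(self.coords) if len(atoms) else None
        self.nonpolar = np.array([a.is_nonpolar for a in atoms], bool)
        self.carbon = np.array([a.element == "C" for a in atoms], bool)
        self.polar = np.array([a.is_polar for a in atoms], bool)
        self.electroneg = np.array([a.is_electronegative for a in atoms], bool)
        self.prot_n = np.array([a.is_protonated_nitrogen for a in atoms], bool)
        self.mg = np.array([a.species == "MG" for a in atoms], bool)
        self.rna_mask = np.array([a.is_rna for a in atoms], bool)
        self.atoms = atoms

    def neighbors(self, point: np.ndarray, radius: float) -> np.ndarray:
        if self.tree is None:
            return np.array([], dtype=int)
        return np.array(self.tree.query_ball_point(point, radius), dtype=int)

    def dists(self, point: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.coords[idx] - point, axis=1)


def _in_range(d: np.ndarray, rng: tuple[float, float]) -> np.ndarray:
    return (d >= rng[0]) & (d <= rng[1])


def geometry_classify(point: np.ndarray, geo: _Geometry,
                      params: SwimParams) -> tuple[str | None, str]:
    """Chemical-geometry part of the peak rules (no map involved).

    A Mg2+ ion requires an electronegative atom (O, or non-protonated N)
    at 1.8-2.5 A, no protonated nitrogen at 1.8-3.4 A, no carbon within
    3.0 A and no atom closer than 1.8 A.  A water requires an N/O at
    2.5-3.4 A or a Mg2+ at 1.8-2.5 A, no C/P within 3.2 A and no N/O
    closer than 2.5 A (the lower bound of each binding range acts as a
    clash floor).  Ion takes precedence, as expected for a cation.
    """
    point = np.asarray(point, float)
    idx = geo.neighbors(point, 3.5)
    if len(idx) == 0:
        return None, "no_binding_partner"
    d = geo.dists(point, idx)

    # ion candidacy
    ion_clash = (np.any(d[geo.carbon[idx]] <= params.ion_clash)
                 or np.any(d < params.ion_coord_range[0]))
    ion_repelled = np.any(
        _in_range(d, params.ion_repel_range) & geo.prot_n[idx])
    ion_coord = np.any(_in_range(d, params.ion_coord_range)
                       & geo.electroneg[idx])
    if ion_coord and not ion_repelled and not ion_clash:
        return "MG", "ion"

    # water candidacy
    water_clash = (np.any(d[geo.nonpolar[idx]] <= params.water_clash)
                   or np.any(d[geo.polar[idx]] < params.water_bond_range[0])
                   or np.any(d[geo.mg[idx]] < params.water_to_ion_range[0]))
    water_bond = (np.any(_in_range(d, params.water_bond_range)
                         & geo.polar[idx])
                  or np.any(_in_range(d, params.water_to_ion_range)
                            & geo.mg[idx]))
    if water_bond and not water_clash:
        return "water", "water"
    if water_clash or ion_clash:
        return None, "clash"
    return None, "no_binding_partner"


def classify_peak(pmax: np.ndarray, full: DensityMap, half1: DensityMap,
                  half2: DensityMap, model: AtomicModel,
                  q_by_residue: dict[tuple[str, int], float],
                  params: SwimParams,
                  geo: _Geometry | None = None,
                  full_stats: MapStats | None = None
                  ) -> tuple[str | None, str, dict]:
    """Apply the SWIM rules at a candidate peak.

    Returns (species or None, reason, diagnostics).  Gates are applied in
    order: peak Q in the full and both half maps, nearest-nucleotide Q,
    5-sigma density, then the geometry rules; the reason names the first
    failed gate.
    """
    pmax = np.asarray(pmax, float)
    geo = geo or _Geometry(model)
    full_stats = full_stats or full.stats()
    diag: dict = {}

    for m in (half1, half2):
        if not m.contains(pmax[None, :])[0]:
            raise ValueError("Pmax outside a half map")

    q_full = q_score(full, pmax, params=params.qscore, tree=geo.tree)
    q_h1 = q_score(half1, pmax, params=params.qscore, tree=geo.tree)
    q_h2 = q_score(half2, pmax, params=params.qscore, tree=geo.tree)
    diag.update(q_full=q_full, q_half1=q_h1, q_half2=q_h2)
    if not (q_full > params.q_peak_min):
        return None, "q_full", diag
    if not (q_h1 > params.q_peak_min and q_h2 > params.q_peak_min):
        return None, "q_half", diag

    # nearest RNA heavy atom's nucleotide must itself be well resolved
    rna_idx = np.flatnonzero(geo.rna_mask)
    if len(rna_idx):
        d_rna = geo.dists(pmax, rna_idx)
        nearest = geo.atoms[rna_idx[int(np.argmin(d_rna))]]
        q_res = q_by_residue.get((nearest.chain, nearest.res_seq), np.nan)
        diag["nearest_residue"] = (nearest.chain, nearest.res_seq)
        diag["residue_q"] = q_res
        if not (q_res >= params.q_res_min):
            return None, "residue_q", diag

    dens = float(full.interpolate(pmax))
    sig = (dens - full_stats.avgD) / full_stats.sigma
    diag.update(peak_density=dens, peak_sigma=sig)
    if dens < full_stats.level(params.density_min_sigma):
        return None, "density", diag

    species, reason = geometry_classify(pmax, geo, params)
    return species, reason, diag


def _bound_atoms(point: np.ndarray, geo: _Geometry, species: str,
                 params: SwimParams) -> list[tuple[str, int, str, float]]:
    rng = (params.ion_coord_range if species == "MG"
           else params.water_bond_range)
    idx = geo.neighbors(point, rng[1])
    out = []
    for i in idx:
        d = float(np.linalg.norm(geo.coords[i] - point))
        ok = _in_range(np.array([d]), rng)[0]
        if species == "water" and geo.mg[i]:
            ok = _in_range(np.array([d]), params.water_to_ion_range)[0]
        if species == "MG" and not geo.electroneg[i]:
            ok = False
        if species == "water" and not (geo.polar[i] or geo.mg[i]):
            ok = False
        if ok:
            a = geo.atoms[i]
            out.append((a.chain, a.res_seq, a.name, d))
    return sorted(out, key=lambda t: t[3])


@dataclass
class SwimResult:
    placements: list[SolventPlacement]
    rejected: list[RejectedPeak]
    iterations: int

    def solvated_model(self, model: AtomicModel) -> AtomicModel:
        start = 1 + max((a.res_seq for a in model), default=0)
        return model.add_atoms([p.as_atom(start + i)
                                for i, p in enumerate(self.placements)])


def run_swim(full: DensityMap, half1: DensityMap, half2: DensityMap,
             model: AtomicModel,
             q_by_residue: dict[tuple[str, int], float],
             params: SwimParams | None = None) -> SwimResult:
    """Run the full iterative placement.

    ``q_by_residue`` carries the per-nucleotide Q-scores of the input RNA
    (compute with :func:`cryoswim.qscore.q_by_residue_dict`).  Determinism:
    segments are visited by decreasing volume, ties by first voxel index.
    """
    params = params or SwimParams()
    for m in (half1, half2):
        if m.shape != full.shape:
            raise ValueError("full and half maps must share a grid")
    stats = full.stats()
    threshold = stats.level(params.seg_threshold_sigma)
    segments = segment_map(full, threshold)

    placements: list[SolventPlacement] = []
    rejected: list[RejectedPeak] = []
    work_model = model
    iteration = 0
    for iteration in range(1, params.max_iterations + 1):
        geo = _Geometry(work_model)
        added: list[SolventPlacement] = []
        for seg in segments:
            if not (full.contains(seg.pmax[None])[0]
                    and half1.contains(seg.pmax[None])[0]
                    and half2.contains(seg.pmax[None])[0]):
                continue
            species, reason, diag = classify_peak(
                seg.pmax, full, half1, half2, work_model, q_by_residue,
                params, geo=geo, full_stats=stats)
            if species is None:
                rejected.append(RejectedPeak(seg.pmax, reason, iteration,
                                             seg.volume))
                continue
            accepted = placements + added
            min_d = (params.min_water_d if species == "water"
                     else params.min_ion_d)
            same = [p for p in accepted if p.species == species]
            if same and min(np.linalg.norm(p.coord - seg.pmax)
                            for p in same) < min_d:
                rejected.append(RejectedPeak(
                    seg.pmax, f"too_close_{species}", iteration, seg.volume))
                continue
            added.append(SolventPlacement(
                species=species, coord=seg.pmax,
                peak_density=diag["peak_density"],
                peak_sigma=diag["peak_sigma"],
                q_full=diag["q_full"], q_half1=diag["q_half1"],
                q_half2=diag["q_half2"],
                bound_atoms=_bound_atoms(seg.pmax, geo, species, params),
                segment_volume=seg.volume, iteration=iteration))
            # newly accepted solvent joins the model immediately
            serial = 9000 + len(placements) + len(added)
            work_model = work_model.add_atoms([added[-1].as_atom(serial)])
            geo = _Geometry(work_model)
        placements.extend(added)
        if not added:
            break
    return SwimResult(placements, rejected, iteration)


def assess_strictness(points: np.ndarray, full: DensityMap,
                      half1: DensityMap, half2: DensityMap,
                      model: AtomicModel,
                      params: SwimParams | None = None) -> dict:
    """Marginal and joint pass rates of the map-based SWIM criteria over
    sampled solvent-shell positions (density >= 5 sigma; Q > 0.7 in the
    full map; Q > 0.7 in both half maps)."""
    from .qscore import q_scores_batch
    params = params or SwimParams()
    points = np.atleast_2d(np.asarray(points, float))
    stats = full.stats()
    geo = _Geometry(model)
    level = stats.level(params.density_min_sigma)
    dens_ok = full.interpolate(points) >= level
    qf = q_scores_batch(full, points, geo.tree, params.qscore)
    q1 = q_scores_batch(half1, points, geo.tree, params.qscore)
    q2 = q_scores_batch(half2, points, geo.tree, params.qscore)
    with np.errstate(invalid="ignore"):
        qf_ok = qf > params.q_peak_min
        qh_ok = (q1 > params.q_peak_min) & (q2 > params.q_peak_min)
    joint = dens_ok & qf_ok & qh_ok
    n = len(points)
    return {
        "n_points": n,
        "density_pass": float(dens_ok.mean()) if n else 0.0,
        "q_full_pass": float(qf_ok.mean()) if n else 0.0,
        "q_half_pass": float(qh_ok.mean()) if n else 0.0,
        "joint_pass": float(joint.mean()) if n else 0.0,
    }


def audit_placements(result: SwimResult, full: DensityMap, half1: DensityMap,
                     half2: DensityMap, model: AtomicModel,
                     q_by_residue: dict[tuple[str, int], float],
                     params: SwimParams | None = None) -> bool:
    """Re-check every accepted placement against all gates post hoc.

    The model used for re-checking is the final solvated model minus the
    placement under audit (its own oxygen must not veto itself).
    """
    params = params or SwimParams()
    final = result.solvated_model(model)
    for k, p in enumerate(result.placements):
        others = AtomicModel([a for a in final.atoms
                              if not np.allclose(a.coord, p.coord)])
        species, _, _ = classify_peak(p.coord, full, half1, half2, others,
                                      q_by_residue, params)
        if species != p.species:
            return False
    return True
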
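"""Q-score atomic resolvability: correlation of the local density profile
around an atom (or candidate peak) with a reference Gaussian.

The reference profile is g(r) = A * exp(-0.5 (r/sigma_ref)^2) + B with
A = avgD + 10 * sigma and B = avgD - sigma taken from whole-map statistics,
so Q is invariant to affine rescaling of the map ("independent of the
contour level").  Sample points closer to another model atom than to the
query point are rejected to avoid neighbor contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .densmap import DensityMap
from .model import AtomicModel, atom_part


@dataclass
class QScoreParams:
    sigma_ref: float = 0.6        # reference Gaussian width, Angstrom
    max_radius: float = 2.0
    radial_step: float = 0.1
    points_per_shell: int = 8

    def __post_init__(self):
        if self.sigma_ref <= 0:
            raise ValueError("sigma_ref must be positive")
        if not (self.max_radius > self.radial_step > 0):
            raise ValueError("need max_radius > radial_step > 0")


def _fibonacci_sphere(n: int, phase: float = 0.0) -> np.ndarray:
    """Deterministic, near-uniform unit vectors; ``phase`` decorrelates shells."""
    i = np.arange(n, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = golden * i + phase
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def shell_sample_points(center: np.ndarray,
                        params: QScoreParams) -> tuple[np.ndarray, np.ndarray]:
    """Points on concentric shells r = 0, step, ..., max_radius and their radii."""
    center = np.asarray(center, float)
    pts = [center[None, :]]
    radii = [np.zeros(1)]
    nshell = int(round(params.max_radius / params.radial_step))
    for s in range(1, nshell + 1):
        r = s * params.radial_step
        dirs = _fibonacci_sphere(params.points_per_shell, phase=0.77 * s)
        pts.append(center + r * dirs)
        radii.append(np.full(len(dirs), r))
    return np.concatenate(pts), np.concatenate(radii)


def q_score(dmap: DensityMap, point: np.ndarray,
            model: AtomicModel | np.ndarray | None = None,
            params: QScoreParams | None = None,
            exclude_index: int | None = None,
            tree: cKDTree | None = None) -> float:
    """Q-score of the density around ``point``.

    ``model`` (or a prebuilt ``tree`` over its coordinates) provides the
    neighboring atoms used for the rejection rule; ``exclude_index`` marks
    the query atom itself when scoring a model atom.  Returns NaN when
    fewer than 4 sample points survive (undefined Q).
    """
    params = params or QScoreParams()
    point = np.asarray(point, float)
    pts, radii = shell_sample_points(point, params)

    inside = dmap.contains(pts)
    keep = inside
    if tree is None and model is not None:
        coords = model.coords if isinstance(model, AtomicModel) else np.asarray(model)
        if len(coords):
            tree = cKDTree(coords)
    if tree is not None:
        k = 2 if exclude_index is not None else 1
        dist, idx = tree.query(pts, k=k)
        if k == 2:
            # use the nearest atom that is not the query atom itself
            use_second = idx[:, 0] == exclude_index
            d_other = np.where(use_second, dist[:, 1], dist[:, 0])
        else:
            d_other = dist
        d_query = np.linalg.norm(pts - point, axis=1)
        keep = keep & ~(d_other < d_query)

    if keep.sum() < 4:
        return float("nan")
    vals = dmap.interpolate(pts[keep])
    stats = dmap.stats()
    A = stats.avgD + 10.0 * stats.sigma
    B = stats.avgD - stats.sigma
    ref = A * np.exp(-0.5 * (radii[keep] / params.sigma_ref) ** 2) + B
    v = vals - vals.mean()
    g = ref - ref.mean()
    denom = np.sqrt((v * v).sum() * (g * g).sum())
    if denom == 0:
        return float("nan")
    return float((v * g).sum() / denom)


def q_scores_batch(dmap: DensityMap, points: np.ndarray,
                   tree: cKDTree | None = None,
                   params: QScoreParams | None = None) -> np.ndarray:
    """Vectorized Q-score for many query points (none of them model atoms).

    Equivalent to calling :func:`q_score` per point; used for shell-wide
    assessments where the per-point loop would dominate.
    """
    params = params or QScoreParams()
    points = np.atleast_2d(np.asarray(points, float))
    n = len(points)
    rel, radii = shell_sample_points(np.zeros(3), params)
    m = len(rel)
    pts = points[:, None, :] + rel[None, :, :]          # (n, m, 3)
    flat = pts.reshape(-1, 3)
    keep = dmap.contains(flat)
    if tree is not None:
        d_other = tree.query(flat, k=1)[0]
        d_query = np.tile(radii, n)
        keep = keep & ~(d_other < d_query)
    vals = np.zeros(len(flat))
    vals[keep] = dmap.interpolate(flat[keep])
    vals = vals.reshape(n, m)
    keep = keep.reshape(n, m)

    stats = dmap.stats()
    A = stats.avgD + 10.0 * stats.sigma
    B = stats.avgD - stats.sigma
    ref = A * np.exp(-0.5 * (radii / params.sigma_ref) ** 2) + B
    ref = np.broadcast_to(ref, (n, m))

    w = keep.astype(float)
    cnt = w.sum(axis=1)
    out = np.full(n, np.nan)
    ok = cnt >= 4
    if not ok.any():
        return out
    vm = (vals * w).sum(axis=1) / np.maximum(cnt, 1)
    gm = (ref * w).sum(axis=1) / np.maximum(cnt, 1)
    dv = (vals - vm[:, None]) * w
    dg = (ref - gm[:, None]) * w
    num = (dv * dg).sum(axis=1)
    den = np.sqrt((dv * dv).sum(axis=1) * (dg * dg).sum(axis=1))
    good = ok & (den > 0)
    out[good] = num[good] / den[good]
    return out


def model_q_scores(dmap: DensityMap, model: AtomicModel,
                   params: QScoreParams | None = None) -> pd.DataFrame:
    """Per-atom Q for every heavy atom of the model.

    Columns: chain, res_seq, res_name, atom, part, Q, B (= 150(1-Q)).
    """
    params = params or QScoreParams()
    coords = model.coords
    tree = cKDTree(coords) if len(coords) else None
    rows = []
    for i, atom in enumerate(model):
        q = q_score(dmap, atom.coord, params=params,
                    exclude_index=i, tree=tree)
        rows.append({
            "chain": atom.chain, "res_seq": atom.res_seq,
            "res_name": atom.res_name, "atom": atom.name,
            "part": atom_part(atom.name), "Q": q,
            "B": q_to_bfactor(q) if np.isfinite(q) else np.nan,
        })
    return pd.DataFrame(rows)


def residue_q(atom_q: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-residue mean Q, overall and per nucleotide part.

    Atoms with unknown part are excluded from part means but included in
    the overall residue mean.
    """
    rows = []
    for (chain, seq), grp in atom_q.groupby(["chain", "res_seq"], sort=False):
        row = {"chain": chain, "res_seq": seq,
               "res_name": grp["res_name"].iloc[0],
               "Q": grp["Q"].mean()}
        for part in ("base", "sugar", "phosphate_oxygens", "phosphorus"):
            sub = grp[grp["part"] == part]
            row[f"Q_{part}"] = sub["Q"].mean() if len(sub) else np.nan
        backbone = grp[grp["part"].isin(
            ["sugar", "phosphate_oxygens", "phosphorus"])]
        row["Q_backbone"] = backbone["Q"].mean() if len(backbone) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def q_by_residue_dict(dmap: DensityMap, model: AtomicModel,
                      params: QScoreParams | None = None
                      ) -> dict[tuple[str, int], float]:
    """Convenience: {(chain, res_seq): residue Q} for the model's RNA."""
    rq = residue_q(model_q_scores(dmap, model.rna, params))
    return {(r.chain, r.res_seq): float(r.Q) for r in rq.itertuples()}


def rolling_residue_q(res_q: pd.DataFrame, window: int = 10,
                      column: str = "Q") -> pd.Series:
    """Rolling mean over ``window`` nucleotides, in residue order."""
    return res_q[column].rolling(window, min_periods=1).mean()


def q_to_bfactor(q: float | np.ndarray) -> float | np.ndarray:
    """B-factor assigned to solvent atoms from their Q-score: B = 150(1-Q)."""
    return 150.0 * (1.0 - np.asarray(q)) if np.ndim(q) else 150.0 * (1.0 - q)
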
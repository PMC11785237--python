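"""Quantitative comparison of solvent-shell densities.

The reference map's solvent shell (voxels 1.8-3.5 A from well-resolved
RNA) is compared against a candidate density (an independent map, a
model-derived map, an ensemble-derived map, or a shuffled control) through
Pearson correlation, mutual information on a 20x20 joint histogram, and a
threshold-classification view: reference voxels above 3 sigma are the
positive class, the candidate's threshold is swept, and
precision/recall/FPR curves with AU-PRC, AU-ROC and max-MCC summarize the
agreement.  AU-PRC is preferred because solvent voxels are a minority
class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .densmap import DensityMap, ShellMask, per_residue_shell_mask
from .model import AtomicModel, superpose


def znorm_shell(dmap: DensityMap, mask: ShellMask | np.ndarray) -> np.ndarray:
    """Z-score the map by whole-grid statistics and return shell values."""
    m = mask.mask if isinstance(mask, ShellMask) else np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty shell mask")
    stats = dmap.stats()
    if stats.sigma == 0:
        raise ValueError("constant map: standard deviation is zero")
    z = (dmap.grid - stats.avgD) / stats.sigma
    return z[m]


def compare_global(reference: np.ndarray, comparison: np.ndarray,
                   bins: int = 20) -> dict:
    """Pearson CC and mutual information over aligned shell vectors.

    MI uses ``bins`` equal-width bins spanning each vector's observed
    range; empty joint cells contribute zero.  Reported in both nats and
    bits (the cited convention does not fix the base).
    """
    r = np.asarray(reference, float).ravel()
    c = np.asarray(comparison, float).ravel()
    if r.shape != c.shape:
        raise ValueError("length mismatch")
    cc = float(np.corrcoef(r, c)[0, 1])
    joint, _, _ = np.histogram2d(r, c, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log(p / (px * py))
    mi_nats = float(np.nansum(term))
    return {"cc": cc, "mi_nats": mi_nats, "mi_bits": mi_nats / np.log(2.0)}


@dataclass
class ClassificationCurves:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    fpr: np.ndarray
    auprc: float
    auroc: float
    max_mcc: float
    prevalence: float
    undefined: bool = False


def classify_solvent(reference: np.ndarray, comparison: np.ndarray,
                     pos_threshold: float = 3.0) -> ClassificationCurves:
    """Threshold-classification curves of a candidate against the
    reference's super-threshold voxels.

    Positives are reference values > ``pos_threshold`` (3 sigma when the
    vectors are z-scored).  The candidate threshold sweeps all unique
    values plus the +/- infinity endpoints; a voxel is predicted positive
    when its candidate value >= threshold.  AU-PRC integrates the
    monotone-interpolated precision staircase by trapezoid over recall;
    AU-ROC by trapezoid over FPR.
    """
    r = np.asarray(reference, float).ravel()
    c = np.asarray(comparison, float).ravel()
    if r.shape != c.shape:
        raise ValueError("length mismatch")
    pos = r > pos_threshold
    P = int(pos.sum())
    N = len(r) - P
    if P == 0:
        return ClassificationCurves(np.array([]), np.array([]), np.array([]),
                                    np.array([]), float("nan"), float("nan"),
                                    float("nan"), 0.0, undefined=True)

    order = np.argsort(-c, kind="stable")
    c_sorted = c[order]
    pos_sorted = pos[order]
    tp_cum = np.cumsum(pos_sorted)
    fp_cum = np.cumsum(~pos_sorted)
    # distinct-threshold boundaries: last occurrence of each value
    last = np.r_[c_sorted[1:] != c_sorted[:-1], True]
    idx = np.flatnonzero(last)
    tp = tp_cum[idx].astype(float)
    fp = fp_cum[idx].astype(float)
    thresholds = np.r_[np.inf, c_sorted[idx]]
    tp = np.r_[0.0, tp]
    fp = np.r_[0.0, fp]

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 1.0)
    recall = tp / P
    fpr = fp / N if N > 0 else np.zeros_like(fp)
    fn = P - tp
    tn = N - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = np.where(denom > 0, (tp * tn - fp * fn) / denom, 0.0)
    max_mcc = float(np.max(mcc))

    # monotone (interpolated) precision: running max from high recall down
    prec_interp = np.maximum.accumulate(precision[::-1])[::-1]
    auprc = float(np.trapezoid(prec_interp, recall))
    auroc = float(np.trapezoid(recall, fpr)) if N > 0 else float("nan")
    return ClassificationCurves(thresholds, precision, recall, fpr,
                                auprc, auroc, max_mcc, P / len(r))


def shuffle_control(dmap: DensityMap, mask: ShellMask | np.ndarray,
                    rng: np.random.Generator | int) -> DensityMap:
    """The map with solvent-shell values randomly permuted in place;
    voxels outside the mask are untouched."""
    m = mask.mask if isinstance(mask, ShellMask) else np.asarray(mask, bool)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = dmap.copy()
    vals = out.grid[m]
    out.grid[m] = rng.permutation(vals)
    return out


def per_nucleotide_score(reference: DensityMap, candidate: DensityMap,
                         independent: DensityMap, shuffled: DensityMap,
                         model: AtomicModel,
                         pos_threshold: float = 3.0,
                         inner: float = 1.8, outer: float = 3.5,
                         exp_floor: float = 0.2) -> dict:
    """Min-max-normalized per-nucleotide AU-PRC of a candidate density.

    For each nucleotide, the reference shell (voxels ``inner``-``outer``
    from its heavy atoms, outside ``inner`` of all RNA) defines positives
    above ``pos_threshold`` sigma; the candidate's AU-PRC is normalized
    with the independent map's AU-PRC as ceiling (1) and the shuffled
    control's as floor (0), clipped to [0, 1].  Nucleotides whose
    experimental ceiling is below ``exp_floor`` are scored 0 (high
    experimental uncertainty); empty shells yield no score.
    """
    scores: dict[tuple[str, int], dict] = {}
    ref_stats = reference.stats()
    zref = (reference.grid - ref_stats.avgD) / ref_stats.sigma
    for residue in model.rna.residues():
        mask = per_residue_shell_mask(reference, model, residue, inner, outer)
        if not mask.any():
            continue
        rvals = zref[mask]
        entry = {}
        for name, dm in (("candidate", candidate),
                         ("independent", independent),
                         ("shuffled", shuffled)):
            st = dm.stats()
            zc = (dm.grid[mask] - st.avgD) / st.sigma if st.sigma > 0 \
                else dm.grid[mask]
            cur = classify_solvent(rvals, zc, pos_threshold)
            entry[f"auprc_{name}"] = cur.auprc
        e = entry["auprc_independent"]
        f = entry["auprc_shuffled"]
        c = entry["auprc_candidate"]
        if not np.isfinite(e) or e < exp_floor:
            score = 0.0
        elif e - f <= 0:
            score = 0.0
        else:
            score = float(np.clip((c - f) / (e - f), 0.0, 1.0))
        entry["score"] = score
        scores[residue] = entry
    return scores


def nucleotide_type_average(dmap: DensityMap, model: AtomicModel,
                            types: tuple[str, ...] = ("A", "C", "G", "U"),
                            box: float = 12.0, voxel: float = 0.5,
                            zone: float = 1.8) -> dict[str, DensityMap]:
    """Average density around each nucleotide type in a common base frame.

    Each residue's base atoms are superposed onto an idealized reference
    base; the map (zoned beyond ``zone`` A of RNA heavy atoms) is
    resampled under that transform onto a local grid and residues of the
    same type are averaged evenly.
    """
    from scipy.spatial import cKDTree
    from .fixtures import base_reference_template
    from .model import BASE_ATOMS

    rna = model.rna
    tree = cKDTree(rna.coords)
    centers = dmap.voxel_centers()
    d = tree.query(centers, k=1)[0].reshape(dmap.shape)
    zoned = dmap.copy()
    zoned.grid[d < zone] = 0.0

    n = int(np.ceil(box / voxel))
    axes = np.arange(-n, n + 1) * voxel
    local_pts = np.stack(np.meshgrid(axes, axes, axes, indexing="ij"),
                         axis=-1).reshape(-1, 3)
    out: dict[str, DensityMap] = {}
    for t in types:
        ref_base = base_reference_template(t)
        acc = None
        count = 0
        for (chain, seq), atoms in rna.residues().items():
            from .model import base_type
            if base_type(atoms[0].res_name) != t:
                continue
            pairs = [(a, ref_base[a.name]) for a in atoms
                     if a.name in ref_base and a.name in BASE_ATOMS]
            if len(pairs) < 3:
                continue
            src = np.array([p[1] for p in pairs])       # reference frame
            dst = np.array([np.asarray(p[0].coord) for p in pairs])
            R, tr = superpose(dst, src)                 # ref -> model frame
            sample_pts = local_pts @ R.T + tr
            inside = dmap.contains(sample_pts)
            vals = np.zeros(len(sample_pts))
            if inside.any():
                vals[inside] = zoned.interpolate(sample_pts[inside])
            grid = vals.reshape(2 * n + 1, 2 * n + 1, 2 * n + 1)
            acc = grid if acc is None else acc + grid
            count += 1
        if count == 0:
            raise ValueError(f"no residues of type {t}")
        out[t] = DensityMap(acc / count, np.full(3, voxel),
                            np.full(3, -n * voxel))
    return out
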
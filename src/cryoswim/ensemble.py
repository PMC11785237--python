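"""Ensemble (MD-style) solvent analysis on coordinate frame sets.

Frames carry RNA coordinates plus water/ion positions (any engine;
multi-model PDB or tabular per-frame coordinates adapt in).  Binding
sites are detected as peaks of per-species occupancy densities, frames
are assigned to sites under local-neighborhood alignment, and sites are
summarized by occupancy, water RMSF and Mg2+ residence time.  Per-residue
RNA flexibility converts RMSF to a B-factor via B = (8 pi^2 / 3) RMSF^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .densmap import DensityMap, segment_map
from .model import AtomicModel, superpose

AVOGADRO = 6.02214076e23


def molarity_to_number_density(molar: float) -> float:
    """mol/L -> particles per cubic Angstrom (1 L = 1e27 A^3)."""
    if molar < 0:
        raise ValueError("concentration must be non-negative")
    return molar * AVOGADRO / 1e27


def number_density_to_molarity(per_A3: float) -> float:
    if per_A3 < 0:
        raise ValueError("number density must be non-negative")
    return per_A3 * 1e27 / AVOGADRO


@dataclass
class EnsembleFrameSet:
    """Per-frame coordinates with constant RNA topology.

    ``frames`` is a list of dicts with keys ``rna`` ((N,3) array, atom
    order constant), ``water`` and ``MG`` ((n,3) arrays, count may vary).
    """
    frames: list[dict]
    rna_atom_keys: list[tuple[str, int, str]]
    frame_interval_ns: float = 1.0

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_fixture(cls, fix) -> "EnsembleFrameSet":
        keys = [a.key for a in fix.model.rna.atoms]
        return cls(fix.frames, keys, fix.spec.frame_interval_ns)

    @classmethod
    def from_table(cls, df: pd.DataFrame,
                   rna_atom_keys: list[tuple[str, int, str]],
                   frame_interval_ns: float = 1.0) -> "EnsembleFrameSet":
        """Adapt a (frame, species, x, y, z) table; species 'rna' rows must
        appear in the same atom order in every frame."""
        frames = []
        for _, grp in df.groupby("frame", sort=True):
            fr = {}
            for sp in ("rna", "water", "MG"):
                sub = grp[grp["species"] == sp]
                fr[sp] = sub[["x", "y", "z"]].to_numpy(float).reshape(-1, 3)
            frames.append(fr)
        return cls(frames, rna_atom_keys, frame_interval_ns)

    def rna_rmsd_to(self, ref_coords: np.ndarray) -> np.ndarray:
        """Per-frame RNA heavy-atom RMSD to a reference after rigid
        superposition on all RNA heavy atoms."""
        out = np.empty(len(self.frames))
        ref = np.asarray(ref_coords, float)
        for f, fr in enumerate(self.frames):
            R, t = superpose(ref, fr["rna"])
            moved = fr["rna"] @ R.T + t
            out[f] = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2,
                                                  axis=1))))
        return out


def retained_frames(ens: EnsembleFrameSet,
                    references: list[np.ndarray],
                    max_rmsd: float = 3.4) -> np.ndarray:
    """Frames whose RNA stays within ``max_rmsd`` of at least one
    reference structure (boolean per frame)."""
    keep = np.zeros(len(ens), bool)
    for ref in references:
        keep |= ens.rna_rmsd_to(ref) <= max_rmsd
    return keep


# ---------------------------------------------------------------------------
# Occupancy densities and binding-site detection

def occupancy_density(ens: EnsembleFrameSet, species: str = "water",
                      voxel: float = 0.5, margin: float = 5.0,
                      frame_mask: np.ndarray | None = None,
                      smooth: float = 0.4) -> DensityMap:
    """Time-averaged number density (per A^3) of a solvent species.

    Counts are Gaussian-smoothed by ``smooth`` A (mean-preserving) so
    that isolated single-frame counts do not masquerade as peaks."""
    pts = []
    n_frames = 0
    for f, fr in enumerate(ens.frames):
        if frame_mask is not None and not frame_mask[f]:
            continue
        n_frames += 1
        if len(fr[species]):
            pts.append(fr[species])
    if n_frames == 0:
        raise ValueError("no frames retained")
    rna0 = ens.frames[0]["rna"]
    lo = rna0.min(0) - margin
    hi = rna0.max(0) + margin
    shape = tuple(np.ceil((hi - lo) / voxel).astype(int) + 1)
    grid = np.zeros(shape)
    if pts:
        allp = np.vstack(pts)
        idx = np.floor((allp - lo) / voxel + 0.5).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        np.add.at(grid, tuple(idx[ok].T), 1.0)
    grid /= n_frames * voxel ** 3
    if smooth > 0:
        from scipy.ndimage import gaussian_filter
        grid = gaussian_filter(grid, sigma=smooth / voxel)
    return DensityMap(grid, np.full(3, voxel), lo)


@dataclass
class BindingSite:
    species: str
    peak: np.ndarray                 # coordinate, Angstrom
    peak_density: float              # per A^3
    bound_atoms: frozenset           # RNA atom keys within the motif range
    occupancy: float = float("nan")
    rmsf: float = float("nan")
    residence_frames: list[int] = field(default_factory=list)


def detect_sites(density: DensityMap, species: str, model: AtomicModel,
                 threshold: float | None = None,
                 min_peak_sep: float = 1.0,
                 binder_range: tuple[float, float] | None = None
                 ) -> list[BindingSite]:
    """Watershed peaks of a species density, de-duplicated at 1 A
    (keeping the denser peak), annotated with their bound-RNA-atom set."""
    if threshold is None:
        # twice the number density of bulk water (55 M)
        threshold = 2.0 * molarity_to_number_density(55.0)
    if binder_range is None:
        binder_range = (1.8, 2.5) if species == "MG" else (2.5, 3.5)
    segs = segment_map(density, threshold)
    peaks = sorted(((s.peak_density, tuple(s.pmax)) for s in segs),
                   reverse=True)
    kept: list[tuple[float, np.ndarray]] = []
    for dens, coord in peaks:
        c = np.array(coord)
        if any(np.linalg.norm(c - k[1]) < min_peak_sep for k in kept):
            continue
        kept.append((dens, c))
    rna = model.rna
    tree = cKDTree(rna.coords)
    sites = []
    for dens, c in kept:
        binders = set()
        for i in tree.query_ball_point(c, binder_range[1]):
            a = rna.atoms[i]
            d = np.linalg.norm(np.asarray(a.coord) - c)
            if binder_range[0] <= d <= binder_range[1]:
                binders.add(a.key)
        sites.append(BindingSite(species, c, float(dens),
                                 frozenset(binders)))
    return sites


def refine_site_binders(ens: EnsembleFrameSet, sites: list[BindingSite],
                        site_radius: float = 2.0) -> list[BindingSite]:
    """Replace each site's geometric binder set with the modal bound-RNA-
    atom set of the solvent found within ``site_radius`` of its peak.

    The binder set read off at the density peak is fragile when an RNA
    atom sits near a cutoff boundary; the most common set among actual
    members is the natural label for "bound to the same RNA atoms".
    Sites with no members keep their geometric set.
    """
    from collections import Counter
    ranges = {"water": (2.5, 3.5), "MG": (1.8, 2.5)}
    counters = [Counter() for _ in sites]
    for fr in ens.frames:
        tree_f = cKDTree(fr["rna"])
        for species in ("water", "MG"):
            for p in fr[species]:
                for s, site in enumerate(sites):
                    if site.species != species:
                        continue
                    if np.linalg.norm(p - site.peak) > site_radius:
                        continue
                    rng = ranges[species]
                    binders = set()
                    for i in tree_f.query_ball_point(p, rng[1]):
                        if rng[0] <= np.linalg.norm(fr["rna"][i] - p) <= rng[1]:
                            binders.add(ens.rna_atom_keys[i])
                    counters[s][frozenset(binders)] += 1
    out = []
    for site, counter in zip(sites, counters):
        binders = (counter.most_common(1)[0][0] if counter
                   else site.bound_atoms)
        out.append(BindingSite(site.species, site.peak, site.peak_density,
                               frozenset(binders)))
    return out


# ---------------------------------------------------------------------------
# Frame assignment

def neighborhoods(model: AtomicModel, radius: float = 10.0
                  ) -> dict[tuple[str, int], list[tuple[str, int]]]:
    """For each nucleotide, the set of nucleotides with any heavy atom
    within ``radius`` of any of its heavy atoms."""
    rna = model.rna
    res = rna.residues()
    keys = list(res)
    coords = {k: np.array([a.coord for a in v]) for k, v in res.items()}
    out = {}
    for k in keys:
        tree = cKDTree(coords[k])
        nb = [k2 for k2 in keys
              if np.min(tree.query(coords[k2], k=1)[0]) <= radius]
        out[k] = nb
    return out


def assign_frames(ens: EnsembleFrameSet, sites: list[BindingSite],
                  model: AtomicModel,
                  nbhd: dict | None = None,
                  site_radius: float = 2.0) -> pd.DataFrame:
    """Assign each frame's solvent to binding sites.

    Every frame is locally aligned to each nucleotide neighborhood; a
    solvent present in several neighborhoods keeps the coordinates from
    the one whose center it is closest to.  A solvent matches a site when
    its locally aligned position is within ``site_radius`` of the peak
    and it binds the identical RNA atom set (motif cutoffs: ions
    1.8-2.5 A, waters 2.5-3.5 A).  Returns rows (frame, site, species,
    x, y, z, distance).
    """
    rna = model.rna
    nbhd = nbhd or neighborhoods(model)
    key_index = {k: i for i, k in enumerate(ens.rna_atom_keys)}
    res_atoms = {}
    for k, atoms in rna.residues().items():
        res_atoms[k] = [key_index[a.key] for a in atoms]
    ref_coords = np.array([rna.atom_by_key(k).coord
                           for k in ens.rna_atom_keys])
    nb_idx = {}
    nb_center = {}
    for k, members in nbhd.items():
        idx = np.concatenate([res_atoms[m] for m in members])
        nb_idx[k] = idx
        nb_center[k] = ref_coords[idx].mean(axis=0)

    ranges = {"water": (2.5, 3.5), "MG": (1.8, 2.5)}
    rows = []
    for f, fr in enumerate(ens.frames):
        frame_rna = fr["rna"]
        # local alignment per neighborhood
        transforms = {}
        for k, idx in nb_idx.items():
            R, t = superpose(ref_coords[idx], frame_rna[idx])
            transforms[k] = (R, t)
        for species in ("water", "MG"):
            pts = fr[species]
            if len(pts) == 0:
                continue
            rng = ranges[species]
            # binder sets in the frame's own geometry
            tree_f = cKDTree(frame_rna)
            for w, p in enumerate(pts):
                # candidate aligned coordinates, one per neighborhood
                best = None
                for k, (R, t) in transforms.items():
                    q = R @ p + t
                    d_center = np.linalg.norm(q - nb_center[k])
                    if d_center > 12.0:
                        continue
                    if best is None or d_center < best[0]:
                        best = (d_center, q)
                if best is None:
                    continue
                q = best[1]
                binders = set()
                for i in tree_f.query_ball_point(p, rng[1]):
                    d = np.linalg.norm(frame_rna[i] - p)
                    if rng[0] <= d <= rng[1]:
                        binders.add(ens.rna_atom_keys[i])
                for s, site in enumerate(sites):
                    if site.species != species:
                        continue
                    d = np.linalg.norm(q - site.peak)
                    if d <= site_radius and binders == set(site.bound_atoms):
                        rows.append({"frame": f, "site": s,
                                     "species": species,
                                     "x": q[0], "y": q[1], "z": q[2],
                                     "distance": d})
                        break
    return pd.DataFrame(rows,
                        columns=["frame", "site", "species",
                                 "x", "y", "z", "distance"])


def _residence_events(present_frames: np.ndarray, n_frames: int,
                      max_gap: int = 1) -> list[int]:
    """Lengths (in frames, inclusive of skipped ones) of presence runs,
    merging runs separated by at most ``max_gap`` absent frames."""
    if len(present_frames) == 0:
        return []
    fr = np.sort(np.unique(present_frames))
    events = []
    start = prev = fr[0]
    for f in fr[1:]:
        if f - prev <= max_gap + 1:
            prev = f
        else:
            events.append(int(prev - start + 1))
            start = prev = f
    events.append(int(prev - start + 1))
    return events


def site_statistics(assignments: pd.DataFrame, sites: list[BindingSite],
                    frame_mask: np.ndarray,
                    gap_frames: int = 1) -> pd.DataFrame:
    """Occupancy, water RMSF and residence times per binding site.

    Occupancy is the fraction of retained frames (``frame_mask``) in
    which the site is bound; RMSF is over the aligned member coordinates
    in retained frames; residence events merge across single-frame gaps.
    """
    n_retained = int(frame_mask.sum())
    if n_retained == 0:
        raise ValueError("no retained frames")
    rows = []
    for s, site in enumerate(sites):
        sub = assignments[(assignments["site"] == s)
                          & assignments["frame"].map(
                              lambda f: bool(frame_mask[f]))]
        frames = sub["frame"].to_numpy()
        occ = len(np.unique(frames)) / n_retained
        if len(sub):
            xyz = sub[["x", "y", "z"]].to_numpy(float)
            mean = xyz.mean(axis=0)
            rmsf = float(np.sqrt(np.mean(np.sum((xyz - mean) ** 2, axis=1))))
        else:
            rmsf = float("nan")
        events = _residence_events(frames, len(frame_mask), gap_frames)
        rows.append({"site": s, "species": site.species,
                     "occupancy": occ, "rmsf": rmsf,
                     "n_events": len(events),
                     "max_residence_frames": max(events) if events else 0,
                     "mean_residence_frames":
                         float(np.mean(events)) if events else 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Composite density and RNA flexibility

def accumulate_density(submaps: list[tuple[np.ndarray, DensityMap]],
                       voxel: float = 0.5,
                       radius: float = 10.0) -> DensityMap:
    """Inverse-distance-weighted composite of locally averaged submaps.

    Each submap has a center; a composite voxel averages the values of
    all submaps whose center lies within ``radius``, weighted by 1/d to
    the submap center.  Voxels covered by no submap are NaN (missing).
    """
    if not submaps:
        raise ValueError("need at least one submap")
    los = [sm.origin for _, sm in submaps]
    his = [sm.to_coord(np.array(sm.shape) - 1) for _, sm in submaps]
    lo = np.min(los, axis=0)
    hi = np.max(his, axis=0)
    shape = tuple(np.ceil((hi - lo) / voxel).astype(int) + 1)
    out = DensityMap(np.zeros(shape), np.full(3, voxel), lo)
    centers = out.voxel_centers()
    num = np.zeros(len(centers))
    den = np.zeros(len(centers))
    eps = 1e-6
    for center, sm in submaps:
        d = np.linalg.norm(centers - np.asarray(center), axis=1)
        near = d <= radius
        inside = sm.contains(centers)
        use = near & inside
        if not use.any():
            continue
        w = 1.0 / np.maximum(d[use], eps)
        vals = sm.interpolate(centers[use])
        num[use] += w * vals
        den[use] += w
    with np.errstate(invalid="ignore"):
        comp = num / den
    comp[den == 0] = np.nan
    grid = comp.reshape(shape)
    obj = out.copy()
    obj.grid = grid
    return obj


def rna_flexibility(ens: EnsembleFrameSet, model: AtomicModel,
                    frame_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-residue RMSF and B = (8 pi^2 / 3) RMSF^2.

    Frames are aligned to the ensemble-average structure (two alignment
    passes) on all RNA heavy atoms; per-atom RMSF is averaged per residue
    without mass weighting.
    """
    frames = [fr["rna"] for f, fr in enumerate(ens.frames)
              if frame_mask is None or frame_mask[f]]
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    ref = frames[0]
    aligned = []
    for X in frames:
        R, t = superpose(ref, X)
        aligned.append(X @ R.T + t)
    mean = np.mean(aligned, axis=0)
    aligned2 = []
    for X in frames:
        R, t = superpose(mean, X)
        aligned2.append(X @ R.T + t)
    A = np.stack(aligned2)
    mean = A.mean(axis=0)
    rmsf_atom = np.sqrt(np.mean(np.sum((A - mean) ** 2, axis=2), axis=0))
    df = pd.DataFrame({"key": ens.rna_atom_keys, "rmsf": rmsf_atom})
    df["chain"] = df["key"].map(lambda k: k[0])
    df["res_seq"] = df["key"].map(lambda k: k[1])
    res = (df.groupby(["chain", "res_seq"], sort=False)["rmsf"]
           .mean().reset_index())
    res["B"] = (8.0 * np.pi ** 2 / 3.0) * res["rmsf"] ** 2
    return res
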
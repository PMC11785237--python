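"""Two-map consensus: cross-validate solvent placements between two
independently determined map/model pairs.

A pair of solvent atoms (one per model) is *consensus* when it passes two
criteria concurrently: superimposable (within 1 A of one another after
least-squares alignment of the local RNA) and same binding site (each
member's close-binder RNA atoms are all found within the expanded range of
the other member, and vice versa).  Non-consensus solvent can additionally
be transplanted into the map it was not modeled from and re-scored against
the map-based SWIM criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .densmap import DensityMap
from .model import AtomicModel, superpose
from .qscore import q_score
from .swim import SwimParams, _Geometry


@dataclass
class MatchCriteria:
    superimpose_max: float = 1.0
    context_radius: float = 10.0          # nucleotides with an atom this close
    water_close: tuple[float, float] = (2.5, 3.2)
    water_expand: float = 0.3             # applied once if close set empty
    water_cross: tuple[float, float] = (2.5, 3.5)
    ion_close: tuple[float, float] = (1.8, 2.2)
    ion_cross: tuple[float, float] = (1.8, 2.5)
    prefilter: float = 3.0                # candidate pairing radius


CATEGORIES = ("consensus", "same-binding-site-only", "superimposable-only",
              "partial-binder-overlap", "no-overlap")


@dataclass
class SolventRecord:
    species: str                 # "water" | "MG"
    coord: np.ndarray
    label: object = None


def solvent_records(model: AtomicModel) -> list[SolventRecord]:
    """Extract water/Mg records from a model's non-RNA residues."""
    out = []
    for a in model.atoms:
        if a.species in ("water", "MG"):
            out.append(SolventRecord("water" if a.species == "water" else "MG",
                                     np.asarray(a.coord), a.key))
    return out


def _close_binders(coord: np.ndarray, rna: AtomicModel, tree: cKDTree,
                   rng: tuple[float, float], expand: float
                   ) -> tuple[set, tuple[float, float]]:
    """Close RNA-atom set; range expanded once (by ``expand``) if empty."""
    idx = tree.query_ball_point(coord, rng[1] + expand)
    atoms = [rna.atoms[i] for i in idx]
    d = np.array([np.linalg.norm(np.asarray(a.coord) - coord) for a in atoms])
    used = rng
    inside = [a.key for a, dd in zip(atoms, d) if rng[0] <= dd <= rng[1]]
    if not inside:
        used = (rng[0], rng[1] + expand)
        inside = [a.key for a, dd in zip(atoms, d)
                  if used[0] <= dd <= used[1]]
    return set(inside), used


def _binders_within(coord: np.ndarray, rna: AtomicModel, tree: cKDTree,
                    rng: tuple[float, float]) -> set:
    idx = tree.query_ball_point(coord, rng[1])
    out = set()
    for i in idx:
        a = rna.atoms[i]
        if rng[0] <= np.linalg.norm(np.asarray(a.coord) - coord) <= rng[1]:
            out.add(a.key)
    return out


def _local_context_pairs(model_a: AtomicModel, model_b: AtomicModel,
                         pa: np.ndarray, pb: np.ndarray,
                         radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Paired heavy-atom coordinates of all nucleotides containing an atom
    within ``radius`` of either solvent, matched by (chain, res, name)."""
    rna_a, rna_b = model_a.rna, model_b.rna
    res_sel = set()
    for rna, p in ((rna_a, pa), (rna_a, pb), (rna_b, pa), (rna_b, pb)):
        for a in rna.atoms:
            if np.linalg.norm(np.asarray(a.coord) - p) <= radius:
                res_sel.add((a.chain, a.res_seq))
    amap = {a.key: a for a in rna_a.atoms if (a.chain, a.res_seq) in res_sel}
    bmap = {a.key: a for a in rna_b.atoms if (a.chain, a.res_seq) in res_sel}
    common = sorted(set(amap) & set(bmap))
    A = np.array([amap[k].coord for k in common]).reshape(-1, 3)
    B = np.array([bmap[k].coord for k in common]).reshape(-1, 3)
    return A, B


@dataclass
class MatchReport:
    pairs: pd.DataFrame              # one row per paired (a, b)
    categories_a: list[str]          # per solvent of model A
    categories_b: list[str]
    criteria: MatchCriteria

    def count(self, category: str, which: str = "a") -> int:
        cats = self.categories_a if which == "a" else self.categories_b
        return sum(c == category for c in cats)

    @property
    def consensus_count(self) -> int:
        return self.count("consensus")

    def summary(self) -> dict:
        return {c: self.count(c) for c in CATEGORIES}


def _species_ranges(species: str, crit: MatchCriteria):
    if species == "MG":
        return crit.ion_close, crit.ion_cross, 0.0
    return crit.water_close, crit.water_cross, crit.water_expand


def match_solvent(model_a: AtomicModel, model_b: AtomicModel,
                  criteria: MatchCriteria | None = None) -> MatchReport:
    """Pair and categorize solvent between two models.

    Candidate pairs within ``prefilter`` A are assigned greedily one-to-one
    by ascending post-alignment displacement; each solvent's category
    reflects its assigned pair (or ``no-overlap``).
    """
    crit = criteria or MatchCriteria()
    sa = solvent_records(model_a)
    sb = solvent_records(model_b)
    rna_a, rna_b = model_a.rna, model_b.rna
    if not (set(k for k in rna_a.residues()) & set(k for k in rna_b.residues())):
        raise ValueError("models share no RNA residue numbering")
    tree_a = cKDTree(rna_a.coords)
    tree_b = cKDTree(rna_b.coords)

    cand = []
    for i, a in enumerate(sa):
        for j, b in enumerate(sb):
            if np.linalg.norm(a.coord - b.coord) > crit.prefilter:
                continue
            A, B = _local_context_pairs(model_a, model_b, a.coord, b.coord,
                                        crit.context_radius)
            if len(A) < 3:
                continue
            R, t = superpose(A, B)
            disp = float(np.linalg.norm(a.coord - (R @ b.coord + t)))
            cand.append((disp, i, j, a, b))
    cand.sort(key=lambda x: (x[0], x[1], x[2]))

    used_a: dict[int, dict] = {}
    used_b: set[int] = set()
    rows = []
    for disp, i, j, a, b in cand:
        if i in used_a or j in used_b:
            continue
        close_a_rng, cross_a_rng, expand_a = _species_ranges(a.species, crit)
        close_b_rng, cross_b_rng, expand_b = _species_ranges(b.species, crit)
        binders_a, _ = _close_binders(a.coord, rna_a, tree_a,
                                      close_a_rng, expand_a)
        binders_b, _ = _close_binders(b.coord, rna_b, tree_b,
                                      close_b_rng, expand_b)
        cross_a = _binders_within(b.coord, rna_b, tree_b, cross_a_rng)
        cross_b = _binders_within(a.coord, rna_a, tree_a, cross_b_rng)
        same_site = (len(binders_a) > 0 and len(binders_b) > 0
                     and binders_a <= cross_a and binders_b <= cross_b)
        partial = len(binders_a & binders_b) > 0
        superimposable = disp <= crit.superimpose_max
        if superimposable and same_site:
            category = "consensus"
        elif same_site:
            category = "same-binding-site-only"
        elif superimposable:
            category = "superimposable-only"
        elif partial:
            category = "partial-binder-overlap"
        else:
            category = "no-overlap"
        used_a[i] = {"j": j, "category": category}
        used_b.add(j)
        rows.append({"i": i, "j": j, "species_a": a.species,
                     "species_b": b.species, "displacement": disp,
                     "superimposable": superimposable,
                     "same_site": same_site, "category": category})

    cats_a = [used_a[i]["category"] if i in used_a else "no-overlap"
              for i in range(len(sa))]
    by_j = {r["j"]: r["category"] for r in rows}
    cats_b = [by_j.get(j, "no-overlap") for j in range(len(sb))]
    return MatchReport(pd.DataFrame(rows), cats_a, cats_b, crit)


def transplant_assess(model_a: AtomicModel, model_b: AtomicModel,
                      full_b: DensityMap, half1_b: DensityMap,
                      half2_b: DensityMap,
                      params: SwimParams | None = None,
                      criteria: MatchCriteria | None = None) -> pd.DataFrame:
    """Place model A's solvent into map B and re-score the map criteria.

    Each solvent is carried into the B frame by least-squares alignment of
    the RNA nucleotides within 10 A, then density (>= 5 sigma), full-map Q
    and both half-map Q (> 0.7) are evaluated at the transplanted point.
    Returns one row per solvent with boolean outcomes; aggregate with
    ``df.mean(numeric_only=True)``.
    """
    params = params or SwimParams()
    crit = criteria or MatchCriteria()
    stats = full_b.stats()
    geo_b = _Geometry(model_b)
    rows = []
    for rec in solvent_records(model_a):
        A, B = _local_context_pairs(model_a, model_b, rec.coord, rec.coord,
                                    crit.context_radius)
        if len(A) < 3:
            continue
        R, t = superpose(B, A)          # A-frame context -> B-frame context
        p = R @ rec.coord + t
        if not full_b.contains(p[None])[0]:
            raise ValueError("transplanted point outside map B")
        dens = float(full_b.interpolate(p))
        qf = q_score(full_b, p, params=params.qscore, tree=geo_b.tree)
        q1 = q_score(half1_b, p, params=params.qscore, tree=geo_b.tree)
        q2 = q_score(half2_b, p, params=params.qscore, tree=geo_b.tree)
        rows.append({
            "species": rec.species, "label": rec.label,
            "density_pass": dens >= stats.level(params.density_min_sigma),
            "q_full_pass": qf > params.q_peak_min,
            "q_half_pass": (q1 > params.q_peak_min
                            and q2 > params.q_peak_min),
            "density_sigma": (dens - stats.avgD) / stats.sigma,
            "q_full": qf, "q_half1": q1, "q_half2": q2,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["density_and_qfull"] = df.density_pass & df.q_full_pass
        df["all_pass"] = df.density_and_qfull & df.q_half_pass
    return df


def binding_motif_table(model: AtomicModel,
                        water_range: tuple[float, float] = (2.5, 3.5),
                        ion_range: tuple[float, float] = (1.8, 2.5)
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Frequency of RNA binding motifs for modeled solvent.

    A solvent's motif is the multiset of RNA atom names within its
    species' distance range, with OP1 and OP2 merged into the single class
    ``OP``.  Returns (motif table, per-atom-type table), each with counts
    and frequencies per species.
    """
    rna = model.rna
    tree = cKDTree(rna.coords)
    motif_rows = []
    atom_rows = []
    for rec in solvent_records(model):
        rng = ion_range if rec.species == "MG" else water_range
        names = []
        for i in tree.query_ball_point(rec.coord, rng[1]):
            a = rna.atoms[i]
            d = np.linalg.norm(np.asarray(a.coord) - rec.coord)
            if rng[0] <= d <= rng[1]:
                names.append("OP" if a.name in ("OP1", "OP2") else a.name)
        if not names:
            continue
        motif = ",".join(sorted(names))
        motif_rows.append({"species": rec.species, "motif": motif})
        for n in names:
            atom_rows.append({"species": rec.species, "atom": n})

    def _tab(rows, key):
        if not rows:
            return pd.DataFrame(columns=["species", key, "count", "frequency"])
        df = (pd.DataFrame(rows).groupby(["species", key])
              .size().reset_index(name="count"))
        df["frequency"] = df["count"] / df.groupby("species")["count"] \
                                          .transform("sum")
        return df.sort_values(["species", "count"],
                              ascending=[True, False]).reset_index(drop=True)

    return _tab(motif_rows, "motif"), _tab(atom_rows, "atom")
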
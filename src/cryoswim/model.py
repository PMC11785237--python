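"""Atomic models of RNA plus solvent: typed atoms, chemistry lookups, file I/O.

Coordinates are Angstroms in the model frame.  Hydrogens are dropped on
input; every analysis in this package considers heavy atoms only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

RNA_RESIDUES = {"A", "C", "G", "U", "RA", "RC", "RG", "RU"}
WATER_RESIDUES = {"HOH", "WAT", "H2O"}
ION_RESIDUES = {"MG": "MG", "NA": "NA"}

# Nitrogens carrying at least one hydrogen in the neutral-pH tautomer of
# each nucleobase.  A protonated nitrogen repels cations; a bare ring
# nitrogen is an acceptor and counts as electronegative.
PROTONATED_NITROGENS = {
    ("A", "N6"),
    ("G", "N1"),
    ("G", "N2"),
    ("C", "N4"),
    ("U", "N3"),
}
NONPROTONATED_NITROGENS = {
    ("A", "N1"), ("A", "N3"), ("A", "N7"),
    ("G", "N3"), ("G", "N7"),
    ("C", "N3"),
    ("A", "N9"), ("G", "N9"), ("C", "N1"), ("U", "N1"),
}

BASE_ATOMS = {
    "N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
    "O2", "O4", "O6", "N2", "N4", "N6",
}
SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'"}
PHOSPHATE_OXYGENS = {"OP1", "OP2", "OP3", "O5'", "O3'"}


def base_type(residue_name: str) -> str:
    """Single-letter nucleotide type for 1- or 2-letter RNA residue names."""
    return residue_name[-1] if residue_name in RNA_RESIDUES else residue_name


def atom_part(name: str) -> str | None:
    """Classify a heavy-atom name into nucleotide parts.

    Returns one of ``base``, ``sugar``, ``phosphate_oxygens``,
    ``phosphorus`` or None for unknown names.
    """
    if name in BASE_ATOMS:
        return "base"
    if name in SUGAR_ATOMS:
        return "sugar"
    if name in PHOSPHATE_OXYGENS:
        return "phosphate_oxygens"
    if name == "P":
        return "phosphorus"
    return None


@dataclass(frozen=True)
class Atom:
    """A heavy atom with the chemistry flags the placement rules consume."""

    element: str
    name: str
    coord: tuple[float, float, float]
    chain: str
    res_seq: int
    res_name: str
    altloc: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_seq, self.name)

    @property
    def is_polar(self) -> bool:
        return self.element in ("N", "O")

    @property
    def is_nonpolar(self) -> bool:
        """Carbon or phosphorus: the atoms a water may not approach."""
        return self.element in ("C", "P")

    @property
    def is_protonated_nitrogen(self) -> bool:
        if self.element != "N":
            return False
        return (base_type(self.res_name), self.name) in PROTONATED_NITROGENS

    @property
    def is_electronegative(self) -> bool:
        """Oxygen, or a nitrogen with no proton to donate."""
        if self.element == "O":
            return True
        return self.element == "N" and not self.is_protonated_nitrogen

    @property
    def is_rna(self) -> bool:
        return self.res_name in RNA_RESIDUES

    @property
    def species(self) -> str:
        """'rna', 'water', 'MG', 'NA' or the raw residue name."""
        if self.res_name in RNA_RESIDUES:
            return "rna"
        if self.res_name in WATER_RESIDUES:
            return "water"
        return ION_RESIDUES.get(self.res_name, self.res_name)


class AtomicModel:
    """A list of heavy atoms with per-residue indexing.

    Invariant: no two atoms share (chain, res_seq, name, altloc).  Only the
    first altloc of an atom is kept (a warning is logged for the rest).
    """

    def __init__(self, atoms: list[Atom]):
        seen: dict[tuple, Atom] = {}
        for a in atoms:
            k = (a.chain, a.res_seq, a.name)
            if k in seen:
                if seen[k].altloc != a.altloc:
                    logger.warning("dropping altloc %r of atom %s", a.altloc, k)
                    continue
                raise ValueError(f"duplicate atom {k} altloc {a.altloc!r}")
            seen[k] = a
        self.atoms: list[Atom] = list(seen.values())

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    def select(self, pred) -> "AtomicModel":
        return AtomicModel([a for a in self.atoms if pred(a)])

    @property
    def rna(self) -> "AtomicModel":
        return self.select(lambda a: a.is_rna)

    @property
    def solvent(self) -> "AtomicModel":
        return self.select(lambda a: a.species in ("water", "MG", "NA"))

    def residues(self) -> dict[tuple[str, int], list[Atom]]:
        """Atoms grouped by (chain, res_seq), in file order."""
        out: dict[tuple[str, int], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault((a.chain, a.res_seq), []).append(a)
        return out

    def residue_names(self) -> dict[tuple[str, int], str]:
        return {(a.chain, a.res_seq): a.res_name for a in self.atoms}

    def atom_by_key(self, key: tuple[str, int, str]) -> Atom:
        for a in self.atoms:
            if a.key == key:
                return a
        raise KeyError(key)

    def add_atoms(self, atoms: list[Atom]) -> "AtomicModel":
        return AtomicModel(self.atoms + list(atoms))


def read_model(path: str) -> AtomicModel:
    """Read a PDB or mmCIF file, keeping heavy atoms only."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms: list[Atom] = []
    for mdl in st:
        for chain in mdl:
            for res in chain:
                for at in res:
                    if at.element.name == "H" or at.element.name == "D":
                        continue
                    atoms.append(Atom(
                        element=at.element.name.upper(),
                        name=at.name,
                        coord=(at.pos.x, at.pos.y, at.pos.z),
                        chain=chain.name,
                        res_seq=res.seqid.num,
                        res_name=res.name.strip(),
                        altloc=at.altloc if at.altloc != "\x00" else "",
                    ))
        break  # first model only
    return AtomicModel(atoms)


def to_gemmi(model: AtomicModel, name: str = "model") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    md = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for (chain_id, seq), atoms in model.residues().items():
        if chain_id not in chains:
            chains[chain_id] = gemmi.Chain(chain_id)
        res = gemmi.Residue()
        res.name = atoms[0].res_name
        res.seqid = gemmi.SeqId(seq, " ")
        for a in atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coord)
            ga.occ = 1.0
            res.add_atom(ga)
        chains[chain_id].add_residue(res)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    return st


def write_model(model: AtomicModel, path: str,
                b_factors: dict[tuple[str, int, str], float] | None = None) -> None:
    """Write PDB or mmCIF by extension; optional per-atom B column."""
    st = to_gemmi(model)
    if b_factors:
        for md in st:
            for chain in md:
                for res in chain:
                    for at in res:
                        key = (chain.name, res.seqid.num, at.name)
                        if key in b_factors:
                            at.b_iso = float(b_factors[key])
    path = str(path)
    if path.endswith(".cif") or path.endswith(".mmcif"):
        st.make_mmcif_document().write_file(path)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st.write_pdb(path)


def superpose(fixed: np.ndarray, moving: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of paired points (Kabsch).

    Returns (R, t) such that moving @ R.T + t approximates fixed.
    """
    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    cf = fixed.mean(axis=0)
    cm = moving.mean(axis=0)
    H = (moving - cm).T @ (fixed - cf)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    return R, t
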
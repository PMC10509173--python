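"""Structure-derived validation metrics.

Reads PDB/mmCIF models (via gemmi), computes Calpha-superposition RMSD
between two depositions, enumerates protein-ligand contacts with the
conventional distance cutoffs (polar <= 3.5 A, hydrophobic <= 4.0 A), and
measures ligand displacement between superposed complexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import gemmi
import numpy as np

POLAR_ELEMENTS = {"N", "O", "S"}
HALOGENS = {"F", "CL", "BR", "I"}

# residue names treated as non-ligand heteroatoms
_SKIP_LIGANDS = {"HOH", "WAT", "NA", "K", "MG", "CL", "ZN", "CA", "MN", "RB"}


class StructureError(ValueError):
    pass


def read_structure(path: str) -> gemmi.Structure:
    """Read a PDB or mmCIF file into a gemmi Structure.

    Only the highest-occupancy alternative location of each atom is kept;
    hydrogens and waters are retained as written.
    """
    try:
        st = gemmi.read_structure(str(path))
    except Exception as e:
        raise StructureError(f"cannot read structure {path}: {e}") from e
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise StructureError(f"structure {path} contains no residues")
    st.setup_entities()
    st.remove_alternative_conformations()
    return st


def _ca_positions(st: gemmi.Structure) -> Dict[Tuple[str, int], np.ndarray]:
    out: Dict[Tuple[str, int], np.ndarray] = {}
    for chain in st[0]:
        for res in chain:
            ca = res.find_atom("CA", "*")
            if ca is not None and res.name != "CA":
                out[(chain.name, res.seqid.num)] = np.array(
                    [ca.pos.x, ca.pos.y, ca.pos.z])
    return out


def superpose(coords_a: np.ndarray, coords_b: np.ndarray
              ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Kabsch superposition of ``coords_b`` onto ``coords_a``.

    Returns (R, t, rmsd) with det(R) = +1 so that ``b @ R.T + t ~ a``.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    H = (b - cb_).T @ (a - ca_)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ca_ - R @ cb_
    diff = b @ R.T + t - a
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def ca_rmsd(a: gemmi.Structure, b: gemmi.Structure,
            chains: Optional[List[str]] = None) -> float:
    """RMSD over all shared Calpha atoms after least-squares superposition.

    Atoms are paired by (chain id, residue number) intersection — no
    sequence alignment, which suits depositions sharing numbering.
    """
    pa, pb = _ca_positions(a), _ca_positions(b)
    keys = sorted(set(pa) & set(pb))
    if chains is not None:
        keys = [k for k in keys if k[0] in chains]
    if len(keys) < 3:
        raise StructureError("fewer than 3 common Calpha atoms")
    A = np.array([pa[k] for k in keys])
    B = np.array([pb[k] for k in keys])
    return superpose(A, B)[2]


@dataclass
class Contact:
    ligand_atom: str
    protein_atom: str
    residue: str  # e.g. "A/GLU 795"
    distance: float
    kind: str  # "polar" | "hydrophobic"


@dataclass
class ContactSet:
    contacts: List[Contact]

    def of_kind(self, kind: str) -> List[Contact]:
        return [c for c in self.contacts if c.kind == kind]

    def min_distance(self, residue_name: str, ligand_atom: Optional[str] = None
                     ) -> float:
        ds = [c.distance for c in self.contacts
              if residue_name in c.residue
              and (ligand_atom is None or c.ligand_atom == ligand_atom)]
        if not ds:
            raise StructureError(f"no contacts to residue {residue_name!r}")
        return min(ds)


def _iter_atoms(st: gemmi.Structure, ligand_name: str, want_ligand: bool):
    for chain in st[0]:
        for res in chain:
            is_lig = res.name == ligand_name
            if is_lig != want_ligand:
                continue
            if want_ligand is False and (res.name in _SKIP_LIGANDS
                                         or res.name == ligand_name):
                continue
            for atom in res:
                el = atom.element.name.upper()
                if el == "H" or el == "D":
                    continue
                yield chain.name, res, atom, el


def list_ligands(st: gemmi.Structure) -> List[str]:
    names = set()
    polymer_names = set()
    for chain in st[0]:
        poly = chain.get_polymer()
        polymer_names.update(r.name for r in poly)
    for chain in st[0]:
        for res in chain:
            if res.name not in polymer_names and res.name not in _SKIP_LIGANDS:
                names.add(res.name)
    return sorted(names)


def ligand_contacts(st: gemmi.Structure, ligand_name: str,
                    polar_cutoff: float = 3.5,
                    hydrophobic_cutoff: float = 4.0) -> ContactSet:
    """All ligand-protein atom pairs within the class-appropriate cutoff.

    Polar: both atoms N/O/S (<= ``polar_cutoff``); ligand halogens paired
    with protein N/O within the polar cutoff are also reported as polar
    (potential halogen bonds).  Hydrophobic: both atoms carbon
    (<= ``hydrophobic_cutoff``).  Each atom pair is classified once.
    """
    lig_atoms = [(ch, res, at, el) for ch, res, at, el
                 in _iter_atoms(st, ligand_name, True)]
    if not lig_atoms:
        raise StructureError(
            f"ligand {ligand_name!r} not found; available: {list_ligands(st)}")
    prot_atoms = [(ch, res, at, el) for ch, res, at, el
                  in _iter_atoms(st, ligand_name, False)]
    contacts: List[Contact] = []
    ppos = np.array([[a.pos.x, a.pos.y, a.pos.z] for _, _, a, _ in prot_atoms])
    for lch, lres, lat, lel in lig_atoms:
        lp = np.array([lat.pos.x, lat.pos.y, lat.pos.z])
        d = np.sqrt(((ppos - lp) ** 2).sum(axis=1))
        near = np.nonzero(d <= max(polar_cutoff, hydrophobic_cutoff))[0]
        for j in near:
            pch, pres, pat, pel = prot_atoms[j]
            dist = float(d[j])
            if dist <= 0:
                continue
            kind = None
            polar_pair = (lel in POLAR_ELEMENTS or lel in HALOGENS) and \
                         (pel in POLAR_ELEMENTS)
            if polar_pair and dist <= polar_cutoff:
                kind = "polar"
            elif lel == "C" and pel == "C" and dist <= hydrophobic_cutoff:
                kind = "hydrophobic"
            if kind:
                contacts.append(Contact(
                    lat.name, pat.name,
                    f"{pch}/{pres.name} {pres.seqid.num}", dist, kind))
    return ContactSet(sorted(contacts, key=lambda c: (c.residue, c.distance)))


def ligand_displacement(a: gemmi.Structure, b: gemmi.Structure,
                        ligand_a: str, ligand_b: Optional[str] = None) -> float:
    """Ligand centroid displacement after protein Calpha superposition.

    Structure ``b`` is superposed onto ``a`` using all shared Calpha
    atoms; the displacement is the distance between the centroids of the
    two ligands' shared heavy-atom framework (atoms paired by name; all
    heavy atoms if the name sets are disjoint).
    """
    ligand_b = ligand_b or ligand_a

    def lig_coords(st, name):
        out = {}
        for _, res, at, el in _iter_atoms(st, name, True):
            out.setdefault(at.name, np.array([at.pos.x, at.pos.y, at.pos.z]))
        if not out:
            raise StructureError(
                f"ligand {name!r} not found; available: {list_ligands(st)}")
        return out

    la, lb = lig_coords(a, ligand_a), lig_coords(b, ligand_b)
    pa, pb = _ca_positions(a), _ca_positions(b)
    keys = sorted(set(pa) & set(pb))
    if len(keys) < 3:
        raise StructureError("fewer than 3 common Calpha atoms")
    A = np.array([pa[k] for k in keys])
    B = np.array([pb[k] for k in keys])
    R, t, _ = superpose(A, B)

    common = sorted(set(la) & set(lb))
    if common:
        ca_ = np.array([la[n] for n in common]).mean(axis=0)
        cb_ = np.array([lb[n] for n in common]).mean(axis=0)
    else:
        ca_ = np.array(list(la.values())).mean(axis=0)
        cb_ = np.array(list(lb.values())).mean(axis=0)
    cb_moved = R @ cb_ + t
    return float(np.linalg.norm(cb_moved - ca_))
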
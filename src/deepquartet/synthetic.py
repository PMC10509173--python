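"""Deterministic synthetic data generators.

Desk-scale stand-ins for the assets the real workflow consumes: a
grammar-generated SMILES corpus of benzyl-ether / benzylamine chemotypes
(in place of ChEMBL), toy pharmacophore models whose features coincide
with a real conformer's perceived features, simulated inhibition plates
with known IC50 / (Vmax, Km, Ki) truth, and small helical protein-ligand
PDB pairs with programmed RMSD, contacts and ligand displacement.

Every generator is reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import canonical_smiles, try_parse_smiles
from .kinetics import PLATE_COLUMNS, competitive_rate, _logistic
from .pharmacophore import (FeatureRules, LigandFeatureSet, PharmacophoreFeature,
                            PharmacophoreModel, etkdg_conformers,
                            perceive_features)

# ---------------------------------------------------------------------------
# SMILES corpus
# ---------------------------------------------------------------------------

_HEAD_METHYLAMINO = "CNC"
_HEADS_OTHER = ["NC", "OC", "CC", "CN(C)C", "C", "OCC"]
_LINKERS = ["OC", "C#C", "CO", "CC", "OCC"]
_RING_TERMINAL = ["c{r}ccccc{r}", "c{r}ccc(Cl)cc{r}", "c{r}ccncc{r}",
                  "C{r}CCCCC{r}", "c{r}ccc(F)cc{r}", "c{r}ccc(C)cc{r}"]
_RING_ATTACH = ["c{r}ccc({s})cc{r}", "c{r}cc(Cl)cc({s})c{r}",
                "c{r}ccc({s})nc{r}", "c{r}cc(C)cc({s})c{r}"]


@dataclass
class CorpusSpec:
    """Grammar parameters for the synthetic training corpus."""

    n: int = 5000
    seed: int = 0
    methylamino_fraction: float = 0.3
    depth_weights: Tuple[float, ...] = (0.35, 0.5, 0.15)  # 1, 2, 3 rings


def make_smiles_corpus(spec: Optional[CorpusSpec] = None) -> List[str]:
    """``n`` unique, valid, canonical SMILES from the block grammar.

    A fraction ``methylamino_fraction`` of molecules carries a terminal
    secondary methylamine head by construction; the remaining heads can
    never produce that group.
    """
    spec = spec or CorpusSpec()
    rng = np.random.default_rng(spec.seed)
    out: List[str] = []
    seen = set()
    weights = np.asarray(spec.depth_weights) / sum(spec.depth_weights)

    def chain(depth: int, r: int) -> str:
        if depth == 1:
            t = _RING_TERMINAL[rng.integers(len(_RING_TERMINAL))]
            return t.format(r=r)
        t = _RING_ATTACH[rng.integers(len(_RING_ATTACH))]
        linker = _LINKERS[rng.integers(len(_LINKERS))]
        return t.format(r=r, s=linker + chain(depth - 1, r + 1))

    target_m = int(round(spec.n * spec.methylamino_fraction))
    n_m = 0
    guard = 0
    while len(out) < spec.n:
        guard += 1
        if guard > spec.n * 500:
            raise RuntimeError("corpus grammar failed to produce enough molecules")
        # quota-based head choice keeps the methylamino fraction exact
        # even after canonical deduplication
        want_m = n_m < target_m and (
            rng.random() < spec.methylamino_fraction
            or (spec.n - len(out)) <= (target_m - n_m))
        if want_m:
            head = _HEAD_METHYLAMINO
        else:
            head = _HEADS_OTHER[rng.integers(len(_HEADS_OTHER))]
        depth = int(rng.choice([1, 2, 3], p=weights))
        smi = head + chain(depth, 1)
        mol = try_parse_smiles(smi)
        if mol is None:
            continue
        can = canonical_smiles(mol)
        if can in seen:
            continue
        seen.add(can)
        out.append(can)
        if want_m:
            n_m += 1
    return out


# ---------------------------------------------------------------------------
# Toy pharmacophore
# ---------------------------------------------------------------------------

@dataclass
class ToyPharmacophore:
    model: PharmacophoreModel
    matching: Chem.Mol          # conformer whose features define the model
    decoy: Chem.Mol             # conformer that cannot satisfy the model
    matching_features: LigandFeatureSet


def make_toy_pharmacophore(seed: int = 0,
                           smiles: str = "CNCc1ccc(OCc2ccccc2OCc2ccccc2)cc1",
                           tolerance_polar: float = 1.5,
                           tolerance_hydrophobic: float = 2.0
                           ) -> ToyPharmacophore:
    """Four-feature model (cationic, 2x aromatic, hydrophobic) placed
    exactly on a real conformer's perceived features, so the matching
    conformer self-fits with score 1.0.  The decoy (benzene) can satisfy
    at most one feature.
    """
    mol = try_parse_smiles(smiles)
    confs = etkdg_conformers(mol, k=1, seed=seed)
    if not confs:
        raise RuntimeError(f"could not embed {smiles}")
    matching = confs[0]
    feats = perceive_features(matching, FeatureRules())
    cat = [f for f in feats.features if f.kind == "cationic"]
    aro = [f for f in feats.features if f.kind == "aromatic"]
    hyd = [f for f in feats.features if f.kind == "hydrophobic"
           and len(f.atom_indices) >= 6]
    if not cat or len(aro) < 2 or not hyd:
        raise RuntimeError("template conformer lacks expected features")
    model = PharmacophoreModel("toy", [
        PharmacophoreFeature("cationic", cat[0].centroid, tolerance_polar,
                             required=True),
        PharmacophoreFeature("aromatic", aro[0].centroid, tolerance_polar),
        PharmacophoreFeature("aromatic", aro[1].centroid, tolerance_polar),
        PharmacophoreFeature("hydrophobic", hyd[-1].centroid,
                             tolerance_hydrophobic),
    ])
    decoy = etkdg_conformers(try_parse_smiles("c1ccccc1"), k=1, seed=seed)[0]
    return ToyPharmacophore(model, matching, decoy, feats)


# ---------------------------------------------------------------------------
# Simulated plates
# ---------------------------------------------------------------------------

@dataclass
class Ic50PlateSpec:
    """Dose-response plate emulating the published assay design:
    12 inhibitor concentrations, triplicate wells, saturating-blocker
    background, multiplicative Gaussian noise."""

    compound: str = "DQ-06"
    ic50: float = 0.70e-6          # M
    hill: float = 1.0
    top: float = 30.0              # umol Pi / mg / h
    bottom: float = 0.0
    baseline: float = 2.0          # non-specific activity, removed by background
    n_conc: int = 12
    n_replicates: int = 3
    span_decades: float = 2.5      # concentrations span ic50 * 10^(+-span)
    k_conc: float = 10e-3          # assay [K+], M
    noise: float = 0.05
    seed: int = 0


def simulate_ic50_plate(spec: Optional[Ic50PlateSpec] = None) -> pd.DataFrame:
    """Simulate one dose-response plate (plus background wells)."""
    spec = spec or Ic50PlateSpec()
    rng = np.random.default_rng(spec.seed)
    concs = np.geomspace(spec.ic50 / 10 ** spec.span_decades,
                         spec.ic50 * 10 ** spec.span_decades, spec.n_conc)
    rows = []

    def noisy(v: float) -> float:
        return float(v * (1.0 + spec.noise * rng.standard_normal())
                     if spec.noise > 0 else v)

    for rep in range(spec.n_replicates):
        for c in concs:
            v = _logistic(np.array([c]), spec.ic50, spec.hill, spec.top,
                          spec.bottom)[0]
            rows.append([spec.compound, float(c), spec.k_conc, rep,
                         noisy(v + spec.baseline), False])
        # saturating-blocker background well: specific activity fully blocked
        rows.append([spec.compound, 0.5e-3, spec.k_conc, rep,
                     noisy(spec.baseline), True])
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


@dataclass
class KiPlateSpec:
    """K+-competition design: four K+-dependent activation series in the
    absence or presence of three inhibitor concentrations, triplicate,
    with K+-free background wells at each inhibitor level."""

    compound: str = "DQ-18"
    vmax: float = 30.0
    km: float = 0.6e-3             # M
    ki: float = 47.6e-9            # M
    k_concs: Tuple[float, ...] = (0.3e-3, 1e-3, 3e-3, 10e-3)
    inhibitor_multiples: Tuple[float, ...] = (0.0, 2.0, 5.0, 10.0)
    baseline: float = 2.0
    n_replicates: int = 3
    noise: float = 0.05
    seed: int = 0


def simulate_ki_plate(spec: Optional[KiPlateSpec] = None) -> pd.DataFrame:
    """Simulate a K+-competition dataset (plus K+-free backgrounds)."""
    spec = spec or KiPlateSpec()
    rng = np.random.default_rng(spec.seed)
    i_concs = [m * spec.ki for m in spec.inhibitor_multiples]
    rows = []

    def noisy(v: float) -> float:
        return float(v * (1.0 + spec.noise * rng.standard_normal())
                     if spec.noise > 0 else v)

    for rep in range(spec.n_replicates):
        for ic in i_concs:
            for kc in spec.k_concs:
                v = competitive_rate(np.array([kc]), np.array([ic]),
                                     spec.vmax, spec.km, spec.ki)[0]
                rows.append([spec.compound, float(ic), float(kc), rep,
                             noisy(v + spec.baseline), False])
            rows.append([spec.compound, float(ic), 0.0, rep,
                         noisy(spec.baseline), True])
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

@dataclass
class ToyStructureSpec:
    n_res: int = 100
    glu_index: int = 50            # 1-based residue number carrying OE1
    contact_distance: float = 3.0  # ligand N1 ... GLU OE1, Angstrom
    hydrophobic_distance: float = 3.8
    rotation_deg: float = 25.0
    translation: Tuple[float, float, float] = (4.0, -2.0, 7.0)
    jitter: float = 0.0            # per-coordinate Gaussian sigma on copy B
    ligand_shift: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0


def _helix_ca(n_res: int) -> np.ndarray:
    """Idealized alpha-helix Calpha trace (2.3 A radius, 1.5 A rise,
    100 degrees per residue)."""
    i = np.arange(n_res)
    theta = np.deg2rad(100.0 * i)
    return np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i], axis=1)


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resseq: int, xyz: np.ndarray, element: str,
                   het: bool = False) -> str:
    rec = "HETATM" if het else "ATOM  "
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (f"{rec}{serial:5d} {nm}{'':1s}{resname:<3s} {chain}{resseq:4d}"
            f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}")


def _structure_text(ca: np.ndarray,
                    glu_atoms: List[Tuple[str, np.ndarray, str]],
                    ligand: List[Tuple[str, np.ndarray, str]],
                    glu_index: int) -> str:
    lines = []
    serial = 1
    for i, pos in enumerate(ca, start=1):
        resname = "GLU" if i == glu_index else "ALA"
        lines.append(_pdb_atom_line(serial, "CA", resname, "A", i, pos, "C"))
        serial += 1
        if i == glu_index:
            for name, apos, element in glu_atoms:
                lines.append(_pdb_atom_line(serial, name, "GLU", "A", i,
                                            apos, element))
                serial += 1
    for name, pos, element in ligand:
        lines.append(_pdb_atom_line(serial, name, "LIG", "L", 900, pos,
                                    element, het=True))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _rotation_matrix(deg: float, axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    a = np.asarray(axis, float)
    a /= np.linalg.norm(a)
    t = np.deg2rad(deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def make_toy_structures(spec: Optional[ToyStructureSpec] = None
                        ) -> Tuple[str, str]:
    """PDB text of a helical peptide + ligand, and a transformed copy.

    Structure A places a GLU residue whose side-chain oxygen (OE1) sits at
    exactly ``contact_distance`` from the ligand nitrogen N1, and a ligand
    carbon C1 at ``hydrophobic_distance`` from a Calpha.  Structure B is A
    after a programmed rigid motion, optional per-coordinate Gaussian
    jitter and an optional extra ligand shift (for displacement tests).
    """
    spec = spec or ToyStructureSpec()
    rng = np.random.default_rng(spec.seed)
    ca = _helix_ca(spec.n_res)
    g = spec.glu_index - 1
    # side-chain oxygen of the GLU, pointing away from the helix axis
    out_dir = ca[g].copy()
    out_dir[2] = 0.0
    out_dir /= np.linalg.norm(out_dir)
    oe1 = ca[g] + out_dir * 3.0
    n1 = oe1 + out_dir * spec.contact_distance
    c_anchor = ca[min(g + 4, spec.n_res - 1)]
    dir2 = c_anchor.copy()
    dir2[2] = 0.0
    dir2 /= np.linalg.norm(dir2)
    c1 = c_anchor + dir2 * spec.hydrophobic_distance
    c2 = n1 + np.array([0.0, 0.0, 1.5])

    glu_atoms = [("CB", ca[g] + np.array([1.2, 0.8, 0.2]), "C"),
                 ("OE1", oe1, "O")]
    ligand = [("N1", n1, "N"), ("C1", c1, "C"), ("C2", c2, "C")]
    text_a = _structure_text(ca, glu_atoms, ligand, spec.glu_index)

    R = _rotation_matrix(spec.rotation_deg)
    t = np.asarray(spec.translation)
    shift = np.asarray(spec.ligand_shift)

    def move(p: np.ndarray, is_ligand: bool = False) -> np.ndarray:
        q = R @ p + t
        if spec.jitter > 0:
            q = q + rng.normal(0.0, spec.jitter, size=3)
        if is_ligand:
            q = q + R @ shift
        return q

    ca_b = np.array([move(p) for p in ca])
    glu_b = [(n, move(p), el) for (n, p, el) in glu_atoms]
    lig_b = [(n, move(p, True), el) for (n, p, el) in ligand]
    text_b = _structure_text(ca_b, glu_b, lig_b, spec.glu_index)
    return text_a, text_b
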
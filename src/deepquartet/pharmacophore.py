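"""3D pharmacophore models and the relative fit score used as RL reward.

A pharmacophore model is a small set (here 4-6) of typed 3D features —
aromatic, hydrophobic, cationic, hydrogen-bond donor — each with a
position and a tolerance radius, derived from drug-bound pump structures.
A ligand conformer is scored by perceiving its own features, enumerating
injective kind-compatible assignments of model features to ligand
features, rigidly aligning matched centers (Kabsch), and keeping the best

    score = w * (n_matched / n_model) + (1 - w) * max(0, 1 - rmsd / rmsd_ref)

over assignments in which every matched pair lies within its model
feature's tolerance after alignment.  With ``w = 0.5`` and ``rmsd_ref``
the mean model tolerance, a conformer that exactly reproduces the model
scores 1.0.  Assignments matching fewer than 3 pairs cannot determine a
rotation and score at most the match fraction term.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

FEATURE_KINDS = ("aromatic", "hydrophobic", "cationic", "hbond_donor")

# protonated at pH 7: aliphatic primary/secondary/tertiary amines (not
# amide, aniline, imine or N-heteroatom), explicit ammonium, amidine and
# guanidine nitrogens
_CATIONIC_SMARTS = [
    "[NX3;H2,H1,H0;!$(NC=[O,S,N]);!$(Nc);!$(N=*);!$([N][!#6;!#1]);!$([N]#*)]",
    "[NX4+]",
    "[NX3][CX3]=[NX2]",
]
_DONOR_SMARTS = "[$([#7,#8;!H0])]"


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    position: tuple  # (x, y, z) in Angstrom
    tolerance: float
    required: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class PharmacophoreModel:
    """A named set of >= 2 features, optionally tied to a template structure."""

    model_id: str
    features: List[PharmacophoreFeature]
    template: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.features) < 2:
            raise ValueError("a pharmacophore model needs >= 2 features")

    @property
    def rmsd_ref(self) -> float:
        return float(np.mean([f.tolerance for f in self.features]))

    def to_json(self) -> str:
        return json.dumps({
            "model_id": self.model_id, "template": self.template,
            "features": [{"kind": f.kind, "position": list(f.position),
                          "tolerance": f.tolerance, "required": f.required}
                         for f in self.features]}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PharmacophoreModel":
        d = json.loads(text)
        feats = [PharmacophoreFeature(f["kind"], tuple(f["position"]),
                                      f["tolerance"], f.get("required", False))
                 for f in d["features"]]
        return cls(d["model_id"], feats, d.get("template"))


@dataclass(frozen=True)
class LigandFeature:
    kind: str
    centroid: tuple
    atom_indices: tuple

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.centroid, dtype=float)


@dataclass
class LigandFeatureSet:
    features: List[LigandFeature]

    def of_kind(self, kind: str) -> List[int]:
        return [i for i, f in enumerate(self.features) if f.kind == kind]


@dataclass
class FeatureRules:
    """Perception knobs: minimum hydrophobic group size and whether
    aromatic rings also count as hydrophobic patches."""

    min_hydrophobic_group: int = 2
    aromatic_is_hydrophobic: bool = True


def perceive_features(mol: Chem.Mol, rules: Optional[FeatureRules] = None,
                      conf_id: int = -1) -> LigandFeatureSet:
    """Perceive typed features from a conformer's 3D coordinates.

    Aromatic: one feature per aromatic ring at the ring-atom centroid.
    Cationic: nitrogens predicted protonated at pH 7.  Donor: N/O carrying
    at least one hydrogen.  Hydrophobic: centroids of contiguous aliphatic
    carbon/halogen groups not adjacent to charged atoms (and, by default,
    aromatic ring centroids as well).
    """
    rules = rules or FeatureRules()
    if mol.GetNumConformers() == 0:
        raise ValueError("molecule has no conformer coordinates")
    conf = mol.GetConformer(conf_id)
    pos = conf.GetPositions()
    feats: List[LigandFeature] = []

    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            c = tuple(pos[list(ring)].mean(axis=0))
            feats.append(LigandFeature("aromatic", c, tuple(ring)))
            if rules.aromatic_is_hydrophobic:
                feats.append(LigandFeature("hydrophobic", c, tuple(ring)))

    cationic_idx = set()
    for sm in _CATIONIC_SMARTS:
        patt = Chem.MolFromSmarts(sm)
        for match in mol.GetSubstructMatches(patt):
            a = mol.GetAtomWithIdx(match[0])
            if a.GetSymbol() == "N":
                cationic_idx.add(match[0])
    for i in sorted(cationic_idx):
        feats.append(LigandFeature("cationic", tuple(pos[i]), (i,)))

    donor = Chem.MolFromSmarts(_DONOR_SMARTS)
    for (i,) in mol.GetSubstructMatches(donor):
        feats.append(LigandFeature("hbond_donor", tuple(pos[i]), (i,)))

    charged = {a.GetIdx() for a in mol.GetAtoms() if a.GetFormalCharge() != 0}
    charged |= cationic_idx
    eligible = set()
    for a in mol.GetAtoms():
        if a.GetIsAromatic():
            continue
        sym = a.GetSymbol()
        if sym == "C" or sym in ("F", "Cl", "Br", "I"):
            if any(n.GetIdx() in charged for n in a.GetNeighbors()):
                continue
            if a.GetIdx() in charged:
                continue
            eligible.add(a.GetIdx())
    # connected components of eligible atoms
    seen: set = set()
    for start in sorted(eligible):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        stack = [start]
        while stack:
            cur = stack.pop()
            for n in mol.GetAtomWithIdx(cur).GetNeighbors():
                j = n.GetIdx()
                if j in eligible and j not in seen:
                    seen.add(j)
                    comp.append(j)
                    stack.append(j)
        if len(comp) >= rules.min_hydrophobic_group:
            comp = sorted(comp)
            feats.append(LigandFeature("hydrophobic",
                                       tuple(pos[comp].mean(axis=0)), tuple(comp)))
    return LigandFeatureSet(feats)


# ---------------------------------------------------------------------------
# Rigid alignment (Kabsch)
# ---------------------------------------------------------------------------

def align_features(pairs: Sequence[Tuple[np.ndarray, np.ndarray]]
                   ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ligand points onto model points.

    ``pairs`` is a list of (model point, ligand point).  Returns
    ``(R, t, rmsd)`` with a proper rotation (det +1) such that
    ``R @ ligand + t`` approximates the model points; 1 pair degenerates
    to a pure translation.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one pair")
    M = np.asarray([np.asarray(m, float) for m, _ in pairs])
    L = np.asarray([np.asarray(l, float) for _, l in pairs])
    cm, cl = M.mean(axis=0), L.mean(axis=0)
    if len(pairs) == 1:
        return np.eye(3), cm - cl, 0.0
    H = (L - cl).T @ (M - cm)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cm - R @ cl
    diff = (L @ R.T + t) - M
    rmsd = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
    return R, t, rmsd


@dataclass
class FitResult:
    assignment: List[Tuple[int, int]]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_matched: int
    n_model: int
    score: float

    @classmethod
    def no_fit(cls, n_model: int) -> "FitResult":
        return cls([], np.eye(3), np.zeros(3), math.inf, 0, n_model, 0.0)


def _compatible(model_feat: PharmacophoreFeature, lig_feat: LigandFeature) -> bool:
    return model_feat.kind == lig_feat.kind


def relative_fit_score(ligand: LigandFeatureSet, model: PharmacophoreModel,
                       w: float = 0.5) -> FitResult:
    """Best fit over all injective kind-compatible feature assignments.

    Assignments are enumerated exhaustively (model size <= 6) with
    pairwise-distance pruning; an assignment is valid only if, after rigid
    alignment, every matched pair lies within the model feature's
    tolerance and every ``required`` model feature is matched.  Returns a
    zero-score :class:`FitResult` when nothing matches.
    """
    n_model = len(model.features)
    rmsd_ref = model.rmsd_ref
    lfeats = ligand.features
    mpos = [f.xyz for f in model.features]
    lpos = [f.xyz for f in lfeats]
    best = FitResult.no_fit(n_model)

    def evaluate(assign: List[Tuple[int, int]]) -> None:
        nonlocal best
        if not assign:
            return
        if any(model.features[i].required and i not in {a for a, _ in assign}
               for i in range(n_model)):
            return
        pairs = [(mpos[i], lpos[j]) for i, j in assign]
        R, t, rmsd = align_features(pairs)
        for i, j in assign:
            if np.linalg.norm(R @ lpos[j] + t - mpos[i]) > model.features[i].tolerance + 1e-9:
                return
        n_matched = len(assign)
        frac = n_matched / n_model
        if n_matched >= 3:
            score = w * frac + (1 - w) * max(0.0, 1.0 - rmsd / rmsd_ref)
        else:
            score = w * frac
        if score > best.score:
            best = FitResult(list(assign), R, t, rmsd, n_matched, n_model, score)

    def recurse(mi: int, assign: List[Tuple[int, int]], used: set) -> None:
        if mi == n_model:
            evaluate(assign)
            return
        mf = model.features[mi]
        # leave this model feature unmatched
        recurse(mi + 1, assign, used)
        for lj, lf in enumerate(lfeats):
            if lj in used or not _compatible(mf, lf):
                continue
            ok = True
            for (pi, pj) in assign:
                dm = np.linalg.norm(mpos[mi] - mpos[pi])
                dl = np.linalg.norm(lpos[lj] - lpos[pj])
                if abs(dm - dl) > mf.tolerance + model.features[pi].tolerance:
                    ok = False
                    break
            if ok:
                assign.append((mi, lj))
                used.add(lj)
                recurse(mi + 1, assign, used)
                assign.pop()
                used.remove(lj)

    recurse(0, [], set())
    return best


# ---------------------------------------------------------------------------
# Conformers and molecule-level scoring
# ---------------------------------------------------------------------------

def etkdg_conformers(mol: Chem.Mol, k: int = 10, seed: int = 0) -> List[Chem.Mol]:
    """Distance-geometry (ETKDG) conformers; returns [] on failure."""
    try:
        molh = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = seed
        ids = AllChem.EmbedMultipleConfs(molh, numConfs=k, params=params)
        if len(ids) == 0:
            return []
        molh = Chem.RemoveHs(molh)
        out = []
        for cid in ids:
            m = Chem.Mol(molh, confId=int(cid))
            out.append(m)
        return out
    except Exception:
        return []


ConformerProvider = Callable[[Chem.Mol, int, int], List[Chem.Mol]]


def score_molecule(mol: Optional[Chem.Mol], model: PharmacophoreModel,
                   conformer_provider: ConformerProvider = etkdg_conformers,
                   k: int = 10, seed: int = 0,
                   rules: Optional[FeatureRules] = None) -> FitResult:
    """Best relative fit over up to ``k`` conformers; failures score 0."""
    if mol is None:
        return FitResult.no_fit(len(model.features))
    confs = conformer_provider(mol, k, seed)
    best = FitResult.no_fit(len(model.features))
    for cm in confs:
        try:
            feats = perceive_features(cm, rules)
        except ValueError:
            continue
        fit = relative_fit_score(feats, model)
        if fit.score > best.score:
            best = fit
    return best


def make_scorer(model: PharmacophoreModel, k: int = 3, seed: int = 0,
                rules: Optional[FeatureRules] = None) -> Callable[[Chem.Mol], float]:
    """Molecule -> [0,1] scoring callable for the RL loop."""
    def scorer(mol: Chem.Mol) -> float:
        return score_molecule(mol, model, k=k, seed=seed, rules=rules).score
    return scorer
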
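"""Molecular graph handling built on RDKit.

SMILES parsing/canonicalization, Bemis-Murcko scaffolds, substructure
matching and a corpus-derived synthetic-accessibility (SA) score in the
spirit of Ertl & Schuffenhauer: a fragment-frequency term plus structural
complexity penalties, rescaled to [1, 10] (1 = easy to make).

Invalid SMILES never raise into the RL loop; callers that need the
non-raising contract use :func:`try_parse_smiles` which returns ``None``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

#: terminal secondary methylamine: CH3 bonded to an NH that carries one
#: further heavy-atom neighbour.  Matches the methylamino head group of the
#: potent P-CAB candidates (e.g. CNCc1...), excludes hydroxy, primary-amine
#: and dimethylamino variants.
METHYLAMINO_SMARTS = "[CH3][NX3;H1][#6]"


class InvalidSmilesError(ValueError):
    """SMILES text could not be parsed (syntax or sanitization failure)."""


class SubstructurePatternError(ValueError):
    """A SMARTS pattern in the configuration is malformed."""


def parse_smiles(text: str) -> Chem.Mol:
    """Parse SMILES into a sanitized RDKit molecule.

    Raises
    ------
    InvalidSmilesError
        on empty input, syntax errors (e.g. unbalanced ring-closure
        digits) or valence violations.  Never returns a partially built
        graph.
    """
    if not text or not text.strip():
        raise InvalidSmilesError("empty SMILES")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {text!r}")
    return mol


def try_parse_smiles(text: str) -> Optional[Chem.Mol]:
    """Like :func:`parse_smiles` but returns ``None`` instead of raising."""
    try:
        return parse_smiles(text)
    except InvalidSmilesError:
        return None


def canonical_smiles(mol_or_smiles: "Chem.Mol | str") -> str:
    """Canonical SMILES, identical for any atom-order permutation."""
    if isinstance(mol_or_smiles, str):
        mol = parse_smiles(mol_or_smiles)
    else:
        mol = mol_or_smiles
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class ScaffoldRecord:
    """Bemis-Murcko framework of a molecule.

    ``scaffold_smiles`` is canonical; the empty string denotes an acyclic
    parent (no ring system to retain).  Stereochemistry is dropped so that
    scaffold identity (tabu membership) ignores chirality.
    """

    scaffold_smiles: str
    parent_id: str = ""


def murcko_scaffold(mol_or_smiles: "Chem.Mol | str", parent_id: str = "") -> ScaffoldRecord:
    """Atomic Bemis-Murcko scaffold: ring systems plus inter-ring linkers.

    Terminal side-chain atoms are pruned to a fixed point; element and bond
    identity are retained (not the generic carbon-skeleton variant).
    """
    if isinstance(mol_or_smiles, str):
        mol = parse_smiles(mol_or_smiles)
    else:
        mol = mol_or_smiles
    if mol.GetRingInfo().NumRings() == 0:
        return ScaffoldRecord("", parent_id)
    core = MurckoScaffold.GetScaffoldForMol(mol)
    smi = Chem.MolToSmiles(core)
    # scaffold identity ignores stereo annotations
    if "@" in smi or "/" in smi or "\\" in smi:
        flat = Chem.MolFromSmiles(smi)
        Chem.RemoveStereochemistry(flat)
        smi = Chem.MolToSmiles(flat)
    return ScaffoldRecord(smi, parent_id)


def matches_substructure(mol_or_smiles: "Chem.Mol | str", pattern: str = METHYLAMINO_SMARTS) -> bool:
    """True iff ``pattern`` (SMARTS) has a subgraph match in the molecule.

    Element, aromaticity, charge and H-count constraints of the pattern are
    honoured (plain RDKit SMARTS semantics).
    """
    if isinstance(mol_or_smiles, str):
        mol = parse_smiles(mol_or_smiles)
    else:
        mol = mol_or_smiles
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise SubstructurePatternError(f"malformed SMARTS: {pattern!r}")
    return mol.HasSubstructMatch(query)


# ---------------------------------------------------------------------------
# Synthetic accessibility
# ---------------------------------------------------------------------------

@dataclass
class FragmentScoreTable:
    """Circular-fragment (Morgan, radius <= 2) log-frequency contributions.

    Built deterministically from a declared corpus: each fragment hash maps
    to ``log10(count / c_ref)`` where ``c_ref`` is the geometric-mean count,
    so corpus-typical fragments contribute ~0 and rare ones negatively.
    Unseen fragments receive ``unseen_score``.
    """

    scores: dict = field(default_factory=dict)
    corpus_size: int = 0
    radius: int = 2
    unseen_score: float = -4.0

    @classmethod
    def from_corpus(cls, smiles: Iterable[str], radius: int = 2) -> "FragmentScoreTable":
        counts: dict = {}
        n = 0
        for smi in smiles:
            mol = try_parse_smiles(smi)
            if mol is None:
                continue
            n += 1
            fp = AllChem.GetMorganFingerprint(mol, radius)
            for h, c in fp.GetNonzeroElements().items():
                counts[h] = counts.get(h, 0) + c
        if not counts:
            raise ValueError("corpus produced no fragments")
        log_ref = sum(math.log10(c) for c in counts.values()) / len(counts)
        scores = {h: math.log10(c) - log_ref for h, c in counts.items()}
        return cls(scores=scores, corpus_size=n, radius=radius)

    def fragment_term(self, mol: Chem.Mol) -> float:
        """Count-weighted mean contribution per fragment occurrence."""
        fp = AllChem.GetMorganFingerprint(mol, self.radius)
        elems = fp.GetNonzeroElements()
        total = sum(elems.values())
        if total == 0:
            raise ValueError("molecule has no fragments")
        s = sum(self.scores.get(h, self.unseen_score) * c for h, c in elems.items())
        return s / total


def _complexity_penalty(mol: Chem.Mol) -> float:
    n_atoms = mol.GetNumAtoms()
    ri = mol.GetRingInfo()
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    n_bridge = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    n_chiral = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True))
    macro = any(len(r) > 8 for r in ri.AtomRings())

    size_penalty = n_atoms ** 1.005 - n_atoms
    stereo_penalty = math.log10(n_chiral + 1)
    spiro_penalty = math.log10(n_spiro + 1)
    bridge_penalty = math.log10(n_bridge + 1)
    macro_penalty = math.log10(2) if macro else 0.0
    return size_penalty + stereo_penalty + spiro_penalty + bridge_penalty + macro_penalty


def sa_score(mol_or_smiles: "Chem.Mol | str", table: FragmentScoreTable) -> float:
    """Synthetic-accessibility estimate in [1, 10]; 1 = easy to synthesize.

    Combines the corpus fragment-frequency term with ring-complexity,
    stereo-centre, macrocycle and size penalties, then rescales to the
    conventional 1-10 range.
    """
    if isinstance(mol_or_smiles, str):
        mol = parse_smiles(mol_or_smiles)
    else:
        mol = mol_or_smiles
    if mol.GetNumAtoms() == 0:
        raise ValueError("empty molecule")

    frag = table.fragment_term(mol)
    raw = frag - _complexity_penalty(mol)
    # empirical span of `raw` on drug-like corpora; rescale so that
    # raw >= hi -> 1 (easy) and raw <= lo -> 10 (hard)
    lo, hi = -9.0, 1.5
    score = 11.0 - (raw - lo) / (hi - lo) * 9.0 - 1.0
    return float(min(10.0, max(1.0, score)))
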
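"""Derive pharmacophore model coordinates from deposited pump structures.

The four binding-site features are anchored to the luminal cavity of the
gastric H+,K+-ATPase:

  I   cationic / H-bond donor near the cation-binding site — centroid of
      the carboxylate oxygens of Glu343, Glu795 and Glu820 (or, when a
      bound blocker with a basic amine is present, its amine nitrogen);
  II  hydrophobic patch between TM1 and TM4 — Ala123 Cbeta region;
  III aromatic stack at the luminal entrance — Tyr799 ring centroid;
  IV  hydrophobic conduit connecting I and III — midpoint of I and III.

Model variants: "A" and "B" are built from an SCH28080-bound template
(e.g. PDB 5YLV), "C" from a vonoprazan-bound one (e.g. 5YLU); variant B
duplicates the aromatic feature at position III (mimicking a fused
bicyclic aromatic).  Download the mmCIF/PDB files yourself, then:

    python scripts/extract_pharmacophore.py 5ylv.cif --variant A --out typeA.json
"""

from __future__ import annotations

import argparse

import numpy as np

from deepquartet.pharmacophore import PharmacophoreFeature, PharmacophoreModel
from deepquartet.structures import read_structure

GLU_SITE = (343, 795, 820)
ALA_TM1 = 123
TYR_LUMEN = 799
TYR_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


def _residue_atoms(st, seqnum, names):
    for chain in st[0]:
        for res in chain:
            if res.seqid.num == seqnum:
                pts = [np.array([a.pos.x, a.pos.y, a.pos.z])
                       for a in res if a.name in names]
                if pts:
                    return np.array(pts)
    raise SystemExit(f"residue {seqnum} (atoms {names}) not found")


def build_model(st, variant: str, template: str) -> PharmacophoreModel:
    glu_o = np.concatenate([_residue_atoms(st, n, ("OE1", "OE2"))
                            for n in GLU_SITE])
    pos_i = glu_o.mean(axis=0)
    pos_ii = _residue_atoms(st, ALA_TM1, ("CB",)).mean(axis=0)
    pos_iii = _residue_atoms(st, TYR_LUMEN, TYR_RING_ATOMS).mean(axis=0)
    pos_iv = 0.5 * (pos_i + pos_iii)

    feats = [
        PharmacophoreFeature("cationic", tuple(pos_i), 1.5, required=True),
        PharmacophoreFeature("hydrophobic", tuple(pos_ii), 2.0),
        PharmacophoreFeature("aromatic", tuple(pos_iii), 1.5),
        PharmacophoreFeature("hydrophobic", tuple(pos_iv), 2.0),
    ]
    if variant == "B":
        # second aromatic ring at position III (fused heteroaromatic)
        feats.insert(3, PharmacophoreFeature(
            "aromatic", tuple(pos_iii + (pos_iii - pos_i) * 0.25), 1.5))
    return PharmacophoreModel(f"Type{variant}", feats, template=template)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("structure", help="PDB or mmCIF file of the template")
    ap.add_argument("--variant", choices=["A", "B", "C"], default="A")
    ap.add_argument("--template-id", default=None,
                    help="accession recorded in the model (default: filename)")
    ap.add_argument("--out", required=True)
    args = ap.parse_args()

    st = read_structure(args.structure)
    model = build_model(st, args.variant, args.template_id or args.structure)
    with open(args.out, "w") as fh:
        fh.write(model.to_json())
    print(f"wrote {model.model_id} ({len(model.features)} features) to {args.out}")


if __name__ == "__main__":
    main()
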
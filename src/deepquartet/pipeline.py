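"""End-to-end orchestration: generation -> scoring -> triage -> report.

The candidate filter mirrors the published selection rule: keep generated
structures that carry a terminal secondary methylamine and reach a
pharmacophore fit score of at least 0.90, ranked by score.  Human
(medicinal-chemistry) selection beyond the ranked table is out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import (METHYLAMINO_SMARTS, FragmentScoreTable, matches_substructure,
                   sa_score, try_parse_smiles)
from .rl import GenerationResult


@dataclass
class TriageConfig:
    min_pharmacophore_score: float = 0.90
    required_substructure: str = METHYLAMINO_SMARTS
    compute_sa: bool = True
    model_id: str = "custom"

    def __post_init__(self) -> None:
        if not 0 <= self.min_pharmacophore_score <= 1:
            raise ValueError("min_pharmacophore_score must be in [0, 1]")


@dataclass
class CandidateRecord:
    smiles: str
    pharmacophore_score: float
    scaffold: str
    sa: Optional[float]
    has_required_substructure: bool
    agent_index: int
    step: int
    model_id: str

    def passes(self, cfg: TriageConfig) -> bool:
        return (self.pharmacophore_score >= cfg.min_pharmacophore_score
                and self.has_required_substructure)


def candidates_from_result(result: GenerationResult, cfg: TriageConfig,
                           table: Optional[FragmentScoreTable] = None
                           ) -> List[CandidateRecord]:
    """Annotate every harvested record with substructure and SA data."""
    out = []
    for r in result.records:
        mol = try_parse_smiles(r.smiles)
        if mol is None:
            continue
        has_sub = matches_substructure(mol, cfg.required_substructure)
        sa = (sa_score(mol, table) if (cfg.compute_sa and table is not None)
              else None)
        out.append(CandidateRecord(r.smiles, r.raw_score, r.scaffold, sa,
                                   has_sub, r.agent_index, r.step, cfg.model_id))
    return out


def select_candidates(records: Sequence[CandidateRecord], cfg: TriageConfig
                      ) -> List[CandidateRecord]:
    """Records passing both filters, unique by SMILES, score descending."""
    best: Dict[str, CandidateRecord] = {}
    for r in records:
        if not r.passes(cfg):
            continue
        cur = best.get(r.smiles)
        if cur is None or r.pharmacophore_score > cur.pharmacophore_score:
            best[r.smiles] = r
    return sorted(best.values(),
                  key=lambda r: (-r.pharmacophore_score, r.smiles))


def summarize_run(result: GenerationResult,
                  candidates: Sequence[CandidateRecord]) -> dict:
    """Per-agent counts, scaffold-diversity and SA summaries, pass counts."""
    unique_smiles = {r.smiles for r in result.records}
    unique_scaffolds = {r.scaffold for r in result.records if r.scaffold}
    sa_values = [c.sa for c in candidates if c.sa is not None]
    return {
        "n_agents": len(result.agents),
        "total_steps": result.total_steps_run,
        "per_agent": [{"agent": a.agent_index, "steps": a.steps,
                       "mean_score": round(a.mean_adjusted_score, 6),
                       "mean_raw_score": round(a.mean_raw_score, 6),
                       "harvested": a.n_harvested,
                       "stop_reason": a.stop_reason}
                      for a in result.agents],
        "n_harvested_records": len(result.records),
        "n_unique_molecules": len(unique_smiles),
        "n_unique_scaffolds": len(unique_scaffolds),
        "scaffold_diversity": (len(unique_scaffolds) / len(unique_smiles)
                               if unique_smiles else 0.0),
        "tabu_size": len(result.tabu),
        "n_candidates": len(candidates),
        "sa_mean": float(np.mean(sa_values)) if sa_values else None,
        "sa_median": float(np.median(sa_values)) if sa_values else None,
    }


CSV_COLUMNS = ["smiles", "score", "scaffold", "sa", "has_required_substructure",
               "agent", "step", "model_id"]


def candidates_to_frame(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    rows = [[r.smiles, f"{r.pharmacophore_score:.6f}", r.scaffold,
             ("" if r.sa is None else f"{r.sa:.6f}"),
             r.has_required_substructure, r.agent_index, r.step, r.model_id]
            for r in records]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_report(path: str, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
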
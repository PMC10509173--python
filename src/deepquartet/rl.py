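"""Agent reinforcement learning with scaffold tabu and early stop & refresh.

The generation loop trains an Agent network, initialized from the Prior,
to minimize the squared deviation of its sequence log-likelihood from the
augmented likelihood ``log P_prior(A) + sigma * S(A)``, where ``S`` is a
[0, 1] scoring function.  Two diversity mechanisms shape the run:

* **scaffold tabu list** — the Bemis-Murcko scaffold of every structure an
  agent generates is appended to a growing tabu set at each refresh; any
  later structure whose scaffold is already tabu is scored exactly 0,
* **early stop & refresh** — whenever the windowed mean score exceeds a
  threshold (default 0.8) or the agent exceeds a step cap (default 1000),
  the agent's top-scoring structures are harvested (default 50) and the
  agent is re-initialized from the Prior; the loop continues until a total
  step budget (default 10,000) is spent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .chem import ScaffoldRecord, murcko_scaffold, try_parse_smiles
from .generator import Adam, RNNModel, grad_weighted_loglik

logger = logging.getLogger(__name__)


@dataclass
class RLConfig:
    """Agent-training knobs; defaults follow the published run settings."""

    sigma: float = 120.0
    total_steps: int = 10_000
    batch_size: int = 32
    learning_rate: float = 1e-3
    replay_size: int = 100
    replay_samples_per_step: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.total_steps < 1:
            raise ValueError("total_steps must be >= 1")


@dataclass
class RefreshPolicy:
    """Early-stop-&-refresh trigger and harvest size."""

    score_threshold: float = 0.8
    max_agent_steps: int = 1000
    top_n: int = 50
    averaging_window: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.score_threshold <= 1:
            raise ValueError("score_threshold must be in (0, 1]")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


class TabuList:
    """Growing set of canonical scaffold SMILES with per-agent history.

    Acyclic molecules (empty scaffold) are never added: one acyclic sample
    must not zero every acyclic molecule forever.
    """

    def __init__(self) -> None:
        self._set: set = set()
        self.history: List[Tuple[int, List[str]]] = []

    def __contains__(self, scaffold: "ScaffoldRecord | str") -> bool:
        smi = scaffold.scaffold_smiles if isinstance(scaffold, ScaffoldRecord) else scaffold
        return smi in self._set

    def __len__(self) -> int:
        return len(self._set)

    @property
    def scaffolds(self) -> frozenset:
        return frozenset(self._set)

    def extend(self, agent_index: int, scaffolds: Sequence[str]) -> None:
        added = sorted({s for s in scaffolds if s and s not in self._set})
        self._set.update(added)
        self.history.append((agent_index, added))


def apply_tabu(raw_score: float, scaffold: ScaffoldRecord, tabu: TabuList) -> float:
    """Zero the score (exactly) when the scaffold is tabu-listed."""
    if scaffold.scaffold_smiles and scaffold in tabu:
        return 0.0
    return raw_score


@dataclass
class GenRecord:
    """One generated structure with its scores and provenance."""

    smiles: str
    raw_score: float
    adjusted_score: float
    scaffold: str
    agent_index: int
    step: int
    was_tabu: bool = False


@dataclass
class AgentState:
    """Agent network plus its optimizer, histories and replay buffer."""

    model: RNNModel
    optimizer: Adam
    step: int = 0
    score_history: List[float] = field(default_factory=list)     # tabu-adjusted batch means
    raw_score_history: List[float] = field(default_factory=list)
    replay: List[Tuple[tuple, float, float]] = field(default_factory=list)

    @classmethod
    def from_prior(cls, prior: RNNModel, learning_rate: float) -> "AgentState":
        model = prior.copy()
        return cls(model=model, optimizer=Adam(model.params, lr=learning_rate))


def agent_update(agent: AgentState, prior: RNNModel,
                 batch: Sequence[Sequence[int]], scores: Sequence[float],
                 config: RLConfig,
                 rng: Optional[np.random.Generator] = None) -> float:
    """One augmented-likelihood gradient step; returns the loss.

    Minimizes ``mean_i (log P_prior(A_i) + sigma * S_i - log P_agent(A_i))^2``
    over the sampled batch plus replayed high-scoring sequences.  The
    replay buffer keeps the ``replay_size`` best-scoring sequences seen so
    far (score descending).
    """
    batch = [list(s) for s in batch]
    scores = np.asarray(scores, dtype=float)
    if len(batch) != len(scores):
        raise ValueError("batch and scores length mismatch")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")

    prior_lls = prior.batch_loglik(batch)

    # replay: previously seen high scorers, agent likelihood recomputed
    replay_seqs: List[list] = []
    replay_scores: List[float] = []
    replay_prior: List[float] = []
    if agent.replay and config.replay_samples_per_step > 0 and rng is not None:
        k = min(config.replay_samples_per_step, len(agent.replay))
        idx = rng.choice(len(agent.replay), size=k, replace=False)
        seen = {tuple(s) for s in batch}
        for i in idx:
            seq, sc, pll = agent.replay[i]
            if seq not in seen:
                replay_seqs.append(list(seq))
                replay_scores.append(sc)
                replay_prior.append(pll)

    all_seqs = batch + replay_seqs
    all_scores = np.concatenate([scores, np.asarray(replay_scores)]) if replay_seqs else scores
    all_prior = np.concatenate([prior_lls, np.asarray(replay_prior)]) if replay_seqs else prior_lls

    augmented = all_prior + config.sigma * all_scores
    n = len(all_seqs)
    # d/dtheta mean (aug - ll)^2  =  sum_i [-2 (aug_i - ll_i) / n] dll_i/dtheta
    agent_lls = agent.model.batch_loglik(all_seqs)
    weights = -2.0 * (augmented - agent_lls) / n
    _, grads = grad_weighted_loglik(agent.model.params, all_seqs,
                                    agent.model.vocab, weights)
    loss = float(np.mean((augmented - agent_lls) ** 2))
    agent.optimizer.step(agent.model.params, grads)

    # update replay with this batch's best-scoring sequences
    pool = {tuple(s): (sc, pll) for (s, sc, pll) in agent.replay}
    for seq, sc, pll in zip(batch, scores, prior_lls):
        t = tuple(seq)
        if t not in pool or pool[t][0] < sc:
            pool[t] = (float(sc), float(pll))
    ranked = sorted(pool.items(), key=lambda kv: (-kv[1][0], kv[0]))
    agent.replay = [(seq, sc, pll) for seq, (sc, pll) in ranked[:config.replay_size]]
    return loss


def should_refresh(agent: AgentState, policy: RefreshPolicy) -> bool:
    """Early-stop trigger: windowed mean score above threshold or step cap."""
    if agent.step < 1:
        raise ValueError("agent has no recorded steps")
    window = agent.score_history[-policy.averaging_window:]
    return (float(np.mean(window)) > policy.score_threshold
            or agent.step >= policy.max_agent_steps)


def harvest_top(records: Sequence[GenRecord], top_n: int) -> List[GenRecord]:
    """Up to ``top_n`` records, unique by canonical SMILES, score descending.

    Ranking uses the raw score; ties break by canonical-SMILES
    lexicographic order, so the result is stable across runs.
    """
    best: Dict[str, GenRecord] = {}
    for r in records:
        cur = best.get(r.smiles)
        if cur is None or r.raw_score > cur.raw_score:
            best[r.smiles] = r
    ranked = sorted(best.values(), key=lambda r: (-r.raw_score, r.smiles))
    return ranked[:top_n]


@dataclass
class AgentSummary:
    agent_index: int
    steps: int
    mean_adjusted_score: float
    mean_raw_score: float
    n_harvested: int
    stop_reason: str
    score_history: List[float] = field(default_factory=list)
    raw_score_history: List[float] = field(default_factory=list)


@dataclass
class GenerationResult:
    """All harvested records with provenance plus the final tabu list."""

    records: List[GenRecord]
    agents: List[AgentSummary]
    tabu: TabuList
    total_steps_run: int


def run_deep_quartet(config: RLConfig, policy: RefreshPolicy,
                     scorer: Callable[[Chem.Mol], float], prior: RNNModel,
                     tabu_enabled: bool = True,
                     tabu_source: str = "all",
                     harvest_excludes_tabu: bool = True) -> GenerationResult:
    """Full generation loop: repeated agent training with tabu and refresh.

    ``scorer`` maps an RDKit molecule to [0, 1]; a scorer exception scores
    that molecule 0 and the run continues.  ``tabu_source`` selects whether
    the scaffolds of all generated structures or only harvested ones are
    appended at refresh.  Fully reproducible for a fixed ``config.seed``.
    """
    if tabu_source not in ("all", "harvested"):
        raise ValueError("tabu_source must be 'all' or 'harvested'")
    rng = np.random.default_rng(config.seed)
    tabu = TabuList()
    all_records: List[GenRecord] = []
    summaries: List[AgentSummary] = []
    scaffold_cache: Dict[str, str] = {}
    score_cache: Dict[str, float] = {}

    cumulative = 0
    agent_index = 0
    while cumulative < config.total_steps:
        agent = AgentState.from_prior(prior, config.learning_rate)
        agent_records: List[GenRecord] = []
        agent_scaffolds: set = set()
        stop_reason = "budget"
        while True:
            sampled = agent.model.sample_batch(config.batch_size, rng)
            seqs = [s for s, _ in sampled]
            raw_scores = np.zeros(len(seqs))
            adj_scores = np.zeros(len(seqs))
            step_records: List[GenRecord] = []
            for i, (seq, _) in enumerate(sampled):
                smi = agent.model.vocab.decode(seq)
                terminated = bool(seq) and seq[-1] == agent.model.vocab.end
                mol = try_parse_smiles(smi) if terminated else None
                if mol is None:
                    continue
                can = Chem.MolToSmiles(mol)
                if can not in scaffold_cache:
                    scaffold_cache[can] = murcko_scaffold(mol).scaffold_smiles
                scaffold = scaffold_cache[can]
                if can not in score_cache:
                    try:
                        score_cache[can] = float(np.clip(scorer(mol), 0.0, 1.0))
                    except Exception:
                        logger.warning("scorer failed on %s; scored 0", can)
                        score_cache[can] = 0.0
                raw = score_cache[can]
                was_tabu = tabu_enabled and bool(scaffold) and scaffold in tabu
                adj = apply_tabu(raw, ScaffoldRecord(scaffold), tabu) if tabu_enabled else raw
                raw_scores[i] = raw
                adj_scores[i] = adj
                agent_scaffolds.add(scaffold)
                step_records.append(GenRecord(can, raw, adj, scaffold,
                                              agent_index, agent.step, was_tabu))
            agent_update(agent, prior, seqs, adj_scores, config, rng)
            agent.step += 1
            agent.score_history.append(float(adj_scores.mean()))
            agent.raw_score_history.append(float(raw_scores.mean()))
            agent_records.extend(step_records)
            cumulative += 1
            if should_refresh(agent, policy):
                window = agent.score_history[-policy.averaging_window:]
                stop_reason = ("threshold"
                               if float(np.mean(window)) > policy.score_threshold
                               else "step_cap")
                break
            if cumulative >= config.total_steps:
                stop_reason = "budget"
                break

        pool = [r for r in agent_records if not (harvest_excludes_tabu and r.was_tabu)]
        harvested = harvest_top(pool, policy.top_n)
        all_records.extend(harvested)
        if tabu_enabled:
            if tabu_source == "all":
                tabu.extend(agent_index, sorted(agent_scaffolds))
            else:
                tabu.extend(agent_index, sorted({r.scaffold for r in harvested}))
        summaries.append(AgentSummary(
            agent_index=agent_index, steps=agent.step,
            mean_adjusted_score=float(np.mean(agent.score_history)),
            mean_raw_score=float(np.mean(agent.raw_score_history)),
            n_harvested=len(harvested), stop_reason=stop_reason,
            score_history=list(agent.score_history),
            raw_score_history=list(agent.raw_score_history)))
        agent_index += 1

    return GenerationResult(records=all_records, agents=summaries, tabu=tabu,
                            total_steps_run=cumulative)
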
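"""RL core: tabu zeroing, refresh trigger, harvesting, augmented loss."""

import numpy as np
import pytest

from deepquartet.chem import ScaffoldRecord, matches_substructure
from deepquartet.generator import (BEGIN, END, PAD, RNNModel, TokenVocabulary,
                                   batch_loglik, init_params)
from deepquartet.rl import (AgentState, GenRecord, RLConfig, RefreshPolicy,
                            TabuList, agent_update, apply_tabu, harvest_top,
                            run_deep_quartet, should_refresh)

BENZ = "c1ccccc1"


class TestApplyTabu:
    def test_zeroed_exactly_when_listed(self):
        tabu = TabuList()
        tabu.extend(0, [BENZ])
        assert apply_tabu(0.95, ScaffoldRecord(BENZ), tabu) == 0.0

    def test_unlisted_unchanged(self):
        tabu = TabuList()
        tabu.extend(0, [BENZ])
        assert apply_tabu(0.95, ScaffoldRecord("c1ccncc1"), tabu) == 0.95

    def test_empty_tabu_identity(self):
        assert apply_tabu(0.4, ScaffoldRecord(BENZ), TabuList()) == 0.4

    def test_acyclic_never_added_nor_zeroed(self):
        tabu = TabuList()
        tabu.extend(0, ["", BENZ])
        assert "" not in tabu
        assert apply_tabu(0.7, ScaffoldRecord(""), tabu) == 0.7

    def test_monotone_growth_with_history(self):
        tabu = TabuList()
        tabu.extend(0, ["A1", "A2"])
        tabu.extend(1, ["A2", "B1"])
        assert len(tabu) == 3
        assert tabu.history[1] == (1, ["B1"])


class TestShouldRefresh:
    def _agent(self, history, step):
        a = AgentState.__new__(AgentState)
        a.score_history = history
        a.step = step
        return a

    def test_threshold_trigger(self):
        a = self._agent([0.85] * 30, 300)
        assert should_refresh(a, RefreshPolicy()) is True

    def test_step_cap_trigger(self):
        a = self._agent([0.2] * 1000, 1000)
        assert should_refresh(a, RefreshPolicy()) is True

    def test_no_trigger(self):
        a = self._agent([0.5] * 400, 400)
        assert should_refresh(a, RefreshPolicy()) is False

    def test_requires_at_least_one_step(self):
        with pytest.raises(ValueError):
            should_refresh(self._agent([], 0), RefreshPolicy())


def _rec(smiles, score):
    return GenRecord(smiles, score, score, "", 0, 0)


class TestHarvestTop:
    def test_selects_highest_unique(self, rng):
        records = []
        for i in range(120):
            records.append(_rec(f"S{i:03d}", i / 120.0))
        # 80 duplicates of existing smiles with lower scores
        for i in range(80):
            records.append(_rec(f"S{i:03d}", 0.0))
        top = harvest_top(records, 50)
        assert len(top) == 50
        assert [r.smiles for r in top[:3]] == ["S119", "S118", "S117"]
        assert len({r.smiles for r in top}) == 50

    def test_fewer_uniques_all_returned(self):
        top = harvest_top([_rec(f"S{i}", 0.5) for i in range(30)], 50)
        assert len(top) == 30

    def test_tie_break_lexicographic_and_stable(self):
        recs = [_rec(s, 0.5) for s in ("CCC", "AAA", "BBB", "DDD")]
        top1 = harvest_top(recs, 2)
        top2 = harvest_top(list(reversed(recs)), 2)
        assert [r.smiles for r in top1] == ["AAA", "BBB"]
        assert [r.smiles for r in top1] == [r.smiles for r in top2]

    def test_duplicate_keeps_best_score(self):
        recs = [_rec("X", 0.2), _rec("X", 0.9), _rec("Y", 0.5)]
        top = harvest_top(recs, 2)
        assert top[0].smiles == "X" and top[0].raw_score == 0.9


def _toy_model(tokens=("C", "O", "N"), hidden=8, emb=6, seed=0, randomize=True):
    vocab = TokenVocabulary([PAD, BEGIN, END] + list(tokens))
    rng = np.random.default_rng(seed)
    p = init_params(len(vocab), emb, hidden, rng)
    if randomize:
        for k in p:
            p[k] = rng.normal(0, 0.3, p[k].shape)
    return RNNModel(vocab, p, emb, hidden, max_len=20)


class TestAgentUpdate:
    def test_zero_scores_at_prior_give_zero_loss_and_no_drift(self):
        """When the agent equals the prior and all scores are 0, the
        augmented target equals the agent likelihood: loss 0, no update."""
        prior = _toy_model()
        agent = AgentState.from_prior(prior, learning_rate=0.1)
        seqs = [prior.vocab.encode(s) for s in ("CO", "NC", "CCC")]
        before = agent.model.param_hash()
        loss = agent_update(agent, prior, seqs, [0.0, 0.0, 0.0],
                            RLConfig(batch_size=3))
        assert loss == pytest.approx(0.0, abs=1e-18)
        assert agent.model.param_hash() == before

    def test_augmented_loss_gradient_matches_finite_differences(self):
        """d/dtheta mean (logP_prior + sigma*S - logP_agent)^2 checked
        against central differences on a 3-token toy model."""
        prior = _toy_model(seed=1)
        agent_model = _toy_model(seed=2)
        vocab = prior.vocab
        seqs = [vocab.encode(s) for s in ("CO", "NNC")]
        scores = np.array([0.8, 0.3])
        sigma = 10.0
        prior_ll = prior.batch_loglik(seqs)

        def loss_at(params):
            ll = batch_loglik(params, seqs, vocab)
            return float(np.mean((prior_ll + sigma * scores - ll) ** 2))

        from deepquartet.generator import grad_weighted_loglik
        ll = batch_loglik(agent_model.params, seqs, vocab)
        w = -2.0 * (prior_ll + sigma * scores - ll) / len(seqs)
        _, grads = grad_weighted_loglik(agent_model.params, seqs, vocab, w)
        rng = np.random.default_rng(0)
        for k in ("Wo", "Uh", "E", "bz"):
            flat = agent_model.params[k].reshape(-1)
            gflat = grads[k].reshape(-1)
            for idx in rng.choice(flat.size, size=3, replace=False):
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss_at(agent_model.params)
                flat[idx] = orig - eps
                lm = loss_at(agent_model.params)
                flat[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert gflat[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_shape_mismatch_rejected(self):
        prior = _toy_model()
        agent = AgentState.from_prior(prior, 0.1)
        with pytest.raises(ValueError):
            agent_update(agent, prior, [prior.vocab.encode("CO")], [0.1, 0.2],
                         RLConfig())

    def test_replay_buffer_bounded_and_sorted(self):
        prior = _toy_model()
        agent = AgentState.from_prior(prior, 0.01)
        cfg = RLConfig(replay_size=5, replay_samples_per_step=2, batch_size=4)
        rng = np.random.default_rng(0)
        for step in range(6):
            seqs = [prior.vocab.encode(s) for s in ("CO", "NC", "CC", "NO")]
            scores = rng.random(4)
            agent_update(agent, prior, seqs, scores, cfg, rng)
        assert len(agent.replay) <= 5
        replay_scores = [s for _, s, _ in agent.replay]
        assert replay_scores == sorted(replay_scores, reverse=True)

    def test_enrichment_toward_rewarded_token(self, small_prior):
        """A scorer rewarding nitrogen-containing molecules shifts the
        agent: after 200 seeded steps its mean batch score exceeds the
        prior's baseline."""
        from deepquartet.chem import try_parse_smiles
        prior = small_prior
        rng = np.random.default_rng(7)

        def score_smiles(smi):
            mol = try_parse_smiles(smi)
            if mol is None:
                return 0.0
            return 1.0 if any(a.GetSymbol() == "N" for a in mol.GetAtoms()) else 0.0

        baseline = np.mean([score_smiles(s)
                            for s, _ in prior.sample_smiles(300, rng)])
        agent = AgentState.from_prior(prior, learning_rate=1e-3)
        cfg = RLConfig(sigma=60.0, batch_size=16)
        means = []
        for step in range(200):
            batch = agent.model.sample_batch(16, rng)
            seqs = [s for s, _ in batch]
            scores = [score_smiles(agent.model.vocab.decode(s)) for s in seqs]
            agent_update(agent, prior, seqs, scores, cfg, rng)
            means.append(np.mean(scores))
        assert np.mean(means[-20:]) > baseline + 0.1


def _cheap_scorer(mol):
    s = 0.5 * matches_substructure(mol)
    s += 0.5 * min(1.0, sum(a.GetSymbol() == "Cl" for a in mol.GetAtoms()) / 2)
    return s


class TestRunDeepQuartet:
    def test_step_cap_arithmetic(self, small_prior):
        """With a scorer that never reaches the threshold every agent runs
        to its step cap: agents = total/cap, cumulative steps exact."""
        cfg = RLConfig(total_steps=40, batch_size=8, seed=1)
        pol = RefreshPolicy(max_agent_steps=10, top_n=5, averaging_window=10)
        res = run_deep_quartet(cfg, pol, lambda mol: 0.0, small_prior)
        assert res.total_steps_run == 40
        assert len(res.agents) == 4
        assert all(a.steps == 10 for a in res.agents)
        assert all(a.stop_reason == "step_cap" for a in res.agents)
        assert all(a.n_harvested <= 5 for a in res.agents)
        assert sum(a.steps for a in res.agents) == res.total_steps_run

    def test_full_run_determinism(self, small_prior):
        cfg = RLConfig(total_steps=30, batch_size=8, seed=5)
        pol = RefreshPolicy(max_agent_steps=15, top_n=10, averaging_window=10)
        r1 = run_deep_quartet(cfg, pol, _cheap_scorer, small_prior)
        r2 = run_deep_quartet(cfg, pol, _cheap_scorer, small_prior)
        assert sorted(r.smiles for r in r1.records) == \
            sorted(r.smiles for r in r2.records)
        assert r1.tabu.scaffolds == r2.tabu.scaffolds

    def test_harvested_scaffolds_in_final_tabu(self, small_prior):
        cfg = RLConfig(total_steps=30, batch_size=8, seed=2)
        pol = RefreshPolicy(max_agent_steps=15, top_n=10, averaging_window=10)
        res = run_deep_quartet(cfg, pol, _cheap_scorer, small_prior)
        for rec in res.records:
            if rec.scaffold:
                assert rec.scaffold in res.tabu

    def test_tabu_zeroing_recorded(self, small_prior):
        cfg = RLConfig(total_steps=60, batch_size=8, seed=3)
        pol = RefreshPolicy(max_agent_steps=20, top_n=10, averaging_window=10)
        res = run_deep_quartet(cfg, pol, _cheap_scorer, small_prior)
        # every record generated while its scaffold was tabu scores 0
        # (re-run to collect records including tabu ones is internal; the
        # invariant is visible through harvested records' flags)
        for rec in res.records:
            assert rec.was_tabu is False  # harvest excludes tabu records
            assert rec.adjusted_score in (rec.raw_score, 0.0)

    def test_scorer_exception_scores_zero_and_run_continues(self, small_prior):
        calls = {"n": 0}

        def flaky(mol):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("boom")
            return 0.5

        cfg = RLConfig(total_steps=10, batch_size=8, seed=4)
        pol = RefreshPolicy(max_agent_steps=10, top_n=5, averaging_window=10)
        res = run_deep_quartet(cfg, pol, flaky, small_prior)
        assert res.total_steps_run == 10
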
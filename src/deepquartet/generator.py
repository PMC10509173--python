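"""SMILES language model: tokenizer, vocabulary and a recurrent network.

The network is a single-layer GRU over SMILES tokens, implemented directly
in NumPy with analytically derived gradients (verified against finite
differences in the test suite).  It provides exactly what the
reinforcement-learning loop needs:

* per-sequence log-likelihood ``log P(sequence)`` including the END token,
* ancestral sampling with the matching log-likelihood,
* gradients of any weighted sum of sequence log-likelihoods, which covers
  both maximum-likelihood pre-training (weights ``-1/N``) and the
  augmented-likelihood squared loss of the RL agent.

All arithmetic is float64; training and sampling are reproducible for a
fixed seed on a given machine.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .chem import try_parse_smiles

PAD, BEGIN, END = "<pad>", "^", "$"

# bracket atoms and two-character elements are single tokens
_TOKEN_RE = re.compile(r"(\[[^\]]*\]|%\d{2}|Cl|Br|.)")


def tokenize_smiles(smiles: str) -> List[str]:
    """Split a SMILES string into grammar tokens (lossless)."""
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"tokenization not lossless for {smiles!r}")
    return tokens


@dataclass
class TokenVocabulary:
    """Ordered token list with PAD/BEGIN/END specials at indices 0..2."""

    tokens: List[str]

    def __post_init__(self) -> None:
        assert self.tokens[:3] == [PAD, BEGIN, END]
        self.stoi = {t: i for i, t in enumerate(self.tokens)}
        if len(self.stoi) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad(self) -> int:
        return 0

    @property
    def begin(self) -> int:
        return 1

    @property
    def end(self) -> int:
        return 2

    def encode(self, smiles: str) -> List[int]:
        """Token indices of ``smiles`` followed by END (no BEGIN)."""
        try:
            idx = [self.stoi[t] for t in tokenize_smiles(smiles)]
        except KeyError as e:
            raise ValueError(f"token {e.args[0]!r} not in vocabulary") from e
        return idx + [self.end]

    def decode(self, seq: Sequence[int]) -> str:
        """SMILES text of a sampled sequence (specials stripped)."""
        out = []
        for i in seq:
            if i == self.end:
                break
            if i in (self.pad, self.begin):
                continue
            out.append(self.tokens[i])
        return "".join(out)


def build_vocabulary(corpus: Iterable[str]) -> TokenVocabulary:
    """Vocabulary covering every token in ``corpus``, deterministic order.

    Lines that are not valid SMILES are reported with their 1-based line
    number.
    """
    seen = set()
    bad = []
    n = 0
    for lineno, smi in enumerate(corpus, start=1):
        smi = smi.strip()
        if not smi:
            continue
        n += 1
        if try_parse_smiles(smi) is None:
            bad.append(lineno)
            continue
        seen.update(tokenize_smiles(smi))
    if n == 0:
        raise ValueError("empty corpus")
    if bad:
        raise ValueError(f"unparseable corpus lines: {bad[:20]}")
    return TokenVocabulary([PAD, BEGIN, END] + sorted(seen))


# ---------------------------------------------------------------------------
# GRU parameters and math
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def init_params(vocab_size: int, emb_size: int, hidden_size: int,
                rng: np.random.Generator) -> dict:
    """Gaussian-initialized GRU with a zeroed output layer.

    The zero output layer makes the untrained model emit an exactly uniform
    distribution over tokens at every step.
    """
    def g(*shape):
        return rng.normal(0.0, 0.1, size=shape)

    V, D, H = vocab_size, emb_size, hidden_size
    p = {"E": g(V, D)}
    for gate in ("z", "r", "h"):
        p[f"W{gate}"] = g(D, H)
        p[f"U{gate}"] = g(H, H)
        p[f"b{gate}"] = np.zeros(H)
    p["Wo"] = np.zeros((H, V))
    p["bo"] = np.zeros(V)
    return p


def _gru_step(p: dict, x: np.ndarray, h: np.ndarray):
    """One GRU step for a batch; returns new hidden state and cache."""
    z = _sigmoid(x @ p["Wz"] + h @ p["Uz"] + p["bz"])
    r = _sigmoid(x @ p["Wr"] + h @ p["Ur"] + p["br"])
    hbar = np.tanh(x @ p["Wh"] + (r * h) @ p["Uh"] + p["bh"])
    h_new = (1.0 - z) * h + z * hbar
    return h_new, (x, h, z, r, hbar)


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    s = logits - m
    return s - np.log(np.exp(s).sum(axis=-1, keepdims=True))


def _pad_batch(seqs: Sequence[Sequence[int]], vocab: TokenVocabulary):
    """Inputs (BEGIN + seq[:-1]), targets (seq) and mask as (B, T) arrays."""
    B = len(seqs)
    T = max(len(s) for s in seqs)
    inputs = np.full((B, T), vocab.pad, dtype=np.int64)
    targets = np.full((B, T), vocab.pad, dtype=np.int64)
    mask = np.zeros((B, T))
    for i, s in enumerate(seqs):
        L = len(s)
        inputs[i, 0] = vocab.begin
        inputs[i, 1:L] = s[:-1]
        targets[i, :L] = s
        mask[i, :L] = 1.0
    return inputs, targets, mask


def batch_loglik(p: dict, seqs: Sequence[Sequence[int]], vocab: TokenVocabulary,
                 return_cache: bool = False):
    """log P of each sequence (END included) under the model.

    With ``return_cache`` the per-step activations are kept for backprop.
    """
    inputs, targets, mask, = _pad_batch(seqs, vocab)
    B, T = inputs.shape
    H = p["bz"].shape[0]
    h = np.zeros((B, H))
    lls = np.zeros(B)
    caches = []
    probs_list = []
    for t in range(T):
        x = p["E"][inputs[:, t]]
        h, cache = _gru_step(p, x, h)
        logits = h @ p["Wo"] + p["bo"]
        logp = _log_softmax(logits)
        lls += logp[np.arange(B), targets[:, t]] * mask[:, t]
        if return_cache:
            caches.append((cache, h))
            probs_list.append(np.exp(logp))
    if return_cache:
        return lls, (inputs, targets, mask, caches, probs_list)
    return lls


def grad_weighted_loglik(p: dict, seqs: Sequence[Sequence[int]],
                         vocab: TokenVocabulary, weights: np.ndarray):
    """Gradients of ``sum_i weights[i] * loglik_i`` w.r.t. every parameter.

    Covers NLL pre-training (weights = -1/N) and the augmented-likelihood
    RL loss (weights = -2 (augmented - agent_ll) / N).  Returns
    ``(loglik per sequence, grads dict)``.
    """
    lls, (inputs, targets, mask, caches, probs_list) = batch_loglik(
        p, seqs, vocab, return_cache=True)
    B, T = inputs.shape
    g = {k: np.zeros_like(v) for k, v in p.items()}
    dh_next = np.zeros_like(caches[0][1])
    w = weights[:, None]
    for t in range(T - 1, -1, -1):
        (x, h_prev, z, r, hbar), h = caches[t]
        probs = probs_list[t]
        # d(sum w*loglik)/dlogits = w * (onehot(target) - probs), masked
        dlogits = -probs * (w * mask[:, t:t + 1])
        dlogits[np.arange(B), targets[:, t]] += weights * mask[:, t]
        g["Wo"] += h.T @ dlogits
        g["bo"] += dlogits.sum(axis=0)
        dh = dlogits @ p["Wo"].T + dh_next

        dz = dh * (hbar - h_prev)
        dhbar = dh * z
        dh_prev = dh * (1.0 - z)

        da_h = dhbar * (1.0 - hbar ** 2)
        g["Wh"] += x.T @ da_h
        g["Uh"] += (r * h_prev).T @ da_h
        g["bh"] += da_h.sum(axis=0)
        drh = da_h @ p["Uh"].T
        dr = drh * h_prev
        dh_prev += drh * r

        da_z = dz * z * (1.0 - z)
        da_r = dr * r * (1.0 - r)
        g["Wz"] += x.T @ da_z
        g["Uz"] += h_prev.T @ da_z
        g["bz"] += da_z.sum(axis=0)
        g["Wr"] += x.T @ da_r
        g["Ur"] += h_prev.T @ da_r
        g["br"] += da_r.sum(axis=0)

        dh_prev += da_z @ p["Uz"].T + da_r @ p["Ur"].T
        dx = da_z @ p["Wz"].T + da_r @ p["Wr"].T + da_h @ p["Wh"].T
        np.add.at(g["E"], inputs[:, t], dx)
        dh_next = dh_prev
    return lls, g


class Adam:
    """Plain Adam over a parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k in params:
            gk = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk ** 2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class RNNModel:
    """GRU SMILES model: parameters + vocabulary + training metadata."""

    vocab: TokenVocabulary
    params: dict
    emb_size: int
    hidden_size: int
    max_len: int = 140
    meta: dict = field(default_factory=dict)

    def copy(self) -> "RNNModel":
        return RNNModel(self.vocab, {k: v.copy() for k, v in self.params.items()},
                        self.emb_size, self.hidden_size, self.max_len, dict(self.meta))

    def param_hash(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()

    # -- likelihoods --------------------------------------------------------
    def sequence_loglik(self, seq: Sequence[int]) -> float:
        """log P of one token sequence (must end with END); <= 0."""
        for tok in seq:
            if not 0 <= tok < len(self.vocab):
                raise ValueError(f"token index {tok} out of vocabulary")
        return float(batch_loglik(self.params, [list(seq)], self.vocab)[0])

    def batch_loglik(self, seqs: Sequence[Sequence[int]]) -> np.ndarray:
        return batch_loglik(self.params, seqs, self.vocab)

    def smiles_loglik(self, smiles: str) -> float:
        return self.sequence_loglik(self.vocab.encode(smiles))

    # -- sampling -----------------------------------------------------------
    def sample_batch(self, n: int, rng: np.random.Generator
                     ) -> List[Tuple[List[int], float]]:
        """Ancestral sampling of ``n`` sequences with their log-likelihoods.

        Each sequence ends with END or is truncated at ``max_len`` (the
        caller scores truncated, hence usually invalid, molecules as 0).
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        p, vocab = self.params, self.vocab
        H = p["bz"].shape[0]
        h = np.zeros((n, H))
        tok = np.full(n, vocab.begin, dtype=np.int64)
        done = np.zeros(n, dtype=bool)
        lls = np.zeros(n)
        seqs: List[List[int]] = [[] for _ in range(n)]
        for _ in range(self.max_len):
            x = p["E"][tok]
            h, _ = _gru_step(p, x, h)
            logits = h @ p["Wo"] + p["bo"]
            logp = _log_softmax(logits)
            probs = np.exp(logp)
            # never emit PAD or BEGIN
            probs[:, vocab.pad] = 0.0
            probs[:, vocab.begin] = 0.0
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n)
            nxt = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
            nxt = np.minimum(nxt, len(vocab) - 1)
            for i in range(n):
                if not done[i]:
                    seqs[i].append(int(nxt[i]))
                    lls[i] += logp[i, nxt[i]]
                    if nxt[i] == vocab.end:
                        done[i] = True
            if done.all():
                break
            tok = np.where(done, vocab.end, nxt)
        return [(seqs[i], float(lls[i])) for i in range(n)]

    def sample_smiles(self, n: int, rng: np.random.Generator
                      ) -> List[Tuple[str, float]]:
        return [(self.vocab.decode(s), ll) for s, ll in self.sample_batch(n, rng)]

    # -- persistence --------------------------------------------------------
    def save(self, path: str) -> None:
        meta = {"tokens": self.vocab.tokens, "emb_size": self.emb_size,
                "hidden_size": self.hidden_size, "max_len": self.max_len,
                "meta": self.meta}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            **{f"p_{k}": v for k, v in self.params.items()})

    @classmethod
    def load(cls, path: str) -> "RNNModel":
        data = np.load(path if str(path).endswith(".npz") else str(path))
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k[2:]: data[k] for k in data.files if k.startswith("p_")}
        return cls(TokenVocabulary(meta["tokens"]), params, meta["emb_size"],
                   meta["hidden_size"], meta["max_len"], meta["meta"])


# ---------------------------------------------------------------------------
# Prior training
# ---------------------------------------------------------------------------

@dataclass
class PriorHyperparams:
    emb_size: int = 64
    hidden_size: int = 128
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 5e-3
    max_len: int = 140
    holdout_fraction: float = 0.1


def train_prior(corpus: Sequence[str], hp: Optional[PriorHyperparams] = None,
                seed: int = 0) -> RNNModel:
    """Maximum-likelihood training of the Prior on a SMILES corpus.

    Returns the model with ``meta['nll_history']`` holding the held-out
    mean negative log-likelihood per token at initialization and after each
    epoch.  Fully reproducible for a fixed seed.
    """
    hp = hp or PriorHyperparams()
    corpus = [s.strip() for s in corpus if s.strip()]
    if len(corpus) < hp.batch_size:
        raise ValueError("corpus smaller than batch size")
    vocab = build_vocabulary(corpus)
    rng = np.random.default_rng(seed)
    params = init_params(len(vocab), hp.emb_size, hp.hidden_size, rng)
    model = RNNModel(vocab, params, hp.emb_size, hp.hidden_size, hp.max_len)

    seqs = [vocab.encode(s) for s in corpus]
    order = rng.permutation(len(seqs))
    n_hold = max(1, int(len(seqs) * hp.holdout_fraction))
    hold = [seqs[i] for i in order[:n_hold]]
    train = [seqs[i] for i in order[n_hold:]]

    def holdout_nll() -> float:
        total_ll, total_tok = 0.0, 0
        for i in range(0, len(hold), 256):
            chunk = hold[i:i + 256]
            total_ll += model.batch_loglik(chunk).sum()
            total_tok += sum(len(s) for s in chunk)
        return -total_ll / total_tok

    history = [holdout_nll()]
    opt = Adam(params, lr=hp.learning_rate)
    for _ in range(hp.epochs):
        perm = rng.permutation(len(train))
        for i in range(0, len(train) - hp.batch_size + 1, hp.batch_size):
            batch = [train[j] for j in perm[i:i + hp.batch_size]]
            w = np.full(len(batch), -1.0 / len(batch))  # minimize mean NLL
            _, grads = grad_weighted_loglik(params, batch, vocab, w)
            opt.step(params, grads)
        history.append(holdout_nll())
    model.meta = {"nll_history": history, "corpus_size": len(corpus),
                  "seed": seed, "epochs": hp.epochs,
                  "corpus_hash": hashlib.sha256(
                      "\n".join(corpus).encode()).hexdigest()[:16]}
    return model
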
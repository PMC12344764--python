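"""Single-step reaction predictors.

A compact attention-based encoder–decoder sequence model over SMILES
tokens, written directly in numpy with hand-derived gradients so that
training is fully deterministic, checkpointable and fast enough on one CPU
for desk-scale corpora. The architecture:

* encoder — token + position embeddings through one tanh layer, giving one
  context vector per source token;
* decoder — at each step, the previous target token's embedding, an
  absolute position embedding and the running mean of the generated prefix
  form a query that attends over the encoder states (scaled dot-product);
  the query and attention context are combined through a tanh layer and
  projected to token logits.

Decoding is k-best beam search; ensemble decoding averages the per-token
log-probabilities of two (or more) models sharing a vocabulary, the
standard NMT ensemble combiner. Retrosynthesis models read a product SMILES
and emit a dot-joined precursor set; forward models read a dot-joined,
canonically sorted precursor set and emit a product.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .chem_core import InvalidSmiles, Molecule, canonicalize, tokenize

PAD, BOS, EOS, UNK = 0, 1, 2, 3
SPECIALS = ("<pad>", "<bos>", "<eos>", "<unk>")

INADMISSIBLE_SCORE = -1.0e9


class VocabMismatch(ValueError):
    """Raised when a checkpoint and a corpus disagree on the vocabulary."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the sequence model.

    The defaults train in minutes on one CPU for toy corpora; larger values
    can be supplied for bigger corpora.
    """

    d_model: int = 64
    max_len: int = 96
    beam_size: int = 10
    lr: float = 3e-3
    batch_size: int = 16
    log_every: int = 100
    grad_clip: float = 5.0


@dataclass(frozen=True)
class Candidate:
    """One ranked decode: a precursor set (retro) or product set (forward),
    or an inadmissible flag when the decoded string is not valid SMILES."""

    rank: int
    molecules: tuple[Molecule, ...] | None
    score: float
    raw_text: str

    @property
    def admissible(self) -> bool:
        return self.molecules is not None

    @property
    def smiles_set(self) -> frozenset[str]:
        return frozenset(m.smiles for m in self.molecules) if self.molecules else frozenset()


@dataclass(frozen=True)
class PredictionSet:
    """Ranked candidate list for one target; scores are total decoder
    log-probabilities, non-increasing with rank."""

    target: Molecule
    candidates: tuple[Candidate, ...]

    def __post_init__(self) -> None:
        scores = [c.score for c in self.candidates]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("candidates must be sorted by score, descending")


def build_vocab(token_sequences: Iterable[Sequence[str]]) -> list[str]:
    """Vocabulary = specials + sorted distinct tokens of the corpus."""
    seen: set[str] = set()
    for seq in token_sequences:
        seen.update(seq)
    return list(SPECIALS) + sorted(seen)


def _init_params(vocab_size: int, cfg: ModelConfig, rng: np.random.Generator) -> dict:
    d = cfg.d_model
    scale = 0.08

    def mat(*shape):
        return (rng.standard_normal(shape) * scale).astype(np.float64)

    return {
        "E": mat(vocab_size, d),
        "Pe": mat(cfg.max_len, d),
        "Pd": mat(cfg.max_len, d),
        "W1": mat(d, d), "b1": np.zeros(d),
        "W2": mat(d, d), "b2": np.zeros(d),
        "W3": mat(2 * d, d), "b3": np.zeros(d),
        "Wo": mat(d, vocab_size), "bo": np.zeros(vocab_size),
    }


class SingleStepModel:
    """A trainable seq2seq predictor with beam-search decoding.

    ``direction`` is ``"retro"`` (product → precursors) or ``"forward"``
    (precursors → product). Prediction is deterministic given a checkpoint,
    an input and a beam width.
    """

    def __init__(
        self,
        vocab: Sequence[str],
        direction: str = "retro",
        config: ModelConfig | None = None,
        seed: int = 0,
    ) -> None:
        if direction not in ("retro", "forward"):
            raise ValueError(f"unknown direction {direction!r}")
        self.vocab = list(vocab)
        self.token_to_id = {t: i for i, t in enumerate(self.vocab)}
        self.direction = direction
        self.config = config or ModelConfig()
        self.params = _init_params(len(self.vocab), self.config, np.random.default_rng(seed))
        # Adam state travels with the checkpoint so training is resumable.
        self.opt_state = {
            "t": 0,
            "m": {k: np.zeros_like(v) for k, v in self.params.items()},
            "v": {k: np.zeros_like(v) for k, v in self.params.items()},
        }

    # ---------------------------------------------------------------- vocab

    def encode_tokens(self, tokens: Sequence[str]) -> list[int]:
        return [self.token_to_id.get(t, UNK) for t in tokens]

    def _check_vocab(self, other_vocab: Sequence[str] | None) -> None:
        if other_vocab is not None and list(other_vocab) != self.vocab:
            raise VocabMismatch("sampler vocabulary differs from checkpoint vocabulary")

    # ------------------------------------------------------------- training

    def _make_arrays(
        self, batch: Sequence[tuple[Sequence[str], Sequence[str]]]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        L = self.config.max_len
        srcs = [self.encode_tokens(s)[:L] for s, _ in batch]
        tgts = [self.encode_tokens(t)[: L - 1] for _, t in batch]
        S = max(len(s) for s in srcs)
        T = max(len(t) for t in tgts) + 1  # room for EOS
        B = len(batch)
        X = np.zeros((B, S), dtype=np.int64)
        Yin = np.zeros((B, T), dtype=np.int64)
        Yout = np.zeros((B, T), dtype=np.int64)
        mask_src = np.zeros((B, S))
        mask_tgt = np.zeros((B, T))
        for i, (s, t) in enumerate(zip(srcs, tgts)):
            X[i, : len(s)] = s
            mask_src[i, : len(s)] = 1.0
            Yin[i, 0] = BOS
            Yin[i, 1 : len(t) + 1] = t
            Yout[i, : len(t)] = t
            Yout[i, len(t)] = EOS
            mask_tgt[i, : len(t) + 1] = 1.0
        return X, Yin, Yout, mask_src, mask_tgt

    def _forward(self, X, Yin, mask_src):
        p = self.params
        d = self.config.d_model
        S, T = X.shape[1], Yin.shape[1]
        Ex = p["E"][X]
        enc_in = Ex + p["Pe"][:S]
        H = np.tanh(enc_in @ p["W1"] + p["b1"])
        Ey = p["E"][Yin]
        denom = np.arange(1, T + 1)[None, :, None]
        m = np.cumsum(Ey, axis=1) / denom
        dec_in = Ey + p["Pd"][:T] + m
        Sdec = np.tanh(dec_in @ p["W2"] + p["b2"])
        scores = np.einsum("btd,bsd->bts", Sdec, H) / np.sqrt(d)
        scores = scores + (1.0 - mask_src[:, None, :]) * -1e9
        scores -= scores.max(axis=-1, keepdims=True)
        exps = np.exp(scores)
        A = exps / exps.sum(axis=-1, keepdims=True)
        C = np.einsum("bts,bsd->btd", A, H)
        ZC = np.concatenate([Sdec, C], axis=-1)
        Z = np.tanh(ZC @ p["W3"] + p["b3"])
        logits = Z @ p["Wo"] + p["bo"]
        cache = (X, Yin, mask_src, Ex, enc_in, H, Ey, denom, dec_in, Sdec, A, C, ZC, Z)
        return logits, cache

    def _loss_and_grads(self, X, Yin, Yout, mask_src, mask_tgt):
        p = self.params
        d = self.config.d_model
        logits, cache = self._forward(X, Yin, mask_src)
        (_, _, _, Ex, enc_in, H, Ey, denom, dec_in, Sdec, A, C, ZC, Z) = cache
        B, T, V = logits.shape

        shifted = logits - logits.max(axis=-1, keepdims=True)
        logZ = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
        logp = shifted - logZ
        n_tok = mask_tgt.sum()
        picked = np.take_along_axis(logp, Yout[..., None], axis=-1)[..., 0]
        loss = -(picked * mask_tgt).sum() / n_tok

        probs = np.exp(logp)
        dlogits = probs.copy()
        np.put_along_axis(
            dlogits, Yout[..., None],
            np.take_along_axis(dlogits, Yout[..., None], axis=-1) - 1.0, axis=-1,
        )
        dlogits *= mask_tgt[..., None] / n_tok

        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Wo"] = np.einsum("btd,btv->dv", Z, dlogits)
        g["bo"] = dlogits.sum(axis=(0, 1))
        dZ = dlogits @ p["Wo"].T
        dpre3 = dZ * (1.0 - Z**2)
        g["W3"] = np.einsum("btk,btd->kd", ZC, dpre3)
        g["b3"] = dpre3.sum(axis=(0, 1))
        dZC = dpre3 @ p["W3"].T
        dSdec = dZC[..., :d].copy()
        dC = dZC[..., d:]
        dA = np.einsum("btd,bsd->bts", dC, H)
        dH = np.einsum("bts,btd->bsd", A, dC)
        dscores = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dSdec += np.einsum("bts,bsd->btd", dscores, H) / np.sqrt(d)
        dH += np.einsum("bts,btd->bsd", dscores, Sdec) / np.sqrt(d)
        dpre2 = dSdec * (1.0 - Sdec**2)
        g["W2"] = np.einsum("btd,bte->de", dec_in, dpre2)
        g["b2"] = dpre2.sum(axis=(0, 1))
        ddec_in = dpre2 @ p["W2"].T
        dEy = ddec_in.copy()
        dm = ddec_in
        dcum = dm / denom
        dEy += np.flip(np.cumsum(np.flip(dcum, axis=1), axis=1), axis=1)
        g["Pd"][: ddec_in.shape[1]] = ddec_in.sum(axis=0)
        dpre1 = dH * (1.0 - H**2)
        g["W1"] = np.einsum("bsd,bse->de", enc_in, dpre1)
        g["b1"] = dpre1.sum(axis=(0, 1))
        denc_in = dpre1 @ p["W1"].T
        g["Pe"][: denc_in.shape[1]] = denc_in.sum(axis=0)
        np.add.at(g["E"], cache[0], denc_in)
        np.add.at(g["E"], cache[1], dEy)
        return loss, g

    def _adam_step(self, grads: dict) -> None:
        cfg = self.config
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        st = self.opt_state
        st["t"] += 1
        t = st["t"]
        norm = np.sqrt(sum(float((gr**2).sum()) for gr in grads.values()))
        scale = min(1.0, cfg.grad_clip / (norm + 1e-12))
        for k, gr in grads.items():
            gr = gr * scale
            st["m"][k] = beta1 * st["m"][k] + (1 - beta1) * gr
            st["v"][k] = beta2 * st["v"][k] + (1 - beta2) * gr**2
            mhat = st["m"][k] / (1 - beta1**t)
            vhat = st["v"][k] / (1 - beta2**t)
            self.params[k] -= cfg.lr * mhat / (np.sqrt(vhat) + eps)

    def train_steps(
        self,
        batches: Iterator[Sequence[tuple[Sequence[str], Sequence[str]]]],
        n_steps: int,
        sampler_vocab: Sequence[str] | None = None,
    ) -> list[tuple[int, float]]:
        """Run exactly ``n_steps`` optimizer steps, consuming one batch per
        step. Returns the logged loss curve [(step, loss), ...]; with
        ``n_steps == 0`` the checkpoint is returned unchanged."""
        self._check_vocab(sampler_vocab)
        curve: list[tuple[int, float]] = []
        for step in range(1, n_steps + 1):
            batch = next(batches)
            X, Yin, Yout, mask_src, mask_tgt = self._make_arrays(batch)
            loss, grads = self._loss_and_grads(X, Yin, Yout, mask_src, mask_tgt)
            self._adam_step(grads)
            if step % self.config.log_every == 0 or step == n_steps:
                curve.append((step, float(loss)))
        return curve

    # ------------------------------------------------------------- decoding

    def _encode_source(self, tokens: Sequence[str]) -> np.ndarray:
        p = self.params
        ids = np.array(self.encode_tokens(tokens)[: self.config.max_len], dtype=np.int64)
        enc_in = p["E"][ids] + p["Pe"][: len(ids)]
        return np.tanh(enc_in @ p["W1"] + p["b1"])

    def _step_logprobs(self, H: np.ndarray, last: np.ndarray, esum: np.ndarray, pos: int) -> np.ndarray:
        """Next-token log-probabilities for a batch of hypotheses.

        ``last``: (n,) last token ids; ``esum``: (n, d) sum of this model's
        embeddings over the decoder prefix (including ``last``); ``pos``:
        0-based position of the last token."""
        p = self.params
        d = self.config.d_model
        ey = p["E"][last]
        m = esum / (pos + 1)
        dec_in = ey + p["Pd"][pos] + m
        s = np.tanh(dec_in @ p["W2"] + p["b2"])
        scores = (s @ H.T) / np.sqrt(d)
        scores -= scores.max(axis=-1, keepdims=True)
        expn = np.exp(scores)
        A = expn / expn.sum(axis=-1, keepdims=True)
        C = A @ H
        Z = np.tanh(np.concatenate([s, C], axis=-1) @ p["W3"] + p["b3"])
        logits = Z @ p["Wo"] + p["bo"]
        shifted = logits - logits.max(axis=-1, keepdims=True)
        return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))

    def save(self, directory: str | os.PathLike) -> None:
        """Checkpoint directory: vocab file, config snapshot, weights blob."""
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "vocab.txt"), "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.vocab) + "\n")
        with open(os.path.join(directory, "config.json"), "w", encoding="utf-8") as fh:
            json.dump({"direction": self.direction, **asdict(self.config)}, fh, indent=1)
        arrays = dict(self.params)
        arrays.update({f"m__{k}": v for k, v in self.opt_state["m"].items()})
        arrays.update({f"v__{k}": v for k, v in self.opt_state["v"].items()})
        arrays["opt_t"] = np.array([self.opt_state["t"]])
        np.savez(os.path.join(directory, "weights.npz"), **arrays)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "SingleStepModel":
        with open(os.path.join(directory, "vocab.txt"), encoding="utf-8") as fh:
            vocab = [line.rstrip("\n") for line in fh if line.rstrip("\n")]
        with open(os.path.join(directory, "config.json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        direction = meta.pop("direction")
        model = cls(vocab, direction=direction, config=ModelConfig(**meta))
        with np.load(os.path.join(directory, "weights.npz")) as blob:
            for k in model.params:
                model.params[k] = blob[k].copy()
                model.opt_state["m"][k] = blob[f"m__{k}"].copy()
                model.opt_state["v"][k] = blob[f"v__{k}"].copy()
            model.opt_state["t"] = int(blob["opt_t"][0])
        return model

    def copy(self) -> "SingleStepModel":
        clone = SingleStepModel(self.vocab, self.direction, self.config)
        clone.params = {k: v.copy() for k, v in self.params.items()}
        clone.opt_state = {
            "t": self.opt_state["t"],
            "m": {k: v.copy() for k, v in self.opt_state["m"].items()},
            "v": {k: v.copy() for k, v in self.opt_state["v"].items()},
        }
        return clone

    # public prediction API ------------------------------------------------

    def predict(self, product: Molecule, k: int = 5) -> PredictionSet:
        """Top-k precursor-set candidates for a product (retro direction)."""
        if self.direction != "retro":
            raise ValueError("predict requires a retro-direction model")
        return _decode([self], product, tokenize(product.smiles).tokens, k)

    def forward_predict(self, precursors: Sequence[Molecule], k: int = 1) -> PredictionSet:
        """Top-k product candidates for a precursor set (forward direction)."""
        if self.direction != "forward":
            raise ValueError("forward_predict requires a forward-direction model")
        if not precursors:
            raise ValueError("empty precursor list")
        src = source_for_precursors(precursors)
        pseudo_target = Molecule(sorted(m.smiles for m in precursors)[0])
        return _decode([self], pseudo_target, tokenize(src).tokens, k)


def source_for_precursors(precursors: Sequence[Molecule]) -> str:
    """Forward-model source: dot-joined, canonically sorted precursor set."""
    return ".".join(sorted(m.smiles for m in precursors))


def ensemble_predict(
    model_a: SingleStepModel, model_b: SingleStepModel, product: Molecule, k: int = 5
) -> PredictionSet:
    """Joint beam search where each step's token log-probability is the
    arithmetic mean of the two models' log-probabilities (geometric mean of
    the probabilities)."""
    if model_a.vocab != model_b.vocab:
        raise VocabMismatch("ensemble members must share a vocabulary")
    if model_a.direction != "retro" or model_b.direction != "retro":
        raise ValueError("ensemble_predict requires retro-direction models")
    return _decode([model_a, model_b], product, tokenize(product.smiles).tokens, k)


def _decode(
    models: Sequence[SingleStepModel],
    target: Molecule,
    src_tokens: Sequence[str],
    k: int,
) -> PredictionSet:
    cfg = models[0].config
    beam = max(cfg.beam_size, k)
    max_len = cfg.max_len
    Hs = [m._encode_source(src_tokens) for m in models]

    # live hypotheses: token id lists (starting at BOS), per-model embedding
    # prefix sums, accumulated log-probability
    tokens: list[list[int]] = [[BOS]]
    esums = [np.stack([m.params["E"][BOS]]) for m in models]
    logps = np.zeros(1)
    finished: dict[str, float] = {}

    for pos in range(max_len - 1):
        last = np.array([t[-1] for t in tokens], dtype=np.int64)
        step_lp = np.mean(
            [m._step_logprobs(H, last, es, pos) for m, H, es in zip(models, Hs, esums)],
            axis=0,
        )
        total = logps[:, None] + step_lp  # (n, V)
        flat = total.ravel()
        n_take = min(beam, flat.size)
        # deterministic: sort by (-score, hypothesis index, token id)
        top = np.argsort(-flat, kind="stable")[: max(4 * beam, n_take)]
        new_tokens: list[list[int]] = []
        new_esums: list[list[np.ndarray]] = [[] for _ in models]
        new_logps: list[float] = []
        for idx in top:
            hyp, tok = divmod(int(idx), step_lp.shape[1])
            if tok in (PAD, BOS):
                continue
            score = float(flat[idx])
            if tok == EOS:
                text = _ids_to_text(models[0], tokens[hyp][1:])
                if text not in finished or score > finished[text]:
                    finished[text] = score
                continue
            if len(new_logps) < beam:
                new_tokens.append(tokens[hyp] + [tok])
                for mi, m in enumerate(models):
                    new_esums[mi].append(esums[mi][hyp] + m.params["E"][tok])
                new_logps.append(score)
        if not new_tokens or (
            len(finished) >= beam
            and new_logps
            and max(new_logps) < min(sorted(finished.values(), reverse=True)[:beam])
        ):
            break
        tokens = new_tokens
        esums = [np.stack(es) for es in new_esums]
        logps = np.array(new_logps)

    ranked = sorted(finished.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    candidates: list[Candidate] = []
    for rank, (text, score) in enumerate(ranked, start=1):
        candidates.append(_make_candidate(rank, text, score))
    while len(candidates) < k:
        candidates.append(
            Candidate(rank=len(candidates) + 1, molecules=None,
                      score=INADMISSIBLE_SCORE, raw_text="")
        )
    return PredictionSet(target=target, candidates=tuple(candidates))


def _ids_to_text(model: SingleStepModel, ids: Sequence[int]) -> str:
    return "".join(model.vocab[i] for i in ids)


def _make_candidate(rank: int, text: str, score: float) -> Candidate:
    try:
        mols = tuple(
            Molecule(canonicalize(part)) for part in text.split(".") if part
        )
        if not mols:
            raise InvalidSmiles(text)
    except InvalidSmiles:
        return Candidate(rank=rank, molecules=None, score=score, raw_text=text)
    return Candidate(rank=rank, molecules=mols, score=score, raw_text=text)


# ----------------------------------------------------------------- corpora


def reaction_to_pair(rec, direction: str = "retro") -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Tokenized (source, target) pair for one reaction record.

    Retro: product SMILES → dot-joined reactant set. Forward: dot-joined
    sorted reactant set → product SMILES. Reagents never appear in targets.
    """
    product = rec.main_product.smiles
    reactants = ".".join(sorted(m.smiles for m in rec.reactants))
    if direction == "retro":
        src, tgt = product, reactants
    else:
        src, tgt = reactants, product
    return tokenize(src).tokens, tokenize(tgt).tokens


def predictions_to_jsonl(prediction_sets: Sequence[PredictionSet], path) -> None:
    """JSON Lines predictions file: one object per target."""
    with open(path, "w", encoding="utf-8") as fh:
        for ps in prediction_sets:
            obj = {
                "target": ps.target.smiles,
                "candidates": [
                    {
                        "rank": c.rank,
                        "smiles": ".".join(sorted(c.smiles_set)) if c.admissible else None,
                        "score": c.score,
                        "admissible": c.admissible,
                    }
                    for c in ps.candidates
                ],
            }
            fh.write(json.dumps(obj) + "\n")
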
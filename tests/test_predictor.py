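"""Sequence model: gradients, training contracts, beam search, ensembles."""

import numpy as np
import pytest

import hetretro as hr
from hetretro.predictor import (
    ModelConfig,
    SingleStepModel,
    build_vocab,
    ensemble_predict,
    reaction_to_pair,
)

TOY_VOCAB = ["<pad>", "<bos>", "<eos>", "<unk>", "a", "b", "c"]


def _const_batches(pairs, seed=0, batch_size=16):
    rng = np.random.default_rng(seed)

    def gen():
        while True:
            idx = rng.choice(len(pairs), size=batch_size)
            yield [pairs[i] for i in idx]

    return gen()


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        cfg = ModelConfig(d_model=6, max_len=12)
        m = SingleStepModel(TOY_VOCAB, "retro", cfg, seed=0)
        batch = [(("a", "b", "c"), ("b", "a")), (("c", "c"), ("a", "b", "b"))]
        arrays = m._make_arrays(batch)
        _, grads = m._loss_and_grads(*arrays)
        eps = 1e-6
        rng = np.random.default_rng(0)
        for name, P in m.params.items():
            flat_idx = rng.choice(P.size, size=min(5, P.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, P.shape)
                orig = P[idx]
                P[idx] = orig + eps
                lp, _ = m._loss_and_grads(*arrays)
                P[idx] = orig - eps
                lm, _ = m._loss_and_grads(*arrays)
                P[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[name][idx]
                assert abs(numeric - analytic) <= 1e-4 * max(1.0, abs(numeric)), name


class TestTraining:
    def test_zero_steps_leaves_checkpoint_unchanged(self):
        m = SingleStepModel(TOY_VOCAB, "retro", ModelConfig(d_model=8), seed=1)
        before = {k: v.copy() for k, v in m.params.items()}
        m.train_steps(iter([]), 0)
        assert all(np.array_equal(before[k], m.params[k]) for k in before)

    def test_seeded_training_is_bitwise_deterministic(self):
        pairs = [(("a", "b"), ("b",)), (("c",), ("a", "c"))]
        curves = []
        for _ in range(2):
            m = SingleStepModel(TOY_VOCAB, "retro", ModelConfig(d_model=8, log_every=5), seed=2)
            curves.append(m.train_steps(_const_batches(pairs, seed=4), 20))
        assert curves[0] == curves[1]

    def test_vocab_mismatch_raises(self):
        m = SingleStepModel(TOY_VOCAB, "retro", ModelConfig(d_model=8))
        with pytest.raises(hr.VocabMismatch):
            m.train_steps(iter([]), 0, sampler_vocab=TOY_VOCAB + ["d"])

    def test_memorizes_fifty_pairs(self, universe):
        records = universe.corpora["general_like"][:50]
        pairs = [reaction_to_pair(rec) for rec in records]
        vocab = build_vocab(tok for pair in pairs for tok in pair)
        m = SingleStepModel(vocab, "retro", ModelConfig(d_model=64, beam_size=5), seed=0)
        m.train_steps(_const_batches(pairs), 1000)
        hits = sum(
            m.predict(rec.main_product, k=1).candidates[0].smiles_set == rec.reactant_smiles
            for rec in records
        )
        assert hits / len(records) >= 0.95

    def test_resumable_from_checkpoint(self, tmp_path):
        pairs = [(("a", "b"), ("b",)), (("c",), ("a", "c"))]
        m = SingleStepModel(TOY_VOCAB, "retro", ModelConfig(d_model=8, log_every=1), seed=5)
        m.train_steps(_const_batches(pairs, seed=6), 10)
        m.save(tmp_path / "ckpt")
        resumed = SingleStepModel.load(tmp_path / "ckpt")
        c1 = m.train_steps(_const_batches(pairs, seed=7), 5)
        c2 = resumed.train_steps(_const_batches(pairs, seed=7), 5)
        assert c1 == c2


class TestDecoding:
    def test_scores_non_increasing(self, trained_tiny_model, tiny_universe):
        for rec in tiny_universe.corpora["general_like"][:10]:
            ps = trained_tiny_model.predict(rec.main_product, k=5)
            scores = [c.score for c in ps.candidates]
            assert scores == sorted(scores, reverse=True)
            assert [c.rank for c in ps.candidates] == [1, 2, 3, 4, 5]

    def test_rank1_stable_across_k(self, trained_tiny_model, tiny_universe):
        rec = tiny_universe.corpora["general_like"][0]
        one = trained_tiny_model.predict(rec.main_product, k=1)
        five = trained_tiny_model.predict(rec.main_product, k=5)
        assert one.candidates[0].raw_text == five.candidates[0].raw_text
        assert one.candidates[0].score == pytest.approx(five.candidates[0].score)

    def test_garbage_decodes_flagged_not_dropped(self):
        # an untrained model on a nonsense vocabulary emits non-SMILES text
        m = SingleStepModel(["<pad>", "<bos>", "<eos>", "<unk>", "!", "?"],
                            "retro", ModelConfig(d_model=8, beam_size=4), seed=0)
        ps = m.predict(hr.Molecule.from_smiles("CCO"), k=4)
        assert len(ps.candidates) == 4
        assert all(not c.admissible for c in ps.candidates)

    def test_save_load_reproduces_predictions(self, trained_tiny_model, tiny_universe, tmp_path):
        trained_tiny_model.save(tmp_path / "m")
        loaded = SingleStepModel.load(tmp_path / "m")
        for rec in tiny_universe.corpora["general_like"][:5]:
            a = trained_tiny_model.predict(rec.main_product, k=3)
            b = loaded.predict(rec.main_product, k=3)
            assert [(c.raw_text, c.score) for c in a.candidates] == [
                (c.raw_text, c.score) for c in b.candidates
            ]

    def test_deterministic_across_calls(self, trained_tiny_model, tiny_universe):
        rec = tiny_universe.corpora["general_like"][1]
        a = trained_tiny_model.predict(rec.main_product, k=3)
        b = trained_tiny_model.predict(rec.main_product, k=3)
        assert [(c.raw_text, c.score) for c in a.candidates] == [
            (c.raw_text, c.score) for c in b.candidates
        ]


class TestForward:
    def test_forward_requires_precursors(self, trained_tiny_model):
        fwd = SingleStepModel(trained_tiny_model.vocab, "forward", ModelConfig(d_model=8))
        with pytest.raises(ValueError):
            fwd.forward_predict([], k=1)

    def test_direction_enforced(self, trained_tiny_model):
        with pytest.raises(ValueError):
            trained_tiny_model.forward_predict([hr.Molecule.from_smiles("CCO")], k=1)


class TestEnsemble:
    def test_identical_members_reproduce_single_model(self, trained_tiny_model, tiny_universe):
        for rec in tiny_universe.corpora["general_like"][:10]:
            single = trained_tiny_model.predict(rec.main_product, k=5)
            joint = ensemble_predict(
                trained_tiny_model, trained_tiny_model, rec.main_product, k=5
            )
            assert [c.raw_text for c in single.candidates] == [
                c.raw_text for c in joint.candidates
            ]
            for cs, cj in zip(single.candidates, joint.candidates):
                assert cs.score == pytest.approx(cj.score, abs=1e-9)

    def test_vocab_mismatch(self, trained_tiny_model):
        other = SingleStepModel(TOY_VOCAB, "retro", ModelConfig(d_model=8))
        with pytest.raises(hr.VocabMismatch):
            ensemble_predict(trained_tiny_model, other, hr.Molecule.from_smiles("CCO"), k=1)

    def test_mean_log_probability_combiner(self):
        # two models with different weights: ensemble step scores are the
        # arithmetic mean of the members' log-probabilities
        a = SingleStepModel(TOY_VOCAB, "retro", ModelConfig(d_model=8, beam_size=3), seed=1)
        b = SingleStepModel(TOY_VOCAB, "retro", ModelConfig(d_model=8, beam_size=3), seed=2)
        src = ("a", "b")
        Ha, Hb = a._encode_source(src), b._encode_source(src)
        last = np.array([1])  # BOS
        esa = a.params["E"][last].copy()
        esb = b.params["E"][last].copy()
        la = a._step_logprobs(Ha, last, esa, 0)
        lb = b._step_logprobs(Hb, last, esb, 0)
        mean = (la + lb) / 2.0
        assert np.all(mean <= np.maximum(la, lb) + 1e-12)
        assert np.all(mean >= np.minimum(la, lb) - 1e-12)
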
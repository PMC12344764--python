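"""Evaluation metrics: reactant accuracy, round-trip family, invariants."""

import pytest

import hetretro as hr
from hetretro.metrics import MetricsConfig, is_ring_breaking
from hetretro.predictor import Candidate, INADMISSIBLE_SCORE, PredictionSet


def _cand(rank, smiles, score=-1.0):
    if smiles is None:
        return Candidate(rank=rank, molecules=None, score=INADMISSIBLE_SCORE, raw_text="??")
    mols = tuple(hr.Molecule.from_smiles(s) for s in smiles.split("."))
    return Candidate(rank=rank, molecules=mols, score=score, raw_text=smiles)


def _pset(target_smiles, *cands):
    return PredictionSet(target=hr.Molecule.from_smiles(target_smiles), candidates=tuple(cands))


class StubForward:
    """Forward model stub: sorted precursor set -> product SMILES."""

    direction = "forward"

    def __init__(self, table):
        self.table = {
            tuple(sorted(hr.canonicalize(x) for x in k.split("."))): hr.canonicalize(v)
            for k, v in table.items()
        }

    def forward_predict(self, precursors, k=1):
        key = tuple(sorted(m.smiles for m in precursors))
        product = self.table.get(key)
        if product is None:
            cands = (Candidate(rank=1, molecules=None, score=INADMISSIBLE_SCORE, raw_text=""),)
        else:
            cands = (_cand(1, product, 0.0),)
        return PredictionSet(target=precursors[0], candidates=cands)


class TestReactantMatch:
    TRUTH = hr.parse_reaction("Nc1ccccc1N.OC=O>>c1ccc2[nH]cnc2c1")

    def test_exact_set_any_order(self):
        assert hr.reactant_match(_cand(1, "OC=O.Nc1ccccc1N"), self.TRUTH)

    def test_extra_molecule_still_matches(self):
        assert hr.reactant_match(_cand(1, "Nc1ccccc1N.OC=O.CCO"), self.TRUTH)

    def test_missing_reactant_fails(self):
        assert not hr.reactant_match(_cand(1, "Nc1ccccc1N"), self.TRUTH)

    def test_inadmissible_fails(self):
        assert not hr.reactant_match(_cand(1, None), self.TRUTH)


class TestTopN:
    def test_all_rank1_correct(self):
        truths = [hr.parse_reaction("CCO.CC(=O)O>>CCOC(C)=O")] * 3
        preds = [_pset("CCOC(C)=O", _cand(1, "CCO.CC(=O)O")) for _ in range(3)]
        for n in (1, 3, 5):
            assert hr.topn_reactant_accuracy(preds, truths, n) == 1.0

    def test_correct_only_at_rank_three(self):
        truth = hr.parse_reaction("CCO.CC(=O)O>>CCOC(C)=O")
        ps = _pset(
            "CCOC(C)=O",
            _cand(1, "CCO", -0.1),
            _cand(2, "CCN", -0.2),
            _cand(3, "CCO.CC(=O)O", -0.3),
        )
        assert hr.topn_reactant_accuracy([ps], [truth], 1) == 0.0
        assert hr.topn_reactant_accuracy([ps], [truth], 3) == 1.0

    def test_empty_test_set_is_an_error(self):
        with pytest.raises(ValueError):
            hr.topn_reactant_accuracy([], [], 1)

    def test_misalignment_is_an_error(self):
        truth = hr.parse_reaction("CCO.CC(=O)O>>CCOC(C)=O")
        with pytest.raises(ValueError):
            hr.topn_reactant_accuracy([], [truth], 1)


class TestRoundTrip:
    FWD = StubForward({"Nc1ccccc1N.OC=O": "c1ccc2[nH]cnc2c1",
                       "CCO.CC(=O)O": "CCOC(C)=O"})

    def test_true_when_forward_regenerates_target(self):
        cand = _cand(1, "Nc1ccccc1N.OC=O")
        assert hr.round_trip_ok(cand, hr.Molecule.from_smiles("c1ccc2[nH]cnc2c1"), self.FWD)

    def test_inadmissible_is_false(self):
        assert not hr.round_trip_ok(
            _cand(1, None), hr.Molecule.from_smiles("c1ccc2[nH]cnc2c1"), self.FWD
        )

    def test_wrong_product_is_false(self):
        cand = _cand(1, "CCO.CC(=O)O")
        assert not hr.round_trip_ok(cand, hr.Molecule.from_smiles("c1ccc2[nH]cnc2c1"), self.FWD)

    def test_ring_breaking_benzimidazole(self):
        # target 2 rings, precursors 1 + 0: valid ring-breaking disconnection
        cand = _cand(1, "Nc1ccccc1N.OC=O")
        target = hr.Molecule.from_smiles("c1ccc2[nH]cnc2c1")
        assert hr.ring_breaking_round_trip_ok(cand, target, self.FWD)

    def test_equal_ring_count_is_not_ring_breaking(self):
        cand = _cand(1, "CCO.CC(=O)O")
        target = hr.Molecule.from_smiles("CCOC(C)=O")
        assert hr.round_trip_ok(cand, target, self.FWD)
        assert not hr.ring_breaking_round_trip_ok(cand, target, self.FWD)

    def test_ring_breaking_but_forward_disagrees(self):
        fwd = StubForward({})
        cand = _cand(1, "Nc1ccccc1N.OC=O")
        target = hr.Molecule.from_smiles("c1ccc2[nH]cnc2c1")
        assert is_ring_breaking(cand, target)
        assert not hr.ring_breaking_round_trip_ok(cand, target, fwd)

    def test_sum_vs_max_precursor_ring_convention(self):
        # two single-ring precursors, two-ring target: sum says not
        # ring-breaking (2 > 2 false), max says it is (2 > 1)
        cand = _cand(1, "c1ccccc1.c1ccncc1")
        target = hr.Molecule.from_smiles("c1ccc2[nH]cnc2c1")
        assert not is_ring_breaking(cand, target, comparison="sum")
        assert is_ring_breaking(cand, target, comparison="max")


class TestEvaluate:
    def _four_target_fixture(self):
        fwd = StubForward({
            "Nc1ccccc1N.OC=O": "c1ccc2[nH]cnc2c1",
            "CCO.CC(=O)O": "CCOC(C)=O",
            "OCc1ccccc1": "O=Cc1ccccc1",
        })
        truths = [
            hr.parse_reaction("Nc1ccccc1N.OC=O>>c1ccc2[nH]cnc2c1"),
            hr.parse_reaction("CCO.CC(=O)O>>CCOC(C)=O"),
            hr.parse_reaction("ClC(Cl)c1ccccc1.O>>O=Cc1ccccc1"),  # truth: hydrolysis
            hr.parse_reaction("CC(C)O.CC(=O)O>>CC(C)OC(C)=O"),
        ]
        preds = [
            # 1: exact truth; round-trip; ring-breaking (2 rings from 1+0)
            _pset("c1ccc2[nH]cnc2c1", _cand(1, "Nc1ccccc1N.OC=O")),
            # 2: exact truth; round-trip; not ring-breaking
            _pset("CCOC(C)=O", _cand(1, "CCO.CC(=O)O")),
            # 3: differs from truth but round-trip-accurate (oxidation route)
            _pset("O=Cc1ccccc1", _cand(1, "OCc1ccccc1")),
            # 4: inadmissible decode
            _pset("CC(C)OC(C)=O", _cand(1, None)),
        ]
        return preds, truths, fwd

    def test_hand_traced_four_target_fixture(self):
        # at N=1: reactant accuracy 2/4, round-trip 3/4, ring-breaking 1/4,
        # inadmissible 1/4
        preds, truths, fwd = self._four_target_fixture()
        report = hr.evaluate(preds, truths, fwd, MetricsConfig(ns=(1,)))
        vals = report.per_n[1]
        assert vals["reactant_accuracy"] == 0.5
        assert vals["round_trip"] == 0.75
        assert vals["ring_breaking_round_trip"] == 0.25
        assert vals["inadmissible"] == 0.25

    def test_all_inadmissible(self):
        truths = [hr.parse_reaction("CCO.CC(=O)O>>CCOC(C)=O")] * 2
        preds = [_pset("CCOC(C)=O", _cand(1, None)) for _ in range(2)]
        report = hr.evaluate(preds, truths, StubForward({}), MetricsConfig(ns=(1,)))
        vals = report.per_n[1]
        assert vals["reactant_accuracy"] == 0.0
        assert vals["inadmissible"] == 1.0
        assert vals["round_trip"] == 0.0

    def test_oracle_closure_on_ring_test_split(self, universe):
        retro, fwd = hr.oracle_retro(universe), hr.oracle_forward(universe)
        spec = hr.SplitSpec(fractions=(0.9, 0.05, 0.05), mode="random", seed=1)
        _, _, test = hr.random_split(universe.corpora["ring_like"], spec)
        preds = [retro.predict(rec.main_product, k=1) for rec in test]
        report = hr.evaluate(preds, test, fwd, MetricsConfig(ns=(1,)))
        vals = report.per_n[1]
        assert vals["reactant_accuracy"] == 1.0
        assert vals["round_trip"] == 1.0
        assert vals["ring_breaking_round_trip"] == 1.0
        assert vals["inadmissible"] == 0.0

    def test_metric_inequalities(self, universe):
        retro, fwd = hr.oracle_retro(universe), hr.oracle_forward(universe)
        test = universe.corpora["ring_like"][:30]
        preds = [retro.predict(rec.main_product, k=5) for rec in test]
        report = hr.evaluate(preds, test, fwd)
        accs = [report.per_n[n]["reactant_accuracy"] for n in (1, 3, 5)]
        assert accs == sorted(accs)
        for n, vals in report.per_n.items():
            assert vals["ring_breaking_round_trip"] <= vals["round_trip"]
            assert vals["round_trip"] <= 1.0 - vals["inadmissible"] + 1e-12

    def test_report_serialization(self, tmp_path):
        preds, truths, fwd = self._four_target_fixture()
        report = hr.evaluate(preds, truths, fwd)
        text = report.to_json(tmp_path / "report.json")
        assert '"conventions"' in text
        assert (tmp_path / "report.json").exists()
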
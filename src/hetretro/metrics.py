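"""Evaluation metrics for single-step retrosynthesis models.

Four metrics per top-N cut (N ∈ {1, 3, 5} by default):

* **reactant accuracy** — fraction of targets for which some candidate in
  ranks 1..N contains *all* ground-truth reactants (extra predicted
  molecules are permitted; reagents are ignored);
* **round-trip accuracy** — proportion of candidates in ranks 1..N, pooled
  across targets, for which a forward model regenerates the target from the
  predicted precursors ("chemical validity");
* **ring-breaking round-trip accuracy** — round-trip-accurate candidates
  whose target has more rings than the predicted precursors, i.e. valid
  predictions that actually disconnect a ring;
* **inadmissible rate** — proportion of candidates in ranks 1..N that are
  not parseable SMILES.

Reactant accuracy follows the usual truth-within-top-N convention; the
round-trip family is a pooled proportion over all candidates at ranks 1..N
(so top-5 round-trip can be lower than top-1). Both conventions are
reported and labeled; a pooled variant of reactant accuracy is included for
completeness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .chem_core import Molecule, ReactionRecord
from .predictor import Candidate, PredictionSet, SingleStepModel


@dataclass(frozen=True)
class MetricsConfig:
    ns: tuple[int, ...] = (1, 3, 5)
    forward_top_f: int = 1
    ring_comparison: str = "sum"  # or "max": reading of "more rings than the precursors"
    stereo_sensitive: bool = True


@dataclass
class MetricsReport:
    """Per-N metrics for one model × test set."""

    n_targets: int
    per_n: dict[int, dict[str, float]]
    conventions: dict[str, str] = field(
        default_factory=lambda: {
            "reactant_accuracy": "truth-within-top-N",
            "reactant_accuracy_pooled": "pooled proportion over ranks 1..N",
            "round_trip": "pooled proportion over ranks 1..N",
            "ring_breaking_round_trip": "pooled proportion over ranks 1..N",
            "inadmissible": "pooled proportion over ranks 1..N",
        }
    )

    def to_json(self, path=None) -> str:
        obj = {
            "n_targets": self.n_targets,
            "per_n": {str(n): vals for n, vals in self.per_n.items()},
            "conventions": self.conventions,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def _strip_stereo(smiles: str) -> str:
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def _match_key(smiles: str, stereo_sensitive: bool) -> str:
    return smiles if stereo_sensitive else _strip_stereo(smiles)


def reactant_match(
    candidate: Candidate, truth: ReactionRecord, stereo_sensitive: bool = True
) -> bool:
    """True iff every ground-truth reactant is among the predicted molecules.

    Extra predicted molecules (e.g. a co-reagent the model emits) do not
    hurt; inadmissible candidates never match.
    """
    if not candidate.admissible:
        return False
    predicted = {_match_key(s, stereo_sensitive) for s in candidate.smiles_set}
    needed = {_match_key(s, stereo_sensitive) for s in truth.reactant_smiles}
    return needed <= predicted


def topn_reactant_accuracy(
    predictions: Sequence[PredictionSet],
    truths: Sequence[ReactionRecord],
    n: int,
    stereo_sensitive: bool = True,
) -> float:
    """Fraction of targets with ≥1 reactant match among ranks 1..n."""
    if len(predictions) != len(truths):
        raise ValueError(
            f"predictions ({len(predictions)}) and truths ({len(truths)}) misaligned"
        )
    if not predictions:
        raise ValueError("empty test set")
    hits = 0
    for ps, truth in zip(predictions, truths):
        if any(
            reactant_match(c, truth, stereo_sensitive) for c in ps.candidates[:n]
        ):
            hits += 1
    return hits / len(predictions)


def round_trip_ok(
    candidate: Candidate,
    target: Molecule,
    forward_model: SingleStepModel,
    top_f: int = 1,
    stereo_sensitive: bool = True,
    _cache: dict | None = None,
) -> bool:
    """True iff the candidate is admissible and the forward model's top-F
    products for its precursors include the target."""
    if not candidate.admissible:
        return False
    key = tuple(sorted(candidate.smiles_set))
    if _cache is not None and key in _cache:
        products = _cache[key]
    else:
        pred = forward_model.forward_predict(candidate.molecules, k=top_f)
        products = {
            s
            for c in pred.candidates[:top_f]
            if c.admissible
            for s in c.smiles_set
        }
        if _cache is not None:
            _cache[key] = products
    want = _match_key(target.smiles, stereo_sensitive)
    return want in {_match_key(s, stereo_sensitive) for s in products}


def _precursor_ring_count(candidate: Candidate, comparison: str) -> int:
    counts = [m.ring_count for m in candidate.molecules]
    return max(counts) if comparison == "max" else sum(counts)


def is_ring_breaking(candidate: Candidate, target: Molecule, comparison: str = "sum") -> bool:
    if not candidate.admissible:
        return False
    return target.ring_count > _precursor_ring_count(candidate, comparison)


def ring_breaking_round_trip_ok(
    candidate: Candidate,
    target: Molecule,
    forward_model: SingleStepModel,
    top_f: int = 1,
    ring_comparison: str = "sum",
    stereo_sensitive: bool = True,
    _cache: dict | None = None,
) -> bool:
    """Round-trip-accurate AND the target has more rings than the predicted
    precursors (the disconnection actually breaks a ring)."""
    return is_ring_breaking(candidate, target, ring_comparison) and round_trip_ok(
        candidate, target, forward_model, top_f, stereo_sensitive, _cache
    )


def evaluate(
    predictions: Sequence[PredictionSet],
    truths: Sequence[ReactionRecord],
    forward_model: SingleStepModel | None,
    config: MetricsConfig | None = None,
) -> MetricsReport:
    """Compute the full metrics report.

    ``forward_model`` may be None, in which case the round-trip family is
    reported as 0 (only reactant accuracy and inadmissible rate are
    meaningful without a forward instrument).
    """
    config = config or MetricsConfig()
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths misaligned")
    if not predictions:
        raise ValueError("empty test set")
    cache: dict = {}
    per_n: dict[int, dict[str, float]] = {}
    for n in config.ns:
        pooled_total = 0
        pooled_inadmissible = 0
        pooled_rt = 0
        pooled_rb_rt = 0
        pooled_reactant = 0
        for ps, truth in zip(predictions, truths):
            for cand in ps.candidates[:n]:
                pooled_total += 1
                if not cand.admissible:
                    pooled_inadmissible += 1
                    continue
                if reactant_match(cand, truth, config.stereo_sensitive):
                    pooled_reactant += 1
                if forward_model is not None and round_trip_ok(
                    cand, ps.target, forward_model, config.forward_top_f,
                    config.stereo_sensitive, cache,
                ):
                    pooled_rt += 1
                    if is_ring_breaking(cand, ps.target, config.ring_comparison):
                        pooled_rb_rt += 1
        per_n[n] = {
            "reactant_accuracy": topn_reactant_accuracy(
                predictions, truths, n, config.stereo_sensitive
            ),
            "reactant_accuracy_pooled": pooled_reactant / pooled_total,
            "round_trip": pooled_rt / pooled_total,
            "ring_breaking_round_trip": pooled_rb_rt / pooled_total,
            "inadmissible": pooled_inadmissible / pooled_total,
        }
    return MetricsReport(n_targets=len(predictions), per_n=per_n)
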
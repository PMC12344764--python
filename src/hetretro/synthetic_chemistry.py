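"""A deterministic toy reaction universe.

Generates a self-consistent miniature of the corpora a heterocycle
retrosynthesis study works with: a majority corpus of acyclic
transformations (``general_like``), a minority corpus of heterocycle
formations (``ring_like``), a small held-out-template corpus
(``recent_like``), multistep routes terminating in a stock set, and exact
retro/forward oracles over everything generated.

Templates are string-rewriting rules over attachment-point fragments with
post-hoc validity checking through the cheminformatics layer — the
generator's job is structural realism of the corpora (ring census,
role structure, vocabulary sharing), not mechanistic realism. Every
emitted reaction parses, canonicalizes, and satisfies the corpus's ring
properties; instances that fail any check are resampled with a bounded
retry count.

The ``recent_like`` corpus uses templates held out from ``ring_like``, so
a model trained on ``ring_like`` alone cannot reproduce its reactions —
mirroring how a corpus of newly published chemistry behaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chem_core import Molecule, ReactionRecord, parse_reaction, write_rsmi
from .curation import is_heterocycle_forming
from .metrics import topn_reactant_accuracy
from .predictor import (
    Candidate,
    INADMISSIBLE_SCORE,
    ModelConfig,
    PredictionSet,
    SingleStepModel,
    build_vocab,
    reaction_to_pair,
)
from .schedules import CorpusSpec, MixSchedule, WeightedCorpusSampler
from .splitting import SplitSpec, random_split


class GenerationError(RuntimeError):
    """A template could not produce a valid, novel instance within the
    retry budget."""


# Substituent fragments; attachment is always at the fragment's first
# written atom (templates paste fragments as suffixes or parenthesised
# branches, never as prefixes, so the attachment point is unambiguous).
ALKYL = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "CC(C)C", "CCC(C)C", "CC(C)(C)C",
    "CCCCC", "CCOC", "CCF", "CC(F)(F)F",
)
ARYL = (
    "c1ccccc1", "c1ccc(C)cc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1",
    "c1ccc(OC)cc1", "c1ccc(CC)cc1", "c1ccc(Br)cc1", "c1ccc(C(C)C)cc1",
    "c1ccc(SC)cc1", "c1ccc(OC(C)C)cc1", "c1cc(C)cc(C)c1", "c1ccc(CCC)cc1",
)
SUBSTITUENTS = ALKYL + ARYL


@dataclass(frozen=True)
class ToyTemplate:
    """A forward transform: substituent tuple → (reactants, product)."""

    name: str
    arity: int
    build: Callable[..., tuple[list[str], str]]
    ring_forming: bool
    hetero_forming: bool


def _ester(r1, r2):
    return [f"OC(=O){r1}", f"OC{r2}"], f"C(=O)(OC{r2}){r1}"


def _amide(r1, r2):
    return [f"OC(=O){r1}", f"NC{r2}"], f"C(=O)(NC{r2}){r1}"


def _ether(r1, r2):
    return [f"OC{r1}", f"BrC{r2}"], f"C(OC{r2}){r1}"


def _amination(r1, r2):
    return [f"NC{r1}", f"BrC{r2}"], f"C(NC{r1}){r2}"


def _oxidation(r1):
    return [f"OC{r1}", "OO"], f"O=C{r1}"


def _bromination(r1):
    return [f"CC(=O){r1}", "BrBr"], f"BrCC(=O){r1}"


def _triazole(r1, r2):
    return [f"C(N=[N+]=[N-]){r1}", f"C#C{r2}"], f"C(n8cc({r2})nn8){r1}"


def _benzimidazole(r1):
    return [f"O=C{r1}", "Nc1ccccc1N"], f"c8({r1})nc9ccccc9[nH]8"


def _pyrazole(r1, r2):
    # the 1,3-diketone is symmetric under r1/r2 exchange while the
    # tautomer-fixed pyrazole SMILES is not; a canonical substituent order
    # keeps the forward map (precursors -> product) single-valued
    r1, r2 = sorted((r1, r2))
    return ["NN", f"C(=O)(CC(=O){r2}){r1}"], f"c8({r1})cc({r2})[nH]n8"


def _thiazole(r1, r2):
    return [f"C(N)(=S){r1}", f"O=C({r2})CBr"], f"c8({r1})nc({r2})cs8"


def _pyrrole(r1, r2, r3):
    return [f"C(=O)(CCC(=O){r2}){r1}", f"NC{r3}"], f"c8({r1})ccc({r2})n8C{r3}"


def _quinoxaline(r1, r2):
    return [f"C(=O)(C(=O){r2}){r1}", "Nc1ccccc1N"], f"c8({r1})nc9ccccc9nc8{r2}"


ACYCLIC_TEMPLATES = (
    ToyTemplate("esterification", 2, _ester, False, False),
    ToyTemplate("amide_coupling", 2, _amide, False, False),
    ToyTemplate("ether_formation", 2, _ether, False, False),
    ToyTemplate("n_alkylation", 2, _amination, False, False),
    ToyTemplate("alcohol_oxidation", 1, _oxidation, False, False),
    ToyTemplate("alpha_bromination", 1, _bromination, False, False),
)
RING_TEMPLATES = (
    ToyTemplate("azide_alkyne_triazole", 2, _triazole, True, True),
    ToyTemplate("benzimidazole_condensation", 1, _benzimidazole, True, True),
    ToyTemplate("pyrazole_condensation", 2, _pyrazole, True, True),
    ToyTemplate("hantzsch_thiazole", 2, _thiazole, True, True),
)
RECENT_TEMPLATES = (
    ToyTemplate("paal_knorr_pyrrole", 3, _pyrrole, True, True),
    ToyTemplate("quinoxaline_condensation", 2, _quinoxaline, True, True),
)


@dataclass(frozen=True)
class RegistryEntry:
    """One known disconnection: product ← precursor set, with a search cost
    (−log pseudo-probability) and template provenance."""

    product: str
    precursors: tuple[str, ...]
    cost: float
    template: str


@dataclass(frozen=True)
class RouteSpec:
    """A generated multistep route: steps ordered leaves-first."""

    target: str
    steps: tuple[RegistryEntry, ...]

    @property
    def leaves(self) -> frozenset[str]:
        produced = {s.product for s in self.steps}
        used: set[str] = set()
        for s in self.steps:
            used.update(s.precursors)
        return frozenset(used - produced)

    @property
    def total_cost(self) -> float:
        return sum(s.cost for s in self.steps)


@dataclass(frozen=True)
class UniverseSizes:
    n_general: int = 500
    n_ring: int = 200
    n_recent: int = 50
    n_blocks: int = 100
    n_multistep_targets: int = 20


@dataclass
class ToyUniverse:
    seed: int
    sizes: UniverseSizes
    corpora: dict[str, list[ReactionRecord]]
    routes: list[RouteSpec]
    registry: dict[str, list[RegistryEntry]]
    forward_registry: dict[tuple[str, ...], list[RegistryEntry]]
    building_blocks: list[str]

    def write(self, outdir) -> None:
        """Emit .rsmi corpora, stock.smi, and the route registry as JSON."""
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, records in self.corpora.items():
            write_rsmi(records, outdir / f"{name}.rsmi")
        with open(outdir / "stock.smi", "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.building_blocks) + "\n")
        routes_obj = [
            {
                "target": r.target,
                "steps": [
                    {
                        "product": s.product,
                        "precursors": list(s.precursors),
                        "cost": s.cost,
                        "template": s.template,
                    }
                    for s in r.steps
                ],
            }
            for r in self.routes
        ]
        with open(outdir / "routes.json", "w", encoding="utf-8") as fh:
            json.dump(routes_obj, fh, indent=1)


def _record_from_strings(
    reactants: Sequence[str], product: str, corpus: str, source: str
) -> ReactionRecord:
    line = ".".join(reactants) + ">>" + product
    return parse_reaction(line, source=source, corpus=corpus)


def _instantiate(
    template: ToyTemplate, rng: np.random.Generator
) -> tuple[list[str], str]:
    subs = [SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))] for _ in range(template.arity)]
    return template.build(*subs)


def _fill_corpus(
    templates: Sequence[ToyTemplate],
    n: int,
    corpus: str,
    rng: np.random.Generator,
    seen_keys: set,
    require_hetero: bool,
    max_tries_per_record: int = 200,
) -> list[ReactionRecord]:
    records: list[ReactionRecord] = []
    while len(records) < n:
        for _ in range(max_tries_per_record):
            template = templates[rng.integers(len(templates))]
            reactants, product = _instantiate(template, rng)
            try:
                rec = _record_from_strings(
                    reactants, product, "synthetic", f"template:{template.name}"
                )
            except ValueError:
                continue
            if rec.key in seen_keys:
                continue
            if is_heterocycle_forming(rec) != require_hetero:
                continue
            seen_keys.add(rec.key)
            records.append(rec)
            break
        else:
            raise GenerationError(
                f"could not draw a fresh valid instance for corpus {corpus!r} "
                f"after {max_tries_per_record} tries ({len(records)}/{n} done)"
            )
    return records


def _canonical_pair(reactants: Sequence[str], product: str) -> tuple[tuple[str, ...], str]:
    rec = _record_from_strings(reactants, product, "synthetic", "")
    return tuple(sorted(rec.reactant_smiles)), rec.main_product.smiles


def _azole_alkylation(azole_product: str, r3: str) -> tuple[list[str], str]:
    # N-alkylate the azole NH of a generated ring product.
    assert "[nH]" in azole_product
    return [azole_product, f"BrC{r3}"], azole_product.replace("[nH]", f"n(C{r3})", 1)


def _make_route(
    kind: int, rng: np.random.Generator
) -> tuple[list[tuple[list[str], str, str]], str]:
    """Return ([(reactants, product, template_name), ...] leaves-first, target)."""
    r = lambda: SUBSTITUENTS[rng.integers(len(SUBSTITUENTS))]
    if kind == 0:  # ketone -> alpha-bromoketone -> thiazole (2 steps)
        r1, r2 = r(), r()
        s1_reactants, bromoketone = _bromination(r2)
        s2_reactants, thiazole = _thiazole(r1, r2)
        steps = [
            (s1_reactants, bromoketone, "alpha_bromination"),
            (s2_reactants, thiazole, "hantzsch_thiazole"),
        ]
        return steps, thiazole
    if kind == 1:  # alcohol -> aldehyde -> benzimidazole (2 steps)
        r1 = r()
        s1_reactants, aldehyde = _oxidation(r1)
        s2_reactants, benz = _benzimidazole(r1)
        return (
            [(s1_reactants, aldehyde, "alcohol_oxidation"),
             (s2_reactants, benz, "benzimidazole_condensation")],
            benz,
        )
    if kind == 2:  # alcohol -> aldehyde -> benzimidazole -> N-alkyl (3 steps)
        r1, r3 = r(), r()
        s1_reactants, aldehyde = _oxidation(r1)
        s2_reactants, benz = _benzimidazole(r1)
        s3_reactants, alk = _azole_alkylation(benz, r3)
        return (
            [(s1_reactants, aldehyde, "alcohol_oxidation"),
             (s2_reactants, benz, "benzimidazole_condensation"),
             (s3_reactants, alk, "azole_n_alkylation")],
            alk,
        )
    # kind == 3: pyrazole -> N-alkyl pyrazole (2 steps)
    r1, r2, r3 = r(), r(), r()
    s1_reactants, pyz = _pyrazole(r1, r2)
    s2_reactants, alk = _azole_alkylation(pyz, r3)
    return (
        [(s1_reactants, pyz, "pyrazole_condensation"),
         (s2_reactants, alk, "azole_n_alkylation")],
        alk,
    )


def generate_universe(seed: int, sizes: UniverseSizes | None = None) -> ToyUniverse:
    """Build the full toy universe, reproducibly from ``seed``.

    Corpora are disjoint in (reactant set, product) keys; every
    ``ring_like`` record forms a new hetero ring and no ``general_like``
    record does; every route's leaves end up in the stock set.
    """
    sizes = sizes or UniverseSizes()
    rng = np.random.default_rng(seed)
    seen_keys: set = set()
    corpora = {
        "general_like": _fill_corpus(
            ACYCLIC_TEMPLATES, sizes.n_general, "general_like", rng, seen_keys, False
        ),
        "ring_like": _fill_corpus(
            RING_TEMPLATES, sizes.n_ring, "ring_like", rng, seen_keys, True
        ),
        "recent_like": _fill_corpus(
            RECENT_TEMPLATES, sizes.n_recent, "recent_like", rng, seen_keys, True
        ),
    }

    # Registry of known disconnections: every corpus record, every route
    # step, plus a single-step "shortcut" from each multistep target
    # straight to its leaves — so searches have genuine alternatives and a
    # well-defined minimum cost.
    registry: dict[str, list[RegistryEntry]] = {}
    forward_registry: dict[tuple[str, ...], list[RegistryEntry]] = {}

    def register(reactant_set: tuple[str, ...], product: str, cost: float, template: str):
        entry = RegistryEntry(product=product, precursors=reactant_set, cost=cost, template=template)
        bucket = registry.setdefault(product, [])
        if any(e.precursors == reactant_set for e in bucket):
            return bucket
        bucket.append(entry)
        forward_registry.setdefault(reactant_set, []).append(entry)
        return bucket

    def step_cost() -> float:
        return float(rng.uniform(0.5, 2.0))

    for records in corpora.values():
        for rec in records:
            register(tuple(sorted(rec.reactant_smiles)), rec.main_product.smiles,
                     step_cost(), rec.source.removeprefix("template:"))

    routes: list[RouteSpec] = []
    route_targets: set[str] = set()
    tries = 0
    while len(routes) < sizes.n_multistep_targets:
        tries += 1
        if tries > 200 * sizes.n_multistep_targets:
            raise GenerationError("could not generate enough distinct multistep targets")
        kind = int(rng.integers(4))
        raw_steps, _ = _make_route(kind, rng)
        entries: list[RegistryEntry] = []
        for reactants, product, template in raw_steps:
            rset, prod = _canonical_pair(reactants, product)
            bucket = registry.get(prod, [])
            existing = next((e for e in bucket if e.precursors == rset), None)
            if existing is None:
                register(rset, prod, step_cost(), template)
                existing = registry[prod][-1]
            entries.append(existing)
        target = entries[-1].product
        if target in route_targets:
            continue
        route = RouteSpec(target=target, steps=tuple(entries))
        # a more expensive (usually) one-shot shortcut to the leaves
        shortcut_cost = route.total_cost + float(rng.uniform(-0.5, 1.5))
        register(tuple(sorted(route.leaves)), target, max(0.1, shortcut_cost), "shortcut")
        routes.append(route)
        route_targets.add(target)

    produced = set(registry.keys())
    used: set[str] = set()
    for bucket in registry.values():
        for entry in bucket:
            used.update(entry.precursors)
    building_blocks = sorted(used - produced)

    return ToyUniverse(
        seed=seed,
        sizes=sizes,
        corpora=corpora,
        routes=routes,
        registry=registry,
        forward_registry=forward_registry,
        building_blocks=building_blocks,
    )


# ------------------------------------------------------------------ oracles


class _RegistryPredictor:
    """Exact predictor backed by the universe registry (score = −cost)."""

    def __init__(self, lookup: dict, direction: str):
        self.direction = direction
        self._lookup = lookup

    def _key(self, query) -> object:
        if self.direction == "retro":
            return query.smiles
        return tuple(sorted(m.smiles for m in query))

    def _target_molecule(self, query) -> Molecule:
        if self.direction == "retro":
            return query
        return Molecule(sorted(m.smiles for m in query)[0])

    def _candidate_molecules(self, entry: RegistryEntry) -> tuple[Molecule, ...]:
        if self.direction == "retro":
            return tuple(Molecule(s) for s in entry.precursors)
        return (Molecule(entry.product),)

    def predict(self, molecule: Molecule, k: int = 5) -> PredictionSet:
        if self.direction != "retro":
            raise ValueError("predict requires the retro oracle")
        return self._predict(molecule, k)

    def forward_predict(self, precursors: Sequence[Molecule], k: int = 1) -> PredictionSet:
        if self.direction != "forward":
            raise ValueError("forward_predict requires the forward oracle")
        if not precursors:
            raise ValueError("empty precursor list")
        return self._predict(precursors, k)

    def _predict(self, query, k: int) -> PredictionSet:
        entries = sorted(
            self._lookup.get(self._key(query), []), key=lambda e: (e.cost, e.precursors)
        )
        candidates: list[Candidate] = []
        for rank, entry in enumerate(entries[:k], start=1):
            mols = self._candidate_molecules(entry)
            candidates.append(
                Candidate(rank=rank, molecules=mols, score=-entry.cost,
                          raw_text=".".join(m.smiles for m in mols))
            )
        while len(candidates) < k:
            candidates.append(
                Candidate(rank=len(candidates) + 1, molecules=None,
                          score=INADMISSIBLE_SCORE, raw_text="")
            )
        return PredictionSet(target=self._target_molecule(query), candidates=tuple(candidates))


def oracle_retro(universe: ToyUniverse) -> _RegistryPredictor:
    """Ground-truth single-step retro policy: inverts the registry; unknown
    molecules yield a single inadmissible candidate."""
    return _RegistryPredictor(universe.registry, "retro")


def oracle_forward(universe: ToyUniverse) -> _RegistryPredictor:
    """Ground-truth forward model keyed by sorted precursor sets."""
    return _RegistryPredictor(universe.forward_registry, "forward")


# -------------------------------------------------- forgetting experiment


@dataclass(frozen=True)
class ForgettingConfig:
    """Desk-scale training protocol for the retention comparison."""

    model: ModelConfig = field(default_factory=lambda: ModelConfig(d_model=96, beam_size=5))
    baseline_steps: int = 1200
    finetune_steps: int = 600
    batch_size: int = 24
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    eval_k: int = 1


def _train_on(
    model: SingleStepModel,
    corpora: Sequence[tuple[str, Sequence[ReactionRecord], float]],
    n_steps: int,
    batch_size: int,
    seed: int,
) -> SingleStepModel:
    schedule = MixSchedule(
        kind="custom" if len(corpora) > 1 else "baseline",
        corpora=tuple(
            CorpusSpec(name=name, path=f"memory:{name}", weight=w)
            for name, _, w in corpora
        ),
        n_steps=n_steps,
        seed=seed,
    )
    sampler = WeightedCorpusSampler(
        schedule, records_by_corpus=[records for _, records, _ in corpora]
    )
    model.train_steps(sampler.batches(batch_size), n_steps)
    return model


def _top1_accuracy(model: SingleStepModel, test: Sequence[ReactionRecord], k: int) -> float:
    preds = [model.predict(rec.main_product, k=k) for rec in test]
    return topn_reactant_accuracy(preds, test, 1)


def forgetting_experiment(
    universe: ToyUniverse,
    config: ForgettingConfig | None = None,
    seeds: Sequence[int] = (0, 1, 2),
) -> pd.DataFrame:
    """Train baseline / fine-tuned / mixed fine-tuned models per seed and
    measure top-1 reactant accuracy on the general and ring test splits.

    Returns a tidy frame (seed, model, test_set, top1_reactant_accuracy);
    the expected retention pattern is: fine-tuning wins on ring chemistry
    but loses the general chemistry it started from, while the 1:1 mixed
    fine-tune largely keeps both.
    """
    config = config or ForgettingConfig()
    general = universe.corpora["general_like"]
    ring = universe.corpora["ring_like"]
    vocab = build_vocab(
        tok
        for rec in general + ring
        for tok in reaction_to_pair(rec)
    )
    rows = []
    for seed in seeds:
        spec = SplitSpec(fractions=config.split_fractions, mode="random", seed=seed)
        g_train, _, g_test = random_split(general, spec)
        r_train, _, r_test = random_split(ring, spec)

        baseline = SingleStepModel(vocab, "retro", config.model, seed=seed)
        _train_on(baseline, [("general", g_train, 1.0)],
                  config.baseline_steps, config.batch_size, seed)
        finetuned = _train_on(
            baseline.copy(), [("ring", r_train, 1.0)],
            config.finetune_steps, config.batch_size, seed + 1000,
        )
        mixed = _train_on(
            baseline.copy(), [("general", g_train, 1.0), ("ring", r_train, 1.0)],
            config.finetune_steps, config.batch_size, seed + 2000,
        )
        for model_name, model in (
            ("baseline", baseline), ("finetuned", finetuned), ("mixed_finetuned", mixed)
        ):
            for set_name, test in (("general", g_test), ("ring", r_test)):
                rows.append(
                    {
                        "seed": seed,
                        "model": model_name,
                        "test_set": set_name,
                        "top1_reactant_accuracy": _top1_accuracy(model, test, config.eval_k),
                    }
                )
    return pd.DataFrame(rows)


def summarize_forgetting(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd of top-1 accuracy per (model, test_set) over seeds."""
    return (
        table.groupby(["model", "test_set"])["top1_reactant_accuracy"]
        .agg(["mean", "std"])
        .reset_index()
    )
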
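# hetretro

Transfer learning for heterocycle retrosynthesis, at desk scale.

Single-step template-free retrosynthesis models are trained on broad patent
chemistry and are notoriously reluctant to propose **ring-breaking
disconnections** — exactly the step that matters when the target's core is a
freshly formed heterocycle. The standard remedy is transfer learning: curate
a corpus of ring-formation reactions and adapt a general-domain seq2seq
model to it. `hetretro` packages that whole workflow as a reusable,
CPU-friendly toolkit for method developers:

* **Curation** — mine heterocycle-forming reactions out of raw
  reaction-SMILES files. A reaction qualifies when a product carries an
  SSSR ring containing N/O/S whose canonical ring skeleton appears in no
  reactant. Every rejected line is logged with a reason code.
* **Splitting** — product-similarity splits (Morgan fingerprints,
  single-linkage clusters at a Tanimoto threshold, whole clusters assigned
  to train/valid/test, default 90:5:5) so near-identical products never
  leak across partitions; seeded random splits for controls.
* **Predictors** — a compact attention-based encoder–decoder over SMILES
  tokens (pure numpy, hand-derived gradients, Adam, checkpointable and
  bitwise-reproducible), with k-best beam search and two-model ensemble
  decoding that averages per-token log-probabilities.
* **Schedules** — the transfer-learning regimes as declarative recipes:
  `baseline`, `ring_only`, `finetune` (6000 steps from the baseline
  checkpoint), `multitask` (General:Ring = 9:1), `mixed_finetune`
  (General:Ring = 1:1, 6000 steps) and `further_finetune`
  (General:Ring:Recent = 4:4:1, 6000 steps), realized as weighted
  per-example corpus sampling.
* **Metrics** — top-N reactant accuracy, round-trip accuracy (a forward
  model must regenerate the target from the predicted precursors),
  **ring-breaking round-trip accuracy** (round-trip-accurate *and* the
  target has more rings than the predicted precursors), and the
  inadmissible-prediction rate.
* **Multistep search** — Retro*-style best-first AND/OR planning over a
  stock set, with an admissible zero heuristic by default (minimum-cost
  routes within the expanded graph) and per-path protection-loop blocking.
* **Synthetic universe** — a deterministic generator of toy corpora
  (majority acyclic chemistry, minority heterocycle formations, held-out
  "recent" templates), multistep routes with a stock set, and exact
  retro/forward oracles, so every component is testable end to end without
  proprietary reaction data.

## Worked example

```python
import hetretro as hr

# a toy universe: 500 general reactions, 200 heterocycle formations
uni = hr.generate_universe(seed=7, sizes=hr.UniverseSizes(500, 200, 50, 100, 20))

# curate a raw stream: accepts exactly the heterocycle formations
lines = [rec.serialize() for rec in uni.corpora["ring_like"][:5]] + ["CCO.CC(=O)O>>CCOC(C)=O"]
result = hr.curate_lines(lines)
print(len(result.accepted), result.reason_counts)
# 5 {'not_ring_forming': 1}

# evaluate the exact oracles on the ring test split
spec = hr.SplitSpec(fractions=(0.9, 0.05, 0.05), mode="random", seed=3)
_, _, test = hr.random_split(uni.corpora["ring_like"], spec)
retro, fwd = hr.oracle_retro(uni), hr.oracle_forward(uni)
preds = [retro.predict(r.main_product, k=1) for r in test]
report = hr.evaluate(preds, test, fwd)
print({k: round(v, 3) for k, v in report.per_n[1].items()})
# {'reactant_accuracy': 1.0, 'reactant_accuracy_pooled': 1.0,
#  'round_trip': 1.0, 'ring_breaking_round_trip': 1.0, 'inadmissible': 0.0}

# plan a 2-step synthesis down to stock
stock = hr.StockSet(uni.building_blocks, canonical=True)
route = hr.plan(hr.Molecule(uni.routes[0].target), retro, stock)
print(len(route.steps), round(route.total_cost, 3))
# 3 3.456
```

A perfect single-step policy closes the loop on every metric (the 1.0s
above), and the planner recovers the registered multistep routes at their
minimum cost — the baselines every learned model in the package is measured
against. The same flows are available from the shell via the `hetretro`
CLI (`simulate`, `curate`, `split`, `train`, `predict`, `evaluate`,
`search`).

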
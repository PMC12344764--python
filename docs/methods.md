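# Methods

## Problem setting

Given a target molecule, single-step retrosynthesis proposes ranked sets of
precursor molecules; multistep planning chains such proposals until every
leaf is purchasable. Models trained on broad patent chemistry under-predict
ring-forming disconnections, so adapting them to a curated corpus of
heterocycle formations — without forgetting general chemistry — is the
central methodological problem this package operationalizes. All components
work at desk scale on a synthetic reaction universe, so the mechanisms
(curation rules, split hygiene, weighted-corpus schedules, metrics, search)
can be verified exactly rather than approximately.

## Molecule and reaction layer

Molecule identity is the RDKit canonical SMILES string; all set comparisons
downstream are string-set comparisons. Ring counting uses the true smallest
set of smallest rings (`GetSSSR`), which equals the cyclomatic number
`bonds − atoms + components`; RDKit's symmetrized ring info would
over-count fused cages. A *heterocycle signature* is the canonical SMILES
of one SSSR ring's bare skeleton — elements, aromatic flags and bond orders
only, hydrogens and substituents stripped. Stripping hydrogens matters:
with H counts retained, N-alkylating a pyrazole would spuriously change the
ring key from `c1cn[nH]c1`-like to `c1cnnc1`-like and the reaction would be
mis-curated as heterocycle-forming. The skeleton form is invariant to
substitution while still separating isomeric ring systems (imidazole vs
pyrazole).

A reaction is **ring-forming** when the maximum SSSR count over products
exceeds the summed count over reactants, and **heterocycle-forming** when
some product carries a hetero-ring signature found in no reactant. The
latter is the curation criterion; the former is the evaluation-side
ring-breaking test run in reverse. They deliberately do not imply one
another (a hetero ring can form while a carbocycle opens).

Tokenization is the standard atom-level SMILES scheme (bracket atoms,
two-letter halogens and `%nn` ring closures as single tokens); any unknown
character becomes a one-character token so tokenization is total and
lossless, and validity is judged only by canonicalization.

## Curation

Pipeline: parse → validity filters → heterocycle-formation test →
deduplication on (canonical reactant set, canonical product set), reagents
excluded from the key. Element whitelist
(H,C,N,O,S,P,F,Cl,Br,I,B,Si) and product heavy-atom bounds (5–70) are
configuration, not constants, because published curation pipelines rarely
agree on them; the defaults cover routine medicinal chemistry.
Multi-product reactions keep the largest product (heavy-atom count, ties by
canonical string) — seq2seq training wants single-product pairs.
Carbocycle-only formations and reactions forming no ring at all get
distinct rejection codes (`not_heterocycle_forming` vs `not_ring_forming`)
so a curation log can be audited line by line. Accepted + rejected always
equals the parsed line count.

## Splitting

Similarity mode embeds each unique product as a Morgan fingerprint
(radius 2, 2048 bits), single-links products at Tanimoto ≥ 0.6 into
clusters, and assigns whole clusters to train/valid/test by greedy deficit
fill in a seeded random cluster order. Records sharing a product — or
connected through a chain of similar products — can therefore never
straddle partitions, which is the property a product-similarity split
exists to guarantee. The 0.6 threshold is a configuration default, not a
claim about any external pipeline. Random mode is a seeded shuffle with
largest-remainder slicing (ties to the earlier partition), so `n = 100` at
80:10:10 is exactly 80/10/10 and a single record lands in train.

## Sequence model

The single-step predictor is a compact encoder–decoder written directly in
numpy with hand-derived gradients (verified against finite differences in
the test suite):

* encoder: token + absolute position embeddings through one tanh layer,
  one state per source token;
* decoder step *t*: the previous target token's embedding, the position
  embedding, and the running mean of the decoded prefix form a query;
  scaled dot-product attention over the encoder states yields a context;
  query ⊕ context pass through a tanh layer and a linear projection to
  token logits.

Training is step-based (not epoch-based) with Adam (lr 3e-3, β = 0.9/0.999,
global-norm clip 5), mean cross-entropy over non-pad positions. The Adam
state travels with the checkpoint, so training is resumable and a resumed
run reproduces the original loss curve bit for bit. Defaults (width 64–96,
batch 16–24) train in minutes on one CPU at toy-corpus sizes and are all
overridable for larger corpora.

Decoding is k-best beam search (beam = max(configured beam, k), default
beam 10). Finished hypotheses are deduplicated by decoded text keeping the
best score; final ranking is by (score, then lexicographic text) for
determinism. Candidates whose text fails canonicalization are kept and
flagged inadmissible — they are counted by the metrics, never silently
dropped — and prediction sets are padded to exactly k entries. Ensemble
decoding runs the same beam over the arithmetic mean of the member models'
per-token log-probabilities (the geometric mean of their distributions, the
standard NMT combiner); with identical members it reproduces single-model
rankings exactly, which the tests assert.

Retro sources are the product SMILES alone; targets are the dot-joined,
canonically sorted reactant set. Reagents never appear in targets. Forward
models read the sorted precursor set and emit the product.

## Training schedules

A schedule is pure data: corpora with positive weights, a step count, an
optional initial checkpoint, a seed. Weights are realized as per-example
sampling probabilities (w_i/Σw) with per-epoch reshuffling inside each
corpus — not corpus duplication — so the batch stream is a deterministic
function of the schedule and 10,000 draws at 9:1 or 1:1 sit inside the 99%
binomial interval of the nominal proportion. The six standard recipes:
baseline (general, fresh), ring-only (ring, fresh), fine-tune (ring, from
baseline, 6000 steps), multitask (9:1, fresh), mixed fine-tune (1:1, from
baseline, 6000 steps), further fine-tune (4:4:1
general:ring:recent, from the mixed checkpoint, 6000 steps). Fine-tuning
continues with the optimizer state unchanged; resetting it is a flag,
off by default, since continued-training semantics are the conservative
reading. Multitask runs the baseline step budget unless overridden.

## Metrics

Reactant accuracy is truth-within-top-N: a target scores when some
candidate at rank ≤ N contains **all** ground-truth reactants (extra
predicted molecules allowed, reagents ignored). The round-trip family —
round-trip, ring-breaking round-trip, inadmissible — is a pooled proportion
over *all* candidates at ranks 1..N across targets, so its top-5 value can
legitimately sit below top-1. Both conventions are computed, labeled in the
report, and a pooled variant of reactant accuracy is included so no
convention question is left implicit. Ring-breaking compares the target's
SSSR count against the **sum** over predicted precursors (the stricter,
disconnection-true reading; max is available by configuration). The forward
instrument checks the target against its top-1 product by default
(configurable top-F). Matching is stereo-sensitive by default with a
config flag to relax. By construction
`ring_breaking_round_trip ≤ round_trip ≤ 1 − inadmissible` at every N.

## Multistep search

Best-first AND/OR search in the style of Retro*: molecule nodes are OR
(any disconnection solves them), reaction nodes are AND (every precursor
must be solved), reaction cost is the negative decoder log-probability.
The frontier molecule node minimizing (accumulated path cost + value
estimate) is expanded with the model's top-k candidates. The default value
estimate is zero — admissible, hence the returned route is minimum-cost
among all routes discoverable in the expanded graph (the tests verify this
against exhaustive enumeration); a constant `depth_penalty` mode trades
that guarantee for goal-directedness. A learned value network is out of
scope. Loop prevention is per path: a reaction regenerating any ancestor
of the expanded node is discarded, which blocks protection/deprotection
cycles. Search stops when no open node's bound can beat the best solved
route, or on budget exhaustion; failures return diagnostics (expansions
used, frontier size), not exceptions. Ties break by insertion order.

## Synthetic universe

The generator emulates the *structure* of the real corpora, not their
chemistry. Six acyclic templates (esterification, amide coupling, ether
formation, N-alkylation, alcohol oxidation, α-bromination) populate the
majority corpus; four heterocycle templates (azide–alkyne triazole,
benzimidazole condensation, pyrazole condensation, Hantzsch thiazole) the
ring corpus; two held-out templates (Paal–Knorr pyrrole, quinoxaline
condensation) the "recent" corpus, so a ring-trained model scores zero on
it by construction. Templates are string rewrites over attachment-point
fragments (24 alkyl/aryl substituents, attachment always at the fragment's
first atom) validated post hoc through the molecule layer; instances that
fail to parse, collide with an existing (reactants, product) key, or
violate the corpus's ring property are resampled with a bounded retry.
Default sizes — 500 general, 200 ring, 50 recent, 20 multistep targets —
are the package's study conditions: large enough for the small model to
separate the corpora, small enough to train on one CPU in minutes.

Multistep routes chain 2–3 templates (bromination→thiazole,
oxidation→benzimidazole(→N-alkylation), pyrazole→N-alkylation); each step
gets a cost drawn from U(0.5, 2), and each target additionally registers a
single-step "shortcut" to its leaves at a perturbed cost so the planner
faces genuine alternatives with a well-defined optimum. The stock set is
every registry reactant that is never produced by any registered reaction,
which guarantees route leaves are purchasable and intermediates are not.
Exact oracles invert the registry (retro: product → precursor sets ranked
by cost; forward: sorted precursor set → product); unknown queries return
a single inadmissible candidate.

What the toy universe does **not** reproduce: real reaction-class frequency
distributions, reagent/condition annotation, stereochemistry-rich targets,
atom-mapping noise, or products with several plausible literature
disconnections. Green tests therefore certify the machinery — corpus
handling, calibration, metric arithmetic, search optimality, the
retention *pattern* — not real-data accuracy levels.

## Retention (catastrophic forgetting) experiment

Per seed: random 80:10:10 splits of the general and ring corpora; a
baseline model (width 96) trained 1200 steps on general-train; a fine-tuned
variant (600 further steps, ring only) and a mixed fine-tuned variant
(600 further steps, 1:1 general:ring), both continuing from the baseline
checkpoint. All three are scored by top-1 reactant accuracy on both test
splits, over three seeds. The asserted pattern is qualitative and per seed:
fine-tuning is at least as good as the baseline on ring chemistry, and
mixed fine-tuning retains at least as much general chemistry as plain
fine-tuning — together with a non-triviality floor (baseline-on-general and
fine-tuned-on-ring both above 5%) so the pattern cannot hold vacuously.
Step counts and widths were chosen so the full three-seed experiment runs
in minutes on one CPU; absolute accuracies at this scale are not
comparable to models trained on real corpora and are reported only as the
experiment's measured output.

## Numerical and degenerate-input choices

* Candidate ties in beam search: lexicographic on decoded text; cluster
  and partition ties: earlier index; search priority ties: insertion order.
* Empty test sets raise errors rather than returning NaN.
* `n_steps = 0` is a valid no-op that leaves a checkpoint unchanged.
* Inadmissible candidates carry a sentinel score of −1e9 (JSON-safe).
* Fractions must sum to 1 within 1e−9; corpus weights must be positive.
* Seeds feed `numpy.random.default_rng` exclusively; all reported
  quantities are deterministic given (seed, inputs).

## Known limitations

The sequence model is deliberately small; it demonstrates mechanism, not
state-of-the-art accuracy. The toy grammar's retro task is easier than real
retrosynthesis (systematic canonical-form rewrites), so accuracy numbers on
it overstate what the same architecture would achieve on patent data. The
similarity split is single-linkage at a fixed threshold, not a learned or
time-aware split. Round-trip accuracy inherits the forward model's errors —
a correct prediction can be scored invalid if the forward instrument
disagrees — which is an acknowledged property of the metric family, not a
bug in its implementation.
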
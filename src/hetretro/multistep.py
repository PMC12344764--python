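"""Multistep route planning: best-first AND/OR search over single-step
predictions, in the style of Retro*.

A molecule node is solved by ANY of its candidate reactions (OR); a
reaction node requires ALL of its precursors to be solved (AND). Search
expands the open molecule node with the smallest lower bound on the total
cost of a route through it — accumulated reaction cost along its path plus
a value estimate for the node itself — where a reaction's cost is the
negative decoder log-probability of the single-step candidate that proposed
it. With the zero value estimate the bound is admissible, so the returned
route is the minimum-cost route discoverable within the expanded graph.

Loops are prevented per path: a reaction is discarded if it regenerates any
ancestor of the molecule being expanded (this blocks the
protection/deprotection cycles that plague sequence models in multistep
search).
"""

from __future__ import annotations

import heapq
import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .chem_core import Molecule, canonicalize
from .predictor import PredictionSet, SingleStepModel

INFINITY = float("inf")


class StockSet:
    """Purchasable molecules, indexed by canonical SMILES."""

    def __init__(self, smiles: Sequence[str], source: str = "", canonical: bool = False):
        if canonical:
            self._set = frozenset(smiles)
        else:
            self._set = frozenset(canonicalize(s) for s in smiles)
        self.source = source

    @classmethod
    def from_file(cls, path) -> "StockSet":
        with open(path, encoding="utf-8") as fh:
            smiles = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
        return cls(smiles, source=str(path))

    def __contains__(self, mol: Molecule | str) -> bool:
        return (mol.smiles if isinstance(mol, Molecule) else mol) in self._set

    def __len__(self) -> int:
        return len(self._set)

    def __iter__(self):
        return iter(sorted(self._set))


@dataclass(frozen=True)
class SearchBudget:
    max_expansions: int = 500
    k_per_expansion: int = 5
    max_depth: int = 10

    def __post_init__(self) -> None:
        if self.max_expansions <= 0 or self.k_per_expansion <= 0 or self.max_depth <= 0:
            raise ValueError("budget fields must be positive")


@dataclass(frozen=True)
class RouteStep:
    product: str
    precursors: tuple[str, ...]
    rank: int
    cost: float


@dataclass
class Route:
    """A solved synthesis route: steps ordered leaves-first (every step's
    product is a precursor of a later step, or the final target); every
    leaf molecule is in stock."""

    target: str
    steps: list[RouteStep]
    leaves: list[str]
    total_cost: float

    def to_json(self, path=None) -> str:
        obj = {
            "target": self.target,
            "total_cost": self.total_cost,
            "steps": [
                {
                    "product": s.product,
                    "precursors": list(s.precursors),
                    "rank": s.rank,
                    "cost": s.cost,
                }
                for s in self.steps
            ],
            "leaves": self.leaves,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


@dataclass
class SearchFailure:
    """Diagnostics for an unsolved search (a result, not an exception)."""

    target: str
    expansions_used: int
    frontier_size: int
    best_partial: list[RouteStep] = field(default_factory=list)


def value_estimate(
    mol: Molecule | str, stock: StockSet, mode: str = "zero", penalty: float = 1.0
) -> float:
    """Lower-bound estimate of the cost to solve ``mol``.

    ``zero`` (default) returns 0 for everything — uniform-cost search,
    admissible, hence optimal within the expanded graph. ``depth_penalty``
    charges a constant per unsolved non-stock molecule, trading optimality
    for goal-directedness."""
    if mol in stock:
        return 0.0
    if mode == "zero":
        return 0.0
    if mode == "depth_penalty":
        return penalty
    raise ValueError(f"unknown value estimate mode {mode!r}")


class _MolNode:
    __slots__ = ("smiles", "depth", "parent_rxn", "children", "expanded", "uid")

    def __init__(self, smiles: str, depth: int, parent_rxn, uid: int):
        self.smiles = smiles
        self.depth = depth
        self.parent_rxn = parent_rxn  # _RxnNode or None for the root
        self.children: list[_RxnNode] = []
        self.expanded = False
        self.uid = uid


class _RxnNode:
    __slots__ = ("parent", "precursors", "cost", "rank")

    def __init__(self, parent: _MolNode, cost: float, rank: int):
        self.parent = parent
        self.precursors: list[_MolNode] = []
        self.cost = cost
        self.rank = rank


def _ancestors(node: _MolNode) -> set[str]:
    out = set()
    cur = node
    while cur is not None:
        out.add(cur.smiles)
        cur = cur.parent_rxn.parent if cur.parent_rxn is not None else None
    return out


def _path_cost(node: _MolNode) -> float:
    cost = 0.0
    cur = node
    while cur.parent_rxn is not None:
        cost += cur.parent_rxn.cost
        cur = cur.parent_rxn.parent
    return cost


def _solved_value(node: _MolNode, stock: StockSet) -> float:
    """Min cost to solve ``node`` using only expanded, fully solved
    subtrees; INFINITY if unsolved."""
    if node.smiles in stock:
        return 0.0
    best = INFINITY
    for rxn in node.children:
        total = rxn.cost + sum(_solved_value(ch, stock) for ch in rxn.precursors)
        best = min(best, total)
    return best


def _extract_steps(node: _MolNode, stock: StockSet, steps: list[RouteStep], leaves: list[str]) -> None:
    if node.smiles in stock:
        leaves.append(node.smiles)
        return
    best_rxn, best_total = None, INFINITY
    for rxn in node.children:
        total = rxn.cost + sum(_solved_value(ch, stock) for ch in rxn.precursors)
        if total < best_total:
            best_rxn, best_total = rxn, total
    assert best_rxn is not None
    for child in best_rxn.precursors:
        _extract_steps(child, stock, steps, leaves)
    steps.append(
        RouteStep(
            product=node.smiles,
            precursors=tuple(sorted(ch.smiles for ch in best_rxn.precursors)),
            rank=best_rxn.rank,
            cost=best_rxn.cost,
        )
    )


def plan(
    target: Molecule,
    model: SingleStepModel | Callable[[Molecule, int], PredictionSet],
    stock: StockSet,
    budget: SearchBudget | None = None,
    value_mode: str = "zero",
    value_penalty: float = 1.0,
) -> Route | SearchFailure:
    """Best-first AND/OR search from ``target`` down to stock molecules.

    ``model`` is a retro-direction :class:`SingleStepModel` or any callable
    ``(molecule, k) -> PredictionSet``. Returns the minimum-cost solved
    :class:`Route` (with the zero value estimate, minimal over every route
    discoverable in the expanded graph) or a :class:`SearchFailure` with
    diagnostics. Deterministic: ties in priority are broken by insertion
    order.
    """
    budget = budget or SearchBudget()
    predict = model.predict if hasattr(model, "predict") else model
    target_smiles = target.smiles
    if target_smiles in stock:
        return Route(target=target_smiles, steps=[], leaves=[target_smiles], total_cost=0.0)

    counter = itertools.count()
    root = _MolNode(target_smiles, depth=0, parent_rxn=None, uid=next(counter))
    frontier: list[tuple[float, int, _MolNode]] = []

    def push(node: _MolNode) -> None:
        priority = _path_cost(node) + value_estimate(
            node.smiles, stock, value_mode, value_penalty
        )
        heapq.heappush(frontier, (priority, node.uid, node))

    push(root)
    expansions = 0
    while frontier and expansions < budget.max_expansions:
        best_solved = _solved_value(root, stock)
        priority, _, node = heapq.heappop(frontier)
        if node.expanded:
            continue
        if priority >= best_solved:
            break  # no open node can beat the best solved route
        if node.depth >= budget.max_depth:
            continue
        node.expanded = True
        expansions += 1
        forbidden = _ancestors(node)
        prediction = predict(Molecule(node.smiles), budget.k_per_expansion)
        for cand in prediction.candidates:
            if not cand.admissible:
                continue
            precursor_smiles = sorted(cand.smiles_set)
            if any(s in forbidden for s in precursor_smiles):
                continue  # would regenerate an ancestor (protection loop)
            rxn = _RxnNode(parent=node, cost=-cand.score, rank=cand.rank)
            for s in precursor_smiles:
                child = _MolNode(s, depth=node.depth + 1, parent_rxn=rxn, uid=next(counter))
                rxn.precursors.append(child)
                if s not in stock:
                    push(child)
            node.children.append(rxn)

    total = _solved_value(root, stock)
    if total == INFINITY:
        return SearchFailure(
            target=target_smiles, expansions_used=expansions, frontier_size=len(frontier)
        )
    steps: list[RouteStep] = []
    leaves: list[str] = []
    _extract_steps(root, stock, steps, leaves)
    return Route(
        target=target_smiles,
        steps=steps,
        leaves=sorted(set(leaves)),
        total_cost=sum(s.cost for s in steps),
    )
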
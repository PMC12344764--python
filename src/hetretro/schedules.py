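"""Transfer-learning training schedules.

A :class:`MixSchedule` is pure data: an ordered list of corpora with
sampling weights, a step count, an optional starting checkpoint and a seed.
The six standard recipes mirror the transfer-learning regimes compared for
heterocycle retrosynthesis:

* ``baseline`` — general corpus only, fresh initialization;
* ``ring_only`` — ring corpus only, fresh initialization;
* ``finetune`` — ring corpus only, starting from the baseline checkpoint,
  6000 steps;
* ``multitask`` — general and ring together at a 9:1 weight ratio, fresh;
* ``mixed_finetune`` — general and ring at 1:1, starting from the baseline
  checkpoint, 6000 steps;
* ``further_finetune`` — general, ring and recent at 4:4:1, starting from
  the mixed-fine-tuned checkpoint, 6000 steps.

Weights are realized as per-example sampling probabilities (each draw picks
corpus *i* with probability w_i/Σw), with per-epoch reshuffling inside each
corpus.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from .chem_core import read_rsmi
from .predictor import reaction_to_pair

DEFAULT_STEPS = 6000

SCHEDULE_KINDS = (
    "baseline", "ring_only", "finetune", "multitask", "mixed_finetune",
    "further_finetune",
)


class MissingCorpus(ValueError):
    """A schedule kind requires a corpus path that was not supplied."""


class MissingCheckpoint(ValueError):
    """A schedule kind requires an initial checkpoint that was not supplied."""


@dataclass(frozen=True)
class CorpusSpec:
    name: str
    path: str
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("corpus weights must be positive")


@dataclass(frozen=True)
class MixSchedule:
    """A declarative training recipe."""

    kind: str
    corpora: tuple[CorpusSpec, ...]
    n_steps: int
    init: str | None = None  # None = fresh initialization
    seed: int = 0

    @property
    def probabilities(self) -> np.ndarray:
        w = np.array([c.weight for c in self.corpora], dtype=float)
        return w / w.sum()

    def to_yaml(self, path) -> None:
        obj = {
            "kind": self.kind,
            "corpora": [asdict(c) for c in self.corpora],
            "steps": self.n_steps,
            "init": self.init,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(obj, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "MixSchedule":
        obj = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            kind=obj["kind"],
            corpora=tuple(CorpusSpec(**c) for c in obj["corpora"]),
            n_steps=int(obj["steps"]),
            init=obj.get("init"),
            seed=int(obj.get("seed", 0)),
        )


_KIND_RECIPES = {
    # kind: (corpus names with weights, needs_init_from)
    "baseline": ((("general", 1.0),), None),
    "ring_only": ((("ring", 1.0),), None),
    "finetune": ((("ring", 1.0),), "baseline"),
    "multitask": ((("general", 9.0), ("ring", 1.0)), None),
    "mixed_finetune": ((("general", 1.0), ("ring", 1.0)), "baseline"),
    "further_finetune": ((("general", 4.0), ("ring", 4.0), ("recent", 1.0)), "mixed"),
}


def make_schedule(
    kind: str,
    paths: dict[str, str],
    n_steps: int | None = None,
    init: str | None = None,
    seed: int = 0,
    weights: Sequence[float] | None = None,
) -> MixSchedule:
    """Build the standard schedule for ``kind``; every default overridable.

    ``paths`` maps corpus names (general/ring/recent) to ``.rsmi`` files and,
    for kinds that continue training, checkpoint roles (baseline/mixed) to
    checkpoint directories.
    """
    if kind not in _KIND_RECIPES:
        raise ValueError(f"unknown schedule kind {kind!r}; expected one of {SCHEDULE_KINDS}")
    recipe, init_role = _KIND_RECIPES[kind]
    corpora = []
    for i, (name, weight) in enumerate(recipe):
        if name not in paths:
            raise MissingCorpus(f"schedule {kind!r} needs a {name!r} corpus path")
        w = weights[i] if weights is not None else weight
        corpora.append(CorpusSpec(name=name, path=str(paths[name]), weight=w))
    if init is None and init_role is not None:
        if init_role not in paths:
            raise MissingCheckpoint(
                f"schedule {kind!r} starts from the {init_role!r} checkpoint; "
                f"supply paths[{init_role!r}] or init="
            )
        init = str(paths[init_role])
    return MixSchedule(
        kind=kind,
        corpora=tuple(corpora),
        n_steps=DEFAULT_STEPS if n_steps is None else n_steps,
        init=init,
        seed=seed,
    )


class WeightedCorpusSampler:
    """Seeded stream of training batches drawn from weighted corpora.

    Each example is drawn from corpus *i* with probability w_i/Σw (with
    replacement across the stream); within a corpus, examples are cycled
    with a reshuffle at every epoch. The stream is a pure function of the
    schedule, so serializing the schedule and re-running reproduces the
    identical batch sequence.
    """

    def __init__(
        self,
        schedule: MixSchedule,
        direction: str = "retro",
        records_by_corpus: Sequence[Sequence] | None = None,
        vocabulary: Sequence[str] | None = None,
    ) -> None:
        self.schedule = schedule
        if records_by_corpus is None:
            records_by_corpus = [read_rsmi(c.path) for c in schedule.corpora]
        self.pairs: list[list[tuple[tuple[str, ...], tuple[str, ...]]]] = [
            [reaction_to_pair(rec, direction) for rec in records]
            for records in records_by_corpus
        ]
        for spec, pairs in zip(schedule.corpora, self.pairs):
            if not pairs:
                raise MissingCorpus(f"corpus {spec.name!r} ({spec.path}) is empty")
        self.vocabulary = list(vocabulary) if vocabulary is not None else None
        self._rng = np.random.default_rng(schedule.seed)
        self._cursors = [len(p) for p in self.pairs]  # force reshuffle on first draw
        self._orders: list[np.ndarray] = [np.arange(len(p)) for p in self.pairs]
        self.draw_counts = np.zeros(len(self.pairs), dtype=np.int64)

    def draw_example(self) -> tuple[int, tuple[tuple[str, ...], tuple[str, ...]]]:
        probs = self.schedule.probabilities
        ci = int(self._rng.choice(len(self.pairs), p=probs))
        if self._cursors[ci] >= len(self.pairs[ci]):
            self._orders[ci] = self._rng.permutation(len(self.pairs[ci]))
            self._cursors[ci] = 0
        pair = self.pairs[ci][self._orders[ci][self._cursors[ci]]]
        self._cursors[ci] += 1
        self.draw_counts[ci] += 1
        return ci, pair

    def batches(self, batch_size: int) -> Iterator[list]:
        while True:
            yield [self.draw_example()[1] for _ in range(batch_size)]

    def all_tokens(self) -> Iterator[tuple[str, ...]]:
        for pairs in self.pairs:
            for src, tgt in pairs:
                yield src
                yield tgt


def sample_batches(
    schedule: MixSchedule, batch_size: int, direction: str = "retro"
) -> Iterator[list]:
    """Convenience wrapper: build a sampler from the schedule's corpus
    paths and stream batches."""
    return WeightedCorpusSampler(schedule, direction=direction).batches(batch_size)
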
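"""Corpus partitioning.

Two split modes:

* ``similarity`` — products are embedded as Morgan fingerprints, clustered
  by single-linkage at a Tanimoto threshold, and whole clusters are
  assigned to train/valid/test so that similar products never leak across
  partitions (the property a 90:5:5 product-similarity split is for).
* ``random`` — seeded shuffle followed by contiguous slicing.

Both modes are deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chem_core import ReactionRecord


class EmptyCorpus(ValueError):
    """Raised when a split is requested on zero records."""


@dataclass(frozen=True)
class FingerprintSpec:
    radius: int = 2
    n_bits: int = 2048


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of a three-way corpus split.

    fractions must sum to 1; ``similarity_threshold`` is the single-linkage
    Tanimoto cut used in similarity mode.
    """

    fractions: tuple[float, float, float] = (0.9, 0.05, 0.05)
    mode: str = "similarity"
    fingerprint: FingerprintSpec = field(default_factory=FingerprintSpec)
    similarity_threshold: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be three non-negative reals")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")
        if self.mode not in ("similarity", "random"):
            raise ValueError(f"unknown split mode {self.mode!r}")


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer partition sizes by the largest-remainder method; ties go to
    the earlier partition."""
    quotas = [n * f for f in fractions]
    sizes = [int(q) for q in quotas]
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(quotas[i] - sizes[i]), i)
    )
    for i in range(n - sum(sizes)):
        sizes[remainders[i % len(fractions)]] += 1
    return sizes


def random_split(
    records: Sequence[ReactionRecord], spec: SplitSpec
) -> tuple[list[ReactionRecord], list[ReactionRecord], list[ReactionRecord]]:
    """Seeded shuffle then contiguous slicing by ``spec.fractions``."""
    if not records:
        raise EmptyCorpus("cannot split an empty corpus")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(records))
    sizes = _largest_remainder_sizes(len(records), spec.fractions)
    shuffled = [records[i] for i in order]
    a, b = sizes[0], sizes[0] + sizes[1]
    return shuffled[:a], shuffled[a:b], shuffled[b:]


def _product_fingerprints(products: Sequence[str], fp_spec: FingerprintSpec):
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=fp_spec.radius, fpSize=fp_spec.n_bits
    )
    return [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in products]


def _single_linkage_clusters(
    products: Sequence[str], fp_spec: FingerprintSpec, threshold: float
) -> list[list[int]]:
    """Union-find single-linkage clustering of unique product strings at a
    Tanimoto threshold."""
    fps = _product_fingerprints(products, fp_spec)
    parent = list(range(len(products)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(1, len(fps)):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        for j, sim in enumerate(sims):
            if sim >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[int]] = {}
    for i in range(len(products)):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def similarity_split(
    records: Sequence[ReactionRecord], spec: SplitSpec
) -> tuple[list[ReactionRecord], list[ReactionRecord], list[ReactionRecord]]:
    """Product-similarity split: whole single-linkage clusters of similar
    products are assigned to partitions by greedy deficit fill.

    Records sharing a canonical main product always land in the same
    partition, and so do records whose products are connected through a
    chain of Tanimoto ≥ threshold neighbours.
    """
    if not records:
        raise EmptyCorpus("cannot split an empty corpus")
    # group records by canonical main product
    by_product: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        by_product.setdefault(rec.main_product.smiles, []).append(idx)
    products = sorted(by_product)
    clusters = _single_linkage_clusters(
        products, spec.fingerprint, spec.similarity_threshold
    )
    # each cluster's weight = number of records it carries
    cluster_records: list[list[int]] = []
    for cluster in clusters:
        rec_idxs: list[int] = []
        for pi in cluster:
            rec_idxs.extend(by_product[products[pi]])
        cluster_records.append(sorted(rec_idxs))

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(cluster_records))
    targets = [f * len(records) for f in spec.fractions]
    counts = [0, 0, 0]
    assignment: list[list[int]] = [[], [], []]
    for ci in order:
        deficits = [targets[p] - counts[p] for p in range(3)]
        best = max(range(3), key=lambda p: (deficits[p], -p))
        assignment[best].extend(cluster_records[ci])
        counts[best] += len(cluster_records[ci])
    return tuple(
        [records[i] for i in sorted(part)] for part in assignment
    )  # type: ignore[return-value]


def split(
    records: Sequence[ReactionRecord], spec: SplitSpec
) -> tuple[list[ReactionRecord], list[ReactionRecord], list[ReactionRecord]]:
    if spec.mode == "similarity":
        return similarity_split(records, spec)
    return random_split(records, spec)
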
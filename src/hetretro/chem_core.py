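"""Molecule and reaction primitives.

SMILES canonicalization, ring census, reaction-SMILES parsing/serialization
and atom-level SMILES tokenization. Everything downstream (curation, corpus
building, metrics, search) speaks canonical SMILES strings produced here, so
molecule identity is always a string comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

HETEROATOMS = frozenset({"N", "O", "S"})

CORPUS_TAGS = ("general", "ring", "recent", "synthetic")


class InvalidSmiles(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class MalformedReaction(ValueError):
    """Raised when a reaction-SMILES line does not have the
    ``reactants>reagents>products`` shape."""


class IdentityReaction(MalformedReaction):
    """Raised when a parsed reaction has a reactant equal to a product."""


def canonicalize(smiles: str) -> str:
    """Return the RDKit-canonical form of ``smiles``.

    Deterministic and idempotent; stereo descriptors are preserved.
    Raises :class:`InvalidSmiles` on unparsable input — callers in the
    prediction pipeline treat that as an inadmissible candidate, never a
    crash.
    """
    if not smiles:
        raise InvalidSmiles("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmiles(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class Molecule:
    """A molecule identified by its canonical SMILES string.

    Ring statistics are computed lazily and cached; two molecules are equal
    iff their canonical strings are equal.
    """

    smiles: str

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        return cls(canonicalize(smiles))

    def _mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:  # pragma: no cover - smiles is canonical by contract
            raise InvalidSmiles(self.smiles)
        return mol

    @cached_property
    def ring_count(self) -> int:
        """SSSR ring count; equals the cyclomatic number of the graph."""
        return count_rings(self)

    @cached_property
    def hetero_ring_signatures(self) -> frozenset[str]:
        return hetero_ring_signatures(self)

    @cached_property
    def heavy_atom_count(self) -> int:
        return self._mol().GetNumHeavyAtoms()

    @cached_property
    def elements(self) -> frozenset[str]:
        return frozenset(a.GetSymbol() for a in self._mol().GetAtoms())

    def __str__(self) -> str:
        return self.smiles


def count_rings(mol: Molecule | str) -> int:
    """SSSR ring count (= bonds − atoms + connected components).

    Uses the true smallest set of smallest rings, not RDKit's symmetrized
    variant, so fused cages (e.g. bicyclooctane) count their cyclomatic
    number.
    """
    if isinstance(mol, str):
        mol = Molecule.from_smiles(mol)
    return len(Chem.GetSSSR(mol._mol()))


def _ring_skeleton_smiles(rdmol: Chem.Mol, ring_atoms: Sequence[int]) -> str:
    """Canonical SMILES of a ring's bare skeleton (elements, aromaticity and
    bond orders only — hydrogen counts and substituents stripped), so the
    key is invariant to e.g. N-alkylation of an azole NH."""
    em = Chem.RWMol()
    idx_map = {}
    for i in ring_atoms:
        a = rdmol.GetAtomWithIdx(i)
        na = Chem.Atom(a.GetAtomicNum())
        na.SetIsAromatic(a.GetIsAromatic())
        na.SetNoImplicit(True)
        idx_map[i] = em.AddAtom(na)
    ring_set = set(ring_atoms)
    for b in rdmol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in ring_set and j in ring_set:
            em.AddBond(idx_map[i], idx_map[j], b.GetBondType())
    return Chem.MolToSmiles(em.GetMol(), canonical=True)


def hetero_ring_signatures(mol: Molecule | str) -> frozenset[str]:
    """Canonical fragment keys of SSSR rings containing ≥1 of N/O/S.

    Each key is the canonical skeleton SMILES of the ring's atoms and ring
    bonds, so e.g. the imidazole ring of benzimidazole contributes one
    signature and the fused benzo ring none.
    """
    if isinstance(mol, str):
        mol = Molecule.from_smiles(mol)
    rdmol = mol._mol()
    out: set[str] = set()
    for ring_atoms in rdmol.GetRingInfo().AtomRings():
        symbols = {rdmol.GetAtomWithIdx(i).GetSymbol() for i in ring_atoms}
        if not (symbols & HETEROATOMS):
            continue
        out.add(_ring_skeleton_smiles(rdmol, ring_atoms))
    return frozenset(out)


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction: reactant/reagent/product molecule lists plus provenance.

    Molecules are canonical and deduplicated within each role. Reactant-set
    comparisons downstream are set comparisons of the canonical strings.
    """

    reactants: tuple[Molecule, ...]
    reagents: tuple[Molecule, ...]
    products: tuple[Molecule, ...]
    source: str = ""
    corpus: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise MalformedReaction("reaction needs ≥1 reactant and ≥1 product")
        if self.corpus not in CORPUS_TAGS:
            raise ValueError(f"unknown corpus tag {self.corpus!r}")

    @property
    def reactant_smiles(self) -> frozenset[str]:
        return frozenset(m.smiles for m in self.reactants)

    @property
    def product_smiles(self) -> frozenset[str]:
        return frozenset(m.smiles for m in self.products)

    @property
    def key(self) -> tuple[frozenset[str], frozenset[str]]:
        """Dedup key: (canonical reactant set, canonical product set)."""
        return (self.reactant_smiles, self.product_smiles)

    @property
    def main_product(self) -> Molecule:
        """Largest product by heavy atoms; ties broken by canonical string."""
        return max(self.products, key=lambda m: (m.heavy_atom_count, m.smiles))

    def serialize(self) -> str:
        return ">".join(
            ".".join(m.smiles for m in part)
            for part in (self.reactants, self.reagents, self.products)
        )


def _dedup(mols: Iterable[Molecule]) -> tuple[Molecule, ...]:
    seen: dict[str, Molecule] = {}
    for m in mols:
        seen.setdefault(m.smiles, m)
    return tuple(seen.values())


def parse_reaction(
    line: str,
    source: str = "",
    corpus: str = "synthetic",
    line_no: int | None = None,
) -> ReactionRecord:
    """Parse one ``reactants>reagents>products`` reaction-SMILES line.

    Molecules are canonicalized and deduplicated within each role. Identity
    reactions (a reactant equal to a product) are rejected.
    """
    where = f" (line {line_no})" if line_no is not None else ""
    parts = line.strip().split(">")
    if len(parts) != 3:
        raise MalformedReaction(
            f"expected exactly two '>' separators, got {len(parts) - 1}{where}"
        )
    try:
        roles = [
            _dedup(Molecule.from_smiles(s) for s in part.split(".") if s)
            for part in parts
        ]
    except InvalidSmiles as exc:
        raise InvalidSmiles(f"{exc}{where}") from exc
    rec = ReactionRecord(
        reactants=roles[0], reagents=roles[1], products=roles[2],
        source=source, corpus=corpus,
    )
    if rec.reactant_smiles & rec.product_smiles:
        raise IdentityReaction(f"reactant equals product{where}: {line.strip()!r}")
    return rec


def read_rsmi(path, corpus: str = "synthetic") -> list[ReactionRecord]:
    """Read a ``.rsmi`` file: one reaction per line, ``#`` comments ignored."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            records.append(parse_reaction(line, source=str(path), corpus=corpus, line_no=i))
    return records


def write_rsmi(records: Iterable[ReactionRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.serialize() + "\n")


# Atom-level SMILES tokenization: bracket atoms, two-letter halogens and
# two-digit ring closures are single tokens. Any character the pattern does
# not know becomes a single-character token, so tokenization is total and
# lossless; validity is checked elsewhere (via canonicalize).
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[NOSPFIbcnosp]|[A-Za-z]|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|\d)"
)


@dataclass(frozen=True)
class TokenSequence:
    """An ordered list of SMILES tokens; joining them restores the source."""

    tokens: tuple[str, ...]

    def detokenize(self) -> str:
        return "".join(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)


def tokenize(s: str) -> TokenSequence:
    """Lossless atom-level tokenization of a SMILES string."""
    tokens: list[str] = []
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m:
            tokens.append(m.group(0))
            pos = m.end()
        else:
            tokens.append(s[pos])
            pos += 1
    return TokenSequence(tuple(tokens))


def detokenize(seq: TokenSequence | Iterable[str]) -> str:
    if isinstance(seq, TokenSequence):
        return seq.detokenize()
    return "".join(seq)
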
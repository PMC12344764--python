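"""Ring-formation corpus curation.

Builds a heterocycle-formation corpus from raw reaction-SMILES files:
validity filtering, ring/heterocycle-formation detection, deduplication,
and a per-line rejection log with reason codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .chem_core import (
    IdentityReaction,
    InvalidSmiles,
    MalformedReaction,
    ReactionRecord,
    parse_reaction,
)

# Rejection reason codes, in the order the pipeline applies them.
REASON_MALFORMED = "malformed"
REASON_INVALID_SMILES = "invalid_smiles"
REASON_IDENTITY = "identity"
REASON_ELEMENT = "element_not_allowed"
REASON_SIZE = "product_size"
REASON_NOT_RING_FORMING = "not_ring_forming"
REASON_NOT_HETERO_FORMING = "not_heterocycle_forming"
REASON_DUPLICATE = "duplicate"


@dataclass(frozen=True)
class CurationConfig:
    """Validity filters for corpus curation.

    The element whitelist and product-size bounds are deliberately exposed
    as configuration rather than constants; the defaults cover standard
    medicinal-chemistry space.
    """

    allowed_elements: frozenset[str] = frozenset(
        {"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si"}
    )
    min_product_heavy_atoms: int = 5
    max_product_heavy_atoms: int = 70
    require_aromatic_hetero: bool = False


@dataclass(frozen=True)
class Rejection:
    line_no: int
    reason: str
    raw_line: str


def is_ring_forming(rxn: ReactionRecord) -> bool:
    """True iff the max product ring count exceeds the reactants' total."""
    max_product = max(m.ring_count for m in rxn.products)
    total_reactant = sum(m.ring_count for m in rxn.reactants)
    return max_product > total_reactant


def new_hetero_signatures(rxn: ReactionRecord) -> frozenset[str]:
    """Hetero-ring signatures present in some product but in no reactant."""
    reactant_sigs: set[str] = set()
    for m in rxn.reactants:
        reactant_sigs |= m.hetero_ring_signatures
    product_sigs: set[str] = set()
    for m in rxn.products:
        product_sigs |= m.hetero_ring_signatures
    return frozenset(product_sigs - reactant_sigs)


def is_heterocycle_forming(rxn: ReactionRecord) -> bool:
    """True iff a product carries a hetero-ring signature absent from every
    reactant (a genuinely new N/O/S-containing ring)."""
    return bool(new_hetero_signatures(rxn))


def deduplicate(records: Sequence[ReactionRecord]) -> list[ReactionRecord]:
    """Collapse records with identical (reactant set, product set) keys to
    the first occurrence; reagents are ignored in the key. Stable order."""
    seen = set()
    out = []
    for rec in records:
        if rec.key in seen:
            continue
        seen.add(rec.key)
        out.append(rec)
    return out


def _is_aromatic_ring_signature(sig: str) -> bool:
    # Aromatic ring fragments are written with lowercase aromatic atoms.
    return any(c.islower() for c in sig if c.isalpha())


def _validity_reason(rec: ReactionRecord, config: CurationConfig) -> str | None:
    for mol in rec.reactants + rec.reagents + rec.products:
        if not mol.elements <= config.allowed_elements:
            return REASON_ELEMENT
    n_heavy = rec.main_product.heavy_atom_count
    if not (config.min_product_heavy_atoms <= n_heavy <= config.max_product_heavy_atoms):
        return REASON_SIZE
    return None


def _hetero_reason(rec: ReactionRecord, config: CurationConfig) -> str | None:
    sigs = new_hetero_signatures(rec)
    if config.require_aromatic_hetero:
        sigs = frozenset(s for s in sigs if _is_aromatic_ring_signature(s))
    if sigs:
        return None
    # Distinguish "nothing cyclizes at all" from "a ring forms but it is
    # not a (qualifying) heterocycle" for an auditable rejection trace.
    return REASON_NOT_HETERO_FORMING if is_ring_forming(rec) else REASON_NOT_RING_FORMING


def _trim_to_main_product(rec: ReactionRecord) -> ReactionRecord:
    if len(rec.products) == 1:
        return rec
    return ReactionRecord(
        reactants=rec.reactants,
        reagents=rec.reagents,
        products=(rec.main_product,),
        source=rec.source,
        corpus=rec.corpus,
    )


@dataclass
class CurationResult:
    accepted: list[ReactionRecord]
    rejections: list[Rejection]
    n_lines: int

    @property
    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rej in self.rejections:
            counts[rej.reason] = counts.get(rej.reason, 0) + 1
        return counts


def curate_lines(
    lines: Iterable[str],
    config: CurationConfig | None = None,
    corpus: str = "ring",
    source: str = "",
) -> CurationResult:
    """Run the curation pipeline over raw reaction-SMILES lines.

    Pipeline: parse → validity filter (element whitelist, product size) →
    heterocycle-formation test → deduplication. Every rejected line is
    logged with a reason code; ``len(accepted) + len(rejections)`` equals
    the number of non-comment input lines.

    Multi-product reactions are trimmed to their largest product (the
    single-product pairs the seq2seq models train on); the trim is recorded
    on the accepted record's source tag, not as a rejection.
    """
    config = config or CurationConfig()
    accepted: list[ReactionRecord] = []
    rejections: list[Rejection] = []
    seen_keys: set = set()
    n_lines = 0
    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        n_lines += 1

        def reject(reason: str) -> None:
            rejections.append(Rejection(line_no, reason, line))

        try:
            rec = parse_reaction(line, source=source, corpus=corpus, line_no=line_no)
        except InvalidSmiles:
            reject(REASON_INVALID_SMILES)
            continue
        except IdentityReaction:
            reject(REASON_IDENTITY)
            continue
        except MalformedReaction:
            reject(REASON_MALFORMED)
            continue
        reason = _validity_reason(rec, config)
        if reason is None:
            reason = _hetero_reason(rec, config)
        if reason is not None:
            reject(reason)
            continue
        rec = _trim_to_main_product(rec)
        if rec.key in seen_keys:
            reject(REASON_DUPLICATE)
            continue
        seen_keys.add(rec.key)
        accepted.append(rec)
    return CurationResult(accepted=accepted, rejections=rejections, n_lines=n_lines)


def curate(
    input_paths: Sequence, config: CurationConfig | None = None, corpus: str = "ring"
) -> CurationResult:
    """Curate one or more raw ``.rsmi`` files into a ring-style corpus."""
    results = CurationResult(accepted=[], rejections=[], n_lines=0)
    seen_keys: set = set()
    for path in input_paths:
        try:
            with open(path, encoding="utf-8") as fh:
                part = curate_lines(fh, config=config, corpus=corpus, source=str(path))
        except OSError as exc:
            raise OSError(f"cannot read reaction file {path}: {exc}") from exc
        # re-deduplicate across files, preserving per-file line numbers
        for rec_idx, rec in enumerate(part.accepted):
            if rec.key in seen_keys:
                part.rejections.append(Rejection(-1, REASON_DUPLICATE, rec.serialize()))
            else:
                seen_keys.add(rec.key)
                results.accepted.append(rec)
        results.rejections.extend(part.rejections)
        results.n_lines += part.n_lines
    return results


def write_rejections(rejections: Sequence[Rejection], path) -> None:
    """TSV rejection log: line_no, reason_code, raw_line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("line_no\treason_code\traw_line\n")
        for rej in rejections:
            fh.write(f"{rej.line_no}\t{rej.reason}\t{rej.raw_line}\n")
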
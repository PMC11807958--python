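"""Proviral architecture classification and the LTR-recombination model.

A provirus is summarized by its ordered repeat-block classes. The grammar
(consecutive INT blocks collapse, OTHER/SVA blocks are transparent):

* ``LTR INT+ LTR``          -> canonical provirus
* ``LTR INT+ LTR INT+ LTR`` -> tandem repeat locus
* ``INT LTR INT``           -> int_sandwich (the inverted insertion structure)
* ``LTR``                   -> solo LTR
* ``LTR INT+`` / ``INT+ LTR`` -> truncated
* anything else             -> other

Homologous recombination between two aligned repeat copies is modelled as a
single crossover: everything from the start of the left repeat up to the
start of the right repeat is removed, so the deleted length is exactly the
distance between the two repeat starts. Recombination between the two outer
LTRs of a canonical provirus leaves a solo LTR; recombination between
adjacent LTRs of a tandem locus collapses it to one canonical provirus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .formats import FEATURE_CLASS, LocusAnnotation
from .locus_sv import LocalizedSV
from .segment import DEFAULT_MIN_BLOCK, BlockStructure, RepeatBlock, segment

ARCHITECTURE_LABELS = (
    "canonical",
    "tandem",
    "int_sandwich",
    "solo_ltr",
    "truncated",
    "other",
)


@dataclass(frozen=True)
class ArchitectureCall:
    label: str
    n_ltr: int
    n_int: int
    evidence: BlockStructure
    terminal_ltr_truncated: bool = False


@dataclass(frozen=True)
class RecombinationEvent:
    left_block: int  # block index of the left repeat in the source structure
    right_block: int
    deleted_length: int
    product: ArchitectureCall


def reference_blocks(locus: LocusAnnotation) -> BlockStructure:
    """The block structure of a reference locus, from its annotation."""
    blocks = tuple(
        RepeatBlock(
            klass=FEATURE_CLASS[ftype],
            query_interval=(ivl.start, ivl.end),
            consensus_interval=(0, ivl.length),
            strand="+",
            identity=1.0,
            truncated=False,
        )
        for ftype, ivl in locus.features
    )
    covered = sum(b.length for b in blocks)
    return BlockStructure(
        source_id=locus.locus_id,
        blocks=blocks,
        unclassified_fraction=1.0 - covered / locus.span.length,
        query_length=locus.span.length,
    )


def call_architecture(structure: BlockStructure) -> ArchitectureCall:
    """Classify a block structure by its collapsed LTR/INT class pattern."""
    classes = [b.klass for b in structure.blocks if b.klass in ("LTR", "INT")]
    n_ltr = classes.count("LTR")
    n_int = classes.count("INT")
    collapsed: list[str] = []
    for k in classes:
        if k == "INT" and collapsed and collapsed[-1] == "INT":
            continue
        collapsed.append(k)
    pattern = tuple(collapsed)
    if not pattern:
        label = "other"
    elif pattern == ("LTR",):
        label = "solo_ltr"
    elif pattern == ("LTR", "INT", "LTR"):
        label = "canonical"
    elif pattern == ("LTR", "INT", "LTR", "INT", "LTR"):
        label = "tandem"
    elif pattern == ("INT", "LTR", "INT"):
        label = "int_sandwich"
    elif pattern in (("LTR", "INT"), ("INT", "LTR")):
        label = "truncated"
    else:
        label = "other"
    ltr_blocks = [b for b in structure.blocks if b.klass == "LTR"]
    terminal_trunc = bool(ltr_blocks) and (
        ltr_blocks[0].truncated or ltr_blocks[-1].truncated
    )
    return ArchitectureCall(
        label=label,
        n_ltr=n_ltr,
        n_int=n_int,
        evidence=structure,
        terminal_ltr_truncated=terminal_trunc,
    )


def apply_recombination(
    structure: BlockStructure, left_repeat_index: int, right_repeat_index: int
) -> tuple[BlockStructure, int]:
    """Single-crossover recombination between two aligned repeat blocks.

    Removes everything from the start of the left repeat through the start of
    the right repeat; the right repeat survives (as the hybrid copy). Returns
    the new structure and the deleted length (the inter-start distance).
    """
    blocks = structure.blocks
    if not (0 <= left_repeat_index < right_repeat_index < len(blocks)):
        raise ValueError("repeat indices out of range or not ordered")
    left, right = blocks[left_repeat_index], blocks[right_repeat_index]
    if left.klass != "LTR" or right.klass != "LTR":
        raise ValueError("recombination requires two LTR-class blocks")
    deleted = right.query_interval[0] - left.query_interval[0]
    if deleted <= 0:
        raise ValueError("repeat blocks are not ordered on the query")
    kept = list(blocks[:left_repeat_index])
    for b in blocks[right_repeat_index:]:
        qs, qe = b.query_interval
        kept.append(
            RepeatBlock(
                klass=b.klass,
                query_interval=(qs - deleted, qe - deleted),
                consensus_interval=b.consensus_interval,
                strand=b.strand,
                identity=b.identity,
                truncated=b.truncated,
            )
        )
    new_len = max(structure.query_length - deleted, sum(b.length for b in kept), 1)
    covered = sum(b.length for b in kept)
    return (
        BlockStructure(
            source_id=structure.source_id,
            blocks=tuple(kept),
            unclassified_fraction=1.0 - covered / new_len,
            query_length=new_len,
        ),
        deleted,
    )


def enumerate_recombinations(structure: BlockStructure) -> list[RecombinationEvent]:
    """Every single-crossover event between an LTR pair and its product."""
    ltr_indices = [
        i for i, b in enumerate(structure.blocks) if b.klass == "LTR"
    ]
    events = []
    for ai in range(len(ltr_indices)):
        for bi in range(ai + 1, len(ltr_indices)):
            i, j = ltr_indices[ai], ltr_indices[bi]
            product, deleted = apply_recombination(structure, i, j)
            events.append(
                RecombinationEvent(
                    left_block=i,
                    right_block=j,
                    deleted_length=deleted,
                    product=call_architecture(product),
                )
            )
    return events


# ---------------------------------------------------------------------------
# Per-sample architecture from a reference locus plus that sample's SVs
# ---------------------------------------------------------------------------

def _subtract(entry: dict, dels: list[tuple[int, int]], min_piece: int) -> list[dict]:
    """Remaining pieces of a genomic block after removing deletion spans."""
    pieces = [(entry["gstart"], entry["gend"])]
    for ds, de in dels:
        nxt = []
        for s, e in pieces:
            if de <= s or e <= ds:
                nxt.append((s, e))
                continue
            if s < ds:
                nxt.append((s, ds))
            if de < e:
                nxt.append((de, e))
        pieces = nxt
    return [
        {"klass": entry["klass"], "gstart": s, "gend": e, "length": e - s,
         "truncated": (e - s) < entry["length"]}
        for s, e in pieces
        if e - s >= min_piece
    ]


def sample_architecture(
    locus: LocusAnnotation,
    sample_svs: Sequence[LocalizedSV],
    consensi: Mapping[str, str] | None = None,
    alt_structures: Mapping[str, BlockStructure] | None = None,
    min_block: int = DEFAULT_MIN_BLOCK,
) -> ArchitectureCall:
    """Architecture of one sample's haplotype at a locus.

    The reference block structure is edited by removing every DEL span and
    splicing the segmented alt structure of every INS at its anchor, then
    classified. Insertions whose alt sequence contains no classifiable repeat
    block leave the structure unchanged. Overlapping deletions within one
    sample are rejected (they would require phased haplotypes to interpret).
    Alt structures are taken from ``alt_structures`` (by SV id) when given,
    otherwise computed from ``consensi``.
    """
    svs = [s for s in sample_svs if s.locus_id == locus.locus_id or s.locus_id is None]
    dels = sorted(
        (s.sv.interval.start, s.sv.interval.end)
        for s in svs
        if s.sv.svtype == "DEL"
    )
    for (s1, e1), (s2, e2) in zip(dels, dels[1:]):
        if s2 < e1:
            raise ValueError(
                f"overlapping deletions in one sample at {locus.locus_id}: "
                f"[{s1},{e1}) and [{s2},{e2})"
            )
    entries = [
        {
            "klass": FEATURE_CLASS[ftype],
            "gstart": ivl.start,
            "gend": ivl.end,
            "length": ivl.length,
            "truncated": False,
        }
        for ftype, ivl in locus.features
    ]
    if dels:
        entries = [p for e in entries for p in _subtract(e, dels, min_block)]

    inss = sorted(
        (s for s in svs if s.sv.svtype == "INS"),
        key=lambda s: s.sv.interval.start,
    )
    for lsv in inss:
        sv = lsv.sv
        alt_struct = None
        if alt_structures is not None and sv.id in alt_structures:
            alt_struct = alt_structures[sv.id]
        elif sv.alt_sequence and consensi is not None and len(sv.alt_sequence) >= min_block:
            alt_struct = segment(
                sv.alt_sequence, consensi, min_block=min_block, source_id=sv.id
            )
        if alt_struct is None:
            continue
        alt_blocks = [
            {
                "klass": b.klass,
                "gstart": None,
                "gend": None,
                "length": b.length,
                "truncated": b.truncated,
            }
            for b in alt_struct.blocks
        ]
        if not alt_blocks:
            continue
        insert_pos = sv.interval.end  # inserted sequence begins here
        idx = len(entries)
        for i, entry in enumerate(entries):
            if entry["gstart"] is None:
                continue
            if entry["gstart"] < insert_pos < entry["gend"]:
                # split the host block; sub-min pieces are dropped
                left = dict(entry, gend=insert_pos, length=insert_pos - entry["gstart"],
                            truncated=True)
                right = dict(entry, gstart=insert_pos,
                             length=entry["gend"] - insert_pos, truncated=True)
                pieces = [p for p in (left, right) if p["length"] >= min_block]
                entries = (
                    entries[:i]
                    + ([left] if left["length"] >= min_block else [])
                    + alt_blocks
                    + ([right] if right["length"] >= min_block else [])
                    + entries[i + 1:]
                )
                idx = None
                break
            if entry["gstart"] >= insert_pos:
                idx = i
                break
        if idx is not None:  # boundary or gap: anchor after the left block
            entries = entries[:idx] + alt_blocks + entries[idx:]

    # rebuild contiguous coordinates in final order
    blocks = []
    cursor = 0
    for entry in entries:
        blocks.append(
            RepeatBlock(
                klass=entry["klass"],
                query_interval=(cursor, cursor + entry["length"]),
                consensus_interval=(0, entry["length"]),
                strand="+",
                identity=1.0,
                truncated=entry["truncated"],
            )
        )
        cursor += entry["length"]
    structure = BlockStructure(
        source_id=locus.locus_id,
        blocks=tuple(blocks),
        unclassified_fraction=0.0,
        query_length=max(cursor, 1),
    )
    return call_architecture(structure)
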
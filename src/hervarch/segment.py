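"""Segmentation of nucleotide sequences into LTR / INT / other repeat blocks.

An insertion sequence (or any query) is decomposed by repeated local
alignment against packaged consensus sequences, one per repeat class, on both
strands. All candidate alignments above a score floor are collected by
iterative masking (best hit, mask it on the query, realign); overlapping
candidates from different classes are then resolved greedily by score (ties:
longer block, then leftmost, then class name). Blocks shorter than
``min_block`` are dropped, which also absorbs the short spurious fragments a
full repeat library would occasionally mislabel.

Scoring is BLAST-like: match +2, mismatch -3, gap open -5, gap extend -2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from biotite.sequence import NucleotideSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

from .formats import StructuralVariant

logger = logging.getLogger("hervarch")

DEFAULT_MIN_BLOCK = 100
DEFAULT_MIN_SCORE = 60

#: Alignment scoring (match, mismatch, gap open, gap extend).
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -3, -5, -2

REPEAT_CLASSES = ("LTR", "INT", "SVA", "OTHER")


def _nt_matrix() -> SubstitutionMatrix:
    """+2/-3 matrix over the ambiguous DNA alphabet; N (and masked bases)
    can never be part of an alignment."""
    alph = NucleotideSequence.alphabet_amb
    n = len(alph)
    scores = np.full((n, n), -10_000, dtype=np.int32)
    for i, a in enumerate(alph):
        for j, b in enumerate(alph):
            if a in "ACGT" and b in "ACGT":
                scores[i, j] = MATCH if a == b else MISMATCH
    return SubstitutionMatrix(alph, alph, scores)


_MATRIX = _nt_matrix()


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class RepeatBlock:
    klass: str
    query_interval: tuple[int, int]  # 0-based half-open on the input
    consensus_interval: tuple[int, int]  # on the consensus, forward coords
    strand: str  # "+" or "-"
    identity: float
    truncated: bool  # consensus coverage < 95%

    @property
    def length(self) -> int:
        return self.query_interval[1] - self.query_interval[0]


@dataclass(frozen=True)
class BlockStructure:
    source_id: str
    blocks: tuple[RepeatBlock, ...]
    unclassified_fraction: float
    query_length: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "blocks",
            tuple(sorted(self.blocks, key=lambda b: b.query_interval[0])),
        )

    @property
    def class_pattern(self) -> tuple[str, ...]:
        return tuple(b.klass for b in self.blocks)


def _candidates_for(
    query: str,
    consensus: str,
    klass: str,
    strand: str,
    min_score: int,
    max_iter: int = 64,
) -> list[dict]:
    """All local alignments of one consensus/strand against the query,
    found by iterative masking of the query."""
    cons = consensus if strand == "+" else revcomp(consensus)
    cons_seq = NucleotideSequence(cons.upper())
    work = list(query.upper())
    out = []
    cons_len = len(consensus)
    for _ in range(max_iter):
        try:
            qseq = NucleotideSequence("".join(work))
        except Exception:  # pragma: no cover - alphabet guard
            break
        alns = align_optimal(
            qseq,
            cons_seq,
            _MATRIX,
            gap_penalty=(GAP_OPEN, GAP_EXTEND),
            local=True,
            max_number=1,
        )
        if not alns:
            break
        aln = alns[0]
        if aln.score < min_score or len(aln.trace) == 0:
            break
        trace = aln.trace
        q, c = trace[:, 0], trace[:, 1]
        q_idx, c_idx = q[q >= 0], c[c >= 0]
        qs, qe = int(q_idx.min()), int(q_idx.max()) + 1
        cs, ce = int(c_idx.min()), int(c_idx.max()) + 1
        if strand == "-":
            cs, ce = cons_len - ce, cons_len - cs
        matches = sum(
            1 for qi, ci in trace if qi >= 0 and ci >= 0 and work[qi] == cons[ci]
        )
        out.append(
            {
                "klass": klass,
                "score": int(aln.score),
                "query": (qs, qe),
                "consensus": (cs, ce),
                "strand": strand,
                "identity": matches / len(trace),
                "coverage": (ce - cs) / cons_len,
            }
        )
        for i in range(qs, qe):  # mask and search for further copies
            work[i] = "N"
    return out


def segment(
    sequence: str,
    consensi: Mapping[str, str],
    min_block: int = DEFAULT_MIN_BLOCK,
    min_score: int = DEFAULT_MIN_SCORE,
    source_id: str = "seq",
) -> BlockStructure:
    """Decompose ``sequence`` into an ordered list of repeat blocks."""
    if not sequence:
        raise ValueError("empty sequence")
    missing = {"LTR", "INT"} - set(consensi)
    if missing:
        raise ValueError(f"consensi must contain at least LTR and INT (missing {missing})")
    candidates: list[dict] = []
    for klass, consensus in consensi.items():
        if klass not in REPEAT_CLASSES:
            raise ValueError(f"unknown repeat class {klass!r}")
        for strand in "+-":
            candidates.extend(
                _candidates_for(sequence, consensus, klass, strand, min_score)
            )
    # greedy resolution: best score, then longer, then leftmost, then class
    candidates.sort(
        key=lambda c: (
            -c["score"],
            -(c["query"][1] - c["query"][0]),
            c["query"][0],
            c["klass"],
        )
    )
    accepted: list[dict] = []
    for cand in candidates:
        qs, qe = cand["query"]
        if qe - qs < min_block:
            continue
        if any(qs < a["query"][1] and a["query"][0] < qe for a in accepted):
            continue
        accepted.append(cand)
    blocks = tuple(
        RepeatBlock(
            klass=c["klass"],
            query_interval=c["query"],
            consensus_interval=c["consensus"],
            strand=c["strand"],
            identity=c["identity"],
            truncated=c["coverage"] < 0.95,
        )
        for c in accepted
    )
    covered = sum(b.length for b in blocks)
    return BlockStructure(
        source_id=source_id,
        blocks=blocks,
        unclassified_fraction=1.0 - covered / len(sequence),
        query_length=len(sequence),
    )


def classify_insertions(
    svs: Sequence[StructuralVariant],
    consensi: Mapping[str, str],
    min_block: int = DEFAULT_MIN_BLOCK,
    min_score: int = DEFAULT_MIN_SCORE,
) -> dict[str, BlockStructure]:
    """Segment the alt sequence of every INS record; DEL/DUP are skipped.

    Identical alt sequences are segmented once and shared.
    """
    cache: dict[str, BlockStructure] = {}
    out: dict[str, BlockStructure] = {}
    for sv in svs:
        if sv.svtype != "INS":
            continue
        if not sv.alt_sequence:
            logger.warning("INS %s has no alt sequence; skipped", sv.id)
            continue
        alt = sv.alt_sequence
        if alt not in cache:
            if len(alt) < min_block:
                cache[alt] = BlockStructure(sv.id, (), 1.0, len(alt))
            else:
                cache[alt] = segment(
                    alt, consensi, min_block=min_block, min_score=min_score,
                    source_id=sv.id,
                )
        base = cache[alt]
        out[sv.id] = BlockStructure(
            sv.id, base.blocks, base.unclassified_fraction, base.query_length
        )
    return out
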
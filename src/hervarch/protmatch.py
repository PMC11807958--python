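"""Scoring of ORF peptides against reference HERV-K proteins.

Peptides are compared to reference proteins by exact Smith-Waterman local
alignment (BLOSUM62, affine gaps: open 11, extend 1). The headline quantity
is ``percent_of_reference`` = 100 x aligned-reference-length / reference
length, i.e. how much of the reference protein the peptide accounts for; a
100% call therefore requires the alignment to span the whole reference.
Coverage of annotated functional domains (e.g. the Env signal peptide or the
Pol reverse-transcriptase region) is reported per domain.

The packaged reference set consists of synthetic mock proteins (fixed-seed
random sequences with declared domain intervals); they stand in for curated
UniProt entries so that the whole pipeline is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

from .orfs import OrfHit

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_AA = set(AMINO_ACIDS + "X")

#: Raw Smith-Waterman score under BLOSUM62/affine(11,1) below which a local
#: hit is considered indistinguishable from the random background and is not
#: reported. Random pairs of unrelated sequences at the lengths handled here
#: (<= ~1000 aa) score well under this floor; genuine domain-length matches
#: score far above it.
DEFAULT_MIN_SCORE = 60

#: Default reporting floor for percent_of_reference (matches as small as a
#: few percent of a reference protein are still listed).
DEFAULT_MIN_REPORT = 5.0

_BLOSUM62 = SubstitutionMatrix.std_protein_matrix()
_GAP_PENALTY = (-11, -1)

#: Fixed seed for the synthetic mock reference proteins. The mock set is part
#: of the package's test surface and must be bit-stable across runs.
MOCK_PROTEIN_SEED = 20250


@dataclass(frozen=True)
class ReferenceProtein:
    name: str
    sequence: str
    domains: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        for dname, start, end in self.domains:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"{self.name}: domain {dname} outside protein")


@dataclass(frozen=True)
class LocalAlignment:
    score: int
    query_interval: tuple[int, int]  # 0-based half-open on the query
    ref_interval: tuple[int, int]
    identity: float
    n_columns: int


@dataclass(frozen=True)
class ProteinMatch:
    orf: OrfHit | None
    protein: str
    alignment: LocalAlignment
    percent_of_reference: float
    domain_coverage: dict[str, float]


def _validate_aa(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_AA
    if bad:
        raise ValueError(f"{what} contains non-amino-acid characters: {sorted(bad)}")
    return seq


def local_align(query: str, reference: str) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of two peptides.

    BLOSUM62 with affine gaps (open 11, extend 1). When several alignments
    are co-optimal the one with the lowest query start, then lowest reference
    start, is returned.
    """
    query = _validate_aa(query, "query")
    reference = _validate_aa(reference, "reference")
    if not query or not reference:
        raise ValueError("empty sequence")
    alns = align_optimal(
        ProteinSequence(query),
        ProteinSequence(reference),
        _BLOSUM62,
        gap_penalty=_GAP_PENALTY,
        local=True,
    )

    def key(aln):
        trace = aln.trace
        q = trace[:, 0]
        r = trace[:, 1]
        return (int(q[q >= 0].min()), int(r[r >= 0].min()))

    aln = min(alns, key=key)
    trace = aln.trace
    q, r = trace[:, 0], trace[:, 1]
    q_idx, r_idx = q[q >= 0], r[r >= 0]
    matches = sum(
        1
        for qi, ri in trace
        if qi >= 0 and ri >= 0 and query[qi] == reference[ri]
    )
    return LocalAlignment(
        score=int(aln.score),
        query_interval=(int(q_idx.min()), int(q_idx.max()) + 1),
        ref_interval=(int(r_idx.min()), int(r_idx.max()) + 1),
        identity=matches / len(trace),
        n_columns=len(trace),
    )


def _domain_coverage(
    ref_interval: tuple[int, int], domains
) -> dict[str, float]:
    cov = {}
    rs, re = ref_interval
    for dname, ds, de in domains:
        overlap = max(0, min(re, de) - max(rs, ds))
        cov[dname] = overlap / (de - ds)
    return cov


def match_peptide(
    peptide: str,
    proteins: Sequence[ReferenceProtein],
    min_report: float = DEFAULT_MIN_REPORT,
    min_score: int = DEFAULT_MIN_SCORE,
    orf: OrfHit | None = None,
) -> list[ProteinMatch]:
    """All reference-protein matches of one peptide, best score first."""
    matches = []
    for prot in proteins:
        aln = local_align(peptide, prot.sequence)
        if aln.score < min_score:
            continue
        ref_len = aln.ref_interval[1] - aln.ref_interval[0]
        pct = 100.0 * ref_len / len(prot.sequence)
        if pct < min_report:
            continue
        matches.append(
            ProteinMatch(
                orf=orf,
                protein=prot.name,
                alignment=aln,
                percent_of_reference=pct,
                domain_coverage=_domain_coverage(aln.ref_interval, prot.domains),
            )
        )
    matches.sort(key=lambda m: -m.alignment.score)
    return matches


def match_orfs(
    orfs: Sequence[OrfHit],
    proteins: Sequence[ReferenceProtein],
    min_report: float = DEFAULT_MIN_REPORT,
    min_score: int = DEFAULT_MIN_SCORE,
) -> list[ProteinMatch]:
    """Score every ORF peptide against every reference protein."""
    if not proteins:
        raise ValueError("no reference proteins given")
    out: list[ProteinMatch] = []
    for orf in orfs:
        out.extend(
            match_peptide(
                orf.peptide, proteins, min_report=min_report, min_score=min_score, orf=orf
            )
        )
    return out


# ---------------------------------------------------------------------------
# Synthetic mock reference proteins
# ---------------------------------------------------------------------------

#: (name, length, domains) of the mock set. Lengths are on the scale of the
#: real HERV-K proteins; domain layout mirrors the annotated functional
#: domains (Pol: RT / RNase H / integrase; Env: SP / SU / TM).
MOCK_PROTEIN_SPEC = (
    ("Gag", 555, ()),
    ("Pro", 140, ()),
    ("Pol", 900, (("RT", 50, 350), ("RNaseH", 350, 490), ("Integrase", 490, 780))),
    ("Env", 699, (("SP", 0, 96), ("SU", 96, 460), ("TM", 460, 699))),
)


def mock_reference_proteins(seed: int = MOCK_PROTEIN_SEED) -> list[ReferenceProtein]:
    """The packaged synthetic HERV-K protein stand-ins (deterministic)."""
    rng = np.random.default_rng(seed)
    out = []
    for name, length, domains in MOCK_PROTEIN_SPEC:
        letters = rng.choice(list(AMINO_ACIDS), size=length)
        seq = "M" + "".join(letters[1:])
        out.append(ReferenceProtein(name=name, sequence=seq, domains=tuple(domains)))
    return out


def read_reference_proteins(fasta: dict[str, str], domains_tsv: str | None = None):
    """Build ReferenceProteins from a FASTA map plus an optional domain TSV.

    The TSV has columns protein, domain, start, end (0-based half-open).
    """
    domain_map: dict[str, list[tuple[str, int, int]]] = {}
    if domains_tsv:
        for line in domains_tsv.splitlines():
            if not line.strip() or line.startswith("protein"):
                continue
            prot, dname, start, end = line.split("\t")[:4]
            domain_map.setdefault(prot, []).append((dname, int(start), int(end)))
    return [
        ReferenceProtein(name, _validate_aa(seq, name), tuple(domain_map.get(name, ())))
        for name, seq in fasta.items()
    ]
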
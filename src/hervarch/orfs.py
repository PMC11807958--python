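"""Six-frame translation and open-reading-frame extraction.

An ORF here is a maximal peptide running from a start codon (M) to the next
stop (*) in one of the six translation frames. Retroviral internal regions
are scanned this way because proviral coding sequences can sit on either
strand; the length filter (default >= 40 aa) removes the dense background of
short spurious peptides that six-frame translation of an ~9-kb provirus
produces. Reverse frames are numbered on the reverse-complement sequence
(frame 1 = first base of the reverse complement).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .formats import GenomicInterval

DEFAULT_MIN_AA = 40

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


@dataclass(frozen=True)
class OrfHit:
    """A translated ORF: peptide starting with M, ending before a stop."""

    source_id: str
    strand: str  # "+" or "-"
    frame: int  # 1..3, on the strand's own sequence
    aa_start: int  # 0-based position in the frame's translation
    aa_end: int  # exclusive
    peptide: str
    nt_interval: GenomicInterval  # codon span on the forward source sequence

    @property
    def frame_label(self) -> str:
        return f"{'+' if self.strand == '+' else '-'}{self.frame}"

    def __len__(self) -> int:
        return len(self.peptide)


def _translate_frame(seq: str, offset: int) -> str:
    sub = seq[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


def six_frame_translate(sequence: str) -> dict[str, str]:
    """Translate a nucleotide sequence in all six frames.

    Returns a map from frame label (``+1..+3, -1..-3``) to amino-acid text.
    Codons containing N translate to X; trailing partial codons are dropped.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    if set(seq) - set("ACGTN"):
        raise ValueError(f"non-nucleotide characters: {set(seq) - set('ACGTN')}")
    rc = str(Seq(seq).reverse_complement())
    out = {}
    for f in range(3):
        out[f"+{f + 1}"] = _translate_frame(seq, f)
        out[f"-{f + 1}"] = _translate_frame(rc, f)
    return out


def _frame_orf_coords(
    aa_start: int, aa_len: int, frame_offset: int, seq_len: int, strand: str
) -> tuple[int, int]:
    """Map an ORF's aa coordinates back to the forward nucleotide sequence."""
    nt_start = frame_offset + 3 * aa_start
    nt_end = nt_start + 3 * aa_len
    if strand == "+":
        return nt_start, nt_end
    # coordinates were on the reverse complement
    return seq_len - nt_end, seq_len - nt_start


def find_orfs(
    sequence: str,
    min_aa: int = DEFAULT_MIN_AA,
    include_open_ended: bool = False,
    source_id: str = "",
    all_starts: bool = False,
) -> list[OrfHit]:
    """Find maximal M->stop peptides of length >= ``min_aa`` in all 6 frames.

    Only the first M of each stop-delimited segment is reported (the maximal
    ORF) unless ``all_starts`` is set. Peptides at the end of a translation
    with no stop codon are included only with ``include_open_ended``.
    """
    translations = six_frame_translate(sequence)
    seq_len = len(sequence)
    hits: list[OrfHit] = []
    for label, aa in translations.items():
        strand, frame = label[0], int(label[1])
        offset = frame - 1
        seg_start = 0
        segments = aa.split("*")
        for i, seg in enumerate(segments):
            has_stop = i < len(segments) - 1
            if has_stop or include_open_ended:
                starts = []
                first = seg.find("M")
                if first != -1:
                    starts.append(first)
                    if all_starts:
                        pos = seg.find("M", first + 1)
                        while pos != -1:
                            starts.append(pos)
                            pos = seg.find("M", pos + 1)
                for m in starts:
                    peptide = seg[m:]
                    if len(peptide) < min_aa:
                        continue
                    aa_start = seg_start + m
                    aa_end = aa_start + len(peptide)
                    nt_s, nt_e = _frame_orf_coords(
                        aa_start, len(peptide), offset, seq_len, strand
                    )
                    hits.append(
                        OrfHit(
                            source_id=source_id,
                            strand=strand,
                            frame=frame,
                            aa_start=aa_start,
                            aa_end=aa_end,
                            peptide=peptide,
                            nt_interval=GenomicInterval(
                                source_id or "seq", nt_s, nt_e, strand
                            ),
                        )
                    )
            seg_start += len(seg) + 1  # account for the stop column
    hits.sort(key=lambda h: (h.strand, h.frame, h.aa_start))
    return hits


def orf_hits_to_rows(hits: list[OrfHit]) -> list[dict]:
    """Flatten OrfHits for TSV output."""
    return [
        {
            "source": h.source_id,
            "strand": h.strand,
            "frame": h.frame,
            "aa_start": h.aa_start,
            "aa_end": h.aa_end,
            "length": len(h.peptide),
            "nt_start": h.nt_interval.start,
            "nt_end": h.nt_interval.end,
            "peptide": h.peptide,
        }
        for h in hits
    ]
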
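"""Readers/writers for the pipeline's file formats and its coordinate layer.

Internal coordinates are 0-based half-open throughout. Coordinates printed in
genome-browser style (e.g. ``chr6:77716945-77726366``) are 1-based inclusive
and must go through :func:`interval_from_1based` on ingest.

Supported formats: FASTA (via biopython), VCF 4.2 with the structural-variant
INFO dialect (SVTYPE/SVLEN/END, read via pysam), BED6 with the name column
encoding ``locus_id:feature_type``, and Newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("hervarch")

#: Sniffles2-style floor: a structural variant is a change >= 50 bases.
MIN_SV_LENGTH = 50

SV_TYPES = ("DEL", "INS", "DUP")

#: Feature types of a proviral locus annotation.
FEATURE_TYPES = ("LTR5", "LTR_MID", "LTR3", "INT_GAGPOL", "INT_ENV", "OTHER")

#: Map from annotation feature type to the repeat class used by the
#: architecture grammar.
FEATURE_CLASS = {
    "LTR5": "LTR",
    "LTR_MID": "LTR",
    "LTR3": "LTR",
    "INT_GAGPOL": "INT",
    "INT_ENV": "INT",
    "OTHER": "OTHER",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shift(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def to_1based(self) -> tuple[str, int, int]:
        """Return browser-style 1-based inclusive coordinates."""
        return self.chrom, self.start + 1, self.end


def interval_from_1based(
    chrom: str, start1: int, end1: int, strand: str = "."
) -> GenomicInterval:
    """Build an interval from 1-based inclusive (printed) coordinates."""
    return GenomicInterval(chrom, start1 - 1, end1, strand)


@dataclass(frozen=True)
class StructuralVariant:
    """One DEL/INS/DUP call.

    For DEL/DUP ``interval`` is the affected span; for INS it is the length-1
    anchor interval (the 0-based position of the VCF padding base). ``svlen``
    is stored as a positive number of bases regardless of the sign convention
    of the caller. ``carriers`` holds sample identifiers with any
    non-reference genotype.
    """

    id: str
    interval: GenomicInterval
    svtype: str
    svlen: int
    alt_sequence: str | None = None
    carriers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"{self.id}: unsupported SVTYPE {self.svtype!r}")
        if self.svlen < MIN_SV_LENGTH:
            raise ValueError(
                f"{self.id}: svlen {self.svlen} below the {MIN_SV_LENGTH}-base floor"
            )
        if self.svtype == "INS":
            if self.interval.length != 1:
                raise ValueError(f"{self.id}: INS anchor must be a length-1 interval")
            if self.alt_sequence is not None and len(self.alt_sequence) != self.svlen:
                raise ValueError(
                    f"{self.id}: INS alt sequence length {len(self.alt_sequence)} "
                    f"!= svlen {self.svlen}"
                )
        object.__setattr__(self, "carriers", frozenset(self.carriers))


@dataclass(frozen=True)
class LocusAnnotation:
    """A proviral locus and its ordered LTR/INT features."""

    locus_id: str
    span: GenomicInterval
    features: tuple[tuple[str, GenomicInterval], ...]

    def __post_init__(self) -> None:
        feats = tuple(sorted(self.features, key=lambda f: f[1].start))
        object.__setattr__(self, "features", feats)
        prev_end = None
        for ftype, ivl in feats:
            if ftype not in FEATURE_TYPES:
                raise ValueError(f"{self.locus_id}: unknown feature type {ftype!r}")
            if not self.span.contains(ivl):
                raise ValueError(
                    f"{self.locus_id}: feature {ftype} {ivl} outside locus span"
                )
            if prev_end is not None and ivl.start < prev_end:
                raise ValueError(
                    f"{self.locus_id}: overlapping features at {ivl.start}"
                )
            prev_end = ivl.end

    def features_of_class(self, klass: str) -> list[tuple[str, GenomicInterval]]:
        return [f for f in self.features if FEATURE_CLASS[f[0]] == klass]

    @property
    def int_features(self) -> list[tuple[str, GenomicInterval]]:
        return self.features_of_class("INT")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _info_scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0]
    return value


def read_sv_vcf(
    path: str | Path,
    cohort: Sequence[str] | None = None,
    min_svlen: int = MIN_SV_LENGTH,
    svtypes: Iterable[str] = SV_TYPES,
) -> list[StructuralVariant]:
    """Read structural variants from a VCF file.

    Records whose SVTYPE is missing are skipped with a logged warning; records
    with malformed coordinates raise. A sample is a carrier of a record when
    any of its genotype alleles is non-reference. VCFs without genotype
    columns mark the whole ``cohort`` (intended for single-sample files) as
    carriers.
    """
    svtypes = set(svtypes)
    out: list[StructuralVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        file_samples = list(vcf.header.samples)
        for rec in vcf:
            rid = rec.id or f"{rec.chrom}_{rec.pos}"
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                logger.warning("record %s has no SVTYPE; skipped", rid)
                continue
            svtype = str(_info_scalar(svtype))
            if svtype not in svtypes:
                continue
            svlen = rec.info.get("SVLEN")
            if svlen is not None:
                svlen = abs(int(_info_scalar(svlen)))
            else:
                end = rec.stop  # INFO END, 1-based inclusive
                svlen = end - rec.pos
            if svlen < min_svlen:
                continue
            pos0 = rec.pos - 1  # 0-based padding base
            if pos0 < 0:
                raise ValueError(f"record {rid}: malformed POS {rec.pos}")
            if svtype == "INS":
                interval = GenomicInterval(rec.chrom, pos0, pos0 + 1)
                alt = None
                if rec.alts and not rec.alts[0].startswith("<"):
                    alt = rec.alts[0][1:]  # strip the padding base
                    if len(alt) != svlen:
                        alt = rec.alts[0][-svlen:]
            else:
                interval = GenomicInterval(rec.chrom, pos0 + 1, pos0 + 1 + svlen)
                alt = None
            if file_samples:
                carriers = set()
                for sample in file_samples:
                    gt = rec.samples[sample].get("GT")
                    if gt and any(a not in (0, None) for a in gt):
                        carriers.add(sample)
            else:
                carriers = set(cohort or [])
            if alt is not None and svtype == "INS" and len(alt) != svlen:
                raise ValueError(f"record {rid}: ALT length != SVLEN")
            out.append(
                StructuralVariant(
                    id=rid,
                    interval=interval,
                    svtype=svtype,
                    svlen=svlen,
                    alt_sequence=alt,
                    carriers=frozenset(carriers),
                )
            )
    return out


def write_sv_vcf(
    path: str | Path,
    svs: Sequence[StructuralVariant],
    cohort: Sequence[str],
    contigs: Mapping[str, int],
    reference: Mapping[str, str] | None = None,
) -> None:
    """Write a multi-sample VCF 4.2 with SVTYPE/SVLEN/END INFO keys.

    Deletion SVLEN is emitted negative, following the long-read SV caller
    convention. INS records with a resolved alt sequence are written
    sequence-resolved (padding base + inserted sequence in ALT).
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of structural variant">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort),
    ]

    def ref_base(chrom: str, pos0: int) -> str:
        if reference is not None and 0 <= pos0 < len(reference[chrom]):
            return reference[chrom][pos0]
        return "N"

    for sv in sorted(svs, key=lambda s: (s.interval.chrom, s.interval.start)):
        if sv.svtype == "INS":
            pos0 = sv.interval.start
            pos = pos0 + 1
            base = ref_base(sv.interval.chrom, pos0)
            if sv.alt_sequence is not None:
                ref_f, alt_f = base, base + sv.alt_sequence
            else:
                ref_f, alt_f = base, "<INS>"
            end = pos
            svlen = sv.svlen
        else:
            pos0 = sv.interval.start - 1
            pos = pos0 + 1
            base = ref_base(sv.interval.chrom, pos0)
            ref_f, alt_f = base, f"<{sv.svtype}>"
            end = sv.interval.end  # 1-based inclusive last affected base
            svlen = -sv.svlen if sv.svtype == "DEL" else sv.svlen
        info = f"SVTYPE={sv.svtype};SVLEN={svlen};END={end}"
        gts = "\t".join("0/1" if s in sv.carriers else "0/0" for s in cohort)
        lines.append(
            f"{sv.interval.chrom}\t{pos}\t{sv.id}\t{ref_f}\t{alt_f}\t.\tPASS\t{info}\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_locus_bed(path: str | Path) -> list[LocusAnnotation]:
    """Read BED6 locus annotations (name column = ``locus_id:feature_type``).

    Lines with feature type ``SPAN`` define the locus span; other lines are
    features. If no SPAN line is present the span is the feature hull.
    """
    loci: dict[str, dict] = {}
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected >=4 BED columns")
        chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        strand = parts[5] if len(parts) > 5 else "."
        if ":" not in name:
            raise ValueError(f"{path}:{ln}: name {name!r} is not locus_id:feature_type")
        locus_id, ftype = name.rsplit(":", 1)
        entry = loci.setdefault(locus_id, {"span": None, "features": []})
        ivl = GenomicInterval(chrom, start, end, strand if strand in "+-" else ".")
        if ftype == "SPAN":
            entry["span"] = ivl
        else:
            entry["features"].append((ftype, ivl))
    out = []
    for locus_id, entry in loci.items():
        feats = entry["features"]
        span = entry["span"]
        if span is None:
            if not feats:
                raise ValueError(f"locus {locus_id} has no features and no span")
            span = GenomicInterval(
                feats[0][1].chrom,
                min(f[1].start for f in feats),
                max(f[1].end for f in feats),
            )
        out.append(LocusAnnotation(locus_id, span, tuple(feats)))
    out.sort(key=lambda l: (l.span.chrom, l.span.start))
    return out


def write_locus_bed(path: str | Path, loci: Sequence[LocusAnnotation]) -> None:
    lines = []
    for locus in loci:
        s = locus.span
        lines.append(f"{s.chrom}\t{s.start}\t{s.end}\t{locus.locus_id}:SPAN\t0\t+")
        for ftype, ivl in locus.features:
            lines.append(
                f"{ivl.chrom}\t{ivl.start}\t{ivl.end}\t{locus.locus_id}:{ftype}\t0\t+"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # biopython wraps at 60 columns


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Write a phylogenetic tree (``hervarch.phylo.PhyloTree``) as Newick."""
    Path(path).write_text(tree.to_newick() + "\n")


def read_newick(path: str | Path):
    """Read a Newick file back into a :class:`hervarch.phylo.PhyloTree`."""
    import dendropy

    from .phylo import PhyloTree, TreeNode

    dtree = dendropy.Tree.get(path=str(path), schema="newick")

    def convert(node) -> TreeNode:
        if node.is_leaf():
            return TreeNode(name=node.taxon.label if node.taxon else node.label)
        children = tuple(
            (convert(ch), ch.edge.length if ch.edge.length is not None else 0.0)
            for ch in node.child_nodes()
        )
        return TreeNode(name=None, children=children)

    return PhyloTree(root=convert(dtree.seed_node))
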
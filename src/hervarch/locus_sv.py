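"""Intersection of structural variants with proviral loci and cohort tables.

An SV is assigned to a locus when it overlaps the locus span by at least one
base (insertions: when the anchor point lies inside the span). Cohort
frequencies are per individual (a sample either carries an SV or does not),
matching how long-read cohort studies report "% of individuals with that SV",
not allele frequencies.

The deletion-size (290 b) and large-SV (8.4 kb) thresholds that appear in the
published frequency statements are configuration constants here, not
hard-coded magic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd

from .formats import FEATURE_CLASS, GenomicInterval, LocusAnnotation, StructuralVariant

#: "DELs over 290 bases in length" — the small-deletion size floor used in
#: the cohort frequency predicates.
DEL_SIZE_THRESHOLD = 290

#: "a DEL or INS over 8.4 kb in length" — the provirus-scale SV threshold.
LARGE_SV_THRESHOLD = 8400


@dataclass(frozen=True)
class LocalizedSV:
    """One SV assigned to (at most) one locus."""

    sv: StructuralVariant
    locus_id: str | None
    features_hit: frozenset[str] = frozenset()
    spans_whole_coding: bool = False
    extends_beyond_locus: bool = False


def _ins_anchor(sv: StructuralVariant) -> int:
    # 0-based padding base of the insertion point
    return sv.interval.start


def _nearest_upstream_feature(
    locus: LocusAnnotation, pos: int
) -> str | None:
    best = None
    for ftype, ivl in locus.features:
        if ivl.end <= pos:
            best = ftype
        elif ivl.start > pos:
            break
    if best is None and locus.features:
        best = locus.features[0][0]  # upstream of everything: nearest feature
    return best


def localize(
    svs: Sequence[StructuralVariant],
    loci: Sequence[LocusAnnotation],
    whole_coding: str = "overlap",
) -> list[LocalizedSV]:
    """Assign each SV to the locus it overlaps and record feature context.

    ``whole_coding`` selects how "DEL spans the whole coding region" is
    judged: ``"overlap"`` (the DEL overlaps every INT feature, default) or
    ``"containment"`` (the DEL fully contains every INT feature). SVs hitting
    no locus are returned with ``locus_id=None``.
    """
    if whole_coding not in ("overlap", "containment"):
        raise ValueError(f"unknown whole_coding mode {whole_coding!r}")
    for i, a in enumerate(loci):
        for b in loci[i + 1:]:
            if a.span.overlaps(b.span):
                raise ValueError(f"loci {a.locus_id} and {b.locus_id} overlap")
    out = []
    for sv in svs:
        assigned: LocusAnnotation | None = None
        for locus in loci:
            if sv.svtype == "INS":
                anchor = _ins_anchor(sv)
                if (
                    locus.span.chrom == sv.interval.chrom
                    and locus.span.start <= anchor < locus.span.end
                ):
                    assigned = locus
                    break
            elif sv.interval.overlaps(locus.span):
                assigned = locus
                break
        if assigned is None:
            out.append(LocalizedSV(sv=sv, locus_id=None))
            continue
        if sv.svtype == "INS":
            anchor = _ins_anchor(sv)
            hit = None
            for ftype, ivl in assigned.features:
                if ivl.start <= anchor < ivl.end:
                    hit = ftype
                    break
            if hit is None:
                hit = _nearest_upstream_feature(assigned, anchor)
            features = frozenset([hit]) if hit else frozenset()
            spans_coding = False
            beyond = False
        else:
            features = frozenset(
                ftype
                for ftype, ivl in assigned.features
                if sv.interval.overlaps(ivl)
            )
            if not features:  # inside the span but between features
                mid = (
                    max(sv.interval.start, assigned.span.start)
                    + min(sv.interval.end, assigned.span.end)
                ) // 2
                up = _nearest_upstream_feature(assigned, mid)
                features = frozenset([up]) if up else frozenset()
            ints = assigned.int_features
            if sv.svtype == "DEL" and ints:
                if whole_coding == "overlap":
                    spans_coding = all(sv.interval.overlaps(ivl) for _, ivl in ints)
                else:
                    spans_coding = all(sv.interval.contains(ivl) for _, ivl in ints)
            else:
                spans_coding = False
            beyond = (
                sv.interval.start < assigned.span.start
                or sv.interval.end > assigned.span.end
            )
        out.append(
            LocalizedSV(
                sv=sv,
                locus_id=assigned.locus_id,
                features_hit=features,
                spans_whole_coding=spans_coding,
                extends_beyond_locus=beyond,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cohort tabulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Predicate:
    """A named pure function over one sample's localized SVs at one locus."""

    name: str
    locus_id: str
    fn: Callable[[list[LocalizedSV]], bool]


def min_dels(locus_id: str, k: int = 1, min_len: int = 0) -> Predicate:
    """At least ``k`` deletions longer than ``min_len`` bases in the locus."""

    def fn(svs: list[LocalizedSV]) -> bool:
        return sum(1 for s in svs if s.sv.svtype == "DEL" and s.sv.svlen > min_len) >= k

    label = f"ge{k}_del_gt{min_len}b" if min_len else f"ge{k}_del"
    return Predicate(label, locus_id, fn)


def any_sv(
    locus_id: str, min_len: int = 0, svtypes: tuple[str, ...] = ("DEL", "INS")
) -> Predicate:
    """Any SV of the given types longer than ``min_len`` bases in the locus."""

    def fn(svs: list[LocalizedSV]) -> bool:
        return any(s.sv.svtype in svtypes and s.sv.svlen > min_len for s in svs)

    label = f"any_{'_'.join(t.lower() for t in svtypes)}_gt{min_len}b"
    return Predicate(label, locus_id, fn)


def ins_in_feature(locus_id: str, feature: str) -> Predicate:
    """Any insertion anchored in the named feature (type or class)."""

    def fn(svs: list[LocalizedSV]) -> bool:
        for s in svs:
            if s.sv.svtype != "INS":
                continue
            if feature in s.features_hit:
                return True
            if any(FEATURE_CLASS.get(f) == feature for f in s.features_hit):
                return True
        return False

    return Predicate(f"ins_in_{feature.lower()}", locus_id, fn)


def no_sv(locus_id: str) -> Predicate:
    """The sample carries no SV at all within the locus (reference state)."""
    return Predicate("reference_no_sv", locus_id, lambda svs: len(svs) == 0)


def default_predicates(
    tandem_locus: str = "sim7p22",
    single_locus: str = "sim6q14",
    del_threshold: int = DEL_SIZE_THRESHOLD,
    large_threshold: int = LARGE_SV_THRESHOLD,
) -> list[Predicate]:
    """The published cohort-frequency predicates."""
    return [
        min_dels(tandem_locus, k=1, min_len=del_threshold),
        min_dels(tandem_locus, k=2, min_len=del_threshold),
        any_sv(single_locus, min_len=large_threshold, svtypes=("DEL", "INS")),
        min_dels(tandem_locus, k=1, min_len=0),
        no_sv(single_locus),
    ]


@dataclass
class CohortTable:
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["locus", "predicate", "n", "N", "fraction"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def fraction(self, locus: str, predicate: str) -> float:
        for row in self.rows:
            if row["locus"] == locus and row["predicate"] == predicate:
                return row["fraction"]
        raise KeyError((locus, predicate))


def sample_locus_svs(
    localized: Sequence[LocalizedSV], cohort: Sequence[str]
) -> dict[str, dict[str, list[LocalizedSV]]]:
    """Group localized SVs by carrier sample and locus."""
    out: dict[str, dict[str, list[LocalizedSV]]] = {s: {} for s in cohort}
    for lsv in localized:
        if lsv.locus_id is None:
            continue
        for sample in lsv.sv.carriers:
            if sample in out:
                out[sample].setdefault(lsv.locus_id, []).append(lsv)
    return out


def tabulate(
    localized: Sequence[LocalizedSV],
    cohort: Sequence[str],
    predicates: Sequence[Predicate],
) -> CohortTable:
    """Count, per (locus, predicate), the samples satisfying the predicate.

    The denominator is always the full cohort size.
    """
    if not cohort:
        raise ValueError("empty cohort")
    per_sample = sample_locus_svs(localized, cohort)
    table = CohortTable()
    for pred in predicates:
        n = sum(
            1
            for sample in cohort
            if pred.fn(per_sample[sample].get(pred.locus_id, []))
        )
        table.rows.append(
            {
                "locus": pred.locus_id,
                "predicate": pred.name,
                "n": n,
                "N": len(cohort),
                "fraction": n / len(cohort),
            }
        )
    return table
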
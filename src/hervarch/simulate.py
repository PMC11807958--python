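"""Synthetic cohort generator for proviral structural-variant analysis.

Builds four mock proviral loci on their own contigs and a multi-sample SV
cohort over them, so that every downstream stage (locus intersection, ORF
scanning, protein matching, repeat segmentation, architecture calling,
phylogeny) can be exercised with no external data:

* ``sim6q14``  — a single canonical provirus (LTR5 - Gag-Pol INT - Env INT -
  LTR3); its internal region carries reverse-orientation coding sequences for
  the packaged mock Gag/Pro/Pol/Env proteins, mirroring a locus that can make
  full-length protein on the reverse strand.
* ``sim7p22``  — a tandem-repeat locus (three LTRs sandwiching two internal
  regions, the two INT copies independently diverged).
* ``sim19q11`` / ``sim11q22`` — control proviruses, each carrying exactly one
  engineered SV site.

Default event prevalences are the published cohort fractions, so recovering
them from the emitted VCF/BED/FASTA is a parameter-recovery experiment. Two
departures from plain per-event independent Bernoulli carriage are supported
because the published joint fractions require them (see docs/methods.md):
mutually exclusive event *groups* (one categorical draw per sample, used for
the 6q14-style whole-provirus DEL vs. tandem-forming INS, which are
alternative states of one locus) and *linked* events (carried only on top of
a parent event, with the configured value still the marginal prevalence).

Everything is deterministic given the config (seed included): two runs with
the same config produce byte-identical FASTA/VCF/BED/TSV output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .formats import (
    GenomicInterval,
    LocusAnnotation,
    StructuralVariant,
    write_fasta,
    write_locus_bed,
    write_sv_vcf,
)
from .protmatch import ReferenceProtein, mock_reference_proteins
from .segment import BlockStructure, RepeatBlock
from .architecture import apply_recombination  # noqa: F401  (re-export: part of this module's surface)

#: Published cohort fractions used as default marginal event prevalences.
DEFAULT_PREVALENCES = {
    # tandem locus: the ~8.5-kb mid-locus recombinational deletion (point 2
    # of the published conclusions: ~80% of individuals)
    "7p22_mid_recombination_del": 0.80,
    # 5'-LTR-spanning deletion; sets tandem retention to ~5-6% of the cohort
    "7p22_ltr5_del": 0.70,
    # the ~75% companion deletion, carried on the recombined haplotype
    "7p22_intb_small_del": 0.75,
    # rare deletion running out of the 3' end of the tandem locus (~1%)
    "7p22_spanning_del": 0.01,
    # rare insertion in the protein-coding region (<1%)
    "7p22_coding_ins": 0.005,
    # single-provirus locus: whole-provirus DEL without concomitant INS (~32%)
    "6q14_provirus_del": 0.32,
    # ~8.4-kb tandem-forming insertion (~4%), exclusive with the DEL above
    "6q14_tandem_ins": 0.04,
    # small insertions in the 5' LTR (~3%) and Gag-Pol region (~2%)
    "6q14_ltr5_ins": 0.03,
    "6q14_gagpol_ins": 0.02,
    # control loci: one engineered SV each (prevalence not published)
    "19q11_int_del": 0.10,
    "11q22_provirus_del": 0.10,
}

EVENT_KINDS = (
    "ltr_ltr_recombination_deletion",
    "tandem_insertion",
    "feature_deletion",
    "small_insertion",
)


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort."""

    n_samples: int = 222
    seed: int = 0
    ltr_length: int = 968
    int_gagpol_length: int = 4886
    int_env_length: int = 2600
    divergence: float = 0.02
    flank: int = 1000
    dropout: float = 0.0  # per-sample per-event false-negative probability
    encode_proteins: bool = True
    prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for name in ("ltr_length", "int_gagpol_length", "int_env_length", "flank"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name, p in self.prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {name}={p} outside [0,1]")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0,1)")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0,1]")

    @property
    def int_length(self) -> int:
        return self.int_gagpol_length + self.int_env_length

    @property
    def canonical_length(self) -> int:
        return 2 * self.ltr_length + self.int_length

    @property
    def tandem_length(self) -> int:
        return 3 * self.ltr_length + 2 * self.int_length


@dataclass(frozen=True)
class SimEvent:
    """One cohort event: a DEL span or an INS anchor, locus-relative."""

    name: str
    kind: str
    locus_id: str
    svtype: str
    span: tuple[int, int] | None = None  # DEL span, locus-relative (may overhang)
    anchor: int | None = None  # INS insertion point, locus-relative
    alt_kind: str | None = None  # "cassette" (LTR+INT copy) or "random"
    alt_length: int = 0
    group: str | None = None  # mutually exclusive group
    linked_to: str | None = None  # carried only on top of this parent event

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.svtype == "DEL" and self.span is None:
            raise ValueError(f"{self.name}: DEL event needs a span")
        if self.svtype == "INS" and (self.anchor is None or self.alt_kind is None):
            raise ValueError(f"{self.name}: INS event needs anchor and alt_kind")


@dataclass
class SimReference:
    sequences: dict[str, str]
    loci: list[LocusAnnotation]
    consensi: dict[str, str]
    proteins: list[ReferenceProtein]

    def locus(self, locus_id: str) -> LocusAnnotation:
        for locus in self.loci:
            if locus.locus_id == locus_id:
                return locus
        raise KeyError(locus_id)


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent substitutions (no indels) at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _codon_table() -> dict[str, list[str]]:
    table: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        table.setdefault(aa, []).append(codon)
    table["*"] = sorted(standard_dna_table.stop_codons)
    for aa in table:
        table[aa].sort()
    return table


_CODONS = _codon_table()


def _encode_cds(rng: np.random.Generator, protein: str) -> str:
    """A coding sequence for the peptide plus a stop codon (random codons)."""
    parts = [
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein + "*"
    ]
    return "".join(parts)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _int_consensus(
    rng: np.random.Generator, config: SimConfig, proteins: Sequence[ReferenceProtein]
) -> str:
    """The internal-region consensus: Gag-Pol part then Env part.

    When they fit, reverse-orientation CDSs for the mock proteins are embedded
    (Gag/Pro/Pol in the Gag-Pol part, Env in the Env part), so six-frame
    scanning of the locus recovers full-length mock proteins on the reverse
    strand. Otherwise the region is random sequence.
    """
    by_name = {p.name: p for p in proteins}
    g_len, e_len = config.int_gagpol_length, config.int_env_length
    gag_pro_pol = sum(len(by_name[n].sequence) + 1 for n in ("Gag", "Pro", "Pol")) * 3
    env = (len(by_name["Env"].sequence) + 1) * 3
    if config.encode_proteins and gag_pro_pol <= g_len and env <= e_len:
        payload_g = (
            _encode_cds(rng, by_name["Gag"].sequence)
            + _encode_cds(rng, by_name["Pro"].sequence)
            + _encode_cds(rng, by_name["Pol"].sequence)
        )
        payload_g += _random_dna(rng, g_len - len(payload_g))
        payload_e = _encode_cds(rng, by_name["Env"].sequence)
        payload_e += _random_dna(rng, e_len - len(payload_e))
        return _revcomp(payload_g) + _revcomp(payload_e)
    return _random_dna(rng, g_len + e_len)


def build_reference(config: SimConfig) -> SimReference:
    """Build the four mock loci, their annotations, and the consensi."""
    rng = np.random.default_rng([config.seed, 0])
    proteins = mock_reference_proteins()
    ltr = _random_dna(rng, config.ltr_length)
    intseq = _int_consensus(rng, config, proteins)
    L, G, E = config.ltr_length, config.int_gagpol_length, config.int_env_length
    I = G + E
    div = config.divergence

    def canonical_parts(pristine_int: bool):
        parts = [
            ("LTR5", _mutate(rng, ltr, div)),
            ("INT", intseq if pristine_int else _mutate(rng, intseq, div)),
            ("LTR3", _mutate(rng, ltr, div)),
        ]
        return parts

    def tandem_parts():
        return [
            ("LTR5", _mutate(rng, ltr, div)),
            ("INT", _mutate(rng, intseq, div)),
            ("LTR_MID", _mutate(rng, ltr, div)),
            ("INT", _mutate(rng, intseq, div)),
            ("LTR3", _mutate(rng, ltr, div)),
        ]

    layouts = {
        # the canonical locus keeps the consensus INT verbatim so its coding
        # potential is intact; repeat copies elsewhere diverge at `divergence`
        "sim6q14": canonical_parts(pristine_int=True),
        "sim7p22": tandem_parts(),
        "sim19q11": canonical_parts(pristine_int=False),
        "sim11q22": canonical_parts(pristine_int=False),
    }
    sequences: dict[str, str] = {}
    loci: list[LocusAnnotation] = []
    for locus_id, parts in layouts.items():
        flank_l = _random_dna(rng, config.flank)
        flank_r = _random_dna(rng, config.flank)
        body = "".join(seq for _, seq in parts)
        sequences[locus_id] = flank_l + body + flank_r
        features = []
        cursor = config.flank
        for ftype, seq in parts:
            if ftype == "INT":
                features.append(
                    ("INT_GAGPOL", GenomicInterval(locus_id, cursor, cursor + G))
                )
                features.append(
                    ("INT_ENV", GenomicInterval(locus_id, cursor + G, cursor + G + E))
                )
            else:
                features.append(
                    (ftype, GenomicInterval(locus_id, cursor, cursor + len(seq)))
                )
            cursor += len(seq)
        span = GenomicInterval(locus_id, config.flank, cursor)
        loci.append(LocusAnnotation(locus_id, span, tuple(features)))
    return SimReference(
        sequences=sequences,
        loci=loci,
        consensi={"LTR": ltr, "INT": intseq},
        proteins=proteins,
    )


# ---------------------------------------------------------------------------
# Default event set
# ---------------------------------------------------------------------------

def default_events(config: SimConfig) -> list[SimEvent]:
    """The default (published-fraction) event set, spans derived from the
    configured block lengths."""
    L, I = config.ltr_length, config.int_length
    G = config.int_gagpol_length
    if L < 600 or G < 3100 or I < 3000:
        raise ValueError(
            "default events need ltr_length >= 600, int_gagpol_length >= 3100; "
            "pass an explicit event list for smaller mock proviruses"
        )
    # tandem locus coordinates (locus-relative):
    # LTR1 [0,L)  INTa [L,L+I)  LTR2 [L+I,2L+I)  INTb [2L+I,2L+2I)  LTR3 [2L+2I,3L+2I)
    c = I - min(2000, I // 2)  # aligned INTxINT crossover offset
    r_start, r_end = L + c, 2 * L + I + c  # deletes end of INTa, LTR2, start of INTb
    a_start = r_end + 300
    overhang = min(200, config.flank // 2)
    events = [
        SimEvent(
            name="7p22_mid_recombination_del",
            kind="ltr_ltr_recombination_deletion",
            locus_id="sim7p22",
            svtype="DEL",
            span=(r_start, r_end),
        ),
        SimEvent(
            name="7p22_ltr5_del",
            kind="feature_deletion",
            locus_id="sim7p22",
            svtype="DEL",
            span=(-overhang, L + 100),  # removes the 5' LTR, runs into INTa
        ),
        SimEvent(
            name="7p22_intb_small_del",
            kind="feature_deletion",
            locus_id="sim7p22",
            svtype="DEL",
            span=(a_start, a_start + 322),
            linked_to="7p22_mid_recombination_del",
        ),
        SimEvent(
            name="7p22_spanning_del",
            kind="feature_deletion",
            locus_id="sim7p22",
            svtype="DEL",
            span=(2 * L + 2 * I - 908, 3 * L + 2 * I + overhang),
        ),
        SimEvent(
            name="7p22_coding_ins",
            kind="small_insertion",
            locus_id="sim7p22",
            svtype="INS",
            anchor=L + 3000,
            alt_kind="random",
            alt_length=300,
        ),
        SimEvent(
            name="6q14_provirus_del",
            kind="ltr_ltr_recombination_deletion",
            locus_id="sim6q14",
            svtype="DEL",
            span=(0, L + I),  # LTR1xLTR3 recombination: solo LTR remains
            group="6q14_core",
        ),
        SimEvent(
            name="6q14_tandem_ins",
            kind="tandem_insertion",
            locus_id="sim6q14",
            svtype="INS",
            anchor=L + I + 1,  # one base into the 3' LTR
            alt_kind="cassette",
            alt_length=L + I,
            group="6q14_core",
        ),
        SimEvent(
            name="6q14_ltr5_ins",
            kind="small_insertion",
            locus_id="sim6q14",
            svtype="INS",
            anchor=500,
            alt_kind="random",
            alt_length=300,
        ),
        SimEvent(
            name="6q14_gagpol_ins",
            kind="small_insertion",
            locus_id="sim6q14",
            svtype="INS",
            anchor=L + 3000,
            alt_kind="random",
            alt_length=300,
        ),
        SimEvent(
            name="19q11_int_del",
            kind="feature_deletion",
            locus_id="sim19q11",
            svtype="DEL",
            span=(L + 1032, L + 1032 + 322),
        ),
        SimEvent(
            name="11q22_provirus_del",
            kind="feature_deletion",
            locus_id="sim11q22",
            svtype="DEL",
            span=(100, 100 + min(8497, 2 * L + I - 200)),
        ),
    ]
    return events


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    events: list[SimEvent]
    samples: list[str]
    carriers: dict[str, frozenset[str]]  # event name -> carrier samples
    svs: list[StructuralVariant]
    truth: pd.DataFrame
    reference: SimReference
    truth_alt_structures: dict[str, BlockStructure]

    def carrier_fraction(self, event_name: str) -> float:
        return len(self.carriers[event_name]) / len(self.samples)


def draw_carriers(
    config: SimConfig,
    events: Sequence[SimEvent],
    rng: np.random.Generator | None = None,
) -> dict[str, frozenset[str]]:
    """Per-sample event carriage.

    Ungrouped, unlinked events are independent Bernoulli draws at their
    configured prevalence. Events sharing a ``group`` are mutually exclusive
    (one categorical draw; prevalences must sum to <= 1). A ``linked_to``
    event occurs only in carriers of its parent, with conditional probability
    prevalence/parent_prevalence, so its configured value stays the marginal.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    n = config.n_samples
    samples = [f"S{i:03d}" for i in range(n)]
    for ev in events:
        if ev.name not in config.prevalences:
            raise ValueError(f"no prevalence configured for event {ev.name!r}")
    by_name = {ev.name: ev for ev in events}
    group_offsets: dict[str, float] = {}
    group_draws: dict[str, np.ndarray] = {}
    for ev in events:
        if ev.group:
            total = group_offsets.get(ev.group, 0.0) + config.prevalences[ev.name]
            if total > 1.0 + 1e-12:
                raise ValueError(f"group {ev.group!r} prevalences sum above 1")
            group_offsets[ev.group] = total
    group_offsets = {g: 0.0 for g in group_offsets}

    carriers: dict[str, frozenset[str]] = {}
    carrier_sets: dict[str, np.ndarray] = {}
    for ev in events:
        u = rng.random(n)  # exactly one draw array per event, in list order
        p = config.prevalences[ev.name]
        if ev.group:
            if ev.group not in group_draws:
                group_draws[ev.group] = u
            gu = group_draws[ev.group]
            lo = group_offsets[ev.group]
            mask = (gu >= lo) & (gu < lo + p)
            group_offsets[ev.group] = lo + p
        elif ev.linked_to:
            parent = by_name.get(ev.linked_to)
            if parent is None:
                raise ValueError(f"{ev.name}: unknown parent event {ev.linked_to!r}")
            pp = config.prevalences[parent.name]
            if p > pp + 1e-12:
                raise ValueError(
                    f"{ev.name}: marginal prevalence {p} exceeds parent's {pp}"
                )
            cond = 0.0 if pp == 0 else p / pp
            parent_mask = carrier_sets[parent.name]
            mask = parent_mask & (u < cond)
        else:
            mask = u < p
        carrier_sets[ev.name] = mask
    if config.dropout > 0:
        for ev in events:
            drop = rng.random(n) < config.dropout
            carrier_sets[ev.name] = carrier_sets[ev.name] & ~drop
    for ev in events:
        carriers[ev.name] = frozenset(
            samples[i] for i in np.flatnonzero(carrier_sets[ev.name])
        )
    return carriers


def _event_alt(
    event: SimEvent, config: SimConfig, reference: SimReference,
    rng: np.random.Generator,
) -> tuple[str, BlockStructure]:
    """Alt sequence of an INS event plus its construction-truth blocks."""
    if event.alt_kind == "cassette":
        ltr = _mutate(rng, reference.consensi["LTR"], config.divergence)
        intseq = _mutate(rng, reference.consensi["INT"], config.divergence)
        alt = ltr + intseq
        blocks = (
            RepeatBlock("LTR", (0, len(ltr)), (0, len(ltr)), "+", 1 - config.divergence, False),
            RepeatBlock("INT", (len(ltr), len(alt)), (0, len(intseq)), "+",
                        1 - config.divergence, False),
        )
        truth = BlockStructure(event.name, blocks, 0.0, len(alt))
    else:
        alt = _random_dna(rng, event.alt_length)
        truth = BlockStructure(event.name, (), 1.0, len(alt))
    return alt, truth


def build_svs(
    config: SimConfig,
    events: Sequence[SimEvent],
    reference: SimReference,
    carriers: Mapping[str, frozenset[str]],
) -> tuple[list[StructuralVariant], dict[str, BlockStructure]]:
    """Materialize carried events as StructuralVariant records."""
    rng = np.random.default_rng([config.seed, 2])
    svs: list[StructuralVariant] = []
    truth_alts: dict[str, BlockStructure] = {}
    for ev in events:
        locus = reference.locus(ev.locus_id)
        offset = locus.span.start
        if ev.svtype == "INS":
            alt, truth = _event_alt(ev, config, reference, rng)  # always drawn
        if not carriers[ev.name]:
            continue
        if ev.svtype == "DEL":
            start = offset + ev.span[0]
            end = offset + ev.span[1]
            contig_len = len(reference.sequences[ev.locus_id])
            if start < 0 or end > contig_len:
                raise ValueError(f"{ev.name}: span outside contig")
            sv = StructuralVariant(
                id=ev.name,
                interval=GenomicInterval(ev.locus_id, start, end),
                svtype="DEL",
                svlen=end - start,
                carriers=carriers[ev.name],
            )
        else:
            point = offset + ev.anchor  # inserted sequence starts here
            sv = StructuralVariant(
                id=ev.name,
                interval=GenomicInterval(ev.locus_id, point - 1, point),
                svtype="INS",
                svlen=len(alt),
                alt_sequence=alt,
                carriers=carriers[ev.name],
            )
            truth_alts[ev.name] = truth
        svs.append(sv)
    return svs, truth_alts


def apply_event_to_sequence(
    reference: SimReference, event: SimEvent, alt: str | None = None
) -> str:
    """The contig sequence after applying one event (for consistency checks)."""
    seq = reference.sequences[event.locus_id]
    offset = reference.locus(event.locus_id).span.start
    if event.svtype == "DEL":
        s, e = offset + event.span[0], offset + event.span[1]
        return seq[:s] + seq[e:]
    if alt is None:
        raise ValueError("INS event needs its alt sequence")
    point = offset + event.anchor
    return seq[:point] + alt + seq[point:]


def simulate_cohort(
    config: SimConfig,
    events: Sequence[SimEvent] | None = None,
    outdir: str | Path | None = None,
) -> SimResult:
    """Generate the cohort; optionally write reference.fa / loci.bed /
    cohort.vcf / consensi.fa / truth.tsv to ``outdir``."""
    if events is None:
        events = default_events(config)
    reference = build_reference(config)
    carriers = draw_carriers(config, events)
    svs, truth_alts = build_svs(config, events, reference, carriers)
    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    rows = []
    by_name = {ev.name: ev for ev in events}
    for sv in svs:
        ev = by_name[sv.id]
        for sample in sorted(sv.carriers):
            rows.append(
                {
                    "sample": sample,
                    "event": ev.name,
                    "locus": ev.locus_id,
                    "kind": ev.kind,
                    "svtype": sv.svtype,
                    "svlen": sv.svlen,
                }
            )
    truth = pd.DataFrame(
        rows, columns=["sample", "event", "locus", "kind", "svtype", "svlen"]
    ).sort_values(["sample", "locus", "event"]).reset_index(drop=True)
    result = SimResult(
        config=config,
        events=list(events),
        samples=samples,
        carriers=carriers,
        svs=svs,
        truth=truth,
        reference=reference,
        truth_alt_structures=truth_alts,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "reference.fa", reference.sequences)
        write_fasta(outdir / "consensi.fa", reference.consensi)
        write_locus_bed(outdir / "loci.bed", reference.loci)
        contigs = {name: len(seq) for name, seq in reference.sequences.items()}
        write_sv_vcf(
            outdir / "cohort.vcf", svs, samples, contigs, reference.sequences
        )
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        manifest = {
            "config": asdict(config),
            "events": [asdict(ev) for ev in events],
            "files": [
                "reference.fa", "consensi.fa", "loci.bed", "cohort.vcf", "truth.tsv",
            ],
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return result
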
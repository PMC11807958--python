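"""Architecture grammar, recombination model, per-sample calls."""

import numpy as np
import pytest

from hervarch import (
    GenomicInterval,
    LocusAnnotation,
    StructuralVariant,
    apply_recombination,
    call_architecture,
    enumerate_recombinations,
    reference_blocks,
    sample_architecture,
)
from hervarch.locus_sv import LocalizedSV, localize
from hervarch.segment import BlockStructure, RepeatBlock


def structure(*klasses, block_len=500):
    blocks = tuple(
        RepeatBlock(k, (i * block_len, (i + 1) * block_len), (0, block_len), "+", 1.0, False)
        for i, k in enumerate(klasses)
    )
    return BlockStructure("s", blocks, 0.0, block_len * len(klasses))


@pytest.mark.parametrize(
    "klasses,label",
    [
        (("LTR", "INT", "LTR"), "canonical"),
        (("LTR", "INT", "INT", "LTR"), "canonical"),  # consecutive INT collapse
        (("LTR", "INT", "LTR", "INT", "LTR"), "tandem"),
        (("LTR", "INT", "INT", "LTR", "INT", "INT", "LTR"), "tandem"),
        (("INT", "LTR", "INT"), "int_sandwich"),
        (("LTR",), "solo_ltr"),
        (("LTR", "INT"), "truncated"),
        (("INT", "LTR"), "truncated"),
        (("INT",), "other"),
        (("LTR", "LTR"), "other"),
        ((), "other"),
    ],
)
def test_architecture_grammar(klasses, label):
    assert call_architecture(structure(*klasses)).label == label


def test_other_blocks_are_transparent():
    with_sva = structure("LTR", "SVA", "INT", "OTHER", "LTR")
    assert call_architecture(with_sva).label == "canonical"


def test_grammar_ignores_block_identity_beyond_class():
    """Permuting strands/identities with the same class pattern keeps the label."""
    a = structure("LTR", "INT", "LTR")
    blocks = tuple(
        RepeatBlock(b.klass, b.query_interval, b.consensus_interval, "-", 0.8, False)
        for b in a.blocks
    )
    b = BlockStructure("s", blocks, 0.0, a.query_length)
    assert call_architecture(a).label == call_architecture(b).label == "canonical"


def test_recombination_tandem_to_canonical():
    tandem = structure("LTR", "INT", "LTR", "INT", "LTR")
    out, deleted = apply_recombination(tandem, 0, 2)
    assert call_architecture(out).label == "canonical"
    assert deleted == 1000  # inter-start distance of LTR#0 and LTR#1


def test_recombination_canonical_to_solo_ltr():
    canonical = structure("LTR", "INT", "LTR")
    out, deleted = apply_recombination(canonical, 0, 2)
    assert call_architecture(out).label == "solo_ltr"
    assert deleted == 1000


def test_recombination_requires_ltr_blocks():
    canonical = structure("LTR", "INT", "LTR")
    with pytest.raises(ValueError, match="LTR"):
        apply_recombination(canonical, 0, 1)
    with pytest.raises(ValueError):
        apply_recombination(canonical, 2, 0)


def test_enumerate_tandem_products():
    """C(3,2) = 3 events on a tandem: two collapse to canonical, the outer
    pair leaves a solo LTR (exhaustive enumeration oracle)."""
    tandem = structure("LTR", "INT", "LTR", "INT", "LTR")
    events = enumerate_recombinations(tandem)
    assert len(events) == 3
    labels = sorted(e.product.label for e in events)
    assert labels == ["canonical", "canonical", "solo_ltr"]


def test_enumerate_canonical_and_solo():
    assert [e.product.label for e in enumerate_recombinations(structure("LTR", "INT", "LTR"))] == ["solo_ltr"]
    assert enumerate_recombinations(structure("LTR")) == []


def test_recombination_closure():
    """Re-applying apply_recombination to each enumerated source reproduces
    the recorded product and deleted length."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        klasses = tuple(rng.choice(["LTR", "INT", "OTHER"], size=rng.integers(2, 8)))
        st = structure(*klasses, block_len=int(rng.integers(200, 900)))
        for ev in enumerate_recombinations(st):
            product, deleted = apply_recombination(st, ev.left_block, ev.right_block)
            assert deleted == ev.deleted_length
            assert call_architecture(product).label == ev.product.label


# ---------------------------------------------------------------------------
# per-sample architecture
# ---------------------------------------------------------------------------

L, G, E = 968, 4886, 2600
I = G + E


def tandem_locus(chrom="simT", start=1000):
    coords = [
        ("LTR5", 0, L),
        ("INT_GAGPOL", L, L + G),
        ("INT_ENV", L + G, L + I),
        ("LTR_MID", L + I, 2 * L + I),
        ("INT_GAGPOL", 2 * L + I, 2 * L + I + G),
        ("INT_ENV", 2 * L + I + G, 2 * L + 2 * I),
        ("LTR3", 2 * L + 2 * I, 3 * L + 2 * I),
    ]
    feats = tuple(
        (f, GenomicInterval(chrom, start + s, start + e)) for f, s, e in coords
    )
    return LocusAnnotation("simT", GenomicInterval(chrom, start, start + 3 * L + 2 * I), feats)


def canonical_locus(chrom="simC", start=1000):
    coords = [
        ("LTR5", 0, L),
        ("INT_GAGPOL", L, L + G),
        ("INT_ENV", L + G, L + I),
        ("LTR3", L + I, 2 * L + I),
    ]
    feats = tuple(
        (f, GenomicInterval(chrom, start + s, start + e)) for f, s, e in coords
    )
    return LocusAnnotation("simC", GenomicInterval(chrom, start, start + 2 * L + I), feats)


def loc(sv, locus):
    return localize([sv], [locus])


def test_reference_architecture_identity():
    assert sample_architecture(tandem_locus(), []).label == "tandem"
    assert sample_architecture(canonical_locus(), []).label == "canonical"


def test_mid_locus_recombination_del_collapses_tandem():
    locus = tandem_locus()
    c = I - 2000  # aligned INT x INT crossover
    start = 1000 + L + c
    sv = StructuralVariant(
        "recomb", GenomicInterval("simT", start, start + L + I), "DEL", L + I,
        carriers=frozenset({"s"}),
    )
    call = sample_architecture(locus, loc(sv, locus))
    assert call.label == "canonical"
    assert call.n_ltr == 2 and call.n_int >= 2  # two INT remnants collapse


def test_tandem_forming_insertion_on_canonical():
    locus = canonical_locus()
    point = 1000 + L + I + 1  # one base into the 3' LTR
    cassette_blocks = BlockStructure(
        "ins",
        (
            RepeatBlock("LTR", (0, L), (0, L), "+", 1.0, False),
            RepeatBlock("INT", (L, L + I), (0, I), "+", 1.0, False),
        ),
        0.0,
        L + I,
    )
    sv = StructuralVariant(
        "ins", GenomicInterval("simC", point - 1, point), "INS", L + I,
        alt_sequence=None, carriers=frozenset({"s"}),
    )
    call = sample_architecture(
        locus, loc(sv, locus), alt_structures={"ins": cassette_blocks}
    )
    assert call.label == "tandem"


def test_unclassifiable_insertion_leaves_structure_unchanged():
    locus = canonical_locus()
    sv = StructuralVariant(
        "noise", GenomicInterval("simC", 1500, 1501), "INS", 300,
        alt_sequence=None, carriers=frozenset({"s"}),
    )
    empty = BlockStructure("noise", (), 1.0, 300)
    call = sample_architecture(locus, loc(sv, locus), alt_structures={"noise": empty})
    assert call.label == "canonical"


def test_whole_provirus_recombination_leaves_solo_ltr():
    locus = canonical_locus()
    sv = StructuralVariant(
        "big", GenomicInterval("simC", 1000, 1000 + L + I), "DEL", L + I,
        carriers=frozenset({"s"}),
    )
    assert sample_architecture(locus, loc(sv, locus)).label == "solo_ltr"


def test_ltr_removing_del_breaks_architecture():
    locus = tandem_locus()
    sv = StructuralVariant(
        "ltr5del", GenomicInterval("simT", 800, 1000 + L + 100), "DEL", L + 300,
        carriers=frozenset({"s"}),
    )
    assert sample_architecture(locus, loc(sv, locus)).label == "other"


def test_overlapping_dels_rejected():
    locus = canonical_locus()
    a = StructuralVariant(
        "a", GenomicInterval("simC", 1500, 2500), "DEL", 1000, carriers=frozenset({"s"})
    )
    b = StructuralVariant(
        "b", GenomicInterval("simC", 2000, 3000), "DEL", 1000, carriers=frozenset({"s"})
    )
    lsvs = localize([a, b], [locus])
    with pytest.raises(ValueError, match="overlapping deletions"):
        sample_architecture(locus, lsvs)


def test_pipeline_architecture_matches_truth(default_cohort_dir):
    """Blind pipeline architecture equals truth-derived architecture for
    every sample and locus (zero-noise recoverability)."""
    from hervarch import read_fasta, read_locus_bed, read_sv_vcf, classify_insertions
    from hervarch.locus_sv import sample_locus_svs

    outdir, result = default_cohort_dir
    svs = read_sv_vcf(outdir / "cohort.vcf", cohort=result.samples)
    loci = read_locus_bed(outdir / "loci.bed")
    consensi = read_fasta(outdir / "consensi.fa")
    localized = localize(svs, loci)
    segmented = classify_insertions(svs, consensi)
    per = sample_locus_svs(localized, result.samples)

    truth_svs = {sv.id: sv for sv in result.svs}
    for sample in result.samples:
        truth_events = set(
            result.truth[result.truth["sample"] == sample]["event"]
        )
        for locus in loci:
            pipeline_call = sample_architecture(
                locus, per[sample].get(locus.locus_id, []), alt_structures=segmented
            )
            truth_lsvs = localize(
                [truth_svs[e] for e in truth_events
                 if truth_svs[e].interval.chrom == locus.span.chrom],
                [locus],
            )
            truth_call = sample_architecture(
                locus, truth_lsvs, alt_structures=result.truth_alt_structures
            )
            assert pipeline_call.label == truth_call.label, (sample, locus.locus_id)
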
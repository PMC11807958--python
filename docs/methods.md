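# Methods

## The analysis, end to end

The pipeline takes three inputs — structural-variant calls in VCF (SVTYPE,
SVLEN or END, inserted sequence in ALT, per-sample genotypes), proviral locus
annotations in BED6 (name column `locus_id:feature_type`, feature types LTR5 /
LTR_MID / LTR3 / INT_GAGPOL / INT_ENV / OTHER), and sequences in FASTA — and
produces per-locus cohort frequencies, per-sample architecture calls, ORF /
protein-match tables and distance trees. Internally all coordinates are
0-based half-open; genome-browser-style printed coordinates are treated as
1-based inclusive and converted on ingest.

### Structural variants

An SV is a change of ≥50 bases (the long-read caller definition); smaller
records are dropped on read. Deletion SVLEN may be negative in the wild and is
stored as an absolute length. An insertion is anchored at its VCF POS: the
record's interval is the length-1 padding-base interval, and the inserted
sequence begins at the following base. Carrier status is per individual (any
non-reference genotype), because the frequencies of interest are "% of
individuals", not allele frequencies; a VCF without genotype columns marks the
supplied cohort (intended: a single-sample file) as carriers.

### Locus intersection and tabulation

A DEL/DUP is assigned to a locus if it overlaps the locus span by ≥1 base —
the most inclusive reading, consistent with deletions that run out past the 5′
LTR still being counted — and an INS iff its anchor base lies inside the span.
`spans_whole_coding` is set for deletions overlapping every INT feature
(a full-containment switch exists). Frequency predicates are pure functions of
one sample's SVs at one locus; the built-ins cover "≥k DELs over L bases",
"any DEL/INS over L bases", "INS in feature F" and "no SV". The 290-b and
8.4-kb thresholds that appear in the published frequency statements are
configuration constants. Length thresholds are strict ("over 290 bases"
excludes exactly 290).

### ORFs and protein matches

Six-frame translation uses the standard code; reverse frames are numbered on
the reverse complement. An ORF is the maximal M→stop peptide of a
stop-delimited segment (first M only, unless `all_starts`); the default length
floor is 40 aa, the conventional cutoff separating plausible retroviral
peptides from six-frame noise — "about 40" in the source method, implemented
as ≥40 and exposed. Open-ended peptides at a translation end are excluded by
default. Matching uses exact Smith–Waterman (BLOSUM62, gap open 11, extend 1
— via biotite's C implementation; a hand-written Gotoh DP serves as the test
oracle). The headline quantity is the aligned reference span as a percentage
of the reference length, so "Gag (100%)" requires covering the whole
reference; domain coverage is the fraction of each annotated domain inside
the aligned reference interval. Hits scoring under a floor of 60 (random
background at these lengths scores well below it, genuine domain-length
matches far above) are not reported, and matches under 5% of the reference
are suppressed by default.

The packaged reference proteins are *synthetic*: fixed-seed random sequences
at realistic HERV-K scales (Gag 555 aa, Pro 140 aa, Pol 900 aa with RT /
RNase H / integrase domains, Env 699 aa with SP / SU / TM domains). They make
the protein stage fully testable offline; real UniProt sequences can be
supplied via `--refs/--domains`.

### Repeat segmentation

Each consensus (LTR, INT, optionally SVA) is locally aligned against the query
on both strands with BLAST-like scores (+2/−3, gaps −5/−2); iterative masking
of the best hit collects all alignments above a score floor (60), and
overlapping candidates are resolved greedily by score (ties: longer block,
then leftmost, then class name). Blocks shorter than `min_block` = 100 b are
dropped — short fragments are exactly the calls a full repeat library tends to
mislabel. `truncated` marks blocks covering <95% of their consensus. Greedy
resolution replaces a full repeat-scoring system and is reliable at the ≤10%
consensus divergences handled here (segmenting 5%-divergent composites
recovers the block order in ≥95% of seeds; at zero divergence boundaries are
exact — both are tested).

### Architecture and recombination

A structure is classified by its ordered LTR/INT class pattern; consecutive
INT blocks collapse (a deletion can split one INT into two remnants without
changing the architecture) and OTHER/SVA blocks are transparent to the
grammar but kept in the evidence. Recombination between two aligned repeats
is a single crossover: the deleted span runs from the start of the left
repeat to the start of the right repeat, making the deleted length exactly
the inter-start distance — a convention chosen because it is the unique
breakpoint-free way to make event lengths well-defined. Per-sample calls edit
the reference block structure: deletion spans are subtracted (pieces under
`min_block` are dropped), then each insertion's segmented alt blocks are
spliced at the anchor (splitting the host block if the anchor is interior;
insertions whose alt contains no classifiable block leave the structure
unchanged). Overlapping deletions within one sample are rejected — they
cannot be interpreted without phased haplotypes, and the simulator never
emits them.

### Phylogeny

The likelihood machinery of the original workflow (MAFFT + ML tree search) is
deliberately replaced by a desk-scale chain — progressive MSA (biotite's
guide-tree aligner; NUC4.4 or BLOSUM62, affine −10/−1), p-distance (mismatch
fraction over columns where neither row is gapped), and hand-written
Saitou–Nei neighbor joining. The claims this stage supports are about
*grouping*, which NJ recovers at these divergence scales and recovers exactly
on additive matrices (tested on 50 random 6-leaf trees). Ties in the Q
criterion are broken on the lexicographically smallest leaf labels, so the
tree is invariant to input order; negative branch estimates are clamped to
zero with a log note; an outgroup, when given, roots the tree at the midpoint
of its pendant edge.

## The synthetic cohort

### What it emulates

A 222-sample long-read SV cohort over four proviral loci, each on its own
contig with 1-kb random flanks:

| locus | structure | role |
|---|---|---|
| `sim6q14` | LTR·INT(GagPol,Env)·LTR, 9,422 b | single canonical provirus; INT encodes the mock proteins reverse-strand |
| `sim7p22` | LTR·INT·LTR·INT·LTR, 17,876 b | tandem-repeat locus; the two INT and three LTR copies independently diverged |
| `sim19q11` | canonical | control, one engineered 322-b DEL |
| `sim11q22` | canonical | control, one engineered 8,497-b DEL |

Defaults: LTR 968 b (a typical HML-2 LTR scale; the real locus LTR lengths
are not published), Gag-Pol region 4,886 b, Env region 2,600 b — so one
LTR + internal region = 8,454 b (the provirus-scale deletion/insertion unit,
matching the ~8.3–8.5 kb range of the real events) and the canonical provirus
is 9,422 b, the printed span length of the real 6q14.1 locus. Repeat copies
diverge by independent substitutions only (rate 0.02), keeping segmentation
exercises honest without an indel model.

### Events and prevalences

Default marginal prevalences are the published cohort fractions; every one is
overridable (`--prevalence NAME=P`).

At the tandem locus: the mid-locus recombinational deletion (80%) removes the
last 2 kb of the first INT, the middle LTR and the first 5.4 kb of the second
INT — an aligned INT×INT crossover, total 8,454 b, leaving exactly one
canonical provirus; a 5′-LTR-spanning deletion (70%, runs 200 b beyond the
locus) that breaks the tandem grammar; a 322-b companion deletion (marginal
75%) carried on the recombined haplotype; a rare 3′-spanning deletion (1%)
and a rare coding-region insertion (0.5%). At the single-provirus locus, the
whole-provirus deletion (32%, an outer-LTR recombination leaving a solo LTR)
and the 8,454-b tandem-forming LTR+INT cassette insertion anchored in the 3′
LTR (4%) are *mutually exclusive alternatives* of one locus, with the
reference state at 64%; small insertions sit in the 5′ LTR (3%) and Gag-Pol
region (2%). Control-locus deletions default to 10% (their real frequencies
are not published; the value is an ordinary polymorphism frequency and
nothing downstream depends on it).

### Why carriage is not purely independent Bernoulli

Unlinked, ungrouped events are independent Bernoulli draws per sample. Two
structured mechanisms exist because the published joint fractions cannot
arise from independent events:

* With the recombinational deletion fixed at 80%, independence caps
  P(≥2 deletions) at ~69% when P(≥1) ≤ ~95% (a Poisson-binomial bound:
  P(exactly 1) ≥ P(0)·(−ln P(0))), far below the observed ~80%. Real
  haplotypes are linked; the 75% companion deletion therefore rides on the
  recombined haplotype (conditional 0.9375, marginal still 0.75).
* The single-locus fractions — 32% whole-provirus DEL *without* concomitant
  INS, 4% tandem-forming INS, 64% reference — sum to 100%: they are
  alternative states of one locus, drawn as one categorical per sample
  (an insertion into a deleted span would be self-contradictory anyway).

Configured values are always *marginal* prevalences; averaged over 200 seeds
at n=222, empirical carrier fractions recover each marginal within 0.01
(tested). A per-sample, per-event false-negative dropout knob exists and
defaults to 0 (no callability model is published).

### What the simulator does not model

Diploidy and phasing (a sample is one haplotype's worth of events), read-level
error, population structure, indel divergence between repeat copies, SV
breakpoint uncertainty, and inter-locus recombination. Passing the recovery
tests therefore shows that the pipeline inverts this generative model exactly
at zero noise and within binomial error at n=222 — not that it would be
equally exact on real long-read call sets, where merging, genotyping error
and haplotype overlap add noise the generator deliberately omits.

## Numerical and degenerate-input choices

* Deterministic everywhere under a fixed config: the generator uses three
  seeded substreams (reference, carriage, alt sequences), one draw array per
  event in declaration order, so outputs are byte-identical across runs.
* Alignment tie-breaks: co-optimal local alignments resolve to lowest query
  start, then lowest reference start; segmentation ties to longer, then
  leftmost, then class name; NJ ties to lexicographic leaf labels.
* Empty inputs: empty sequence, empty cohort, missing prevalence, <3 NJ taxa,
  outgroup not in labels, overlapping loci, overlapping per-sample deletions
  and malformed coordinates are hard errors; records missing SVTYPE and
  insertions without alt sequence are skipped with a logged warning.
* Block splitting drops sub-`min_block` pieces; p-distance raises if a pair
  has no comparable columns; interval invariants (0 ≤ start < end) are
  enforced at construction.

## Problem sizes

The shipped configuration is the full study scale: 222 samples, four loci,
provirus-scale events (the whole acceptance run, including segmentation of
the 8.4-kb cassette and 888 per-sample architecture calls, completes in
about a minute on one CPU). Tests that sweep seeds (segmentation robustness,
NJ consistency, frequency recovery) use desk-scale consensi (0.3–0.8 kb) or
distance matrices so the whole suite stays fast.

## Known limitations

* Segmentation block boundaries on real, indel-divergent repeats are
  approximate by design; only the zero-divergence case is boundary-exact.
* `percent_of_reference` uses the aligned reference span, which exact local
  alignment can extend a few residues into unrelated flanking sequence when
  net-positive; the quantity is stable to within the flank length.
* The architecture grammar describes one haplotype; samples carrying
  incompatible SV combinations on two haplotypes need phased input.
* NJ branch lengths are p-distance-based and not comparable to
  maximum-likelihood branch lengths; only grouping should be interpreted.
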
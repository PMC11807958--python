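# hervarch

Structural variation inside HERV-K (HML-2) proviral loci, from long-read
structural-variant calls.

Human endogenous retrovirus K (subtype HML-2) proviruses — an internal
protein-coding region (*gag*, *pro*, *pol*, *env*) flanked by two long
terminal repeats (LTRs) — are among the most polymorphic repetitive elements
in the human genome. Long-read sequencing finally resolves provirus-scale
deletions and insertions inside these loci, and the picture it gives is that
*variation from the reference genome is the rule*: most individuals do not
carry the reference haplotype of the well-studied 6q14.1 and 7p22.1a
proviruses. `hervarch` packages the analysis behind that observation as a
reusable, tested pipeline:

* **Locus-restricted SV genotyping** — intersect VCF structural variants
  (SVTYPE/SVLEN/END, ≥50 b) with annotated proviral loci and tabulate
  per-individual cohort frequencies for named predicates (e.g. "≥2 DELs over
  290 b within the tandem locus").
* **Protein-coding potential** — six-frame translation, extraction of maximal
  M→stop ORFs of ≥40 aa, and exact Smith–Waterman scoring (BLOSUM62, affine
  gaps 11/1) against reference HERV-K proteins, reporting
  `percent_of_reference = 100 · aligned reference length / reference length`
  and per-domain coverage (Env SP/SU/TM; Pol RT/RNase H/integrase).
* **Repeat-block segmentation** — decompose an insertion sequence into an
  ordered list of LTR/INT/other blocks by iterated local alignment against
  consensus sequences (a desk-scale RepeatMasker stand-in).
* **Architecture model** — classify block structures as canonical
  (LTR·INT·LTR), tandem (LTR·INT·LTR·INT·LTR), INT-sandwich, solo LTR,
  truncated or other, and enumerate the single-crossover LTR×LTR
  recombination events that interconvert them (deleted length = inter-repeat
  start distance; outer-LTR recombination of a canonical provirus leaves a
  solo LTR).
* **Phylogeny** — progressive multiple alignment, p-distance, and
  neighbor joining (exact on additive matrices, deterministic tie-breaking,
  optional outgroup rooting), for nucleotide or amino-acid input.
* **Synthetic cohort generator** — builds mock proviral loci (a canonical
  provirus whose internal region encodes mock Gag/Pro/Pol/Env on the reverse
  strand, a tandem-repeat locus, two single-SV control loci) and a
  222-sample cohort whose event prevalences default to the published cohort
  fractions, emitting `reference.fa`, `loci.bed`, `cohort.vcf` (multi-sample,
  sequence-resolved insertions), `consensi.fa` and a `truth.tsv`.

## Worked example

Simulate the default cohort and recover its frequencies blind from the
emitted files:

```bash
hervarch reproduce --n 222 --seed 1 --out run/
column -t run/frequencies.tsv
```

```
locus    predicate            n    N    fraction
sim7p22  ge1_del_gt290b       212  222  0.954955
sim7p22  ge2_del_gt290b       181  222  0.815315
sim6q14  any_del_ins_gt8400b  79   222  0.355856
sim7p22  ge1_del              212  222  0.954955
sim6q14  reference_no_sv      134  222  0.603604
```

Reading the rows: 95.5% of the 222 simulated individuals carry at least one
deletion longer than 290 b in the tandem locus and 81.5% carry at least two;
35.6% carry a provirus-scale (>8.4 kb) deletion or insertion at the
single-provirus locus; 60.4% carry no SV at all there. `run/` also contains
`architectures.tsv` (per-sample architecture calls — e.g. the ~80% of samples
whose tandem locus collapsed to one canonical provirus via the ~8.5-kb
mid-locus recombinational deletion), `orfs.tsv`, `matches.tsv` (the canonical
locus makes full-length mock Gag/Pro/Pol/Env, all on the reverse strand),
Newick trees, and a run manifest; two runs with the same seed are
byte-identical.

The same stages run on your own files:

```bash
hervarch genotype --vcf cohort.vcf --bed loci.bed --out table.tsv
hervarch segment  --fasta ins.fa --consensi consensi.fa --out blocks.tsv
hervarch classify --vcf cohort.vcf --bed loci.bed --consensi consensi.fa --out arch.tsv
hervarch orfscan  --fasta seqs.fa --min-aa 40 --out orfs.tsv
hervarch protmatch --orfs orfs.tsv --refs refs.fa --domains domains.tsv --out matches.tsv
hervarch tree     --fasta seqs.fa --type nt --outgroup LABEL --out tree.nwk
```

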
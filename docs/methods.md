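# Methods

## Scope and coordinate conventions

`lincseek` identifies multi-exon lincRNAs from *assembled* transcripts;
read cleaning, mapping and assembly are upstream of the package, which
consumes a GTF plus genome FASTA. All in-memory coordinates are 0-based
half-open; GTF (1-based inclusive) and BLAST-style tables (1-based
inclusive) are converted at the I/O boundary. "Transcript length"
always means mature (spliced) length — the sum of exon lengths — since
the size filter and the structural summaries are defined on the mature
RNA, not the genomic span.

## The filter cascade

Stages run in a fixed order, (1) size/structure → (2) protein-gene
overlap → (3) coding potential → (4) protein similarity → (5) protein
domains → (6) small-RNA families → (7) UTR coverage. Every stage
records its parameters and removed ids; the report enforces
`n_input = n_removed + n_surviving` and exact chaining, so the cascade
is fully auditable and order-stable (the surviving *set* is invariant
to input order).

Boundary semantics, chosen once and asserted by tests:

| quantity | rule |
|---|---|
| mature length | < 200 removes (a 200-nt transcript survives) |
| protein-gene overlap | any shared base removes; computed on locus spans, strand-agnostic; an exon-level mode is available behind a flag |
| coding score | > 0 removes (a score of exactly 0 survives) |
| similarity / domain E-value | ≤ 1e−5 removes (inclusive) |
| UTR coverage | > 0.9 removes (exactly 0.9 survives) |
| coding classification | identity ≥ 96 **and** alignment/reference length ≥ 0.90, both inclusive |
| liftover remap ratio | ≥ 0.5 succeeds (inclusive, liftOver semantics) |

Gene-span (rather than exon-level) overlap at stage 2 reflects that the
filter is defined against *genes*; the stricter exon-level variant is a
config switch. Reading "overlap (>1 bp)" as "≥ 1 shared base" keeps the
cascade maximally stringent; the alternative reading (≥ 2 bases) would
admit single-base overlaps with coding genes.

### The built-in coding score

Stage 3 emulates an ORF-feature coding classifier rather than
reimplementing any SVM. Per strand, with L the longest ATG-initiated
ORF in codons (open-ended ORFs count to the last full codon) and
C = 3L / mature length:

    s = min(L, 300) / 300 + C − 1

Full-length ORFs (≥ 300 codons covering the transcript) score ≈ +1;
ORF-free sequences score −1. The sign convention matches classifiers
whose positive scores mean "coding", so external score tables (e.g.
CPC output) drop in unchanged. The 300-codon saturation point marks the
ORF length at which length evidence alone is maximal; it interacts with
the generator's suppression caps (below).

## Synthetic data: what it emulates, and what it does not

The generator stands in for an RNA-seq assembly with known composition.
One seeded NumPy generator drives everything, so identical
configurations give byte-identical FASTA/GTF/TSV/chain outputs. The
frozen default study is 2 chromosomes × 200 kb, uniform-random
sequence, with 30 lincRNAs, 30 coding genes and 10 each of four decoy
classes (seed 1), placed without overlap (rejection sampling with a
50 bp margin, error after 5,000 attempts).

* **lincRNAs** — 2–4 exons of 120–600 bp (mature ≥ 300 nt), introns of
  40–400 bp rewritten to GT..AG on the transcript strand. ORFs are
  suppressed by overwriting a mid-run codon with an in-frame stop
  whenever any of the six frames holds an ATG run longer than
  `min(99, largest L with 3L < mature/2)` codons. Both caps are needed:
  a 99-codon ORF in a 300-nt transcript would otherwise reach
  coverage 0.99 and score positive. TAA (forward) and TTA (its
  reverse-strand image) cannot create a new ATG on either strand, so
  the rewrite converges; tests verify the caps with an independent
  brute-force six-frame enumeration.
* **Coding genes** — 4–6 exons; one ORF of non-stop codons covering 85%
  of the mature length, flanked by UTRs whose genomic intervals feed
  stage 7. Each coding gene has an annotation twin (`NM_`-style id)
  forming the protein gene set of stage 2, a strong Swiss-Prot-style
  hit, a Pfam-style domain hit, and a high-identity alignment to its
  reference mRNA for the protein-coding classifier.
* **Decoys** — single-exon (300–1,500 nt) and short (two-exon,
  < 200 nt) transcripts die at stage 1; small-RNA-like transcripts
  (70–150 nt, with an Rfam-style hit) also die at stage 1, so stage 6
  is exercised by dedicated unit tests with surviving-size transcripts
  instead. UTR fragments are two-exon transcripts planted wholly inside
  the 3′ UTR of a dedicated donor locus that contributes UTR intervals
  but is excluded from the stage-2 gene set and emits no assembled
  transcript — by construction stage 7 is the only stage that can
  remove them. lincRNAs additionally carry sub-threshold protein hits
  (E between 1e−3 and 1), so stage 4 filters by threshold, not by hit
  presence.
* **Repeats** — 65% of lincRNAs receive one repeat whose exonic
  footprint is Beta(1, 2.57) × mature length (mean ≈ 0.28, density
  decreasing with content), contiguous in mature coordinates and split
  into genomic pieces where it crosses an intron. Families are drawn
  from a categorical mix (SINE .35, LINE .23, LTR .155, simple .10,
  low-complexity .09, DNA .05, other .025). Repeats are annotation
  intervals only; the underlying sequence is not made repetitive.
* **Ortholog genome** — an i.i.d. 5% base-substituted copy at identity
  coordinates. 60% of lincRNAs are "conserved" (ortholog transcripts
  emitted on the second genome); a disjoint 20% are "unmappable" —
  their loci fall in regions deleted from the chain, which otherwise
  covers each chromosome in 10-kb blocks.
* **Ct tables** — `Ct(target) = 25 − log2(fold) + ε`,
  `Ct(reference) = 20 + ε`, ε ~ N(0, 0.2 cycles), 6 replicates; at zero
  noise the 2^−ΔΔCt estimate recovers the planted fold exactly.

Passing on this fixture shows the *logic* of every stage is correct
under planted truth; it does not show robustness to real-data features
the generator omits: assembly fragmentation beyond the decoy classes,
expression levels, non-uniform base composition, genuine repeat-derived
sequence, gapped ortholog alignment, or mis-annotated references.

## Conservation analysis

The homology searcher is a desk-scale seed-and-extend: exact 11-mer
seeds over the subject set, ungapped extension at +1/−2 with X-drop 20,
`E = K·m·n·e^(−λS)` with fixed λ = 1.28, K = 0.46 (m = query length,
n = summed subject length). Agreement with NCBI BLASTN E-values is a
non-goal; the contract is threshold behaviour at E ≤ 1e−5, verified by
full recall of the planted 5%-divergent ortholog pairs. External
outfmt-6 tables are accepted wherever segments are consumed. Boundary
conservation flags a segment end as at an intron–exon junction when its
mature-coordinate position is within a tolerance (default 0) of either
side of a junction.

Liftover maps an interval through chain blocks by interval arithmetic
(the test suite checks it base-by-base); success needs remap ratio
≥ 0.5 and all images on one target chromosome and orientation — split
images fail, as in liftOver. The mapped interval is the hull of the
images. Chains use the UCSC format restricted to ungapped blocks;
negative-strand targets are stored in forward coordinates with an
orientation flag.

## Quantification

2^−ΔΔCt pairs target and reference Cts positionally per (sample,
replicate); the calibrator ΔCt is the arithmetic mean over its
replicates. Because figure legends and methods sections disagree on
dispersion conventions in this field, both SD (ddof = 1) and
SEM = SD/√n are computed and labelled. The t-test is the classical
pooled-variance Student's test (Welch behind a flag); identical groups
give t = 0, p = 1, while zero pooled variance is an error. Percent
input adjusts the input Ct by log2(1/input_fraction) before
exponentiating; the input fraction has no default — it is an
experiment-specific required parameter.

## Numerical and design notes

* Unstranded ('.') transcripts are read as '+' for sequence extraction
  but treated strand-agnostically in all overlap filters, since
  assemblers can emit unstranded models and the overlap filters are
  defined on positions.
* RepeatMasker class/family strings collapse on the text before "/"
  into a closed set {SINE, LINE, LTR, DNA, Simple_repeat,
  Low_complexity, Other}.
* Upstream/downstream neighbors are genomic left/right (lincRNA strand
  ignored); distances are span gaps, strict < 10 kb, overlap and
  zero-gap adjacency excluded. A reflection property test pins the
  symmetry.
* Repeat-content histogram bins are [0,10) … [90,100] percent;
  repeat-free transcripts are counted in the first bin.
* Reported structural summaries include true min/max mature lengths;
  published lincRNA catalogues occasionally print internally
  inconsistent ranges, so the package never back-fits a range.
* Problem sizes were chosen so the full suite and the acceptance script
  each complete in seconds: the 400-kb fixture is large enough for
  ~90 non-overlapping loci and stable summary statistics while keeping
  homology search and per-base oracles cheap.

## Known limitations

The built-in coding score is an ORF-feature stand-in, not a trained
classifier; with real data, supplying an external score table is
preferred. The homology searcher is ungapped and will fragment
alignments across indels. Stage 2 depends entirely on the completeness
of the protein annotation, and stage 7 on UTR annotation quality. The
generator's uniform base composition makes seed statistics slightly
conservative relative to GC-skewed genomes.
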
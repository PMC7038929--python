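# Methods

## Scope and data model

`rnachimera` operates strictly downstream of a fusion caller. Its unit of
input is a *call*: one predicted chimera in one sample, carrying gene
symbols, per-gene genomic breakpoints and strands, the caller's junction
sequence (junction at its midpoint), a prediction score in [0, 1], and
read-count-based expression of the chimera and both parents. A *unique
chimera* is the equivalence class of calls sharing the full junction key
(gene5, gene3, chrom5, pos5, strand5, chrom3, pos3, strand3) — i.e.
isoform resolution, not gene-pair resolution: two junctions of the same
gene pair (e.g. e1e2 vs e4e2) are distinct entities. Gene-pair collapsing
is applied only where databases force it (overlap analysis).

Breakpoint convention: `pos5` is the 1-based genomic coordinate of the
last base contributed by the 5' gene and `pos3` the first base of the 3'
gene, the dominant fusion-caller dialect. Internally all intervals are
0-based half-open; conversion happens only in `rnachimera.io`.

Frequency counts **distinct samples** — not supporting reads, and not
donors. Multi-sample donors therefore contribute once per sample, which is
what the per-tissue thresholds are calibrated against.

## Classification

*Junction class.* A donor-side breakpoint is `E` when it equals the
transcript-orientation 3'-most base of any exon of any annotated
transcript of the gene; acceptor-side, the 5'-most base. Matching is exact
by default (`tolerance=0`); a ±bp tolerance is exposed for callers with
imprecise junctions. When transcripts disagree, `exon_end` wins — callers
report junctions against their best-matching transcript, so the most
permissive reading toward `E` is the faithful one. A breakpoint inside the
gene but at no qualifying end is `M`; a breakpoint outside every exon is
classified conservatively as `M` (the four-class scheme has no fifth
category) and logged.

*Gene-pair class.* Read-through (cis-SAGe) requires same chromosome, same
strand, the 5' gene strictly upstream in transcription direction, and an
intergenic gap of at most `readthrough_max_gap` = 100 000 bp. No published
definition quantifies "proximity"; 100 kb covers the well-known cis-SAGe
pairs while excluding most distal same-chromosome events, and the knob is
config-exposed, as is an optional requirement that no same-strand gene lie
wholly inside the gap. Overlapping gene spans fall back to intra-others
with a warning.

*Frame class.* Evaluated over **all** coding transcript pairs: in-frame if
any pair continues the codon walk ((phase(b5)+1) mod 3 = phase(b3)),
frame-shift if some pair has both sides in CDS but none is compatible, NA
otherwise. The permissive any-pair rule follows common fusion-annotation
practice; a single-canonical-transcript rule would silently depend on
which transcript set the caller used.

*Splice motifs.* Donor: the two transcript-strand bases ending at pos5
read AG and the next two read GT; acceptor: the two bases before pos3 read
AG and the base at pos3 reads G. Minus-strand genes are evaluated on the
reverse complement. Windows running off a contig return an undefined flag
and are excluded from percentage denominators.

*Isoform names.* `e<N>e<M>` from exon ordinals in transcript orientation,
using per gene the transcript whose exon boundary matches the breakpoint,
longest spliced transcript on ties (deterministic); non-exonic breakpoints
are unnamed.

## The filter ladder

Fixed order: score → identity → ratio → dedupe/classify → non-M/M →
recurrence. Classification runs once per unique key, after the row-level
filters. Every stage emits a report with kept + removed = input asserted;
rows with missing breakpoints are flagged at read time and accounted for
in the score stage rather than dropped by the parser.

Boundaries are as written in their definitions: score < 0.6 is discarded
(0.6 kept); an expression ratio of exactly 1 is not "exceeded" (kept);
tissue thresholds use closed bounds n ≤ 100 / n ≤ 300 / n > 300; q < 0.05
is strict.

*Expression-ratio filter.* Both ratios chimera/parent5 and chimera/parent3
are computed (parent = 0 gives +∞ if the chimera is expressed, 0 if not);
the default `either` mode removes a call when either ratio exceeds 1, with
`both`/`five_prime`/`three_prime` available since the source rule names
only "the ratio".

*Identity filter.* A concretization of a blat-style 90 %-identity screen:
exact 11-mer seeding over the reference transcriptome, then local
alignment (match +1, mismatch −1, gap −2) of the junction sequence against
a window around each seed diagonal. A call is removed when some single
transcript yields an alignment with ≥ 90 % identity (matches / alignment
columns) that spans the junction midpoint with ≥ 10 aligned query bases on
each side **and** ≥ 90 % identity on each side separately (gap columns
included in the per-side denominators). The per-side requirement is the
package's own refinement: a genuine chimeric junction matches its parent
transcript perfectly on one side, and under local alignment that perfect
run can subsidize a low-quality gapped extension across the junction that
clears a purely global cutoff; requiring both sides to meet the cutoff
restores the intended semantics ("this junction is explainable by one
transcript") and, on synthetic cohorts, separates verbatim reference
copies from genuine junctions with zero error. All parameters (k, scores,
min_flank, cutoff) are exposed.

*Recurrence.* Global: frequency ≥ 5 distinct samples. Per tissue of n
samples: ≥ 2 (n ≤ 100), ≥ 3 (n ≤ 300), ≥ 5 (n > 300). Tissue-specific
chimeras are, strictly, recurrent in one tissue and detected in **zero**
samples of any other; a relaxed mode (recurrent in exactly one tissue)
exists because only per-tissue recurrence, not specificity, has a fixed
definition.

Stage ordering note: the ratio filter is applied per call, before
deduplication, and the ordering is recorded in every run manifest.

## Profiling

Presence matrices are {0,1} pandas DataFrames with lexicographically
sorted rows and columns, so exports are byte-reproducible. Parental-gene
expression is binarized at FPKM ≥ 0.04 — the lowest chimera expression
observed in a recurrent set, so a parent counts as "present" on the same
footing as its chimera. SMC histograms default to bins [0, 0.25) /
[0.25, 0.6) / [0.6, 1] ("dissimilar" / intermediate / "high similarity").
The embedding export records duplicate-row/column counts (embedding tools
can fail on matrices with many identical rows) but draws no conclusion.

## Peptides

Junction sequences default to **genomic** (unspliced) 200 bp windows on
each side of the breakpoint, in each gene's transcript orientation,
truncated (not padded) at contig edges; a `spliced` mode walks exons of
the best-matching transcripts instead, because whether the windows should
cross introns is genuinely ambiguous — both are implemented and the mode
is recorded. Three-frame translation keeps stops as segment separators;
codons containing N give X. Trypsin cleaves after K/R except before P
(the proline rule is standard EMBOSS-pepdigest behavior; a flag disables
it) with zero missed cleavages by default (0–2 supported). Per frame, at
most one fragment is retained: the tryptic fragment inside the stop-free
segment containing the junction that has ≥ 2 residues strictly on each
side of the junction boundary; a codon straddling the boundary counts
toward neither side. With missed cleavages enabled, several fragments may
qualify and the shortest is kept (deterministic).

The search database is FASTA with headers
`chim|<key>|frame=<f>|left=<n>|right=<m>` followed by reference proteins.
PSM filtering matches peptides to database entries by exact sequence;
q < 0.05 strict. The reference-proteome screen splits each peptide at the
junction and searches each half as an exact substring; `no_hit` and
`one_side` peptides are the candidates not explainable by a regular
transcript.

## Overlap with fusion databases

Gene-pair matching is ordered by default (5'/3' orientation is
biologically meaningful); an unordered flag accommodates databases with
loose conventions, and symbol normalization is uppercase plus an optional
user alias table (no network lookups). Database records carrying mRNA
breakpoints are converted to genomic coordinates through their named
transcripts and matched exactly against the chimera keys; records whose
transcripts are missing from the user's annotation are skipped and
counted. Normal-baseline filtering is set arithmetic at gene-pair
resolution: eliminated = cancer ∩ control, with percentages reported at
one decimal using round-half-even so printed summaries are reproducible.

## Summaries

Stage distributions are normalized class proportions over labeled unique
chimeras. Relative-expression CDFs are evaluated on a fixed 0–1 grid
(step 0.05); the per-chimera ratio is the maximum per-sample ratio against
each parent (an aggregation choice; mean/median would be defensible too).
Gene-level 3'UTR length is the **maximum** over coding transcripts —
stable under annotation subsetting, unlike the mean. The 3'UTR comparison
uses the two-sided Mann-Whitney U test, exact by enumeration when the
combined sample is ≤ 20 without ties, otherwise the normal approximation
with continuity and tie corrections (scipy). Chromosome-level correlation
between annotated-gene and chimera-parent counts is Pearson's r; constant
counts on either axis are flagged undefined rather than reported as 0.

## The synthetic-data generator

The generator emulates the statistical structure of a large multi-tissue
chimera survey at desk scale. Defaults: 4 chromosomes × 12 genes (4–7
exons, first and last exons UTR, internal exons CDS trimmed to a codon
multiple, in-frame stops scrubbed so proteins are intact); 4 tissues of
(50, 150, 350, 20) samples, hitting all three per-tissue recurrence
regimes; 120 true chimeras with junction classes mixed (EE 4 %, EM 14 %,
ME 14 %, MM 68 %), pair classes (read-through 4 %, intra-others 16 %,
inter-chromosomal 80 %) and frames (25/35/40 %), mirroring the qualitative
shape of real call sets; plus 20 reference-copy decoys, 12 low-score
calls, 5 missing-breakpoint rows and 12 ratio violators. Splice-motif
rates per class default to (EE 0.42/0.425, EM 0.155/0.10, ME 0.06/0.348,
MM 0.017/0.094), reproducing the observed ordering EE ≫ EM/ME ≫ MM.
Recurrence is planted as a mixture: ~5 % housekeeping-like chimeras
present in every tissue, ~12 % tissue-specific, and a background whose
frequency is boosted for E/E and read-through chimeras so those classes
enrich along the ladder. Expression ratios for surviving calls are drawn
uniformly below 1 (so about half the chimeras sit at ≥ 50 % of parental
expression); parental genes are expressed in ~95 % of samples while
chimeras are sparse, which is why chimera-versus-parent SMC mass lands in
the lowest bin.

Planting is by construction unambiguous: E breakpoints are real annotated
exon ends, M breakpoints sit strictly inside exons at least 6 bp from any
end or previously planted site, motif flags are realized by editing the
genome at the breakpoint (the reference transcriptome is derived after
all edits), decoy junctions are verbatim transcript windows, and true
junctions join flanks of two different genes so no single transcript
explains them. An `adversarial` flag adds exon-skipping isoforms that
create transcript-dependent boundary roles, for robustness testing without
exactness claims.

What the generator does **not** emulate: read-level noise and alignment
artifacts (scores and expressions are drawn, not derived from reads),
homologous gene families and paralog-driven false positives, imprecise
breakpoints, correlated junction/pair classes, and real splice-site
sequence context beyond the planted 4–5 bp motifs. Passing the recovery
suite therefore demonstrates correctness of the pipeline's logic under
its stated definitions, not caller-level sensitivity or specificity on
real tissue.

## Problem sizes and numerical choices

Test and acceptance runs use the small preset (2 chromosomes × 8 genes,
2 tissues, 24 true chimeras) for unit-level checks and the paper-shaped
preset (above) for end-to-end recovery; class-mix convergence is checked
at n = 2000 planted chimeras on an 8 × 25-gene universe. Oracle suites use
500 random junction fixtures (peptides), 1000 random peptides (digestion
partition), 10 000 random vector pairs (SMC) and 200 null replicates
(rank-sum calibration). All randomness flows from a single integer seed
through `numpy.random.default_rng`; reruns are byte-identical.

Degenerate inputs have defined behavior throughout: empty reference
transcriptome → error; 0/0 expression ratio → 0; empty chimera set →
0-column matrix; empty junction-class cell → absent from summaries, not
0 %; constant chromosome counts → correlation flagged undefined; empty
cancer set → error.

## Limitations

* The identity filter is a reimplementation faithful to a 90 %-identity
  screen's intent, not a byte-level blat reimplementation; borderline
  alignments may differ from blat's scoring.
* Gene-level queries union over all annotated transcripts; results depend
  on the annotation provided, and no liftover between genome builds is
  attempted.
* PSM handling consumes a search engine's output table; spectra, decoy
  databases and FDR estimation are out of scope.
* The normal-baseline filter is set arithmetic at gene-pair resolution;
  it does not model expression-level evidence in the control set.
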
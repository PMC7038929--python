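# rnachimera

Post-detection analysis of chimeric RNA (fusion transcript) call sets.

Fusion callers applied to bulk RNA-seq emit large tables of candidate
chimeras — one predicted junction per sample per row — of which the great
majority are artifacts of library construction or alignment. `rnachimera`
implements the downstream analysis that turns such call sets into a
curated landscape: junction classification, a staged filtering ladder,
recurrence calling across tissues of unequal size, binary presence
profiling, in-silico chimeric-peptide prediction for proteomic validation,
and overlap analysis against cancer fusion databases (including using a
normal-tissue chimera set as a baseline filter for cancer call sets).

It is written for computational biologists who already have caller output
(EricScript-style TSVs, or any dialect mapped via a column dictionary) and
want a tested, reproducible implementation of the standard post-detection
steps rather than a fusion caller itself.

## The model

For a chimera joining a 5' gene at genomic breakpoint `b5` and a 3' gene
at `b3`:

* **Junction class** — each breakpoint either coincides with an annotated
  exon end (`E`) or falls mid-exon (`M`), giving classes E/E, E/M, M/E and
  M/M. The donor-side end of an exon is its 3'-most base in transcript
  orientation, the acceptor-side end its 5'-most base. M/M chimeras have
  low validation rates and are removed before recurrence analysis.
* **Gene-pair class** — *read-through* (cis-SAGe) when the parents are
  same-strand neighbors with `b5`'s gene transcriptionally upstream and an
  intergenic gap ≤ 100 kb (configurable); *inter-chromosomal* when the
  parents lie on different chromosomes; *intra-others* otherwise.
* **Frame class** — with CDS phase φ(b) = (0-based spliced-CDS offset
  mod 3), the junction is *in-frame* when (φ(b5)+1) mod 3 = φ(b3) for some
  coding transcript pair, *frame-shift* when both sides are coding but no
  pair is compatible, and *NA* when either side is UTR/intronic/noncoding.
* **Filter ladder** — discard calls with prediction score < 0.6 or without
  breakpoints; remove junction sequences explainable by a single reference
  transcript (k-mer seeded local alignment, ≥ 90 % identity spanning the
  junction with ≥ 10 aligned bases per side); remove calls whose
  chimera/parent read-count ratio exceeds 1; deduplicate to unique
  junction keys; drop M/M; keep chimeras seen in ≥ 5 distinct samples
  (globally) or, per tissue of n samples, in ≥ 2 (n ≤ 100), ≥ 3
  (n ≤ 300) or ≥ 5 (n > 300) samples.
* **Profiling** — samples × chimeras binary presence matrices; parental
  genes binarized at FPKM ≥ 0.04; similarity by the Simple Matching
  Coefficient SMC(a, b) = |{i : aᵢ = bᵢ}| / n.
* **Peptides** — 200 bp of sequence on each side of the junction is
  translated in three frames, digested in silico with trypsin (cleave
  after K/R, not before P), and per frame the junction-spanning fragment
  with ≥ 2 residues on each side is retained; PSM tables are filtered at
  q < 0.05 and screened against a reference proteome by exact substring
  match of each junction half.

A synthetic-data generator (`rnachimera.simulate`) builds a complete toy
universe — genome, GTF, transcriptome, proteome, call tables, expression,
PSMs — with planted ground truth for every one of these quantities, so the
whole pipeline is testable without any controlled-access data.

## Worked example

```python
from rnachimera import simulate as sim, filters as flt
from rnachimera.pipeline import label_uniques

cfg = sim.preset("small", seed=1)
universe, cohort = sim.simulate_cohort(cfg)

kept, _, rep = flt.score_filter(cohort.calls)
kept, _, rep_id = flt.identity_filter(kept, universe.transcriptome())
kept, _, rep_ratio = flt.ratio_filter(kept)
uniques = flt.dedupe(kept, cohort.metadata)
uniques, _ = label_uniques(uniques, universe.annotation, universe.genome)
non_mm, _, _ = flt.remove_mm(uniques)
```

printing the stage reports gives:

```
cohort: 68 calls, 23 samples, 2 tissues
score filter:    68 -> 60  {'missing_breakpoint': 3, 'low_score': 5}
identity filter: 60 -> 54  {'reference_match': 6}
ratio filter:    54 -> 49  {'ratio_exceeds_1': 5}
non-M/M:         24 -> 8
example: GENE0001>GENE0002@chr1:5407:+~chr1:9055:+
         class=ME/read_through/frame_shift isoform=e5e2 freq=4
```

Reading the example line: the chimera joins exon 5 of GENE0001 to exon 2
of its downstream neighbor GENE0002 (a read-through), the 5' breakpoint
falls mid-exon (M/E), the reading frames are incompatible, and the event
was called in 4 distinct samples. The 68 input calls collapse to 24 unique
junctions after the row-level filters; removing M/M leaves 8.

The same ladder is available from the shell:

```sh
rnachimera simulate --preset small --seed 1 --outdir cohort/
rnachimera run-all --cohort-dir cohort/ --outdir run/
rnachimera report --manifest run/manifest.json
```

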
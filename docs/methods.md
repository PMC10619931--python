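# Methods

## Model and scope

The package quantifies transcription of individual LINE-1 loci and
subfamilies from already-aligned reads. It does not align reads,
cluster cells or fit differential-expression models; it consumes
coordinate-level alignments (SAM/BAM with NH/NM and, for single-nucleus
data, CB/UB tags), TE annotations (TEtranscripts-dialect GTF or
RepeatMasker BED), gene/transcript models, cluster maps and QC tables,
and produces count matrices, detection calls, chimera tables, motif
reports and coverage profiles.

All genomic coordinates are 0-based half-open internally; GTF I/O
converts at the file boundary (disk GTF is 1-based closed). A single
convention avoids off-by-one drift when BED, GTF and alignment
coordinates are mixed, at the cost of one conversion per record. The
"±100 bp" TSS window is therefore a 201-base half-open interval
covering the same bases as the closed-coordinate tool convention.

## Pseudo-bulk machinery

Droplet single-nucleus libraries are far too shallow to see individual
repeat loci per cell, so reads of all cells in a transcriptomic cluster
are pooled into one bulk-like library per cluster.

*Cell QC.* Cells with mitochondrial content above 10% are dropped. The
feature-count filter removes cells above mean + 2 SD in their sample
(doublet guard) and, in `adult` mode, below mean − 1 SD (low-quality
nuclei) or, in `fetal` mode, below an absolute 2000-feature floor.
Mean and SD use the n−1 denominator and are computed per sample over
all cells before any exclusion — the two filters refer to the same
original population, so their order cannot matter. Single-cell samples
are an error because the SD is undefined.

*UMI deduplication.* The default duplicate key is (cell barcode, UMI,
contig, alignment start). Including the position avoids collapsing
distinct molecules that collide on a short UMI by chance; a stricter
(barcode, UMI)-only key is available via `key="cb-umi"` for datasets
where fragmentation scatters duplicate positions. The first record in
coordinate order is kept, making the operation deterministic on sorted
input and idempotent.

*Merging.* Same-labelled cluster collections are concatenated across
samples; a label absent from one sample contributes an empty collection
(logged, not fatal). An optional relabelling maps cluster labels onto
coarser groups (cell types, cell-cycle states).

## Strand splitting and unique counting

For a reverse-stranded paired-end library the transcribed strand is a
pure function of three flag bits: records with (second mate ∧ forward)
or (first mate ∧ reverse) come from forward transcription; (second
mate ∧ reverse) or (first mate ∧ forward) from reverse transcription.
The two sets partition the paired input exactly, and both mates of a
proper pair always land in the same set. Single-end data are only
routed when `single_end_rule` is enabled (reverse-stranded chemistry:
a reverse alignment is forward transcription) — off by default because
the flag rules above are only defined for pairs.

Unique-mode counting keeps primary records with `NH == 1` and a
mismatch-to-mapped-length ratio ≤ 0.03 (at 150 bp this passes up to 4
mismatches and rejects 5+). A record is assigned to a feature it
overlaps by at least 1 bp; a record overlapping two or more distinct
features is discarded as ambiguous — the conservative default of
overlap-counting tools — and tallied in the report. Counting operates
on records (mates counted separately), matching the flag-split
procedure, which routes mates independently. Sense/antisense tables
are element-relative: sense = forward-transcription counts on `+`
features plus reverse-transcription counts on `−` features. The
`reverse-forced` counting mode restricts countable features to the
strand matching the supplied transcription-strand label — this is the
sense-only projection of the same arithmetic and is what the
transcript-expression step uses.

## EM assignment of multimapping reads

Subfamily-level counts admit multimappers. Records sharing a read id
(mates and secondary hits) form one read whose candidate set is the set
of subfamilies its hits overlap. Uniquely-assignable reads fix unit
mass on their subfamily. Ambiguous reads start uniformly over their
candidates; each E-step reassigns their mass proportionally to current
subfamily abundances among the candidates, each M-step recomputes
abundances. Iteration stops when the largest absolute abundance change
drops below `tol` (default 1e-4) or after `max_iter` (default 100)
rounds. Total assigned mass equals the number of reads with at least
one TE-overlapping hit at every iteration (checked to 1e-6 in tests).
Reads whose hits touch no TE contribute nothing and are reported. The
EM runs over TE candidates only; down-weighting reads also compatible
with genes is left to the caller via the feature set supplied.

## Normalization and detection

Size factors come from the gene count matrix by median-of-ratios: the
per-gene reference is the geometric mean across units over genes with
strictly positive counts everywhere; a unit's factor is the median of
count/reference. TE counts are divided by these gene-derived factors —
repeat counts themselves are too sparse and too condition-dependent to
estimate sequencing depth. Factors are identifiable only up to the
geometric-mean constraint: scaling one unit by c changes the
between-unit factor ratio by exactly c and the normalized matrix by a
single global constant (this exact form, not naive per-column
invariance, is what the tests assert). Log display values are
log2(x + 0.5). An element is *detected* in a group of units when its
group-mean normalized count is strictly greater than 10; the detected
ratio divides by the total number of annotated elements of the
subfamily in the supplied annotation. Groups are an explicit input
because the grouping of units is analysis-specific.

## Chimera detection

Assembled transcripts are collapsed on (contig, start, end, strand) —
the dedup key is coordinate identity, since assembled duplicates carry
arbitrary ids — and kept when strictly longer than 1000 bp. Each
transcript is reduced to its TSS (interval start on `+`, end−1 on `−`)
± 100 bp, clipped to contig bounds. A candidate pair requires ≥ 1 bp
overlap between the window and a full-length (> 6 kbp) L1 *and*
opposite strands. A candidate is an expressed chimera when its
normalized expression (gene-derived size factors) strictly exceeds 20
in at least one unit; the per-unit table is always carried in the call
so the any-unit aggregation can be revisited. Peak-to-element
association is plain any-overlap, strand-agnostic, half-open.

## Promoter motif and profile analyses

Element prefixes are extracted strand-aware (reverse complement of the
last n genomic bases for `−` elements), so "first 100 bp" always means
the element's own 5′ end. The YY1 scan requires an exact, fully
contained match of `CAAGATGGCCG` within the prefix — a match
overhanging base 100 does not count. ORF0 status is read from a
caller-supplied offset within the antisense-promoter sequence: ATG is
intact, anything else is disrupted and reported with its amino acid
(ACG → Thr is the Met→Thr start loss; locating ORF0 de novo is out of
scope since that requires cross-species alignment).

Coverage meta-profiles bin each element body into a fixed number of
bins (scale-regions semantics, so bodies of unequal length share a
heatmap) and flanks at a fixed bp-per-bin; rows of `−` elements are
reversed so every row reads 5′→3′. A read contributes to every bin it
overlaps. Bins extending beyond contig bounds are missing (NaN), which
is distinct from zero coverage. RPKM for a bin is reads / (bin length
in kb × total mapped reads in millions).

## The synthetic study

The generator plants the statistical structure the pipeline must
resolve, with per-read truth. Defaults define the study conditions:

- genome: 2 contigs × 260 kb; subfamilies L1HS/L1PA2 (6 copies, 4
  full-length each), L1PA3/L1PA4 (5 copies, 3 full-length), plus an
  ancient L1MA4 (8 truncated copies). Copies derive from a shared
  family consensus via per-subfamily divergence (1–20%); within-
  subfamily identity 93–98.5% drives multimapping. All copies are
  3′-anchored (L1 truncates from the 5′ end), full-length bodies are
  6050–6400 bp, truncated 600–3000 bp, strands balanced.
- 8 genes (8–14 kb); half of the truncated copies are intragenic.
  Full-length copies are intergenic so that read-through cannot leak
  into the full-length detection universe — mirroring that detection
  is defined over full-length elements.
- transcripts: one antisense chimera (3 kb, TSS 400 bp inside a
  full-length host, opposite strand) and three decoys — same-strand
  TSS-in-L1, a 900-bp antisense transcript, and an antisense candidate
  covered by only ~6 read pairs per sample (below the expression-20
  threshold). Hosts are excluded from the sense-expressed set so decoy
  expression is controlled exactly.
- reads: bulk 30k pairs/sample × 2 samples, 2 × 150 bp reverse-
  stranded, fragment 250–450 bp; class mix 60% genes, 18% L1
  (promoter-driven fraction 0.8, the rest read-through), 8% planted
  transcripts, ~14% intergenic background placed only in annotation
  gaps. Single-nucleus: 4 clusters × 25 cells/sample, Poisson(1000)
  reads/cell, single-end records with CB/UB; L1-active clusters draw
  15% of reads from the expressed elements, inactive clusters none.
  PCR duplicate rate 0.15 (duplicates copy position + CB + UB of their
  template; distinct molecules are guaranteed distinct keys), multimap
  rate 0.2 (secondary hits at the homologous 3′-anchored offset of
  other full-length young copies), 4% of reads fail the 0.03 mismatch
  filter. Half of full-length young copies per subfamily are
  sense-expressed; YY1 present in 60% of full-length elements
  (planted at offset 6, chance matches scrubbed from non-carriers);
  ORF0 intact in 50%.
- QC: 5% of cells get mitochondrial content > 10%; feature counts are
  Normal(3000, 300). Mitochondrial content is simulated as a per-cell
  percentage, not as reads on a mito contig, because the QC rule
  consumes only the percentage.

The promoter-vs-read-through fraction, depths and rates are free
parameters of the simulation, not claims about any real tissue. What
passing tests show is that the *machinery* is exact: flags encode the
transcribed strand losslessly, planted duplicates and only they are
removed, planted expression and only it is detected at the stated
depths. Real data add what the generator omits: base-quality and
sequencing-error structure, polymorphic non-reference insertions,
splicing, ambient RNA and doublets, and read-through depths that need
not sit comfortably below detection thresholds.

## Numerical and design choices

- Strict inequalities at every printed threshold (6 kbp, 10, 1 kbp,
  20, first 100 bp) — boundary values are excluded.
- EM: uniform initialisation, abundance-proportional E-step, tol 1e-4,
  max_iter 100; identical candidate sets are pooled for speed.
- Degenerate inputs: empty alignment sets give full zero-count
  indexes; empty groups, missing size factors, non-positive
  pseudocounts, truncated codons and out-of-range ratios raise.
- Ties in deduplication resolve to the first record in coordinate
  order (contig, start, read id, flag).
- The analysis drivers rebuild the simulation from the seed instead of
  passing intermediates; the simulation is byte-deterministic, so all
  drivers see identical data while staying independently runnable.
- The library surface (modules + analysis drivers) is the interface;
  no shell CLI is shipped, as every operation is a few lines against
  the library and the drivers document the canonical call order.
- Problem sizes in tests and the acceptance script (~200 cells, ~200k
  single-nucleus reads, 30k bulk pairs/sample, EM mixtures of 5000
  reads) were chosen as the smallest study at which detection margins
  are separated from thresholds by several standard deviations.

## Known limitations

- Counting is per record; fragment-level counting (counting a proper
  pair once) is not implemented.
- The EM does not model gene-vs-TE assignment hierarchies or positional
  bias within elements.
- CRAM input, bigwig output and image rendering are out of scope
  (bedGraph/TSV suffice; conversion is external).
- The chimera caller does not classify sense- vs antisense-promoter
  origin beyond strand orientation, and does not predict ORFs on the
  chimeric transcripts.
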
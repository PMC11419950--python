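# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `scicounter`, module by module.

## Droplet barcode detection and correction (`demux`)

Observed barcodes are counted and sorted by read count, ties broken
lexicographically so runs are reproducible across platforms.  Detection is
a single greedy pass: the highest-count free barcode is promoted to a
droplet barcode; all free barcodes within Levenshtein distance 1 are
absorbed onto it and removed; the loop stops when the best free barcode
has fewer than `min_reads` reads (default 20) or `max_droplets` (default
100 000) droplets exist.  Consequences worth stating as normative
behavior:

* Droplet barcodes are pairwise at distance ≥ 2 by construction; the
  result object's `validate()` asserts this on every pipeline run.
* A barcode within distance 1 of two droplet candidates is absorbed by the
  earlier-promoted (higher-count) one.
* The `min_reads` floor applies to a barcode's **own** (pre-absorption)
  read count, not the post-absorption total.
* With a whitelist, unlisted barcodes are never promoted but remain
  absorbable as sequencing errors of a listed droplet — error reads must
  still be rescued.

The distance-1 search enumerates the candidate's substitution
(3·L), deletion (L) and insertion (4·(L+1)) neighborhood and looks each
neighbor up in a hash map of free barcodes, which is exact for edit
distance 1 and independent of how the search is partitioned into batches
(`n_batches` exists purely as a parallelization unit; tests assert
equality for 1 and 50 batches).  The pairwise primitive
`levenshtein_within_1` delegates to `edlib` with a cost cut-off of 1 and
is checked against an unbanded dynamic-programming oracle.

Barcode/UMI extraction assumes the layout `[barcode][UMI][adapter][cDNA]`
and locates the adapter on either strand within the first 200 nt allowing
`max_adapter_dist` edits (default 2).  The exact chemistry layout varies
between kits, so lengths and adapter are parameters rather than constants.

## Region splitting (`regions`)

Work units target 5 Mb (`target`) but a boundary may only be placed inside
a gene-free run of at least 250 kb (`free_window`), at the run's
**midpoint** — guaranteeing ≥ 125 kb of clearance on both sides, far
beyond any read length, so no molecule's alignments can straddle two
regions.  Placement is a greedy left-to-right pass: cut at the first legal
midpoint at or beyond `current_start + target`.  Regions tile each
chromosome exactly; a chromosome with no legal split point stays whole.
Whether boundaries belong at window edges or midpoints was an open design
choice; the midpoint maximizes clearance and is what the region-split
equivalence tests certify.

## Assignment adaptation (`assignments`)

Input is a tab-separated read-assignment dialect (columns `read_id`,
`chrom`, `strand`, `isoform_id`, `gene_id`, `assignment_type`,
`assignment_events`, `exons`, `additional_info`; '#'-prefixed header;
gzip-transparent; coordinates 0-based half-open).  Adaptation proceeds:

1. **known/novel merge** — a read present in the novel-model table has its
   assignment replaced by the novel model's; other reads keep their
   reference assignment.  Duplicate `(read, transcript)` rows within one
   table are a validation error.
2. **novel renaming** — novel transcripts become
   `novelt_<chrom>_<start>_<end>_<strand>_<hash8>` where `hash8` is an
   md5 prefix of the intron chain; novel genes become
   `novelg_<chrom>_<start>_<end>_<strand>`.  Identical models discovered
   in different region partitions therefore coincide, and distinct chains
   at one locus never collide.
3. **molecule blocks** — rows are sorted by (barcode, UMI, read name)
   with a stable chunked external merge sort (bounded memory; spill chunks
   on disk) and grouped into blocks; reads without barcode/UMI form
   singleton blocks keyed by read name.
4. **resolution** — within a block, an assignment is dropped when it hits
   no gene while another does, or when its aligned length is below
   `short_frac` (default 0.5) of the block's longest gene-bearing
   alignment.  The 50 % threshold quantifies "significantly shorter"
   conservatively: genuine multi-mapped full-length reads are retained,
   adapter fragments and chimeric tails are not.
5. **correction factors** — `umicount` is the number of reads retaining at
   least one assignment in the block; `ambiguity` and `gambiguity` are
   **per read**: the distinct transcripts, and distinct genes or loci
   (gene-less assignments bucketed by chromosome and 10 kb start window),
   that the read supports.  Defining the factors per read is what makes
   the counting weights below sum to exactly one per molecule.
6. final output is re-sorted by genomic location.

`covered_pct` is taken from the input when present; otherwise it is
computed from the read's aligned blocks against the assigned isoform.
`inconsistency` is carried as an opaque reportable integer and never used
as a filter.

## Count flavors (`counting`)

For every read assignment to transcript T in cell c:
`weighted[T,c] += 1/(ambiguity × umicount)`.  Summed over a molecule's
retained assignments this is exactly 1, so total weighted counts equal
total molecules (asserted to 1e-9; deviations are float accumulation
ulps).  `unique` counts molecules whose retained assignments support a
single transcript — within-molecule consensus is required, so a molecule
whose reads disagree counts toward no transcript, avoiding double
counting.  `strict` additionally requires the molecule's best
`covered_pct` among supporting reads to reach 0.90, **inclusive** at the
boundary.  The polyA-restricted flavors (`aweighted`, `aunique`,
`astrict`) use the same weights and rules but only reads with a detected
polyA tail; because weights are unchanged, every a-flavor is bounded by
its unrestricted counterpart row by row.

Gene counts: per read and distinct gene,
`count[g,c] += 1/(gambiguity × umicount)` including intronic-only reads;
`nicount` accrues the same weight only when the read matches an isoform of
the gene.  Deduplication is per (read, gene) so a read with two isoform
assignments in one gene contributes once.

Outputs: tidy TSV plus one MatrixMarket matrix per flavor with
feature/barcode sidecars.

## Organelle counting (`organelle`)

Only gene locations are held in memory; alignments stream through one at a
time.  A CIGAR is parsed into maximal reference intervals (M/=/X/D extend,
N splits, S/H/I/P consume nothing).  For each gene, `overlap_pct` is the
overlapping fraction of the **read's** aligned bases; a gene is a
candidate when that fraction is ≥ 5 % and the overlap also covers ≥ 5 %
of the **gene**.  The two denominators are genuinely ambiguous in common
usage, so both thresholds are explicit parameters; applying both is the
conservative intersection.  Among candidates the non-rRNA gene with the
highest `overlap_pct` wins; if only rRNA genes qualify the best rRNA gene
is used rather than discarding the read (rRNA is de-prioritized, not
banned).  Events: `mono_exon_match` when both alignment ends are within 3
bases of the gene ends, `mono_exon_enclosed` when the alignment lies
inside the gene, else `mono_exon_overlap`.  Counting mirrors the gene
formulas; molecules whose best event is `mono_exon_overlap` are excluded
from unique counts.

## Cell calling, pseudobulk, multi-sample merge (`cells`)

Cell calling is a deliberately simplified re-implementation in the spirit
of EmptyDrops; exact parity with the published implementation is not
claimed and all calibration claims are against this package's own
simulations.  Barcodes with total count ≤ `lower` (default 100) define the
ambient profile (≥ 10 such barcodes required); a pseudocount of 1e-10 on
the ambient proportions avoids log-of-zero for genes absent from the
ambient pool.  Each deeper barcode receives a Monte Carlo p-value: the
fraction of `n_iter` (default 1000) multinomial draws at its depth whose
log-likelihood under the ambient proportions is at most the observed one,
with the +1 correction so p ≥ 1/(n_iter+1).  Draws are shared across
barcodes of equal depth.  Benjamini–Hochberg (statsmodels) controls FDR at
`fdr` (default 0.01).

Barcodes above a knee in the ranked-depth curve are additionally always
retained.  The knee is defined as the largest log10 jump between
consecutive ranked totals above `lower`, accepted only when the jump
exceeds `knee_prominence` (default 0.3 ≈ 2-fold) with at least
`knee_min_above` (default 5) barcodes above it.  This deliberately differs
from curvature-based knee finders: adjacent order statistics of a smooth
ambient depth distribution are close together, so an ambient-only dataset
has no knee and the null calibration of the caller is preserved, while a
cell population stacked well above the ambient tail produces a cliff that
always fires.  Novel genes are excluded from the matrix handed to cell
calling by default (`exclude_novel`), keeping the ambient test on the
reference annotation.

Pseudobulk sums one count flavor over the cells of each group; cells
absent from the group file aggregate under `unassigned`, so totals are
conserved exactly and a re-run after editing the group file changes only
the affected columns.  Multi-sample merging matches known features by ID
and novel spliced transcripts by (chrom, strand, exact intron chain);
single-exon novel transcripts match when both ends agree within
`end_tolerance` (default 50 nt — spliced transcripts need no tolerance
because the junction chain is exact, while mono-exonic ends wobble with
read truncation).  Clustering of mono-exonic models runs over the sorted
union of all samples' models, making the merge invariant to sample order.
A merged row takes the union span; conflicting strands for one intron
chain are a validation error.

## Synthetic data (`fixtures`)

The generator emulates, at desk scale, the regime of a droplet-based
single-nucleus long-read experiment (tens of thousands of nuclei, skewed
depth, an ambient tail reaching well into empty-droplet territory):

* per-cell depth ~ log-normal (default mean 50 reads, sigma 0.6); ambient
  depth ~ geometric (default mean 3) — together they reproduce the knee
  shape the demultiplexer must traverse;
* 16 nt barcodes drawn at pairwise Levenshtein distance ≥ 3 (so a single
  error never makes two cells ambiguous), 12 nt UMIs, a fixed 10 nt
  linker, per-base errors at 2 % split 8:1:1
  substitution:insertion:deletion;
* covered isoform fraction ~ Beta(5, 1) (mean ≈ 0.83, so sub-90 % reads
  arise naturally); polyA detected on 80 % of reads;
* assignment tables with 10 % multi-isoform molecules, 5 % multi-gene
  molecules, 20 % UMI duplication and 5 % short intergenic junk rows.

Barcode universes at `min_dist` 3 are screened with distance-1
neighborhood sets (two sequences are within distance 2 iff their
distance-1 balls intersect), which keeps generation linear-ish in n;
larger distances fall back to pairwise banded alignment.

What the generator does **not** emulate: realistic base-error profiles of
any specific chemistry, quality scores beyond a constant, positional error
hotspots, barcode swapping/chimeras, doublets, or biologically structured
expression programs.  Passing tests therefore certify the algorithmic
contracts (correction, weighting, conservation, calibration under the
stated noise model), not end-to-end accuracy on real libraries.

## Fixture scales used by the test suite and acceptance script

Chosen so the whole suite runs in well under a minute of CPU while keeping
every mechanism exercised: 100 random barcode tables (≤ 200 barcodes) for
the demultiplexer-vs-oracle check; 500 true barcodes × ~100 reads/cell
(~45 000 reads) at 2 % error for the rescue-rate measurement — this
fixture uses depth sigma 0.3 so that every true barcode clears the 20-read
promotion floor and the measurement isolates error correction rather than
depth skew; 20 random assignment fixtures for conservation; 10 000 random
organelle alignments × 20 genes for the classifier oracle; 5 000 ambient
barcodes with 1 000 Monte Carlo iterations for null calibration plus 100
planted cells at 20× ambient depth for recall; and a full pipeline run
repeated serially and with 4 workers for byte-level determinism.

## Known limitations

* UMIs are matched exactly; no directional/network UMI collapsing.
* `unique` requires within-molecule consensus; pipelines that count any
  unique read once per molecule will report slightly higher unique counts
  on discordant molecules.
* The cell caller is a simplified ambient test: no Good–Turing smoothing
  of the ambient profile and no Dirichlet overdispersion, so it is
  anti-conservative for strongly overdispersed ambient pools.
* Transcript-model discovery, alignment, clustering and cell typing are
  out of scope; the package consumes their outputs (assignment tables,
  group files).
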
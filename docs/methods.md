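# Methods

## The problem and the model

Nanopore amplicon reads of a mitochondrial barcode locus carry a combined
substitution/insertion/deletion error around 13% per base. Species
delimitation from barcodes typically demands ≥98% identity to a reference,
so single reads cannot be classified reliably. The workflow groups reads
that descend from the same template species (greedy identity clustering),
averages their errors away column-by-column (multiple alignment + majority
consensus) and only then applies the identity/coverage thresholds. Two
markers (cytb, COI) are combined because primer sets fail for some species
and reference databases are incomplete for others: a species missed or
under-resolved by one marker is recovered by the other.

## Stages and parameters

All defaults live in `PipelineConfig`; each is the workflow's operating
point, overridable per run.

| Stage | Parameter | Default | Meaning |
|---|---|---|---|
| filter | `min_mean_q` | 10 | arithmetic mean of per-base Phred scores |
| filter | `min_len`, `max_len` | 500, 800 nt | inclusive read-length window for full-length amplicons |
| primers | `max_error_rate` | 0.20 | edit budget = floor(rate × span) of a hit |
| primers | `min_overlap` | 15 nt | minimum read-side span of a primer hit |
| clustering | `cluster_threshold` | 80% | identity to the representative (matched columns / shorter length) |
| clustering | `kmer_prescreen` | 5 | q-gram word size of the exact skip test (None disables) |
| clustering | `min_cluster_size` | 5 | clusters below this yield no consensus |
| consensus | `subsample_cap` | 100 | reads entering the MSA per cluster |
| consensus | `consensus_threshold` | 0.30 | a column's winner must exceed this frequency |
| taxonomy | `min_identity` | 98% | over aligned columns of the local alignment |
| taxonomy | `min_coverage` | 90% | query-side span of the local alignment |
| taxonomy | `score_margin` | 0 | hits within this raw score of the best remain candidates |

### Primer matching

A primer is located by semi-global edit-distance alignment in which the
read's flanks are free and the primer may overhang either read end at no
cost. A placement qualifies when its read-side span is at least
`min_overlap` and its edit distance is within `floor(max_error_rate ×
span)`; among qualifying placements the fewest-edit one wins, ties going to
the leftmost, then longest. IUPAC degeneracy is free on the primer side
only; an `N` in the read matches nothing. The search runs as a single
bit-parallel infix query over a sentinel-padded read; if every minimum-edit
placement fails its own span budget (an adversarial corner), an exact
dynamic-programming enumeration takes over. Marker classification requires
a forward primer at one end and a reverse-primer complement at the other
(either strand); single-ended evidence suffices when the opposite end is
eroded, two-ended evidence wins otherwise, and exact ties between markers
leave the read unassigned.

### Clustering

Greedy and longest-first, as in CD-HIT-EST: each read joins the existing
cluster whose representative it matches best at ≥ threshold (best-cluster
joining rather than first-fit — deterministic and at least as cohesive),
else founds a new cluster. Candidates are compared on both strands because
nanopore libraries are unstranded. Identity is the number of identical
columns of a unit-cost global alignment divided by the shorter length;
since cost-optimal alignments can differ in identical-column count, the
pair is aligned in a canonical argument order to make the value
deterministic and symmetric. Two exact accelerators are used: a banded
distance screen (identity ≥ t requires edit distance ≤ len_a + len_b −
2·ceil(t·min_len)) and a q-gram count bound (each edit destroys at most k
k-mers); both only skip pairs that provably fall below the threshold, so
enabling them never changes the clustering.

### Consensus

Per cluster: subsample (uniform, seeded) to ≤100 reads, flip each read onto
the representative's strand (decided by unit-cost alignment distance — for
full-length amplicon copies the wrong strand is unambiguous), then build a
center-star MSA: the center is the read with the highest mean identity to a
sample of ≤20 cluster mates (ranked by the distance-derived bound
(la+lb−d)/2/min_len, which at within-cluster similarity tracks identity
closely), every read is aligned to the center with a unit-cost global
aligner, and the pairwise gaps are merged into common coordinates (once a
gap, always a gap; insertions between the same center positions stack
left-justified without being aligned to each other). The 30% majority rule
then scans columns: frequencies of A/C/G/T/− are computed over the non-N
symbols; the winner is emitted iff it is a base and its frequency strictly
exceeds 0.30. Columns won by a gap are dropped, which is what makes the
consensus length track the template length: a deletion in a minority of
reads is outvoted, an insertion private to few reads forms a gap-majority
column and vanishes. Base-vs-gap frequency ties favour the base; base-base
ties go alphabetically. Remaining primer residues at the termini are
removed with the same matcher used for demultiplexing (search window: twice
the primer length at each end; interior hits untouched).

Why this corrects errors: with per-base error ~13% split as 8%
substitution / 2.5% insertion / 2.5% deletion, the correct symbol wins a
column with overwhelming probability at depth 100 (the strongest competitor
base sits near 2.7%), so residual consensus error is dominated by rare
pile-ups and center-star merge artefacts; measured, it is ~0.2%, an
order of magnitude under the 2% target.

### Taxonomic assignment and marker combination

Consensi are aligned locally (Smith–Waterman, match +1, mismatch −2, linear
gap −2, both strands) against every reference of their marker — reference
sets here are small curated FASTAs, so exhaustive alignment replaces
heuristic database search, and at fixed scoring parameters ranking by raw
score is equivalent to bit-score ranking. Hits passing identity ≥98% and
query coverage ≥90% are candidates; those within `score_margin` of the top
score are kept and resolved to their lowest common rank. A zero margin
keeps exact ties only; a margin of ~20 (used in the mixture benchmarks)
keeps hits a few substitutions off the best, which is what lets a species
absent from the database resolve to its family via two close confamilial
references instead of being forced onto an arbitrary sibling species.
Distinct true species in these benchmarks are ≥8% divergent (score gap
≈130), far beyond the margin.

Across markers, each species-level call stands provided every other
marker's call for that lineage is an ancestor rank or absent; ancestor
calls with a species descendant are absorbed as corroboration, the rest
surface as genus-/family-level conclusions. Sibling species called at
species rank by different markers are treated as two detections (this is
exactly the congener situation the two-marker design exists for); an
optional strict mode collapses such pairs into a flagged genus-level
conclusion when neither is corroborated by the other marker.

### Error metric

Error percent = 100 × (mismatches + insertions + deletions) / (sum of query
lengths), from a global alignment with unit penalties for substitutions and
for every gapped position. Among cost-optimal alignments the one with the
fewest gap columns is preferred; given total cost, gap count and the length
difference, the three counts are fully determined, so the implementation
minimises (cost, gaps) lexicographically in one packed dynamic program and
never needs a traceback. Queries are full primer-trimmed reads (or
consensi) of their target, so global rather than local alignment is the
right scope.

## What the simulator does and does not emulate

`simdata` draws i.i.d. per-base events: delete (2.5%), substitute to a
uniformly chosen different base (8%), and insert a uniform base after a
position (2.5%); reads are full-length amplicon copies, reverse-complemented
with probability 0.5, with integer qualities around mean 12 (s.d. 3,
clipped to [1, 41]). Reference sets derive congeners from a genus root
(pairwise species divergence ≈ the requested value, default 8%), genera
from a family root (default ≈20% apart), and families independently.
Mixtures allocate reads multinomially by weight fraction; dropout
species/marker pairs contribute nothing (their share is not reallocated);
carry-over injects a stated fraction of reads from another run.

Not modelled: homopolymer-biased and positionally correlated errors, read
fragmentation and chimeras, quality–error correlation, abundance-dependent
PCR bias. Consequently, passing benchmarks demonstrate the pipeline's
statistical logic (clustering separability, consensus convergence,
threshold behaviour, dropout bookkeeping) under the stated error budget —
not robustness to nanopore-specific systematic artefacts; on real data,
homopolymer indels are the likeliest residual consensus error.

## Benchmark problem sizes

The two mixture benchmarks simulate 8000 reads per marker (six- and
eleven-species tables) against references with ≥8% inter-species
divergence; the consensus-error benchmark pools ten independent 100-read
clusters of a 600-nt amplicon (~5500 consensus bases scored). These sizes
keep a full run in a few minutes on one CPU while leaving every species'
expected read count (≥330) far above the minimum cluster size.

## Known limitations

- Center-star MSA is not iterative; insertions private to subsets of reads
  are stacked, not aligned, slightly inflating gap-majority columns. For
  ≤100 reads at ≤20% divergence from the center this does not measurably
  affect the consensus.
- Identity and error counts are properties of one cost-optimal alignment;
  conventions (canonical argument order, min-gap preference) make them
  deterministic, but other tools' optima may differ in the last decimal.
- The assignment rule resolves ranks from margin-tied hits only; it does
  not model E-values, nor taxa above family rank.
- Quality scores are carried through trimming but never weight the
  consensus (the filter alone consumes them), matching the workflow this
  package implements.
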
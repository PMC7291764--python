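# Methods

## Scope and model

`habitax` constructs habitat-specific 16S rRNA gene training sets at
species/supraspecies resolution and assigns taxonomy with a bootstrap
naïve Bayesian k-mer classifier (Wang-style word statistics). The package
assumes a curated reference database as its starting point: one stable
taxon identifier per species-level taxon, each represented by one to a few
close-to-full-length, correctly annotated reference sequences with a
seven-rank lineage (Kingdom;Phylum;Class;Order;Family;Genus;Species). The
quality of everything downstream is bounded by the quality of that
database; the package performs no annotation correction of its own.

### Word model

With N training sequences, n(w) of which contain the length-k word w
(presence within a sequence, not multiplicity), the prior is
Pi(w) = (n(w)+0.5)/(N+1). For a leaf class c — a unique full lineage —
with M_c sequences, m_c(w) of which contain w, the log conditional is
L_c(w) = log[(m_c(w)+Pi(w))/(M_c+1)]. A query is scored by summing L_c
over its distinct words; 100 bootstrap iterations each resample ⌊W/8⌋ of
the W distinct query words with replacement and re-run the argmax. The
bootstrap percentage of a rank is the share of iterations carrying its
modal label; because every leaf vote also votes for its ancestors, these
percentages never increase from kingdom to species. Assignments below the
minBoot threshold are masked top-down (a masked rank masks all deeper
ranks).

Design points that were genuinely open, and the choices made:

* **Subsample size ⌊W/8⌋ and presence scoring** follow the canonical
  formulation of the algorithm; word multiplicity is ignored both in
  training and in queries.
* **Reported label per rank is the modal label over bootstrap winners**,
  not the full-word argmax (which is recorded separately); this keeps the
  label and its bootstrap percentage referring to the same quantity.
* **All ties** (argmax ties within an iteration, modal-label ties across
  iterations) are broken by a seeded uniform choice, making runs exactly
  reproducible. Two classes with identical word statistics therefore split
  votes ≈50/50 rather than one of them winning deterministically.
* **Orientation**: queries are classified as given; an optional
  try-reverse-complement mode classifies both orientations and keeps the
  higher species bootstrap (off by default).
* A scoring property worth knowing: duplicating every training sequence
  doubles N, M_c, n, m_c exactly and preserves the winning class of a
  query, but the ordering *below* the winner can shift slightly, because
  the absent-word term log(Pi/(M_c+1)) moves by a class-size-dependent
  amount. Class sizes therefore matter beyond simple proportions: classes
  with few members are favoured on words absent from the model, which is
  precisely why compiling many sequences per taxon changes behaviour.

### Training-set construction ladder

1. **Trimming** (`trim_start=28`, `trim_end=1373`, 1-based inclusive):
   removes hanging 5'/3' ends that would distort identity; references
   shorter than the window are truncated with a warning, references
   shorter than the window start are an error.
2. **Recruitment** (`candidate_min_identity=97`, `recruit_min_identity=99`,
   `recruit_min_coverage=98` (% of the reference length aligned),
   `min_subject_len=1000`, `whole_subject_max_len=2000` nt): precomputed
   BLAST tabular hit tables are accepted, and a built-in candidate-pool
   mode computes the same quantities without any network access by
   aligning each trimmed reference semi-globally into each candidate with
   an edit-distance aligner (edlib); gaps at the candidate's ends are
   free, identity is computed over the aligned span and coverage as the
   fraction of reference positions covered. An affine gap model adds
   nothing at ≥97% identity on this gene, and the edit-distance aligner is
   orders of magnitude faster. Subjects within [1000, 2000] nt join as
   whole sequences; longer subjects (genomes) contribute only the aligned
   portion. A subject matching several taxa goes to its best
   (identity, coverage) taxon; exact ties are broken by a seeded uniform
   choice recorded in the build manifest — without a seed this step is
   irreproducible.
3. **Region extraction** (`region_start=40`, `region_end=880`, columns of
   the gapped reference alignment): with a supplied multiple alignment the
   stated columns are cut and degapped. The built-in mode instead aligns
   each member pairwise to its own reference and maps ungapped reference
   positions [40, 880] of the trimmed reference through that alignment;
   on indel-free data the two agree exactly, and deviations from a
   particular multiple-aligner's column numbering are possible otherwise.
   Members with no aligned bases in the region are dropped with a warning.
4. **Curation** (`intergenus_min_support=4`): exactly identical region
   sequences collapse to one record; species labels of all taxa involved
   are concatenated with ":" in lexicographic order (concatenation
   components are kept sorted and duplicate-free everywhere, so label
   comparisons are order-insensitive). Same-species duplicates keep their
   name. Merges spanning two or more genera are accepted only with at
   least 4 supporting duplicate records — a merge supported by 2–3
   sequences is treated as unreliable — in which case genus labels (and
   any higher ranks that disagree) are concatenated too. Rejected
   intergenus merges are resolved by a configurable policy:
   `drop-minority` (default — the duplicates of all but the
   best-supported genus are removed, the rest collapse normally),
   `drop-all`, or `keep-best-supported`. The choice of what to do with
   rejected merges is not dictated by the construction itself; dropping
   the minority keeps the best-supported signal while removing the
   ambiguous records.
5. **Supraspecies** (`supraspecies_distance=0.005`, strictly-less-than at
   machine precision): taxa are grouped by single linkage over the
   relation "some sequence pair is closer than the threshold"; connected
   components with ≥2 taxa become supraspecies, labelled with the ":"
   concatenation of member species labels. Sequences are carried over
   byte-identically; only headers change. Records that already carry a
   concatenated species label keep it at both the supraspecies and
   species levels; unmerged taxa repeat their species label. Distances
   default to pairwise Jukes–Cantor, d = −(3/4)·ln(1−(4/3)p) with p the
   proportion of differing sites over columns where both sequences have
   an unambiguous base (p ≥ 0.75 reports +inf); a patristic backend sums
   branch lengths on a supplied newick tree instead. The two backends can
   disagree marginally for pairs near the 0.005 boundary; group
   differences there are expected and logged rather than hidden.

### Read simulation

One read per unique sequence of the (region-trimmed) training set: exactly
round(error_rate × L) distinct positions substituted (half-away-from-zero
rounding; the count is forced per read, not just in expectation), each to
a uniformly chosen different base; then the first `r2_len` bases (5'/V1
end) and last `r1_len` bases (3'/V3 end) are joined as R2 + 10×N + R1,
both fragments in the forward orientation. Defaults: `error_rate=0.01`,
`r2_len=250`, `r1_len=100` — a realistic non-overlapping paired-end
configuration for this region. The 10-N linker contributes no words, so
the classifier sees exactly the union of the fragments' word sets; a flag
can emit R1 reverse-complemented to mimic raw sequencer output.

## The synthetic habitat

The generator emulates the phylogenetic structure the construction is
designed for: a few genera (~10% pairwise divergence), congeneric species
(~2%), within-species variants (≤0.5%), with a configurable number of
congeneric species pairs forced to share an identical sequenced
sub-region (the situation that motivates curation and supraspecies).
Divergences are realised as seeded point substitutions from a common
ancestor at half the target pairwise rate per lineage; the first variant
of every species is the reference sequence itself, since public
repositories contain the reference's own record. The default evaluation
habitat is 6 genera × 4 species × 10 variants (240 candidates, 24 taxa)
with one forced pair and 500 reads — small enough for the whole pipeline
plus five classifier sweeps to run in seconds, large enough for the
mechanism contrasts to be far outside sampling noise.

What the generator does **not** emulate: indels and chimeras, ambiguity
codes, platform-specific error profiles, rate variation along the gene,
unequal species abundances, and taxa absent from the reference database.
Passing tests on this habitat demonstrate the construction and classifier
mechanics — they do not certify accuracy on real reads, where reads from
species missing from the database are necessarily forced onto their
nearest present relative. Simulated reads also share their origin with
the training set (each read's parent sequence is a training member),
which flatters absolute accuracy; the evaluation therefore leans on
*contrasts between training sets* under identical reads rather than on
absolute numbers.

## What the evaluation shows

On the default habitat, three contrasts are measured across minBoot
50–100 (reads scored against their parent lineage; a ":"-concatenated
label counts as correct when its component set intersects the truth
label's components):

* **Compilation vs single-reference**: with one sequence per taxon, reads
  from the identical-region pair tie exactly between the two classes and
  the seeded coin-flip votes produce low-bootstrap, half-wrong species
  calls (~3.4% of classified reads misclassified at minBoot 50); with ten
  variants per taxon the read's parent neighbourhood dominates and
  misclassification drops by well over half at every threshold.
* **Supraspecies vs curated**: reads whose species votes split between
  indistinguishable species fall below threshold in the depth-7 curated
  set and default to genus; the depth-8 set assigns them their
  supraspecies label at high bootstrap instead (≈3 percentage points more
  reads kept below genus at minBoot 70, at equal or lower error).
* **Region trimming alone**: trimming the compilation to the region
  without curation leaves accuracy essentially unchanged in this model —
  every word of a region-confined read lies inside the region, where the
  trimmed and full-length models have identical statistics, so the two
  assign reads identically. The accuracy gain of the short-read ladder
  comes from the curation and supraspecies steps, not from trimming per
  se.

## Numerical and degenerate-input conventions

* All sequence coordinates are 1-based inclusive; headers use ";" between
  ranks, ":" within concatenated labels; trailing ";" is tolerated on
  read and never written.
* Training sequences shorter than k are excluded from the model with a
  warning; queries with fewer than k distinct words are an error.
* Bootstrap subsample size is max(1, ⌊W/8⌋).
* The supraspecies threshold comparison is strictly-less-than; distances
  at exactly 0.005 do not merge.
* Percentages in emitted tables are rounded to one decimal; internal
  computations are full precision.
* Identity/coverage from tabular hits are taken as printed; the built-in
  aligner recomputes them from the alignment path.

## Problem sizes

Default test and reproduction runs use the 6×4×10 habitat (264-member
compilation, ~230-record curated set), 500 simulated reads and 100
bootstrap iterations; the construction ladder takes well under a second
and a full five-training-set sweep a few seconds. All steps scale
linearly in members × reads except pairwise distances (quadratic in
curated records; vectorised Hamming + Jukes–Cantor keeps a few hundred
records instantaneous, and a few tens of thousands feasible).

## Known limitations

* Closed-reference assignment: species absent from the database cannot be
  called, only their nearest present relative.
* The supraspecies rank is training-set-specific and not a valid formal
  taxonomic designation; it must be rebuilt for every region and database
  revision.
* The built-in aligner is edit-distance based; highly gapped or partial
  candidates are better served by supplying precomputed hit tables.
* The classifier holds a dense (classes × 4^8) count matrix; hundreds of
  thousands of leaf classes would need a sparse backend.
* Single-gene taxonomy: copies of the 16S gene within one genome can
  differ, and the model treats each sequence independently.
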
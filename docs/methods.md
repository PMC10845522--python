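# Methods

This note documents the models and procedures implemented in `vitiscape`,
the defaults chosen where the underlying methods literature leaves the
choice open, and what the synthetic-data experiments do and do not
demonstrate about real resequencing data.

## Synthetic data model

The generator (`vitiscape.simdata`) produces a multi-chromosome reference
with i.i.d. base composition, an optional repeat mask, and four kinds of
implanted features, all recorded in a ground-truth table:

* **Copy-number events** (duplications CN > 2, deletions CN < 2) belong to a
  named sample and exist only as a per-base CN track over reference
  coordinates; the reference sequence itself is unchanged.
* **Satellite arrays**: a random monomer of the requested length and A+T
  fraction, concatenated with independent per-copy substitutions at the
  requested divergence.
* **Dispersed repeat families**: copies of one element implanted at random
  positions, each copy independently diverged.  Insertions keep at least
  `min_separation` (default 500) bases of unique sequence between any two
  elements.  This models isolated insertions: no 100-nt read, nor any chain
  of overlapping 100-nt reads at the low sampled coverages used downstream,
  can span from one element into another, which keeps read clusters of
  different families disjoint.  Real genomes contain nested and adjacent
  insertions; see *Limitations*.
* **Reads**: depth is simulated directly on reference coordinates — the
  read-start count at position *p* is Poisson with mean
  `coverage/read_length · CN(p)/2` — so the per-window depth signal that
  WSSD exploits is reproduced exactly without an aligner, and no mapping
  ambiguity, GC bias or fragment-size structure is modelled.  Sequenced
  reads (for the repeatome arm) are uniform draws from the genome with
  substitution errors only; qualities are flat Q30 with an optional
  binomial-length Q10 3′ tail so that Q < 20 trimming rules have something
  to act on.

Everything is a pure function of (configuration, seed); identical inputs
give byte-identical FASTA/FASTQ/BED output.

## Copy-number profiling

Windows hold exactly *W* = 1000 unmasked bases; the genomic span grows over
masked bases, the terminal sub-*W* remainder of each chromosome is dropped.
A read is credited to the window owning the left-most unmasked base its
alignment span overlaps, so every read counts exactly once even at window
borders; window depth is `reads · read_length / W`.

GC correction (off by default, since the simulator is GC-unbiased) scales
each window by (global median / median of its GC bin) over 20 equal-width
bins, bins with fewer than 10 windows inheriting the nearest populated
bin's factor.

Absolute copy number calibrates depth against a diploid control set found
by iterative 3σ trimming: starting from all windows, windows outside
mean ± 3 sd are removed (removed windows never re-enter) until the set is
stable; `CN = 2·depth/control_mean`.  Trimming that discards more than 90%
of windows aborts with an error — such profiles have no identifiable
diploid background.  On 30×, 1-Mb simulations the estimator recovers
implanted CN ∈ {1, 3, 4} within ±0.3 (tests), with CN linearity exact under
any rescaling of depth.

## WSSD and digital CGH calling

Duplications/deletions are maximal runs of at least `min_windows = 5`
consecutive windows with CN above 2.5 / below 1.5; region bounds are the
genomic bounds of the first and last member window.  Thresholding is
per-window; an optional centered rolling mean (`smooth`) is available but
off by default, keeping the "five consecutive windows" reading literal.
One sub-threshold window splits a run — no gap tolerance — which is the
conservative reading of "consecutive".

Digital CGH computes `L2R = log2(CN_s/CN_r)` per window on a shared window
set; windows where either CN < 0.1 are undefined and removed before
segmentation (runs may therefore bridge removed windows).  Gains/losses are
runs with |L2R| > 0.25 whose genomic length exceeds 10 kbp; the loss
threshold is the negated gain threshold.  No merging of nearby regions is
performed before the length filter.

Shared CNVRs are the base-wise intersection of same-kind regions across all
samples (verified exactly against a per-base boolean-AND oracle in the
tests); regions touching no shared interval are sample-specific.  Gene
content comes from GFF3 `gene` features; a region "contains a gene" when it
overlaps any part of one.

## Variant distribution across chromosomes

Expected counts are length-proportional:
`E_c = rate · L_c/1000` with `rate = total/Σ(L_c/1000)`, so ΣE = ΣO by
construction.  The genome-wide statistic `Σ(O−E)²/E` uses n−1 degrees of
freedom, treating the rate as estimated from the observed total;
per-chromosome components are reported descriptively with one df each and
no multiple-testing correction, and chromosomes are flagged
enriched/depleted at |standardized residual| ≥ 2.  Under a
length-proportional multinomial null the test's type-I error is 0.05 ± 0.02
(2,000 simulations, tests).  Term enrichment uses the upper-tail
hypergeometric with Benjamini–Hochberg FDR.

## Repeatome profiling

Read standardization follows the fixed recipe: sample 1 M reads without
replacement (default seed 100), trim 3′ bases while Q < 20, drop reads
shorter than 100 nt, cut survivors to 100 nt, and keep a final uniform
250,000.

Clustering is by shared canonical 17-mers: two reads are linked when they
share at least 10, and clusters are connected components; components
smaller than 0.01% of reads (or singletons) are discarded.  This stands in
for graph-based community-detection clustering of unassembled reads with
the same input/output contract (read clusters + genome proportions); it
does not split chimeric or nested-repeat communities the way modularity
clustering can, and one family may come out as several components —
abundances are therefore aggregated per family label, not per cluster.

The implementation builds the graph through k-mer buckets.  For buckets of
at most 50 reads, every co-occurring pair is enumerated; a pair's bucket
multiplicity is exactly its shared-k-mer count, so the ≥ 10 rule is applied
exactly.  Deeper buckets (k-mers of high-copy repeats, where pair
enumeration would be quadratic) instead *assimilate* reads: a read joins
the component holding the majority of a deep bucket only when it co-occurs
with that component in at least 10 deep buckets — i.e. when it genuinely
shares ≥ 10 k-mers with the cluster.  A single chance k-mer collision
between unrelated sequences (expected a handful of times per 10⁸ bases)
therefore never merges two clusters, which exact chain-unioning of deep
buckets would allow.

Classification matches each member read to reference sequences by canonical
k-mer containment; containment *c* estimates identity as c^(1/k), and the
default `min_identity = 0.8` is applied on that scale.  A cluster takes a
family label when more than half of its matched members agree; exact 50/50
splits and matchless clusters are `unclassified`.

Genome proportion is (reads in the family's clusters)/(total sampled
reads).  Because reads are drawn uniformly, this estimates the family's
genomic fraction; on 100-Mb genomes with families at 2/5/10% and 250,000
reads the estimates are within a few percent relative error (tests allow
±20%).  The sampled coverage in these experiments is ~0.25×, the low-pass
regime this approach assumes — at high coverage single-copy sequence would
itself percolate into clusters and the proportion estimates would lose
meaning.

Landscape comparison centers and unit-scales family columns, runs PCA and
K-means (k = 2 by default) on the retained components, and tests each
family between groups with a two-sided Wilcoxon rank-sum (exact for small
tie-free samples), flagging p ≤ 0.05 without correction (a BH option
exists).  When groups are known a priori — and always when calibrating the
test — the `groups` argument bypasses K-means, since testing groups chosen
by clustering the same matrix biases p-values; under an identical-groups
null the observed flag rate is ≈ 0.043 at α = 0.05 (the exact test is
slightly conservative at n = 10 + 10).

## Satellite characterization and mapping

**Period.**  For candidate periods p ∈ [10, min(2000, length/3)], the score
is the fraction of positions i with base(i) = base(i+p).  The reported
monomer length is the smallest p that is a local maximum, exceeds 0.8 and
lies ≥ 0.05 above the median score; taking the smallest qualifying p
rejects dimer/multimer harmonics.  At 5% per-copy divergence the expected
score at the true period is ≈ 0.90, comfortably above threshold; recovery
is 100% over 40 arrays for each of the 107/187/677/964/994-nt families in
the acceptance run.

**Consensus** is per-column majority over period-phased frames (later
sequences rotated to the best-matching phase; ties break to the
alphabetically first base).  At ≤ 5% divergence and ≥ 25 copies the
consensus equals the true monomer with overwhelming probability.

**Palindromes** are substrings equal to their own reverse complement with
at most 2 internal mismatches, scanned circularly by center expansion.  The
outermost pair must be complementary — mismatched flanks are never
absorbed, so an implanted near-perfect palindrome is reported at its exact
length.  An odd-length palindrome's central base cannot pair with its own
complement and always costs one mismatch.

**Mapping** is seeded ungapped alignment: exact 12-mer seeds nominate
diagonal placements on both strands, each candidate is scored over the full
monomer length, candidates with identity ≥ 0.8 are kept, and overlaps are
resolved greedily by identity.  Grape satellite variants are similar enough
that gapped alignment adds nothing at this scale; arrays whose copies
diverge mainly by indels would need a different mapper.  Hits on one
chromosome closer than twice the monomer length chain into tandem loci
(≥ 5 hits); per-chromosome locus counts are the in-silico analogue of FISH
signal counts.  Haplotype comparison pairs loci on homologous chromosomes
(explicit homology table, since haplotype naming conventions differ between
assemblies) at ≥ 10% reciprocal overlap; unpaired loci are hemizygous.

## Numerical and design choices

* Coordinates are 0-based half-open (BED convention) everywhere; GFF3 input
  is converted on read.
* Window/depth arithmetic is exact integer counting; no pseudocounts.
* K-means uses a fixed `random_state` and 10 restarts; PCA component count
  defaults to the maximum informative number (min(n−1, families)).
* The chi-square comparison requires ΣO = ΣE to machine precision and
  rejects otherwise, as a guard against mixing expectation sources.
* The repeat-proportion experiments use 100-Mb genomes with 5-kb elements:
  large enough that 250,000 100-nt reads stay in the low-coverage regime,
  small enough to run in seconds; the CNV experiments use 1-Mb genomes at
  30×, where a 20-kb duplication spans ~20 windows.

## Limitations

* Depth simulation bypasses alignment, so mapping ambiguity in repeats —
  the main practical confounder of read-depth CN in real data — is not
  represented; the recovery results certify the window/calibration/calling
  logic, not robustness to mis-mapping.
* Read errors are substitutions only; no indels, adapters or quality decay
  profiles.
* The shared-k-mer clustering is a connected-components stand-in for
  community detection; cluster granularity differs from RepeatExplorer2
  even where family-level abundances agree, and nested/chimeric repeats
  would merge.
* Satellite mapping is ungapped and will under-report arrays whose copies
  differ by indels from the consensus.
* The hemizygosity analysis trusts the supplied chromosome-homology table;
  translocations between haplotypes are not detected.
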
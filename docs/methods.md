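# Methods

## The phasing model

haploclust phases a polyploid genome by agglomerative clustering of long
reads reduced to their base calls at known heterozygous SNP positions.
The premise: two reads drawn from the same haplotype agree at almost all
heterozygous sites they share (disagreements are sequencing errors),
while reads from different haplotypes disagree at a large fraction of
shared sites. Iteratively merging the most similar reads and groups of
reads therefore reconstructs the haplotypes — without ever being told,
or trying to infer, how many there are. The number of clusters per
region is an output, not an input.

Assumptions inherited from this design:

- heterozygous sites are known in advance (from short-read variant
  calling); SNPs the caller missed cannot be phased, though they remain
  recoverable from the per-haplotig read sets;
- reads are aligned to a single reference, so phasing quality degrades
  with reference divergence and in repetitive regions;
- only SNPs are phased — insertions and deletions are excluded by
  design, and no error correction is ever applied to the reads, because
  correction tends to flatten or mis-assign genuine heterozygosity.

## Pipeline stages

### Read reduction (`variantio`)

Alignments are filtered to primary and supplementary records (secondary
and unmapped excluded, i.e. `samtools view -F 260` semantics). Each
alignment becomes a *reduced read*: its aligned base at every
heterozygous site it covers, 1-based, strictly increasing, A/C/G/T only
(ambiguity codes are treated as no-call; deleted or clipped sites are
simply absent). Supplementary alignments and primaries carrying an SA
tag become split-read *segments* sharing an id prefix. Reads whose call
sets are subsets of another read's are removed (one representative
survives among exact duplicates); they add no linkage information and
only cost time.

A plain five-column TSV (`read_id`, `chromosome`, `pos:base,...`,
split flag, truth label or `.`) round-trips reduced reads exactly, so
the entire engine is testable without any alignment file.

### Context coverage (`context`)

Every call is weighted by how often the whole dataset saw that call in
the same local context: the call's two nearest upstream and two nearest
downstream heterozygous calls *within the same read*, bases included,
with explicit edge markers where fewer flanks exist. A sequencing error
that converts a well-supported SNP into a base well-supported on another
haplotype still sits in a context the other haplotype's reads do not
share, so it keeps weight ≈ 1 while genuine calls carry the local read
support (≈ coverage). The table is built once over all reduced reads —
split segments included — and weights are never updated during
clustering.

### Clustering engine (`phaser`)

All reads start as singleton clusters. Each step:

1. **Scoring.** For every candidate pair, similarity
   `S = N_shared_variants / N_shared_positions` over the positions both
   consensus sequences cover (a tied consensus position matches if the
   base sets intersect). A pair is a candidate only if it shares at
   least `min_overlap_count` (10) positions, has `S ≥ min_similarity`
   (0.01), and — unless it shares more than `overlap_ignore_threshold`
   (100) positions — the shared count is at least `min_overlap_fraction`
   (O = 0.1) of the positions covered by the smaller sequence, smaller
   meaning fewer covered het positions, not shorter.
2. **Selection.** Highest S wins; ties go to the larger shared count;
   exact ties are broken uniformly at random from a seeded generator
   (the only place randomness enters).
3. **Identity gate.** See below. A pair failing the gate is forbidden
   permanently (both endpoints are immutable until merged).
4. **Consensus.** The merged cluster's tallies are the per-position,
   per-base sums of context-coverage vote weights; the consensus is the
   argmax set (ties keep every tied base).

Reads from different chromosomes can never merge. The loop ends when no
allowed pair remains; clusters with fewer than `min_cluster_reads`
(L, default 0) members are then dropped.

The engine caches pair scores and, after each merge, rescores only pairs
involving the new cluster. This is a pure optimization: a dedicated
test drives 200 random instances through an exhaustive oracle that
re-scores every pair from scratch each step and requires identical final
partitions. Internally, per chromosome, consensus sequences live in a
base-bitmask array over the chromosome's het-position index and tallies
in an integer position-by-base matrix, so scoring and identity checks
are a handful of vector operations; all tallies are exact integers, so
ties and thresholds are reproducible to the bit.

### Cluster identity maintenance

Merging must not be allowed to erase haplotype identity, or the greedy
loop would always end in one cluster per region. Over the *common
region* (positions covered by both clusters), a cluster's consensus
base *loses* the other cluster's votes wherever those votes back a
different base — counted even when the base remains consensus after the
merge; votes reinforcing the consensus (positive changes) count nothing.

Two normalizations are provided (`PhaseParams.identity_mode`):

- **`per_cluster` (default).** Each cluster's lost votes are divided by
  its own common-region votes, and the merge is vetoed when the
  *smaller* of the two changes exceeds `max_id_change` (ID = 0.05) —
  i.e. only when the merge perturbs *both* clusters. A handful of noisy
  reads cannot be kept out of a deep cluster (their arrival barely
  moves it), but two well-supported distinct haplotypes can never
  swallow each other. This is the default because it is the only
  reading that keeps clustering viable when the per-call error rate
  exceeds ID: under the summed rule a read with error rate e presents
  an identity change of ≈ e against any large cluster, and at e = 10%
  (raw nanopore scale) with ID = 5% no typical read could ever join a
  cluster — the dataset would shatter into hundreds of fragments, which
  is not how this family of methods behaves on real nanopore data.
- **`summed`.** Pooled lost votes over pooled common-region votes — the
  stricter, symmetric reading. Appropriate when per-call error is
  comfortably below ID.

A known consequence of the per-cluster gate, visible in real data too:
a small cluster of one haplotype *can* be absorbed by a much deeper
cluster of another (the deep side barely changes) — the chimeric-cluster
failure mode that the allele-frequency diagnostic exists to catch.

### Split-read stitching (`stitcher`)

Split reads mark structural variants; trusted blindly they create
chimeras, so only their most trustworthy calls are used. After a first
pass on ordinary reads, the SNPs at each cluster's edges (first and last
E covered positions) are collected; each split read — its
same-chromosome segments *rejoined into one read*, since only a joined
read can link SNPs on both sides of a breakpoint — is restricted to
those edge SNPs (segments keep the vote weights of their full-length
contexts; the table is not rebuilt), and the clustering is re-run with
the restricted reads included. Cross-chromosome merging remains
impossible, so stitching can only improve same-chromosome contiguity.

E defaults to `max(10, min_overlap_count, ceil(O × largest first-pass
cluster))`: a restricted read shares at most E positions with a block,
and once absorbed into one block it offers the other block exactly E
shared positions, so E must be at least O times the smaller block's
covered positions or the closure merge would always fail the overlap
rule. A fixed `--edge-size` can override this.

### Automated cleaning (`cleaner`)

Three ordered steps on the raw clusters:

1. **Discordance-gated merging.** A cluster's discordance is the
   fraction of member base calls disagreeing with its consensus (the
   summed minor allele frequencies); single-read clusters score 0.
   Overlapping same-chromosome pairs are merged lowest hypothetical
   merged discordance first, while that discordance stays below a
   threshold fixed before any merge. The default threshold is the
   call-weighted (pooled) mean discordance of the raw clusters — the
   dataset's noise floor, which a same-haplotype merge matches and a
   cross-haplotype merge clearly exceeds. The unweighted per-cluster
   mean is available (`threshold_mode="cluster_mean"`) but degenerates
   on uniformly noisy data: perfectly concordant midget clusters pull it
   below the noise floor and block every merge. Cleaning tallies are
   read counts (one vote per read), not context weights.
2. **Low-coverage filtering.** Clusters are dropped smallest-first
   while the cumulative removed coverage (summed member het-position
   counts) stays within `filter_fraction` (1%) of the total; at least
   one cluster always survives.
3. **Gap filling.** Per chromosome, each haplotig counts as 1X over the
   het positions in its span; the target multiplicity n is the rounded
   mean of this profile, *fixed before any split* (recomputing it after
   splits is self-amplifying). Every maximal deficit region — at least
   10 het positions **and** at least the median member-read length in
   bp, since a deficit too short to hold a read is span-placement
   raggedness, not a missing haplotype — is filled by splitting the
   region's most-covered cluster's reads there into two balanced seeded
   halves, presuming the gap is a haplotype present in more than one
   genomic copy. Donors with fewer than two reads in the region leave
   it unfilled.

Steps 1 and 3 conserve the read multiset; step 2 removes reads only
with their whole cluster. Gap filling can be disabled for very
fragmented inputs, where splitting donors manufactures haplotigs faster
than it recovers duplicated haplotypes.

### Evaluation (`evaluate`)

With truth, each haplotig is assigned to the haplotype maximizing its
matching consensus calls (ties: match fraction, then name). Per
truth-haplotype SNP: **TP** if some assigned haplotig calls the correct
base; **FP** per haplotig consensus position whose base set misses the
assigned haplotype's base (a tied position counts once, and is erroneous
only if no tied base matches); **FN** for truth SNPs covered by no
assigned haplotig of their haplotype. All three rates share the
denominator TP+FP+FN, so accuracy + error + missing = 100 exactly.
Contiguity is reported as haplotigs per haplotype (count/ploidy,
genome-wide and per chromosome) and L90 — the minimal number of assigned
haplotigs covering ≥ 90% of a haplotype's truth SNPs on a chromosome,
computed by greedy maximal-marginal-cover (exact minimal set cover is
NP-hard; the greedy answer is 1 whenever 1 is attainable, which is the
case the number is read for). Switch-error rate is deliberately not
reported: with blocks this accurate, raw proportions of
correct/incorrect/missing calls are the more direct statement.

Without truth: windowed (default 5 kb) mean read depth per haplotig,
optionally restricted to the largest haplotigs holding 90% of coverage;
and the in-cluster allele-frequency distribution at positions with ≥ 20
member reads, flagging clusters where ≥ 10% of qualifying positions have
a major-allele frequency ≤ 0.7 as candidate chimeras (a pure cluster at
10% read error leaves < 2% of positions below that line; a balanced
chimera puts every divergent position near 0.5).

## The simulator and what it does not emulate

`simulate` builds virtual polyploids directly in reduced-read space:
k haplotypes over named chromosomes; heterozygous sites sampled
uniformly at rate h; at each site two distinct bases split the
haplotypes either into two random groups (probability `p_shared`, 0.5)
or private-vs-rest — shared alleles are what makes polyploid phasing
hard, and virtual polyploids built from related strains have many.
Reads: truncated-normal lengths, starts uniform over the extended
interval so coverage is uniform to the chromosome ends, per-call
substitution errors at rate e, optional split reads emitted as two
displaced same-chromosome segments, and a hidden source-haplotype label
used only by evaluation. `degrade_variant_calls` removes a seeded
fraction of sites to emulate variant-caller misses. Everything is
deterministic given the config seed.

Defaults are the hardest routinely reported benchmark regime: k = 4,
h = 0.5%, 20X per haplotype, 20 kb ± 8 kb reads, e = 0.10 (raw nanopore
scale), two 200 kb chromosomes — sized so a full study (simulate, phase,
clean, evaluate, five replicate seeds) runs in about a minute on one
core.

Not emulated: clustered heterozygosity (real het sites come in runs and
deserts), coverage unevenness and mapping dropout, reference bias,
repeat-induced mismapping, homopolymer-biased nanopore error profiles,
and INDELs. Passing tests therefore demonstrate the engine's behavior
under its own model — correct clustering, gating, cleaning, stitching
and scoring — not performance on any particular real genome, where
fragmentation is typically higher and accuracy lower than the synthetic
numbers.

## Numerical choices

- Integer vote tallies throughout; similarity and identity changes are
  ratios of exact integers, so cross-implementation comparisons (array
  engine vs dict oracle) are bitwise.
- All randomness flows from named seeds; per-chromosome generators are
  seeded as `f"{seed}:{chromosome}"` so chromosome results do not depend
  on which other chromosomes are processed.
- Deterministic orderings everywhere (reads by first position and id,
  clusters by span and id, TSV rows sorted), so reruns are
  byte-comparable; manifests store relative paths.
- Degenerate inputs: empty read sets phase to empty output; an empty
  haplotig set evaluates to accuracy 0 / missing 100; single-read
  clusters have discordance 0; a single cluster survives any filter.

## Problem sizes in the test suite

Unit fixtures use a few reads over tens of positions. The end-to-end
suites use one-or-two-chromosome genomes of 100–200 kb — about
350–1700 reads and 500–2000 het sites per study, five seeds for the
noisy study — chosen so the full pytest run completes in well under a
minute of compute per suite while every rate estimate has a few
thousand calls behind it.

## Known limitations

- The identity gate's per-cluster default can absorb a shallow cluster
  of one haplotype into a deep cluster of another; inspect flagged
  allele-frequency distributions before trusting a low haplotig count.
- Gap filling presumes deficits are duplicated haplotypes; on data
  whose raw result is highly fragmented, disable it.
- L90 is a greedy upper bound on the true minimal cover (exact at 1).
- The simulator's uniformity makes synthetic accuracy an upper bound on
  real-data accuracy at the same nominal parameters.
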
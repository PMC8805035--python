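# Methods

## Problem and model

MtrCAB is a transmembrane electron conduit: a periplasmic decaheme
cytochrome (MtrA) threaded through an outer-membrane beta-barrel (MtrB),
passing electrons to an extracellular decaheme cytochrome (MtrC).  In
genomes the three genes occur as a compact cluster, frequently with
accessory mtrC/omcA-family paralogs and with group-specific electron-carrier
genes (cymA, pdsA, mtoC/mtoD, novel cytochromes) nearby.  The pipeline
operationalizes a survey of such clusters as five stages: curation of
homology hits, proximity-based cluster calling, concatenated-protein
distance phylogenetics, anchor-based locus comparison for horizontal-
transfer evidence, and presence/absence census statistics.

## Cluster calling

**Proximity rule.**  Two coding sequences belong to one cluster when they
lie within `proximity_bp` = 3,500 bp of each other on a replicon, and
cluster membership is the transitive closure of that relation.  Because the
inter-feature boundary gap is monotone in coordinate rank, single-linkage
sweeping of the hit-bearing genes in coordinate order computes exactly the
connected components of the pairwise proximity graph (property-tested
against a brute-force union-find oracle).

**Gap convention.**  "Within 3,500 bp" is ambiguous between a boundary gap
and a start-to-start distance.  The default is the boundary gap —
`max(0, start(downstream) − end(upstream) − 1)`, 0 for overlapping or
book-ended genes — because it is robust to gene length.  The alternative is
exposed as `CurationParams.gap_mode = "start_start"`.

**Completeness and paralog splitting.**  A cluster is retained only if its
core carries all of {mtrA, mtrB, mtrC}, in any genomic order.  Candidates
with duplicated core families (tandem whole-cluster duplications) are split
greedily left-to-right into maximal complete cores; this is deterministic
and order-stable, at the cost of one arbitrary choice when a stray mtrC sits
exactly between two cores (it is attached to the right-hand core as an
accessory).  Leftover mtrA/mtrB fragments are dropped as incomplete.

**Contig-majority filter.**  For metagenome-assembled genomes only, a
cluster holding ≥ `contig_majority_num` = 3 genes on a contig of ≤
`contig_majority_den` = 11 total genes is removed — a short contig dominated
by the cluster gives no taxonomic confidence.  Isolate assemblies are never
filtered.

**MtrDEF labelling.**  In the Shewanellaceae/Ferrimonadaceae (the
configured "Group-1" families) a complete cluster whose genes read A-B-C in
ascending coordinates is labelled DEF, the paralogous cluster delineated in
*S. oneidensis* MR-1; C-A-B is CAB.  Outside those families the label is
always CAB and the raw order string is retained as metadata — A-B-C order
alone (as in some Ectothiorhodospiraceae) does not imply the paralog.
Strand is recorded but ignored throughout: the cluster definition is
order-free and the source delineation is by coordinate order.

**Accessory chaining.**  mtrC/omcA-family hits with E-value ≤
`accessory_evalue_max` = 1e-10 (and no disqualifying extra domain) are
chained onto a complete cluster whenever they fall within the proximity
threshold of any current member, repeated to a fixpoint, so a run
core–omcA–undA joins entirely.  The same 3,500-bp threshold is reused for
"next to"; strict adjacency would be stricter than the calling rule itself
and is not what locus diagrams of real clusters show.  Duplicate protein
ids collapse to their leftmost feature.

**Curation filters.**  The domain filter removes the *protein* (hence all
its hits) when any of its conserved-domain calls falls outside the query
family's allowed set; proteins without domain calls pass.  The allowed set
is a required configuration input (`DEFAULT_ALLOWED_DOMAINS` covers the
synthetic data; real runs must supply their own, since no canonical "Mtr
domain list" exists).  Species dedup keeps one genome per (genus, species)
chosen uniformly under a seeded RNG, independent of input order; "sp."
placeholder records are never grouped.  Genus rules handle sampling bias:
`drop_sp` (Shewanella, Vibrio) removes "sp." records outright,
`require_strain` (Aeromonas) keeps them only with a strain designation.

## Phylogenetics

Per-gene alignments (alignment computation itself is upstream of this
package) are concatenated in the fixed order mtrA‖mtrB‖mtrC into a
supermatrix with recorded partitions; clusters missing any gene are excluded
with a warning.  Pairwise distances are p-distances over columns where both
rows are non-gap, optionally Poisson-corrected (d = −ln(1 − p)); saturated
pairs (p ≥ 1) and pairs with no comparable columns are errors rather than
silently infinite.

The tree is Saitou–Nei neighbor joining with the standard Q-criterion.
Determinism: Q-ties are broken lexicographically on the (sorted) labels of
the joined nodes, with each internal node labelled by its smallest
descendant tip.  A negative branch length is clamped to zero and the deficit
transferred to the sibling branch, preserving the joined pair's path length.
NJ is exact on additive matrices (tested to 1e-9 on path lengths) and
matches scikit-bio's implementation topologically; scikit-bio is used only
as a cross-check oracle.  Full likelihood optimization and substitution-
model selection are a documented extension point, not implemented: at the
scales this package targets, the distance tree already supports every
claim the tests exercise, and the NJ tree is the standard starting point
for such optimization.

Bootstrap supports are computed by resampling supermatrix columns with
replacement (n replicates over all columns, seeded), rebuilding the NJ tree
per replicate, and mapping the percentage of replicates containing each
internal bipartition onto the point-estimate tree.  Majority-rule consensus
is the alternative summary; mapping onto the point estimate was chosen
because the point topology is the deliverable.  The point-estimate topology
is seed-independent.

Clade assignment is exemplar-supervised: each unlabeled leaf takes the
group (or mtrC subfamily) of its nearest reference leaf by patristic
distance; ties leave the leaf unassigned.  The seven-group cut of the
concatenated tree is a judgement call in the source analysis, so exemplars
are an explicit input rather than an automatic cut.  Monophyly of each
induced group is reported; the `monophyly_fraction` statistic (share of
rank labels whose leaf set forms one side of a bipartition of the unrooted
tree) quantifies gene-tree/taxonomy incongruence, the hallmark of HGT.

## Synteny and scars

Locus comparison is at gene granularity: nucleotide whole-genome alignment
adds nothing for scar evidence that is expressible as gene presence, order
and orientation, and gene-level anchoring keeps the analysis free of
external aligners.  The bearer window is the cluster ± k = 10 flank genes
(matching the neighborhood catalog width, which covers every accessory
operon the forge plants).  Flank families are matched to the comparator
replicon sharing the most families by longest-common-subsequence, order
preserving; bearer genes left unmatched are retried against the reversed
comparator, and only runs of ≥ 2 consecutive reversed matches count as a
flipped block (a single gene carries no orientation at gene granularity).

Scar calls, not mutually exclusive, on the comparator gap between the
innermost flank anchors: **insertion** when the gap holds ≤ 1 intervening
gene (slack for annotation noise; configurable) while the bearer holds the
cluster between the same anchors; **element_replacement** when the gap
carries a mobility-token gene (transposase, integrase, endonuclease,
recombinase); **inversion** when a flipped anchor block exists;
**tRNA_flanked** when the bearer cluster's immediate neighbours on both
sides are tRNA genes; **plain_absence** when no anchors exist at all.
These rules are an explicit operationalization of what is, in the source
analyses, expert visual inspection of alignments — reports should treat
them as such.

A passenger candidate is a non-core bearer-window family absent from the
comparator's anchored window; a genome-wide search sets a
`present_elsewhere` flag distinguishing a travelling gene from a family the
comparator carries natively elsewhere.

## Census

Prevalence counts one strain per species per genus ("sp." records count per
strain, subject to the genus rules above) and reports the fraction of a
genus' species with ≥ 1 retained cluster.  The component census reports,
per tree group, the fraction of member clusters whose neighborhood catalog
or accessory list carries each component token; denominators are group
sizes.  The Group-1 mtrC-subfamily census pools at species level (a species
carrying a subfamily in any of its clusters counts once, so duplicating a
cluster row never changes the statistic — property-tested); it also reports
per-cluster accessory-copy counts and the fraction of all clusters with ≥ 1
accessory mtrC.  Summary percentages round to the nearest integer; TSVs
keep exact numerator/denominator pairs.

## Synthetic data

The forge emulates the input formats end to end: GFF3 + protein FASTA per
genome, 12-column BLAST-tabular hit tables, domain-call and taxonomy TSVs.
Study conditions for the recovery benchmarks: 100 genomes of 20–40 genes
(intergenic gaps 50–400 bp, gene lengths 900–1,500 bp), one planted cluster
in ~40% of genomes with varied gene orders, accessory copies and flanks
(inter-gene gaps up to 3,400 bp, i.e. inside the threshold), a 30% decoy
rate (an mtr hit carrying an extra non-Mtr domain), and 20% MAG-style
genomes split into ≤ 11-gene contigs; the contig carrying a planted cluster
is given ≥ 12 genes so the truth set is exactly what an error-free caller
should return.  Protein sequences of non-simulated genes are random 120–400
aa strings — calling reads hit tables, never sequence content.

Alignments are simulated under a 20-state uniform-exchangeability
(Jukes–Cantor-style) replacement process: per branch of length b the
per-site change probability is (19/20)(1 − e^{−(20/19)·b·rate}), which the
simulator's tests check against the closed form and its saturation limit of
0.95.  A WAG-style empirical exchange matrix would add realism but not
change topology-recovery behavior at the tested scales.  Zero-length
branches copy sequences; negative lengths are an error.

What the forge does **not** emulate: realistic codon usage and GC content,
gene-length and intergenic distributions of real genomes, alignment error
(simulated alignments are true alignments), annotation noise (split/merged
genes), and homology-search noise beyond the planted decoys.  Passing the
planted-recovery tests therefore shows the machinery is correct under the
stated rules, not that the thresholds are optimal for any real survey.

## Numerical choices and problem sizes

All randomness flows through seeded `numpy.random.default_rng`
generators; dedup survivor choice, bootstrap resampling, the forge and the
simulators are deterministic given a seed, and outputs are byte-stable.
Tie-breaking is lexicographic on identifiers everywhere a choice is
arbitrary.  The benchmark sizes — ten 100-genome datasets for recovery,
fifty 8-leaf/10,000-site replicates for NJ recovery, one hundred scar pairs
— were chosen as the smallest sizes at which the statistics are stable;
each benchmark runs in seconds.

## Packaged fixtures

The survey behind this pipeline drew on a mid-2020 NCBI snapshot that
cannot be redistributed.  The tables under `src/mtrscan/data/` are
synthetic stand-ins constructed once so that their **aggregates** match the
published summary statistics (Group-1 subfamily carriage 49/64/30/11/34%
for MtrF/OmcA/UndA/MtrG/MtrH over 47 species; 78 of 177 clusters with ≥ 1
accessory mtrC, i.e. 44%; 40 of 45 Shewanella species bearing clusters).
Row-level content — species names, per-row subfamily combinations — is
invented; filenames carry a `_synthetic` suffix.  Census code computes the
statistics by counting these rows; it does not store the percentages.

## Known limitations

* No maximum-likelihood tree optimization or substitution-model selection;
  NJ with Poisson correction is the deliverable.
* Gene-level anchoring cannot see sub-gene breakpoints or intergenic
  scars; inversions are detected only when ≥ 2 anchored genes flip.
* The greedy left-to-right core split can misassign an accessory mtrC that
  sits exactly between two tandem complete cores.
* Taxonomy is an input table; no name reconciliation or lineage lookup.
* The scar rule set is a fixed operationalization of what is inherently a
  judgement call; its thresholds (adjacency slack 1, flank k = 10) are
  configurable but not fitted.
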
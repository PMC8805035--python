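# mtrscan

Comparative-genomics pipeline for surveying **MtrCAB-like multi-gene
clusters** — the three-protein outer-membrane conduit (periplasmic decaheme
cytochrome MtrA, beta-barrel MtrB, extracellular decaheme cytochrome MtrC)
that lets Gram-negative bacteria exchange electrons with minerals and
electrodes outside the cell (extracellular electron transfer, EET).

The package is for microbial genomics researchers who want to detect such
clusters in annotated genomes, curate the hits, and ask how the system
spread: vertically within a lineage, or horizontally as a mobile element.
It provides:

* **Cluster calling by genomic proximity** — homology hits to mtrA/mtrB/mtrC
  are grouped by single-linkage transitive closure over the rule *"two
  coding sequences within 3,500 bp belong to one cluster"*, then filtered
  for core completeness ({A, B, C} in any order), metagenome contig-majority
  artefacts (a cluster of ≥ 3 genes on a MAG contig of ≤ 11 genes is
  discarded), and per-genus sampling-bias rules. The *Shewanella*-group
  paralog is labelled **MtrDEF** when the genomic gene order reads A-B-C
  instead of the canonical C-A-B, and accessory mtrC/omcA-family genes
  (E ≤ 1e-10) are chained onto the core to a fixpoint.
* **Concatenated distance phylogenetics** — per-gene alignments are
  concatenated into a supermatrix; pairwise Poisson-corrected distances
  d = −ln(1 − p) feed a Saitou–Nei neighbor-joining tree with nonparametric
  bootstrap supports; clades (the seven diversification groups, and the
  mtrC subfamilies MtrC/MtrF/OmcA/UndA/MtrG/MtrH) are assigned by nearest
  patristic distance to exemplar leaves; gene-tree/taxonomy incongruence is
  quantified as a monophyly fraction.
* **HGT scar detection** — a cluster-bearing locus is anchored onto a
  cluster-lacking relative by order-preserving longest-common-subsequence
  matching of flank gene families; the comparator gap is classified as an
  insertion site (flanks adjacent), mobile-element replacement (transposase/
  integrase/endonuclease/recombinase in the gap), inversion (reversed anchor
  block), or tandem-tRNA flanking, and co-travelling "passenger" genes are
  called.
* **A synthetic-genome forge** — seeded generation of annotated genomes,
  BLAST-style hit tables, domain calls, decoys, MAG-style short contigs,
  scar genome pairs and alignments simulated on a known tree, each with a
  machine-readable truth set, so the whole pipeline is testable without any
  downloads.

## Worked example

```bash
python analysis/01_forge_dataset.py --seed 0     # forge 100 genomes
python analysis/02_call_clusters.py --seed 0     # curate + call clusters
python analysis/03_build_tree.py    --seed 0     # supermatrix NJ + bootstrap
python analysis/04_scar_survey.py   --seed 0     # classify 100 scar pairs
python analysis/05_census.py                     # census tables
```

Output printed by the drivers (seed 0):

```
Forged 100 genomes (23 MAG-style), 25 planted clusters, 37 decoy proteins, 124 hits -> results/dataset
Called 25 clusters against 25 planted: sensitivity 1.000, FDR 0.000; 37 decoy proteins removed by the domain filter.
Supermatrix: 28 clusters x 900 columns (300 sites per gene).
Clade edges of the generating tree recovered: 7/7 (median bootstrap support 100%).
Group assignment: 28/28 leaves correct from 7 exemplars; all groups monophyletic: True.
Monophyly fraction: 1.00 for clade-sorted taxonomy vs 0.00 for scrambled taxonomy (low = HGT-like incongruence).
Classified 100 pairs (25 per type):
  insertion            recovered 25/25; cross-type calls: none
  element_replacement  recovered 25/25; cross-type calls: none
  inversion            recovered 25/25; cross-type calls: none
  tRNA_flanked         recovered 25/25; cross-type calls: none
Fixture census: MtrC 100%, MtrF 49%, OmcA 64%, UndA 30%, MtrG 11%, MtrH 34%; accessory mtrC in 44% of clusters; Shewanella 40/45 bearer species.
```

Reading these numbers: every planted cluster was recovered with no false
calls (the decoy proteins, which carry a disqualifying extra domain, were
all removed before calling); the NJ tree resolved all seven planted clades
with full bootstrap support and the exemplar-supervised group assignment
labelled every leaf correctly; each of the four forged HGT scar types was
classified exactly; and the packaged census tables give the Group-1 mtrC
subfamily carriage percentages and the fraction of clusters with accessory
mtrC copies.

The same stages are available as a single config-driven run
(`mtrscan.pipeline.run_pipeline`, TOML config; see
`tests/test_pipeline.py` for a minimal config).

## Layout

```
src/mtrscan/       library: model, io, forge, curation, clusters, phylo,
                   synteny, census, fixtures, pipeline, viz, benchmarks
analysis/          numbered narrative drivers (write under results/)
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance harness
docs/methods.md    models, parameters, numerical choices, limitations
```
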
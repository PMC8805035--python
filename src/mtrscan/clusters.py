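"""Proximity-based mtr gene-cluster calling.

Two coding sequences within ``proximity_bp`` (default 3,500 bp) of each
other on the same replicon belong to the same cluster; membership is the
transitive closure of that relation (single linkage over the hit-bearing
genes in coordinate order).  Candidate clusters are then filtered for core
completeness ({mtrA, mtrB, mtrC} all present, any order), metagenome
contig-majority artefacts are removed, the Shewanella-group MtrDEF paralog
is labelled by its genomic gene order, accessory mtrC/omcA-family genes are
chained on, and the flanking gene neighborhood is catalogued.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional

from .model import (
    FAMILY_LETTER,
    CurationParams,
    GeneFeature,
    GenomeAnnotation,
    MtrCluster,
    ProteinHit,
    TaxonRecord,
)

#: Families whose Group-1 members get the D-E-F paralog labelling rule.
GROUP1_FAMILIES = frozenset({"Shewanellaceae", "Ferrimonadaceae"})


def gene_gap(f1: GeneFeature, f2: GeneFeature, mode: str = "boundary") -> int:
    """Base-pair distance between two features on one replicon.

    ``boundary`` mode returns the number of bases strictly between the two
    features: ``max(0, start(downstream) - end(upstream) - 1)``; overlapping
    or book-ended features score 0.  ``start_start`` returns the absolute
    start-coordinate difference.  Symmetric in both modes.
    """
    if f1.replicon_id != f2.replicon_id:
        raise ValueError(
            f"features on different replicons: {f1.replicon_id} vs {f2.replicon_id}"
        )
    if mode == "start_start":
        return abs(f1.start - f2.start)
    a, b = (f1, f2) if f1.start <= f2.start else (f2, f1)
    return max(0, b.start - a.end - 1)


def _within(f1: GeneFeature, f2: GeneFeature, params: CurationParams) -> bool:
    return gene_gap(f1, f2, params.gap_mode) <= params.proximity_bp


def call_candidate_clusters(
    features: Iterable[GeneFeature],
    hits: Iterable[ProteinHit],
    params: CurationParams,
) -> list[MtrCluster]:
    """Group hit-bearing features into candidate clusters by proximity.

    Hits must already be domain-filtered.  Returns one candidate per
    connected component of the proximity graph on each replicon, with core
    members in coordinate order.  Hit proteins that resolve to no feature
    are ignored (callers may cross-check ids themselves).  The result is
    invariant to the input ordering of both features and hits.
    """
    fam_by_protein: dict[str, str] = {}
    for h in hits:
        fam_by_protein[h.protein_id] = h.query_family

    by_replicon: dict[tuple[str, str], list[GeneFeature]] = defaultdict(list)
    for f in features:
        if f.protein_id is not None and f.protein_id in fam_by_protein:
            by_replicon[(f.genome_id, f.replicon_id)].append(f)

    clusters: list[MtrCluster] = []
    for (gid, rid), feats in sorted(by_replicon.items()):
        feats.sort(key=lambda f: (f.start, f.end, f.feature_id))
        # single linkage in coordinate order == transitive closure of the
        # pairwise proximity relation (gap is monotone in coordinate rank)
        runs: list[list[GeneFeature]] = [[feats[0]]]
        for f in feats[1:]:
            if _within(runs[-1][-1], f, params):
                runs[-1].append(f)
            else:
                runs.append([f])
        for run in runs:
            core = [(f, FAMILY_LETTER[fam_by_protein[f.protein_id]]) for f in run]
            c = MtrCluster(
                cluster_id=f"{gid}:{rid}:{run[0].start}",
                genome_id=gid,
                replicon_id=rid,
                core=core,
                order_string="-".join(l for _, l in core),
            )
            clusters.append(c)
    return clusters


def filter_complete(
    clusters: Iterable[MtrCluster],
) -> tuple[list[MtrCluster], list[MtrCluster]]:
    """Keep clusters whose core carries all of {A, B, C}, in any order.

    Candidates with duplicated core families (e.g. tandem duplicated whole
    clusters) are split greedily left-to-right into maximal complete cores;
    leftover mtrC homologs are demoted to accessory members of the last
    complete core, leftover A/B fragments are dropped as incomplete.
    """
    kept: list[MtrCluster] = []
    removed: list[MtrCluster] = []
    for c in clusters:
        letters = [fam for _, fam in c.core]
        if sorted(set(letters)) != ["A", "B", "C"]:
            c.flags.add("incomplete")
            removed.append(c)
            continue
        if len(letters) == 3:
            kept.append(c)
            continue
        # greedy left-to-right split into complete cores
        parts: list[list[tuple[GeneFeature, str]]] = []
        current: list[tuple[GeneFeature, str]] = []
        need = {"A", "B", "C"}
        leftover_c: list[GeneFeature] = []
        leftover_other: list[tuple[GeneFeature, str]] = []
        for f, fam in c.core:
            if fam in need:
                current.append((f, fam))
                need.discard(fam)
                if not need:
                    parts.append(current)
                    current = []
                    need = {"A", "B", "C"}
            elif fam == "C":
                leftover_c.append(f)
            else:
                leftover_other.append((f, fam))
        # whatever is left in `current` never completed
        for f, fam in current:
            if fam == "C":
                leftover_c.append(f)
            else:
                leftover_other.append((f, fam))
        if not parts:
            c.flags.add("incomplete")
            removed.append(c)
            continue
        for i, part in enumerate(parts):
            sub = MtrCluster(
                cluster_id=f"{c.cluster_id}.{i}" if len(parts) > 1 else c.cluster_id,
                genome_id=c.genome_id,
                replicon_id=c.replicon_id,
                core=part,
                order_string="-".join(l for _, l in part),
                flags=set(c.flags),
            )
            kept.append(sub)
        if leftover_c:
            target = kept[-1]
            target.accessory_mtrC.extend(sorted(leftover_c, key=lambda f: f.start))
    return kept, removed


def filter_contig_majority(
    clusters: Iterable[MtrCluster],
    annotations: dict[str, GenomeAnnotation],
    params: CurationParams,
) -> tuple[list[MtrCluster], list[MtrCluster]]:
    """Remove MAG clusters that make up the majority of a short contig.

    A cluster on a metagenome-assembled genome is removed iff it holds at
    least ``contig_majority_num`` genes (default 3) on a contig with at most
    ``contig_majority_den`` genes in total (default 11).  Isolate genomes
    are never filtered.
    """
    kept, removed = [], []
    for c in clusters:
        ann = annotations[c.genome_id]
        if ann.taxon.assembly_type != "MAG":
            kept.append(c)
            continue
        total = len(ann.replicons.get(c.replicon_id, []))
        n_cluster = len(c.members)
        if n_cluster >= params.contig_majority_num and total <= params.contig_majority_den:
            c.flags.add("contig_majority_removed")
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


def label_cluster_order(
    cluster: MtrCluster,
    taxon: TaxonRecord,
    group1_families: frozenset[str] = GROUP1_FAMILIES,
) -> MtrCluster:
    """Label a complete cluster CAB or DEF from its genomic gene order.

    In the Shewanella/Ferrimonas group the paralogous cluster encodes its
    genes in the order mtrA-mtrB-mtrC (reading coordinate-ascending) and is
    named MtrDEF after the S. oneidensis MR-1 delineation; the canonical
    C-A-B order is MtrCAB.  Outside that group all clusters are labelled
    CAB, with the raw order string retained as metadata.
    """
    if not cluster.is_complete():
        raise ValueError(f"cannot label incomplete cluster {cluster.cluster_id}")
    if taxon.family in group1_families and cluster.order_string == "A-B-C":
        cluster.label = "DEF"
    else:
        cluster.label = "CAB"
    return cluster


def attach_accessory_mtrC(
    cluster: MtrCluster,
    mtrC_hits: Iterable[ProteinHit],
    features: Iterable[GeneFeature],
    params: CurationParams,
) -> MtrCluster:
    """Chain accessory mtrC/omcA-family genes onto a complete cluster.

    A candidate must hit the mtrC family at E-value <= the accessory cutoff
    (default 1e-10, domain screening assumed done upstream) and lie within
    the proximity threshold of a current cluster member; chaining repeats to
    fixpoint so a run core--omcA--undA joins entirely.  Duplicate protein
    ids collapse to their first (leftmost) feature.
    """
    core_ids = {f.feature_id for f, _ in cluster.core}
    eligible: dict[str, GeneFeature] = {}
    ok_proteins = {
        h.protein_id
        for h in mtrC_hits
        if h.query_family == "mtrC" and h.evalue <= params.accessory_evalue_max
    }
    for f in sorted(features, key=lambda f: (f.start, f.feature_id)):
        if (
            f.replicon_id == cluster.replicon_id
            and f.genome_id == cluster.genome_id
            and f.protein_id in ok_proteins
            and f.feature_id not in core_ids
            and f.protein_id not in eligible
        ):
            eligible[f.protein_id] = f

    attached: list[GeneFeature] = list(cluster.accessory_mtrC)
    attached_ids = {f.feature_id for f in attached}
    changed = True
    while changed:
        changed = False
        members = [f for f, _ in cluster.core] + attached
        for f in eligible.values():
            if f.feature_id in attached_ids:
                continue
            if any(_within(f, m, params) for m in members):
                attached.append(f)
                attached_ids.add(f.feature_id)
                changed = True
    cluster.accessory_mtrC = sorted(attached, key=lambda f: f.start)
    return cluster


def catalog_neighborhood(
    cluster: MtrCluster,
    annotation: GenomeAnnotation,
    n_genes: Optional[int] = None,
    params: Optional[CurationParams] = None,
) -> MtrCluster:
    """Record the ``n_genes`` nearest genes on each side of the cluster.

    Offsets are signed gene counts: -1 is the nearest upstream gene, +1 the
    nearest downstream.  Cluster members themselves are excluded; a cluster
    at a contig edge simply gets a one-sided catalog.
    """
    if n_genes is None:
        n_genes = (params or CurationParams()).neighborhood_genes
    feats = annotation.replicons.get(cluster.replicon_id, [])
    member_ids = {f.feature_id for f in cluster.members}
    lo, hi = cluster.span
    upstream = [f for f in feats if f.feature_id not in member_ids and f.end < lo]
    downstream = [f for f in feats if f.feature_id not in member_ids and f.start > hi]
    neighborhood: list[tuple[GeneFeature, int]] = []
    for i, f in enumerate(reversed(upstream[-n_genes:] if n_genes else [])):
        neighborhood.append((f, -(i + 1)))
    for i, f in enumerate(downstream[:n_genes] if n_genes else []):
        neighborhood.append((f, i + 1))
    neighborhood.sort(key=lambda pair: pair[1])
    cluster.neighborhood = neighborhood
    return cluster


def call_clusters(
    annotations: dict[str, GenomeAnnotation],
    hits: Iterable[ProteinHit],
    params: CurationParams,
    taxa: Optional[dict[str, TaxonRecord]] = None,
) -> tuple[list[MtrCluster], dict[str, list[MtrCluster]]]:
    """Full calling stage: candidates -> completeness -> contig-majority ->
    labels -> accessory chaining -> neighborhoods.

    Returns the kept clusters and a dict of removal audit lists.
    """
    hits = list(hits)
    all_features = [f for ann in annotations.values() for f in ann.all_features()]
    candidates = call_candidate_clusters(all_features, hits, params)
    complete, incomplete = filter_complete(candidates)
    kept, majority_removed = filter_contig_majority(complete, annotations, params)
    for c in kept:
        taxon = (taxa or {}).get(c.genome_id) or annotations[c.genome_id].taxon
        label_cluster_order(c, taxon)
        genome_feats = annotations[c.genome_id].all_features()
        attach_accessory_mtrC(c, hits, genome_feats, params)
        catalog_neighborhood(c, annotations[c.genome_id], params.neighborhood_genes)
    kept.sort(key=lambda c: c.cluster_id)
    return kept, {"incomplete": incomplete, "contig_majority": majority_removed}
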
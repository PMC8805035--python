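"""Anchor-based locus comparison for HGT scar classification.

A cluster-bearing locus (the cluster ± k flanking genes) is compared
against a cluster-lacking relative at gene granularity: flank gene
families are matched to comparator features by longest-common-subsequence
anchoring (order-preserving; a second pass against the reversed comparator
catches inverted blocks).  The comparator gap between the innermost flank
anchors is then inspected for scar evidence — adjacency (insertion site),
mobility genes (element replacement), flipped anchors (inversion) — and
tandem tRNA flanking of the bearer cluster is recorded.  Non-core bearer
families missing from the comparator's anchored window are candidate
passenger genes; a genome-wide search distinguishes true passengers from
natively present families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import MOBILITY_TOKENS, GeneFeature, GenomeAnnotation, MtrCluster

CORE_PRODUCTS = frozenset({"mtrA_like", "mtrB_like", "mtrC_like"})


@dataclass
class Anchor:
    bearer_feature: GeneFeature
    comparator_feature: GeneFeature
    orientation: str  # "same" | "flipped"


@dataclass
class SyntenyComparison:
    bearer_genome: str
    cluster_id: str
    comparator_genome: str
    anchors: list[Anchor] = field(default_factory=list)
    gap_content: list[GeneFeature] = field(default_factory=list)
    scar_calls: set[str] = field(default_factory=set)
    passengers: list[tuple[str, bool]] = field(default_factory=list)


def _family(f: GeneFeature) -> str:
    return f.product_label


def _lcs_pairs(a: list[str], b: list[str]) -> list[tuple[int, int]]:
    """Index pairs of one longest common subsequence of a and b."""
    n, m = len(a), len(b)
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                L[i][j] = 1 + L[i + 1][j + 1]
            else:
                L[i][j] = max(L[i + 1][j], L[i][j + 1])
    pairs = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j]:
            pairs.append((i, j))
            i += 1
            j += 1
        elif L[i + 1][j] >= L[i][j + 1]:
            i += 1
        else:
            j += 1
    return pairs


def bearer_window(
    cluster: MtrCluster, annotation: GenomeAnnotation, k: int = 10
) -> list[GeneFeature]:
    """The cluster plus up to k flanking genes on each side, in order."""
    feats = annotation.replicons[cluster.replicon_id]
    member_ids = {f.feature_id for f in cluster.members}
    lo, hi = cluster.span
    upstream = [f for f in feats if f.feature_id not in member_ids and f.end < lo]
    downstream = [f for f in feats if f.feature_id not in member_ids and f.start > hi]
    inside = [f for f in feats if f.feature_id in member_ids or (lo <= f.start <= hi)]
    return (upstream[-k:] if k else []) + inside + (downstream[:k] if k else [])


def anchor_neighborhoods(
    window: list[GeneFeature],
    comparator: GenomeAnnotation,
    k: int = 10,
    cluster: Optional[MtrCluster] = None,
) -> SyntenyComparison:
    """Anchor the bearer window's flank families onto a comparator genome.

    Greedy LCS on family labels, order-preserving; bearer flank genes left
    unmatched are retried against the reversed comparator and recorded as
    ``flipped`` anchors.  Core mtr genes are never anchored.  With no
    anchors on either flank the result is empty (downstream classification
    calls plain_absence).
    """
    member_ids = {f.feature_id for f in cluster.members} if cluster else set()
    flank = [
        f for f in window
        if f.feature_id not in member_ids and _family(f) not in CORE_PRODUCTS
    ]

    comparison = SyntenyComparison(
        bearer_genome=window[0].genome_id if window else "",
        cluster_id=cluster.cluster_id if cluster else "",
        comparator_genome=comparator.genome_id,
    )
    if not flank:
        return comparison

    # compare against the comparator replicon sharing the most families
    flank_fams = [_family(f) for f in flank]
    best_rid, best_shared = None, -1
    for rid, feats in comparator.replicons.items():
        shared = len(set(flank_fams) & {_family(f) for f in feats})
        if shared > best_shared:
            best_rid, best_shared = rid, shared
    comp_feats = comparator.replicons.get(best_rid, [])
    comp_fams = [_family(f) for f in comp_feats]

    pairs = _lcs_pairs(flank_fams, comp_fams)
    matched_bearer = {i for i, _ in pairs}
    matched_comp = {j for _, j in pairs}
    for i, j in pairs:
        comparison.anchors.append(Anchor(flank[i], comp_feats[j], "same"))

    # second pass: unmatched bearer flank genes against the reversed comparator
    rest_bearer = [i for i in range(len(flank)) if i not in matched_bearer]
    rest_comp = [j for j in range(len(comp_feats) - 1, -1, -1) if j not in matched_comp]
    rev_pairs = _lcs_pairs(
        [flank_fams[i] for i in rest_bearer], [comp_fams[j] for j in rest_comp]
    )
    # a lone reversed match carries no orientation at gene granularity;
    # only runs of >= 2 consecutive matches count as an inverted block
    runs: list[list[tuple[int, int]]] = []
    for bi, cj in rev_pairs:
        if runs and bi == runs[-1][-1][0] + 1 and cj == runs[-1][-1][1] + 1:
            runs[-1].append((bi, cj))
        else:
            runs.append([(bi, cj)])
    for run in runs:
        if len(run) < 2:
            continue
        for bi, cj in run:
            comparison.anchors.append(
                Anchor(flank[rest_bearer[bi]], comp_feats[rest_comp[cj]], "flipped")
            )
    comparison.anchors.sort(key=lambda a: a.bearer_feature.start)

    # gap content: comparator genes strictly between the innermost anchors
    # flanking the cluster position on the bearer
    if cluster is not None and comparison.anchors:
        lo, hi = cluster.span
        left_anchors = [a for a in comparison.anchors if a.bearer_feature.end < lo]
        right_anchors = [a for a in comparison.anchors if a.bearer_feature.start > hi]
        if left_anchors and right_anchors:
            left_inner = max(left_anchors, key=lambda a: a.bearer_feature.start)
            right_inner = min(right_anchors, key=lambda a: a.bearer_feature.start)
            ci = sorted(
                (
                    comp_feats.index(left_inner.comparator_feature),
                    comp_feats.index(right_inner.comparator_feature),
                )
            )
            comparison.gap_content = comp_feats[ci[0] + 1 : ci[1]]
    return comparison


def classify_scar(
    comp: SyntenyComparison,
    cluster: MtrCluster,
    bearer: GenomeAnnotation,
    mobility_tokens: frozenset[str] = MOBILITY_TOKENS,
    adjacency_slack: int = 1,
) -> set[str]:
    """Classify HGT scar evidence; calls are not mutually exclusive.

    insertion: innermost flank anchors are adjacent (<= ``adjacency_slack``
    intervening comparator genes) while the bearer holds the cluster
    between them.  element_replacement: the comparator gap carries >= 1
    mobility-token gene.  inversion: >= 1 flipped anchor.  tRNA_flanked:
    the bearer cluster's immediate neighbours on both sides are tRNA genes.
    plain_absence: no anchors at all.
    """
    calls: set[str] = set()
    if not comp.anchors:
        calls.add("plain_absence")
        comp.scar_calls = calls
        return calls

    lo, hi = cluster.span
    left = [a for a in comp.anchors if a.bearer_feature.end < lo]
    right = [a for a in comp.anchors if a.bearer_feature.start > hi]
    if left and right and len(comp.gap_content) <= adjacency_slack:
        calls.add("insertion")
    if any(f.product_label in mobility_tokens for f in comp.gap_content):
        calls.add("element_replacement")
    if any(a.orientation == "flipped" for a in comp.anchors):
        calls.add("inversion")

    feats = bearer.replicons[cluster.replicon_id]
    member_ids = {f.feature_id for f in cluster.members}
    ups = [f for f in feats if f.feature_id not in member_ids and f.end < lo]
    downs = [f for f in feats if f.feature_id not in member_ids and f.start > hi]
    if ups and downs and ups[-1].product_label == "tRNA" and downs[0].product_label == "tRNA":
        calls.add("tRNA_flanked")

    comp.scar_calls = calls
    return calls


def detect_passengers(
    window: list[GeneFeature],
    comparator: GenomeAnnotation,
    comp: SyntenyComparison,
    cluster: MtrCluster,
) -> list[tuple[str, bool]]:
    """Call candidate passenger genes.

    A non-core bearer-window family absent from the comparator's anchored
    window is a passenger candidate; the boolean flags whether the family
    occurs anywhere else in the comparator genome (a natively present
    family rather than a travelling one).
    """
    member_ids = {f.feature_id for f in cluster.members}
    anchored_fams = {_family(a.comparator_feature) for a in comp.anchors} | {
        _family(f) for f in comp.gap_content
    }
    genome_fams = {_family(f) for f in comparator.all_features()}
    passengers: list[tuple[str, bool]] = []
    seen: set[str] = set()
    for f in window:
        fam = _family(f)
        if f.feature_id in member_ids or fam in CORE_PRODUCTS or fam in seen:
            continue
        seen.add(fam)
        if fam not in anchored_fams:
            passengers.append((fam, fam in genome_fams))
    comp.passengers = passengers
    return passengers


def compare_locus(
    cluster: MtrCluster,
    bearer: GenomeAnnotation,
    comparator: GenomeAnnotation,
    k: int = 10,
) -> SyntenyComparison:
    """Full bearer-vs-comparator comparison: anchor, classify, call passengers."""
    window = bearer_window(cluster, bearer, k)
    comp = anchor_neighborhoods(window, comparator, k, cluster=cluster)
    classify_scar(comp, cluster, bearer)
    detect_passengers(window, comparator, comp, cluster)
    return comp
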
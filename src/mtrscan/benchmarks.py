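"""Whole-pipeline benchmark routines on forged data.

Each routine regenerates its inputs from a seed, runs the relevant pipeline
stages from scratch, and scores the result against the forge's truth set.
Used by the acceptance harness and by end-to-end tests; problem sizes are
deliberately desk-scale (see docs/methods.md).
"""

from __future__ import annotations

import io as _io

import numpy as np
from skbio.tree import TreeNode

from .clusters import call_clusters
from .curation import filter_domain_hits
from .forge import (
    SCAR_TYPES,
    ClusterArchitecture,
    ForgeSpec,
    bearer_cluster,
    forge_genomes,
    forge_scar_pair,
    random_tree,
    simulate_alignment,
)
from .model import CurationParams
from .phylo import DistanceMatrix, Supermatrix, nj_tree, protein_distance, rf_distance
from .synteny import compare_locus


def _standard_spec(seed: int, n_genomes: int = 100) -> ForgeSpec:
    """Planted-recovery study conditions: 100 genomes, one planted cluster
    in ~40% of genomes with varied architectures, 30% decoy rate, 20% MAGs."""
    architectures = []
    orders = ("C,A,B", "A,B,C", "B,C,A", "C,A,B,omcA", "C,A,B,omcA,undA", "A,B,C,mtrF")
    gaps = (200, 1500, 3400)
    for i, g in enumerate(range(0, n_genomes, 5)):
        architectures.append(
            ClusterArchitecture(
                order_string=orders[i % len(orders)],
                inter_gene_gaps=(gaps[i % len(gaps)],),
                flank=("none", "tandem_tRNA", "transposase")[i % 3],
                target_genome=g,
            )
        )
        if i % 4 == 0 and g + 2 < n_genomes:
            architectures.append(
                ClusterArchitecture("C,A,B", (3400,), "none", g + 2)
            )
    return ForgeSpec(
        n_genomes=n_genomes,
        planted_clusters=tuple(architectures),
        decoy_rate=0.3,
        metagenome_fraction=0.2,
        seed=seed,
    )


def planted_recovery(seed: int, n_genomes: int = 100) -> tuple[float, float, int]:
    """Run forge -> curation -> calling; return (sensitivity, FDR, n planted)."""
    anns, hits, domains, truth = forge_genomes(_standard_spec(seed, n_genomes))
    kept_hits, _ = filter_domain_hits(hits, domains)
    clusters, _ = call_clusters({a.genome_id: a for a in anns}, kept_hits, CurationParams())
    truth_cores = {frozenset(p.core_feature_ids) for p in truth.planted}
    called_cores = {frozenset(f.feature_id for f, _ in c.core) for c in clusters}
    tp = len(truth_cores & called_cores)
    sensitivity = tp / len(truth_cores) if truth_cores else 1.0
    fdr = (len(called_cores) - tp) / len(called_cores) if called_cores else 0.0
    return sensitivity, fdr, len(truth_cores)


def nj_additive_max_error(seed: int, n_leaves: int = 7) -> float:
    """Max |path length - input distance| after NJ on an additive matrix."""
    truth = TreeNode.read(_io.StringIO(random_tree(n_leaves, seed=seed)))
    dm = truth.tip_tip_distances()
    est = nj_tree(DistanceMatrix(list(dm.ids), dm.data))
    if rf_distance(est, truth) != 0:
        return float("inf")
    est_dm = est.tip_tip_distances()
    return float(
        max(abs(est_dm[i, j] - dm[i, j]) for i in dm.ids for j in dm.ids)
    )


def nj_topology_recovery_rate(
    seed: int, n_replicates: int = 50, n_leaves: int = 8, n_sites: int = 10_000
) -> float:
    """Fraction of simulated alignments whose NJ tree matches the generating
    topology (RF = 0)."""
    hits = 0
    for r in range(n_replicates):
        nwk = random_tree(n_leaves, seed=seed + r)
        truth = TreeNode.read(_io.StringIO(nwk))
        aln = simulate_alignment(nwk, n_sites, subst_rate=1.0, seed=seed + 1000 + r)
        leaves = sorted(aln)
        sm = Supermatrix(
            leaves=leaves,
            partitions=[("sim", (0, n_sites))],
            matrix=np.array([list(aln[l]) for l in leaves], dtype="<U1"),
        )
        est = nj_tree(protein_distance(sm, "poisson"))
        hits += rf_distance(est, truth) == 0
    return hits / n_replicates


def scar_recovery(seed: int, n_pairs: int = 100) -> tuple[float, int]:
    """Classify forged scar pairs; return (sensitivity, cross-type false
    calls).  Pairs are split evenly across the four scar types."""
    per_type = n_pairs // len(SCAR_TYPES)
    correct = 0
    false_calls = 0
    total = 0
    for t_i, scar_type in enumerate(SCAR_TYPES):
        for i in range(per_type):
            bearer, comparator, _ = forge_scar_pair(scar_type, seed=seed + t_i * 1000 + i)
            comp = compare_locus(bearer_cluster(bearer), bearer, comparator)
            total += 1
            if scar_type in comp.scar_calls:
                correct += 1
            false_calls += len(comp.scar_calls - {scar_type})
    return correct / total, false_calls
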
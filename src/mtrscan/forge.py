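"""Seeded synthetic-genome forge with machine-readable ground truth.

Generates annotated genomes (GFF3-equivalent in-memory objects), BLAST-like
hit tables, domain-call tables, HGT scar genome pairs, and alignments
simulated on a known tree — everything the downstream stages consume —
with a :class:`TruthSet` recording exactly what was planted.  All output is
deterministic for a given seed.

Protein sequences for non-simulated genes are random 120–400 aa strings:
cluster calling never reads sequence content, only hit tables.  The
alignment simulator uses a uniform-exchangeability (Jukes–Cantor-style,
20-state) amino-acid replacement process, sufficient for topology-recovery
testing.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skbio.tree import TreeNode

from .model import (
    DomainCall,
    GeneFeature,
    GenomeAnnotation,
    ProteinHit,
    TaxonRecord,
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Core/accessory tokens understood in architecture order strings, mapped to
#: (product_label, hit_family or None).
_TOKEN_MAP: dict[str, tuple[str, Optional[str]]] = {
    "A": ("mtrA_like", "mtrA"),
    "B": ("mtrB_like", "mtrB"),
    "C": ("mtrC_like", "mtrC"),
    "omcA": ("mtrC_like", "mtrC"),
    "undA": ("mtrC_like", "mtrC"),
    "mtrF": ("mtrC_like", "mtrC"),
    "mtrG": ("mtrC_like", "mtrC"),
    "mtrH": ("mtrC_like", "mtrC"),
    "cymA": ("cymA", None),
    "pdsA": ("pdsA", None),
    "mtoC": ("mtoC", None),
    "mtoD": ("mtoD", None),
    "tRNA": ("tRNA", None),
    "transposase": ("transposase", None),
    "integrase": ("integrase", None),
    "endonuclease": ("endonuclease", None),
    "hemH": ("hem", None),
}

#: Multi-gene operon tokens expand to runs of genes sharing a product label.
_OPERON_MAP: dict[str, tuple[str, int]] = {
    "ccmA-I": ("ccm", 9),
    "frdABCD": ("frd", 4),
}

DECOY_DOMAIN = "TonB_dep_Rec"
_ALLOWED_DOMAIN = {"mtrA": "MtrA", "mtrB": "MtrB", "mtrC": "MtrC"}


@dataclass(frozen=True)
class ClusterArchitecture:
    """Blueprint for one planted cluster.

    ``order_string`` is a comma-separated token list (e.g. ``"C,A,B"`` or
    ``"C,A,B,omcA,ccmA-I"``); ``inter_gene_gaps`` gives the bp gap between
    consecutive planted genes (len = number of genes - 1, or a single value
    reused throughout); ``flank`` plants tandem tRNA or transposase genes
    immediately around the cluster.
    """

    order_string: str = "C,A,B"
    inter_gene_gaps: tuple[int, ...] = (200,)
    flank: str = "none"
    target_genome: int = 0

    def tokens(self) -> list[str]:
        return [t.strip() for t in self.order_string.split(",") if t.strip()]

    def __post_init__(self) -> None:
        if self.flank not in ("none", "tandem_tRNA", "transposase"):
            raise ValueError(f"unknown flank type {self.flank!r}")
        for t in self.tokens():
            if t not in _TOKEN_MAP and t not in _OPERON_MAP:
                raise ValueError(f"unknown architecture token {t!r}")


@dataclass(frozen=True)
class ForgeSpec:
    n_genomes: int = 10
    genes_per_replicon: tuple[int, int] = (20, 40)
    intergenic_bp: tuple[int, int] = (50, 400)
    planted_clusters: tuple[ClusterArchitecture, ...] = ()
    decoy_rate: float = 0.0
    metagenome_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_replicon[0] > self.genes_per_replicon[1]:
            raise ValueError("genes_per_replicon range is empty")
        if self.intergenic_bp[0] > self.intergenic_bp[1]:
            raise ValueError("intergenic_bp range is empty")
        for rate in (self.decoy_rate, self.metagenome_fraction):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0, 1]")
        for arch in self.planted_clusters:
            if not (0 <= arch.target_genome < self.n_genomes):
                raise ValueError(
                    f"architecture targets genome {arch.target_genome} "
                    f"but only {self.n_genomes} genomes forged"
                )


@dataclass
class PlantedCluster:
    genome_id: str
    replicon_id: str
    core_feature_ids: list[str]
    accessory_feature_ids: list[str]
    member_protein_ids: list[str]
    order_string: str
    flank: str


@dataclass
class TruthSet:
    """Machine-readable record of everything the forge planted."""

    planted: list[PlantedCluster] = field(default_factory=list)
    decoy_protein_ids: list[str] = field(default_factory=list)
    scar_type: Optional[str] = None
    passenger_families: list[str] = field(default_factory=list)
    tree_newick: Optional[str] = None


@dataclass
class _Gene:
    product: str
    hit_family: Optional[str]
    gap_before: int  # bp between previous gene's end and this gene's start
    is_core: bool = False
    is_accessory: bool = False
    length: Optional[int] = None


def _random_protein(rng: np.random.Generator) -> str:
    n = int(rng.integers(120, 401))
    return "".join(np.array(list(AA_ALPHABET))[rng.integers(0, 20, size=n)])


def _expand_architecture(arch: ClusterArchitecture) -> list[_Gene]:
    tokens: list[tuple[str, Optional[str], bool, bool]] = []
    for t in arch.tokens():
        if t in _OPERON_MAP:
            product, count = _OPERON_MAP[t]
            tokens.extend((product, None, False, False) for _ in range(count))
        else:
            product, fam = _TOKEN_MAP[t]
            core = t in ("A", "B", "C")
            tokens.append((product, fam, core, fam == "mtrC" and not core))
    gaps = list(arch.inter_gene_gaps)
    if len(gaps) == 1:
        gaps = gaps * (len(tokens) - 1)
    if len(gaps) != len(tokens) - 1:
        raise ValueError(
            f"architecture needs {len(tokens) - 1} inter-gene gaps, got {len(gaps)}"
        )
    genes = []
    for i, (product, fam, core, acc) in enumerate(tokens):
        genes.append(
            _Gene(
                product=product,
                hit_family=fam,
                gap_before=0 if i == 0 else gaps[i - 1],
                is_core=core,
                is_accessory=acc,
            )
        )
    if arch.flank == "tandem_tRNA":
        genes.insert(0, _Gene("tRNA", None, 0))
        genes.append(_Gene("tRNA", None, 120))
    elif arch.flank == "transposase":
        genes.insert(0, _Gene("transposase", None, 0))
        genes.append(_Gene("transposase", None, 120))
    return genes


def _lay_out(
    genes: list[_Gene],
    genome_id: str,
    replicon_id: str,
    rng: np.random.Generator,
    proteins: dict[str, str],
    start_at: int = 1,
) -> list[GeneFeature]:
    """Assign coordinates and protein ids; gap_before of planted genes is
    honoured exactly."""
    feats = []
    pos = start_at
    for i, g in enumerate(genes):
        if i > 0:
            pos += g.gap_before
        length = g.length or int(rng.integers(900, 1501))
        pid = f"{genome_id}_p{len(proteins):04d}"
        proteins[pid] = _random_protein(rng)
        feats.append(
            GeneFeature(
                feature_id=f"{genome_id}_{replicon_id}_g{i:04d}",
                genome_id=genome_id,
                replicon_id=replicon_id,
                start=pos,
                end=pos + length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                product_label=g.product,
                protein_id=pid,
            )
        )
        pos += length + 1
    return feats


def forge_genomes(
    spec: ForgeSpec,
) -> tuple[list[GenomeAnnotation], list[ProteinHit], list[DomainCall], TruthSet]:
    """Forge ``spec.n_genomes`` annotated genomes with planted clusters,
    decoy hits and MAG-style short contigs, plus the matching hit/domain
    tables and truth set."""
    rng = np.random.default_rng(spec.seed)
    truth = TruthSet()
    annotations: list[GenomeAnnotation] = []
    hits: list[ProteinHit] = []
    domains: list[DomainCall] = []

    arch_by_genome: dict[int, list[ClusterArchitecture]] = {}
    for arch in spec.planted_clusters:
        arch_by_genome.setdefault(arch.target_genome, []).append(arch)

    for g in range(spec.n_genomes):
        genome_id = f"G{g:04d}"
        is_mag = bool(rng.random() < spec.metagenome_fraction)
        taxon = TaxonRecord(
            genome_id=genome_id,
            phylum="Proteobacteria",
            klass="Gammaproteobacteria",
            order=f"Order{g % 7}",
            family=f"Family{g % 11}",
            genus=f"Genus{g:03d}",
            species=f"species{g:03d}",
            strain=f"st{g}",
            assembly_type="MAG" if is_mag else "isolate",
        )

        n_background = int(rng.integers(*spec.genes_per_replicon, endpoint=True))
        genes: list[_Gene] = [
            _Gene(
                product="other:hyp",
                hit_family=None,
                gap_before=int(rng.integers(*spec.intergenic_bp, endpoint=True)),
            )
            for _ in range(n_background)
        ]

        # plant clusters at a random insertion point, remembering which slice
        planted_slices: list[tuple[int, int, ClusterArchitecture]] = []
        for arch in arch_by_genome.get(g, []):
            block = _expand_architecture(arch)
            # keep the block clear of replicon ends (and, for MAGs, leave
            # room for a >= 12-gene contig around it)
            hi_bound = max(3, n_background - 12)
            idx = int(rng.integers(2, hi_bound))
            while any(lo <= idx < hi for lo, hi, _ in planted_slices):
                idx = int(rng.integers(2, hi_bound))
            block[0].gap_before = 4000  # isolate the block from upstream genes
            for gi in genes[idx:idx + 1]:
                gi.gap_before = 4000  # and from downstream genes
            planted_slices = [
                (lo + len(block), hi + len(block), a) if lo >= idx else (lo, hi, a)
                for lo, hi, a in planted_slices
            ]
            genes[idx:idx] = block
            planted_slices.append((idx, idx + len(block), arch))

        # decoy: an mtr hit carrying an extra non-Mtr domain
        decoy_index = None
        if rng.random() < spec.decoy_rate:
            decoy_index = int(rng.integers(0, len(genes)))
            while any(lo <= decoy_index < hi for lo, hi, _ in planted_slices):
                decoy_index = int(rng.integers(0, len(genes)))

        # split into contigs
        if is_mag:
            contigs: list[tuple[int, int]] = []
            i = 0
            while i < len(genes):
                size = int(rng.integers(5, 12))
                j = min(i + size, len(genes))
                # never cut inside a planted block; give its contig >= 12 genes
                for lo, hi, _ in planted_slices:
                    if i <= lo < j or (lo < i < hi):
                        j = max(j, hi, lo + 12, i + 12)
                j = min(j, len(genes))
                contigs.append((i, j))
                i = j
        else:
            contigs = [(0, len(genes))]

        ann = GenomeAnnotation(genome_id=genome_id, taxon=taxon)
        feature_of_gene: dict[int, GeneFeature] = {}
        for ci, (lo, hi) in enumerate(contigs):
            rid = f"{genome_id}_c{ci}"
            feats = _lay_out(genes[lo:hi], genome_id, rid, rng, ann.proteins)
            ann.replicons[rid] = feats
            for offset, f in enumerate(feats):
                feature_of_gene[lo + offset] = f
        ann.sort()
        annotations.append(ann)

        for gi, gene in enumerate(genes):
            f = feature_of_gene[gi]
            if gene.hit_family is not None:
                evalue = 10 ** float(rng.uniform(-80, -30))
                hits.append(ProteinHit(gene.hit_family, f.protein_id, evalue, 500.0, 85.0))
                domains.append(DomainCall(f.protein_id, _ALLOWED_DOMAIN[gene.hit_family]))
        if decoy_index is not None:
            f = feature_of_gene[decoy_index]
            fam = ("mtrA", "mtrB", "mtrC")[int(rng.integers(3))]
            hits.append(ProteinHit(fam, f.protein_id, 1e-40, 300.0, 40.0))
            domains.append(DomainCall(f.protein_id, _ALLOWED_DOMAIN[fam]))
            domains.append(DomainCall(f.protein_id, DECOY_DOMAIN))
            truth.decoy_protein_ids.append(f.protein_id)

        for lo, hi, arch in planted_slices:
            block_feats = [feature_of_gene[i] for i in range(lo, hi)]
            block_genes = genes[lo:hi]
            truth.planted.append(
                PlantedCluster(
                    genome_id=genome_id,
                    replicon_id=block_feats[0].replicon_id,
                    core_feature_ids=[
                        f.feature_id for f, gg in zip(block_feats, block_genes) if gg.is_core
                    ],
                    accessory_feature_ids=[
                        f.feature_id for f, gg in zip(block_feats, block_genes) if gg.is_accessory
                    ],
                    member_protein_ids=[
                        f.protein_id
                        for f, gg in zip(block_feats, block_genes)
                        if gg.is_core or gg.is_accessory
                    ],
                    order_string=arch.order_string,
                    flank=arch.flank,
                )
            )

    return annotations, hits, domains, truth


# ---------------------------------------------------------------------------
# Scar pairs
# ---------------------------------------------------------------------------

SCAR_TYPES = ("insertion", "element_replacement", "inversion", "tRNA_flanked")


def _mk_genome(
    genome_id: str,
    gene_specs: list[_Gene],
    rng: np.random.Generator,
    genus: str = "ScarGenus",
    species: str = "bearer",
) -> GenomeAnnotation:
    taxon = TaxonRecord(
        genome_id=genome_id,
        phylum="Proteobacteria", klass="Gammaproteobacteria", order="OrderX",
        family="FamilyX", genus=genus, species=species, strain="s1",
    )
    ann = GenomeAnnotation(genome_id=genome_id, taxon=taxon)
    feats = _lay_out(gene_specs, genome_id, f"{genome_id}_c0", rng, ann.proteins)
    ann.replicons[f"{genome_id}_c0"] = feats
    ann.sort()
    return ann


def forge_scar_pair(
    scar_type: str, seed: int, with_passenger: bool = False
) -> tuple[GenomeAnnotation, GenomeAnnotation, TruthSet]:
    """Forge a bearer/comparator genome pair realizing one HGT scar type.

    The bearer carries a planted C-A-B cluster between shared flanking gene
    families; the comparator realizes the requested scar: contiguous flanks
    (``insertion``), mobility genes in the gap (``element_replacement``), a
    reversed flank block (``inversion``), or — for ``tRNA_flanked`` — the
    bearer cluster sits between two tandem tRNA genes while the comparator
    gap holds neutral genes.  With ``with_passenger`` a cymA gene travels
    with the cluster and is absent from the comparator.
    """
    if scar_type not in SCAR_TYPES:
        raise ValueError(f"unknown scar type {scar_type!r}")
    rng = np.random.default_rng(seed)
    n_flank = 5
    left = [f"other:famL{i}" for i in range(n_flank)]
    right = [f"other:famR{i}" for i in range(n_flank)]
    gap = 150

    bearer_genes: list[_Gene] = [_Gene(p, None, gap) for p in left]
    if scar_type == "tRNA_flanked":
        bearer_genes.append(_Gene("tRNA", None, gap))
    cluster_block = [
        _Gene("mtrC_like", "mtrC", gap),
        _Gene("mtrA_like", "mtrA", 200),
        _Gene("mtrB_like", "mtrB", 200),
    ]
    bearer_genes.extend(cluster_block)
    if with_passenger:
        bearer_genes.append(_Gene("cymA", None, 200))
    if scar_type == "tRNA_flanked":
        bearer_genes.append(_Gene("tRNA", None, gap))
    bearer_genes.extend(_Gene(p, None, gap) for p in right)

    comp_genes: list[_Gene] = [_Gene(p, None, gap) for p in left]
    if scar_type == "insertion":
        pass  # flanks directly adjacent
    elif scar_type == "element_replacement":
        comp_genes.append(_Gene("transposase", None, gap))
        comp_genes.append(_Gene("endonuclease", None, gap))
    elif scar_type in ("inversion", "tRNA_flanked"):
        comp_genes.append(_Gene("other:filler0", None, gap))
        comp_genes.append(_Gene("other:filler1", None, gap))
    if scar_type == "inversion":
        comp_genes.extend(_Gene(p, None, gap) for p in reversed(right))
    else:
        comp_genes.extend(_Gene(p, None, gap) for p in right)

    bearer = _mk_genome("BEARER", bearer_genes, rng, species="bearer")
    comparator = _mk_genome("COMP", comp_genes, rng, species="relative")

    truth = TruthSet(scar_type=scar_type)
    core_feats = [
        f for f in bearer.all_features()
        if f.product_label in ("mtrA_like", "mtrB_like", "mtrC_like")
    ]
    truth.planted.append(
        PlantedCluster(
            genome_id=bearer.genome_id,
            replicon_id=core_feats[0].replicon_id,
            core_feature_ids=[f.feature_id for f in core_feats],
            accessory_feature_ids=[],
            member_protein_ids=[f.protein_id for f in core_feats],
            order_string="C,A,B",
            flank="tandem_tRNA" if scar_type == "tRNA_flanked" else "none",
        )
    )
    if with_passenger:
        truth.passenger_families = ["cymA"]
    return bearer, comparator, truth


def bearer_cluster(bearer: GenomeAnnotation):
    """Build the MtrCluster object for a forged scar-pair bearer genome
    straight from its product labels (the pair carries no hit table)."""
    from .model import MtrCluster

    letter = {"mtrA_like": "A", "mtrB_like": "B", "mtrC_like": "C"}
    core = [
        (f, letter[f.product_label])
        for f in sorted(bearer.all_features(), key=lambda f: f.start)
        if f.product_label in letter
    ]
    return MtrCluster(
        cluster_id=f"{bearer.genome_id}:planted",
        genome_id=bearer.genome_id,
        replicon_id=core[0][0].replicon_id,
        core=core,
        order_string="-".join(l for _, l in core),
        label="CAB",
    )


# ---------------------------------------------------------------------------
# Sequence simulation on a known tree
# ---------------------------------------------------------------------------

def _jc_p_change(d: float) -> float:
    """Probability a site differs after evolutionary distance d under the
    20-state uniform replacement model."""
    return (19.0 / 20.0) * (1.0 - np.exp(-(20.0 / 19.0) * d))


def simulate_alignment(
    tree_newick: str, n_sites: int, subst_rate: float = 1.0, seed: int = 0
) -> dict[str, str]:
    """Evolve an amino-acid alignment down a tree.

    Per-site independent substitutions under a 20-state uniform-replacement
    (Jukes–Cantor-style) process; the per-branch change probability is
    ``(19/20)(1 - exp(-(20/19) * b * subst_rate))`` for branch length ``b``.
    Zero-length branches copy the parent sequence; negative branch lengths
    are an error.  Deterministic given the seed.
    """
    tree = TreeNode.read(_io.StringIO(tree_newick), convert_underscores=False)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length {node.length} at {node.name}")
    rng = np.random.default_rng(seed)
    alphabet = np.arange(20)

    def evolve(parent_seq: np.ndarray, branch: float) -> np.ndarray:
        p = _jc_p_change(branch * subst_rate)
        seq = parent_seq.copy()
        mutate = rng.random(n_sites) < p
        n_mut = int(mutate.sum())
        if n_mut:
            # uniform over the 19 states different from the current one
            shift = rng.integers(1, 20, size=n_mut)
            seq[mutate] = (seq[mutate] + shift) % 20
        return seq

    out: dict[str, str] = {}
    root_seq = rng.integers(0, 20, size=n_sites)

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = evolve(seq, float(child.length))
            if child.is_tip():
                out[child.name] = "".join(AA_ALPHABET[i] for i in child_seq)
            else:
                walk(child, child_seq)

    walk(tree, root_seq)
    _ = alphabet
    return out


def random_tree(n_leaves: int, seed: int, min_bl: float = 0.02, max_bl: float = 0.25) -> str:
    """Random binary unrooted tree (newick) with uniform branch lengths,
    leaves a0..a{n-1}; used by recovery tests."""
    rng = np.random.default_rng(seed)
    nodes = [f"a{i}" for i in range(n_leaves)]
    subtrees = {name: name for name in nodes}
    active = list(nodes)
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        bl_a = rng.uniform(min_bl, max_bl)
        bl_b = rng.uniform(min_bl, max_bl)
        merged = f"({subtrees[a]}:{bl_a:.6f},{subtrees[b]}:{bl_b:.6f})"
        key = min(a, b)
        subtrees[key] = merged
        active = [x for x in active if x not in (a, b)] + [key]
    parts = [f"{subtrees[x]}:{rng.uniform(min_bl, max_bl):.6f}" for x in active]
    return "(" + ",".join(parts) + ");"
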
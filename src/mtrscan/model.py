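"""Domain types shared across the pipeline.

The coordinate convention is GFF3: 1-based, inclusive on both ends.  All
proximity arithmetic ("within 3,500 bp") is done at the computation sites in
:mod:`mtrscan.clusters`; coordinates are never stored half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

#: Controlled vocabulary for product labels.  Anything outside this set is
#: normalised to ``other:<raw>`` on read.
PRODUCT_TOKENS = frozenset(
    {
        "mtrA_like",
        "mtrB_like",
        "mtrC_like",
        "transposase",
        "integrase",
        "endonuclease",
        "recombinase",
        "tRNA",
        "ccm",
        "frd",
        "hem",
        "cymA",
        "pdsA",
        "mtoC",
        "mtoD",
    }
)

#: Gene families whose presence in a comparator gap is evidence of a prior
#: mobile-element event (loss scar).
MOBILITY_TOKENS = frozenset({"transposase", "integrase", "endonuclease", "recombinase"})

FAMILIES = ("mtrA", "mtrB", "mtrC")

#: Family -> single-letter code used in cluster order strings.
FAMILY_LETTER = {"mtrA": "A", "mtrB": "B", "mtrC": "C"}


def normalize_product(raw: str) -> str:
    """Map a free-text product string onto the controlled vocabulary."""
    raw = raw.strip()
    if raw in PRODUCT_TOKENS or raw.startswith("other:"):
        return raw
    return f"other:{raw}"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene (GFF3 coordinates, 1-based inclusive)."""

    feature_id: str
    genome_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    product_label: str
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start} ({self.feature_id})")
        if self.end < self.start:
            raise ValueError(
                f"end < start ({self.end} < {self.start}) for feature {self.feature_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class ProteinHit:
    """A homology hit of one of the three query families to a protein."""

    query_family: str
    protein_id: str
    evalue: float
    bitscore: float
    percent_identity: float

    def __post_init__(self) -> None:
        if self.query_family not in FAMILIES:
            raise ValueError(f"unknown query family {self.query_family!r}")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent identity must be in [0, 100]")


@dataclass(frozen=True)
class DomainCall:
    """One conserved-domain call on a protein (input table row)."""

    protein_id: str
    domain_name: str

    def __post_init__(self) -> None:
        if not self.protein_id or not self.domain_name:
            raise ValueError("protein_id and domain_name must be non-empty")


@dataclass(frozen=True)
class TaxonRecord:
    """Taxonomy for one genome; ranks down to genus are required."""

    genome_id: str
    phylum: str
    klass: str
    order: str
    family: str
    genus: str
    species: str
    strain: Optional[str] = None
    assembly_type: str = "isolate"

    def __post_init__(self) -> None:
        for rank in ("phylum", "klass", "order", "family", "genus"):
            if not getattr(self, rank):
                raise ValueError(f"rank {rank} must be non-empty for {self.genome_id}")
        if self.assembly_type not in ("isolate", "MAG"):
            raise ValueError(f"assembly_type must be isolate|MAG, got {self.assembly_type!r}")


@dataclass
class GenomeAnnotation:
    """One genome: taxonomy, features per replicon (sorted by start), proteins."""

    genome_id: str
    taxon: TaxonRecord
    replicons: dict[str, list[GeneFeature]] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)

    def sort(self) -> None:
        for rid in self.replicons:
            self.replicons[rid].sort(key=lambda f: (f.start, f.end, f.feature_id))

    def validate(self) -> None:
        seen: set[str] = set()
        for rid, feats in self.replicons.items():
            prev = 0
            for f in feats:
                if f.replicon_id != rid:
                    raise ValueError(f"feature {f.feature_id} filed under wrong replicon {rid}")
                if f.start < prev:
                    raise ValueError(f"replicon {rid} not sorted by start")
                prev = f.start
                if f.feature_id in seen:
                    raise ValueError(f"duplicate feature id {f.feature_id}")
                seen.add(f.feature_id)
        missing = sorted(
            f.protein_id
            for feats in self.replicons.values()
            for f in feats
            if f.protein_id is not None and f.protein_id not in self.proteins
        )
        if missing:
            raise ValueError(f"features reference missing protein sequences: {missing}")

    def all_features(self) -> list[GeneFeature]:
        return [f for feats in self.replicons.values() for f in feats]


@dataclass(frozen=True)
class CurationParams:
    """Thresholds for curation and cluster calling.

    proximity_bp
        Two coding sequences within this many base pairs belong to one
        cluster (default 3,500).
    accessory_evalue_max
        Accessory mtrC/omcA-family hits with E-value above this are
        discarded (default 1e-10).
    contig_majority_num / contig_majority_den
        A MAG cluster comprising >= num genes on a contig of <= den total
        genes is removed (default 3 of <= 11).
    neighborhood_genes
        Genes catalogued on each side of a cluster (default 10).
    gap_mode
        'boundary' measures the inter-feature gap (end-to-start); the
        alternative 'start_start' measures start-to-start distance.
    """

    proximity_bp: int = 3500
    accessory_evalue_max: float = 1e-10
    contig_majority_num: int = 3
    contig_majority_den: int = 11
    neighborhood_genes: int = 10
    bootstrap_n: int = 100
    seed: int = 0
    gap_mode: str = "boundary"

    def __post_init__(self) -> None:
        for name in (
            "proximity_bp",
            "accessory_evalue_max",
            "contig_majority_num",
            "contig_majority_den",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.neighborhood_genes < 0 or self.bootstrap_n < 1:
            raise ValueError("neighborhood_genes >= 0 and bootstrap_n >= 1 required")
        if self.gap_mode not in ("boundary", "start_start"):
            raise ValueError(f"gap_mode must be boundary|start_start, got {self.gap_mode!r}")


@dataclass
class MtrCluster:
    """A called mtr gene cluster.

    ``core`` holds (feature, family-letter) pairs in coordinate order;
    ``order_string`` is e.g. ``"C-A-B"``.  ``label`` distinguishes the
    Shewanella-group MtrDEF paralog (genomic order A-B-C) from canonical
    MtrCAB.
    """

    cluster_id: str
    genome_id: str
    replicon_id: str
    core: list[tuple[GeneFeature, str]] = field(default_factory=list)
    order_string: str = ""
    label: str = "unlabeled"
    accessory_mtrC: list[GeneFeature] = field(default_factory=list)
    neighborhood: list[tuple[GeneFeature, int]] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    @property
    def members(self) -> list[GeneFeature]:
        return [f for f, _ in self.core] + list(self.accessory_mtrC)

    @property
    def span(self) -> tuple[int, int]:
        ms = self.members
        return (min(f.start for f in ms), max(f.end for f in ms))

    def is_complete(self) -> bool:
        letters = [fam for _, fam in self.core]
        return sorted(letters) == ["A", "B", "C"]


__all__ = [
    "PRODUCT_TOKENS",
    "MOBILITY_TOKENS",
    "FAMILIES",
    "FAMILY_LETTER",
    "normalize_product",
    "GeneFeature",
    "ProteinHit",
    "DomainCall",
    "TaxonRecord",
    "GenomeAnnotation",
    "CurationParams",
    "MtrCluster",
    "replace",
]
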
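"""Hit- and genome-level curation filters applied before cluster calling.

Three filters: (i) proteins carrying conserved domains outside a per-family
allowed set are dropped (all their hits with them); (ii) species
represented by several strains/genomes are collapsed to one genome chosen
uniformly at random under a seeded RNG; (iii) genus-specific sampling-bias
rules remove under-designated genomes (Shewanella/Vibrio "sp." dropped;
Aeromonas "sp." kept only with a strain designation).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .model import DomainCall, GenomeAnnotation, ProteinHit

#: Default allowed (non-disqualifying) domain names per query family, used
#: for synthetic data.  Real runs should configure this from their domain
#: annotation source.
DEFAULT_ALLOWED_DOMAINS: dict[str, frozenset[str]] = {
    "mtrA": frozenset({"MtrA", "Cytochrom_C", "DHC"}),
    "mtrB": frozenset({"MtrB", "MtrB_PioB"}),
    "mtrC": frozenset({"MtrC", "Cytochrom_C", "OmcA_MtrC"}),
}


@dataclass
class CurationReport:
    """Audit of what each filter removed; kept/removed sets partition input."""

    removed_by_domain: list[str] = field(default_factory=list)
    removed_duplicates: list[str] = field(default_factory=list)
    removed_by_genus_rule: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "removed_by_domain": self.removed_by_domain,
            "removed_duplicates": self.removed_duplicates,
            "removed_by_genus_rule": self.removed_by_genus_rule,
            "kept": self.kept,
        }


def filter_domain_hits(
    hits: Iterable[ProteinHit],
    domains: Iterable[DomainCall],
    allowed: dict[str, frozenset[str]] | dict[str, set[str]] = DEFAULT_ALLOWED_DOMAINS,
) -> tuple[list[ProteinHit], list[str]]:
    """Drop hits whose protein carries a domain outside the family's allowed set.

    The filter operates on the protein: one disqualifying domain removes
    every hit to that protein.  Proteins with no domain calls at all pass.
    """
    hits = list(hits)
    dom_by_protein: dict[str, set[str]] = defaultdict(set)
    for d in domains:
        dom_by_protein[d.protein_id].add(d.domain_name)

    bad: set[str] = set()
    for h in hits:
        extra = dom_by_protein.get(h.protein_id, set()) - set(allowed.get(h.query_family, ()))
        if extra:
            bad.add(h.protein_id)
    kept = [h for h in hits if h.protein_id not in bad]
    return kept, sorted(bad)


def dedupe_species(
    genomes: list[GenomeAnnotation], seed: int
) -> tuple[list[GenomeAnnotation], CurationReport]:
    """Keep one genome per (genus, species) group, chosen uniformly at random.

    Genomes whose species field is the placeholder "sp." are not grouped
    (each is kept); selection is deterministic for a given seed and
    independent of input order.
    """
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str], list[GenomeAnnotation]] = defaultdict(list)
    singles: list[GenomeAnnotation] = []
    for g in genomes:
        t = g.taxon
        if t.species == "sp.":
            singles.append(g)
        else:
            groups[(t.genus, t.species)].append(g)

    report = CurationReport()
    kept: list[GenomeAnnotation] = list(singles)
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda g: g.genome_id)
        survivor = members[int(rng.integers(len(members)))]
        kept.append(survivor)
        report.removed_duplicates.extend(
            g.genome_id for g in members if g.genome_id != survivor.genome_id
        )
    order = {g.genome_id: i for i, g in enumerate(genomes)}
    kept.sort(key=lambda g: order[g.genome_id])
    report.kept = [g.genome_id for g in kept]
    return kept, report


def apply_genus_rules(
    genomes: list[GenomeAnnotation],
    rules: dict[str, str] | None = None,
) -> tuple[list[GenomeAnnotation], CurationReport]:
    """Apply genus-specific curation rules.

    ``rules`` maps genus -> action; actions are ``drop_sp`` (remove genomes
    whose species is "sp.") and ``require_strain`` (remove "sp." genomes
    lacking a strain designation).  The default reproduces the study rules:
    Shewanella and Vibrio drop_sp, Aeromonas require_strain.
    """
    if rules is None:
        rules = {"Shewanella": "drop_sp", "Vibrio": "drop_sp", "Aeromonas": "require_strain"}
    for genus, action in rules.items():
        if action not in ("drop_sp", "require_strain"):
            raise ValueError(f"unknown genus-rule action {action!r} for {genus}")

    report = CurationReport()
    kept: list[GenomeAnnotation] = []
    for g in genomes:
        t = g.taxon
        action = rules.get(t.genus)
        drop = False
        if action == "drop_sp" and t.species == "sp.":
            drop = True
        elif action == "require_strain" and t.species == "sp." and not t.strain:
            drop = True
        if drop:
            report.removed_by_genus_rule.append(g.genome_id)
        else:
            kept.append(g)
    report.kept = [g.genome_id for g in kept]
    return kept, report
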
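"""Presence/absence census statistics over called clusters.

Three summaries: per-genus prevalence (fraction of a genus' species that
encode a complete cluster), per-group component carriage (fraction of
group members whose cluster neighborhood or accessory list carries a given
component token), and the Group-1 mtrC-subfamily census (species-level
carriage of MtrC/MtrF/OmcA/UndA/MtrG/MtrH plus accessory-copy counts).
All denominators are exact integers; summary percentages round to the
nearest integer while the underlying fractions stay exact.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .model import MtrCluster, TaxonRecord
from .phylo import SUBFAMILIES


@dataclass
class PrevalenceRow:
    genus: str
    n_species_with_cluster: int
    n_assemblies_assessed: int

    @property
    def fraction(self) -> float:
        return (
            self.n_species_with_cluster / self.n_assemblies_assessed
            if self.n_assemblies_assessed
            else 0.0
        )


@dataclass
class CensusTable:
    """(group, component token) -> numerator/denominator counts."""

    rows: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def fraction(self, group: str, token: str) -> float:
        num, den = self.rows[(group, token)]
        return num / den if den else 0.0

    def percent(self, group: str, token: str) -> int:
        return int(round(100 * self.fraction(group, token)))

    def to_frame(self) -> pd.DataFrame:
        records = [
            {"group": g, "component": t, "numerator": n, "denominator": d,
             "fraction": (n / d if d else 0.0)}
            for (g, t), (n, d) in sorted(self.rows.items())
        ]
        return pd.DataFrame.from_records(
            records, columns=["group", "component", "numerator", "denominator", "fraction"]
        )


def _species_unit(t: TaxonRecord) -> tuple[str, str, str]:
    """Counting unit: one strain per species; 'sp.' records are counted per
    strain (they are not a resolvable species)."""
    if t.species == "sp.":
        return (t.genus, "sp.", t.strain or t.genome_id)
    return (t.genus, t.species, "")


def prevalence_table(
    clusters: Iterable[MtrCluster],
    inventory: list[TaxonRecord],
    rules: Optional[dict[str, str]] = None,
) -> list[PrevalenceRow]:
    """Per-genus fraction of species that encode >= 1 retained cluster.

    ``inventory`` lists every assembly assessed (one row per genome);
    species are collapsed to one counting unit each.  Genus rules mirror
    the curation stage: under ``drop_sp`` a genus' "sp." records are not
    counted at all; under ``require_strain`` they count only with a strain
    designation.  A genus present among clusters but absent from the
    inventory is a consistency error.
    """
    if rules is None:
        rules = {"Shewanella": "drop_sp", "Vibrio": "drop_sp", "Aeromonas": "require_strain"}

    def countable(t: TaxonRecord) -> bool:
        action = rules.get(t.genus)
        if t.species != "sp.":
            return True
        if action == "drop_sp":
            return False
        if action == "require_strain":
            return bool(t.strain)
        return True

    units_by_genus: dict[str, set[tuple[str, str, str]]] = defaultdict(set)
    taxon_by_genome: dict[str, TaxonRecord] = {}
    for t in inventory:
        taxon_by_genome[t.genome_id] = t
        if countable(t):
            units_by_genus[t.genus].add(_species_unit(t))

    bearers_by_genus: dict[str, set[tuple[str, str, str]]] = defaultdict(set)
    for c in clusters:
        t = taxon_by_genome.get(c.genome_id)
        if t is None:
            raise ValueError(
                f"cluster genome {c.genome_id} absent from the taxon inventory"
            )
        if countable(t):
            bearers_by_genus[t.genus].add(_species_unit(t))

    rows = []
    for genus in sorted(units_by_genus):
        rows.append(
            PrevalenceRow(
                genus=genus,
                n_species_with_cluster=len(bearers_by_genus.get(genus, set())),
                n_assemblies_assessed=len(units_by_genus[genus]),
            )
        )
    return rows


def _cluster_tokens(c: MtrCluster) -> set[str]:
    tokens = {f.product_label for f, _ in c.neighborhood}
    tokens |= {f.product_label for f in c.accessory_mtrC}
    return tokens


def component_census(
    clusters: Iterable[MtrCluster],
    groups: dict[str, str],
    component_tokens: Iterable[str],
) -> CensusTable:
    """Fraction of each group's members whose cluster carries each token
    (in the neighborhood catalog or accessory list); denominators are
    group sizes.  Empty groups are omitted."""
    clusters = list(clusters)
    component_tokens = list(component_tokens)
    members: dict[str, list[MtrCluster]] = defaultdict(list)
    for c in clusters:
        if c.cluster_id not in groups:
            raise ValueError(f"cluster {c.cluster_id} has no group assignment")
        members[groups[c.cluster_id]].append(c)

    table = CensusTable()
    for group in sorted(members):
        den = len(members[group])
        for token in component_tokens:
            num = sum(1 for c in members[group] if token in _cluster_tokens(c))
            table.rows[(group, token)] = (num, den)
    return table


def group1_subfamily_census(
    group1_clusters: Iterable[MtrCluster],
    subfamily_of_feature: dict[str, str],
    species_of_genome: dict[str, str],
    all_clusters: Optional[Iterable[MtrCluster]] = None,
) -> tuple[CensusTable, dict[str, int], float]:
    """Group-1 mtrC-subfamily census.

    ``subfamily_of_feature`` labels every core-C and accessory mtrC feature
    id with its subfamily; an unlabeled Group-1 mtrC gene is an error.
    Species-level pooling: a species carrying a subfamily in any of its
    clusters counts once.  Returns (per-subfamily carriage table, per-
    cluster accessory-copy counts, fraction of all clusters with >= 1
    accessory mtrC).
    """
    group1_clusters = list(group1_clusters)
    unlabeled = []
    carriage: dict[str, set[str]] = {s: set() for s in SUBFAMILIES}
    species_seen: set[str] = set()
    acc_counts: dict[str, int] = {}
    for c in group1_clusters:
        species = species_of_genome[c.genome_id]
        species_seen.add(species)
        acc_counts[c.cluster_id] = len(c.accessory_mtrC)
        mtrc_feats = [f for f, fam in c.core if fam == "C"] + list(c.accessory_mtrC)
        for f in mtrc_feats:
            sub = subfamily_of_feature.get(f.feature_id)
            if sub is None:
                unlabeled.append(f.feature_id)
            elif sub in carriage:
                carriage[sub].add(species)
    if unlabeled:
        raise ValueError(f"unlabeled Group-1 mtrC genes: {sorted(unlabeled)}")

    table = CensusTable()
    den = len(species_seen)
    for sub in SUBFAMILIES:
        table.rows[("1", sub)] = (len(carriage[sub]), den)

    pool = list(all_clusters) if all_clusters is not None else group1_clusters
    with_acc = sum(1 for c in pool if len(c.accessory_mtrC) >= 1)
    acc_fraction = with_acc / len(pool) if pool else 0.0
    return table, acc_counts, acc_fraction


def prevalence_frame(rows: list[PrevalenceRow]) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "genus": r.genus,
                "n_species_with_cluster": r.n_species_with_cluster,
                "n_assemblies_assessed": r.n_assemblies_assessed,
                "fraction": r.fraction,
            }
            for r in rows
        ],
        columns=["genus", "n_species_with_cluster", "n_assemblies_assessed", "fraction"],
    )
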
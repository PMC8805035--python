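"""End-to-end pipeline driver: curation -> cluster calling -> census.

Configured by a TOML file::

    [inputs]
    annotations_dir = "genomes"   # <genome>.gff3 + <genome>.faa pairs
    hits = "hits.tsv"
    domains = "domains.tsv"

    [params]
    proximity_bp = 3500
    seed = 0

    [output]
    dir = "out"

Writes the cluster table (TSV + JSON sidecar), the curation report (JSON),
census TSVs and a markdown summary; every removal count is logged.  Output
is deterministic for a given config + seed.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import census as census_mod
from . import curation, io
from .clusters import call_clusters
from .model import CurationParams, GenomeAnnotation, MtrCluster

log = logging.getLogger("mtrscan")


@dataclass
class ReportBundle:
    out_dir: Path
    clusters: list[MtrCluster] = field(default_factory=list)
    curation_report: dict = field(default_factory=dict)
    n_genomes_in: int = 0
    n_genomes_kept: int = 0


def _load_genomes(annotations_dir: Path) -> list[GenomeAnnotation]:
    genomes = []
    for gff in sorted(annotations_dir.glob("*.gff3")):
        faa = gff.with_suffix(".faa")
        if not faa.exists():
            raise FileNotFoundError(f"protein FASTA missing for {gff.name}: {faa.name}")
        genomes.append(io.read_annotations(gff, faa))
    return genomes


def run_pipeline(config_path: str | Path) -> ReportBundle:
    """Run curation, cluster calling and the census end to end."""
    config_path = Path(config_path)
    with open(config_path, "rb") as fh:
        cfg = tomllib.load(fh)

    base = config_path.parent
    inputs = cfg.get("inputs", {})
    out_dir = base / cfg.get("output", {}).get("dir", "out")
    out_dir.mkdir(parents=True, exist_ok=True)
    params = CurationParams(**cfg.get("params", {}))
    genus_rules = cfg.get("curation", {}).get("genus_rules")

    bundle = ReportBundle(out_dir=out_dir)

    ann_dir = base / inputs.get("annotations_dir", "genomes")
    genomes = _load_genomes(ann_dir) if ann_dir.exists() else []
    bundle.n_genomes_in = len(genomes)
    if not genomes:
        (out_dir / "summary.md").write_text("# mtrscan report\n\nNo genomes found.\n")
        io.write_clusters([], out_dir / "clusters.tsv")
        log.info("no genomes under %s; wrote empty report", ann_dir)
        return bundle

    hits = io.read_hits(base / inputs["hits"]) if "hits" in inputs else []
    domains = io.read_domains(base / inputs["domains"]) if "domains" in inputs else []

    kept_hits, removed_proteins = curation.filter_domain_hits(hits, domains)
    log.info("domain filter removed %d proteins", len(removed_proteins))
    genomes, dedup_report = curation.dedupe_species(genomes, seed=params.seed)
    log.info("species dedup removed %d genomes", len(dedup_report.removed_duplicates))
    genomes, genus_report = curation.apply_genus_rules(genomes, genus_rules)
    log.info("genus rules removed %d genomes", len(genus_report.removed_by_genus_rule))
    bundle.n_genomes_kept = len(genomes)

    annotations = {g.genome_id: g for g in genomes}
    clusters, removals = call_clusters(annotations, kept_hits, params)
    log.info(
        "called %d clusters (%d incomplete, %d contig-majority removed)",
        len(clusters), len(removals["incomplete"]), len(removals["contig_majority"]),
    )
    bundle.clusters = clusters

    io.write_clusters(clusters, out_dir / "clusters.tsv")
    bundle.curation_report = {
        "removed_by_domain": removed_proteins,
        "removed_duplicates": dedup_report.removed_duplicates,
        "removed_by_genus_rule": genus_report.removed_by_genus_rule,
        "kept": sorted(annotations),
        "n_incomplete": len(removals["incomplete"]),
        "n_contig_majority_removed": len(removals["contig_majority"]),
    }
    with open(out_dir / "curation_report.json", "w") as fh:
        json.dump(bundle.curation_report, fh, indent=1, sort_keys=True)

    inventory = [g.taxon for g in genomes]
    prevalence = census_mod.prevalence_table(clusters, inventory, genus_rules)
    census_mod.prevalence_frame(prevalence).to_csv(
        out_dir / "prevalence.tsv", sep="\t", index=False
    )

    lines = [
        "# mtrscan report",
        "",
        f"Genomes read: {bundle.n_genomes_in}; kept after curation: {bundle.n_genomes_kept}.",
        f"Proteins removed by the domain filter: {len(removed_proteins)}.",
        f"Complete clusters called: {len(clusters)} "
        f"(incomplete candidates removed: {len(removals['incomplete'])}; "
        f"contig-majority removed: {len(removals['contig_majority'])}).",
        "",
        "| cluster | genome | order | label | accessory mtrC |",
        "|---|---|---|---|---|",
    ]
    for c in clusters:
        lines.append(
            f"| {c.cluster_id} | {c.genome_id} | {c.order_string} | {c.label} "
            f"| {len(c.accessory_mtrC)} |"
        )
    (out_dir / "summary.md").write_text("\n".join(lines) + "\n")
    return bundle
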
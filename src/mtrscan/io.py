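"""Readers and writers for every external format the pipeline touches.

Formats: GFF3 (gene/CDS records) + protein FASTA per genome, BLAST
outfmt-6-style hit tables (TSV), domain-call tables (TSV), taxonomy tables
(TSV), cluster tables (TSV + JSON sidecar), aligned FASTA.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    FAMILIES,
    DomainCall,
    GeneFeature,
    GenomeAnnotation,
    MtrCluster,
    ProteinHit,
    TaxonRecord,
    normalize_product,
)


class GFFParseError(ValueError):
    """Raised for a malformed GFF3 line; message names the line number."""


# ---------------------------------------------------------------------------
# GFF3 + protein FASTA
# ---------------------------------------------------------------------------

def _parse_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field.split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"attribute {part!r} lacks '='")
        k, v = part.split("=", 1)
        attrs[k] = v
    return attrs


def read_annotations(
    gff_path: str | Path,
    fasta_path: str | Path,
    taxon: Optional[TaxonRecord] = None,
) -> GenomeAnnotation:
    """Read one genome's GFF3 + protein FASTA into a :class:`GenomeAnnotation`.

    Features are sorted by start within each replicon.  Product strings
    outside the controlled vocabulary become ``other:<raw>``.  A feature
    referencing a protein id absent from the FASTA raises a
    missing-sequence error listing the ids.
    """
    gff_path = Path(gff_path)
    fasta_path = Path(fasta_path)

    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}

    genome_id = None
    taxon_meta: dict[str, str] = {}
    replicons: dict[str, list[GeneFeature]] = {}
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##genome-id"):
                genome_id = line.split(None, 1)[1].strip()
                continue
            if line.startswith("##taxon"):
                # ##taxon key value
                _, key, value = line.split(None, 2)
                taxon_meta[key] = value.strip()
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFFParseError(f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype not in ("gene", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GFFParseError(f"line {lineno}: non-integer coordinates") from exc
            try:
                attrs = _parse_attributes(attr_s)
            except ValueError as exc:
                raise GFFParseError(f"line {lineno}: {exc}") from exc
            fid = attrs.get("ID")
            if fid is None:
                raise GFFParseError(f"line {lineno}: missing ID attribute")
            if strand not in ("+", "-"):
                raise GFFParseError(f"line {lineno}: bad strand {strand!r}")
            if end < start or start < 1:
                raise GFFParseError(f"line {lineno}: invalid coordinates {start}..{end}")
            gid = attrs.get("genome_id", genome_id or gff_path.stem)
            feat = GeneFeature(
                feature_id=fid,
                genome_id=gid,
                replicon_id=seqid,
                start=start,
                end=end,
                strand=strand,
                product_label=normalize_product(attrs.get("product", "other:unknown")),
                protein_id=attrs.get("protein_id") or None,
            )
            replicons.setdefault(seqid, []).append(feat)

    genome_id = genome_id or gff_path.stem
    if taxon is None:
        if taxon_meta:
            taxon = TaxonRecord(
                genome_id=genome_id,
                phylum=taxon_meta.get("phylum", "NA"),
                klass=taxon_meta.get("class", "NA"),
                order=taxon_meta.get("order", "NA"),
                family=taxon_meta.get("family", "NA"),
                genus=taxon_meta.get("genus", "NA"),
                species=taxon_meta.get("species", "sp."),
                strain=taxon_meta.get("strain") or None,
                assembly_type=taxon_meta.get("assembly_type", "isolate"),
            )
        else:
            taxon = TaxonRecord(
                genome_id=genome_id,
                phylum="NA", klass="NA", order="NA", family="NA",
                genus="NA", species="sp.",
            )

    ann = GenomeAnnotation(genome_id=genome_id, taxon=taxon, replicons=replicons, proteins=proteins)
    ann.sort()
    missing = sorted(
        {f.protein_id for f in ann.all_features() if f.protein_id and f.protein_id not in proteins}
    )
    if missing:
        raise ValueError(f"proteins referenced but absent from FASTA: {missing}")
    return ann


def write_annotations(ann: GenomeAnnotation, gff_path: str | Path, fasta_path: str | Path) -> None:
    """Write a genome back to GFF3 + protein FASTA (inverse of read_annotations)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##genome-id {ann.genome_id}\n")
        t = ann.taxon
        for key, value in (
            ("phylum", t.phylum), ("class", t.klass), ("order", t.order),
            ("family", t.family), ("genus", t.genus), ("species", t.species),
            ("strain", t.strain or ""), ("assembly_type", t.assembly_type),
        ):
            if value:
                fh.write(f"##taxon {key} {value}\n")
        for rid in ann.replicons:
            for f in ann.replicons[rid]:
                attrs = [f"ID={f.feature_id}", f"product={f.product_label}"]
                if f.protein_id:
                    attrs.append(f"protein_id={f.protein_id}")
                fh.write(
                    "\t".join(
                        [rid, "mtrscan", "CDS", str(f.start), str(f.end), ".",
                         f.strand, "0", ";".join(attrs)]
                    )
                    + "\n"
                )
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sorted(ann.proteins.items())
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# Hit / domain / taxonomy tables
# ---------------------------------------------------------------------------

def read_hits(tsv_path: str | Path, family_map: Optional[dict[str, str]] = None) -> list[ProteinHit]:
    """Read a 12-column BLAST-tabular hit table.

    Columns 1, 2, 3, 11, 12 are query family, subject protein id, percent
    identity, E-value and bit score.  The query column must map onto one of
    mtrA/mtrB/mtrC (``family_map`` may translate other query labels).
    """
    family_map = family_map or {}
    hits: list[ProteinHit] = []
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"hit table line {lineno}: expected 12 columns, got {len(cols)}")
            query = family_map.get(cols[0], cols[0])
            if query not in FAMILIES:
                raise ValueError(f"hit table line {lineno}: unknown query family {cols[0]!r}")
            try:
                pident = float(cols[2])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise ValueError(f"hit table line {lineno}: unparseable numeric field") from exc
            hits.append(ProteinHit(query, cols[1], evalue, bitscore, pident))
    return hits


def write_hits(hits: Iterable[ProteinHit], tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        for h in hits:
            row = [
                h.query_family, h.protein_id, f"{h.percent_identity:g}",
                "100", "0", "0", "1", "100", "1", "100",
                f"{h.evalue:g}", f"{h.bitscore:g}",
            ]
            fh.write("\t".join(row) + "\n")


def read_domains(tsv_path: str | Path) -> list[DomainCall]:
    calls = []
    with open(tsv_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, dom = line.split("\t")[:2]
            calls.append(DomainCall(pid, dom))
    return calls


def write_domains(calls: Iterable[DomainCall], tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        for c in calls:
            fh.write(f"{c.protein_id}\t{c.domain_name}\n")


_TAXA_COLS = ["genome_id", "phylum", "class", "order", "family", "genus",
              "species", "strain", "assembly_type"]


def read_taxa(tsv_path: str | Path) -> list[TaxonRecord]:
    records = []
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            records.append(
                TaxonRecord(
                    genome_id=row["genome_id"], phylum=row["phylum"], klass=row["class"],
                    order=row["order"], family=row["family"], genus=row["genus"],
                    species=row["species"], strain=row.get("strain") or None,
                    assembly_type=row.get("assembly_type", "isolate"),
                )
            )
    return records


def write_taxa(records: Iterable[TaxonRecord], tsv_path: str | Path) -> None:
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TAXA_COLS)
        for t in records:
            w.writerow([t.genome_id, t.phylum, t.klass, t.order, t.family,
                        t.genus, t.species, t.strain or "", t.assembly_type])


# ---------------------------------------------------------------------------
# Clusters (TSV per gene + JSON sidecar)
# ---------------------------------------------------------------------------

_CLUSTER_COLS = ["cluster_id", "genome_id", "replicon", "start", "end",
                 "strand", "role", "label"]


def _feature_to_dict(f: GeneFeature) -> dict:
    return {
        "feature_id": f.feature_id, "genome_id": f.genome_id,
        "replicon_id": f.replicon_id, "start": f.start, "end": f.end,
        "strand": f.strand, "product_label": f.product_label,
        "protein_id": f.protein_id,
    }


def _feature_from_dict(d: dict) -> GeneFeature:
    return GeneFeature(**d)


def write_clusters(clusters: list[MtrCluster], path: str | Path) -> None:
    """Write clusters as a per-gene TSV plus a JSON sidecar (``<path>.json``).

    The sidecar carries the full objects; :func:`read_clusters` reproduces
    them exactly.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_CLUSTER_COLS)
        for c in clusters:
            for f, fam in c.core:
                w.writerow([c.cluster_id, c.genome_id, c.replicon_id, f.start,
                            f.end, f.strand, f"core_{fam}", c.label])
            for f in c.accessory_mtrC:
                w.writerow([c.cluster_id, c.genome_id, c.replicon_id, f.start,
                            f.end, f.strand, "accessory_mtrC", c.label])
    payload = []
    for c in clusters:
        payload.append(
            {
                "cluster_id": c.cluster_id,
                "genome_id": c.genome_id,
                "replicon_id": c.replicon_id,
                "core": [[_feature_to_dict(f), fam] for f, fam in c.core],
                "order_string": c.order_string,
                "label": c.label,
                "accessory_mtrC": [_feature_to_dict(f) for f in c.accessory_mtrC],
                "neighborhood": [[_feature_to_dict(f), off] for f, off in c.neighborhood],
                "flags": sorted(c.flags),
            }
        )
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(payload, fh, indent=1)


def read_clusters(path: str | Path) -> list[MtrCluster]:
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        payload = json.load(fh)
    clusters = []
    for d in payload:
        clusters.append(
            MtrCluster(
                cluster_id=d["cluster_id"],
                genome_id=d["genome_id"],
                replicon_id=d["replicon_id"],
                core=[(_feature_from_dict(fd), fam) for fd, fam in d["core"]],
                order_string=d["order_string"],
                label=d["label"],
                accessory_mtrC=[_feature_from_dict(fd) for fd in d["accessory_mtrC"]],
                neighborhood=[(_feature_from_dict(fd), off) for fd, off in d["neighborhood"]],
                flags=set(d["flags"]),
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# Aligned FASTA
# ---------------------------------------------------------------------------

def read_alignment(fasta_path: str | Path) -> dict[str, str]:
    """Read an aligned protein FASTA; all rows must share one length."""
    aln = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
    return aln


def write_alignment(aln: dict[str, str], fasta_path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in aln.items()]
    SeqIO.write(records, str(fasta_path), "fasta")
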
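#!/usr/bin/env python
"""Forge the synthetic study dataset.

Writes 100 annotated genomes (GFF3 + protein FASTA), the BLAST-style hit
table, the domain-call table, the taxonomy table and the machine-readable
truth set under results/dataset/.  Roughly 40% of genomes carry one planted
mtr cluster (varied gene orders, accessory mtrC copies, tRNA/transposase
flanks), 30% carry a decoy hit with a disqualifying extra domain, and 20%
are metagenome-style assemblies split into short contigs.
"""

import argparse
import dataclasses
import json
from pathlib import Path

from mtrscan import io
from mtrscan.benchmarks import _standard_spec
from mtrscan.forge import forge_genomes


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/dataset"))
    args = ap.parse_args()

    spec = _standard_spec(args.seed, n_genomes=100)
    anns, hits, domains, truth = forge_genomes(spec)

    gdir = args.out / "genomes"
    gdir.mkdir(parents=True, exist_ok=True)
    for ann in anns:
        io.write_annotations(ann, gdir / f"{ann.genome_id}.gff3", gdir / f"{ann.genome_id}.faa")
    io.write_hits(hits, args.out / "hits.tsv")
    io.write_domains(domains, args.out / "domains.tsv")
    io.write_taxa([a.taxon for a in anns], args.out / "taxa.tsv")
    with open(args.out / "truth.json", "w") as fh:
        json.dump(
            {
                "planted": [dataclasses.asdict(p) for p in truth.planted],
                "decoy_protein_ids": truth.decoy_protein_ids,
            },
            fh,
            indent=1,
        )

    n_mag = sum(1 for a in anns if a.taxon.assembly_type == "MAG")
    print(
        f"Forged {len(anns)} genomes ({n_mag} MAG-style), "
        f"{len(truth.planted)} planted clusters, "
        f"{len(truth.decoy_protein_ids)} decoy proteins, "
        f"{len(hits)} hits -> {args.out}"
    )


if __name__ == "__main__":
    main()
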
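#!/usr/bin/env python
"""Census statistics: called-cluster prevalence plus the packaged fixture.

Part 1 computes per-genus prevalence and the per-label cluster counts from
the clusters called in 02_call_clusters.py.  Part 2 recomputes the Group-1
mtrC-subfamily carriage percentages and the accessory-copy prevalence from
the packaged (synthetic, aggregate-matched) fixture tables.  Writes
results/census/.
"""

import argparse
from pathlib import Path

import pandas as pd

from mtrscan import fixtures, io
from mtrscan.census import prevalence_frame, prevalence_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dataset", type=Path, default=Path("results/dataset"))
    ap.add_argument("--clusters", type=Path, default=Path("results/clusters.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/census"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    clusters = io.read_clusters(args.clusters)
    inventory = io.read_taxa(args.dataset / "taxa.tsv")
    rows = prevalence_table(clusters, inventory)
    frame = prevalence_frame(rows)
    frame.to_csv(args.out / "prevalence.tsv", sep="\t", index=False)
    n_bearing = int((frame["n_species_with_cluster"] > 0).sum())
    print(
        f"Prevalence over {len(frame)} genera: {n_bearing} have >= 1 bearer species; "
        f"{sum(len(c.accessory_mtrC) for c in clusters)} accessory mtrC genes chained "
        f"across {len(clusters)} clusters."
    )

    pct = fixtures.group1_subfamily_percentages()
    fixture_rows = [
        {"statistic": f"group1_{sub}_pct", "value": pct[sub]} for sub in pct
    ] + [
        {"statistic": "accessory_mtrC_pct", "value": fixtures.accessory_mtrC_percent()},
        {
            "statistic": "shewanella_bearers_of_assessed",
            "value": "%d/%d" % fixtures.genus_prevalence_fraction("Shewanella"),
        },
    ]
    pd.DataFrame(fixture_rows).to_csv(args.out / "fixture_census.tsv", sep="\t", index=False)
    print(
        "Fixture census: "
        + ", ".join(f"{s} {v}%" for s, v in pct.items())
        + f"; accessory mtrC in {fixtures.accessory_mtrC_percent()}% of clusters; "
        + "Shewanella %d/%d bearer species." % fixtures.genus_prevalence_fraction("Shewanella")
    )


if __name__ == "__main__":
    main()
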
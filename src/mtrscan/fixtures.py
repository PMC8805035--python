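"""Packaged census fixtures.

The real survey behind this pipeline drew on a 2020 NCBI snapshot that
cannot be redistributed; the tables under ``data/`` are synthetic
stand-ins, constructed once so that their aggregate counts match the
survey's published summary statistics (Group-1 subfamily carriage,
accessory-copy prevalence, Shewanella-group prevalence) while every row —
species names, per-row subfamily combinations — is invented.  Filenames
carry the ``_synthetic`` suffix to make this explicit.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .phylo import SUBFAMILIES


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("mtrscan.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_group1_subfamilies() -> pd.DataFrame:
    """Synthetic Group-1 species x subfamily presence table (0/1)."""
    return _read("group1_subfamilies_synthetic.tsv")


def load_cluster_inventory() -> pd.DataFrame:
    """Synthetic cluster inventory: cluster_id, group, n_accessory_mtrC."""
    return _read("cluster_inventory_synthetic.tsv")


def load_genus_prevalence() -> pd.DataFrame:
    """Synthetic per-genus prevalence counts (bearer species / assessed)."""
    return _read("genus_prevalence_synthetic.tsv")


def group1_subfamily_percentages() -> dict[str, int]:
    """Percent of Group-1 species carrying each mtrC subfamily, computed by
    counting the fixture rows (nearest-integer percentages)."""
    df = load_group1_subfamilies()
    n = len(df)
    return {s: int(round(100 * int(df[s].sum()) / n)) for s in SUBFAMILIES}


def accessory_mtrC_percent() -> int:
    """Percent of all fixture clusters carrying >= 1 accessory mtrC copy."""
    df = load_cluster_inventory()
    return int(round(100 * int((df["n_accessory_mtrC"] >= 1).sum()) / len(df)))


def genus_prevalence_fraction(genus: str) -> tuple[int, int]:
    """(bearer species, assemblies assessed) for one genus in the fixture."""
    df = load_genus_prevalence()
    row = df[df["genus"] == genus]
    if row.empty:
        raise KeyError(f"genus {genus!r} not in fixture")
    return int(row["n_species_with_cluster"].iloc[0]), int(row["n_assemblies_assessed"].iloc[0])
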
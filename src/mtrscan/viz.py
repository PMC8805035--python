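"""Minimal locus diagrams (SVG via matplotlib).

One- or two-track gene-arrow plots of cluster loci, in the style of
pairwise locus comparison figures.  Cosmetic only; no analysis happens
here.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import FancyArrow

from .model import GeneFeature

_COLORS = {
    "mtrA_like": "#d95f02",
    "mtrB_like": "#7570b3",
    "mtrC_like": "#1b9e77",
    "transposase": "#e7298a",
    "integrase": "#e7298a",
    "endonuclease": "#e7298a",
    "recombinase": "#e7298a",
    "tRNA": "#666666",
    "cymA": "#66a61e",
    "pdsA": "#66a61e",
    "ccm": "#a6761d",
    "frd": "#a6761d",
    "hem": "#a6761d",
}


def _draw_track(ax, features: list[GeneFeature], y: float) -> None:
    if not features:
        return
    x0 = min(f.start for f in features)
    for f in features:
        width = f.end - f.start + 1
        color = _COLORS.get(f.product_label, "#cccccc")
        if f.strand == "+":
            arrow = FancyArrow(f.start - x0, y, width, 0, width=0.25,
                               head_width=0.4, head_length=min(300, width * 0.3),
                               length_includes_head=True, color=color)
        else:
            arrow = FancyArrow(f.end - x0, y, -width, 0, width=0.25,
                               head_width=0.4, head_length=min(300, width * 0.3),
                               length_includes_head=True, color=color)
        ax.add_patch(arrow)


def plot_locus(
    features: list[GeneFeature],
    path,
    comparator_features: list[GeneFeature] | None = None,
    title: str = "",
) -> None:
    """Write an SVG gene-arrow diagram of one locus (optionally two tracks)."""
    fig, ax = plt.subplots(figsize=(10, 2 if comparator_features is None else 3))
    _draw_track(ax, features, 1.0)
    if comparator_features:
        _draw_track(ax, comparator_features, 0.0)
    ax.autoscale()
    ax.set_yticks([])
    ax.set_xlabel("bp (locus-relative)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
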
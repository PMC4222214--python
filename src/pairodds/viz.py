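"""Render the association diagram.

Nodes are species, colour-banded by overall presence (red for the most
common, through orange, light brown, yellow and green, to blue for the
rarest). Arrows run from predictor to target: red for indication, blue
for contraindication, with thickness proportional to the strength of the
association (the larger directed value when both directions qualify).
"Perfect" associations get their own colours — magenta for an infinite
odds ratio, black for zero — rather than extreme thickness.

Node placement is a seeded force-directed layout in which attraction
acts only along substantial-association edges, weighted by |ln OR|, so
mutually associated clusters sit together; any subset of positions can
be pinned by hand, reproducing publication-style manual arrangements,
and layouts are import/exportable as coordinate tables so the same
arrangement can be reused across habitat subsets.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from matplotlib.lines import Line2D
from matplotlib.patches import FancyArrowPatch

from .assemble import AssociationNetwork, edge_display_weight

__all__ = [
    "DiagramStyle",
    "assign_node_band",
    "layout_nodes",
    "render_diagram",
    "save_layout",
    "load_layout",
]

# byte-stable SVG output: fixed hash salt instead of a per-process one
matplotlib.rcParams["svg.hashsalt"] = "pairodds"


@dataclass(frozen=True)
class DiagramStyle:
    """Colours, prevalence bands and scaling of the association diagram."""

    band_edges: tuple[float, ...] = (0.036, 0.10, 0.25, 0.50, 0.75)
    band_colors: tuple[str, ...] = ("blue", "green", "yellow", "tan", "orange", "red")
    indication_color: str = "red"
    contraindication_color: str = "blue"
    infinite_color: str = "magenta"
    zero_color: str = "black"
    thickness_scale: float = 0.35
    node_size: float = 600.0

    def __post_init__(self) -> None:
        edges = self.band_edges
        if any(not 0.0 < e < 1.0 for e in edges) or list(edges) != sorted(set(edges)):
            raise ValueError("band_edges must be strictly increasing within (0, 1)")
        if len(self.band_colors) != len(edges) + 1:
            raise ValueError("need exactly one more colour than band edges")
        if self.thickness_scale <= 0:
            raise ValueError("thickness_scale must be positive")


def assign_node_band(prevalence: float, style: DiagramStyle = DiagramStyle()) -> str:
    """Colour band for a node's prevalence.

    Bands are half-open, upper-inclusive: with the default edges,
    [0, 0.036] blue, (0.036, 0.10] green, (0.10, 0.25] yellow,
    (0.25, 0.50] light brown, (0.50, 0.75] orange, (0.75, 1] red.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    idx = int(np.searchsorted(style.band_edges, prevalence, side="left"))
    return style.band_colors[idx]


def _edge_weight(or_value: float, cap: float = math.log(1000.0)) -> float:
    """Layout attraction weight |ln OR|, capped for zero/infinite ORs."""
    if or_value == 0.0 or math.isinf(or_value):
        return cap
    return min(abs(math.log(or_value)), cap)


def layout_nodes(
    network: AssociationNetwork,
    seed: int = 0,
    fixed_positions: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Seeded force-directed node placement.

    Attraction acts only along classified (substantial) edges, with
    weight |ln OR| so stronger associations pull harder; unconnected
    species drift to the periphery. Entries of ``fixed_positions`` are
    pinned. Deterministic for a given network and seed.
    """
    species = network.species
    if not species:
        raise ValueError("cannot lay out an empty network")
    if len(species) == 1:
        name = species[0]
        if fixed_positions and name in fixed_positions:
            return {name: tuple(fixed_positions[name])}
        return {name: (0.0, 0.0)}
    g = nx.Graph()
    g.add_nodes_from(species)
    for e in network.edges:
        w = _edge_weight(e.or_value)
        if g.has_edge(e.predictor, e.target):
            g[e.predictor][e.target]["weight"] = max(
                g[e.predictor][e.target]["weight"], w
            )
        else:
            g.add_edge(e.predictor, e.target, weight=w)
    fixed = None
    pos = None
    if fixed_positions:
        pos = {s: tuple(xy) for s, xy in fixed_positions.items()}
        fixed = [s for s in pos if s in g]
        if set(fixed) == set(species):
            return {s: pos[s] for s in species}
        for s in species:  # spring_layout needs an initial guess for all
            if s not in pos:
                pos[s] = None
        pos = {s: xy for s, xy in pos.items() if xy is not None}
        fixed = fixed or None
    layout = nx.spring_layout(g, weight="weight", seed=seed, pos=pos, fixed=fixed)
    return {s: (float(x), float(y)) for s, (x, y) in layout.items()}


def save_layout(positions: Mapping[str, tuple[float, float]], path) -> None:
    """Write positions as a species,x,y coordinate table."""
    frame = pd.DataFrame(
        {"species": list(positions), "x": [p[0] for p in positions.values()],
         "y": [p[1] for p in positions.values()]}
    )
    frame.to_csv(path, index=False)


def load_layout(path) -> dict[str, tuple[float, float]]:
    frame = pd.read_csv(path)
    return {
        str(r.species): (float(r.x), float(r.y)) for r in frame.itertuples(index=False)
    }


def _paired_weights(network: AssociationNetwork) -> dict[tuple[str, str], float]:
    """Display weight per unordered pair (max rule over both directions)."""
    by_pair: dict[tuple[str, str], list[float]] = {}
    for e in network.edges:
        key = tuple(sorted((e.predictor, e.target)))
        by_pair.setdefault(key, []).append(e.or_value)
    cfg = network.config
    return {
        key: edge_display_weight(
            vals[0], vals[1] if len(vals) > 1 else None,
            or_upper=cfg.or_upper, or_lower=cfg.or_lower,
        )
        for key, vals in by_pair.items()
    }


def render_diagram(
    network: AssociationNetwork,
    positions: Mapping[str, tuple[float, float]] | None = None,
    style: DiagramStyle = DiagramStyle(),
    output_path=None,
    *,
    seed: int = 0,
    labels: bool = True,
) -> dict:
    """Draw the association diagram and return a summary of drawn elements.

    Arrows point from predictor to target. Thickness is
    ``thickness_scale`` times the pair's display weight; infinite-OR
    edges are drawn at the 99th percentile of the finite weights in
    their own colour. Output format follows the file extension
    (``.svg``/``.pdf`` vector, ``.png`` raster); vector output is
    byte-stable for identical inputs. The returned summary counts drawn
    arrows by class and colour, one entry per classified edge.
    """
    if positions is None:
        positions = layout_nodes(network, seed=seed)
    missing = [s for s in network.species if s not in positions]
    if missing:
        raise ValueError(f"positions missing for species: {missing[:5]}")
    t0 = time.perf_counter()
    pair_weight = _paired_weights(network)
    finite = [w for w in pair_weight.values() if math.isfinite(w)]
    inf_weight = float(np.percentile(finite, 99)) if finite else network.config.or_upper

    fig, ax = plt.subplots(figsize=(9, 9))
    ax.set_axis_off()
    ax.set_aspect("equal")

    drawn = {"indication": 0, "contraindication": 0, "infinite": 0, "zero": 0}
    arrows = []
    for e in sorted(
        network.edges, key=lambda e: (e.predictor, e.target)
    ):  # stable draw order for reproducible output
        if e.is_zero:
            color = style.zero_color
            drawn["zero"] += 1
        elif e.is_infinite:
            color = style.infinite_color
            drawn["infinite"] += 1
        elif e.kind == "indication":
            color = style.indication_color
            drawn["indication"] += 1
        else:
            color = style.contraindication_color
            drawn["contraindication"] += 1
        w = pair_weight[tuple(sorted((e.predictor, e.target)))]
        lw = style.thickness_scale * (inf_weight if math.isinf(w) else w)
        p0 = positions[e.predictor]
        p1 = positions[e.target]
        patch = FancyArrowPatch(
            p0,
            p1,
            arrowstyle="-|>",
            mutation_scale=12,
            linewidth=max(lw, 0.4),
            color=color,
            shrinkA=10,
            shrinkB=10,
            connectionstyle="arc3,rad=0.08",
            zorder=1,
        )
        ax.add_patch(patch)
        arrows.append((e.predictor, e.target, color))

    xs = [positions[s][0] for s in network.species]
    ys = [positions[s][1] for s in network.species]
    colors = [
        assign_node_band(network.nodes.loc[s, "prevalence"], style)
        if not math.isnan(network.nodes.loc[s, "prevalence"])
        else "lightgrey"
        for s in network.species
    ]
    ax.scatter(xs, ys, s=style.node_size, c=colors, edgecolors="black", zorder=2)
    if labels:
        for s in network.species:
            ax.annotate(
                s, positions[s], ha="center", va="center", fontsize=7, zorder=3
            )

    band_labels = _band_labels(style)
    handles = [
        Line2D([], [], marker="o", linestyle="", markerfacecolor=c,
               markeredgecolor="black", label=lbl)
        for c, lbl in zip(style.band_colors, band_labels)
    ]
    handles += [
        Line2D([], [], color=style.indication_color, label="indication (OR > upper)"),
        Line2D([], [], color=style.contraindication_color,
               label="contraindication (OR < lower)"),
        Line2D([], [], color=style.infinite_color, label="infinite OR"),
        Line2D([], [], color=style.zero_color, label="zero OR"),
    ]
    ax.legend(handles=handles, loc="lower left", fontsize=7, framealpha=0.9)
    ax.relim()
    ax.autoscale_view()

    if output_path is not None:
        fig.savefig(output_path, bbox_inches="tight", metadata=_stable_metadata(output_path))
    plt.close(fig)
    drawn["arrows"] = arrows
    drawn["n_nodes"] = len(network.species)
    drawn["seconds"] = time.perf_counter() - t0
    return drawn


def _band_labels(style: DiagramStyle) -> list[str]:
    edges = [0.0, *style.band_edges, 1.0]
    return [
        f"{lo:.1%}-{hi:.1%} presence" for lo, hi in zip(edges[:-1], edges[1:])
    ]


def _stable_metadata(path) -> dict | None:
    """Strip timestamps so vector output is reproducible byte-for-byte."""
    p = str(path).lower()
    if p.endswith(".svg"):
        return {"Date": None}
    if p.endswith(".pdf"):
        return {"CreationDate": None}
    return None
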
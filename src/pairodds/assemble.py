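"""Assemble pairwise estimates into a directed association network.

Species below a prevalence floor (10% of surveys by default) are dropped
before estimation; among the retained species, a directed estimate with
OR > 3 becomes an *indication* edge and one with OR < 1/3 a
*contraindication* edge (strict inequalities; the thresholds mark an
ecologically substantial association and are configurable). Edges keep
both an unadjusted significance flag (Wald p < alpha) and a conservative
Bonferroni flag at alpha / n, where n is the number of retained species:
the n(n-1) odds ratios are strongly intercorrelated, being derived from
just n presence variables, so dividing by the pair count would
overcorrect (a pairs divisor is available as an option). Non-significant
substantial edges stay in the network carrying their flags — the diagram
is drawn from the OR criterion, with significance reported alongside.

Zero and infinite odds ratios are kept as special edges ("perfect"
contraindication / indication, drawn black / magenta) with undefined
standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import networkx as nx
import pandas as pd

from .estimation import PairEstimate, SurveyTable, estimates_to_frame

__all__ = [
    "AssemblyConfig",
    "AssociationEdge",
    "AssociationNetwork",
    "filter_by_prevalence",
    "classify_edges",
    "edge_display_weight",
]


@dataclass(frozen=True)
class AssemblyConfig:
    """Thresholds and multiplicity handling for network assembly."""

    prevalence_min: float = 0.10
    or_upper: float = 3.0
    or_lower: float = 1.0 / 3.0
    alpha: float = 0.05
    multiplicity: Literal["none", "bonferroni_by_species", "bonferroni_by_pairs"] = (
        "bonferroni_by_species"
    )
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.or_lower < 1.0 < self.or_upper):
            raise ValueError("need 0 < or_lower < 1 < or_upper")
        if not 0.0 < self.prevalence_min < 1.0:
            raise ValueError("prevalence_min must be in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def adjusted_alpha(self, n_species: int) -> float:
        """Per-test cutoff after the configured multiplicity adjustment."""
        if self.multiplicity == "none":
            return self.alpha
        if self.multiplicity == "bonferroni_by_species":
            return self.alpha / n_species
        if self.multiplicity == "bonferroni_by_pairs":
            return self.alpha / (n_species * (n_species - 1))
        raise ValueError(f"unknown multiplicity rule {self.multiplicity!r}")


@dataclass(frozen=True)
class AssociationEdge:
    """A classified directed association (predictor -> target arrow)."""

    predictor: str
    target: str
    kind: Literal["indication", "contraindication"]
    or_value: float
    log_or_se: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    significant_adjusted: bool
    is_zero: bool = False
    is_infinite: bool = False


@dataclass
class AssociationNetwork:
    """Filtered species set plus classified directed edges."""

    nodes: pd.DataFrame  # index: species; columns: prevalence
    edges: list[AssociationEdge]
    config: AssemblyConfig
    estimator: str = ""

    @property
    def species(self) -> list[str]:
        return list(self.nodes.index)

    @property
    def n_indications(self) -> int:
        return sum(e.kind == "indication" for e in self.edges)

    @property
    def n_contraindications(self) -> int:
        return sum(e.kind == "contraindication" for e in self.edges)

    def edge_frame(self) -> pd.DataFrame:
        """Flat directed edge list (one row per classified association)."""
        return pd.DataFrame(
            {
                "target": [e.target for e in self.edges],
                "predictor": [e.predictor for e in self.edges],
                "odds_ratio": [e.or_value for e in self.edges],
                "log_or_se": [e.log_or_se for e in self.edges],
                "ci_low": [e.ci_low for e in self.edges],
                "ci_high": [e.ci_high for e in self.edges],
                "p_value": [e.p_value for e in self.edges],
                "class": [e.kind for e in self.edges],
                "significant": [e.significant for e in self.edges],
                "significant_adjusted": [e.significant_adjusted for e in self.edges],
                "zero_or": [e.is_zero for e in self.edges],
                "infinite_or": [e.is_infinite for e in self.edges],
            }
        )

    def node_frame(self) -> pd.DataFrame:
        return self.nodes.reset_index(names="species")

    def to_graph(self) -> nx.DiGraph:
        """networkx digraph (edges run predictor -> target)."""
        g = nx.DiGraph(estimator=self.estimator)
        for sp, row in self.nodes.iterrows():
            g.add_node(sp, prevalence=float(row["prevalence"]))
        for e in self.edges:
            g.add_edge(
                e.predictor,
                e.target,
                kind=e.kind,
                odds_ratio=e.or_value,
                p_value=e.p_value,
                significant=e.significant,
                significant_adjusted=e.significant_adjusted,
                zero_or=e.is_zero,
                infinite_or=e.is_infinite,
            )
        return g

    def to_graphml(self, path) -> None:
        g = self.to_graph()
        for _, _, attrs in g.edges(data=True):
            # GraphML has no infinity literal for doubles in all readers;
            # store as a very large sentinel plus the explicit flag.
            if math.isinf(attrs["odds_ratio"]):
                attrs["odds_ratio"] = 1e308
            for k, v in list(attrs.items()):
                if isinstance(v, float) and math.isnan(v):
                    attrs[k] = -1.0
        nx.write_graphml(g, path)


def filter_by_prevalence(
    data: SurveyTable, threshold: float = 0.10
) -> tuple[SurveyTable, pd.DataFrame]:
    """Retain species present in at least ``threshold`` of the surveys.

    Returns the filtered table and a report of dropped species with
    their prevalences. Applied to a subset of surveys, the prevalences
    are recomputed within that subset. ``threshold=0`` is the identity.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    prev = data.prevalence()
    keep = prev[prev >= threshold]
    dropped = prev[prev < threshold]
    report = pd.DataFrame(
        {"species": dropped.index, "prevalence": dropped.to_numpy(), "retained": False}
    )
    if len(keep) == 0:
        import warnings

        warnings.warn("no species meet the prevalence threshold", stacklevel=2)
    return data.select_species(list(keep.index)), report


def classify_edges(
    estimates: Sequence[PairEstimate],
    config: AssemblyConfig = AssemblyConfig(),
    prevalences: pd.Series | dict | None = None,
    estimator: str | None = None,
) -> AssociationNetwork:
    """Classify directed estimates into indication/contraindication edges.

    Estimates with OR strictly above ``or_upper`` become indications,
    strictly below ``or_lower`` contraindications; everything else (and
    degenerate pairs) is omitted. A pair of species that never co-occurs
    yields two zero-OR contraindication edges. Pure function of its
    inputs: identical estimates and config give an identical network.
    """
    species = sorted({e.target for e in estimates} | {e.predictor for e in estimates})
    n = len(species)
    cutoff = config.adjusted_alpha(n) if n else config.alpha
    if prevalences is None:
        prevalences = {s: math.nan for s in species}
    prev = pd.Series(prevalences, dtype=float).reindex(species)
    nodes = pd.DataFrame({"prevalence": prev})
    nodes.index.name = "species"

    edges: list[AssociationEdge] = []
    for est in estimates:
        orv = est.or_value
        if est.status == "degenerate" or math.isnan(orv):
            continue
        if orv > config.or_upper:
            kind = "indication"
        elif orv < config.or_lower:
            kind = "contraindication"
        else:
            continue
        has_p = not math.isnan(est.p_value)
        edges.append(
            AssociationEdge(
                predictor=est.predictor,
                target=est.target,
                kind=kind,
                or_value=orv,
                log_or_se=est.log_or_se,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                p_value=est.p_value,
                significant=bool(has_p and est.p_value < config.alpha),
                significant_adjusted=bool(has_p and est.p_value < cutoff),
                is_zero=orv == 0.0,
                is_infinite=math.isinf(orv),
            )
        )
    est_name = estimator if estimator is not None else (
        estimates[0].estimator if estimates else ""
    )
    return AssociationNetwork(nodes=nodes, edges=edges, config=config, estimator=est_name)


def edge_display_weight(
    or_ab: float | None,
    or_ba: float | None,
    *,
    or_upper: float = 3.0,
    or_lower: float = 1.0 / 3.0,
) -> float:
    """Scalar strength driving an edge's drawn thickness.

    The larger of the two directed values when both qualify: for
    indications the larger OR, for contraindications the larger
    reciprocal. Sign concordance guarantees a pair never has a
    qualifying indication one way and contraindication the other.
    """
    values = [v for v in (or_ab, or_ba) if v is not None and not math.isnan(v)]
    if not values:
        raise ValueError("at least one directed value is required")
    indications = [v for v in values if v > or_upper]
    contraindications = [v for v in values if v < or_lower]
    if indications and contraindications:
        raise ValueError(
            "a pair cannot carry both an indication and a contraindication"
        )
    if indications:
        return max(indications)
    if contraindications:
        strongest = min(contraindications)
        return math.inf if strongest == 0.0 else 1.0 / strongest
    raise ValueError("neither direction passes a classification threshold")
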
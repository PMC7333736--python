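"""Phase 1 — fuse TAP purification evidence with GO similarity per PPI edge.

Each PPI edge gets a GO semantic weight ``W_GO ∈ [0,1]`` and a TAP weight
``W_TAP ∈ [0,1]``.  ``W_TAP`` is the mean of the min–max-normalised LCMS and
MALDI purification scores when both exist, the available one when only one
exists, and the neutral value 0.5 when neither does (so edges missing from
TAP are unaffected).  TAP acts as a multiplicative coefficient on W_GO::

    alpha_tap = 1 + (W_TAP − 0.5) · γ        ∈ [1 − γ/2, 1 + γ/2]
    W         = alpha_tap · W_GO

γ ∈ [0,1] is the TAP impact factor: γ=0 (or the TAP-off switch) reduces W to
the pure GO weight.  TAP pairs not present in the PPI network never create
edges; only existing interactions are re-weighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import networkx as nx

from .io_formats import PPIEdgeList, TapScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedPPINetwork",
    "network_from_records",
    "normalize_tap",
    "tap_weight",
    "tap_coefficient",
    "fuse_edge_weight",
    "build_weighted_network",
]

#: Neutral TAP weight assigned to edges absent from both purification tables.
TAP_NEUTRAL = 0.5


@dataclass
class WeightedPPINetwork:
    """An undirected protein graph whose edges carry the fused weights.

    Backed by a :class:`networkx.Graph`; each edge has attributes ``w``
    (fused weight), ``w_go``, ``w_tap`` and ``alpha_tap``.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    gamma: float = 0.0

    @property
    def proteins(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_records(self) -> dict[frozenset[str], dict[str, float]]:
        """Edge → attribute mapping in the inter-stage TSV layout."""
        return {
            frozenset((a, b)): {"w": d["w"], "w_go": d["w_go"], "w_tap": d["w_tap"]}
            for a, b, d in self.graph.edges(data=True)
        }

    def induced(self, proteins: set[str]) -> "WeightedPPINetwork":
        """Subnetwork induced on ``proteins ∩ nodes`` (weights preserved)."""
        nodes = proteins & set(self.graph.nodes)
        return WeightedPPINetwork(graph=self.graph.subgraph(nodes).copy(), gamma=self.gamma)


def network_from_records(
    records: Mapping[frozenset[str], Mapping[str, float]], gamma: float = 0.0
) -> WeightedPPINetwork:
    """Rebuild a weighted network from the inter-stage edge records
    (``pair → {w, w_go, w_tap}``), e.g. after :func:`io_formats.read_weighted_edges`."""
    net = WeightedPPINetwork(gamma=gamma)
    for pair, rec in records.items():
        a, b = sorted(pair)
        net.graph.add_edge(a, b, w=rec["w"], w_go=rec["w_go"], w_tap=rec["w_tap"])
    return net


def normalize_tap(table: TapScoreTable) -> TapScoreTable:
    """Min–max normalise one TAP source into [0, 1].

    All scores equal (including a single entry) map to 1.0; an empty table is
    returned unchanged.
    """
    if not table.scores:
        return TapScoreTable(source=table.source, scores={})
    values = table.scores.values()
    lo, hi = min(values), max(values)
    if hi == lo:
        scores = {pair: 1.0 for pair in table.scores}
    else:
        scores = {pair: (s - lo) / (hi - lo) for pair, s in table.scores.items()}
    return TapScoreTable(source=table.source, scores=scores)


def tap_weight(p1: str, p2: str, lcms: TapScoreTable, maldi: TapScoreTable) -> float:
    """Combined normalised TAP weight for one pair.

    Mean of the two sources when both report the pair, the available score
    when only one does, and the neutral 0.5 when neither does.
    """
    a = lcms.get(p1, p2)
    b = maldi.get(p1, p2)
    if a is not None and b is not None:
        return (a + b) / 2.0
    if a is not None:
        return a
    if b is not None:
        return b
    return TAP_NEUTRAL


def tap_coefficient(w_tap: float, gamma: float) -> float:
    """``1 + (W_TAP − 0.5)·γ``; lies in [1 − γ/2, 1 + γ/2]."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    return 1.0 + (w_tap - 0.5) * gamma


def fuse_edge_weight(w_go: float, alpha_tap: float) -> float:
    """Final edge weight ``W = alpha_tap · W_GO``."""
    return alpha_tap * w_go


def build_weighted_network(
    ppi: PPIEdgeList,
    go_weight: Callable[[str, str], float] | Mapping[frozenset[str], float],
    lcms: TapScoreTable,
    maldi: TapScoreTable,
    gamma: float,
    tap_enabled: bool = True,
) -> WeightedPPINetwork:
    """Assemble the TAP-aware weighted PPI network.

    ``go_weight`` is either a callable ``(p1, p2) → W_GO`` or a precomputed
    pair → weight mapping (missing pairs get 0).  TAP tables are normalised
    here; with ``tap_enabled=False`` every ``alpha_tap`` is 1 and ``W`` equals
    ``W_GO`` (the GO-only ablation mode).
    """
    lcms_n = normalize_tap(lcms)
    maldi_n = normalize_tap(maldi)
    if callable(go_weight):
        get_go = go_weight
    else:
        mapping = go_weight
        get_go = lambda a, b: mapping.get(frozenset((a, b)), 0.0)  # noqa: E731

    net = WeightedPPINetwork(gamma=gamma if tap_enabled else 0.0)
    graph = net.graph
    graph.add_nodes_from(ppi.proteins)
    for pair in ppi.edges:
        a, b = sorted(pair)
        w_go = float(get_go(a, b))
        w_tap = tap_weight(a, b, lcms_n, maldi_n)
        alpha = tap_coefficient(w_tap, gamma) if tap_enabled else 1.0
        graph.add_edge(
            a, b, w=fuse_edge_weight(w_go, alpha), w_go=w_go, w_tap=w_tap, alpha_tap=alpha
        )
    return net
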
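"""Phase 3 — core–attachment complex detection on a weighted subnetwork.

Each dynamic subnetwork is mined in four deterministic steps:

1. *Seeding* — score every protein by its weighted local clustering
   coefficient ``WCC(v) = Σ_{e ∈ L} W(e) / (|L|·(|L|−1))`` where L is the set
   of edges incident to v in the graph under consideration (0 when |L| ≤ 1,
   where the formula is undefined).  Seeds are the proteins whose score
   reaches the ``alpha_seed`` quantile of the nonzero-score distribution —
   a scale-free threshold, so the same ``alpha_seed`` is meaningful across
   networks with different weight scales.  Lower ``alpha_seed`` ⇒ more seeds.
2. *Core growth* — from each seed, greedily add the neighbour with the
   largest total edge weight into the current core, accepting it only if the
   core's weighted edge density (summed intra-core edge weight over the
   number of member pairs) does not decrease.  Density, unlike the WCC of
   Eqs-style node scores, is constant across cliques of any size, so dense
   modules are grown in full while weakly attached neighbours are rejected.
3. *Attachment* — a neighbour u joins the complex if its interaction count
   with the core is at least ``beta · |core|``; higher ``beta`` ⇒ smaller
   complexes.  Attachments are judged against the original core.
4. *Redundancy filtering* — complexes are kept greedily (best score first)
   so that every kept pair has Jaccard below the redundancy threshold.

The seeding threshold, core-acceptance rule and attachment normalisation
are reconstructions: the four-step outline and the WCC formulas are given,
but the original detector's exact internal criteria are not restated here,
so this module re-uses the WCC machinery for all three (documented in
docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .weighting import WeightedPPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinComplex",
    "DetectionParams",
    "wcc_node",
    "wcc_complex",
    "select_seeds",
    "grow_core",
    "add_attachments",
    "filter_redundant",
    "detect_complexes",
]


@dataclass
class ProteinComplex:
    """A detected complex: protein set, its score, and its origin subnetwork."""

    proteins: frozenset[str]
    wcc: float = 0.0
    origin: str = ""

    def __len__(self) -> int:
        return len(self.proteins)


@dataclass
class DetectionParams:
    """Seed-quantile ``alpha_seed``, attachment threshold ``beta``, and the
    redundancy Jaccard cut-off — all in [0, 1]."""

    alpha_seed: float = 0.5
    beta: float = 0.5
    redundancy_threshold: float = 0.8

    def __post_init__(self) -> None:
        for name in ("alpha_seed", "beta", "redundancy_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def wcc_node(v: str, net: WeightedPPINetwork) -> float:
    """Weighted local clustering coefficient ``Σ W(e) / (|L|(|L|−1))``.

    L is v's incident edge set in ``net``; degree ≤ 1 scores 0 (the formula's
    denominator vanishes and such nodes carry no clustering evidence).
    """
    graph = net.graph
    if v not in graph:
        raise KeyError(f"protein {v!r} not in network")
    degree = graph.degree(v)
    if degree <= 1:
        return 0.0
    total = sum(d["w"] for _, _, d in graph.edges(v, data=True))
    return total / (degree * (degree - 1))


def wcc_complex(proteins: set[str] | frozenset[str], net: WeightedPPINetwork) -> float:
    """Complex-level score: mean node WCC over the members, edges restricted
    to pairs inside the complex.  Edgeless or empty complexes score 0."""
    members = set(proteins)
    if not members:
        return 0.0
    if not members <= set(net.graph.nodes):
        missing = members - set(net.graph.nodes)
        raise KeyError(f"proteins not in network: {sorted(missing)[:5]}")
    sub = WeightedPPINetwork(graph=net.graph.subgraph(members), gamma=net.gamma)
    # fixed summation order keeps the score bit-identical across processes
    return sum(wcc_node(v, sub) for v in sorted(members)) / len(members)


def weighted_density(proteins: set[str] | frozenset[str], net: WeightedPPINetwork) -> float:
    """Summed intra-complex edge weight over the number of member pairs.

    1.0 for a unit-weight clique of any size; 0 for fewer than two members.
    """
    members = list(proteins)
    k = len(members)
    if k < 2:
        return 0.0
    sub = net.graph.subgraph(members)
    total = sum(d["w"] for _, _, d in sub.edges(data=True))
    return total / (k * (k - 1) / 2)


def select_seeds(net: WeightedPPINetwork, alpha_seed: float) -> list[str]:
    """Proteins at or above the ``alpha_seed`` quantile of nonzero node WCC.

    Ordered by WCC descending, ties by protein ID; ``alpha_seed=0`` admits
    every protein with a nonzero score (i.e. degree ≥ 2).
    """
    scores = {v: wcc_node(v, net) for v in net.graph.nodes}
    nonzero = [s for s in scores.values() if s > 0.0]
    if not nonzero:
        return []
    cutoff = float(np.quantile(nonzero, alpha_seed))
    seeds = [v for v, s in scores.items() if s > 0.0 and s >= cutoff]
    seeds.sort(key=lambda v: (-scores[v], v))
    return seeds


def grow_core(seed: str, net: WeightedPPINetwork) -> set[str]:
    """Greedy core growth from a seed.

    Repeatedly pick the outside neighbour with the largest summed edge
    weight into the current core (ties by protein ID) and keep it only if
    the core's weighted edge density does not decrease; stop at the first
    rejection or when no neighbour remains.  The seed always stays in the
    core.
    """
    graph = net.graph
    if seed not in graph:
        raise KeyError(f"seed {seed!r} not in network")
    core: set[str] = {seed}
    current = weighted_density(core, net)
    while True:
        # candidate neighbours with their attachment weight into the core
        weights: dict[str, float] = {}
        for member in sorted(core):  # fixed order → reproducible float sums
            for u, d in graph[member].items():
                if u not in core:
                    weights[u] = weights.get(u, 0.0) + d["w"]
        if not weights:
            return core
        best = min(weights, key=lambda u: (-weights[u], u))
        candidate_score = weighted_density(core | {best}, net)
        if candidate_score >= current:
            core.add(best)
            current = candidate_score
        else:
            return core


def add_attachments(core: set[str], net: WeightedPPINetwork, beta: float) -> set[str]:
    """Attach every outside neighbour with ``|edges(u, core)| / |core| ≥ beta``.

    Candidates are evaluated against the original core (not incrementally),
    so the result does not depend on attachment order.  Returns
    ``core ∪ attachments``.
    """
    if not core:
        raise ValueError("add_attachments: core must be non-empty")
    graph = net.graph
    counts: dict[str, int] = {}
    for member in core:
        for u in graph[member]:
            if u not in core:
                counts[u] = counts.get(u, 0) + 1
    attachments = {u for u, c in counts.items() if c / len(core) >= beta}
    return set(core) | attachments


def filter_redundant(
    complexes: list[ProteinComplex], threshold: float = 0.8
) -> list[ProteinComplex]:
    """Greedy redundancy filter.

    Sorted by (WCC desc, size desc, lexicographic members), a complex is
    kept iff its Jaccard with every already-kept complex is below the
    threshold; the output is therefore pairwise non-redundant.
    """
    from .aggregation import jaccard

    ordered = sorted(
        complexes, key=lambda c: (-c.wcc, -len(c.proteins), sorted(c.proteins))
    )
    kept: list[ProteinComplex] = []
    for cand in ordered:
        if all(jaccard(cand.proteins, k.proteins) < threshold for k in kept):
            kept.append(cand)
    return kept


def detect_complexes(
    subnet: WeightedPPINetwork,
    params: DetectionParams | None = None,
    origin: str = "",
) -> list[ProteinComplex]:
    """Run the four steps (seed → core → attachments → filter) on one
    subnetwork.  Deterministic: no randomness is involved in this phase."""
    params = params or DetectionParams()
    raw: list[ProteinComplex] = []
    for seed in select_seeds(subnet, params.alpha_seed):
        core = grow_core(seed, subnet)
        members = add_attachments(core, subnet, params.beta)
        raw.append(
            ProteinComplex(
                proteins=frozenset(members),
                wcc=wcc_complex(members, subnet),
                origin=origin,
            )
        )
    return filter_redundant(raw, params.redundancy_threshold)
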
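"""Phase 4 — pool, de-duplicate and merge the per-subnetwork complex sets.

Because biclusters overlap, the same complex is often detected (fully or
partially) from several dynamic subnetworks.  The aggregation pass:

1. pools all detections into a global list G and drops complexes with fewer
   than 3 proteins;
2. passes complexes of size 3–5 straight to the final result;
3. greedily groups complexes of size ≥ 6 into *categories* such that every
   pair within a category has Jaccard similarity > 0.8;
4. reduces each category to its ``CommonPart``: first the intersection of
   all members, then every residual protein occurring in at least half of
   the members is moved in; the augmented CommonPart joins the final
   result;
5. each remaining residual protein is tried one at a time on a copy of the
   CommonPart and the enlarged complex is emitted only if its weighted
   clustering coefficient (on the full weighted network — categories mix
   subnetworks, so no single subnetwork applies) strictly exceeds the
   CommonPart's own.

The final set is de-duplicated on exact protein-set equality.  With
post-processing disabled, aggregation is the identity on G up to exact
duplicates — the ablation mode for measuring what the merge phase buys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .detection import ProteinComplex, wcc_complex
from .weighting import WeightedPPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "Category",
    "jaccard",
    "partition_global_set",
    "extract_common_part",
    "majority_augment",
    "wcc_guarded_expansion",
    "aggregate",
]

#: Similarity above which two large complexes are considered redundant.
CATEGORY_SIMILARITY = 0.8
#: Complexes smaller than this are discarded outright.
MIN_COMPLEX_SIZE = 3
#: Complexes smaller than this skip categorisation and pass through.
PASSTHROUGH_MAX_SIZE = 5


def jaccard(c1: set[str] | frozenset[str], c2: set[str] | frozenset[str]) -> float:
    """|C1 ∩ C2| / |C1 ∪ C2|; two empty sets score 0 (avoids 0/0)."""
    c1, c2 = set(c1), set(c2)
    union = c1 | c2
    if not union:
        return 0.0
    return len(c1 & c2) / len(union)


@dataclass
class Category:
    """A group of pairwise-similar (Jaccard > 0.8) large complexes.

    ``members`` are mutable protein sets consumed by the merge phases;
    ``originals`` keeps the untouched member sets for auditing.
    """

    members: list[set[str]] = field(default_factory=list)
    originals: list[frozenset[str]] = field(default_factory=list)
    common_part: set[str] = field(default_factory=set)


def partition_global_set(
    G: list[ProteinComplex],
) -> tuple[list[ProteinComplex], list[Category]]:
    """Split the pooled complex list into pass-throughs and categories.

    Complexes with < 3 proteins are removed; 3–5 go to the pass-through
    list; ≥ 6 are assigned greedily — in (size descending, lexicographic)
    order — to the first category where they exceed Jaccard 0.8 with *every*
    current member, else they open a new category.
    """
    passthrough: list[ProteinComplex] = []
    categories: list[Category] = []
    large = []
    for cpx in G:
        if len(cpx.proteins) < MIN_COMPLEX_SIZE:
            continue
        if len(cpx.proteins) <= PASSTHROUGH_MAX_SIZE:
            passthrough.append(cpx)
        else:
            large.append(cpx)
    large.sort(key=lambda c: (-len(c.proteins), sorted(c.proteins)))
    for cpx in large:
        members = set(cpx.proteins)
        for cat in categories:
            if all(jaccard(members, other) > CATEGORY_SIMILARITY for other in cat.members):
                cat.members.append(members)
                cat.originals.append(frozenset(members))
                break
        else:
            categories.append(
                Category(members=[members], originals=[frozenset(members)])
            )
    return passthrough, categories


def extract_common_part(cat: Category) -> set[str]:
    """Intersection of all members; those proteins are removed from members."""
    if not cat.members:
        raise ValueError("extract_common_part: empty category")
    common = set.intersection(*(set(m) for m in cat.members))
    for member in cat.members:
        member -= common
    cat.common_part = set(common)
    return cat.common_part


def majority_augment(cat: Category) -> set[str]:
    """Move residual proteins present in ≥ half the members into CommonPart.

    "Half" counts the category's member complexes (⌈members/2⌉); the
    augmented CommonPart is what enters the final result.
    """
    n = len(cat.members)
    counts: dict[str, int] = {}
    for member in cat.members:
        for p in member:
            counts[p] = counts.get(p, 0) + 1
    promoted = {p for p, c in counts.items() if 2 * c >= n}
    cat.common_part |= promoted
    for member in cat.members:
        member -= promoted
    return cat.common_part


def wcc_guarded_expansion(cat: Category, net: WeightedPPINetwork) -> list[frozenset[str]]:
    """Try each residual protein on a copy of the CommonPart.

    Residues are deduplicated and processed in lexicographic order; each
    candidate ``CommonPart ∪ {p}`` is emitted iff its complex WCC on ``net``
    strictly exceeds the CommonPart's.  Candidates never accumulate — every
    protein is judged against the original CommonPart — so the order cannot
    change the emitted set.  All member lists end empty.
    """
    residues = sorted({p for member in cat.members for p in member})
    for member in cat.members:
        member.clear()
    known = set(net.graph.nodes)
    if not cat.common_part <= known:
        # proteins outside the weighting network carry no edges; score them in
        base_nodes = cat.common_part & known
    else:
        base_nodes = cat.common_part
    base = wcc_complex(base_nodes, net) if base_nodes else 0.0
    emitted: list[frozenset[str]] = []
    for p in residues:
        candidate_nodes = (cat.common_part | {p}) & known
        score = wcc_complex(candidate_nodes, net) if candidate_nodes else 0.0
        if score > base:
            emitted.append(frozenset(cat.common_part | {p}))
    return emitted


def aggregate(
    G: list[ProteinComplex],
    net: WeightedPPINetwork,
    postprocessing_enabled: bool = True,
) -> list[ProteinComplex]:
    """Full aggregation of the pooled detections.

    With ``postprocessing_enabled=False``, returns G minus exact duplicate
    protein sets (the ablation mode).  Otherwise runs the size filter,
    pass-through, categorisation and the three merge phases; the final list
    is de-duplicated on exact protein-set equality and scored on ``net``.
    """
    if not postprocessing_enabled:
        out: list[ProteinComplex] = []
        seen: set[frozenset[str]] = set()
        for cpx in G:
            if cpx.proteins not in seen:
                seen.add(cpx.proteins)
                out.append(cpx)
        return out

    passthrough, categories = partition_global_set(G)
    final_sets: list[frozenset[str]] = [c.proteins for c in passthrough]
    known = set(net.graph.nodes)
    for cat in categories:
        extract_common_part(cat)
        common = majority_augment(cat)
        final_sets.append(frozenset(common))
        final_sets.extend(wcc_guarded_expansion(cat, net))
        logger.info(
            "aggregate: category of %d members → CommonPart of %d proteins",
            len(cat.originals),
            len(common),
        )
    result: list[ProteinComplex] = []
    seen = set()
    for members in final_sets:
        if len(members) < MIN_COMPLEX_SIZE or members in seen:
            continue
        seen.add(members)
        score = wcc_complex(members & known, net) if members & known else 0.0
        result.append(ProteinComplex(proteins=members, wcc=score, origin="aggregated"))
    return result
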
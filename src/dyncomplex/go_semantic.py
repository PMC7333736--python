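"""GO-based functional similarity of protein pairs (SimGIC).

The Gene Ontology is three rooted DAGs — Biological Process (BP), Cellular
Component (CC), Molecular Function (MF).  A protein annotated with a set of
terms implicitly carries every ancestor of those terms (the *closure*).  The
information content of a term is ``ic(t) = −ln p(t)`` with ``p(t)`` the
fraction of corpus proteins whose closure contains ``t``; ubiquitous terms
(the roots) have zero IC.

SimGIC scores two proteins within one aspect as the IC-weighted Jaccard of
their closures::

    simgic(a, b) = Σ_{t ∈ cl(a) ∩ cl(b)} ic(t) / Σ_{t ∈ cl(a) ∪ cl(b)} ic(t)

The per-edge GO weight ``W_GO`` averages the three aspect similarities.  When
a protein is unannotated in some aspect, that aspect is skipped and the
average runs over the aspects where both proteins are annotated (``W_GO = 0``
if there are none) — this avoids penalising sparsely annotated proteins with
arbitrary zeros.

Only ``is_a`` edges are traversed when building closures; ``part_of`` and
other relationships are ignored.  The log base of the IC cancels in the
SimGIC ratio, so natural log is used throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from .io_formats import ParseError, _data_lines

logger = logging.getLogger(__name__)

ASPECTS = ("BP", "CC", "MF")

#: GAF column 9 codes → aspect names.
_GAF_ASPECT = {"P": "BP", "C": "CC", "F": "MF"}

__all__ = [
    "ASPECTS",
    "OntologyDAG",
    "AnnotationTable",
    "ICTable",
    "MISSING",
    "load_obo",
    "read_gaf",
    "read_pair_weight_table",
    "build_closure",
    "information_content",
    "simgic",
    "go_pair_weight",
    "make_pair_weight",
    "pair_weight_from_table",
]

#: Sentinel returned by :func:`simgic` when a protein lacks annotation in the
#: requested aspect; the averaging rule in :func:`go_pair_weight` skips it.
MISSING = None


@dataclass
class OntologyDAG:
    """An is_a ontology: term → parent set, term → aspect, one root per aspect."""

    parents: dict[str, set[str]]
    aspect: dict[str, str]
    roots: dict[str, str] = field(default_factory=dict)  # aspect → root term

    def __post_init__(self) -> None:
        if not self.roots:
            for term, parent_set in self.parents.items():
                if not parent_set:
                    self.roots[self.aspect[term]] = term
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(t: str, stack: list[str]) -> None:
            if state.get(t) == 1:
                return
            if state.get(t) == 0:
                raise ValueError(f"ontology cycle through term {t!r}")
            state[t] = 0
            for p in self.parents.get(t, ()):
                visit(p, stack)
            state[t] = 1

        for term in self.parents:
            visit(term, [])

    def ancestors(self, term: str) -> set[str]:
        """The term itself plus all is_a ancestors."""
        out: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in out:
                continue
            out.add(t)
            stack.extend(self.parents.get(t, ()))
        return out


@dataclass
class AnnotationTable:
    """Direct and (optionally) closed per-aspect annotations per protein.

    ``direct[protein][aspect]`` and ``closure[protein][aspect]`` are term-ID
    sets; closure is empty until :func:`build_closure` fills it.
    """

    direct: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    closure: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add(self, protein: str, aspect: str, term: str) -> None:
        self.direct.setdefault(protein, {}).setdefault(aspect, set()).add(term)

    def closure_of(self, protein: str, aspect: str) -> set[str]:
        return self.closure.get(protein, {}).get(aspect, set())

    def annotated(self, protein: str, aspect: str) -> bool:
        return bool(self.closure_of(protein, aspect))


@dataclass
class ICTable:
    """Information content per term, natural-log units; unused terms get 0."""

    ic: dict[str, float]
    unused: set[str] = field(default_factory=set)


def load_obo(path: str | Path) -> OntologyDAG:
    """Parse an OBO file into an :class:`OntologyDAG` (is_a edges only)."""
    import obonet

    graph = obonet.read_obo(str(path))
    namespace_map = {
        "biological_process": "BP",
        "cellular_component": "CC",
        "molecular_function": "MF",
    }
    parents: dict[str, set[str]] = {}
    aspect: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns not in namespace_map:
            continue
        aspect[term] = namespace_map[ns]
        parents[term] = set()
    # obonet edges point child → parent with the relationship as the key
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a" and child in aspect and parent in aspect:
            parents[child].add(parent)
    return OntologyDAG(parents=parents, aspect=aspect)


def read_gaf(path: str | Path, dag: OntologyDAG) -> AnnotationTable:
    """Parse a GAF 2.x annotation file (columns 2=protein, 5=GO ID, 9=aspect).

    Lines starting with ``!`` or ``#`` are comments.  Annotations to terms
    absent from the ontology raise an error naming the term.
    """
    path = Path(path)
    table = AnnotationTable()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("!", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ParseError(f"{path}:{lineno}: GAF line has {len(cols)} columns, expected ≥9")
            protein, term, code = cols[1], cols[4], cols[8]
            if code not in _GAF_ASPECT:
                raise ParseError(f"{path}:{lineno}: unknown aspect code {code!r}")
            if term not in dag.aspect:
                raise ValueError(f"{path}:{lineno}: annotation to unknown term {term!r}")
            table.add(protein, _GAF_ASPECT[code], term)
    return table


def read_pair_weight_table(path: str | Path) -> dict[frozenset[str], dict[str, float]]:
    """Read a precomputed 4-column TSV ``p1 p2 aspect weight``.

    This bypasses OBO/GAF entirely for users who already ran an external
    semantic-similarity tool; returns pair → {aspect: weight}.
    """
    path = Path(path)
    out: dict[frozenset[str], dict[str, float]] = {}
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) != 4:
            raise ParseError(f"{path}:{lineno}: expected 'p1 p2 aspect weight'")
        aspect = tokens[2]
        if aspect not in ASPECTS:
            raise ParseError(f"{path}:{lineno}: unknown aspect {aspect!r}")
        try:
            weight = float(tokens[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric weight") from exc
        out.setdefault(frozenset(tokens[:2]), {})[aspect] = weight
    return out


def build_closure(dag: OntologyDAG, annotations: AnnotationTable) -> AnnotationTable:
    """Fill each protein's per-aspect ancestral closure (in place, returned).

    ``closure(p) = ∪_{t direct} ancestors-inclusive(t)`` per aspect.
    """
    cache: dict[str, set[str]] = {}
    for protein, per_aspect in annotations.direct.items():
        for aspect, terms in per_aspect.items():
            closed: set[str] = set()
            for term in terms:
                if term not in dag.aspect:
                    raise ValueError(f"annotation of {protein!r} to unknown term {term!r}")
                if term not in cache:
                    cache[term] = dag.ancestors(term)
                closed |= cache[term]
            annotations.closure.setdefault(protein, {})[aspect] = closed
    return annotations


def information_content(
    dag: OntologyDAG, annotations: AnnotationTable, corpus: set[str]
) -> ICTable:
    """Corpus-frequency IC: ``ic(t) = −ln(|{p: t ∈ closure(p)}| / |corpus|)``.

    Terms annotating no corpus protein are flagged unused and get IC 0.
    """
    if not corpus:
        raise ValueError("information_content: corpus must be non-empty")
    counts: dict[str, int] = {}
    for protein in corpus:
        seen: set[str] = set()
        for aspect in ASPECTS:
            seen |= annotations.closure_of(protein, aspect)
        for term in seen:
            counts[term] = counts.get(term, 0) + 1
    n = len(corpus)
    ic: dict[str, float] = {}
    unused: set[str] = set()
    for term in dag.aspect:
        c = counts.get(term, 0)
        if c == 0:
            ic[term] = 0.0
            unused.add(term)
        else:
            ic[term] = -math.log(c / n)
    return ICTable(ic=ic, unused=unused)


def simgic(
    p1: str, p2: str, aspect: str, annotations: AnnotationTable, ic: ICTable
) -> float | None:
    """IC-weighted Jaccard of the two closures within one aspect, in [0, 1].

    Returns :data:`MISSING` if either protein has no annotation in the
    aspect; returns 0.0 when the union carries only zero-IC terms.
    """
    cl1 = annotations.closure_of(p1, aspect)
    cl2 = annotations.closure_of(p2, aspect)
    if not cl1 or not cl2:
        return MISSING
    # summing in sorted term order makes the score exactly symmetric and
    # independent of set iteration order (hash randomisation)
    num = sum(ic.ic.get(t, 0.0) for t in sorted(cl1 & cl2))
    den = sum(ic.ic.get(t, 0.0) for t in sorted(cl1 | cl2))
    if den == 0.0:
        return 0.0
    return num / den


def go_pair_weight(
    p1: str, p2: str, annotations: AnnotationTable, ic: ICTable
) -> float:
    """Average SimGIC over the aspects where both proteins are annotated.

    With all three aspects available this is the plain mean of
    (W_BP, W_CC, W_MF); aspects where either protein is unannotated are
    skipped, and the weight is 0 when no aspect is available.
    """
    values = [
        v
        for aspect in ASPECTS
        if (v := simgic(p1, p2, aspect, annotations, ic)) is not MISSING
    ]
    if not values:
        return 0.0
    return sum(values) / len(values)


def make_pair_weight(dag: OntologyDAG, annotations: AnnotationTable, corpus: set[str]):
    """Close the annotations, compute IC over ``corpus``, and return the
    ``(p1, p2) → W_GO`` callable the weighting phase consumes."""
    build_closure(dag, annotations)
    ic = information_content(dag, annotations, corpus)
    return lambda p1, p2: go_pair_weight(p1, p2, annotations, ic)


def pair_weight_from_table(
    p1: str, p2: str, table: dict[frozenset[str], dict[str, float]]
) -> float:
    """W_GO from a precomputed per-aspect weight table (same averaging rule)."""
    per_aspect = table.get(frozenset((p1, p2)), {})
    values = [per_aspect[a] for a in ASPECTS if a in per_aspect]
    if not values:
        return 0.0
    return sum(values) / len(values)
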
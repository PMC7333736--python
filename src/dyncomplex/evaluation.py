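"""Benchmark scoring: Jaccard matching with precision / recall / F-1.

A detected complex c counts as a true detection if some benchmark complex b
has ``J(c, b) ≥ th`` (default 0.25, the conventional threshold for complex
matching); a benchmark complex counts as recovered if some detection matches
it the same way.  Matching is deliberately many-to-many — both definitions
are existential, with no one-to-one assignment — so one detection may cover
several benchmark complexes and vice versa::

    precision = |{c ∈ C : ∃ b, J(c,b) ≥ th}| / |C|
    recall    = |{b ∈ B : ∃ c, J(b,c) ≥ th}| / |B|
    F1        = 2·P·R / (P + R)        (0 when P + R = 0)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .aggregation import jaccard

__all__ = ["EvaluationResult", "evaluate"]

DEFAULT_MATCH_THRESHOLD = 0.25


@dataclass
class EvaluationResult:
    precision: float
    recall: float
    f1: float
    th: float
    matched_detected: list[frozenset[str]] = field(default_factory=list)
    matched_benchmark: list[frozenset[str]] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"precision={self.precision:.3f} recall={self.recall:.3f} "
            f"f1={self.f1:.3f} (th={self.th})"
        )


def evaluate(
    detected: Iterable[Iterable[str]],
    benchmark: Iterable[Iterable[str]],
    th: float = DEFAULT_MATCH_THRESHOLD,
) -> EvaluationResult:
    """Score a detected complex set against a benchmark catalog.

    ``th ∈ (0, 1]`` is the Jaccard matching threshold.  An empty detected
    set scores zero precision/recall; an empty benchmark is an error (the
    evaluation would be meaningless).
    """
    if not 0.0 < th <= 1.0:
        raise ValueError(f"matching threshold must be in (0, 1], got {th}")
    C = [frozenset(c) for c in detected]
    B = [frozenset(b) for b in benchmark]
    if not B:
        raise ValueError("evaluate: benchmark complex set is empty")
    matched_c = [c for c in C if any(jaccard(c, b) >= th for b in B)]
    matched_b = [b for b in B if any(jaccard(b, c) >= th for c in C)]
    precision = len(matched_c) / len(C) if C else 0.0
    recall = len(matched_b) / len(B)
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return EvaluationResult(
        precision=precision,
        recall=recall,
        f1=f1,
        th=th,
        matched_detected=matched_c,
        matched_benchmark=matched_b,
    )
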
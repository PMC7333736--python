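"""Readers and writers for the flat-file formats the pipeline consumes.

All formats are whitespace/tab-delimited text:

* PPI edge list — two or more columns, first two are protein IDs (extra
  columns, as in BioGrid exports, are ignored).
* TAP purification score table — three columns ``proteinA proteinB score``.
* Gene-expression matrix — header row of time-point labels, then one row per
  protein: ID followed by one real value per time point.
* Complex set — one complex per line, whitespace-separated protein IDs
  (CYC2008/MIPS style).
* Weighted edge table — ``p1 p2 W W_GO W_TAP``, the inter-stage format of the
  weighting phase.

Protein-ID matching throughout the package is exact, case-sensitive string
equality; no identifier mapping is attempted.  Lines starting with ``#`` are
comments and are skipped everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "TapSource",
    "PPIEdgeList",
    "TapScoreTable",
    "ComplexSetFile",
    "read_ppi_edgelist",
    "read_tap_scores",
    "read_ge_matrix",
    "write_ge_matrix",
    "read_complex_set",
    "write_complex_set",
    "read_weighted_edges",
    "write_weighted_edges",
]


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class TapSource(str, Enum):
    """The two tandem-affinity-purification score sources (LCMS and MALDI
    mass-spectrometry read-outs of the same purification screens)."""

    LCMS = "LCMS"
    MALDI = "MALDI"


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line) skipping comments/blanks."""
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


@dataclass
class PPIEdgeList:
    """An undirected, simple protein-interaction edge list.

    Invariants: no self-loops, no duplicate unordered pairs, non-empty IDs.
    """

    edges: list[frozenset[str]] = field(default_factory=list)
    proteins: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.edges)


def read_ppi_edgelist(path: str | Path) -> PPIEdgeList:
    """Load a PPI edge list, dropping self-loops and duplicate pairs.

    The first two whitespace-separated tokens of each line are protein IDs;
    any further columns are ignored.  The number of dropped self-loops and
    collapsed duplicates is logged.
    """
    path = Path(path)
    seen: set[frozenset[str]] = set()
    edges: list[frozenset[str]] = []
    proteins: set[str] = set()
    n_self, n_dup = 0, 0
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 columns, got {len(tokens)}")
        a, b = tokens[0], tokens[1]
        if a == b:
            n_self += 1
            continue
        pair = frozenset((a, b))
        if pair in seen:
            n_dup += 1
            continue
        seen.add(pair)
        edges.append(pair)
        proteins.update(pair)
    if n_self or n_dup:
        logger.info("read_ppi_edgelist(%s): dropped %d self-loops, %d duplicates", path, n_self, n_dup)
    return PPIEdgeList(edges=edges, proteins=proteins)


@dataclass
class TapScoreTable:
    """Raw or normalized purification scores for unordered protein pairs."""

    source: TapSource
    scores: dict[frozenset[str], float] = field(default_factory=dict)

    def get(self, p1: str, p2: str) -> float | None:
        return self.scores.get(frozenset((p1, p2)))

    def __len__(self) -> int:
        return len(self.scores)


def read_tap_scores(path: str | Path, source: TapSource | str) -> TapScoreTable:
    """Load a three-column TAP score table; duplicate pairs keep the maximum."""
    path = Path(path)
    source = TapSource(source)
    scores: dict[frozenset[str], float] = {}
    n_dup = 0
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns 'p1 p2 score'")
        try:
            value = float(tokens[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric score {tokens[2]!r}") from exc
        pair = frozenset((tokens[0], tokens[1]))
        if pair in scores:
            n_dup += 1
            scores[pair] = max(scores[pair], value)
        else:
            scores[pair] = value
    if n_dup:
        logger.info("read_tap_scores(%s): %d duplicate pairs collapsed (max kept)", path, n_dup)
    return TapScoreTable(source=source, scores=scores)


def read_ge_matrix(path: str | Path) -> pd.DataFrame:
    """Load a time-course expression matrix as a proteins × time-points frame.

    The first non-comment line is the header of time-point labels; each
    following line is a protein ID and one value per time point.  Ragged rows
    and duplicate protein IDs are errors.
    """
    path = Path(path)
    lines = list(_data_lines(path))
    if not lines:
        raise ParseError(f"{path}: empty expression file (no header)")
    header = lines[0][1].split()
    n = len(header)
    ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        tokens = line.split()
        pid = tokens[0]
        if len(tokens) - 1 != n:
            raise ParseError(
                f"{path}:{lineno}: protein {pid!r} has {len(tokens) - 1} values, expected {n}"
            )
        if pid in set(ids):
            raise ParseError(f"{path}:{lineno}: duplicate protein row {pid!r}")
        try:
            rows.append([float(t) for t in tokens[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric expression value") from exc
        ids.append(pid)
    frame = pd.DataFrame(rows, index=ids, columns=header, dtype=float)
    if not frame.to_numpy().size == 0 and not pd.notna(frame.to_numpy()).all():
        raise ParseError(f"{path}: non-finite expression values")
    return frame


def write_ge_matrix(ge: pd.DataFrame, path: str | Path) -> Path:
    """Write an expression matrix in the header + ID-per-row dialect."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(str(c) for c in ge.columns) + "\n")
        for pid, row in ge.iterrows():
            fh.write(str(pid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    return path


@dataclass
class ComplexSetFile:
    """A list of protein complexes, each a set of protein IDs."""

    complexes: list[set[str]] = field(default_factory=list)

    def as_frozensets(self) -> set[frozenset[str]]:
        return {frozenset(c) for c in self.complexes}

    def __len__(self) -> int:
        return len(self.complexes)


def read_complex_set(path: str | Path) -> ComplexSetFile:
    """Read one-complex-per-line files; blank lines are skipped with a log."""
    path = Path(path)
    complexes: list[set[str]] = []
    n_blank = 0
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                n_blank += 1
                continue
            complexes.append(set(line.split()))
    # only interior/trailing blanks are worth reporting; a final newline is not
    if n_blank:
        logger.info("read_complex_set(%s): %d blank lines skipped", path, n_blank)
    return ComplexSetFile(complexes=complexes)


def write_complex_set(complexes: Iterable[Iterable[str]], path: str | Path) -> Path:
    """Write complexes one per line, deterministically ordered.

    Complexes are sorted by descending size, then by the lexicographically
    first member; members within a line are sorted.  The output is
    byte-identical across runs for the same input.
    """
    path = Path(path)
    normalized = [sorted(set(c)) for c in complexes]
    normalized.sort(key=lambda members: (-len(members), members))
    with open(path, "w", encoding="utf-8") as fh:
        for members in normalized:
            fh.write(" ".join(members) + "\n")
    return path


def write_weighted_edges(
    records: Mapping[frozenset[str], Mapping[str, float]], path: str | Path
) -> Path:
    """Write the weighted-edge TSV ``p1 p2 W W_GO W_TAP`` (sorted edges)."""
    path = Path(path)
    rows = []
    for pair, rec in records.items():
        a, b = sorted(pair)
        rows.append((a, b, rec["w"], rec["w_go"], rec["w_tap"]))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#p1\tp2\tW\tW_GO\tW_TAP\n")
        for a, b, w, w_go, w_tap in rows:
            fh.write(f"{a}\t{b}\t{w:.10g}\t{w_go:.10g}\t{w_tap:.10g}\n")
    return path


def read_weighted_edges(path: str | Path) -> dict[frozenset[str], dict[str, float]]:
    """Read the weighted-edge TSV back into a pair → record mapping."""
    path = Path(path)
    records: dict[frozenset[str], dict[str, float]] = {}
    for lineno, line in _data_lines(path):
        tokens = line.split()
        if len(tokens) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 columns 'p1 p2 W W_GO W_TAP'")
        try:
            w, w_go, w_tap = (float(t) for t in tokens[2:5])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric weight") from exc
        records[frozenset(tokens[:2])] = {"w": w, "w_go": w_go, "w_tap": w_tap}
    return records
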
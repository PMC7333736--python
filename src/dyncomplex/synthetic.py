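"""Internally consistent synthetic data for every pipeline stage.

The generator plants ground truth at three levels and emits all the input
files the pipeline reads, so each stage — and the whole chain — can be
tested without downloads:

* **PPI**: dense planted complexes (near-cliques) on top of an Erdős–Rényi
  background.
* **TAP**: two purification-score tables (LCMS/MALDI dialects) whose scores
  are drawn higher for intra-complex pairs, with a configurable fraction of
  pairs missing per source.
* **GO**: a toy three-aspect ontology.  Each aspect has a root, a layer of
  "domain" terms, and "function group" terms under them; every planted
  complex gets a marker term and its members share one function group, so
  co-complex pairs are GO-coherent.  The MF aspect annotates only half of
  the proteins, exercising the missing-aspect averaging rule.
* **Expression**: a continuous matrix constructed *backwards* from a target
  binary activity pattern, so that binarisation at the configured ε recovers
  the pattern (verified post-hoc).  The pattern contains the planted
  bicluster blocks (protein block × time block, fully active by default)
  over scattered background activity.

Construction feasibility: with two-level rows (low ≈ ``low_level``, high ≈
1.0) the threshold ``|μ − σ·ε|`` separates the levels iff the row's active
fraction f satisfies ``sqrt(f/(1−f)) > ε``, i.e. ``f > ε²/(1+ε²)``; rows
with f → 1 are degenerate (σ → 0 puts the threshold inside the noise).  The
generator therefore clamps every row's active count into the feasible band
and treats the clamped pattern as the ground truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biclustering import Bicluster, binarize
from .go_semantic import ASPECTS, AnnotationTable, OntologyDAG
from .io_formats import (
    PPIEdgeList,
    TapScoreTable,
    TapSource,
    write_complex_set,
    write_ge_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["FixtureConfig", "FixtureBundle", "generate", "write_bundle"]


def _default_complexes() -> list[tuple[int, float, bool]]:
    return [(5, 1.0, True), (6, 1.0, True), (7, 0.95, True), (8, 0.95, True), (10, 0.95, True), (12, 0.95, True)]


@dataclass
class FixtureConfig:
    """Geometry and noise levels of the synthetic bundle.

    Defaults describe a small yeast-like study: 300 proteins over 12 time
    points, six planted complexes (sizes 5–12) whose members are
    co-expressed, three planted bicluster blocks of 30 proteins × 6 time
    points, a sparse interaction background, and TAP tables with a high
    missing fraction (TAP is treated as complementary evidence precisely
    because it is sparse).
    """

    n_proteins: int = 300
    #: (size, internal edge probability, GO-coherent members) per complex
    planted_complexes: list[tuple[int, float, bool]] = field(default_factory=_default_complexes)
    background_edge_prob: float = 0.005
    n_timepoints: int = 12
    #: (protein indices, time-point indices, per-cell active probability);
    #: None derives three 30-protein × 6-time-point blocks containing the
    #: planted complexes.
    planted_biclusters: list[tuple[list[int], list[int], float]] | None = None
    background_active_prob: float = 1.0 / 3.0
    tap_signal: float = 0.8
    tap_noise: float = 0.3
    tap_missing_fraction: float = 0.7
    noise_scale: float = 0.01
    low_level: float = 0.05
    epsilon: float = 0.6
    #: background proteins per GO function group
    group_size: int = 10
    rng_seed: int = 0

    def protein_names(self) -> list[str]:
        width = len(str(self.n_proteins - 1))
        return [f"P{i:0{width}d}" for i in range(self.n_proteins)]

    def timepoint_names(self) -> list[str]:
        return [f"T{j:02d}" for j in range(self.n_timepoints)]

    def validate(self) -> None:
        for name in ("background_edge_prob", "background_active_prob", "tap_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tap_signal <= self.tap_noise:
            raise ValueError("tap_signal must exceed tap_noise")
        if sum(size for size, _, _ in self.planted_complexes) > self.n_proteins:
            raise ValueError("planted complexes do not fit in n_proteins")
        for block_p, block_t, p_in in self.resolved_biclusters():
            if not block_p or not block_t:
                raise ValueError("empty bicluster block")
            if max(block_p) >= self.n_proteins or max(block_t) >= self.n_timepoints:
                raise ValueError("bicluster block exceeds matrix bounds")
            if not p_in > self.background_active_prob:
                raise ValueError("p_in must exceed background_active_prob")

    def resolved_biclusters(self) -> list[tuple[list[int], list[int], float]]:
        if self.planted_biclusters is not None:
            return self.planted_biclusters
        if self.n_proteins < 180 or self.n_timepoints < 12:
            raise ValueError(
                "default bicluster layout needs ≥180 proteins and ≥12 time points; "
                "pass planted_biclusters explicitly"
            )
        return [
            (list(range(0, 60)), [0, 1, 2, 3], 1.0),
            (list(range(60, 120)), [4, 5, 6, 7], 1.0),
            (list(range(120, 180)), [8, 9, 10, 11], 1.0),
        ]

    def complex_members(self) -> list[list[int]]:
        """Protein indices per planted complex (consecutive, adjacent
        complexes share one protein so truth complexes overlap)."""
        out = []
        start = 0
        blocks = self.resolved_biclusters()
        if self.planted_biclusters is None:
            # pack two complexes into each default block, overlapping by one
            sizes = [size for size, _, _ in self.planted_complexes]
            out = []
            for k, size in enumerate(sizes):
                block = blocks[(k // 2) % len(blocks)][0]
                offset = 0 if k % 2 == 0 else sizes[k - 1] - 1
                members = block[offset : offset + size]
                if len(members) < size:
                    raise ValueError("planted complex does not fit in its bicluster block")
                out.append(members)
            return out
        for size, _, _ in self.planted_complexes:
            out.append(list(range(start, start + size)))
            start += size
        return out


@dataclass
class FixtureBundle:
    """In-memory counterpart of the files the generator writes."""

    config: FixtureConfig
    proteins: list[str]
    ppi: PPIEdgeList
    tap_lcms: TapScoreTable
    tap_maldi: TapScoreTable
    ge: pd.DataFrame
    dag: OntologyDAG
    annotations: AnnotationTable  # direct annotations only
    truth_complexes: list[set[str]]
    truth_biclusters: list[Bicluster]
    truth_pattern: np.ndarray  # the clamped binary activity ground truth
    nge_agreement: float  # fraction of cells where binarize() recovers it


def _build_ppi(config: FixtureConfig, members: list[list[int]], names: list[str], rng: np.random.Generator) -> PPIEdgeList:
    edges: set[frozenset[str]] = set()
    for (size, p_edge, _), idx in zip(config.planted_complexes, members):
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if rng.random() < p_edge:
                    edges.add(frozenset((names[idx[a]], names[idx[b]])))
    n = config.n_proteins
    if config.background_edge_prob > 0:
        # vectorised Erdős–Rényi over the upper triangle
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < config.background_edge_prob
        for a, b in zip(iu[mask], ju[mask]):
            edges.add(frozenset((names[a], names[b])))
    proteins = set(names)  # every protein is a node, even if isolated
    edge_list = sorted(edges, key=lambda e: tuple(sorted(e)))
    return PPIEdgeList(edges=edge_list, proteins=proteins)


def _build_tap(
    config: FixtureConfig,
    ppi: PPIEdgeList,
    co_complex: set[frozenset[str]],
    source: TapSource,
    rng: np.random.Generator,
) -> TapScoreTable:
    scores: dict[frozenset[str], float] = {}
    for pair in ppi.edges:
        if rng.random() < config.tap_missing_fraction:
            continue
        mean = config.tap_signal if pair in co_complex else config.tap_noise
        scores[pair] = float(np.clip(rng.normal(mean, 0.08), 0.0, 1.5))
    return TapScoreTable(source=source, scores=scores)


def _build_ontology(
    config: FixtureConfig, members: list[list[int]], names: list[str], rng: np.random.Generator
) -> tuple[OntologyDAG, AnnotationTable]:
    parents: dict[str, set[str]] = {}
    aspect: dict[str, str] = {}
    annotations = AnnotationTable()

    in_complex = sorted({i for idx in members for i in idx})
    background = [i for i in range(config.n_proteins) if i not in set(in_complex)]

    for asp in ASPECTS:
        root = f"{asp}:0000000"
        parents[root] = set()
        aspect[root] = asp
        # background function groups sit directly under the root, so proteins
        # from different groups share only the zero-IC root (similarity 0)
        n_groups = max(1, math.ceil(len(background) / config.group_size))
        groups = []
        for g in range(n_groups):
            term = f"{asp}:2{g:06d}"
            parents[term] = {root}
            aspect[term] = asp
            groups.append(term)
        # one function-group term per complex with a marker term below it;
        # members are annotated to the marker, so co-complex closures match
        for k, (size, _, coherent) in enumerate(config.planted_complexes):
            cgroup = f"{asp}:4{k:06d}"
            parents[cgroup] = {root}
            aspect[cgroup] = asp
            marker = f"{asp}:3{k:06d}"
            parents[marker] = {cgroup}
            aspect[marker] = asp
            if not coherent:
                continue
            for i in members[k]:
                if asp == "MF" and i % 2 == 1:
                    continue  # MF annotates only even proteins (sparse aspect)
                annotations.add(names[i], asp, marker)
        # background proteins: one function group per aspect
        perm = rng.permutation(len(background))
        for pos, bi in enumerate(perm):
            i = background[bi]
            if asp == "MF" and i % 2 == 1:
                continue
            annotations.add(names[i], asp, groups[pos // config.group_size])
    dag = OntologyDAG(parents=parents, aspect=aspect)
    return dag, annotations


def _feasible_band(config: FixtureConfig) -> tuple[int, int]:
    """Smallest/largest per-row active counts that binarise cleanly."""
    n = config.n_timepoints
    eps = config.epsilon
    f_min = eps * eps / (1.0 + eps * eps)
    k_min = int(math.floor(f_min * n)) + 1
    # require a noise margin beyond the exact feasibility bound
    while k_min < n and (k_min / n - f_min) * (1.0 - config.low_level) < 4 * config.noise_scale:
        k_min += 1
    k_max = n - 1
    return k_min, k_max


def _build_pattern(config: FixtureConfig, rng: np.random.Generator) -> np.ndarray:
    """Target binary pattern: planted blocks over scattered background rows.

    Block rows are active (with probability ``p_in``) exactly on their
    block's time points; background rows get a clamped-binomial number of
    active cells at uniform positions.  Every row's active count is clamped
    into the band where the threshold ``|mu - sigma*eps|`` separates the two
    expression levels, so the pattern is recoverable by construction.
    """
    m, n = config.n_proteins, config.n_timepoints
    pattern = np.zeros((m, n), dtype=np.uint8)
    protected = np.zeros((m, n), dtype=bool)
    block_rows: set[int] = set()
    for block_p, block_t, p_in in config.resolved_biclusters():
        rows = np.asarray(block_p)
        cols = np.asarray(block_t)
        active = rng.random((rows.size, cols.size)) < p_in
        pattern[np.ix_(rows, cols)] |= active.astype(np.uint8)
        protected[np.ix_(rows, cols)] = True
        block_rows.update(block_p)
    k_min, k_max = _feasible_band(config)
    for i in range(m):
        if i not in block_rows:
            k = int(np.clip(rng.binomial(n, config.background_active_prob), k_min, k_max))
            picks = rng.choice(n, size=k, replace=False)
            pattern[i, picks] = 1
            continue
        count = int(pattern[i].sum())
        if count < k_min:
            off = np.flatnonzero(pattern[i] == 0)
            picks = rng.choice(off, size=k_min - count, replace=False)
            pattern[i, picks] = 1
        elif count > k_max:
            on = np.flatnonzero((pattern[i] == 1) & ~protected[i])
            if on.size < count - k_max:
                raise ValueError(f"row {i}: cannot clamp activity below feasible maximum")
            picks = rng.choice(on, size=count - k_max, replace=False)
            pattern[i, picks] = 0
    return pattern


def _pattern_to_expression(
    config: FixtureConfig, pattern: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    values = np.where(pattern == 1, 1.0, config.low_level)
    return values + rng.normal(0.0, config.noise_scale, size=values.shape)


def generate(config: FixtureConfig | None = None, rng_seed: int | None = None) -> FixtureBundle:
    """Build the full synthetic bundle; deterministic for a given seed."""
    config = config or FixtureConfig()
    config.validate()
    seed = config.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    names = config.protein_names()
    members = config.complex_members()

    ppi = _build_ppi(config, members, names, rng)
    co_complex = {
        frozenset((names[a], names[b]))
        for idx in members
        for a in idx
        for b in idx
        if a < b
    }
    tap_lcms = _build_tap(config, ppi, co_complex, TapSource.LCMS, rng)
    tap_maldi = _build_tap(config, ppi, co_complex, TapSource.MALDI, rng)
    dag, annotations = _build_ontology(config, members, names, rng)

    pattern = _build_pattern(config, rng)
    values = _pattern_to_expression(config, pattern, rng)
    ge = pd.DataFrame(values, index=names, columns=config.timepoint_names())
    agreement = float(
        (binarize(ge, config.epsilon).nge == pattern).mean()
    )
    if agreement < 0.95:
        logger.warning("synthetic expression binarises at only %.1f%% agreement", 100 * agreement)

    truth_complexes = [{names[i] for i in idx} for idx in members]
    tnames = config.timepoint_names()
    truth_biclusters = [
        Bicluster(
            proteins=[names[i] for i in block_p],
            timepoints=[tnames[j] for j in block_t],
            fitness=1.0,
        )
        for block_p, block_t, _ in config.resolved_biclusters()
    ]
    return FixtureBundle(
        config=config,
        proteins=names,
        ppi=ppi,
        tap_lcms=tap_lcms,
        tap_maldi=tap_maldi,
        ge=ge,
        dag=dag,
        annotations=annotations,
        truth_complexes=truth_complexes,
        truth_biclusters=truth_biclusters,
        truth_pattern=pattern,
        nge_agreement=agreement,
    )


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every bundle component in its external dialect.

    Returns a name → path mapping: ppi.tsv, tap_lcms.tsv, tap_maldi.tsv,
    ge.tsv, go.obo, annotations.gaf, truth_complexes.txt,
    truth_biclusters.tsv.  Output is byte-identical for identical bundles.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = outdir / "ppi.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("#protein_a\tprotein_b\n")
        for pair in bundle.ppi.edges:
            a, b = sorted(pair)
            fh.write(f"{a}\t{b}\n")
    paths["ppi"] = p

    for key, table in (("tap_lcms", bundle.tap_lcms), ("tap_maldi", bundle.tap_maldi)):
        p = outdir / f"{key}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("#protein_a\tprotein_b\tscore\n")
            for pair in sorted(table.scores, key=lambda e: tuple(sorted(e))):
                a, b = sorted(pair)
                fh.write(f"{a}\t{b}\t{table.scores[pair]:.6f}\n")
        paths[key] = p

    paths["ge"] = write_ge_matrix(bundle.ge, outdir / "ge.tsv")

    p = outdir / "go.obo"
    namespace = {"BP": "biological_process", "CC": "cellular_component", "MF": "molecular_function"}
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: toy\n")
        for term in sorted(bundle.dag.aspect):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            fh.write(f"namespace: {namespace[bundle.dag.aspect[term]]}\n")
            for parent in sorted(bundle.dag.parents.get(term, ())):
                fh.write(f"is_a: {parent} ! {parent}\n")
    paths["obo"] = p

    p = outdir / "annotations.gaf"
    code = {"BP": "P", "CC": "C", "MF": "F"}
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for protein in sorted(bundle.annotations.direct):
            for asp in ASPECTS:
                for term in sorted(bundle.annotations.direct[protein].get(asp, ())):
                    cols = [
                        "TOY", protein, protein, "", term, "TOY:0", "IEA", "",
                        code[asp], "", "", "protein", "taxon:4932", "20200101", "TOY",
                    ]
                    fh.write("\t".join(cols) + "\n")
    paths["gaf"] = p

    paths["truth_complexes"] = write_complex_set(
        bundle.truth_complexes, outdir / "truth_complexes.txt"
    )

    p = outdir / "truth_biclusters.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("#bicluster_id\tproteins\ttimepoints\tfitness\n")
        for k, b in enumerate(bundle.truth_biclusters):
            fh.write(f"{k}\t{','.join(sorted(b.proteins))}\t{','.join(b.timepoints)}\t{b.fitness:.6f}\n")
    paths["truth_biclusters"] = p
    return paths
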
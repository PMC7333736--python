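"""Phase 2 — binarise time-course expression and bicluster it memetically.

Binarisation is per protein (row): with row mean μ and *population* standard
deviation σ (divide by n), a cell is active (1) iff its expression is at
least the dynamic threshold ``|μ − σ·ε|``; ε ≥ 0 is a penalty factor.  The
rule depends only on the row itself, so rows binarise independently, and a
per-row affine rescaling of the data leaves the binary matrix unchanged.

Biclusters — submatrices of mostly-active cells — are searched for by a
steady-state Lamarckian memetic algorithm.  A chromosome is a binary vector
of length m+n: the first m bits select proteins (the set I), the last n bits
select time points (J).  Fitness is the active fraction of the selected
submatrix::

    F_b = Σ_{i∈I} Σ_{j∈J} [NGE[i][j] = 1] / (|I|·|J|)

(0 when I or J is empty).  Each iteration draws two parents by binary
tournament, applies two-point crossover restricted to the protein part
(probability 0.9), mutates (protein bits 0.001, time bits 0.1 — the time
part is never crossed over, so it mutates faster), hill-climbs each child
with a single randomly-ordered bit-flip pass (each bit tested with
probability 0.8, a flip kept only if fitness strictly increases), inserts
both children and removes the two worst individuals.  The locally improved
children enter the population directly — the Lamarckian scheme — so the
best fitness never decreases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .weighting import WeightedPPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryActivityMatrix",
    "Chromosome",
    "Bicluster",
    "MemeticConfig",
    "binarize",
    "fitness",
    "tournament_select",
    "two_point_crossover",
    "mutate",
    "local_search",
    "run_memetic",
    "extract_subnetwork",
]


@dataclass
class BinaryActivityMatrix:
    """Binary activity calls with the per-row statistics that produced them."""

    nge: np.ndarray  # m×n uint8
    mu: np.ndarray  # per-row mean
    sigma: np.ndarray  # per-row population SD
    epsilon: float
    proteins: list[str]
    timepoints: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.nge.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.nge, index=self.proteins, columns=self.timepoints)


def binarize(ge: pd.DataFrame, epsilon: float, prescale: bool = False) -> BinaryActivityMatrix:
    """Call each expression cell active/inactive against its row threshold.

    ``nge[i][j] = 1`` iff ``GE[i][j] ≥ |μ[i] − σ[i]·ε|`` (ties are active);
    σ is the population SD.  ``prescale`` optionally min–max rescales each
    row to [0, 1] first — a provable no-op on the binary output (the
    threshold is row-affine-equivariant), provided for parity with
    pipelines that pre-normalise expression.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be ≥ 0, got {epsilon}")
    values = ge.to_numpy(dtype=float)
    if prescale and values.size:
        lo = values.min(axis=1, keepdims=True)
        span = values.max(axis=1, keepdims=True) - lo
        span[span == 0.0] = 1.0
        values = (values - lo) / span
    mu = values.mean(axis=1)
    sigma = values.std(axis=1)  # population SD (ddof=0)
    threshold = np.abs(mu - sigma * epsilon)
    nge = (values >= threshold[:, None]).astype(np.uint8)
    return BinaryActivityMatrix(
        nge=nge,
        mu=mu,
        sigma=sigma,
        epsilon=epsilon,
        proteins=[str(p) for p in ge.index],
        timepoints=[str(t) for t in ge.columns],
    )


@dataclass(eq=False)  # identity equality: bits are numpy arrays
class Chromosome:
    """A candidate bicluster: m protein bits followed by n time-point bits."""

    bits: np.ndarray  # bool, length m+n
    m: int
    fitness: float = 0.0

    @property
    def protein_part(self) -> np.ndarray:
        return self.bits[: self.m]

    @property
    def time_part(self) -> np.ndarray:
        return self.bits[self.m :]

    def copy(self) -> "Chromosome":
        return Chromosome(bits=self.bits.copy(), m=self.m, fitness=self.fitness)

    def key(self) -> bytes:
        return self.bits.tobytes()


@dataclass
class Bicluster:
    """A decoded bicluster: protein subset I, time-point subset J, fitness."""

    proteins: list[str]
    timepoints: list[str]
    fitness: float


@dataclass
class MemeticConfig:
    """Knobs of the memetic biclusterer.

    The operator probabilities are fixed by the method (crossover 0.9,
    protein-bit mutation 0.001, time-bit mutation 0.1, local-search bit test
    0.8); population size and iteration budget are implementation defaults.
    Setting ``local_search_enabled=False`` and ``p_mut_time = p_mut_protein``
    degrades the algorithm to a plain genetic search — the ablation used to
    measure what the memetic refinement buys.
    """

    population_size: int = 100
    max_iterations: int = 2000
    fitness_goal: float = 0.95
    p_crossover: float = 0.9
    p_mut_protein: float = 0.001
    p_mut_time: float = 0.1
    p_localsearch_bit: float = 0.8
    n_biclusters: int = 10
    #: independent restarts per requested bicluster (coverage of attractors)
    restarts_per_bicluster: int = 3
    rng_seed: int = 0
    local_search_enabled: bool = True

    def validate(self) -> None:
        for name in ("p_crossover", "p_mut_protein", "p_mut_time", "p_localsearch_bit", "fitness_goal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.population_size < 4:
            raise ValueError("population_size must be ≥ 4")
        if self.max_iterations < 1 or self.n_biclusters < 1:
            raise ValueError("max_iterations and n_biclusters must be positive")
        if self.restarts_per_bicluster < 1:
            raise ValueError("restarts_per_bicluster must be positive")


def fitness(chrom: Chromosome, nge: BinaryActivityMatrix) -> float:
    """Active fraction of the selected submatrix; 0 if I or J is empty."""
    rows = chrom.protein_part
    cols = chrom.time_part
    n_i = int(rows.sum())
    n_j = int(cols.sum())
    if n_i == 0 or n_j == 0:
        return 0.0
    return float(nge.nge[np.ix_(rows, cols)].sum()) / (n_i * n_j)


def tournament_select(
    population: list[Chromosome], rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Two binary tournaments: each parent is the fitter of 2 distinct draws.

    Draws are without replacement within a tournament (the two contestants
    differ) and with replacement across the two tournaments; ties go to the
    first-drawn contestant.
    """
    if len(population) < 2:
        raise ValueError("tournament selection needs a population of ≥ 2")

    def one() -> Chromosome:
        i, j = rng.choice(len(population), size=2, replace=False)
        a, b = population[i], population[j]
        return a if a.fitness >= b.fitness else b

    return one(), one()


def two_point_crossover(
    a: Chromosome, b: Chromosome, rng: np.random.Generator, p_crossover: float = 0.9
) -> tuple[Chromosome, Chromosome]:
    """Swap a random protein-part segment between the parents.

    With probability ``p_crossover``, two distinct cut positions are drawn
    uniformly in [0, m] and the protein bits between them are exchanged; the
    time-point parts are always copied unchanged.  Otherwise the children
    are clones.
    """
    if a.bits.shape != b.bits.shape or a.m != b.m:
        raise ValueError("crossover requires equal-length chromosomes")
    c1, c2 = a.copy(), b.copy()
    if rng.random() < p_crossover and a.m >= 1:
        lo, hi = sorted(rng.choice(a.m + 1, size=2, replace=False))
        c1.bits[lo:hi], c2.bits[lo:hi] = b.bits[lo:hi].copy(), a.bits[lo:hi].copy()
    return c1, c2


def mutate(
    chrom: Chromosome,
    rng: np.random.Generator,
    p_protein: float = 0.001,
    p_time: float = 0.1,
) -> Chromosome:
    """Flip each protein bit w.p. ``p_protein`` and each time bit w.p. ``p_time``."""
    out = chrom.copy()
    m = chrom.m
    n = chrom.bits.size - m
    flips_p = rng.random(m) < p_protein
    flips_t = rng.random(n) < p_time
    out.bits[:m] ^= flips_p
    out.bits[m:] ^= flips_t
    return out


class _IncrementalFitness:
    """O(1) fitness deltas for single-bit flips of one chromosome.

    Maintains the selected-submatrix active-cell total together with per-row
    sums over the selected columns and per-column sums over the selected
    rows, so testing a flip is constant-time and applying one costs O(m) or
    O(n).
    """

    def __init__(self, bits: np.ndarray, m: int, nge: np.ndarray):
        self.nge = nge
        self.m = m
        self.rows = bits[:m].copy()
        self.cols = bits[m:].copy()
        self.row_sums = nge[:, self.cols].sum(axis=1).astype(np.int64)
        self.col_sums = nge[self.rows, :].sum(axis=0).astype(np.int64)
        self.total = int(self.row_sums[self.rows].sum())
        self.n_i = int(self.rows.sum())
        self.n_j = int(self.cols.sum())

    def value(self) -> float:
        if self.n_i == 0 or self.n_j == 0:
            return 0.0
        return self.total / (self.n_i * self.n_j)

    def flipped_value(self, bit: int) -> float:
        if bit < self.m:
            on = self.rows[bit]
            n_i = self.n_i + (-1 if on else 1)
            total = self.total + (-1 if on else 1) * int(self.row_sums[bit])
            n_j = self.n_j
        else:
            j = bit - self.m
            on = self.cols[j]
            n_j = self.n_j + (-1 if on else 1)
            total = self.total + (-1 if on else 1) * int(self.col_sums[j])
            n_i = self.n_i
        if n_i == 0 or n_j == 0:
            return 0.0
        return total / (n_i * n_j)

    def apply_flip(self, bit: int) -> None:
        if bit < self.m:
            on = self.rows[bit]
            delta = -1 if on else 1
            self.total += delta * int(self.row_sums[bit])
            self.col_sums += delta * self.nge[bit, :].astype(np.int64)
            self.rows[bit] = not on
            self.n_i += delta
        else:
            j = bit - self.m
            on = self.cols[j]
            delta = -1 if on else 1
            self.total += delta * int(self.col_sums[j])
            self.row_sums += delta * self.nge[:, j].astype(np.int64)
            self.cols[j] = not on
            self.n_j += delta

    def bits(self) -> np.ndarray:
        return np.concatenate([self.rows, self.cols])


def local_search(
    chrom: Chromosome,
    nge: BinaryActivityMatrix,
    rng: np.random.Generator,
    p_bit: float = 0.8,
) -> Chromosome:
    """One Lamarckian hill-climbing pass over the bits.

    Bits are visited once each, in a random order drawn per pass (a fixed
    left-to-right order would systematically favour low-index proteins and
    early time points, because flips are easiest to accept while the
    running fitness is still low).  Each visited bit is tested with
    probability ``p_bit``; the flip is kept only if fitness strictly
    increases.  The returned fitness is therefore never below the input
    fitness, and the pass is deterministic given the generator state.
    """
    inc = _IncrementalFitness(chrom.bits, chrom.m, nge.nge)
    current = inc.value()
    order = rng.permutation(chrom.bits.size)
    tested = rng.random(chrom.bits.size) < p_bit
    for bit in order:
        if not tested[bit]:
            continue
        candidate = inc.flipped_value(int(bit))
        if candidate > current:
            inc.apply_flip(int(bit))
            current = candidate
    return Chromosome(bits=inc.bits(), m=chrom.m, fitness=current)


def _random_chromosome(m: int, n: int, rng: np.random.Generator) -> Chromosome:
    bits = rng.random(m + n) < 0.5
    return Chromosome(bits=bits, m=m)


def decode(chrom: Chromosome, nge: BinaryActivityMatrix) -> Bicluster:
    """Chromosome → named protein/time-point subsets with its fitness."""
    proteins = [nge.proteins[i] for i in np.flatnonzero(chrom.protein_part)]
    timepoints = [nge.timepoints[j] for j in np.flatnonzero(chrom.time_part)]
    return Bicluster(proteins=proteins, timepoints=timepoints, fitness=chrom.fitness)


def _rank_key(chrom: Chromosome) -> tuple[float, int]:
    """Fitness first; ties broken by the selected submatrix area.

    Among equally pure biclusters the larger one is scientifically
    preferable (the fitness of a perfect sub-block equals that of the full
    block), so area is the natural secondary criterion wherever the method
    orders individuals by fitness alone.
    """
    area = int(chrom.protein_part.sum()) * int(chrom.time_part.sum())
    return (chrom.fitness, area)


def _memetic_run(
    nge: BinaryActivityMatrix, config: MemeticConfig, rng: np.random.Generator
) -> list[Chromosome]:
    """One steady-state run; returns the final population, best first."""
    m, n = nge.shape
    population = [_random_chromosome(m, n, rng) for _ in range(config.population_size)]
    for chrom in population:
        chrom.fitness = fitness(chrom, nge)

    for _ in range(config.max_iterations):
        p1, p2 = tournament_select(population, rng)
        c1, c2 = two_point_crossover(p1, p2, rng, config.p_crossover)
        children = [
            mutate(c, rng, config.p_mut_protein, config.p_mut_time) for c in (c1, c2)
        ]
        for child in children:
            child.fitness = fitness(child, nge)
        if config.local_search_enabled:
            children = [
                local_search(c, nge, rng, config.p_localsearch_bit) for c in children
            ]
        population.extend(children)
        population.sort(key=_rank_key, reverse=True)
        del population[-2:]
        if population[-1].fitness >= config.fitness_goal:
            break

    population.sort(key=_rank_key, reverse=True)
    return population


def run_memetic(nge: BinaryActivityMatrix, config: MemeticConfig) -> list[Bicluster]:
    """Memetic biclustering returning the top distinct biclusters.

    Each steady-state run iterates: tournament selection → protein-part
    crossover → mutation → fitness evaluation → local search (Lamarckian
    write-back) → insert the two children and drop the two worst, keeping
    the population size constant.  A run stops at ``max_iterations`` or once
    every individual's fitness reaches ``fitness_goal`` (the population has
    converged; stopping on the single best would abandon the rest of the
    population mid-search).

    Because a plain steady-state population ultimately converges on a
    single attractor, the search is restarted ``restarts_per_bicluster``
    times per requested bicluster (sub-seeds spawned deterministically from
    ``rng_seed``) and the final populations are pooled.  Degenerate
    chromosomes (empty I or J), exact duplicates, and near-duplicates of an
    already-selected bicluster (protein-set Jaccard > 0.8, the same
    redundancy notion used downstream) are dropped before taking the best
    ``n_biclusters`` by (fitness, area); fewer are returned, with a log
    message, if the pool does not contain that many distinct solutions.
    """
    from .aggregation import jaccard

    config.validate()
    n_runs = config.n_biclusters * config.restarts_per_bicluster
    seeds = np.random.SeedSequence(config.rng_seed).spawn(n_runs)
    pool: list[Chromosome] = []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        population = _memetic_run(nge, config, rng)
        pool.extend(population[: config.n_biclusters])

    pool.sort(key=_rank_key, reverse=True)
    result: list[Bicluster] = []
    seen: set[bytes] = set()
    for chrom in pool:
        if len(result) >= config.n_biclusters:
            break
        if chrom.protein_part.sum() == 0 or chrom.time_part.sum() == 0:
            continue
        key = chrom.key()
        if key in seen:
            continue
        seen.add(key)
        candidate = decode(chrom, nge)
        if any(
            jaccard(set(candidate.proteins), set(prev.proteins)) > 0.8
            for prev in result
        ):
            continue
        result.append(candidate)
    if len(result) < config.n_biclusters:
        logger.info(
            "run_memetic: only %d distinct non-degenerate biclusters available (asked for %d)",
            len(result),
            config.n_biclusters,
        )
    return result


def extract_subnetwork(bicluster: Bicluster, twppi: WeightedPPINetwork) -> WeightedPPINetwork:
    """Dynamic subnetwork: the weighted PPI induced on the bicluster proteins.

    Proteins absent from the PPI network are dropped (with a warning when
    none remain); isolated nodes are retained.
    """
    members = set(bicluster.proteins)
    subnet = twppi.induced(members)
    if members and not subnet.graph.nodes:
        logger.warning("extract_subnetwork: no bicluster protein occurs in the PPI network")
    return subnet


def write_biclusters(biclusters: list[Bicluster], path) -> None:
    """TSV dump: ``id <tab> proteins <tab> timepoints <tab> fitness``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#bicluster_id\tproteins\ttimepoints\tfitness\n")
        for k, b in enumerate(biclusters):
            fh.write(
                f"{k}\t{','.join(sorted(b.proteins))}\t{','.join(b.timepoints)}\t{b.fitness:.6f}\n"
            )


def read_biclusters(path) -> list[Bicluster]:
    """Read the bicluster TSV written by :func:`write_biclusters`."""
    out: list[Bicluster] = []
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            _, proteins, timepoints, fit = line.split("\t")
            out.append(
                Bicluster(
                    proteins=proteins.split(",") if proteins else [],
                    timepoints=timepoints.split(",") if timepoints else [],
                    fitness=float(fit),
                )
            )
    return out
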
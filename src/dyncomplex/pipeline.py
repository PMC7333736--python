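"""End-to-end orchestration of the four detection phases.

Phase 1 builds the TAP-aware weighted PPI network, phase 2 binarises the
expression matrix and biclusters it into dynamic subnetworks, phase 3 runs
core–attachment detection on each subnetwork, and phase 4 aggregates the
pooled results.  The run is deterministic for a given seed: the only
stochastic stage (the memetic biclusterer) draws from a single generator
seeded once.

Two parameter profiles mirror the published tuning for the two yeast
interaction datasets: ``dip`` (alpha_seed=0.55, beta=0.7, gamma=0.3,
epsilon=0.6, n_biclusters=27) and ``biogrid`` (0.3, 0.5, 0.4, 0.6, 30).
Three ablation switches expose the analysis modes: ``tap_enabled``
(GO-only weighting when off), ``local_search_enabled`` (plain genetic
search when off, with the time-bit mutation rate lowered to the protein
rate), and ``postprocessing_enabled`` (skip the aggregation merge when
off).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

from .aggregation import aggregate
from .biclustering import (
    BinaryActivityMatrix,
    MemeticConfig,
    binarize,
    extract_subnetwork,
    run_memetic,
)
from .detection import DetectionParams, ProteinComplex, detect_complexes
from .evaluation import EvaluationResult, evaluate
from .io_formats import PPIEdgeList, TapScoreTable
from .weighting import WeightedPPINetwork, build_weighted_network

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "PROFILES", "run_pipeline"]

#: Published per-dataset tunings: (alpha_seed, beta, gamma, epsilon, n_biclusters)
PROFILES: dict[str, dict[str, float | int]] = {
    "dip": {"alpha_seed": 0.55, "beta": 0.7, "gamma": 0.3, "epsilon": 0.6, "n_biclusters": 27},
    "biogrid": {"alpha_seed": 0.3, "beta": 0.5, "gamma": 0.4, "epsilon": 0.6, "n_biclusters": 30},
}


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run.

    ``alpha_seed`` and ``beta`` are hard-bounded to [0, 1]; values outside
    the published tuning range [0.1, 0.9] are legal but warned about.
    """

    alpha_seed: float = 0.55
    beta: float = 0.7
    gamma: float = 0.3
    epsilon: float = 0.6
    n_biclusters: int = 27
    memetic: MemeticConfig = field(default_factory=MemeticConfig)
    tap_enabled: bool = True
    postprocessing_enabled: bool = True
    local_search_enabled: bool = True
    match_threshold: float = 0.25
    rng_seed: int = 0

    @classmethod
    def from_profile(cls, profile: str, **overrides) -> "PipelineConfig":
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
        params = {**PROFILES[profile], **overrides}
        return cls(**params)  # type: ignore[arg-type]

    def validate(self) -> None:
        for name in ("alpha_seed", "beta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
            if not 0.1 <= v <= 0.9:
                logger.warning("%s=%.3f is outside the usual tuning range [0.1, 0.9]", name, v)
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be ≥ 0, got {self.epsilon}")


@dataclass
class PipelineResult:
    complexes: list[ProteinComplex]
    network: WeightedPPINetwork
    nge: BinaryActivityMatrix
    biclusters: list
    subnetwork_complexes: list[ProteinComplex]
    evaluation: EvaluationResult | None
    manifest: dict


def run_pipeline(
    ppi: PPIEdgeList,
    go_weight: Callable[[str, str], float] | Mapping,
    tap_lcms: TapScoreTable,
    tap_maldi: TapScoreTable,
    ge,
    config: PipelineConfig | None = None,
    benchmark: list[set[str]] | None = None,
) -> PipelineResult:
    """Run weighting → biclustering → detection → aggregation (→ evaluation).

    ``go_weight`` is a ``(p1, p2) → W_GO`` callable or a precomputed pair →
    weight mapping; ``ge`` is the proteins × time-points expression frame.
    When ``benchmark`` is given the final set is scored against it at
    ``config.match_threshold``.  The manifest records per-stage counts and
    wall times.
    """
    config = config or PipelineConfig()
    config.validate()
    manifest: dict = {"config": {
        "alpha_seed": config.alpha_seed, "beta": config.beta, "gamma": config.gamma,
        "epsilon": config.epsilon, "n_biclusters": config.n_biclusters,
        "tap_enabled": config.tap_enabled,
        "postprocessing_enabled": config.postprocessing_enabled,
        "local_search_enabled": config.local_search_enabled,
        "rng_seed": config.rng_seed,
    }, "stages": {}}

    def stage(name: str):
        return _StageTimer(manifest["stages"], name)

    with stage("weighting"):
        network = build_weighted_network(
            ppi, go_weight, tap_lcms, tap_maldi, config.gamma, config.tap_enabled
        )
        manifest["stages"]["weighting"]["edges"] = network.graph.number_of_edges()

    with stage("biclustering"):
        nge = binarize(ge, config.epsilon)
        mconfig = replace(
            config.memetic,
            n_biclusters=config.n_biclusters,
            rng_seed=config.rng_seed,
            local_search_enabled=config.local_search_enabled,
        )
        if not config.local_search_enabled:
            # genetic-only ablation: equalise the mutation rates as well
            mconfig = replace(mconfig, p_mut_time=mconfig.p_mut_protein)
        biclusters = run_memetic(nge, mconfig)
        manifest["stages"]["biclustering"]["biclusters"] = len(biclusters)

    with stage("detection"):
        params = DetectionParams(alpha_seed=config.alpha_seed, beta=config.beta)
        pooled: list[ProteinComplex] = []
        for k, bic in enumerate(biclusters):
            subnet = extract_subnetwork(bic, network)
            pooled.extend(detect_complexes(subnet, params, origin=f"subnetwork_{k}"))
        manifest["stages"]["detection"]["pooled_complexes"] = len(pooled)

    with stage("aggregation"):
        final = aggregate(pooled, network, config.postprocessing_enabled)
        manifest["stages"]["aggregation"]["final_complexes"] = len(final)

    result_eval = None
    if benchmark is not None:
        with stage("evaluation"):
            result_eval = evaluate(
                [c.proteins for c in final], benchmark, config.match_threshold
            )
            manifest["stages"]["evaluation"].update(
                precision=result_eval.precision,
                recall=result_eval.recall,
                f1=result_eval.f1,
            )

    return PipelineResult(
        complexes=final,
        network=network,
        nge=nge,
        biclusters=biclusters,
        subnetwork_complexes=pooled,
        evaluation=result_eval,
        manifest=manifest,
    )


class _StageTimer:
    def __init__(self, stages: dict, name: str):
        self.stages = stages
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        self.stages[self.name] = {}
        return self

    def __exit__(self, exc_type, exc, tb):
        self.stages[self.name]["seconds"] = round(time.perf_counter() - self.t0, 3)
        if exc is not None:
            raise RuntimeError(f"pipeline stage {self.name!r} failed: {exc}") from exc
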
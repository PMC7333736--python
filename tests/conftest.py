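"""Shared fixtures: one synthetic bundle and the expensive stage results.

The bundle and the memetic/pipeline runs are session-scoped because they
are deterministic for a fixed seed and several test modules assert
different properties of the same run.
"""

from __future__ import annotations

import pytest

from dyncomplex import go_semantic, pipeline, synthetic
from dyncomplex.biclustering import MemeticConfig, binarize, run_memetic


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic bundle (seed 0)."""
    return synthetic.generate(synthetic.FixtureConfig(rng_seed=0))


@pytest.fixture(scope="session")
def go_weight_fn(bundle):
    return go_semantic.make_pair_weight(
        bundle.dag, bundle.annotations, set(bundle.proteins)
    )


@pytest.fixture(scope="session")
def memetic_result(bundle):
    """Biclusters of the default bundle at the reference settings (seed 1)."""
    nge = binarize(bundle.ge, 0.6)
    return run_memetic(nge, MemeticConfig(n_biclusters=10, rng_seed=1))


@pytest.fixture(scope="session")
def pipeline_result(bundle, go_weight_fn):
    """Full pipeline on the default bundle at the reference settings."""
    config = pipeline.PipelineConfig(
        alpha_seed=0.5, beta=0.5, gamma=0.4, epsilon=0.6, n_biclusters=10, rng_seed=1
    )
    return pipeline.run_pipeline(
        bundle.ppi,
        go_weight_fn,
        bundle.tap_lcms,
        bundle.tap_maldi,
        bundle.ge,
        config,
        benchmark=bundle.truth_complexes,
    )
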
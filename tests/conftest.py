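import numpy as np
import pytest

from survnet.simulate import (
    ModuleSpec,
    PerturbationSpec,
    SimulationConfig,
    generate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def null_cohort_config(seed: int, n_genes: int = 2000) -> SimulationConfig:
    """A cohort with no planted effects of any kind."""
    return SimulationConfig(
        n_genes=n_genes,
        n_deg=0,
        modules=[],
        perturbation=PerturbationSpec(0, 0, 1, 4.0),
        seed=seed,
    )


def module_cohort_config(seed: int) -> SimulationConfig:
    """Five planted 50-gene modules (loading 0.8) among 500 genes, 19 samples."""
    return SimulationConfig(
        n_genes=500,
        n_deg=0,
        modules=[ModuleSpec(50, 0.8, 0.8, "biomarker")]
        + [ModuleSpec(50, 0.8) for _ in range(4)],
        perturbation=PerturbationSpec(0, 0, 1, 4.0),
        seed=seed,
    )


def peep_cohort_config(seed: int) -> SimulationConfig:
    """Planted per-individual perturbations at delta = 4 SD, 1000 genes."""
    return SimulationConfig(
        n_genes=1000,
        n_deg=0,
        modules=[],
        perturbation=PerturbationSpec(n_private=30, n_shared=10, share_k=5, delta=4.0),
        seed=seed,
    )


@pytest.fixture
def small_cohort():
    """A small cohort with planted DEGs and perturbations for plumbing tests."""
    cfg = SimulationConfig(
        n_genes=300,
        n_deg=20,
        modules=[],
        perturbation=PerturbationSpec(10, 5, 5, 4.0),
        seed=7,
    )
    return generate_cohort(cfg)
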
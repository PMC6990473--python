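import numpy as np
import pytest

from latticerd import (
    InitialPlacement,
    LatticeConfig,
    LoggerSpec,
    ModelConfig,
    ReactionSpec,
    SpeciesSpec,
)


@pytest.fixture
def small_lattice():
    return LatticeConfig(dims=(8, 8, 8), voxel_radius=1.0)


def build_model(
    dims=(12, 12, 12),
    r_v=5e-3,
    species=None,
    reactions=(),
    initial=(),
    loggers=None,
    t_end=1e-5,
    seed=0,
    placement_mode="fail_if_full",
):
    """Compact model builder for unit tests."""
    if loggers is None:
        loggers = [LoggerSpec(kind="numbers", interval=t_end / 10)]
    return ModelConfig(
        lattice=LatticeConfig(dims=dims, voxel_radius=r_v),
        species=list(species or [SpeciesSpec(name="A", D=1.0)]),
        reactions=list(reactions),
        initial=list(initial or [InitialPlacement(species="A", count=10)]),
        loggers=list(loggers),
        t_end=t_end,
        seed=seed,
        placement_mode=placement_mode,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
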
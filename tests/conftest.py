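"""Shared fixtures.

The trained desk-scale model is expensive (a few CPU-minutes), so it is
built once per session and shared by every test that needs inference.
"""

from __future__ import annotations

import numpy as np
import pytest

from pleuravol import PhantomSpec, PlaqueParams
from pleuravol.experiments import evaluate_desk_model, run_longitudinal_benchmark, train_desk_model

BENCH_SEED = 1


@pytest.fixture(scope="session")
def desk_weights():
    """Desk-profile U-Net trained on the seeded synthetic cohort."""
    return train_desk_model(BENCH_SEED)


@pytest.fixture(scope="session")
def desk_benchmark(desk_weights):
    """Held-out evaluation of the session model."""
    return evaluate_desk_model(desk_weights, BENCH_SEED)


@pytest.fixture(scope="session")
def longitudinal_result(desk_weights):
    """Longitudinal growth recovery with the session model."""
    return run_longitudinal_benchmark(desk_weights, BENCH_SEED)


@pytest.fixture
def one_plaque_spec() -> PhantomSpec:
    """Small exam with a single soft plaque of known geometry."""
    return PhantomSpec.desk(
        seed=11,
        plaque_params=(PlaqueParams(40.0, 90.0, 4.0, 2, 14, calcified=False, side="left"),),
    )


@pytest.fixture
def mixed_plaque_spec() -> PhantomSpec:
    """Exam with one soft and one calcified plaque."""
    return PhantomSpec.desk(
        seed=12,
        plaque_params=(
            PlaqueParams(40.0, 90.0, 4.0, 2, 14, calcified=False, side="left"),
            PlaqueParams(200.0, 70.0, 5.0, 5, 10, calcified=True, side="right"),
        ),
    )
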
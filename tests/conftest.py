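import dataclasses

import numpy as np
import pytest

from zoodemog import SilerParams
from zoodemog.synthetic import ScenarioSpec, generate_census


@pytest.fixture
def bathtub_params():
    """A generic well-behaved bathtub hazard."""
    return SilerParams(a0=0.0, a1=1.0, c=0.1, b0=-2.0, b1=0.2)


@pytest.fixture
def constant_hazard():
    """Effectively constant hazard 0.2: both exponential terms suppressed."""
    return SilerParams(a0=-30.0, a1=1.0, c=0.2, b0=-30.0, b1=0.01)


def random_valid_params(rng, n):
    """Random parameter sets inside a well-conditioned box."""
    out = []
    for _ in range(n):
        out.append(
            SilerParams(
                a0=rng.uniform(-3, 1),
                a1=rng.uniform(0.3, 2.0),
                c=rng.uniform(0.0, 0.3),
                b0=rng.uniform(-6, -2),
                b1=rng.uniform(0.05, 0.3),
            )
        )
    return out


def simple_cohort_spec(
    params: SilerParams,
    n: int,
    seed: int,
    frac_wild: float = 0.0,
    transfer_rate: float = 0.0,
    frac_unknown_birth: float = 0.0,
    **kwargs,
) -> ScenarioSpec:
    """One-period scenario with identical truth for both sexes."""
    return ScenarioSpec(
        name="test",
        true_params={"1960-2021": {"F": params, "M": params}},
        window_start=1960.0,
        window_end=2021.0,
        period_breaks=(),
        n_individuals=n,
        frac_wild=frac_wild,
        transfer_rate=transfer_rate,
        frac_unknown_birth=frac_unknown_birth,
        seed=seed,
        **kwargs,
    )


def make_cohort(params, n, seed, **kwargs):
    spec = simple_cohort_spec(params, n, seed, **kwargs)
    return generate_census(spec)
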
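import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def brute_force_loglik(
    deck_letters,
    nets,
    a,
    lam,
    A,
    c,
    payoff_scale=0.01,
    rule="as_printed",
):
    """Independent trial-by-trial recomputation of the PVL log-likelihood.

    Deliberately naive: dict-based expectancies, plain math, no stabilised
    softmax and no shared code with the package implementation.
    """
    E = {d: 0.0 for d in "ABCD"}
    ll = 0.0
    for t, (d, x) in enumerate(zip(deck_letters, nets), start=1):
        theta = 3.0**c - 1.0 if rule == "as_printed" else (t / 10.0) ** c
        w = {k: math.exp(theta * E[k]) for k in "ABCD"}
        total = sum(w.values())
        p = w[d] / total
        ll += math.log(max(p, 1e-12))
        xs = x * payoff_scale
        if xs > 0:
            u = xs**a
        elif xs == 0:
            u = 0.0
        else:
            u = -lam * abs(xs) ** a
        for k in "ABCD":
            E[k] *= A
        E[d] += u
    return ll


@pytest.fixture(scope="session")
def default_schedule():
    from pvl_igt import build_default_schedule

    return build_default_schedule()


@pytest.fixture(scope="session")
def small_cohort():
    """One default-size synthetic cohort shared across tests."""
    from pvl_igt import generate_cohort

    return generate_cohort(seed=12345)
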
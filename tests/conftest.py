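"""Shared fixtures and deterministic hypothesis settings."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import netkin
from netkin import models

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# Demonstration parameter set for the four-variable peroxidase-oxidase
# model, chosen inside its chaotic window (aperiodic bounded oscillations,
# positive largest Lyapunov exponent). Dimensionless units.
OLSEN_CHAOTIC = dict(
    k1=0.35,
    k2=250.0,
    k3=0.035,
    k4=20.0,
    k5=5.35,
    k6=1e-5,
    k7=0.1,
    k8=0.825,
    o2_feed=8.0,
    nadh_feed=1.0,
    int1_feed=1.0,
)
OLSEN_INITIAL = (4.0, 80.0, 0.01, 0.01)


@pytest.fixture(scope="session")
def diels_alder_fixture():
    return models.diels_alder()


@pytest.fixture(scope="session")
def olsen_chaotic_fixture():
    return models.olsen(**OLSEN_CHAOTIC, initial=OLSEN_INITIAL)


@pytest.fixture(scope="session")
def chapman_demo_fixture():
    """Chapman structure with synthetic order-of-magnitude parameters.

    The values are placeholders exercising the machinery (slow photolysis,
    fast recombination), not a literature parameter set.
    """
    return models.chapman(
        k1=3e-12, k2=1.0e6, k3=5.5e-4, k4=6.9e6, m=1.0,
        o2_0=1e-2, o_0=0.0, o3_0=0.0, total_time=8e7,
    )


def scheme_equilibrium_conversion(k1: float, k2: float) -> float:
    """Algebraic equilibrium root of A + B <=> C with [A]0=[B]0=1, [C]0=0.

    Solves k1 (1-c)^2 = k2 c for the physical root via a stable fixed-point
    form c = 1 - sqrt(k2 c / k1), exact for the huge k1/k2 of the
    cycloaddition fixture.
    """
    c = 1.0
    for _ in range(200):
        c_new = 1.0 - math.sqrt(k2 * c / k1)
        if abs(c_new - c) < 1e-18:
            return c_new
        c = c_new
    return c
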
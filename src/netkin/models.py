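"""Built-in kinetic models and a random-scheme generator for property tests.

The catalogue covers the classic teaching systems: exponential decay, a
two-step decay chain, a reversible isomerisation, the damped harmonic
oscillator in both its mechanical and series-RLC guises, the Diels-Alder
cycloaddition of s-cis-1,3-butadiene with ethene (rate constants computed
from transition-state free-energy barriers), the four-step Chapman mechanism
for stratospheric ozone, and the eight-step Olsen model of the chaotic
peroxidase-oxidase reaction.

Chapman and Olsen ship as structure only: their rate constants and initial
concentrations are required caller arguments, because the quantitative
parameter sets belong to the primary literature on those mechanisms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import STANDARD_TEMPERATURE
from .errors import InvalidParameterError
from .scheme import (
    KineticScheme,
    RateConstant,
    RateEquation,
    RateTerm,
    Reaction,
    Species,
    equations_from_reactions,
)
from .solver import SimulationOptions

__all__ = [
    "Fixture",
    "decay",
    "decay_chain",
    "reversible_pair",
    "oscillator",
    "diels_alder",
    "chapman",
    "olsen",
    "random_scheme",
    "catalog",
]

DIELS_ALDER_FORWARD_BARRIER = 113110.8
"""Free energy of activation of the forward cycloaddition, J/mol."""

DIELS_ALDER_REVERSE_BARRIER = 248626.4
"""Free energy of activation of the retro reaction, J/mol."""


@dataclass(frozen=True)
class Fixture:
    """A ready-to-run model: scheme, recommended options, free-form notes."""

    scheme: KineticScheme
    options: SimulationOptions
    notes: str = ""


def decay(k: float = 1.0, x0: float = 1.0) -> Fixture:
    """First-order decay A -> B with rate constant ``k`` (1/s)."""
    scheme = KineticScheme(
        species=(Species("A", x0), Species("B", 0.0)),
        constants=(RateConstant("k", k),),
        equations=tuple(
            equations_from_reactions(
                [Reaction({"A": 1}, {"B": 1}, "k")], ("A", "B")
            )
        ),
        name="decay",
    )
    return Fixture(
        scheme=scheme,
        options=SimulationOptions(total_time=5.0 / k, print_step=0.05 / k),
        notes="closed form [A](t) = [A]0 exp(-k t)",
    )


def decay_chain(
    k1: float = 1.0, k2: float = 2.0, a0: float = 1.0
) -> Fixture:
    """Sequential decay A -> B -> C; B is the canonical SSA intermediate."""
    scheme = KineticScheme(
        species=(Species("A", a0), Species("B", 0.0), Species("C", 0.0)),
        constants=(RateConstant("k1", k1), RateConstant("k2", k2)),
        equations=tuple(
            equations_from_reactions(
                [
                    Reaction({"A": 1}, {"B": 1}, "k1"),
                    Reaction({"B": 1}, {"C": 1}, "k2"),
                ],
                ("A", "B", "C"),
            )
        ),
        name="decay-chain",
    )
    return Fixture(
        scheme=scheme,
        options=SimulationOptions(total_time=5.0 / k1, print_step=0.05 / k1),
        notes="closed form B(t) = k1 a0 (e^{-k1 t} - e^{-k2 t})/(k2-k1); "
        "quasi-steady [B] ~ k1[A]/k2 when k2 >> k1",
    )


def reversible_pair(
    k_f: float = 1.0, k_r: float = 0.5, a0: float = 1.0, b0: float = 0.0
) -> Fixture:
    """Reversible isomerisation A <=> B."""
    scheme = KineticScheme(
        species=(Species("A", a0), Species("B", b0)),
        constants=(RateConstant("kf", k_f), RateConstant("kr", k_r)),
        equations=tuple(
            equations_from_reactions(
                [Reaction({"A": 1}, {"B": 1}, "kf", "kr")], ("A", "B")
            )
        ),
        name="reversible-pair",
    )
    return Fixture(
        scheme=scheme,
        options=SimulationOptions(
            total_time=10.0 / (k_f + k_r), print_step=0.1 / (k_f + k_r)
        ),
        notes="relaxes to equilibrium with rate k_f + k_r; "
        "A_eq = (kr a0 + kr b0)/(kf + kr)",
    )


def oscillator(
    m: float | None = None,
    b: float | None = None,
    k: float | None = None,
    *,
    l: float | None = None,
    r: float | None = None,
    c: float | None = None,
    x0: float = 1.0,
    v0: float = 0.0,
) -> Fixture:
    """Damped harmonic oscillator as a two-variable first-order system.

    Mechanical form ``m x'' + b x' + k x = 0`` (pass m, b, k) or the series
    RLC circuit ``L q'' + R q' + q/C = 0`` (pass l, r, c). The two
    constructors produce *identical* schemes under the textbook mapping
    m -> L, b -> R, k -> 1/C, x -> q. State variables are the coordinate
    ``x`` and velocity ``v``; b = 0 (undamped) is allowed.
    """
    mechanical = m is not None or b is not None or k is not None
    electrical = l is not None or r is not None or c is not None
    if mechanical and electrical:
        raise InvalidParameterError(
            "pass either (m, b, k) or (l, r, c), not both"
        )
    if electrical:
        if l is None or r is None or c is None:
            raise InvalidParameterError("electrical form needs l, r and c")
        if l <= 0 or c <= 0 or r < 0:
            raise InvalidParameterError("need L > 0, C > 0, R >= 0")
        m, b, k = l, r, 1.0 / c
    if m is None or b is None or k is None:
        raise InvalidParameterError("mechanical form needs m, b and k")
    if m <= 0 or k <= 0 or b < 0:
        raise InvalidParameterError(
            "need m > 0, k > 0, b >= 0 (L > 0, C > 0, R >= 0)"
        )
    constants = [RateConstant("unit", 1.0), RateConstant("w02", k / m)]
    v_terms = [RateTerm(-1, "w02", (("x", 1.0),))]
    if b > 0:
        constants.append(RateConstant("gam", b / m))
        v_terms.append(RateTerm(-1, "gam", (("v", 1.0),)))
    scheme = KineticScheme(
        species=(Species("x", x0), Species("v", v0)),
        constants=tuple(constants),
        equations=(
            RateEquation("x", (RateTerm(+1, "unit", (("v", 1.0),)),)),
            RateEquation("v", tuple(v_terms)),
        ),
        name="oscillator",
    )
    period = 2 * math.pi / math.sqrt(k / m)
    return Fixture(
        scheme=scheme,
        options=SimulationOptions(
            total_time=10 * period, print_step=period / 50
        ),
        notes="x'' + (b/m) x' + (k/m) x = 0; underdamped closed form "
        "x(t) = e^{-g t}(x0 cos wt + (v0+g x0)/w sin wt), g = b/2m, "
        "w = sqrt(k/m - g^2)",
    )


def diels_alder(temperature: float = STANDARD_TEMPERATURE) -> Fixture:
    """Diels-Alder cycloaddition A + B <=> C (butadiene + ethene -> cyclohexene).

    Forward and reverse rate constants are computed by the Eyring equation
    from the free-energy barriers 113110.8 and 248626.4 J/mol at
    ``temperature`` (default 298.15 K). Initial state [A]0 = [B]0 = 1 mol/l,
    [C]0 = 0; the recommended horizon is 1e7 s. The enormous equilibrium
    constant k1/k2 drives conversion essentially to completion.
    """
    k1 = RateConstant.from_barrier("k1", DIELS_ALDER_FORWARD_BARRIER, temperature)
    k2 = RateConstant.from_barrier("k2", DIELS_ALDER_REVERSE_BARRIER, temperature)
    scheme = KineticScheme(
        species=(Species("A", 1.0), Species("B", 1.0), Species("C", 0.0)),
        constants=(k1, k2),
        equations=tuple(
            equations_from_reactions(
                [Reaction({"A": 1, "B": 1}, {"C": 1}, "k1", "k2")],
                ("A", "B", "C"),
            )
        ),
        name="diels-alder",
    )
    return Fixture(
        scheme=scheme,
        options=SimulationOptions(total_time=1e7, print_step=5e4),
        notes="d[A]/dt = -k1[A][B] + k2[C]; [A](t) = [B](t) by symmetry; "
        "[A] + [C] = 1 mol/l conserved",
    )


def chapman(
    k1: float,
    k2: float,
    k3: float,
    k4: float,
    m: float,
    o2_0: float,
    o_0: float = 0.0,
    o3_0: float = 0.0,
    *,
    total_time: float = 1e7,
) -> Fixture:
    """Chapman mechanism for stratospheric ozone (structure only).

    Steps: (1) O2 -> 2 O (photolysis, k1); (2) O + O2 + M -> O3 + M (k2);
    (3) O3 -> O2 + O (photolysis, k3); (4) O + O3 -> 2 O2 (k4). The bath
    species M (N2/O2 stabiliser) is held constant and folded into an
    effective constant k2M = k2 * [M]. All rate constants and initial
    concentrations are caller-supplied: quantitative parameter sets belong
    to the atmospheric-chemistry literature and are not shipped.

    The resulting equations are

        d[O2]/dt = -k1[O2] - k2M[O][O2] + k3[O3] + 2 k4[O][O3]
        d[O]/dt  = 2 k1[O2] - k2M[O][O2] + k3[O3] - k4[O][O3]
        d[O3]/dt = k2M[O][O2] - k3[O3] - k4[O][O3]

    which conserve total oxygen atoms 2[O2] + [O] + 3[O3].
    """
    for name, value in (("k1", k1), ("k2", k2), ("k3", k3), ("k4", k4),
                        ("m", m)):
        if value is None:
            raise InvalidParameterError(f"chapman: missing parameter {name}")
    constants = [
        RateConstant("k1", k1),
        RateConstant("k2M", k2 * m),
        RateConstant("k3", k3),
        RateConstant("k4", k4),
    ]
    prod_oo2 = (("O", 1.0), ("O2", 1.0))
    prod_oo3 = (("O", 1.0), ("O3", 1.0))
    equations = (
        RateEquation("O2", (
            RateTerm(-1, "k1", (("O2", 1.0),)),
            RateTerm(-1, "k2M", prod_oo2),
            RateTerm(+1, "k3", (("O3", 1.0),)),
            RateTerm(+1, "k4", prod_oo3, multiplier=2.0),
        )),
        RateEquation("O", (
            RateTerm(+1, "k1", (("O2", 1.0),), multiplier=2.0),
            RateTerm(-1, "k2M", prod_oo2),
            RateTerm(+1, "k3", (("O3", 1.0),)),
            RateTerm(-1, "k4", prod_oo3),
        )),
        RateEquation("O3", (
            RateTerm(+1, "k2M", prod_oo2),
            RateTerm(-1, "k3", (("O3", 1.0),)),
            RateTerm(-1, "k4", prod_oo3),
        )),
    )
    scheme = KineticScheme(
        species=(Species("O2", o2_0), Species("O", o_0), Species("O3", o3_0)),
        constants=tuple(constants),
        equations=equations,
        name="chapman",
    )
    return Fixture(
        scheme=scheme,
        options=SimulationOptions(total_time=total_time,
                                  print_step=total_time / 400),
        notes="SSA benchmark: set d[O]/dt = d[O3]/dt = 0 with [O2] clamped "
        "and compare the algebraic [O3] with the integrated plateau",
    )


def olsen(
    k1: float,
    k2: float,
    k3: float,
    k4: float,
    k5: float,
    k6: float,
    k7: float,
    k8: float,
    o2_feed: float = 1.0,
    nadh_feed: float = 1.0,
    int1_feed: float = 1.0,
    initial: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0),
    *,
    total_time: float = 500.0,
) -> Fixture:
    """Eight-step Olsen model of the peroxidase-oxidase reaction (structure).

    Species: O2, NADH and the radical intermediates INT1, INT2. Steps 6-8
    are constant feeds: their feed levels [INT1]0, [O2]0, [NADH]0 are folded
    into effective zeroth-order constants (k6f = k6*[INT1]0, k7f = k7*[O2]0,
    k8f = k8*[NADH]0), and oxygen exchange with the gas phase contributes
    the linear -k7[O2] term. All eight rate constants are caller-supplied
    (literature parameter sets are not shipped). Equations:

        d[O2]/dt   = -k3[O2][NADH][INT2] + k7f - k7[O2]
        d[NADH]/dt = -k1[NADH][INT1] - k3[O2][NADH][INT2] + k8f
        d[INT1]/dt = k1[NADH][INT1] - 2 k2[INT1]^2
                     + 3 k3[O2][NADH][INT2] - k4[INT1] + k6f
        d[INT2]/dt = 2 k2[INT1]^2 - k3[O2][NADH][INT2] - k5[INT2]
    """
    for name, value in (("k1", k1), ("k2", k2), ("k3", k3), ("k4", k4),
                        ("k5", k5), ("k6", k6), ("k7", k7), ("k8", k8)):
        if value is None:
            raise InvalidParameterError(f"olsen: missing parameter {name}")
    tri = (("INT2", 1.0), ("NADH", 1.0), ("O2", 1.0))
    constants = (
        RateConstant("k1", k1),
        RateConstant("k2", k2),
        RateConstant("k3", k3),
        RateConstant("k4", k4),
        RateConstant("k5", k5),
        RateConstant("k6f", k6 * int1_feed),
        RateConstant("k7", k7),
        RateConstant("k7f", k7 * o2_feed),
        RateConstant("k8f", k8 * nadh_feed),
    )
    equations = (
        RateEquation("O2", (
            RateTerm(-1, "k3", tri),
            RateTerm(+1, "k7f", ()),
            RateTerm(-1, "k7", (("O2", 1.0),)),
        )),
        RateEquation("NADH", (
            RateTerm(-1, "k1", (("INT1", 1.0), ("NADH", 1.0))),
            RateTerm(-1, "k3", tri),
            RateTerm(+1, "k8f", ()),
        )),
        RateEquation("INT1", (
            RateTerm(+1, "k1", (("INT1", 1.0), ("NADH", 1.0))),
            RateTerm(-1, "k2", (("INT1", 2.0),), multiplier=2.0),
            RateTerm(+1, "k3", tri, multiplier=3.0),
            RateTerm(-1, "k4", (("INT1", 1.0),)),
            RateTerm(+1, "k6f", ()),
        )),
        RateEquation("INT2", (
            RateTerm(+1, "k2", (("INT1", 2.0),), multiplier=2.0),
            RateTerm(-1, "k3", tri),
            RateTerm(-1, "k5", (("INT2", 1.0),)),
        )),
    )
    scheme = KineticScheme(
        species=(
            Species("O2", initial[0]),
            Species("NADH", initial[1]),
            Species("INT1", initial[2]),
            Species("INT2", initial[3]),
        ),
        constants=constants,
        equations=equations,
        name="olsen",
    )
    return Fixture(
        scheme=scheme,
        options=SimulationOptions(total_time=total_time,
                                  print_step=total_time / 5000),
        notes="periodic or chaotic depending on the rate constants; "
        "time and concentrations dimensionless",
    )


def random_scheme(
    n_species: int,
    n_reactions: int | None = None,
    rate_scale_range: tuple[float, float] = (0.1, 10.0),
    rng_seed: int = 0,
    *,
    closed: bool = True,
) -> KineticScheme:
    """Reproducible random mass-action scheme for property tests.

    ``closed=True`` (default) draws reactions from count-conserving
    templates (A -> B, A + B -> C + D, 2A -> B + C and their reversible
    variants), so the all-ones weight vector is a conserved quantity, states
    stay non-negative and trajectories stay bounded — the regime the
    brute-force oracle comparisons need. ``closed=False`` adds a
    non-conserving template for structural tests. Rate constants are drawn
    log-uniformly over ``rate_scale_range``; when the scheme has at least
    two reactions the first two are pinned to the range endpoints, so a wide
    range guarantees the stated stiffness ratio by construction.
    """
    if n_species < 1:
        raise InvalidParameterError("need at least one species")
    rng = np.random.default_rng(rng_seed)
    if n_reactions is None:
        n_reactions = max(1, n_species)
    names = [f"S{i+1}" for i in range(n_species)]
    lo, hi = rate_scale_range
    log_lo, log_hi = math.log10(lo), math.log10(hi)
    rates = 10.0 ** rng.uniform(log_lo, log_hi, size=2 * n_reactions)
    if n_reactions >= 2:
        rates[0], rates[1] = lo, hi

    reactions = []
    constants = []
    k_index = 0

    def next_constant():
        nonlocal k_index
        name = f"k{k_index + 1}"
        constants.append(RateConstant(name, float(rates[k_index % rates.size])))
        k_index += 1
        return name

    templates = ["iso", "exchange", "dimer"]
    if not closed:
        templates.append("open")
    for _ in range(n_reactions):
        template = templates[rng.integers(len(templates))]
        reversible = bool(rng.integers(2))
        if template == "iso" or n_species < 3:
            a, b = rng.choice(n_species, size=2, replace=False) \
                if n_species >= 2 else (0, 0)
            if n_species == 1:
                break
            reactants, products = {names[a]: 1}, {names[b]: 1}
        elif template == "exchange" and n_species >= 4:
            a, b, c, d = rng.choice(n_species, size=4, replace=False)
            reactants = {names[a]: 1, names[b]: 1}
            products = {names[c]: 1, names[d]: 1}
        elif template == "dimer":
            a, b, c = rng.choice(n_species, size=3, replace=False)
            reactants = {names[a]: 2}
            products = {names[b]: 1, names[c]: 1}
        else:  # open: A -> 2B, breaks count conservation
            a, b = rng.choice(n_species, size=2, replace=False)
            reactants, products = {names[a]: 1}, {names[b]: 2}
        k_f = next_constant()
        k_r = next_constant() if reversible else None
        reactions.append(Reaction(reactants, products, k_f, k_r))

    species = tuple(
        Species(n, float(rng.uniform(0.2, 1.0))) for n in names
    )
    return KineticScheme(
        species=species,
        constants=tuple(constants),
        equations=tuple(equations_from_reactions(reactions, names)),
        name=f"random-{rng_seed}",
    )


def catalog() -> dict:
    """Named fixture constructors, keyed by model name."""
    return {
        "decay": decay,
        "decay_chain": decay_chain,
        "reversible_pair": reversible_pair,
        "oscillator": oscillator,
        "diels_alder": diels_alder,
        "chapman": chapman,
        "olsen": olsen,
    }
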
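"""Scheme data model, Eyring rates, reaction expansion and file round trips."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from netkin import (
    KineticScheme,
    RateConstant,
    RateEquation,
    RateTerm,
    Reaction,
    Species,
    expand_reaction,
    eyring_rate,
    read_scheme,
    write_scheme,
)
from netkin.constants import BOLTZMANN, GAS_CONSTANT, PLANCK
from netkin.errors import (
    InvalidParameterError,
    ResolutionError,
    SchemeError,
    SchemeSyntaxError,
)
from netkin import models


def eyring_reference(barrier, temperature):
    """Independent evaluation of the transition-state-theory formula."""
    return (
        1.380649e-23 * temperature / 6.62607015e-34
        * math.exp(-barrier / (8.31446261815324 * temperature))
    )


class TestEyringRate:
    @pytest.mark.parametrize(
        "barrier, expected",
        [
            (0.0, 6.212437991620116e12),  # pure k_B T / h prefactor
            (113110.8, 9.486527058123766e-08),  # forward cycloaddition
            (248626.4, 1.7210809345235516e-31),  # retro reaction
        ],
    )
    def test_printed_barriers_at_room_temperature(self, barrier, expected):
        value = eyring_rate(barrier, 298.15)
        assert value == pytest.approx(expected, rel=1e-12)
        assert value == pytest.approx(eyring_reference(barrier, 298.15), rel=1e-12)

    def test_matches_reference_formula_on_a_grid(self):
        for barrier in (-5e3, 0.0, 1e4, 1e5, 3e5):
            for temperature in (200.0, 298.15, 400.0, 1000.0):
                assert eyring_rate(barrier, temperature) == pytest.approx(
                    eyring_reference(barrier, temperature), rel=1e-12
                )

    @pytest.mark.parametrize("temperature", [0.0, -1.0, -300.0])
    def test_non_positive_temperature_rejected(self, temperature):
        with pytest.raises(InvalidParameterError):
            eyring_rate(1e4, temperature)

    def test_non_finite_barrier_rejected(self):
        with pytest.raises(InvalidParameterError):
            eyring_rate(math.nan, 298.15)

    @given(
        b1=st.floats(min_value=-1e5, max_value=3e5),
        delta=st.floats(min_value=1e-3, max_value=2e5),
        temperature=st.floats(min_value=10.0, max_value=2000.0),
    )
    def test_strictly_decreasing_in_barrier(self, b1, delta, temperature):
        from hypothesis import assume

        # stay away from exponent underflow and sub-ulp barrier differences
        assume((b1 + delta) / (GAS_CONSTANT * temperature) < 700.0)
        assume(delta / (GAS_CONSTANT * temperature) > 1e-12)
        assert eyring_rate(b1, temperature) > eyring_rate(b1 + delta, temperature)

    @given(
        barrier=st.floats(min_value=1e3, max_value=3e5),
        t1=st.floats(min_value=10.0, max_value=1000.0),
        dt=st.floats(min_value=1e-2, max_value=500.0),
    )
    def test_strictly_increasing_in_temperature_for_positive_barrier(
        self, barrier, t1, dt
    ):
        from hypothesis import assume

        assume(barrier / (GAS_CONSTANT * t1) < 700.0)
        assume(dt / t1 > 1e-12)
        assert eyring_rate(barrier, t1 + dt) > eyring_rate(barrier, t1)


class TestDomainTypes:
    def test_species_invariants(self):
        with pytest.raises(SchemeError):
            Species("has space", 1.0)
        with pytest.raises(SchemeError):
            Species("A+B", 1.0)
        with pytest.raises(SchemeError):
            Species("A", -0.1)

    def test_barrier_constant_value_must_match_eyring(self):
        ok = RateConstant.from_barrier("k", 1e4, 298.15)
        assert ok.value == pytest.approx(eyring_reference(1e4, 298.15), rel=1e-12)
        with pytest.raises(SchemeError):
            RateConstant("k", ok.value * 1.001, origin="barrier",
                         barrier=1e4, temperature=298.15)

    def test_rate_constant_must_be_positive(self):
        with pytest.raises(SchemeError):
            RateConstant("k", 0.0)
        with pytest.raises(SchemeError):
            RateConstant("k", -1.0)

    def test_reaction_coefficients_positive_integers_and_disjoint_sides(self):
        with pytest.raises(SchemeError):
            Reaction({"A": 0}, {"B": 1}, "k")
        with pytest.raises(SchemeError):
            Reaction({"A": 1.5}, {"B": 1}, "k")
        with pytest.raises(SchemeError):
            Reaction({"A": 1}, {"A": 2}, "k")

    def test_scheme_rejects_duplicate_and_unresolved_names(self):
        sp = (Species("A", 1.0),)
        k = (RateConstant("A_rate", 1.0),)
        eq = (RateEquation("A", (RateTerm(-1, "A_rate", (("A", 1.0),)),)),)
        KineticScheme(sp, k, eq)  # valid
        with pytest.raises(SchemeError):
            KineticScheme(sp, (RateConstant("A", 1.0),), eq)
        with pytest.raises(ResolutionError):
            KineticScheme(
                sp, k,
                (RateEquation("A", (RateTerm(-1, "missing", (("A", 1.0),)),)),),
            )
        with pytest.raises(ResolutionError):
            KineticScheme(sp, k, ())  # species without an equation


class TestExpandReaction:
    def test_bimolecular_reversible_association(self):
        """A + B <=> C yields the cycloaddition rate equations."""
        eqs = {e.species: e for e in expand_reaction(
            Reaction({"A": 1, "B": 1}, {"C": 1}, "k1", "k2"))}
        assert set(eqs) == {"A", "B", "C"}
        a = eqs["A"]
        assert [t.sign for t in a.terms] == [-1, +1]
        assert a.terms[0].constant == "k1"
        assert dict(a.terms[0].factors) == {"A": 1.0, "B": 1.0}
        assert a.terms[1].constant == "k2"
        assert dict(a.terms[1].factors) == {"C": 1.0}
        c = eqs["C"]
        assert [t.sign for t in c.terms] == [+1, -1]
        # A and B equations are identical term lists
        assert eqs["A"].terms == eqs["B"].terms

    def test_irreversible_single_step(self):
        eqs = {e.species: e for e in expand_reaction(
            Reaction({"A": 1}, {"B": 1}, "k"))}
        assert len(eqs["A"].terms) == 1 and len(eqs["B"].terms) == 1
        assert eqs["A"].terms[0].sign == -1
        assert eqs["B"].terms[0].sign == +1
        assert dict(eqs["B"].terms[0].factors) == {"A": 1.0}

    def test_dimerisation_carries_stoichiometric_multipliers(self):
        """2X -> Y: d[X]/dt = -2k[X]^2 while d[Y]/dt = +k[X]^2."""
        eqs = {e.species: e for e in expand_reaction(
            Reaction({"X": 2}, {"Y": 1}, "k"))}
        assert eqs["X"].terms[0].multiplier == 2.0
        assert dict(eqs["X"].terms[0].factors) == {"X": 2.0}
        assert eqs["Y"].terms[0].multiplier == 1.0

    @given(
        a=st.integers(min_value=1, max_value=3),
        b=st.integers(min_value=1, max_value=3),
        c=st.integers(min_value=1, max_value=3),
        reversible=st.booleans(),
    )
    def test_rhs_proportional_to_signed_stoichiometry(self, a, b, c, reversible):
        """All species of one step share a single scalar reaction flow:
        the rate-equation vector is (-a_i, +b_j) times one rate."""
        reaction = Reaction(
            {"R1": a, "R2": b}, {"P1": c}, "kf", "kr" if reversible else None
        )
        eqs = {e.species: e for e in expand_reaction(reaction)}
        coeffs = {"R1": -a, "R2": -b, "P1": +c}
        for name, eq in eqs.items():
            for term, ref_term in zip(eq.terms, eqs["R1"].terms):
                assert term.constant == ref_term.constant
                assert term.factors == ref_term.factors
                assert term.sign * term.multiplier == pytest.approx(
                    coeffs[name] / coeffs["R1"]
                    * ref_term.sign * ref_term.multiplier
                )


def _random_scheme_strategy():
    names = st.lists(
        st.from_regex(r"[A-Z][a-z0-9_]{0,5}", fullmatch=True),
        min_size=1, max_size=5, unique=True,
    )
    concentration = st.floats(
        min_value=0.0, max_value=1e3, allow_nan=False, allow_infinity=False
    )
    rate = st.floats(min_value=1e-12, max_value=1e12)

    @st.composite
    def build(draw):
        species_names = draw(names)
        n_constants = draw(st.integers(1, 4))
        constant_names = [f"k{i}" for i in range(n_constants)]
        species = tuple(
            Species(n, draw(concentration)) for n in species_names
        )
        constants = tuple(
            RateConstant(n, draw(rate)) for n in constant_names
        )
        equations = []
        for name in species_names:
            terms = []
            for _ in range(draw(st.integers(0, 3))):
                factors = tuple(
                    (draw(st.sampled_from(species_names)),
                     float(draw(st.sampled_from([1, 2, 3]))))
                    for _ in range(draw(st.integers(0, 2)))
                )
                terms.append(RateTerm(
                    draw(st.sampled_from([-1, +1])),
                    draw(st.sampled_from(constant_names)),
                    factors,
                    multiplier=float(draw(st.sampled_from([1, 2, 3]))),
                ))
            equations.append(RateEquation(name, tuple(terms)))
        return KineticScheme(species, constants, tuple(equations))

    return build()


class TestSchemeFile:
    def test_cycloaddition_round_trip(self, diels_alder_fixture):
        scheme = diels_alder_fixture.scheme
        assert read_scheme(write_scheme(scheme)) == scheme

    def test_peroxidase_oxidase_round_trip(self):
        from conftest import OLSEN_CHAOTIC, OLSEN_INITIAL

        scheme = models.olsen(**OLSEN_CHAOTIC, initial=OLSEN_INITIAL).scheme
        assert read_scheme(write_scheme(scheme)) == scheme

    @given(scheme=_random_scheme_strategy())
    def test_round_trip_identity_on_random_schemes(self, scheme):
        assert read_scheme(write_scheme(scheme)) == scheme

    def test_unknown_species_in_equation_names_it(self):
        text = (
            "[species]\nA = 1.0\n"
            "[constants]\nk = 1.0\n"
            "[equations]\nd[A]/dt = - k*A\nd[D]/dt = k*A\n"
        )
        with pytest.raises(ResolutionError, match="'D'"):
            read_scheme(text)

    def test_syntax_error_reports_line_number(self):
        text = "[species]\nA = 1.0\nnot a valid line without equals sign!\n"
        with pytest.raises(SchemeSyntaxError, match="line 3"):
            read_scheme(text)

    def test_duplicate_name_rejected(self):
        text = (
            "[species]\nA = 1.0\n"
            "[constants]\nA = 2.0\n"
            "[equations]\nd[A]/dt = 0\n"
        )
        with pytest.raises(SchemeError, match="duplicate"):
            read_scheme(text)

    def test_barrier_constants_survive_round_trip_exactly(self):
        scheme = models.diels_alder().scheme
        again = read_scheme(write_scheme(scheme))
        for k1, k2 in zip(scheme.constants, again.constants):
            assert k1.value == k2.value  # bit-exact
            assert k1.barrier == k2.barrier

    def test_zeroth_order_terms_round_trip(self):
        text = (
            "[species]\nA = 0.0\n"
            "[constants]\nfeed = 0.5\nk = 1.0\n"
            "[equations]\nd[A]/dt = feed - k*A\n"
        )
        scheme = read_scheme(text)
        terms = scheme.equation("A").terms
        assert terms[0].factors == ()
        assert read_scheme(write_scheme(scheme)) == scheme
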
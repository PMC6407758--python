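"""Kinetic-scheme data model and the plain-text scheme file format.

A scheme is a list of species with initial concentrations (mol/l), a list of
positive rate constants (given directly or as transition-state free-energy
barriers), and one signed mass-action rate equation per species:

    d[x_n]/dt = sum_i  s_i * m_i * k_i * prod_j [x_ij]^a_ij

with s_i = +-1 and m_i a positive stoichiometric multiplier (e.g. the 2 in
``2 k [X]^2`` for a dimerisation step). Zeroth-order terms (constant feeds)
have an empty factor list.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import BOLTZMANN, GAS_CONSTANT, PLANCK
from .errors import (
    InvalidParameterError,
    ResolutionError,
    SchemeError,
    SchemeSyntaxError,
)

__all__ = [
    "Species",
    "RateConstant",
    "RateTerm",
    "RateEquation",
    "Reaction",
    "KineticScheme",
    "eyring_rate",
    "expand_reaction",
    "equations_from_reactions",
    "read_scheme",
    "write_scheme",
]

logger = logging.getLogger(__name__)

_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")

SCHEME_FORMAT_VERSION = 1
_HEADER_RE = re.compile(r"^#\s*netkin\s+scheme\s+v(\d+)\s*$")


def _check_name(name: str, what: str) -> None:
    if not _NAME_RE.match(name):
        raise SchemeError(
            f"invalid {what} name {name!r}: must match [A-Za-z][A-Za-z0-9_]* "
            "(no whitespace or netlist-reserved characters)"
        )


def eyring_rate(barrier: float, temperature: float) -> float:
    """Transition-state-theory rate constant k = (k_B T / h) exp(-dG/(R T)).

    Parameters
    ----------
    barrier : float
        Free energy of activation dG, J/mol. Negative barriers are allowed
        (the exponential simply exceeds 1) but are logged as unusual.
    temperature : float
        Absolute temperature, K. Must be positive.

    Returns
    -------
    float
        Rate constant on the s^-1 scale, transmission coefficient 1. For
        multimolecular steps the standard-state concentration 1 mol/l is
        implied, so the value is used as-is with mol/l concentrations.
    """
    if not (temperature > 0) or not math.isfinite(temperature):
        raise InvalidParameterError(
            f"temperature must be positive and finite, got {temperature!r}"
        )
    if not math.isfinite(barrier):
        raise InvalidParameterError(f"barrier must be finite, got {barrier!r}")
    if barrier < 0:
        logger.warning("negative free-energy barrier %g J/mol", barrier)
    return BOLTZMANN * temperature / PLANCK * math.exp(
        -barrier / (GAS_CONSTANT * temperature)
    )


@dataclass(frozen=True)
class Species:
    """A chemical species and its initial concentration in mol/l."""

    name: str
    initial_concentration: float = 0.0

    def __post_init__(self):
        _check_name(self.name, "species")
        c = self.initial_concentration
        if not (c >= 0) or not math.isfinite(c):
            raise SchemeError(
                f"species {self.name!r}: initial concentration must be a "
                f"finite non-negative number, got {c!r}"
            )


@dataclass(frozen=True)
class RateConstant:
    """A positive rate constant, given directly or via an Eyring barrier.

    Units are implied by the term the constant multiplies (s^-1 for
    unimolecular terms, l mol^-1 s^-1 for bimolecular ones, ...).
    """

    name: str
    value: float
    origin: str = "direct"  # "direct" | "barrier"
    barrier: float | None = None  # dG, J/mol (iff origin == "barrier")
    temperature: float | None = None  # K (iff origin == "barrier")

    def __post_init__(self):
        _check_name(self.name, "rate constant")
        if not (self.value > 0) or not math.isfinite(self.value):
            raise SchemeError(
                f"rate constant {self.name!r}: value must be positive and "
                f"finite, got {self.value!r}"
            )
        if self.origin not in ("direct", "barrier"):
            raise SchemeError(
                f"rate constant {self.name!r}: origin must be 'direct' or "
                f"'barrier', got {self.origin!r}"
            )
        if self.origin == "barrier":
            if self.barrier is None or self.temperature is None:
                raise SchemeError(
                    f"rate constant {self.name!r}: barrier origin requires "
                    "both barrier and temperature"
                )
            expected = eyring_rate(self.barrier, self.temperature)
            if not math.isclose(self.value, expected, rel_tol=1e-12):
                raise SchemeError(
                    f"rate constant {self.name!r}: value {self.value!r} does "
                    f"not match the Eyring rate {expected!r} for barrier "
                    f"{self.barrier} J/mol at {self.temperature} K"
                )
        elif self.barrier is not None or self.temperature is not None:
            raise SchemeError(
                f"rate constant {self.name!r}: barrier/temperature are only "
                "meaningful with origin='barrier'"
            )

    @classmethod
    def from_barrier(
        cls, name: str, barrier: float, temperature: float
    ) -> "RateConstant":
        """Build a constant whose value is computed from an Eyring barrier."""
        return cls(
            name=name,
            value=eyring_rate(barrier, temperature),
            origin="barrier",
            barrier=float(barrier),
            temperature=float(temperature),
        )


@dataclass(frozen=True)
class RateTerm:
    """One signed addend of a rate equation: s * m * k * prod [x_j]^a_j.

    ``factors`` may be empty (zeroth-order feed term whose feed concentration
    has been folded into the constant).
    """

    sign: int
    constant: str
    factors: tuple[tuple[str, float], ...] = ()
    multiplier: float = 1.0

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise SchemeError(f"term sign must be +1 or -1, got {self.sign!r}")
        if not (self.multiplier > 0) or not math.isfinite(self.multiplier):
            raise SchemeError(
                f"term multiplier must be positive and finite, "
                f"got {self.multiplier!r}"
            )
        object.__setattr__(
            self,
            "factors",
            tuple((str(s), float(a)) for s, a in self.factors),
        )
        for sp, alpha in self.factors:
            if not (alpha > 0) or not math.isfinite(alpha):
                raise SchemeError(
                    f"exponent of {sp!r} must be positive, got {alpha!r}"
                )


@dataclass(frozen=True)
class RateEquation:
    """d[species]/dt as an ordered list of RateTerms (may be empty)."""

    species: str
    terms: tuple[RateTerm, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))


@dataclass(frozen=True)
class Reaction:
    """A single (possibly reversible) reaction step.

    sum_i a_i R_i  <=>  sum_j b_j P_j  with forward constant ``k_forward``
    and optional reverse constant ``k_reverse`` (absent = irreversible).
    Coefficients are positive integers; reactant and product sets are
    disjoint.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    k_forward: str
    k_reverse: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))
        if not self.reactants or not self.products:
            raise SchemeError("reaction needs at least one reactant and one product")
        for side in (self.reactants, self.products):
            for name, coeff in side.items():
                if not isinstance(coeff, (int, np.integer)) or coeff <= 0:
                    raise SchemeError(
                        f"stoichiometric coefficient of {name!r} must be a "
                        f"positive integer, got {coeff!r}"
                    )
        overlap = set(self.reactants) & set(self.products)
        if overlap:
            raise SchemeError(
                f"species {sorted(overlap)} appear on both sides of a step"
            )


def expand_reaction(reaction: Reaction) -> list[RateEquation]:
    """Mass-action rate equations of a single reaction step.

    For reactant R_i: d[R_i]/dt = -a_i kF prod[R]^a + a_i kR prod[P]^b, and
    symmetrically for products; reverse terms are omitted for irreversible
    steps. Returns one equation per species that appears in the step, in
    reactant-then-product order.
    """
    fwd_factors = tuple(sorted(reaction.reactants.items()))
    rev_factors = tuple(sorted(reaction.products.items()))
    equations = []
    for name, coeff in reaction.reactants.items():
        terms = [
            RateTerm(-1, reaction.k_forward, fwd_factors, multiplier=coeff)
        ]
        if reaction.k_reverse is not None:
            terms.append(
                RateTerm(+1, reaction.k_reverse, rev_factors, multiplier=coeff)
            )
        equations.append(RateEquation(name, tuple(terms)))
    for name, coeff in reaction.products.items():
        terms = [
            RateTerm(+1, reaction.k_forward, fwd_factors, multiplier=coeff)
        ]
        if reaction.k_reverse is not None:
            terms.append(
                RateTerm(-1, reaction.k_reverse, rev_factors, multiplier=coeff)
            )
        equations.append(RateEquation(name, tuple(terms)))
    return equations


def equations_from_reactions(
    reactions: Iterable[Reaction], species_order: Sequence[str]
) -> list[RateEquation]:
    """Merge the expanded equations of several steps, one per species.

    Species in ``species_order`` that take part in no step get an empty
    (all-derivatives-zero) equation.
    """
    terms: dict[str, list[RateTerm]] = {name: [] for name in species_order}
    for reaction in reactions:
        for eq in expand_reaction(reaction):
            if eq.species not in terms:
                raise ResolutionError(
                    f"reaction references unknown species {eq.species!r}"
                )
            terms[eq.species].extend(eq.terms)
    return [RateEquation(name, tuple(terms[name])) for name in species_order]


@dataclass(frozen=True)
class KineticScheme:
    """A complete kinetic model: species, constants and one ODE per species."""

    species: tuple[Species, ...]
    constants: tuple[RateConstant, ...]
    equations: tuple[RateEquation, ...]
    name: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "constants", tuple(self.constants))
        object.__setattr__(self, "equations", tuple(self.equations))
        self.validate()

    # -- structural invariants ------------------------------------------
    def validate(self) -> None:
        names = [s.name for s in self.species] + [k.name for k in self.constants]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemeError(
                f"duplicate names across species and constants: {sorted(dupes)}"
            )
        species_names = {s.name for s in self.species}
        constant_names = {k.name for k in self.constants}
        eq_species = [eq.species for eq in self.equations]
        if sorted(eq_species) != sorted(species_names):
            missing = species_names - set(eq_species)
            extra = set(eq_species) - species_names
            problems = []
            if missing:
                problems.append(f"species without an equation: {sorted(missing)}")
            if extra:
                problems.append(f"equations for unknown species: {sorted(extra)}")
            if len(eq_species) != len(set(eq_species)):
                problems.append("duplicate equations for a species")
            raise ResolutionError("; ".join(problems) or "equation/species mismatch")
        for eq in self.equations:
            for term in eq.terms:
                if term.constant not in constant_names:
                    raise ResolutionError(
                        f"equation for {eq.species!r} references unknown "
                        f"rate constant {term.constant!r}"
                    )
                for sp, _ in term.factors:
                    if sp not in species_names:
                        raise ResolutionError(
                            f"equation for {eq.species!r} references unknown "
                            f"species {sp!r}"
                        )

    # -- convenience accessors ------------------------------------------
    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise ResolutionError(f"unknown species {name!r}") from None

    def constant(self, name: str) -> RateConstant:
        for k in self.constants:
            if k.name == name:
                return k
        raise ResolutionError(f"unknown rate constant {name!r}")

    def equation(self, species: str) -> RateEquation:
        for eq in self.equations:
            if eq.species == species:
                return eq
        raise ResolutionError(f"no equation for species {species!r}")

    def initial_state(self) -> np.ndarray:
        """Initial concentration vector in species order."""
        return np.array(
            [s.initial_concentration for s in self.species], dtype=float
        )

    def n_terms(self) -> int:
        return sum(len(eq.terms) for eq in self.equations)

    def symbolic_rhs(self):
        """The right-hand sides as sympy expressions, one per species.

        Concentrations are sympy symbols named after the species; rate
        constants enter by numeric value. Used by the network module's
        Kirchhoff-current-law equivalence checks.
        """
        import sympy

        symbols = {n: sympy.Symbol(n, nonnegative=True) for n in self.species_names}
        out = []
        for name in self.species_names:
            expr = sympy.Integer(0)
            for term in self.equation(name).terms:
                addend = (
                    sympy.Integer(term.sign)
                    * sympy.nsimplify(term.multiplier, rational=True)
                    * sympy.Float(self.constant(term.constant).value, 17)
                )
                for sp, alpha in term.factors:
                    addend *= symbols[sp] ** sympy.nsimplify(alpha, rational=True)
                expr += addend
            out.append(expr)
        return out

    def with_initial(self, **concentrations: float) -> "KineticScheme":
        """Copy of the scheme with some initial concentrations replaced."""
        unknown = set(concentrations) - set(self.species_names)
        if unknown:
            raise ResolutionError(f"unknown species {sorted(unknown)}")
        new_species = tuple(
            replace(s, initial_concentration=concentrations.get(
                s.name, s.initial_concentration))
            for s in self.species
        )
        return replace(self, species=new_species)


# ---------------------------------------------------------------------------
# Plain-text scheme file format (the package's own standard, version 1)
#
#   # netkin scheme v1
#   name = diels-alder            (optional)
#   [species]
#   A = 1.0
#   [constants]
#   k1 = 0.5                      (direct value)
#   k2 = barrier:113110.8@298.15  (Eyring: dG[J/mol] @ T[K])
#   [equations]
#   d[A]/dt = - k1*A*B + k2*C     (terms: [mult*]const[*species[^exp]]...)
#   d[X]/dt = 0                   (empty equation)
# ---------------------------------------------------------------------------

_FLOAT_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_EQ_LHS_RE = re.compile(r"^d\[([^\]\s]+)\]/dt$")


def _format_float(x: float) -> str:
    return repr(float(x))


def _format_exponent(a: float) -> str:
    return str(int(a)) if float(a).is_integer() else repr(float(a))


def _format_term(term: RateTerm) -> str:
    parts = []
    if term.multiplier != 1.0:
        parts.append(_format_exponent(term.multiplier))
    parts.append(term.constant)
    for sp, alpha in term.factors:
        parts.append(sp if alpha == 1.0 else f"{sp}^{_format_exponent(alpha)}")
    return ("- " if term.sign < 0 else "+ ") + "*".join(parts)


def write_scheme(scheme: KineticScheme) -> str:
    """Serialise a scheme to the versioned plain-text format."""
    lines = [f"# netkin scheme v{SCHEME_FORMAT_VERSION}"]
    if scheme.name:
        lines.append(f"name = {scheme.name}")
    lines.append("")
    lines.append("[species]")
    for s in scheme.species:
        lines.append(f"{s.name} = {_format_float(s.initial_concentration)}")
    lines.append("")
    lines.append("[constants]")
    for k in scheme.constants:
        if k.origin == "barrier":
            lines.append(
                f"{k.name} = barrier:{_format_float(k.barrier)}"
                f"@{_format_float(k.temperature)}"
            )
        else:
            lines.append(f"{k.name} = {_format_float(k.value)}")
    lines.append("")
    lines.append("[equations]")
    for name in scheme.species_names:
        eq = scheme.equation(name)
        rhs = " ".join(_format_term(t) for t in eq.terms) or "0"
        if rhs.startswith("+ "):
            rhs = rhs[2:]
        lines.append(f"d[{name}]/dt = {rhs}")
    return "\n".join(lines) + "\n"


def _parse_term_chunk(
    chunk: str,
    sign: int,
    lineno: int,
    species_names: set[str],
    constant_names: set[str],
) -> RateTerm:
    parts = [p.strip() for p in chunk.split("*")]
    if any(not p for p in parts):
        raise SchemeSyntaxError(f"malformed term {chunk!r}", lineno)
    multiplier = 1.0
    if _FLOAT_RE.match(parts[0]):
        multiplier = float(parts[0])
        parts = parts[1:]
        if not parts:
            raise SchemeSyntaxError(
                f"term {chunk!r} has no rate constant", lineno
            )
    const = parts[0]
    if const not in constant_names:
        if const in species_names:
            raise SchemeSyntaxError(
                f"term {chunk!r} must start with a rate constant, "
                f"{const!r} is a species",
                lineno,
            )
        raise ResolutionError(
            f"line {lineno}: unknown rate constant {const!r}"
        )
    factors = []
    for part in parts[1:]:
        if "^" in part:
            base, _, expo = part.partition("^")
            base, expo = base.strip(), expo.strip()
            if not _FLOAT_RE.match(expo):
                raise SchemeSyntaxError(f"bad exponent {expo!r}", lineno)
            alpha = float(expo)
        else:
            base, alpha = part, 1.0
        if base not in species_names:
            raise ResolutionError(f"line {lineno}: unknown species {base!r}")
        factors.append((base, alpha))
    return RateTerm(sign, const, tuple(factors), multiplier=multiplier)


def _split_signed(rhs: str) -> list[tuple[int, str]]:
    """Split '- k1*A + k2*C' into [(-1, 'k1*A'), (+1, 'k2*C')]."""
    chunks: list[tuple[int, str]] = []
    sign = +1
    current: list[str] = []
    for token in re.split(r"(?<![eE])([+-])", rhs):
        token = token.strip()
        if token in ("+", "-"):
            if current and "".join(current).strip():
                chunks.append((sign, "".join(current).strip()))
                current = []
            elif chunks and not current:
                # consecutive signs like '+ -'
                raise SchemeSyntaxError(f"dangling sign in {rhs!r}")
            sign = +1 if token == "+" else -1
        else:
            current.append(token)
    tail = "".join(current).strip()
    if tail:
        chunks.append((sign, tail))
    return chunks


def read_scheme(text: str) -> KineticScheme:
    """Parse the plain-text scheme format into a validated KineticScheme.

    Raises SchemeSyntaxError (with line number), ResolutionError or
    SchemeError on malformed input. ``read_scheme(write_scheme(s))`` is the
    identity on valid schemes.
    """
    species: list[Species] = []
    constants: list[RateConstant] = []
    raw_equations: list[tuple[int, str, str]] = []  # (lineno, species, rhs)
    name: str | None = None
    section = None
    lines = text.splitlines()

    for lineno0, raw in enumerate(lines):
        lineno = lineno0 + 1
        header = _HEADER_RE.match(raw.strip())
        if header:
            version = int(header.group(1))
            if version > SCHEME_FORMAT_VERSION:
                raise SchemeSyntaxError(
                    f"unsupported scheme format version {version}", lineno
                )
            continue
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in ("species", "constants", "equations"):
                raise SchemeSyntaxError(f"unknown section {section!r}", lineno)
            continue
        if section is None:
            if line.lower().startswith("name") and "=" in line:
                name = line.split("=", 1)[1].strip() or None
                continue
            raise SchemeSyntaxError(
                f"content before any section: {line!r}", lineno
            )
        if "=" not in line:
            raise SchemeSyntaxError(f"expected 'lhs = rhs', got {line!r}", lineno)
        lhs, rhs = (part.strip() for part in line.split("=", 1))
        if section == "species":
            if not _FLOAT_RE.match(rhs):
                raise SchemeSyntaxError(
                    f"bad initial concentration {rhs!r}", lineno
                )
            try:
                species.append(Species(lhs, float(rhs)))
            except SchemeError as exc:
                raise SchemeSyntaxError(str(exc), lineno) from exc
        elif section == "constants":
            try:
                if rhs.startswith("barrier:"):
                    payload = rhs[len("barrier:"):]
                    if "@" not in payload:
                        raise SchemeSyntaxError(
                            "barrier constants need 'barrier:<J/mol>@<K>'",
                            lineno,
                        )
                    dg, _, temp = payload.partition("@")
                    constants.append(
                        RateConstant.from_barrier(lhs, float(dg), float(temp))
                    )
                else:
                    if not _FLOAT_RE.match(rhs):
                        raise SchemeSyntaxError(
                            f"bad rate-constant value {rhs!r}", lineno
                        )
                    constants.append(RateConstant(lhs, float(rhs)))
            except (SchemeSyntaxError, ResolutionError):
                raise
            except (SchemeError, InvalidParameterError, ValueError) as exc:
                raise SchemeSyntaxError(str(exc), lineno) from exc
        else:  # equations
            match = _EQ_LHS_RE.match(lhs)
            if not match:
                raise SchemeSyntaxError(
                    f"equation left side must be 'd[name]/dt', got {lhs!r}",
                    lineno,
                )
            raw_equations.append((lineno, match.group(1), rhs))

    species_names = {s.name for s in species}
    constant_names = {k.name for k in constants}
    equations = []
    for lineno, sp_name, rhs in raw_equations:
        if sp_name not in species_names:
            raise ResolutionError(
                f"line {lineno}: equation for unknown species {sp_name!r}"
            )
        if rhs.strip() == "0":
            equations.append(RateEquation(sp_name, ()))
            continue
        try:
            chunks = _split_signed(rhs)
        except SchemeSyntaxError as exc:
            raise SchemeSyntaxError(str(exc), lineno) from exc
        terms = [
            _parse_term_chunk(chunk, sign, lineno, species_names, constant_names)
            for sign, chunk in chunks
        ]
        if not terms:
            raise SchemeSyntaxError(f"empty equation right side", lineno)
        equations.append(RateEquation(sp_name, tuple(terms)))

    return KineticScheme(
        species=tuple(species),
        constants=tuple(constants),
        equations=tuple(equations),
        name=name,
    )
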
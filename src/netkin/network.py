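"""The equivalent electrical network of a kinetic scheme.

Each species becomes one circuit node whose voltage is its concentration
(1 mol/l == 1 V). Per node the network carries:

* a grounded capacitor of capacitance 1 F, so the capacitor current equals
  d[x]/dt (the renormalised reaction flow);
* one voltage-controlled current source per rate-equation addend, injecting
  ``sign * m * k * prod V^a`` into the node — the coupling between equations;
* a grounded continuity resistor of very high value, present only so that
  every node has a DC path to ground; it must not perturb the chemistry.

Kirchhoff's current law at a node is then exactly that species' mass-balance
rate equation, which is the whole content of the analogy. The network can be
exported as a PSpice-dialect ``.CIR`` netlist and parsed back.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ExportError, NetlistParseError, SchemeError
from .scheme import KineticScheme, RateTerm

__all__ = [
    "CurrentSource",
    "NetworkModel",
    "build_network",
    "compile_rhs",
    "export_cir",
    "parse_cir",
]

DEFAULT_RESISTANCE = 1e15
"""Continuity resistor, ohm. High enough that the leak current (conductance
times node voltage) is negligible against every kinetic flow over the
simulated horizons."""


@dataclass(frozen=True)
class CurrentSource:
    """One voltage-controlled current source: injects
    ``coefficient * prod_j V(node_j)^alpha_j`` amperes into ``node``.

    ``coefficient`` is the signed effective rate coefficient
    sign * multiplier * k.
    """

    name: str
    node: str
    coefficient: float
    factors: tuple[tuple[str, float], ...] = ()


@dataclass(frozen=True)
class NetworkModel:
    """The NSM circuit: nodes, capacitors, sources, continuity resistors."""

    nodes: tuple[str, ...]
    initial_voltages: tuple[float, ...]
    sources: tuple[CurrentSource, ...]
    capacitance: float = 1.0
    resistance: float = DEFAULT_RESISTANCE
    title: str = "netkin network"

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_capacitors(self) -> int:
        return self.n_nodes

    @property
    def n_resistors(self) -> int:
        return self.n_nodes

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    def node_index(self, name: str) -> int:
        return self.nodes.index(name)

    def symbolic_rhs(self, include_resistors: bool = False):
        """Per-node dV/dt from Kirchhoff's current law, as sympy expressions.

        KCL: C dV/dt = sum of source currents (- V/R). With C = 1 the result
        is term-for-term the rate equation of the species at that node.
        """
        import sympy

        symbols = {n: sympy.Symbol(n, nonnegative=True) for n in self.nodes}
        exprs = {n: sympy.Integer(0) for n in self.nodes}
        for src in self.sources:
            addend = sympy.Float(src.coefficient, 17)
            for sp, alpha in src.factors:
                addend *= symbols[sp] ** sympy.nsimplify(alpha, rational=True)
            exprs[src.node] += addend
        if include_resistors:
            for n in self.nodes:
                exprs[n] -= symbols[n] / sympy.Float(self.resistance, 17)
        c = sympy.Float(self.capacitance, 17)
        return [exprs[n] / c for n in self.nodes]

    def rhs(self, include_resistors: bool = True):
        """Compiled numeric evaluator f(t, V) -> dV/dt for this circuit."""
        coef, expo, target = _source_arrays(self)
        leak = np.full(self.n_nodes, 1.0 / self.resistance) if include_resistors \
            else np.zeros(self.n_nodes)
        return _compile(coef, expo, target, self.nodes, leak / self.capacitance,
                        1.0 / self.capacitance)

    def equivalent(self, other: "NetworkModel", rel_tol: float = 1e-12) -> bool:
        """Structural equivalence up to element naming."""
        if self.nodes != other.nodes or self.n_sources != other.n_sources:
            return False
        if not np.allclose(self.initial_voltages, other.initial_voltages,
                           rtol=rel_tol, atol=0):
            return False
        if not (math.isclose(self.capacitance, other.capacitance, rel_tol=rel_tol)
                and math.isclose(self.resistance, other.resistance,
                                 rel_tol=rel_tol)):
            return False
        def key(s: CurrentSource):
            return (s.node, s.coefficient, tuple(sorted(s.factors)))
        return sorted(map(key, self.sources)) == sorted(map(key, other.sources))


def build_network(
    scheme: KineticScheme, resistance: float = DEFAULT_RESISTANCE
) -> NetworkModel:
    """Construct the equivalent circuit of a kinetic scheme.

    One node + capacitor + continuity resistor per species, one controlled
    current source per rate-equation addend. KCL at every node reproduces
    that species' rate equation exactly.
    """
    sources = []
    for name in scheme.species_names:
        for i, term in enumerate(scheme.equation(name).terms, start=1):
            k = scheme.constant(term.constant).value
            sources.append(
                CurrentSource(
                    name=f"{name}_{i}",
                    node=name,
                    coefficient=term.sign * term.multiplier * k,
                    factors=term.factors,
                )
            )
    return NetworkModel(
        nodes=scheme.species_names,
        initial_voltages=tuple(s.initial_concentration for s in scheme.species),
        sources=tuple(sources),
        resistance=resistance,
        title=scheme.name or "netkin network",
    )


# ---------------------------------------------------------------------------
# Compiled mass-action right-hand side
# ---------------------------------------------------------------------------

def _source_arrays(model: NetworkModel):
    index = {n: i for i, n in enumerate(model.nodes)}
    n_terms = model.n_sources
    coef = np.zeros(n_terms)
    expo = np.zeros((n_terms, model.n_nodes))
    target = np.zeros(n_terms, dtype=np.int64)
    for t, src in enumerate(model.sources):
        coef[t] = src.coefficient
        target[t] = index[src.node]
        for sp, alpha in src.factors:
            expo[t, index[sp]] += alpha
    return coef, expo, target


def _term_arrays(scheme: KineticScheme):
    """(coef, expo, target) arrays of the scheme's mass-action terms."""
    index = {n: i for i, n in enumerate(scheme.species_names)}
    rows = []
    for name in scheme.species_names:
        for term in scheme.equation(name).terms:
            k = scheme.constant(term.constant).value
            rows.append((term.sign * term.multiplier * k, term.factors,
                         index[name]))
    n = len(scheme.species_names)
    coef = np.array([r[0] for r in rows], dtype=float)
    expo = np.zeros((len(rows), n))
    target = np.array([r[2] for r in rows], dtype=np.int64)
    for t, (_, factors, _) in enumerate(rows):
        for sp, alpha in factors:
            expo[t, index[sp]] += alpha
    return coef, expo, target


def _compile(coef, expo, target, species, leak, inv_c=1.0):
    n = len(species)
    nz = [np.nonzero(expo[t])[0] for t in range(len(coef))]

    def f(t, x):
        x = np.asarray(x, dtype=float)
        if x.shape != (n,):
            raise SchemeError(
                f"state dimension {x.shape} does not match {n} species"
            )
        rates = coef * np.prod(np.power(x[None, :], expo), axis=1)
        dx = np.zeros(n)
        np.add.at(dx, target, rates)
        return (dx - leak * x) * inv_c

    def jacobian(t, x):
        x = np.asarray(x, dtype=float)
        jac = np.zeros((n, n))
        for tr in range(len(coef)):
            base = coef[tr]
            cols = nz[tr]
            vals = x[cols] ** expo[tr, cols]
            prod_all = base * np.prod(vals)
            for pos, j in enumerate(cols):
                a = expo[tr, j]
                rest = base * np.prod(np.delete(vals, pos))
                jac[target[tr], j] += rest * a * x[j] ** (a - 1.0)
        jac -= np.diag(leak)
        return jac * inv_c

    f.jacobian = jacobian
    f.species = tuple(species)
    f.term_arrays = (coef.copy(), expo.copy(), target.copy())
    f.n_species = n
    return f


def compile_rhs(scheme: KineticScheme):
    """Compile a scheme into a pure evaluator ``f(t, x) -> dx/dt``.

    The returned callable carries ``f.jacobian(t, x)`` (exact partial
    derivatives of the mass-action polynomial), ``f.species`` and the raw
    ``f.term_arrays`` used by brute-force cross-check integrators. The state
    vector is ordered as the scheme's species list.
    """
    coef, expo, target = _term_arrays(scheme)
    n = len(scheme.species_names)
    return _compile(coef, expo, target, scheme.species_names, np.zeros(n))


# ---------------------------------------------------------------------------
# Netlist export / parse (PSpice ABM dialect, the package's own standard)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


def _mangle(name: str) -> str:
    return "N_" + name.upper()


def _value_expr(src: CurrentSource) -> str:
    parts = [_fmt(src.coefficient)]
    for sp, alpha in src.factors:
        v = f"V({_mangle(sp)})"
        parts.append(v if alpha == 1.0 else f"PWR({v},{_fmt(alpha)})")
    return "*".join(parts)


def export_cir(model: NetworkModel, options=None) -> str:
    """Serialise the network as a PSpice-dialect transient netlist.

    Cards: one capacitor per node with ``IC=`` initial condition, one
    behavioural ``G`` source per rate term (current injected into the node,
    expression = the signed term in node voltages), one continuity resistor
    per node, then ``.OPTIONS``/``.TRAN ... UIC``/``.PRINT TRAN``. Element
    ordering is deterministic (node order, then term order), so the output is
    byte-identical across runs.
    """
    mangled = [_mangle(n) for n in model.nodes]
    if len(set(mangled)) != len(mangled):
        raise ExportError(
            "species names collide after netlist mangling "
            f"(upper-cased): {model.nodes}"
        )
    lines = [f"* {model.title}", f"* species: {' '.join(model.nodes)}"]
    for node, ic in zip(model.nodes, model.initial_voltages):
        lines.append(
            f"C_{node.upper()} {_mangle(node)} 0 {_fmt(model.capacitance)} "
            f"IC={_fmt(ic)}"
        )
    counter: dict[str, int] = {}
    for src in model.sources:
        i = counter.get(src.node, 0) + 1
        counter[src.node] = i
        lines.append(
            f"G_{src.node.upper()}_{i} 0 {_mangle(src.node)} "
            f"VALUE = {{ {_value_expr(src)} }}"
        )
    for node in model.nodes:
        lines.append(f"R_{node.upper()} {_mangle(node)} 0 {_fmt(model.resistance)}")
    if options is not None:
        opts = options.resolved() if hasattr(options, "resolved") else options
        lines.append(
            f".OPTIONS RELTOL={_fmt(opts.reltol)} NUMDGT={opts.numdgt}"
        )
        lines.append(f".TRAN {_fmt(opts.print_step)} {_fmt(opts.total_time)} UIC")
    lines.append(".PRINT TRAN " + " ".join(f"V({m})" for m in mangled))
    lines.append(".END")
    return "\n".join(lines) + "\n"


_CAP_RE = re.compile(
    r"^C(\S*)\s+(\S+)\s+0\s+(\S+)\s+IC=(\S+)\s*$", re.IGNORECASE
)
_SRC_RE = re.compile(
    r"^G(\S*)\s+0\s+(\S+)\s+VALUE\s*=\s*\{(.+)\}\s*$", re.IGNORECASE
)
_RES_RE = re.compile(r"^R(\S*)\s+(\S+)\s+0\s+(\S+)\s*$", re.IGNORECASE)
_PWR_RE = re.compile(r"^PWR\(V\((\S+)\),([^)]+)\)$", re.IGNORECASE)
_V_RE = re.compile(r"^V\((\S+)\)$", re.IGNORECASE)
_SPECIES_COMMENT_RE = re.compile(r"^\*\s*species:\s*(.+)$", re.IGNORECASE)


def _parse_value_expr(expr: str, lineno: int) -> tuple[float, list]:
    parts = [p.strip() for p in expr.strip().split("*")]
    try:
        coefficient = float(parts[0])
    except ValueError:
        raise NetlistParseError(
            f"source expression must start with a numeric coefficient, "
            f"got {parts[0]!r}",
            lineno,
        ) from None
    factors = []
    for part in parts[1:]:
        m = _PWR_RE.match(part)
        if m:
            factors.append((m.group(1), float(m.group(2))))
            continue
        m = _V_RE.match(part)
        if m:
            factors.append((m.group(1), 1.0))
            continue
        raise NetlistParseError(f"unsupported factor {part!r}", lineno)
    return coefficient, factors


def parse_cir(text: str) -> NetworkModel:
    """Parse a netlist in the dialect emitted by :func:`export_cir`.

    Inverse of export up to element naming. Unsupported element cards (L, V,
    I, ...) raise NetlistParseError with the offending line number.
    """
    title = "netkin network"
    species_order: list[str] | None = None
    caps: list[tuple[str, float, float]] = []  # node, C, IC
    raw_sources: list[tuple[str, float, list]] = []
    resistors: dict[str, float] = {}
    node_names: dict[str, str] = {}  # mangled -> original

    lines = text.splitlines()
    for lineno0, raw in enumerate(lines):
        lineno = lineno0 + 1
        line = raw.strip()
        if not line:
            continue
        if line.startswith("*"):
            m = _SPECIES_COMMENT_RE.match(line)
            if m:
                species_order = m.group(1).split()
            elif lineno == 1:
                title = line[1:].strip()
            continue
        if line.startswith("."):
            continue  # analysis/option cards carry no topology
        card = line[0].upper()
        if card == "C":
            m = _CAP_RE.match(line)
            if not m:
                raise NetlistParseError(f"malformed capacitor card {line!r}", lineno)
            caps.append((m.group(2), float(m.group(3)), float(m.group(4))))
        elif card == "G":
            m = _SRC_RE.match(line)
            if not m:
                raise NetlistParseError(f"malformed source card {line!r}", lineno)
            coefficient, factors = _parse_value_expr(m.group(3), lineno)
            raw_sources.append((m.group(2), coefficient, factors))
        elif card == "R":
            m = _RES_RE.match(line)
            if not m:
                raise NetlistParseError(f"malformed resistor card {line!r}", lineno)
            resistors[m.group(2)] = float(m.group(3))
        else:
            raise NetlistParseError(
                f"unsupported element card {line.split()[0]!r}", lineno
            )

    if not caps:
        raise NetlistParseError("netlist defines no capacitor nodes")

    mangled_order = [node for node, _, _ in caps]
    if species_order is not None and len(species_order) == len(mangled_order):
        node_names = dict(zip(mangled_order, species_order))
    else:
        node_names = {
            m: (m[2:] if m.startswith("N_") else m) for m in mangled_order
        }

    def demangle(m: str, lineno: int = 0) -> str:
        if m not in node_names:
            raise NetlistParseError(f"reference to unknown node {m!r}")
        return node_names[m]

    capacitances = {node: c for node, c, _ in caps}
    if len(set(capacitances.values())) > 1:
        raise NetlistParseError("all capacitors must share one capacitance")
    res_values = set(resistors.values())
    if resistors and len(res_values) > 1:
        raise NetlistParseError("all continuity resistors must share one value")

    sources = []
    for i, (node_m, coefficient, factors) in enumerate(raw_sources, start=1):
        node = demangle(node_m)
        sources.append(
            CurrentSource(
                name=f"{node}_{i}",
                node=node,
                coefficient=coefficient,
                factors=tuple((demangle(sp), a) for sp, a in factors),
            )
        )
    return NetworkModel(
        nodes=tuple(node_names[m] for m in mangled_order),
        initial_voltages=tuple(ic for _, _, ic in caps),
        sources=tuple(sources),
        capacitance=next(iter(capacitances.values()), 1.0),
        resistance=next(iter(res_values), DEFAULT_RESISTANCE),
        title=title,
    )
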
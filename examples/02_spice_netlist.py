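"""The electrical analogue of a kinetic scheme, as a SPICE netlist.

Each species becomes a circuit node: a 1 F capacitor holds its
concentration as a voltage, one behavioural current source per rate-law
addend injects the signed reaction flow, and a very high-value resistor
provides the DC path SPICE requires. Kirchhoff's current law at each node
IS the species' rate equation.
"""

from netkin import (
    SimulationOptions,
    build_network,
    export_cir,
    models,
    parse_cir,
)

fixture = models.diels_alder()
model = build_network(fixture.scheme)
print(f"nodes: {model.n_nodes}, capacitors: {model.n_capacitors}, "
      f"sources: {model.n_sources}, resistors: {model.n_resistors}")

netlist = export_cir(model, SimulationOptions(total_time=1e7, print_step=5e4))
print("\n--- model.cir " + "-" * 50)
print(netlist)

# The netlist round-trips: parsing it back reconstructs the same circuit.
again = parse_cir(netlist)
print(f"parse_cir(export_cir(model)) equivalent: {model.equivalent(again)}")
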
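"""When does the steady-state approximation hold?

The SSA replaces d[intermediate]/dt = 0 by algebra. For the sequential
decay A -> B -> C it predicts [B] = k1 [A] / k2, which is excellent when
k2 >> k1 and useless when the timescales are comparable. compare_ssa runs
the full integration and the algebraic solve side by side and reports the
ratio of the two answers per intermediate.
"""

from netkin import SimulationOptions, models
from netkin.analysis import compare_ssa

print("decay chain A -> B -> C, intermediate B, increasing k2/k1:")
for separation in (1e1, 1e2, 1e4, 1e6):
    fixture = models.decay_chain(k1=1.0, k2=separation)
    report = compare_ssa(
        fixture.scheme,
        {"B"},
        SimulationOptions(total_time=10.0 / separation,
                          print_step=0.1 / separation, reltol=1e-8),
    )
    ratio = report.ratios["B"]
    verdict = "ok" if report.valid["B"] else "SSA-invalid"
    print(f"  k2/k1 = {separation:>9.0e}: full/SSA = {ratio:.6f}  [{verdict}]")

print("\nreversible pair A <=> B without timescale separation:")
fixture = models.reversible_pair(k_f=1.0, k_r=0.5)
report = compare_ssa(
    fixture.scheme, {"B"},
    SimulationOptions(total_time=40.0, print_step=0.2, reltol=1e-8),
)
print(report.as_text())
# The ratio sits near 1/3 because clamping [A] at its initial value ignores
# that half of A converts before equilibrium: the approximation fails, and
# the report says so.
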
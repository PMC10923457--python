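"""Evaluate and invert the knife calibration polynomials.

Prints the four canonical operating points: for each knife power, the tip
temperature predicted by the fitted quadratic, and the waste-gas, tar and
particle source rates that feed the theatre simulation.
"""

from theatresmoke import (eval_tip_temperature, eval_waste_gas_flow,
                          eval_tar_rate, power_for_temperature)
from theatresmoke.empirical import eval_particle_rate

print(f"{'P (W)':>6} {'T_tip (degC)':>13} {'G_gas (m3/s)':>13} "
      f"{'F_tar (g/s)':>12} {'F_part (g/s)':>13}")
for power in (20, 60, 70, 80):
    print(f"{power:6.0f} {eval_tip_temperature(power):13.1f} "
          f"{eval_waste_gas_flow(power):13.4e} {eval_tar_rate(power):12.4f} "
          f"{eval_particle_rate(power):13.4f}")

print()
p, unreachable = power_for_temperature(500.0)
print(f"exact power for 500 degC : {p:.2f} W (published rounding: 80 W)")
p, unreachable = power_for_temperature(200.0)
print(f"200 degC is below the curve minimum (~214.6 degC): closest power "
      f"{p:.2f} W, unreachable={unreachable}")
# The rising rate of tip temperature accelerates above ~60 W; the printed
# 100-degC levels come from rounding the quadratic at 20/60/70/80 W.
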
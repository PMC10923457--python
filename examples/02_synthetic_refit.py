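"""Generate a noisy synthetic power sweep and refit the calibrations.

Emulates the in vitro bench experiment (powers 20-80 W, multiplicative
measurement noise) and shows that ordinary least squares recovers the
generating coefficients; the bias/RMSE table quantifies recovery quality
over repeated experiments.
"""

from theatresmoke import SweepDesign, generate_sweep, recovery_experiment
from theatresmoke.empirical import fit_calibration

design = SweepDesign(noise_cv=0.02, seed=1, replicate_count=3)
records = generate_sweep(design)
fitted, rss = fit_calibration(records)

print("fitted tip-temperature quadratic:", [round(c, 4) for c in fitted.temp_coeffs])
print("residual sum of squares per response:")
for name, v in rss.items():
    print(f"  {name:16s} {v:.3e}")

table = recovery_experiment(design, trials=50)
quad = table[table.response == "temp_coeffs"]
print("\ncoefficient recovery over 50 simulated experiments (temp quadratic):")
print(quad[["order", "truth", "bias", "rmse"]].to_string(index=False))
# |bias| << rmse: the estimator is unbiased; rmse shrinks with replicates.
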
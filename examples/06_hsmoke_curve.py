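"""The H_smoke vs tip-temperature relation.

Evaluates the published quadratic (exponent-restored coefficients
1.14, -6.37e-4, 2.45e-6) at the four canonical temperatures and refits a
quadratic through those points, demonstrating the fit utility used by the
full temperature sweep.
"""

from theatresmoke import fit_H_smoke_curve, published_h_smoke

temps = [200.0, 300.0, 400.0, 500.0]
points = [(t, published_h_smoke(t)) for t in temps]
for t, h in points:
    print(f"T_tip {t:5.0f} degC -> H_smoke {h:.3f} m")

fit = fit_H_smoke_curve(points)
print("\nrefit quadratic coefficients:", [f"{c:.4g}" for c in fit.coeffs])
print("max |residual|:", max(abs(r) for r in fit.residuals))
# The curve rises from ~1.11 m at 200 degC to ~1.43 m at 500 degC: a
# hotter tip drives a stronger buoyant plume that penetrates the
# ventilation downflow further.
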
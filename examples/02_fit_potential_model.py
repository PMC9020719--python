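"""Calibrate a spatial-lag change-potential model on a synthetic landscape.

A landscape is generated from a known spatial-lag process, a response field
is drawn with ρ = 0.5 and known driver coefficients, candidate drivers are
screened for collinearity (Spearman |rho| ≤ 0.6), and the model is selected
by significance and AIC.  The printed estimates should sit close to the
true parameters — that is the calibration-recovery property the engine's
potential component relies on.
"""

import numpy as np

from landshift import build_weights, select_model, spearman_screen
from landshift.synthetic import LagParams, SyntheticSpec, gen_landscape, gen_lag_response

spec = SyntheticSpec(seed=8)
grid = gen_landscape(spec)
W = build_weights(grid)  # queen contiguity, row-standardized

truth = LagParams(rho=0.5, beta={"suitability": 1.0, "water_deficit": 2.0},
                  intercept=0.5, sigma=0.1)
rng = np.random.default_rng(12)
response = gen_lag_response(grid.drivers, W, truth, rng)

kept = spearman_screen(grid.drivers, response, threshold=0.60, valid=grid.valid)
print(f"drivers retained after collinearity screen: {kept}")

model = select_model("demo", response, grid.drivers, [kept], W)
print(f"\nselected model (pseudo-R² = {model.pseudo_r2:.3f}, AIC = {model.aic:.1f})")
print(f"  rho        = {model.rho:+.4f}   (true 0.5)")
for name in model.driver_names:
    b = model.coefficients[name]
    p = model.p_values[name]
    tv = truth.beta.get(name, 0.0)
    print(f"  {name:18s} = {b:+.4f}  p = {p:.2e}  (true {tv:+.2f})")
print(
    "\nDrivers absent from the generating process get near-zero, mostly"
    "\nnon-significant coefficients; ρ and the true β are recovered closely."
)
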
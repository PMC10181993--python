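"""Fit a xylem vulnerability curve from a centrifuge conductivity sweep.

Generates one synthetic plant from known truth (psi50 = -2.8 MPa,
S = 90 % MPa^-1), computes PLC against the -0.8 MPa reference reading,
fits the Pammenter sigmoid and prints the estimated thresholds.
"""

from vitivc import VarietyTruth, compute_plc, fit_pammenter, gen_sweep

truth = VarietyTruth("Syrah", true_psi50=-2.8, true_slope=90.0)
sweep, record = gen_sweep(truth, noise_cv=0.05, seed=12, plant_id="syrah-01")

curve = compute_plc(sweep)
fit = fit_pammenter(curve)

print(f"true psi50 = {record['psi50']:.2f} MPa, true S = {record['slope']:.0f} %/MPa")
print(f"fitted psi50 = {fit.psi50:.2f} MPa, S = {fit.slope:.0f} %/MPa "
      f"(converged: {fit.converged})")
print(f"thresholds: psi12 = {fit.psi12:.2f} MPa (embolism onset), "
      f"psi88 = {fit.psi88:.2f} MPa (lethal)")
# psi12/psi88 are where the fitted sigmoid predicts 12% and 88% loss of
# conductivity; the gap between them narrows as the slope steepens.
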
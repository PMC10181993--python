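"""Xylem anatomical traits and theoretical conductivity for one section.

Generates a vessel table (lognormal diameters, median 50 um) and computes
the equivalent circle diameters, hydraulically weighted diameter, vessel
density, and the Hagen-Poiseuille theoretical specific conductivity.
"""

from vitivc import analyze_section, gen_vessels

vessels, truth = gen_vessels(n=120, xylem_area_mm2=2.0, seed=4, variety="Merlot")
traits = analyze_section(vessels)

print(f"{len(traits.diameters_um)} vessels in {traits.xylem_area_m2 * 1e6:.1f} mm2")
print(f"mean diameter D = {traits.d_mean_um:.1f} um")
print(f"hydraulic diameter D_H = {traits.d_hydraulic_um:.1f} um (>= mean: flow "
      "weighting favours wide vessels)")
print(f"vessel density V_D = {traits.vessel_density_mm2:.1f} mm^-2")
print(f"k_th = {traits.k_th:.2f} kg s^-1 m^-1 MPa^-1")
# k_th sums pi*D^4*rho/(128*eta) over vessels and normalises by xylem
# area: the conductivity the section would have if every vessel were an
# ideal capillary — an upper bound on the measured conductivity.
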
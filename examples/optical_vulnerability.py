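"""Optical vulnerability curve from a leaf dehydration image stack.

Builds a synthetic stack whose cumulative embolized area follows a known
sigmoid (psi50 = -2.0 MPa, S = 60) along a linear drydown, runs the
detection chain (frame subtraction, thresholding, particle filtering,
pixel accumulation, water-potential mapping) and fits the optical curve.
"""

from vitivc import analyze_stack, gen_psi_timeline, gen_sigmoid_stack, optical_vc

timeline = gen_psi_timeline(psi_start=-0.5, psi_end=-3.5, duration_h=13.0)
stack, truth = gen_sigmoid_stack(
    truth_psi50=-2.0, truth_slope=60.0, timeline=timeline,
    n_frames=150, total_px=4000, background_noise_sd=0.5, seed=3,
)

series = analyze_stack(stack, timeline, intensity_threshold=5.0, min_area_px=20)
fit = optical_vc(series)

print(f"injected {truth['n_events']} events totalling {truth['total_px']} px")
print(f"recovered {int(series.event_frames['event_count'].sum())} events, "
      f"{series.total_px} px")
print(f"optical psi50 = {fit.psi50:.2f} MPa (truth -2.00)")
# Every embolism event is an abrupt light-transmission change between two
# consecutive 5-min scans; PEP (percent embolized pixels) normalises the
# cumulative count to the dehydration total, and fitting PEP against stem
# water potential yields the leaf's vulnerability curve.
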
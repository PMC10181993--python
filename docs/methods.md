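# Methods

## Vulnerability curves

A flow-centrifuge sweep spins a stem segment at increasing speed, imposing
xylem pressures from −0.8 MPa downward in −0.5 MPa steps while measuring
hydraulic conductivity `k_i` (kg m⁻¹ s⁻¹ MPa⁻¹). PLC is computed against
the first-pressure reading:

    PLC_i = 100 · (1 − k_i / k_max),   k_max = k at the first pressure.

`k_max` is always the first reading, never the maximum over the sweep —
the protocol fixes the reference at −0.8 MPa. Two consequences worth
knowing:

* **Negative PLC.** Measurement noise can push a later reading above the
  reference; the raw negative PLC is retained for fitting (least squares
  is unbiased around the truth, and clamping would bias the shallow end of
  the curve upward). Curves containing negative values are flagged in QC
  output.
* **Reference truncation.** If a genotype already has some embolism at
  −0.8 MPa (a shallow curve), the computed PLC understates the model PLC
  by that margin, and a fit to sweep-derived PLC recovers slightly biased
  parameters even without noise. This is a property of the measurement
  protocol, not of the fitting code: the noiseless round-trip
  (generate → PLC → fit) is exact to solver tolerance only for curves that
  are essentially intact at the reference pressure, and the bias for
  realistic grapevine parameters is on the order of hundredths of a MPa.

### Sigmoid model and fitting

    PLC(Ψ) = 100 / (1 + exp(S/25 · (Ψ − Ψ50)))

with Ψ50 (MPa) the pressure at 50% loss and S (% MPa⁻¹) the slope at the
inflexion. Thresholds follow analytically: Ψ12 = Ψ50 + 50/S and
Ψ88 = Ψ50 − 50/S, at which the sigmoid evaluates to 100/(1+e²) ≈ 11.92%
and 100/(1+e⁻²) ≈ 88.08%.

Fitting is trust-region nonlinear least squares
(`scipy.optimize.least_squares`) with:

* initial Ψ50 from linear interpolation of the pressure at PLC = 50
  (median sweep pressure when the curve never crosses 50); initial
  S = 50 % MPa⁻¹;
* box bounds Ψ50 ∈ [−10, 0] MPa, S ∈ (0, 500] % MPa⁻¹ — generous relative
  to anything published for woody plants;
* tolerances 10⁻⁸ (ftol/xtol/gtol), at most 1000 function evaluations;
* an honest `converged` flag; non-converged fits are excluded from
  aggregation.

Curves with fewer than 4 points or a PLC span under 30 units are refused
outright rather than fitted: a near-flat curve cannot constrain a
two-parameter sigmoid and would return boundary artefacts. Tests verify
the optimiser is never beaten by a 200×200 grid search over the bounded
parameter box.

Variety/season summaries are arithmetic means with standard errors
(SE undefined, not zero, for single-plant groups). Seasonal and varietal
contrasts use a two-sided pooled-variance Student's t-test; degenerate
zero-variance cases are reported explicitly (t = 0, p = 1 for identical
groups; infinite t for distinct constants) rather than NaN. Hydraulic
vulnerability segmentation is leaf minus stem at Ψ12 and Ψ50, positive
when the leaf embolizes at less negative potentials (the leaf-as-fuse
pattern); it requires matching variety and season.

## Optical vulnerability

The chain mirrors open-source optical-vulnerability practice: absolute
difference of consecutive 8-bit frames (stamped with the later frame's
time), binary threshold, connected-component labelling, size filtering,
pixel accumulation, and normalisation to the dehydration total (PEP).

Defaults — threshold 5 gray levels, minimum component 20 px, 8-connected
labelling — are configuration keys, since published workflows choose them
per scanner and leaf. The psychrometer series is cleaned to its running
minimum before interpolation: embolism cannot reverse during a drydown,
and raw sensor blips would otherwise fold the PEP–Ψ mapping back on
itself. Interpolation is linear and strictly interior — frames outside
the timeline span raise rather than extrapolate. No image registration is
applied (leaves are physically clamped in the protocol), but a QC check
flags frame pairs whose global translation exceeds 2 px by phase
cross-correlation.

All-zero frames before the first event are retained in the PEP curve
(an intact leaf at high Ψ is a real observation); the sigmoid is fitted to
(Ψ, PEP) exactly as to (Ψ, PLC).

## Anatomy

Equivalent circle diameter D = 2·√(area/π) per vessel; hydraulically
weighted diameter D_H = ΣD⁵/ΣD⁴ (the standard flow-weighted convention —
each vessel weighted by its D⁴ conductance); vessel density = count per
mm² of xylem. Theoretical specific conductivity:

    k_th = Σ(π·D⁴·ρ / (128·η)) / A_xyl

with D in metres, ρ = 998.2 kg m⁻³ and η = 1.002×10⁻⁹ MPa·s (water at
20 °C; equal to 1.002×10⁻³ Pa·s). Unit handling is tested both ways
(µm-input path versus all-SI) to 10⁻¹² relative. The anatomy–hydraulics
correlation screen is a plain Pearson report over matched varieties,
refused below 3 matches; it is descriptive, not a mixed model.

## Clustering and regional risk

Variety means of Ψ12/Ψ50/Ψ88 (slope excluded — the classification is
about thresholds, not propagation speed) are Z-scored per column with the
sample (n−1) standard deviation, then Ward-clustered on Euclidean
distances (Ward.D2 convention, the default of modern libraries) and cut at
k = 4. Clusters are ranked by raw Ψ50 centroid, most negative (most
resistant) first: low → low-to-medium → medium-to-high → high, with ties
broken by the Ψ88 then Ψ12 centroid. Each class carries the midpoint of
its quarter of a 0–1 vulnerability scale: 0.125, 0.375, 0.625, 0.875.

The regional index weights each class's bearing area (percent of the
total regional winegrape area):

    RI = 0.125·a_low + 0.375·a_lm + 0.625·a_mh + 0.875·a_high ∈ [0, 87.5].

Bearing percents are taken relative to the *total* regional area including
varieties outside the panel, and uncovered area contributes zero — so RI
can fall below the 12.5 floor that full low-vulnerability coverage would
impose. There is no renormalisation by coverage. The reporting filter is
inclusive: coverage ≥ 40% is reported. Varieties without a cluster label
are logged and treated as uncovered.

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes, at the study's own scales:

* **Sweeps**: pressure grid −0.8 to −5.3 MPa in −0.5 steps (10 points);
  per-plant (Ψ50, S) drawn Normal around variety truth; conductivity
  noise multiplicative Gaussian with coefficient of variation 0.05 by
  default — conductivity error scales with the flow measured, and no
  published magnitude exists for this instrument, so the default is a
  free parameter chosen to represent a well-run centrifuge bench.
* **Cohorts**: tens of varieties × several plants, mirroring a
  multi-genotype screening campaign.
* **Image stacks**: 8-bit frames at 5-min spacing; events are contiguous
  quasi-disc blobs with a permanent +40 gray-level step (≥5× the default
  background noise sd) so detector behaviour is controllable.
  `gen_sigmoid_stack` places events on a disjoint spatial grid so the
  injected event count and pixel total are exactly recoverable; increments
  below the particle-filter minimum are carried into the next event.
* **Timelines**: 30-min psychrometer spacing; linear or exponential
  drydown; default span 130 h (a summer dehydration; spring runs nearer
  80 h).
* **Vessels**: lognormal diameters, median 50 µm — typical grapevine stem
  metaxylem.
* **Bearing tables**: per region, an uncovered fraction is drawn, and the
  covered remainder is split across panel varieties by a symmetric
  Dirichlet.

Every generator is deterministic per seed (sub-draws derive from one
`numpy` Generator) and returns a truth log sufficient for recovery tests.

What the generators do **not** emulate: scanner optics, leaf shrinkage
and registration drift, psychrometer calibration error, open-vessel
artefacts in long-vesseled species, and the spatial autocorrelation of
real varietal plantings. Passing tests therefore demonstrate that the
analysis chain is correct and invertible under its stated assumptions, not
that those assumptions hold for any particular laboratory's data.

## Problem sizes and numerical choices

The test-suite and demo runs use deliberately compact sizes — e.g. 200
synthetic plants for parameter-recovery checks, 150-frame 256×256 stacks
for the optical round trip, 6 varieties × 4 plants × 3 regions for the
end-to-end demo — chosen so a full run completes in well under two minutes
on a single core while still exercising every code path at realistic
parameter values.

Tie-breaks and degenerate inputs are handled explicitly: zero-variance
Z-score columns raise; Ward clustering is deterministic for identical
input; cluster-rank ties fall back to Ψ88 then Ψ12; zero reference
conductivity, empty vessel sets, all-zero event series and
out-of-timeline frames all raise named errors instead of propagating NaN.

## Known limitations

* Only the Pammenter sigmoid is implemented; Weibull and incomplete-gamma
  VC models are out of scope.
* The group contrast is a plain Student's t — no post-hoc family or nested
  random effects.
* The optical module does not classify vein orders or detect the
  mesophyll-death endpoint.
* The risk index treats each bearing-table row as independent and makes no
  assumption about region/country double counting in source databases.
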
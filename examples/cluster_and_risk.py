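"""From variety thresholds to vulnerability clusters to regional risk.

Z-scores a small panel's psi12/psi50/psi88 means, Ward-clusters it into
the four ordered vulnerability classes, joins the class weights with a
synthetic regional bearing-area table and prints each region's risk index.
"""

import pandas as pd

from vitivc import cluster_varieties, gen_bearing_table, regional_risk, ri_report

means = pd.DataFrame(
    dict(
        variety=["Sultanine", "Chardonnay", "Ugni blanc", "Syrah", "Pinot noir", "110R"],
        psi50=[-1.9, -2.3, -2.5, -3.0, -3.3, -3.4],
    )
)
means["psi12"] = means["psi50"] + 0.5
means["psi88"] = means["psi50"] - 0.5

assignment = cluster_varieties(means, k=4)
print(assignment.to_string(index=False))

bearing, _ = gen_bearing_table(
    regions=4, varieties=means["variety"].tolist(),
    uncovered_fraction_range=(0.0, 0.4), seed=8,
)
risks = regional_risk(bearing, assignment, min_coverage=40.0)
report, summary = ri_report(risks)
print(report[["region", "coverage_percent", "ri", "included"]].round(1).to_string(index=False))
print(f"RI range over reported regions: {summary['ri_min']:.1f}-{summary['ri_max']:.1f} "
      f"(scale 0-87.5; higher = more bearing area on vulnerable varieties)")
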
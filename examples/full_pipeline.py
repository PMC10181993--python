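"""One-call end-to-end run: simulate -> fit -> aggregate -> cluster -> risk.

Writes every artefact (sweeps, fits, variety summary, cluster assignment,
regional risks, manifest with checksums) under ./vitivc-demo.
"""

import pandas as pd

from vitivc import RunConfig, run_all

manifest = run_all(RunConfig(out_dir="vitivc-demo", seed=1, n_regions=3))

print("stages:", " -> ".join(manifest.stages))
risks = pd.read_csv("vitivc-demo/risks.csv")
print(risks[["region", "coverage_percent", "ri"]].round(1).to_string(index=False))
print(f"{len(manifest.outputs)} artefacts written, each checksummed in "
      "vitivc-demo/manifest.json; rerunning with the same seed reproduces "
      "identical hashes.")
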
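"""Run the whole pipeline end to end on the built-in synthetic demo.

simulate -> resilience -> aci -> anova, all from one config with one seed.
Writes panel.csv, aci_*.csv, experiment.csv, per-stage JSON reports and a
provenance-stamped report.json under ./demo_output, then prints the
headline numbers.
"""

import json
from pathlib import Path

from c4drought import pipeline

cfg = pipeline.demo_config(seed=42)
report = pipeline.run_all(cfg, "demo_output")

print({name: st["status"] for name, st in report["stages"].items()})

res = json.loads(Path("demo_output/resilience.json").read_text())
for sp, r in res.items():
    beta_true = cfg["simulate"]["timeseries"][sp]["beta"]
    print(f"{sp}: resistance {r['resistance']:.2f} "
          f"(truth {-2 * beta_true:.2f}), AR order {r['order']}")

aci = report["stages"]["aci"]["summary"]
print(f"mean RSL = {aci['mean_RSL_pct']:.1f}%, mean RML = {aci['mean_RML_pct']:.1f}% "
      f"over {aci['n_partitions']} drought leaves")

anova = json.loads(Path("demo_output/anova.json").read_text())
for sp, rep in anova.items():
    drought = next(c for c in rep["contrasts"] if c["label"] == "treatment=drought")
    print(f"{sp}: Pr(drought effect) = {drought['pr']:.3f} [{drought['significance']}]")
print()
print("The sensitive species should show a significant drought effect on "
      "relative water content and a stronger (more negative) resistance; "
      "rerunning with the same seed reproduces every file byte-for-byte.")
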
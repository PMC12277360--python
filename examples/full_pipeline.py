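"""Run every stage end-to-end from one config and inspect the manifest.

simulate -> questionnaire scoring -> metric panel -> cutotype/aging labels
-> microbiome clustering -> core-genus selection -> type models, with all
outputs and a reproducibility manifest written to a run directory.
"""

import json

from kscope.pipeline import RunConfig, run

config = RunConfig(n_subjects=250, seed=9)
manifest = run(config, "scratch/example_run")

print("Stages executed:", ", ".join(manifest["stages"]))
print("Cluster stage:", json.dumps(manifest["stages"]["cluster"], indent=1))
print("Core stage:", manifest["stages"]["core"])
print("Outputs written:")
for name, entry in manifest["outputs"].items():
    print(f"  {name:<22s} {entry['path']}")
print("\nRe-running with the same config reproduces identical sha256 hashes "
      "for every output (the manifest records them).")
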
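"""Run the entire pipeline on a simulated bundle and show the manifest.

Equivalent shell command:  ambropop run --simulate --seed 7 --out out/
"""

import json
import tempfile
from pathlib import Path

from ambropop.pipeline import PipelineConfig, run_pipeline
from ambropop.simulate import SimulationConfig

with tempfile.TemporaryDirectory() as tmp:
    manifest = run_pipeline(PipelineConfig(seed=7), None, tmp,
                            simulate=SimulationConfig(seed=7))
    print("stages run:", [s["name"] for s in manifest["stages"]])
    print("\noutputs written:")
    for p in sorted(Path(tmp).glob("*")):
        print(" ", p.name)
    net_stage = next(s for s in manifest["stages"] if s["name"] == "network")
    print("\nmodule conservation summary:",
          json.dumps(net_stage["class_counts"]))
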
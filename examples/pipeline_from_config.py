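"""Run a reproducible end-to-end pipeline from a configuration dict.

The same configuration (including the seed) always produces byte-identical
outputs; the resolved parameter set is written next to the results.
"""

import json
import tempfile
from pathlib import Path

from granulekit.io import run_pipeline

out = Path(tempfile.mkdtemp()) / "frap_run"
config = {
    "pipeline": "frap",
    "seed": 2,
    "simulate": {
        "truth": {"mobile_fraction": 0.436, "rate_per_s": 0.066,
                  "bleach_depth": 0.8},
        "n_traces": 10,
        "duration_s": 240.0,
        "config": {"poisson": False, "gaussian_sigma": 0.02},
    },
    "params": {"mode": "full_scale"},
}
results = run_pipeline(config, out)
print(f"outputs written to {out}:")
for p in sorted(out.iterdir()):
    print(f"  {p.name}")
fit = json.loads((out / "fit.json").read_text())
print(f"fitted mobile fraction: {fit['mobile_fraction']:.1f} % "
      f"(simulated truth 43.6 %)")
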
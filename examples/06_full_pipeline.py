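"""The complete analysis chain in one call.

Runs quantification -> isotope partitioning -> ammonia speciation ->
community FBA (both scenarios) -> thermodynamic sweep on synthetic inputs
and prints the machine-readable summary that `run_all` writes to disk.
"""

import json
import tempfile

from syntrophyflux.orchestrate import run_all

config = {
    "seed": 1,
    "proteomics": {"synthetic": {}},
    "headspace": {"synthetic": {}},
    "ammonia": {"tan": 1.6, "ph": 8.0, "temperature": 328.15},
}

with tempfile.TemporaryDirectory() as out_dir:
    summary = run_all(config, out_dir)

print(json.dumps({k: summary[k] for k in
                  ("quant", "partition", "ammonia", "fba", "fba_dropped", "thermo")},
                 indent=1, default=float))
print("\nEach block is produced by one module; rerunning with the same seed "
      "and configuration reproduces the file byte for byte.")
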
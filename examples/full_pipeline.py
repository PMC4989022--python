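"""Run the whole study pipeline from a YAML configuration.

Writes the ladder, simulated trial logs, threshold report with sensitivity
groups, a discrimination-panel table and a rating summary, plus a manifest
recording the seed and configuration hash, into ./pipeline_out.
"""

import tempfile
from pathlib import Path

from fattaste import StudyConfig, run_pipeline

CONFIG = """
seed: 2024
out_dir: pipeline_out
series: {bottom: 0.0028, n_levels: 12, log_step: 0.25}
staircase: {min_reversals: 4}
classification: {rule: tail, alpha: 0.05}
cohort: {n_observers: 51, sigma: 0.25, lapse: 0.01}
panel:
  n_assessors: 51
  dprimes: {"0vs2.5": 0.53, "0vs5": 1.12, "0vs7.5": 1.02, "2.5vs5": 0.32}
ratings: {n_participants: 51}
"""

with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as fh:
    fh.write(CONFIG)
    cfg_path = fh.name

paths = run_pipeline(StudyConfig.from_yaml(cfg_path))
for name, path in paths.items():
    print(f"{name:15s} -> {path}")
print("\nRe-running with the same seed reproduces every file byte for byte.")
Path(cfg_path).unlink()
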
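"""One-call end-to-end run: simulate, preprocess, compare, regress, report.

Writes every table (subject metrics, group comparisons, coefficient
functions with bands, significant windows, F-tests) to a run directory,
including the 60-minute sensitivity pass. Reruns with the same seed are
byte-identical.
"""

import json
from pathlib import Path

import pandas as pd

from actirar import PipelineConfig, SimConfig, run_pipeline

config = PipelineConfig(
    out_dir="scratch/example_run",
    sim=SimConfig(),
    seed=42,
    n_sim=5000,
    n_perm=999,
)
out = run_pipeline(config)
print(f"run directory: {out}")
for p in sorted(out.iterdir()):
    print(f"  {p.name}")

table = pd.read_csv(out / "rar_comparison_30min.csv")
print("\nscalar rhythm metrics by group (30-min bins):")
print(table[["outcome", "mean_pos", "mean_neg", "p_unadjusted", "B",
             "p_adjusted"]].to_string(index=False, float_format="%.3f"))

windows = pd.read_csv(out / "fosr_mean_30min_windows.csv")
sim_w = windows[(windows.covariate == "abeta") & (windows.band == "simultaneous")]
print("\nsimultaneous-band group windows (mean profiles):")
print(sim_w.to_string(index=False) if len(sim_w) else "  none")

ftests = json.loads((out / "ftests.json").read_text())
print("\nglobal F-tests:", {k: round(v["p"], 4) for k, v in ftests.items()})
print("\nThe time-localised windows are detected even when single-number "
      "metrics miss the difference; the 60-min pass shows the cost of "
      "coarser time resolution.")
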
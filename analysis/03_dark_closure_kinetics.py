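"""Quantify stomatal closure after lights-off for every leaf.

Baseline Gs, closure amplitude, t50 and t_max (with the post-lights-off
artifact window excluded), the two closure speeds, and the percentage of
baseline Gs remaining after 1 h of darkness. Writes results/kinetics.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import load_or_simulate, results_dir

from leafgas import io as lgio
from leafgas.kinetics import closure_kinetics

study = load_or_simulate()
results = [closure_kinetics(series) for series in study.darkness]
out = results_dir() / "kinetics.csv"
lgio.write_kinetics(results, out)
print(f"closure kinetics for {len(results)} leaves -> {out}")

table = pd.read_csv(out)
print(table.groupby(["species", "treatment"])
      [["gs0", "t50_s", "speed50", "pct_gs_1h"]].mean().round(2).to_string())
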
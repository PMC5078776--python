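"""Fit the FvCB model (finite mesophyll conductance) to every A/Ci sweep.

Two-pass fitting: per-leaf bounded least squares, then an empirical-Bayes
refit that shrinks weakly identified gm estimates toward the study
consensus. Writes one row per leaf to results/fits.csv and prints the
per-cell capacity means.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import load_or_simulate, results_dir

from leafgas.pipeline import fit_study_aci
from leafgas import io as lgio

study = load_or_simulate()
fits = fit_study_aci(study.aci)
out = results_dir() / "fits.csv"
lgio.write_fits(fits, out)
print(f"fitted {len(fits)} A/Ci curves -> {out}")

table = pd.read_csv(out)
unreliable = int((~table["converged"]).sum())
print(f"converged: {len(table) - unreliable}/{len(table)}")
print(table.groupby(["species", "treatment"])[["vcmax", "jmax", "gm"]]
      .mean().round(1).to_string())
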
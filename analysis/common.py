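"""Shared plumbing for the analysis drivers: one canonical simulated study.

The drivers analyse the default five-crop, 400-vs-2000-ppm study at master
seed 0. The raw per-leaf data tree lives under scratch/ (it is bulky);
summary tables land in results/.
"""

from pathlib import Path

from leafgas import io as lgio
from leafgas.synthetic import StudyData, default_study_design, simulate_study

MASTER_SEED = 0
ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "study_data"
RESULTS_DIR = ROOT / "results"


def load_or_simulate() -> StudyData:
    """Read the canonical study from scratch/, simulating it if absent."""
    if (DATA_DIR / "manifest.json").exists():
        return lgio.read_study(DATA_DIR)
    design = default_study_design(master_seed=MASTER_SEED)
    study = simulate_study(design)
    lgio.write_study(study, DATA_DIR, master_seed=MASTER_SEED)
    return study


def results_dir() -> Path:
    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    return RESULTS_DIR
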
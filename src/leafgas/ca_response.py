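"""Stomatal sensitivity to step changes in external CO2 (Ca).

In the stepped-Ca protocol the cuvette CO2 is raised through plateaus
(200, 400, 750, 1000, 2000 ppm) at constant light, temperature and VPD, and
the stabilized Gs_H2O is recorded at each step. Stomatal closure to CO2 is
the percentage of the 400-ppm conductance remaining at 2000 ppm; maximum
stomatal conductance (Gs_max) is the reading at 50 ppm Ca, which induces
full stomatal opening.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CaStepSeries",
    "PROTOCOL_CA_STEPS",
    "closure_to_ca",
    "gs_max",
    "plateau_from_trace",
    "sensitivity_profile",
]

#: Super-ambient step sequence of the protocol (ppm).
PROTOCOL_CA_STEPS = (200.0, 400.0, 750.0, 1000.0, 2000.0)


@dataclass
class CaStepSeries:
    """Plateau Gs_H2O (mmol m^-2 s^-1) at each applied Ca step (ppm).

    ``gs_at_50`` holds the separate 50-ppm full-opening reading; it sits
    outside the monotone step sequence.
    """

    ca: np.ndarray
    gs_h2o: np.ndarray
    gs_at_50: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.gs_h2o = np.asarray(self.gs_h2o, dtype=float)
        if self.ca.shape != self.gs_h2o.shape or self.ca.ndim != 1:
            raise ValueError("ca and gs_h2o must be equal-length 1-D arrays")
        if np.any(self.gs_h2o < 0):
            raise ValueError("gs_h2o must be non-negative")
        if self.gs_at_50 is not None and self.gs_at_50 < 0:
            raise ValueError("gs_at_50 must be non-negative")

    def gs_at(self, ca: float, atol: float = 0.5) -> float:
        hit = np.isclose(self.ca, ca, atol=atol)
        if not hit.any():
            raise ValueError(f"no recorded step at Ca = {ca:g} ppm")
        return float(self.gs_h2o[hit][0])


def closure_to_ca(series: CaStepSeries) -> float:
    """Stomatal closure to CO2: 100 * gs(2000 ppm) / gs(400 ppm).

    100 means no closure (the insensitive phenotype); smaller values mean
    tighter closure at high CO2.
    """
    gs400 = series.gs_at(400.0)
    gs2000 = series.gs_at(2000.0)
    if gs400 <= 0:
        raise ValueError("gs at 400 ppm must be positive")
    return 100.0 * gs2000 / gs400


def gs_max(series: CaStepSeries) -> float:
    """Maximum stomatal conductance: the Gs_H2O reading at 50 ppm Ca."""
    if series.gs_at_50 is None:
        raise ValueError("no 50-ppm (full-opening) Gs record in this series")
    return float(series.gs_at_50)


def sensitivity_profile(series: CaStepSeries) -> pd.Series:
    """Per-step Gs normalized to the 400-ppm value, in protocol order (%)."""
    gs400 = series.gs_at(400.0)
    if gs400 <= 0:
        raise ValueError("gs at 400 ppm must be positive")
    order = np.argsort(series.ca)
    return pd.Series(
        100.0 * series.gs_h2o[order] / gs400,
        index=pd.Index(series.ca[order], name="ca_ppm"),
        name="gs_pct_of_400",
    )


def plateau_from_trace(
    t: np.ndarray, gs_h2o: np.ndarray, window_s: float = 60.0
) -> float:
    """Plateau conductance from a raw step trace: mean of the final window."""
    t = np.asarray(t, dtype=float)
    gs = np.asarray(gs_h2o, dtype=float)
    mask = t >= t[-1] - window_s
    return float(np.mean(gs[mask]))
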
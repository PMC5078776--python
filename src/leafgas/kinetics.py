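"""Stomatal closure kinetics after a light-to-dark transition.

After illumination ceases, stomatal conductance to water vapor (Gs_H2O,
mmol m^-2 s^-1, logged at ~10-s cadence) relaxes toward a dark plateau. The
closure speed is not uniform, so two summary rates are reported: the mean
rate over the first 50% of the closure amplitude (speed50 = 0.5*amplitude /
t50) and the mean rate to the maximum extent of closure (speed_max =
amplitude / t_max). Tightness of closure is the percentage of the pre-dark
baseline remaining one hour into darkness.

Cuvette traces show an unstable transient for a short period immediately
after lights-off (a measurement artifact of the humidity/temperature
control), so a configurable artifact window is excluded before the minimum
and crossing detection; the trace is smoothed with a centered moving median
to resist single-sample spikes, and crossing times are refined by linear
interpolation between the bracketing samples so the sampling cadence does
not quantize speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClosureKinetics",
    "GsTimeSeries",
    "KineticsConfig",
    "baseline_gs",
    "closure_kinetics",
    "closure_percentage_dark",
]


@dataclass
class GsTimeSeries:
    """A logged Gs_H2O trace around a lights-off event.

    t is seconds since recording start (strictly increasing), gs_h2o in
    mmol m^-2 s^-1, lights_off_t the instant illumination ceased.
    """

    t: np.ndarray
    gs_h2o: np.ndarray
    lights_off_t: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gs_h2o = np.asarray(self.gs_h2o, dtype=float)
        if self.t.shape != self.gs_h2o.shape or self.t.ndim != 1:
            raise ValueError("t and gs_h2o must be equal-length 1-D arrays")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.gs_h2o < 0):
            raise ValueError("gs_h2o must be non-negative")


@dataclass(frozen=True)
class KineticsConfig:
    """Operational definitions for closure detection.

    artifact_window_s: seconds after lights-off excluded from detection.
    smooth_samples: width of the centered moving median (odd).
    plateau_tol_frac: band above gs_min, as a fraction of amplitude, whose
        sustained first entry defines attainment of maximum closure.
    plateau_hold_samples: consecutive in-band samples required.
    baseline_window_s: pre-dark averaging window for gs0.
    baseline_cv_threshold: CV above which the baseline is flagged unstable.
    min_amplitude: closure amplitude (mmol m^-2 s^-1) below which the trace
        is flagged "no-closure" and speeds are undefined.
    """

    artifact_window_s: float = 120.0
    smooth_samples: int = 5
    plateau_tol_frac: float = 0.02
    plateau_hold_samples: int = 3
    baseline_window_s: float = 60.0
    baseline_cv_threshold: float = 0.02
    min_amplitude: float = 5.0


@dataclass
class ClosureKinetics:
    """Summary of one dark-closure trace (units as GsTimeSeries)."""

    gs0: float
    gs_min: float
    amplitude: float
    t50: float | None
    t_max: float | None
    speed50: float | None
    speed_max: float | None
    pct_gs_1h: float
    no_closure: bool = False
    baseline_unstable: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def pct_closed_1h(self) -> float:
        return 100.0 - self.pct_gs_1h


def baseline_gs(
    series: GsTimeSeries, window_s: float = 60.0
) -> tuple[float, float]:
    """Mean and CV of gs over the ``window_s`` seconds before lights-off."""
    mask = (series.t >= series.lights_off_t - window_s) & (
        series.t < series.lights_off_t
    )
    if np.count_nonzero(mask) < 3:
        raise ValueError(
            f"fewer than 3 samples in the {window_s}-s pre-dark window"
        )
    vals = series.gs_h2o[mask]
    mean = float(np.mean(vals))
    cv = float(np.std(vals) / mean) if mean > 0 else 0.0
    return mean, cv


def _moving_median(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.copy()
    if width % 2 == 0:
        raise ValueError("smoothing width must be odd")
    half = width // 2
    padded = np.pad(x, half, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(padded, width)
    return np.median(windows, axis=1)


def _first_crossing_time(
    t: np.ndarray, y: np.ndarray, threshold: float
) -> float | None:
    """First time y falls to/below threshold, linearly interpolated."""
    below = y <= threshold
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0 or y[i - 1] <= threshold:
        return float(t[i])
    # linear interpolation between the bracketing samples
    t0, t1 = t[i - 1], t[i]
    y0, y1 = y[i - 1], y[i]
    return float(t0 + (y0 - threshold) / (y0 - y1) * (t1 - t0))


def closure_kinetics(
    series: GsTimeSeries, config: KineticsConfig | None = None
) -> ClosureKinetics:
    """Quantify dark-induced stomatal closure from a Gs time series.

    gs_min is the minimum of the smoothed post-artifact dark trace; t50 is
    the interpolated first crossing of gs0 - 0.5*amplitude; t_max the first
    entry into the plateau band (gs_min + plateau_tol_frac*amplitude) that
    is held for ``plateau_hold_samples`` consecutive samples. Times are
    seconds since lights-off.
    """
    config = config or KineticsConfig()
    t_off = series.lights_off_t
    if series.t[-1] < t_off + 3600.0:
        raise ValueError("series must extend at least 1 h past lights-off")
    gs0, cv = baseline_gs(series, config.baseline_window_s)
    unstable = cv > config.baseline_cv_threshold

    dark = series.t >= t_off
    t_dark = series.t[dark] - t_off
    gs_dark = _moving_median(series.gs_h2o[dark], config.smooth_samples)

    detect = t_dark >= config.artifact_window_s
    if not detect.any():
        raise ValueError("no samples beyond the artifact window")
    gs_min = float(np.min(gs_dark[detect]))
    amplitude = gs0 - gs_min

    # percent of baseline remaining after 1 h of darkness (smoothed trace)
    i_1h = int(np.argmin(np.abs(t_dark - 3600.0)))
    if abs(t_dark[i_1h] - 3600.0) > 60.0:
        raise ValueError("no sample within 60 s of 1 h after lights-off")
    pct_1h = 100.0 * float(gs_dark[i_1h]) / gs0

    if amplitude < config.min_amplitude:
        return ClosureKinetics(
            gs0=gs0, gs_min=gs_min, amplitude=amplitude,
            t50=None, t_max=None, speed50=None, speed_max=None,
            pct_gs_1h=pct_1h, no_closure=True, baseline_unstable=unstable,
            meta=dict(series.meta),
        )

    t_det = t_dark[detect]
    gs_det = gs_dark[detect]
    t50 = _first_crossing_time(t_det, gs_det, gs0 - 0.5 * amplitude)

    band = gs_min + config.plateau_tol_frac * amplitude
    in_band = gs_det <= band
    t_max = None
    hold = config.plateau_hold_samples
    for i in np.flatnonzero(in_band):
        if i + hold <= in_band.size and in_band[i : i + hold].all():
            t_max = _first_crossing_time(t_det[: i + 1], gs_det[: i + 1], band)
            break

    speed50 = (0.5 * amplitude / t50) if t50 is not None and t50 > 0 else None
    speed_max = (amplitude / t_max) if t_max is not None and t_max > 0 else None
    return ClosureKinetics(
        gs0=gs0, gs_min=gs_min, amplitude=amplitude,
        t50=t50, t_max=t_max, speed50=speed50, speed_max=speed_max,
        pct_gs_1h=pct_1h, no_closure=False, baseline_unstable=unstable,
        meta=dict(series.meta),
    )


def closure_percentage_dark(
    series: GsTimeSeries, config: KineticsConfig | None = None
) -> float:
    """Percentage of the pre-dark baseline Gs remaining after 1 h of darkness."""
    config = config or KineticsConfig()
    gs0, _ = baseline_gs(series, config.baseline_window_s)
    dark = series.t >= series.lights_off_t
    t_dark = series.t[dark] - series.lights_off_t
    gs_dark = _moving_median(series.gs_h2o[dark], config.smooth_samples)
    i = int(np.argmin(np.abs(t_dark - 3600.0)))
    if abs(t_dark[i] - 3600.0) > 60.0:
        raise ValueError("no sample within 60 s of 1 h after lights-off")
    return 100.0 * float(gs_dark[i]) / gs0
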
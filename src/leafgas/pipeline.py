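"""End-to-end study analysis: per-leaf estimates, Delta tables, and the
capacity-vs-stomatal-control regressions.

Takes a study's per-leaf datasets (measured or simulated), runs each
protocol's estimator, assembles a tidy per-leaf table, reduces it to
per-species Delta values (elevated as % of ambient) and regresses the
relative change in photosynthetic capacity against the relative change in
stomatal control.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from leafgas.ca_response import closure_to_ca, gs_max
from leafgas.fvcb import FitConfig, KineticConstants, fit_aci
from leafgas.kinetics import KineticsConfig, closure_kinetics
from leafgas.stats import (
    RegressionResult,
    delta_table,
    fv_fm,
    ols_regression,
    phi_psii,
)
from leafgas.synthetic import StudyData

__all__ = [
    "DELTA_PARAMETERS",
    "analyze_study",
    "delta_regression",
    "fit_study_aci",
    "study_delta_table",
]

#: Parameters the Delta table is computed over (those present are used).
DELTA_PARAMETERS = (
    "vcmax", "jmax", "gm", "pn_max", "gs0",
    "closure_to_dark", "speed50", "speed_max",
    "gs_max", "closure_to_ca", "fv_fm", "phi_psii",
)


def fit_study_aci(
    curves,
    constants: KineticConstants | None = None,
    config: FitConfig | None = None,
    gm_shrinkage: bool = True,
) -> list:
    """Per-leaf FvCB fits, optionally with a second empirical-Bayes pass.

    A single A/Ci curve identifies gm only jointly with vcmax (the familiar
    ridge), and low-signal curves can land on a wrong-mode solution (gm far
    too small, vcmax far too large) with nearly the same RSS. The second
    pass shrinks log-gm toward the consensus of the first-pass fits with a
    weak lognormal penalty scaled by each curve's residual noise, which
    resolves those ambiguous modes without constraining well-identified
    curves.
    """
    config = config or FitConfig()
    fits = [fit_aci(c, constants=constants, config=config) for c in curves]
    if not gm_shrinkage or len(fits) < 3 or config.gm_log_prior is not None:
        return fits
    log_gm = np.array([
        np.log(f.params.gm) for f in fits if f.reliable
    ])
    if log_gm.size < 3:
        return fits
    mu = float(np.median(log_gm))
    mad_sd = 1.4826 * float(np.median(np.abs(log_gm - mu)))
    sigma = max(mad_sd, 0.25)
    refits = []
    for curve, first in zip(curves, fits):
        dof = max(first.n_points - 4, 1)
        noise_sd = max(np.sqrt(first.rss / dof), 1e-3)
        cfg = replace(config, gm_log_prior=(mu, sigma),
                      prior_noise_sd=float(noise_sd))
        refits.append(fit_aci(curve, constants=constants, config=cfg,
                              initial=first.params))
    return refits


def analyze_study(
    study: StudyData,
    constants: KineticConstants | None = None,
    fit_config: FitConfig | None = None,
    kinetics_config: KineticsConfig | None = None,
    gm_shrinkage: bool = True,
) -> pd.DataFrame:
    """Run every estimator over a study's datasets.

    Returns one row per leaf keyed by (species, treatment, replicate) with
    whichever estimates that leaf's protocols support: FvCB parameters from
    the A/Ci fit (with study-level gm shrinkage unless disabled), closure
    kinetics from the darkness trace (closure_to_dark is the percent of
    baseline Gs *closed* after 1 h), Gs_max and closure to Ca from the step
    session, and fluorescence indices.
    """
    rows: dict[tuple, dict] = {}

    def row(meta: dict) -> dict:
        key = (meta.get("species"), meta.get("treatment"), meta.get("replicate"))
        return rows.setdefault(
            key, {"species": key[0], "treatment": key[1], "replicate": key[2]}
        )

    fits = fit_study_aci(study.aci, constants, fit_config, gm_shrinkage)
    for curve, fit in zip(study.aci, fits):
        r = row(curve.meta)
        # QC: boundary-gm or unconstrained fits carry NaN parameters so they
        # drop out of treatment means instead of distorting them
        nan = float("nan")
        r.update(
            vcmax=fit.params.vcmax if fit.reliable else nan,
            jmax=fit.params.jmax if fit.reliable else nan,
            rd=fit.params.rd if fit.reliable else nan,
            gm=fit.params.gm if fit.reliable else nan,
            pn_max=fit.pn_max, rss=fit.rss,
            fit_converged=fit.converged, fit_reliable=fit.reliable,
        )

    for series in study.darkness:
        kin = closure_kinetics(series, kinetics_config)
        r = row(series.meta)
        r.update(
            gs0=kin.gs0, gs_min=kin.gs_min,
            t50=kin.t50, t_max=kin.t_max,
            speed50=kin.speed50, speed_max=kin.speed_max,
            pct_gs_1h=kin.pct_gs_1h,
            closure_to_dark=kin.pct_closed_1h,
            no_closure=kin.no_closure,
        )

    for steps in study.ca_steps:
        r = row(steps.meta)
        r.update(gs_max=gs_max(steps), closure_to_ca=closure_to_ca(steps))

    if study.fluorescence is not None:
        for _, fl in study.fluorescence.iterrows():
            r = row(fl.to_dict())
            r.update(
                fv_fm=fv_fm(fl["fo"], fl["fm"]),
                phi_psii=phi_psii(fl["fs"], fl["fm_prime"]),
            )

    return pd.DataFrame(sorted(rows.values(),
                               key=lambda d: (d["species"], d["treatment"],
                                              d["replicate"])))


def study_delta_table(
    per_leaf: pd.DataFrame,
    parameters: tuple[str, ...] = DELTA_PARAMETERS,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Delta (% of ambient) per species for every available parameter."""
    present = [p for p in parameters if p in per_leaf.columns]
    return delta_table(per_leaf, present, n_boot=n_boot, seed=seed)


def delta_regression(
    deltas: pd.DataFrame,
    x_parameter: str = "vcmax",
    y_parameter: str = "closure_to_dark",
) -> RegressionResult:
    """OLS of one parameter's per-species Delta against another's.

    The headline comparison is Delta closure-to-darkness (tightness of dark
    closure retained at elevated CO2) against Delta vcmax: species that keep
    their carboxylation capacity also keep closing their stomata.
    """
    wide = deltas.pivot(index="species", columns="parameter", values="delta_pct")
    for p in (x_parameter, y_parameter):
        if p not in wide.columns:
            raise ValueError(f"no Delta values for parameter {p!r}")
    sub = wide[[x_parameter, y_parameter]].dropna()
    return ols_regression(sub[x_parameter].to_numpy(),
                          sub[y_parameter].to_numpy())
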
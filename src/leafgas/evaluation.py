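"""Verification experiments: oracle agreement, parameter recovery, test-size
calibration, and the end-to-end capacity/closure direction check.

Each function here re-runs one self-contained experiment from scratch and
returns plain numbers, so the same code backs both the test suite and the
reproduction script. All randomness is seeded explicitly.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from leafgas.fvcb import (
    AciCurve,
    FvcbParams,
    KineticConstants,
    fit_aci,
    fixed_point_assimilation,
    forward_fvcb,
)
from leafgas.kinetics import KineticsConfig, closure_kinetics
from leafgas.pipeline import analyze_study, delta_regression, study_delta_table
from leafgas.stats import delta_change, ols_regression, two_way_anova
from leafgas.synthetic import (
    ACI_CA_SEQUENCE,
    default_study_design,
    null_study_design,
    simulate_study,
)

__all__ = [
    "REPORTED_GS_H2O",
    "coupled_impairment_study",
    "gs_delta_summary",
    "kinetics_closed_form_check",
    "recovery_study",
    "solver_oracle_agreement",
    "stats_oracle_checks",
    "twoway_null_calibration",
]

#: Published per-species Gs_H2O treatment means (mmol m^-2 s^-1) at growth
#: CO2, ambient (400 ppm) vs elevated (2000 ppm).
REPORTED_GS_H2O = {
    "oat": (669.7, 439.4),
    "wheat": (511.2, 416.4),
    "cotton": (138.3, 137.7),
    "sunflower": (976.5, 498.6),
    "barley": (874.0, 585.5),
}

#: The reference truth used throughout the recovery experiments.
RECOVERY_TRUTH = FvcbParams(vcmax=100.0, jmax=150.0, rd=1.5, gm=0.3)


def gs_delta_summary() -> dict[str, float]:
    """Percent reduction in Gs_H2O at elevated growth CO2 per species."""
    return {species: delta_change(amb, elev).pct_lower
            for species, (amb, elev) in REPORTED_GS_H2O.items()}


def solver_oracle_agreement(
    n_ci: int = 50,
    n_gm: int = 20,
    constants: KineticConstants | None = None,
) -> dict[str, float]:
    """Quadratic-root solver vs the damped fixed-point oracle on a
    (ci, gm) grid, plus the infinite-gm rectangular limit."""
    constants = constants or KineticConstants()
    ci_grid = np.linspace(50.0, 2000.0, n_ci)
    gm_values = np.geomspace(0.05, 5.0, n_gm)
    worst = 0.0
    n_points = 0
    for gm in gm_values:
        params = replace(RECOVERY_TRUTH, gm=gm)
        for ci in ci_grid:
            a_quad = forward_fvcb(params, constants, float(ci)).a
            a_fp = fixed_point_assimilation(params, constants, float(ci))
            worst = max(worst, abs(a_quad - a_fp))
            n_points += 1
    # infinite-gm limit against the closed rectangular form
    inf_params = replace(RECOVERY_TRUTH, gm=math.inf)
    gs, km = constants.gamma_star, constants.km_effective
    worst_inf = 0.0
    for ci in ci_grid:
        a = forward_fvcb(inf_params, constants, float(ci)).a
        rect = min(
            inf_params.vcmax * (ci - gs) / (ci + km),
            inf_params.jmax / 4.0 * (ci - gs) / (ci + 2 * gs),
        ) - inf_params.rd
        worst_inf = max(worst_inf, abs(a - rect))
    return {"max_abs_da": worst, "n_grid": n_points,
            "max_abs_da_infinite_gm": worst_inf}


def recovery_study(
    n_curves: int = 100,
    noise_sd: float = 0.5,
    seed: int = 0,
    constants: KineticConstants | None = None,
) -> dict[str, float]:
    """Monte-Carlo self-consistency of the A/Ci estimator.

    Noiseless forward curves at the 16-step protocol grid are perturbed with
    Gaussian noise and refitted; reports median |relative error| of vcmax
    and jmax, the fraction of gm estimates within a factor 1.5 of truth, and
    the worst-case noiseless recovery error.
    """
    constants = constants or KineticConstants()
    ci = np.asarray(ACI_CA_SEQUENCE, dtype=float)
    a_true = forward_fvcb(RECOVERY_TRUTH, constants, ci).a

    fit0 = fit_aci(AciCurve(ci=ci, a=a_true, ca=ci), constants)
    noiseless_err = max(
        abs(getattr(fit0.params, n) - getattr(RECOVERY_TRUTH, n))
        / getattr(RECOVERY_TRUTH, n)
        for n in ("vcmax", "jmax", "rd", "gm")
    )

    seeds = np.random.SeedSequence(seed).generate_state(n_curves) % (2**31)
    err_v, err_j, gm_ok = [], [], 0
    for s in seeds:
        rng = np.random.default_rng(int(s))
        curve = AciCurve(ci=ci, a=a_true + rng.normal(0, noise_sd, ci.size),
                         ca=ci)
        fit = fit_aci(curve, constants)
        err_v.append(abs(fit.params.vcmax - RECOVERY_TRUTH.vcmax)
                     / RECOVERY_TRUTH.vcmax)
        err_j.append(abs(fit.params.jmax - RECOVERY_TRUTH.jmax)
                     / RECOVERY_TRUTH.jmax)
        ratio = fit.params.gm / RECOVERY_TRUTH.gm
        gm_ok += (1 / 1.5 <= ratio <= 1.5)
    return {
        "noiseless_max_rel_err_pct": 100.0 * noiseless_err,
        "vcmax_median_rel_err_pct": 100.0 * float(np.median(err_v)),
        "jmax_median_rel_err_pct": 100.0 * float(np.median(err_j)),
        "gm_within_factor_1p5_pct": 100.0 * gm_ok / n_curves,
        "n_curves": n_curves,
    }


def kinetics_closed_form_check(
    taus: tuple[float, ...] = (100.0, 300.0, 600.0),
    cadence: float = 10.0,
    gs0: float = 600.0,
    floor: float = 100.0,
) -> dict[str, float]:
    """Closure-time estimates on noiseless exponential decay vs closed form.

    t50 should land within one sampling interval of tau ln 2 and t_max
    within one interval of tau ln 50 at the 2% plateau tolerance.
    """
    from leafgas.kinetics import GsTimeSeries

    worst_t50 = worst_tmax = 0.0
    speed_ok = True
    for tau in taus:
        t = np.arange(0.0, 900.0 + max(3700.0, 8 * tau), cadence)
        dt = t - 900.0
        gs = np.where(dt < 0, gs0,
                      floor + (gs0 - floor) * np.exp(-np.maximum(dt, 0) / tau))
        series = GsTimeSeries(t=t, gs_h2o=gs, lights_off_t=900.0)
        kin = closure_kinetics(series, KineticsConfig(artifact_window_s=0.0))
        worst_t50 = max(worst_t50, abs(kin.t50 - tau * math.log(2)))
        worst_tmax = max(worst_tmax, abs(kin.t_max - tau * math.log(50)))
        speed_ok &= kin.speed50 >= kin.speed_max
    return {"max_t50_error_s": worst_t50, "max_tmax_error_s": worst_tmax,
            "speed50_geq_speedmax": float(speed_ok),
            "cadence_s": cadence}


def stats_oracle_checks(seed: int = 0) -> dict[str, float]:
    """OLS vs normal equations, the F identity, and ANOVA SS conservation."""
    rng = np.random.default_rng(seed)
    worst_beta = worst_f = worst_ss = 0.0
    for _ in range(20):
        n = int(rng.integers(8, 40))
        x = rng.uniform(0, 10, n)
        y = rng.normal(1.0 + 0.7 * x, 1.0)
        res = ols_regression(x, y)
        X = np.column_stack([np.ones(n), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        worst_beta = max(worst_beta, abs(res.intercept - beta[0]),
                         abs(res.slope - beta[1]))
        worst_f = max(worst_f,
                      abs(res.f_stat - res.r2 / (1 - res.r2) * (n - 2)))
        # one-way SS conservation on a 3-group split of the same data
        groups = np.array_split(y, 3)
        grand = y.mean()
        ss_total = float(np.sum((y - grand) ** 2))
        ss_between = float(sum(g.size * (g.mean() - grand) ** 2
                               for g in groups))
        ss_within = float(sum(np.sum((g - g.mean()) ** 2) for g in groups))
        worst_ss = max(worst_ss, abs(ss_total - ss_between - ss_within))
    return {"ols_max_abs_diff": worst_beta, "f_identity_max_abs_diff": worst_f,
            "anova_ss_max_abs_diff": worst_ss}


def twoway_null_calibration(n_seeds: int = 200, seed: int = 0) -> dict[str, float]:
    """Size calibration of the CO2 main effect: under a null study design
    the two-way-ANOVA p-values should be uniform (KS test)."""
    from scipy import stats as sps

    from leafgas.ca_response import gs_max

    base_seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    pvals = []
    for s in base_seeds:
        design = null_study_design(master_seed=int(s))
        study = simulate_study(design)
        values, fa, fb = [], [], []
        for steps in study.ca_steps:
            values.append(gs_max(steps))
            fa.append(steps.meta["species"])
            fb.append(steps.meta["treatment"])
        res = two_way_anova(values, fa, fb)
        pvals.append(res["factor_b"].p_value)
    ks = sps.kstest(pvals, "uniform")
    return {"ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
            "n_seeds": n_seeds}


def coupled_impairment_study(n_studies: int = 100, seed: int = 0) -> dict[str, float]:
    """The headline direction check: across seeded replicate studies of the
    default five-crop design, the per-species Delta-vcmax vs
    Delta-closure-to-darkness regression should recover a positive slope at
    p < 0.05 in nearly all studies."""
    base_seeds = np.random.SeedSequence(seed).generate_state(n_studies) % (2**31)
    n_pass = 0
    slopes = []
    for s in base_seeds:
        design = default_study_design(master_seed=int(s),
                                      protocols=("aci", "darkness"))
        study = simulate_study(design)
        per_leaf = analyze_study(study)
        deltas = study_delta_table(per_leaf, n_boot=0)
        reg = delta_regression(deltas)
        slopes.append(reg.slope)
        n_pass += (reg.slope > 0 and reg.p_value < 0.05)
    return {
        "positive_significant_pct": 100.0 * n_pass / n_studies,
        "median_slope": float(np.median(slopes)),
        "n_studies": n_studies,
    }
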
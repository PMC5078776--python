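"""Relative-change (Delta) statistics, regressions, ANOVA and fluorescence
indices for two-treatment gas-exchange studies.

The central comparison is the relative change Delta: a parameter's value
under elevated growth CO2 expressed as a percentage of its ambient-CO2
value, computed per species on treatment means. Simple OLS regressions with
F tests relate Delta values of photosynthetic capacity to Delta values of
stomatal control across species; one-way ANOVA tests treatment effects
within a species, and an additive two-way ANOVA tests species and CO2 main
effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "DeltaChange",
    "DeltaRecord",
    "RegressionResult",
    "delta_change",
    "delta_table",
    "fv_fm",
    "one_way_anova",
    "ols_regression",
    "phi_psii",
    "two_way_anova",
]


class DeltaChange(NamedTuple):
    """Elevated value as a percentage of ambient, and its complement."""

    pct_of_ambient: float
    pct_lower: float


def delta_change(ambient: float, elevated: float) -> DeltaChange:
    """Relative change: 100 * elevated / ambient (percent), with the
    companion "percent lower" = 100 - that."""
    if not ambient > 0:
        raise ValueError(f"ambient value must be positive, got {ambient}")
    pct = 100.0 * elevated / ambient
    return DeltaChange(pct_of_ambient=pct, pct_lower=100.0 - pct)


@dataclass
class DeltaRecord:
    """Per-species relative change of one parameter."""

    species: str
    parameter: str
    value_ambient: float
    value_elevated: float

    @property
    def delta_pct(self) -> float:
        return delta_change(self.value_ambient, self.value_elevated).pct_of_ambient


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS fit with the F test of the slope."""

    slope: float
    intercept: float
    r2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    n: int


def ols_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares line y = a + b x with R^2 and the F(1, n-2) slope test.

    F is computed from R^2 via F = R^2 / (1 - R^2) * (n - 2), the identity
    that holds exactly for simple OLS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    fit = sps.linregress(x, y)
    r2 = float(fit.rvalue**2)
    n = int(x.size)
    df = (1, n - 2)
    if r2 >= 1.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = r2 / (1.0 - r2) * (n - 2)
        p = float(sps.f.sf(f_stat, *df))
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r2=r2, f_stat=f_stat, df=df, p_value=p, n=n,
    )


class AnovaResult(NamedTuple):
    f_stat: float
    df: tuple[int, int]
    p_value: float


def one_way_anova(groups: Iterable[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA (between/within decomposition)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("one-way ANOVA requires >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group requires >= 2 observations")
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return AnovaResult(float(f), (k - 1, n - k), float(p))


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str],
) -> dict[str, AnovaResult]:
    """Additive (no-interaction) two-way ANOVA main-effect F tests.

    For a balanced crossed design this is the classical sequential
    decomposition; the error df is N - a - b + 1. Returns a result per
    factor, keyed "factor_a" and "factor_b".
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factor labels must have equal length")
    levels_a, ia = np.unique(fa, return_inverse=True)
    levels_b, ib = np.unique(fb, return_inverse=True)
    a, b = levels_a.size, levels_b.size
    if a < 2 or b < 2:
        raise ValueError("each factor requires >= 2 levels")
    counts = np.zeros((a, b), dtype=int)
    np.add.at(counts, (ia, ib), 1)
    if np.any(counts == 0):
        raise ValueError("incomplete crossed design: empty cells")
    if np.ptp(counts) != 0:
        raise ValueError("unbalanced design not supported by the additive model")
    n = y.size
    grand = y.mean()
    # balanced design: factor SS are sums of squared marginal-mean deviations
    mean_a = np.array([y[ia == i].mean() for i in range(a)])
    mean_b = np.array([y[ib == j].mean() for j in range(b)])
    n_per_a = n // a
    n_per_b = n // b
    ss_a = n_per_a * float(np.sum((mean_a - grand) ** 2))
    ss_b = n_per_b * float(np.sum((mean_b - grand) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    df_err = n - a - b + 1
    ss_err = ss_total - ss_a - ss_b
    ms_err = ss_err / df_err
    out = {}
    for key, ss, df in (("factor_a", ss_a, a - 1), ("factor_b", ss_b, b - 1)):
        f = (ss / df) / ms_err
        out[key] = AnovaResult(float(f), (df, df_err),
                               float(sps.f.sf(f, df, df_err)))
    return out


def fv_fm(fo: float, fm: float) -> float:
    """Maximum quantum efficiency of PSII, (Fm - Fo)/Fm, in (0, 1)."""
    if not (fm > fo > 0):
        raise ValueError("requires fm > fo > 0")
    return (fm - fo) / fm


def phi_psii(fs: float, fm_prime: float) -> float:
    """Operating quantum efficiency of PSII, (Fm' - Fs)/Fm', in (0, 1)."""
    if not (fm_prime > fs > 0):
        raise ValueError("requires fm_prime > fs > 0")
    return (fm_prime - fs) / fm_prime


def delta_table(
    per_leaf: pd.DataFrame,
    parameters: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-species Delta (% of ambient) for each parameter.

    ``per_leaf`` is tidy: one row per leaf with ``species`` and ``treatment``
    ("ambient"/"elevated") columns plus one column per parameter. Delta is
    the ratio of treatment means; a seeded nonparametric bootstrap over
    replicates supplies a standard error (n_boot = 0 skips it).
    """
    required = {"species", "treatment"}
    if not required <= set(per_leaf.columns):
        raise ValueError(f"per-leaf table must contain columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    rows = []
    for species, grp in per_leaf.groupby("species", sort=True):
        amb = grp[grp["treatment"] == "ambient"]
        ele = grp[grp["treatment"] == "elevated"]
        if amb.empty or ele.empty:
            raise ValueError(f"species {species!r} lacks one treatment")
        for param in parameters:
            va = amb[param].to_numpy(dtype=float)
            ve = ele[param].to_numpy(dtype=float)
            va = va[np.isfinite(va)]
            ve = ve[np.isfinite(ve)]
            if va.size == 0 or ve.size == 0:
                continue
            dc = delta_change(float(va.mean()), float(ve.mean()))
            se = np.nan
            if n_boot > 0 and va.size > 1 and ve.size > 1:
                ba = va[rng.integers(0, va.size, size=(n_boot, va.size))].mean(axis=1)
                be = ve[rng.integers(0, ve.size, size=(n_boot, ve.size))].mean(axis=1)
                ok = ba > 0
                se = float(np.std(100.0 * be[ok] / ba[ok]))
            rows.append({
                "species": species, "parameter": param,
                "value_ambient": float(va.mean()),
                "value_elevated": float(ve.mean()),
                "delta_pct": dc.pct_of_ambient,
                "pct_lower": dc.pct_lower,
                "delta_se": se,
            })
    return pd.DataFrame(rows)
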
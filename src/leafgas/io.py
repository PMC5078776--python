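"""Delimited-text readers and writers for gas-exchange datasets.

There is no standard interchange format for leaf gas-exchange traces, so the
package uses plain CSV with a small documented column dictionary:

A/Ci sweeps          ca_ppm, ci_ppm, a_umol   (+ optional gsw_mmol, tleaf_c,
                                               vpd_kpa, par_umol, replicate)
Ca step sessions     ca_ppm, gsw_mmol          (a 50-ppm row is the separate
                                               full-opening Gs_max reading)
Lights-off traces    t_s, gsw_mmol             (+ optional event column with
                                               a "lights_off" marker row)

Conductances are mmol m^-2 s^-1 H2O unless the ``gs_unit="mol"`` dialect flag
is passed, in which case they are converted on load. Simulated studies are
written as one file per leaf and protocol plus a truth table and a JSON
manifest (seed, config hash, package version) sufficient to regenerate the
tree bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from leafgas.ca_response import CaStepSeries
from leafgas.fvcb import AciCurve, FvcbFit
from leafgas.kinetics import ClosureKinetics, GsTimeSeries
from leafgas.synthetic import StudyData

__all__ = [
    "RunConfig",
    "read_aci",
    "read_ca_steps",
    "read_gas_exchange",
    "read_gs_timeseries",
    "read_study",
    "write_aci",
    "write_ca_steps",
    "write_fits",
    "write_gs_timeseries",
    "write_kinetics",
    "write_study",
]

_ACI_REQUIRED = ("ca_ppm", "ci_ppm", "a_umol")
_STEPS_REQUIRED = ("ca_ppm", "gsw_mmol")
_TRACE_REQUIRED = ("t_s", "gsw_mmol")


def _read_table(path: str | Path, required: tuple[str, ...],
                sep: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _gs_to_mmol(values: np.ndarray, gs_unit: str) -> np.ndarray:
    if gs_unit == "mmol":
        return values
    if gs_unit == "mol":
        return values * 1000.0
    raise ValueError(f"unknown gs unit dialect {gs_unit!r}")


def read_aci(path: str | Path, sep: str = ",",
             meta: dict | None = None) -> AciCurve:
    """Read one leaf's A/Ci sweep."""
    df = _read_table(path, _ACI_REQUIRED, sep)
    bad = df.index[df["ci_ppm"] <= 0].tolist()
    if bad:
        raise ValueError(f"{path}: non-positive ci at rows {bad}")
    return AciCurve(
        ci=df["ci_ppm"].to_numpy(float),
        a=df["a_umol"].to_numpy(float),
        ca=df["ca_ppm"].to_numpy(float),
        meta=dict(meta or {}),
    )


def write_aci(curve: AciCurve, path: str | Path) -> None:
    pd.DataFrame({
        "ca_ppm": curve.ca if curve.ca is not None else np.nan,
        "ci_ppm": curve.ci,
        "a_umol": curve.a,
    }).to_csv(path, index=False)


def read_ca_steps(path: str | Path, sep: str = ",", gs_unit: str = "mmol",
                  meta: dict | None = None) -> CaStepSeries:
    """Read a reduced step table; a 50-ppm row becomes the Gs_max reading."""
    df = _read_table(path, _STEPS_REQUIRED, sep)
    gs = _gs_to_mmol(df["gsw_mmol"].to_numpy(float), gs_unit)
    bad = df.index[gs < 0].tolist()
    if bad:
        raise ValueError(f"{path}: negative conductance at rows {bad}")
    is50 = np.isclose(df["ca_ppm"].to_numpy(float), 50.0, atol=0.5)
    gs_at_50 = float(gs[is50][0]) if is50.any() else None
    return CaStepSeries(
        ca=df["ca_ppm"].to_numpy(float)[~is50],
        gs_h2o=gs[~is50],
        gs_at_50=gs_at_50,
        meta=dict(meta or {}),
    )


def write_ca_steps(series: CaStepSeries, path: str | Path) -> None:
    ca = list(series.ca)
    gs = list(series.gs_h2o)
    if series.gs_at_50 is not None:
        ca.append(50.0)
        gs.append(series.gs_at_50)
    pd.DataFrame({"ca_ppm": ca, "gsw_mmol": gs}).to_csv(path, index=False)


def read_gs_timeseries(path: str | Path, lights_off_t: float | None = None,
                       sep: str = ",", gs_unit: str = "mmol",
                       meta: dict | None = None) -> GsTimeSeries:
    """Read a lights-off trace. The lights-off instant comes from the
    ``lights_off_t`` argument or an ``event`` column's "lights_off" row."""
    df = _read_table(path, _TRACE_REQUIRED, sep)
    t = df["t_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValueError(f"{path}: non-monotone time at row {bad}")
    gs = _gs_to_mmol(df["gsw_mmol"].to_numpy(float), gs_unit)
    bad = df.index[gs < 0].tolist()
    if bad:
        raise ValueError(f"{path}: negative conductance at rows {bad}")
    if lights_off_t is None:
        if "event" in df.columns:
            marked = df.index[df["event"] == "lights_off"]
            if len(marked):
                lights_off_t = float(t[marked[0]])
    if lights_off_t is None:
        raise ValueError(
            f"{path}: lights-off instant not supplied and no event column"
        )
    return GsTimeSeries(t=t, gs_h2o=gs, lights_off_t=lights_off_t,
                        meta=dict(meta or {}))


def write_gs_timeseries(series: GsTimeSeries, path: str | Path) -> None:
    event = np.where(series.t == series.lights_off_t, "lights_off", "")
    if not (event == "lights_off").any():
        # mark the first dark sample so the instant survives the round trip
        idx = int(np.argmax(series.t >= series.lights_off_t))
        event = event.astype(object)
        event[idx] = "lights_off"
    pd.DataFrame({
        "t_s": series.t, "gsw_mmol": series.gs_h2o, "event": event,
    }).to_csv(path, index=False)


def read_gas_exchange(path: str | Path, protocol: str, **kwargs):
    """Dispatch to the protocol-specific reader (aci | ca_steps | darkness)."""
    readers = {"aci": read_aci, "ca_steps": read_ca_steps,
               "darkness": read_gs_timeseries}
    if protocol not in readers:
        raise ValueError(f"unknown protocol {protocol!r}")
    return readers[protocol](path, **kwargs)


def write_fits(fits: list[FvcbFit], path: str | Path) -> None:
    """One row per leaf plus a JSON sidecar of per-point limitation labels."""
    path = Path(path)
    rows = []
    sidecar = {}
    for i, fit in enumerate(fits):
        label = "{species}_{treatment}_rep{replicate}".format(
            species=fit.meta.get("species", "leaf"),
            treatment=fit.meta.get("treatment", "na"),
            replicate=fit.meta.get("replicate", i + 1),
        )
        rows.append({
            "leaf": label,
            "species": fit.meta.get("species"),
            "treatment": fit.meta.get("treatment"),
            "replicate": fit.meta.get("replicate"),
            "vcmax": fit.params.vcmax, "jmax": fit.params.jmax,
            "rd": fit.params.rd, "gm": fit.params.gm,
            "rss": fit.rss, "pn_max": fit.pn_max,
            "converged": fit.converged,
            "gm_effectively_infinite": fit.gm_effectively_infinite,
        })
        sidecar[label] = fit.limitation
    pd.DataFrame(rows).to_csv(path, index=False)
    path.with_suffix(".limitations.json").write_text(
        json.dumps(sidecar, indent=1)
    )


def write_kinetics(results: list[ClosureKinetics], path: str | Path) -> None:
    rows = [{
        "species": k.meta.get("species"),
        "treatment": k.meta.get("treatment"),
        "replicate": k.meta.get("replicate"),
        "gs0": k.gs0, "gs_min": k.gs_min, "amplitude": k.amplitude,
        "t50_s": k.t50, "tmax_s": k.t_max,
        "speed50": k.speed50, "speed_max": k.speed_max,
        "pct_gs_1h": k.pct_gs_1h, "pct_closed_1h": k.pct_closed_1h,
        "no_closure": k.no_closure,
        "baseline_unstable": k.baseline_unstable,
    } for k in results]
    pd.DataFrame(rows).to_csv(path, index=False)


def _leaf_stem(meta: dict) -> str:
    return "{}_{}_rep{}".format(meta.get("species", "leaf"),
                                meta.get("treatment", "na"),
                                meta.get("replicate", 0))


def write_study(study: StudyData, out_dir: str | Path,
                master_seed: int | None = None,
                config: dict | None = None) -> Path:
    """Write a simulated study as a file tree with truth table and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for curve in study.aci:
        p = out / f"{_leaf_stem(curve.meta)}_aci.csv"
        write_aci(curve, p)
        files.append(p.name)
    for steps in study.ca_steps:
        p = out / f"{_leaf_stem(steps.meta)}_ca_steps.csv"
        write_ca_steps(steps, p)
        files.append(p.name)
    for series in study.darkness:
        p = out / f"{_leaf_stem(series.meta)}_darkness.csv"
        write_gs_timeseries(series, p)
        files.append(p.name)
    if study.fluorescence is not None:
        study.fluorescence.to_csv(out / "fluorescence.csv", index=False)
        files.append("fluorescence.csv")
    if study.truth is not None:
        study.truth.to_csv(out / "truth.csv", index=False)
        files.append("truth.csv")
    cfg = config or {}
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    from leafgas import __version__
    manifest = {
        "package_version": __version__,
        "master_seed": master_seed,
        "config_hash": cfg_hash,
        "config": cfg,
        "files": sorted(files),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_study(in_dir: str | Path) -> StudyData:
    """Read a study file tree written by ``write_study``."""
    in_dir = Path(in_dir)
    study = StudyData()

    def meta_from(stem: str) -> dict:
        species, treatment, rep = stem.rsplit("_", 2)
        return {"species": species, "treatment": treatment,
                "replicate": int(rep.removeprefix("rep"))}

    for p in sorted(in_dir.glob("*_aci.csv")):
        study.aci.append(read_aci(p, meta=meta_from(p.stem.removesuffix("_aci"))))
    for p in sorted(in_dir.glob("*_ca_steps.csv")):
        study.ca_steps.append(
            read_ca_steps(p, meta=meta_from(p.stem.removesuffix("_ca_steps")))
        )
    for p in sorted(in_dir.glob("*_darkness.csv")):
        study.darkness.append(
            read_gs_timeseries(p, meta=meta_from(p.stem.removesuffix("_darkness")))
        )
    fl = in_dir / "fluorescence.csv"
    if fl.exists():
        study.fluorescence = pd.read_csv(fl)
    tr = in_dir / "truth.csv"
    if tr.exists():
        study.truth = pd.read_csv(tr)
    return study


@dataclass
class RunConfig:
    """Validated run configuration (YAML file with CLI-flag overrides).

    Unknown keys are rejected so typos fail loudly; every run writes its
    resolved configuration next to its outputs.
    """

    protocol: str = "study"
    seed: int = 0
    lights_off_t: float | None = None
    fit: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    simulator: dict = field(default_factory=dict)
    verbosity: str = "info"

    _KNOWN = {"protocol", "seed", "lights_off_t", "fit", "kinetics",
              "simulator", "verbosity"}

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        data = {}
        if path is not None:
            data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if cfg.protocol not in {"aci", "ca_steps", "darkness", "study"}:
            raise ValueError(f"unknown protocol {cfg.protocol!r}")
        return cfg

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
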
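"""Synthetic instrument-style gas-exchange data with known ground truth.

Generates the three measurement protocols the analysis consumes — A/Ci
sweeps, stepped-Ca sessions, and 10-s-cadence lights-off traces — from a
mechanistic leaf model: FvCB photosynthesis (finite mesophyll conductance)
coupled at steady state to a Ball–Berry stomatal model
``gs = g0 + g1 * A * rh / ca`` (floored at g0), solved by bisection on the
sub-stomatal CO2 budget ``ci = ca - A / gs_co2``. Dark closure is modelled
as first-order exponential relaxation of Gs toward a dark floor, with an
optional short post-lights-off artifact transient mimicking the cuvette
humidity/temperature disturbance seen in real traces.

``default_study_design`` encodes a five-crop, two-growth-CO2 (400 vs
2000 ppm) study with per-species photosynthetic capacities on the scale
reported for oat, wheat, cotton, sunflower and barley, four replicates per
cell, and coupled impairment: species that lose carboxylation capacity at
elevated growth CO2 also close their stomata less tightly in darkness.

All randomness flows from explicit integer seeds; a fixed master seed gives
byte-identical output.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from leafgas.ca_response import CaStepSeries, PROTOCOL_CA_STEPS
from leafgas.fvcb import (
    AciCurve,
    FvcbParams,
    KineticConstants,
    forward_fvcb,
    gs_h2o_to_co2,
)
from leafgas.kinetics import GsTimeSeries

__all__ = [
    "ArtifactSpec",
    "Fluorescence",
    "LeafScenario",
    "ACI_CA_SEQUENCE",
    "StudyDesign",
    "StudyData",
    "default_study_design",
    "simulate_aci",
    "simulate_ca_steps",
    "simulate_darkness",
    "simulate_fluorescence",
    "simulate_study",
    "solve_coupled",
]

#: Applied-Ca sequence of the A/Ci protocol (ppm).
ACI_CA_SEQUENCE = (
    350.0, 250.0, 150.0, 50.0, 100.0, 200.0, 300.0, 400.0,
    600.0, 800.0, 1000.0, 1200.0, 1400.0, 1600.0, 1800.0, 2000.0,
)


@dataclass(frozen=True)
class ArtifactSpec:
    """Post-lights-off cuvette transient: a half-sine bump added to Gs."""

    duration_s: float = 90.0
    amplitude: float = 30.0


@dataclass(frozen=True)
class LeafScenario:
    """Generating parameters for one synthetic leaf.

    Conductances in mmol m^-2 s^-1 (H2O basis) except the FvCB gm;
    tau_close is the dark-closure time constant in seconds; rh the relative
    humidity fraction at the leaf surface.
    """

    fvcb: FvcbParams
    bb_g1: float = 9.0
    bb_g0: float = 20.0
    tau_close: float = 420.0
    gs_dark_floor: float = 60.0
    rh: float = 0.5
    noise_sd_a: float = 0.5
    noise_sd_gs: float = 5.0
    artifact: ArtifactSpec | None = ArtifactSpec()
    seed: int = 0
    gs_open_factor: float = 1.2
    fv_fm_target: float = 0.84
    phi_psii_target: float = 0.45

    def __post_init__(self) -> None:
        if not 0 < self.rh < 1:
            raise ValueError("rh must be in (0, 1)")
        for name in ("bb_g1", "bb_g0", "tau_close"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.gs_dark_floor < 0:
            raise ValueError("gs_dark_floor must be non-negative")


class CoupledState(NamedTuple):
    """Steady state of the coupled FvCB / Ball-Berry leaf at one Ca."""

    a: float
    ci: float
    gs_h2o: float


def _ball_berry_gs(scenario: LeafScenario, a: float, ca: float) -> float:
    """Ball-Berry Gs_H2O in mmol m^-2 s^-1, floored at g0."""
    return scenario.bb_g0 + max(0.0, 1000.0 * scenario.bb_g1 * a * scenario.rh / ca)


def solve_coupled(
    scenario: LeafScenario,
    ca: float,
    constants: KineticConstants | None = None,
    tol: float = 1e-6,
) -> CoupledState:
    """Solve the steady-state (A, ci, gs) triple at applied Ca by bisection.

    Finds the ci satisfying the diffusion budget ci = ca - A(ci)/gs_co2(A),
    with A from the FvCB model and gs from Ball-Berry.
    """
    constants = constants or KineticConstants()

    def residual(ci: float) -> float:
        a = forward_fvcb(scenario.fvcb, constants, ci).a
        gs_co2 = gs_h2o_to_co2(_ball_berry_gs(scenario, a, ca))
        return ca - a / gs_co2 - ci

    lo = 1e-3
    # at high ci the leaf assimilates, pushing the implied ci below ca
    hi = ca + scenario.fvcb.rd / gs_h2o_to_co2(scenario.bb_g0) + 1.0
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo < 0 or f_hi > 0:
        raise RuntimeError(
            f"coupled solver could not bracket a root at ca={ca}: {scenario}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
    ci = 0.5 * (lo + hi)
    a = float(forward_fvcb(scenario.fvcb, constants, ci).a)
    return CoupledState(a=a, ci=ci, gs_h2o=_ball_berry_gs(scenario, a, ca))


def simulate_aci(
    scenario: LeafScenario,
    ca_sequence: Sequence[float] = ACI_CA_SEQUENCE,
    constants: KineticConstants | None = None,
    meta: dict | None = None,
) -> AciCurve:
    """Simulate one A/Ci sweep over the applied-Ca protocol.

    At each Ca the coupled steady state is solved; the recorded A carries
    Gaussian instrument noise (sd ``noise_sd_a``), ci is the solver value.
    """
    rng = np.random.default_rng(scenario.seed)
    states = [solve_coupled(scenario, ca, constants) for ca in ca_sequence]
    a = np.array([s.a for s in states])
    ci = np.array([s.ci for s in states])
    a_noisy = a + rng.normal(0.0, scenario.noise_sd_a, size=a.size)
    return AciCurve(ci=ci, a=a_noisy, ca=np.asarray(ca_sequence, float),
                    meta=dict(meta or {}))


def simulate_ca_steps(
    scenario: LeafScenario,
    steps: Sequence[float] = PROTOCOL_CA_STEPS,
    constants: KineticConstants | None = None,
    meta: dict | None = None,
) -> CaStepSeries:
    """Simulate a stepped-Ca session: plateau Gs at each step plus the
    separate 50-ppm full-opening reading.

    Ball-Berry couples Gs to assimilation, which collapses at 50 ppm, so the
    low-CO2 opening response is modelled directly: the 50-ppm reading is
    ``gs_open_factor`` times the largest noiseless step plateau.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    gs = np.array(
        [solve_coupled(scenario, ca, constants).gs_h2o for ca in steps]
    )
    gs_noisy = np.clip(gs + rng.normal(0.0, scenario.noise_sd_gs, gs.size), 0, None)
    gs_50 = scenario.gs_open_factor * float(gs.max()) + float(
        rng.normal(0.0, scenario.noise_sd_gs)
    )
    return CaStepSeries(ca=np.asarray(steps, float), gs_h2o=gs_noisy,
                        gs_at_50=gs_50, meta=dict(meta or {}))


def simulate_darkness(
    scenario: LeafScenario,
    duration_s: float = 4800.0,
    cadence_s: float = 10.0,
    lights_off_t: float = 900.0,
    ca: float = 400.0,
    constants: KineticConstants | None = None,
    meta: dict | None = None,
) -> GsTimeSeries:
    """Simulate a lights-off trace at the protocol's 10-s cadence.

    The light-on baseline is the coupled steady-state Gs at 400 ppm; after
    lights-off Gs relaxes exponentially (time constant ``tau_close``) to
    ``gs_dark_floor``, with the optional artifact bump and Gaussian noise.
    """
    if cadence_s <= 0:
        raise ValueError("cadence_s must be positive")
    if duration_s < lights_off_t + 3600.0:
        raise ValueError("duration must extend at least 1 h past lights-off")
    rng = np.random.default_rng(scenario.seed + 2)
    gs0 = solve_coupled(scenario, ca, constants).gs_h2o
    t = np.arange(0.0, duration_s + 0.5 * cadence_s, cadence_s)
    dt = t - lights_off_t
    floor = scenario.gs_dark_floor
    gs = np.where(dt < 0, gs0, floor + (gs0 - floor) * np.exp(-np.maximum(dt, 0) / scenario.tau_close))
    if scenario.artifact is not None and scenario.artifact.amplitude != 0:
        bump = (dt >= 0) & (dt < scenario.artifact.duration_s)
        gs = gs + np.where(
            bump,
            scenario.artifact.amplitude
            * np.sin(np.pi * np.clip(dt, 0, None) / scenario.artifact.duration_s),
            0.0,
        )
    gs = np.clip(gs + rng.normal(0.0, scenario.noise_sd_gs, gs.size), 0.0, None)
    return GsTimeSeries(t=t, gs_h2o=gs, lights_off_t=lights_off_t,
                        meta=dict(meta or {}))


class Fluorescence(NamedTuple):
    """Raw modulated-fluorescence readings (arbitrary units)."""

    fo: float
    fm: float
    fs: float
    fm_prime: float


def simulate_fluorescence(
    scenario: LeafScenario, fm_scale: float = 1250.0
) -> Fluorescence:
    """Emit raw fluorescence values whose derived indices equal the
    scenario targets: (Fm - Fo)/Fm = fv_fm_target and
    (Fm' - Fs)/Fm' = phi_psii_target."""
    if not 0 < scenario.fv_fm_target < 1:
        raise ValueError("fv_fm_target must be in (0, 1)")
    if not 0 < scenario.phi_psii_target < 1:
        raise ValueError("phi_psii_target must be in (0, 1)")
    rng = np.random.default_rng(scenario.seed + 3)
    fm = fm_scale * float(rng.uniform(0.9, 1.1))
    fo = fm * (1.0 - scenario.fv_fm_target)
    fm_prime = fm * float(rng.uniform(0.45, 0.65))
    fs = fm_prime * (1.0 - scenario.phi_psii_target)
    return Fluorescence(fo=fo, fm=fm, fs=fs, fm_prime=fm_prime)


@dataclass
class StudyDesign:
    """A two-growth-CO2, multi-species study layout.

    ``species`` maps a label to its (ambient, elevated) LeafScenario pair;
    ``rep_param_cv`` is the lognormal coefficient of variation applied to
    vcmax, jmax, tau_close and gs_dark_floor across replicates (biological
    leaf-to-leaf variation).
    """

    species: dict[str, tuple[LeafScenario, LeafScenario]]
    n_replicates: int = 4
    protocols: tuple[str, ...] = ("aci", "ca_steps", "darkness")
    master_seed: int = 0
    rep_param_cv: float = 0.07

    def __post_init__(self) -> None:
        if self.n_replicates < 3:
            raise ValueError("study designs require >= 3 replicates per cell")
        unknown = set(self.protocols) - {"aci", "ca_steps", "darkness"}
        if unknown:
            raise ValueError(f"unknown protocols: {sorted(unknown)}")


@dataclass
class StudyData:
    """In-memory result of ``simulate_study``: per-leaf datasets plus the
    truth table of generating parameters."""

    aci: list[AciCurve] = field(default_factory=list)
    ca_steps: list[CaStepSeries] = field(default_factory=list)
    darkness: list[GsTimeSeries] = field(default_factory=list)
    fluorescence: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None


def _replicate_seed(master_seed: int, species: str, treatment: str, rep: int) -> int:
    """Stable per-replicate seed from a SHA-256 of the cell coordinates."""
    key = f"{master_seed}:{species}:{treatment}:{rep}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def _jitter_scenario(
    scenario: LeafScenario, seed: int, cv: float
) -> LeafScenario:
    """Apply lognormal leaf-to-leaf variation to the biological parameters."""
    if cv <= 0:
        return replace(scenario, seed=seed)
    rng = np.random.default_rng(seed ^ 0x5EED)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    f_v, f_j, f_tau, f_floor = np.exp(rng.normal(0.0, sigma, 4))
    fv = replace(scenario.fvcb, vcmax=scenario.fvcb.vcmax * f_v,
                 jmax=scenario.fvcb.jmax * f_j)
    return replace(
        scenario,
        fvcb=fv,
        tau_close=scenario.tau_close * f_tau,
        gs_dark_floor=scenario.gs_dark_floor * f_floor,
        seed=seed,
    )


def simulate_study(
    design: StudyDesign,
    constants: KineticConstants | None = None,
) -> StudyData:
    """Emit every requested protocol for every replicate of every cell.

    Per-replicate seeds are derived by hashing (master seed, species,
    treatment, replicate), so streams are independent yet reproducible. The
    truth table records the jittered generating parameters of each leaf.
    """
    data = StudyData()
    truth_rows = []
    fluo_rows = []
    for species, (amb, elev) in design.species.items():
        for treatment, base in (("ambient", amb), ("elevated", elev)):
            for rep in range(1, design.n_replicates + 1):
                seed = _replicate_seed(design.master_seed, species, treatment, rep)
                scen = _jitter_scenario(base, seed, design.rep_param_cv)
                meta = {"species": species, "treatment": treatment,
                        "replicate": rep}
                if "aci" in design.protocols:
                    data.aci.append(simulate_aci(scen, constants=constants,
                                                 meta=meta))
                if "ca_steps" in design.protocols:
                    data.ca_steps.append(
                        simulate_ca_steps(scen, constants=constants, meta=meta)
                    )
                if "darkness" in design.protocols:
                    data.darkness.append(
                        simulate_darkness(scen, constants=constants, meta=meta)
                    )
                fl = simulate_fluorescence(scen)
                fluo_rows.append({**meta, "fo": fl.fo, "fm": fl.fm,
                                  "fs": fl.fs, "fm_prime": fl.fm_prime})
                truth_rows.append({
                    **meta,
                    "vcmax": scen.fvcb.vcmax, "jmax": scen.fvcb.jmax,
                    "rd": scen.fvcb.rd, "gm": scen.fvcb.gm,
                    "bb_g1": scen.bb_g1, "bb_g0": scen.bb_g0,
                    "tau_close": scen.tau_close,
                    "gs_dark_floor": scen.gs_dark_floor,
                    "fv_fm_target": scen.fv_fm_target,
                    "phi_psii_target": scen.phi_psii_target,
                    "seed": seed,
                })
    data.truth = pd.DataFrame(truth_rows)
    data.fluorescence = pd.DataFrame(fluo_rows)
    return data


# Ambient-growth (vcmax, jmax, Gs-scale Ball-Berry slope) and the elevated:
# ambient capacity ratios of the five crops; the two dicots (cotton,
# sunflower) lose roughly half their carboxylation capacity at 2000 ppm
# growth CO2 while the grasses largely retain theirs.
_SPECIES_BASE = {
    #  name        vcmax   jmax   g1   vc_mult  j_mult  fvfm_a fvfm_e phi_a  phi_e
    "oat":       (87.8, 144.6, 23.0, 0.805, 0.854, 0.842, 0.858, 0.427, 0.436),
    "wheat":     (133.0, 174.9, 11.0, 0.917, 0.846, 0.838, 0.837, 0.505, 0.494),
    "cotton":    (68.4, 73.5, 7.0, 0.500, 1.022, 0.827, 0.823, 0.233, 0.338),
    "sunflower": (123.4, 173.3, 24.0, 0.495, 0.559, 0.854, 0.858, 0.566, 0.560),
    "barley":    (72.4, 137.0, 37.0, 0.924, 0.882, 0.845, 0.840, 0.438, 0.397),
}

#: Fraction of the light-on baseline Gs retained in darkness by an
#: unimpaired leaf; impairment raises it in proportion to the lost vcmax.
_DARK_FLOOR_FRAC_AMBIENT = 0.10
_DARK_FLOOR_IMPAIRMENT_GAIN = 0.5


def default_study_design(
    master_seed: int = 0,
    n_replicates: int = 4,
    protocols: tuple[str, ...] = ("aci", "ca_steps", "darkness"),
    noise_sd_a: float = 0.5,
    noise_sd_gs: float = 8.0,
) -> StudyDesign:
    """The default five-crop, 400-vs-2000-ppm study.

    Elevated-CO2 scenarios scale vcmax/jmax by the per-species capacity
    ratios and couple closure impairment to the capacity loss: the dark
    floor fraction rises, and the closure time constant lengthens, in
    proportion to the vcmax reduction.
    """
    species = {}
    for name, (vc, jm, g1, mv, mj, fvfm_a, fvfm_e, phi_a, phi_e) in _SPECIES_BASE.items():
        amb = LeafScenario(
            fvcb=FvcbParams(vcmax=vc, jmax=jm, rd=1.5, gm=0.3),
            bb_g1=g1, noise_sd_a=noise_sd_a, noise_sd_gs=noise_sd_gs,
            fv_fm_target=fvfm_a, phi_psii_target=phi_a,
        )
        elev = LeafScenario(
            fvcb=FvcbParams(vcmax=vc * mv, jmax=jm * mj, rd=1.5, gm=0.3),
            bb_g1=g1, noise_sd_a=noise_sd_a, noise_sd_gs=noise_sd_gs,
            tau_close=420.0 * (2.0 - mv),
            fv_fm_target=fvfm_e, phi_psii_target=phi_e,
        )
        frac_amb = _DARK_FLOOR_FRAC_AMBIENT
        frac_elev = frac_amb + _DARK_FLOOR_IMPAIRMENT_GAIN * (1.0 - mv)
        gs0_amb = solve_coupled(amb, 400.0).gs_h2o
        gs0_elev = solve_coupled(elev, 400.0).gs_h2o
        amb = replace(amb, gs_dark_floor=frac_amb * gs0_amb)
        elev = replace(elev, gs_dark_floor=frac_elev * gs0_elev)
        species[name] = (amb, elev)
    return StudyDesign(
        species=species, n_replicates=n_replicates, protocols=protocols,
        master_seed=master_seed,
    )


def null_study_design(master_seed: int = 0, n_replicates: int = 4,
                      protocols: tuple[str, ...] = ("ca_steps",),
                      rep_param_cv: float = 0.0) -> StudyDesign:
    """A null design: elevated scenarios identical to ambient ones, so every
    treatment contrast is pure measurement noise (used to calibrate the
    size of the ANOVA treatment test; biological jitter off by default so
    the null sampling model is exactly Gaussian)."""
    design = default_study_design(master_seed=master_seed,
                                  n_replicates=n_replicates,
                                  protocols=protocols)
    species = {name: (amb, amb) for name, (amb, _) in design.species.items()}
    return StudyDesign(species=species, n_replicates=n_replicates,
                       protocols=protocols, master_seed=master_seed,
                       rep_param_cv=rep_param_cv)
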
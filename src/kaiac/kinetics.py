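"""Reaction network assembly and stiff ODE integration.

The network couples four reaction classes among the 16 KaiC states:

* phosphotransfer  C_TP^X <-> C_DP^Y for (X,Y) in {(U,T),(U,S),(T,D),(S,D)},
  with and without KaiA bound.  ATP-bound states cannot dephosphorylate and
  ADP-bound states cannot phosphorylate (the gamma-phosphate shuttles
  between the site and the bound nucleotide).
* irreversible ATP hydrolysis  C_TP^X -> C_DP^X + Pi.
* reversible KaiA (un)binding  C + A <-> A-C (second order in free KaiA
  dimer; free KaiA is obtained algebraically from conservation).
* KaiA-dependent nucleotide exchange  A-C_DP^X -> A-C_TP^X at rate
  krDP * dkTPA_X * (%ATP / 100); KaiC alone has no exchange activity, and
  the reverse (ATP release) rate is identically zero.

Internal rates are in s^-1 (ka in s^-1 uM^-1); trajectories use hours.
The factor 3600 is applied once when the compiled system is built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .params import RateParameterSet
from .states import (
    N_FREE_STATES,
    N_STATES,
    PHOSPHOFORMS,
    PHOSPHOTRANSFER_PAIRS,
    STATE_LABELS,
    Nucleotide,
    Phosphoform,
    state_index,
)

SECONDS_PER_HOUR = 3600.0

RTOL = 1e-6
ATOL = 1e-9  # uM

# LSODA switches to a BDF multistep scheme in stiff regions and runs its
# stepping loop in compiled code; it is the default stiff integrator here.
ODE_METHOD = "LSODA"


class Protocol(str, Enum):
    PHOSPHORYLATION = "phosphorylation"
    DEPHOSPHORYLATION_TWO_STAGE = "dephosphorylation_two_stage"


@dataclass(frozen=True)
class SimulationCondition:
    """Experimental condition for one reaction.

    kaiA_total_monomer is the monomer concentration as pipetted; KaiA acts
    as a dimer, so the concentration entering the rate laws is half of it.
    The solution nucleotide pool ([ATP]+[ADP]) is constant; pct_ATP is
    100*[ATP]/([ATP]+[ADP]).
    """

    kaiC_total: float = 3.5  # uM
    kaiA_total_monomer: float = 1.5  # uM
    pct_ATP: float = 100.0
    duration: float = 24.0  # hours
    protocol: Protocol = Protocol.PHOSPHORYLATION

    def __post_init__(self):
        if not (0.0 < self.pct_ATP <= 100.0):
            raise ValueError("pct_ATP must be in (0, 100]")
        if self.kaiC_total <= 0 or self.kaiA_total_monomer < 0:
            raise ValueError("concentrations must be non-negative (KaiC positive)")

    @property
    def kaiA_dimer(self) -> float:
        return self.kaiA_total_monomer / 2.0


def exchange_rate(krDP_effective: float, pct_ATP: float) -> float:
    """One-step ADP->ATP exchange rate: krDP_eff * [ATP]/([ATP]+[ADP]).

    The reverse exchange rate is identically zero because ATP release
    (krTP) is fixed at zero.
    """
    if krDP_effective < 0:
        raise ValueError("exchange rate must be non-negative")
    if not (0.0 < pct_ATP <= 100.0):
        raise ValueError("pct_ATP must be in (0, 100]")
    return krDP_effective * pct_ATP / 100.0


@dataclass
class Reaction:
    """One elementary reaction arrow with its first-order rate constant
    (s^-1).  Second-order KaiA binding carries the on-rate constant in
    s^-1 uM^-1 and order == 2 (flux = rate * [A_free_dimer] * [source])."""

    source: int
    target: int
    rate: float  # s^-1 (order 1) or s^-1 uM^-1 (order 2)
    kind: str  # phosphotransfer | hydrolysis | exchange | kaiA_on | kaiA_off
    order: int = 1


def build_reaction_rates(
    params: RateParameterSet, condition: SimulationCondition
) -> list[Reaction]:
    """Enumerate every reaction arrow with its rate constant.

    Detailed balance has already been applied inside the parameter set;
    the derived KaiA-on modifiers are used where needed.
    """
    br = params.base_rates
    rxns: list[Reaction] = []

    for bound in (False, True):
        # phosphotransfer; the bare (kp, kd) pair anchors U<->T without KaiA
        for X, Y in PHOSPHOTRANSFER_PAIRS:
            i = state_index(X.value, "TP", bound)
            j = state_index(Y.value, "DP", bound)
            if bound:
                fwd = params.delta(f"dkpA_{X.value}{Y.value}")
                rev = params.delta(f"dkdA_{Y.value}{X.value}")
            else:
                fwd = params.delta(f"dkp_{X.value}{Y.value}") if (X, Y) != (
                    Phosphoform.U,
                    Phosphoform.T,
                ) else 1.0
                rev = params.delta(f"dkd_{Y.value}{X.value}") if (X, Y) != (
                    Phosphoform.U,
                    Phosphoform.T,
                ) else 1.0
            rxns.append(Reaction(i, j, br["kp"] * fwd, "phosphotransfer"))
            rxns.append(Reaction(j, i, br["kd"] * rev, "phosphotransfer"))
        # hydrolysis on every ATP-bound state
        for X in PHOSPHOFORMS:
            i = state_index(X.value, "TP", bound)
            j = state_index(X.value, "DP", bound)
            mod = (
                params.delta(f"dkhA_{X.value}")
                if bound
                else params.delta(f"dkh_{X.value}")  # dkh_U is baseline -> 1
            )
            rxns.append(Reaction(i, j, br["kh"] * mod, "hydrolysis"))
        # nucleotide exchange, KaiA-bound ADP states only
        if bound:
            for X in PHOSPHOFORMS:
                i = state_index(X.value, "DP", True)
                j = state_index(X.value, "TP", True)
                k = exchange_rate(
                    br["krDP"] * params.delta(f"dkTPA_{X.value}"), condition.pct_ATP
                )
                rxns.append(Reaction(i, j, k, "exchange"))

    # KaiA binding / unbinding between free state i and bound state i+8
    for X in PHOSPHOFORMS:
        for nuc in (Nucleotide.TP, Nucleotide.DP):
            i = state_index(X.value, nuc.value, False)
            on = br["ka"] * params.delta(f"dka_{X.value}_{nuc.value}")
            off = br["kb"] * params.delta(f"dkb_{X.value}_{nuc.value}")
            rxns.append(Reaction(i, i + 8, on, "kaiA_on", order=2))
            rxns.append(Reaction(i + 8, i, off, "kaiA_off"))

    return rxns


def compile_system(
    params: RateParameterSet, condition: SimulationCondition
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the compiled ODE system in per-hour units.

    Returns (lin, kon): lin is the 17x17 first-order matrix over the 16
    states plus cumulative Pi; kon is the length-8 on-rate vector for the
    bilinear KaiA-binding fluxes (free state i -> bound state i+8).
    """
    lin = np.zeros((N_STATES + 1, N_STATES + 1))
    kon = np.zeros(N_FREE_STATES)
    for r in build_reaction_rates(params, condition):
        rate_h = r.rate * SECONDS_PER_HOUR
        if r.order == 2:
            kon[r.source] = rate_h
            continue
        lin[r.source, r.source] -= rate_h
        lin[r.target, r.source] += rate_h
        if r.kind == "hydrolysis":
            lin[N_STATES, r.source] += rate_h  # Pi released per hydrolysis
    return lin, kon


@njit(cache=False)
def _rhs(t, y, lin, kon, a_dimer):
    dy = lin @ y
    a_free = a_dimer - np.sum(y[8:16])
    for i in range(8):
        f = kon[i] * a_free * y[i]
        dy[i] -= f
        dy[8 + i] += f
    return dy


@njit(cache=False)
def _jac(t, y, lin, kon, a_dimer):
    J = lin.copy()
    a_free = a_dimer - np.sum(y[8:16])
    for i in range(8):
        J[i, i] -= kon[i] * a_free
        J[8 + i, i] += kon[i] * a_free
        for j in range(8, 16):
            J[i, j] += kon[i] * y[i]
            J[8 + i, j] -= kon[i] * y[i]
    return J


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; callers fitting the model treat
    the parameter set as invalid (log-posterior -inf)."""


@dataclass
class Trajectory:
    """Solution of the 16-state system on a time grid (hours, uM)."""

    time_grid: np.ndarray
    concentrations: np.ndarray  # (16, n_times)
    cumulative_Pi: np.ndarray  # (n_times,)
    condition: SimulationCondition
    kaiC_total: float  # total KaiC actually present (stage 2 may be reduced)
    state_labels: tuple = field(default=STATE_LABELS, repr=False)

    @property
    def free_kaiA_dimer(self) -> np.ndarray:
        return self.condition.kaiA_dimer - self.concentrations[8:16].sum(axis=0)


def _integrate(
    params: RateParameterSet,
    condition: SimulationCondition,
    y0: np.ndarray,
    t_grid: np.ndarray,
    a_dimer: float,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    lin, kon = compile_system(params, condition)
    t_grid = np.asarray(t_grid, dtype=float)
    y = np.zeros(N_STATES + 1)
    y[:N_STATES] = y0
    try:
        with warnings.catch_warnings():
            # LSODA emits chatty warnings for proposals it fails on; failure
            # is reported through sol.success and handled by the caller
            warnings.simplefilter("ignore")
            sol = solve_ivp(
                _rhs,
                (0.0, float(t_grid[-1])),
                y,
                method=ODE_METHOD,
                t_eval=t_grid,
                rtol=rtol,
                atol=atol,
                jac=_jac,
                args=(lin, kon, a_dimer),
            )
    except Exception as exc:  # pragma: no cover - defensive
        raise IntegrationError(str(exc)) from exc
    if not sol.success:
        raise IntegrationError(sol.message)
    return Trajectory(
        time_grid=t_grid,
        concentrations=sol.y[:N_STATES],
        cumulative_Pi=sol.y[N_STATES],
        condition=condition,
        kaiC_total=float(y0.sum()),
    )


def simulate(
    params: RateParameterSet,
    condition: SimulationCondition,
    t_grid: np.ndarray,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate a phosphorylation reaction.

    At t=0 KaiA is mixed with KaiC, so the KaiA-bound states are empty and
    the eight free states carry the fitted initial fractions of total KaiC.
    """
    if condition.protocol is Protocol.DEPHOSPHORYLATION_TWO_STAGE:
        return simulate_dephosphorylation_protocol(params, t_grid, condition)
    fracs = params.all_init_fractions()
    if np.any(fracs < -1e-12) or fracs.sum() > 1 + 1e-9:
        raise ValueError("initial fractions outside the simplex")
    y0 = np.zeros(N_STATES)
    y0[:N_FREE_STATES] = np.clip(fracs, 0.0, None) * condition.kaiC_total
    return _integrate(params, condition, y0, t_grid, condition.kaiA_dimer,
                      rtol=rtol, atol=atol)


# Stage-1 constants of the dephosphorylation protocol: dephosphorylated KaiC
# is first phosphorylated with KaiA at 100% ATP for 20 h, then KaiA (free
# and KaiC-bound) is pulled down and autodephosphorylation is followed.
DEPHOS_STAGE1_KAIC = 3.4  # uM, all C_TP^U at onset
DEPHOS_STAGE1_KAIA = 1.3  # uM monomer
DEPHOS_STAGE1_HOURS = 20.0


def simulate_dephosphorylation_protocol(
    params: RateParameterSet,
    t_grid: np.ndarray,
    condition: SimulationCondition | None = None,
) -> Trajectory:
    """Two-stage dephosphorylation protocol; returns the stage-2 trajectory.

    Stage 2 starts from the stage-1 endpoint with all free KaiA and all
    KaiA-bound KaiC states removed (the pull-down), so total KaiC is
    reduced by the amount complexed at 20 h.  Stage 2 has no KaiA, hence
    no exchange and no %ATP dependence.
    """
    stage1_cond = SimulationCondition(
        kaiC_total=DEPHOS_STAGE1_KAIC,
        kaiA_total_monomer=DEPHOS_STAGE1_KAIA,
        pct_ATP=100.0,
        duration=DEPHOS_STAGE1_HOURS,
        protocol=Protocol.PHOSPHORYLATION,
    )
    y0 = np.zeros(N_STATES)
    y0[state_index("U", "TP", False)] = DEPHOS_STAGE1_KAIC
    stage1 = _integrate(
        params,
        stage1_cond,
        y0,
        np.array([0.0, DEPHOS_STAGE1_HOURS]),
        stage1_cond.kaiA_dimer,
    )
    y1 = stage1.concentrations[:, -1].copy()
    y1[N_FREE_STATES:] = 0.0  # pull-down removes KaiA-bound KaiC
    y1 = np.clip(y1, 0.0, None)
    stage2_cond = SimulationCondition(
        kaiC_total=float(y1.sum()),
        kaiA_total_monomer=0.0,
        pct_ATP=condition.pct_ATP if condition is not None else 100.0,
        duration=float(np.asarray(t_grid)[-1]),
        protocol=Protocol.DEPHOSPHORYLATION_TWO_STAGE,
    )
    return _integrate(params, stage2_cond, y1, np.asarray(t_grid, float), 0.0)


@dataclass
class Observables:
    """Phosphoform percentages on the trajectory grid plus the hydrolysis
    observable (total ADP produced over [0, 12 h], uM)."""

    time_grid: np.ndarray
    pct: dict[str, np.ndarray]  # keys U, T, S, D, CP
    adp_produced_12h: float


def observables(traj: Trajectory, t12: float = 12.0) -> Observables:
    """Phosphoform percentages and the 12-h ADP-production observable.

    Percentages are relative to the trajectory's own total KaiC (which is
    reduced in stage 2 of the dephosphorylation protocol).  Concentrations
    within solver tolerance below zero are clamped for reporting only.
    ADP produced = cumulative Pi release + ADP-bound KaiC at t = 12 h.
    """
    conc = np.clip(traj.concentrations, 0.0, None)
    total = traj.kaiC_total
    pct = {}
    for p in "UTSD":
        idx = [
            state_index(p, nuc, bound)
            for nuc in ("TP", "DP")
            for bound in (False, True)
        ]
        pct[p] = conc[idx].sum(axis=0) / total * 100.0
    pct["CP"] = pct["T"] + pct["S"] + pct["D"]

    t = traj.time_grid
    if t[-1] >= t12:
        dp_idx = [
            state_index(p, "DP", bound) for p in "UTSD" for bound in (False, True)
        ]
        adp_bound = np.interp(t12, t, conc[dp_idx].sum(axis=0))
        pi = np.interp(t12, t, traj.cumulative_Pi)
        adp = float(pi + adp_bound)
    else:
        adp = float("nan")
    return Observables(time_grid=t, pct=pct, adp_produced_12h=adp)
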
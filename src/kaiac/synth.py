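"""Synthetic fitting datasets with the statistical structure the analysis
assumes: forward-model trajectories under known ground-truth parameters
plus i.i.d. Gaussian noise with a single global standard deviation.

The default design mirrors the experimental one: 6 [KaiA] levels x 3 %ATP
levels x 8 phosphorylation time points (12.25 h among them) with U, T, D
recorded (S is the conservation-constrained phosphoform), a 21-point
dephosphorylation time series carrying likelihood weight 4, and the
hydrolysis upper bound attached to the three lowest-[KaiA]
phosphorylation conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import Protocol, SimulationCondition, observables, simulate, \
    simulate_dephosphorylation_protocol
from .likelihood import (
    DEPHOS_WEIGHT,
    HYDROLYSIS_KAIA_LEVELS,
    HydrolysisBound,
    KineticsDataset,
    OBSERVED_PHOSPHOFORMS,
)
from .params import RateParameterSet


@dataclass
class SyntheticDesign:
    """Experimental design constants of the synthetic datasets."""

    kaiA_levels: tuple = (0.375, 0.75, 1.50, 3.00, 4.50, 6.00)  # uM monomer
    pctATP_levels: tuple = (10.0, 25.0, 100.0)
    phos_times: tuple = (0.0, 1.0, 2.0, 4.0, 8.0, 12.25, 18.0, 24.0)  # h
    dephos_times: tuple = tuple(np.linspace(0.0, 20.0, 21))
    kaiC_total: float = 3.5  # uM
    noise_sd: float = 1.0  # percentage points
    include_dephos: bool = True
    include_hydrolysis: bool = True

    def conditions(self) -> dict[str, SimulationCondition]:
        conds = {}
        for a in self.kaiA_levels:
            for p in self.pctATP_levels:
                cid = f"phos_A{a:g}_ATP{p:g}"
                conds[cid] = SimulationCondition(
                    kaiC_total=self.kaiC_total,
                    kaiA_total_monomer=a,
                    pct_ATP=p,
                    duration=max(self.phos_times),
                    protocol=Protocol.PHOSPHORYLATION,
                )
        if self.include_dephos:
            conds["dephos"] = SimulationCondition(
                kaiC_total=self.kaiC_total,
                kaiA_total_monomer=0.0,
                pct_ATP=100.0,
                duration=max(self.dephos_times),
                protocol=Protocol.DEPHOSPHORYLATION_TWO_STAGE,
            )
        return conds

    def hydrolysis_condition_ids(self) -> tuple:
        return tuple(
            f"phos_A{a:g}_ATP100" for a in self.kaiA_levels
            if a in HYDROLYSIS_KAIA_LEVELS and 100.0 in self.pctATP_levels
        )


@dataclass
class GroundTruth:
    """A full parameter set plus the noise level used to generate data."""

    params: RateParameterSet
    noise_sd: float = 1.0


def generate(
    design: SyntheticDesign, truth: GroundTruth, seed: int
) -> KineticsDataset:
    """Simulate the full design under the truth and add observation noise.

    Reported values are clipped to [0, 100] after noise addition; the
    likelihood ignores the clipping (a documented approximation, relevant
    only near the extremes at low noise).
    """
    rng = np.random.default_rng(seed)
    conds = design.conditions()
    rows = []
    for cid, cond in conds.items():
        if cond.protocol is Protocol.DEPHOSPHORYLATION_TWO_STAGE:
            times = np.asarray(design.dephos_times)
            traj = simulate_dephosphorylation_protocol(truth.params, times)
            weight = DEPHOS_WEIGHT
        else:
            times = np.asarray(design.phos_times)
            traj = simulate(truth.params, cond, times)
            weight = 1.0
        obs = observables(traj)
        for p in OBSERVED_PHOSPHOFORMS:
            clean = np.interp(times, traj.time_grid, obs.pct[p])
            noisy = clean + rng.normal(0.0, truth.noise_sd, size=len(times))
            noisy = np.clip(noisy, 0.0, 100.0)
            for t, v in zip(times, noisy):
                rows.append(
                    {
                        "condition_id": cid,
                        "time_h": float(t),
                        "phosphoform": p,
                        "value_pct": float(v),
                        "weight": weight,
                    }
                )
    hydro = None
    if design.include_hydrolysis:
        ids = design.hydrolysis_condition_ids()
        if ids:
            hydro = HydrolysisBound.default(design.kaiC_total, ids)
    return KineticsDataset(
        records=pd.DataFrame(rows), conditions=conds, hydrolysis=hydro
    )


# Ground-truth modifiers (log10).  KaiA binds the ADP-bound U phosphoform
# orders of magnitude more tightly than any other state -- the substrate
# competition that produces the threshold-hyperbolic response -- while the
# T/S/D off rates sit at their dwell-time prior centres.  Dephosphorylation
# runs preferentially D -> S, phosphorylation U -> T over U -> S.
_TRUTH_DELTAS = {
    # nucleotide exchange modifiers
    "dkTPA_T": 0.0, "dkTPA_S": 0.0, "dkTPA_D": 0.0,
    # hydrolysis; the KaiA-bound U state cycles fast (exchange vs hydrolysis
    # futile cycle, the engine of the phosphorylation threshold)
    "dkh_T": 0.0, "dkh_S": 0.0, "dkh_D": 0.0,
    "dkhA_U": 0.5, "dkhA_T": 0.0, "dkhA_S": 0.0, "dkhA_D": 0.0,
    # KaiA on: very fast capture of the ADP-bound U state
    "dka_U_DP": 2.5, "dka_D_DP": 0.0, "dka_D_TP": 0.0,
    # KaiA off: U/ADP nearly irreversible; others at dwell-time centres
    "dkb_U_DP": -2.5,
    "dkb_T_DP": 1.178, "dkb_T_TP": 1.178,
    "dkb_S_DP": 1.545, "dkb_S_TP": 1.545,
    "dkb_D_DP": 1.764, "dkb_D_TP": 1.764,
    # phosphotransfer without KaiA
    "dkp_US": -0.5, "dkd_SU": 0.0, "dkp_TD": 0.0, "dkd_DT": -0.5,
    "dkp_SD": 0.0, "dkd_DS": 0.5,
    # phosphotransfer with KaiA bound: strong forward commitment U -> T -> D
    "dkpA_UT": 1.3, "dkdA_TU": -0.6, "dkpA_TD": 0.8, "dkdA_DT": -0.5,
    "dkpA_SD": 0.5, "dkdA_DS": -0.3, "dkpA_US": -0.3, "dkdA_SU": -0.3,
}

_TRUTH_BASE = {
    "kp": 2.0e-4,  # s^-1, bare U<->T phosphotransfer
    "kd": 1.0e-3,
    "ka": 0.0279,  # s^-1 uM^-1, measured on-rate
    "kb": 0.0663,  # s^-1, measured off-rate
    "krDP": 3.0e-3,  # s^-1, ADP release with KaiA bound
    "kh": 1.5e-4,  # s^-1, CII hydrolysis
}

_TRUTH_INIT = {
    "init_CTPU": 0.15, "init_CDPU": 0.79, "init_CTPT": 0.01,
    "init_CDPT": 0.01, "init_CTPS": 0.01, "init_CDPS": 0.01,
    "init_CTPD": 0.01,
}  # CDPD = 0.01 by conservation


def default_truth(noise_sd: float = 1.0) -> GroundTruth:
    """The documented ground-truth parameter set used across the analysis.

    It phosphorylates to a plateau within 24 h at 1.5 uM KaiA / 100% ATP,
    dephosphorylates fully without KaiA, and produces a threshold-
    hyperbolic %CP stimulus-response curve (tight KaiA binding to the
    ADP-bound U state).
    """
    params = RateParameterSet(
        base_rates=dict(_TRUTH_BASE),
        delta_log10=dict(_TRUTH_DELTAS),
        sigma2=(noise_sd / 100.0 * 3.5) ** 2,  # uM^2, matches noise_sd
        init_fractions=dict(_TRUTH_INIT),
    )
    return GroundTruth(params=params, noise_sd=noise_sd)
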
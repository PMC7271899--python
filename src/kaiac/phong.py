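"""Monomer-cycle oscillator with finite KaiA sequestration affinity and an
optional ultrasensitive phosphorylation threshold.

The model tracks the KaiC phosphoform cycle U -> T -> D -> S -> U of a
monomer ensemble, with each (de)phosphorylation step rate a
Michaelis-Menten function of active KaiA,

    k_XY(A) = k0_XY + kA_XY * A / (Khalf + A),

plus two KaiB-bound states ^BC^S and ^BC^D that sequester KaiA and
provide the delayed negative feedback.  Solution %ATP scales the four
phosphorylation steps through the relative nucleotide occupancy
pct / (pct + Krel * (100 - pct)).

Two modifications probe robustness:

* a finite KaiA sequestration affinity K_D: active KaiA follows from the
  one-site quasi-equilibrium between total KaiA and the sequestration
  capacity carried by the KaiB-bound states (K_D -> 0 recovers the
  original min-rule of complete sequestration);
* an ultrasensitive phosphorylation threshold theta(%ATP, [C^U]): the
  KaiA drive entering k_XY becomes max(0, active - theta), emulating the
  substrate-competition suppression of phosphorylation by the U
  phosphoform.  theta = 0 reproduces the unpatched model exactly.

The phosphoform-cycle rate constants follow the classic monomer-model
calibration (h^-1, Khalf in uM); the KaiB-binding branch is this
package's own synthetic reconstruction, calibrated for stable ~daily
oscillations at the standard 3.5 uM KaiC / 1.5 uM KaiA condition, and is
versioned here rather than taken from any single published table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

STATE_NAMES = ("U", "T", "D", "S", "BS", "BD")


@dataclass
class PhongParams:
    """Rate constants (h^-1) and concentrations (uM) of the oscillator."""

    kaiC_total: float = 3.5
    kaiA_total: float = 1.5
    # Michaelis-Menten KaiA dependence of the phosphoform cycle
    khalf: float = 0.43
    k0: dict = field(default_factory=lambda: {
        "UT": 0.0, "TD": 0.0, "SD": 0.0, "US": 0.0,
        "TU": 0.21, "DT": 0.0, "DS": 0.31, "SU": 0.11,
    })
    kA: dict = field(default_factory=lambda: {
        "UT": 0.479077, "TD": 0.212923, "SD": 0.505692, "US": 0.0532308,
        "TU": 0.0798462, "DT": 0.173000, "DS": -0.319385, "SU": -0.133077,
    })
    krel_adp: float = 0.1  # relative ADP affinity in the %ATP scaling
    # KaiB branch (synthetic reconstruction): KaiB binds the S phosphoform
    # (the KaiB-binding trigger); complexes keep their CII kinetics (KaiB
    # acts through CI) and the D form in complex can release KaiB
    kon_B: float = 5.0  # C^S -> BC^S, h^-1
    koff_B: float = 5.0  # BC^S -> C^S and BC^D -> C^D, h^-1
    seq_sites: float = 4.0  # KaiA monomers sequestered per complex
    # ultrasensitive threshold theta = c * [C^U] * (a + (100 - pct)/100)
    theta_c: float = 0.1
    theta_a: float = 0.15


def active_kaiA(A_total: float, sequestration_capacity: float, K_D: float) -> float:
    """Active (unsequestered) KaiA from the one-site quasi-equilibrium.

    Solves bound^2 - bound (A + cap + K_D) + A*cap = 0 for the physical
    root; K_D -> 0 recovers active = max(0, A - cap) (complete
    sequestration up to capacity).
    """
    a, cap = float(A_total), float(sequestration_capacity)
    if a < 0 or cap < 0 or K_D < 0:
        raise ValueError("inputs must be non-negative")
    if K_D == 0.0:
        return max(0.0, a - cap)
    s = a + cap + K_D
    disc = s * s - 4.0 * a * cap
    bound = 0.5 * (s - math.sqrt(max(disc, 0.0)))
    return max(0.0, a - bound)


def threshold_patch(active_A: float, pct_ATP: float, C_U: float,
                    params: PhongParams, patched: bool) -> float:
    """Effective KaiA drive for the phosphorylation rate function.

    theta grows with the U phosphoform pool and with decreasing %ATP, so
    low-%ATP conditions need more active KaiA before phosphorylation
    restarts.  theta = 0 (unpatched) is the identity.
    """
    if not patched:
        return active_A
    theta = params.theta_c * C_U * (params.theta_a + (100.0 - pct_ATP) / 100.0)
    return max(0.0, active_A - theta)


def _atp_scale(pct_ATP: float, krel: float) -> float:
    return pct_ATP / (pct_ATP + krel * (100.0 - pct_ATP))


def _rhs(t, y, params: PhongParams, pct_ATP: float, K_D: float, patched: bool):
    U, T, D, S, BS, BD = y
    cap = params.seq_sites * (BS + BD)
    act = active_kaiA(params.kaiA_total, cap, K_D)
    # the threshold gates the four phosphorylation steps only;
    # dephosphorylation responds to active KaiA directly
    drive = threshold_patch(act, pct_ATP, max(U, 0.0), params, patched)
    mm_ph = drive / (params.khalf + drive)
    mm_de = act / (params.khalf + act)
    s_atp = _atp_scale(pct_ATP, params.krel_adp)

    def k(name, phospho):
        if phospho:
            return max(0.0, params.k0[name] + params.kA[name] * mm_ph) * s_atp
        return max(0.0, params.k0[name] + params.kA[name] * mm_de)

    kUT, kTD, kSD, kUS = (k(n, True) for n in ("UT", "TD", "SD", "US"))
    kTU, kDT, kDS, kSU = (k(n, False) for n in ("TU", "DT", "DS", "SU"))
    kon, koff = params.kon_B, params.koff_B

    dU = kTU * T + kSU * S + kSU * BS - (kUT + kUS) * U
    dT = kUT * U + kDT * D - (kTU + kTD) * T
    dD = kTD * T + kSD * S - (kDT + kDS) * D + koff * BD
    dS = kUS * U + kDS * D - (kSU + kSD) * S + koff * BS - kon * S
    dBS = kon * S - koff * BS + kDS * BD - (kSU + kSD) * BS
    dBD = kSD * BS - kDS * BD - koff * BD
    return [dU, dT, dD, dS, dBS, dBD]


class OscClass(str, Enum):
    OSCILLATORY = "oscillatory"
    WEAK = "weak"
    DAMPED = "damped"
    TOO_FEW_TROUGHS = "too_few_troughs"
    INVALID = "invalid"


@dataclass
class OscillationReport:
    classification: OscClass
    period: float | None  # hours, defined only when oscillatory
    trough_times: np.ndarray
    trough_values: np.ndarray
    cp_std: float


SIM_HOURS = 200.0
DISCARD_HOURS = 100.0
RESAMPLE_DT = 0.1
TROUGH_PROMINENCE = 0.01  # uM
WEAK_STD = 0.1  # uM
DAMPED_TROUGH_STD = 1e-3  # uM


def total_cp(y: np.ndarray) -> np.ndarray:
    """[C^P] = [C^T] + [C^S] + [C^D] + [^BC^S] + [^BC^D]."""
    return y[1] + y[2] + y[3] + y[4] + y[5]


def classify_series(t: np.ndarray, cp: np.ndarray) -> OscillationReport:
    """Apply the three non-oscillation criteria to a resampled [C^P]
    series (post-transient): weak if std < 0.1 uM, damped if the trough
    amplitudes drift (std > 0.001 uM), too-few if < 3 troughs; otherwise
    the period is the mean trough-to-trough time."""
    cp_std = float(np.std(cp))
    troughs, _ = find_peaks(-cp, prominence=TROUGH_PROMINENCE)
    t_troughs = t[troughs]
    v_troughs = cp[troughs]
    if cp_std < WEAK_STD:
        cls, period = OscClass.WEAK, None
    elif len(troughs) < 3:
        cls, period = OscClass.TOO_FEW_TROUGHS, None
    elif float(np.std(v_troughs)) > DAMPED_TROUGH_STD:
        cls, period = OscClass.DAMPED, None
    else:
        cls = OscClass.OSCILLATORY
        period = float(np.mean(np.diff(t_troughs)))
    return OscillationReport(cls, period, t_troughs, v_troughs, cp_std)


def simulate_phong(
    params: PhongParams, pct_ATP: float, K_D: float, patched: bool,
    hours: float = SIM_HOURS,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the oscillator and return (t, states) resampled at 0.1 h."""
    y0 = np.array([params.kaiC_total, 0.0, 0.0, 0.0, 0.0, 0.0])
    t_eval = np.arange(0.0, hours + RESAMPLE_DT / 2, RESAMPLE_DT)
    sol = solve_ivp(
        _rhs, (0.0, hours), y0, method="LSODA", t_eval=t_eval,
        rtol=1e-8, atol=1e-10, args=(params, pct_ATP, K_D, patched),
    )
    if not sol.success:
        raise RuntimeError(sol.message)
    return sol.t, sol.y


def simulate_and_classify(
    params: PhongParams, pct_ATP: float, K_D: float, patched: bool,
) -> OscillationReport:
    """200 h simulation, first 100 h discarded, then classification."""
    try:
        t, y = simulate_phong(params, pct_ATP, K_D, patched)
    except RuntimeError:
        return OscillationReport(OscClass.INVALID, None, np.array([]), np.array([]), float("nan"))
    keep = t >= DISCARD_HOURS
    return classify_series(t[keep], total_cp(y)[keep])


@dataclass
class ScanResult:
    pct_ATP_grid: np.ndarray
    K_D_grid: np.ndarray
    period: np.ndarray  # (n_atp, n_kd), nan where not oscillatory
    classification: np.ndarray  # object array of OscClass values

    def oscillatory_mask(self) -> np.ndarray:
        return np.array(
            [[c is OscClass.OSCILLATORY for c in row] for row in self.classification]
        )

    def n_oscillatory(self) -> int:
        return int(self.oscillatory_mask().sum())


def scan(
    pct_ATP_grid: np.ndarray,
    K_D_grid: np.ndarray,
    patched: bool,
    params: PhongParams | None = None,
) -> ScanResult:
    """Classify the oscillator over a %ATP x K_D grid; per-cell failures
    are recorded as invalid and the scan continues."""
    params = params or PhongParams()
    pct_ATP_grid = np.asarray(pct_ATP_grid, float)
    K_D_grid = np.asarray(K_D_grid, float)
    period = np.full((len(pct_ATP_grid), len(K_D_grid)), np.nan)
    cls = np.empty((len(pct_ATP_grid), len(K_D_grid)), dtype=object)
    for i, pct in enumerate(pct_ATP_grid):
        for j, kd in enumerate(K_D_grid):
            rep = simulate_and_classify(params, float(pct), float(kd), patched)
            cls[i, j] = rep.classification
            if rep.classification is OscClass.OSCILLATORY:
                period[i, j] = rep.period
    return ScanResult(pct_ATP_grid, K_D_grid, period, cls)
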
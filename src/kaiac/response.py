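"""Steady-state stimulus-response analysis and shape metrics.

The stimulus is KaiA concentration, the response the near-steady-state
total phosphorylation %C^P = %T + %S + %D.  Two metrics of Gunawardena
quantify curve shape: EC10 (threshold-like behaviour) and EC90 - EC10
(switch-like behaviour), where ECx is the stimulus at which the response
reaches x% of its saturation level above baseline.  A pure hyperbola
[A]/(K+[A]) has (EC10, EC90-EC10) = (K/9, 80K/9), i.e. a switch-to-
threshold ratio of exactly 80; threshold-hyperbolic (ultrasensitive)
curves push EC10 far above K/9.

The phenomenological competition model is the Ferrell-Ha inhibitor
ultrasensitivity scheme: a stoichiometric inhibitor I buffers the kinase
K with dissociation constant K2, and the response is hyperbolic (scale
K1) in the remaining free kinase.  As K2 -> 0 this reduces to the
right-shifted threshold-hyperbola Pmax (K-I)/(K1+K-I) H(K-I) + b.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

from .kinetics import SimulationCondition, observables, simulate
from .params import RateParameterSet

DEFAULT_KAIA_GRID = np.geomspace(0.01, 10.0, 40)  # uM monomer
DEFAULT_EVAL_TIME = 24.0  # h
SETTLE_SLOPE = 0.1  # %CP per hour


@dataclass
class StimulusResponseCurve:
    kaiA_grid: np.ndarray  # uM monomer
    response: np.ndarray  # %CP at eval_time
    per_phosphoform: dict[str, np.ndarray]
    pct_ATP: float
    eval_time: float
    settled: np.ndarray  # bool per grid point


def steady_state_response(
    params: RateParameterSet,
    pct_ATP: float,
    kaiA_grid: np.ndarray = DEFAULT_KAIA_GRID,
    eval_time: float = DEFAULT_EVAL_TIME,
    kaiC_total: float = 3.5,
) -> StimulusResponseCurve:
    """One ODE solve per [KaiA] grid point; response read at eval_time.

    Settledness is checked from the numerical slope of %CP over the final
    hour; non-settled points are flagged, not discarded.
    """
    kaiA_grid = np.asarray(kaiA_grid, float)
    resp = np.empty_like(kaiA_grid)
    per = {p: np.empty_like(kaiA_grid) for p in "UTSD"}
    settled = np.empty(kaiA_grid.shape, dtype=bool)
    t_grid = np.array([0.0, eval_time - 1.0, eval_time])
    for i, a in enumerate(kaiA_grid):
        cond = SimulationCondition(
            kaiC_total=kaiC_total,
            kaiA_total_monomer=float(a),
            pct_ATP=pct_ATP,
            duration=eval_time,
        )
        obs = observables(simulate(params, cond, t_grid))
        resp[i] = obs.pct["CP"][-1]
        settled[i] = abs(obs.pct["CP"][-1] - obs.pct["CP"][-2]) < SETTLE_SLOPE
        for p in "UTSD":
            per[p][i] = obs.pct[p][-1]
    return StimulusResponseCurve(
        kaiA_grid=kaiA_grid,
        response=resp,
        per_phosphoform=per,
        pct_ATP=pct_ATP,
        eval_time=eval_time,
        settled=settled,
    )


PLATEAU_REL_SLOPE = 0.01  # fractional change per decade of stimulus


def _saturation(curve_x: np.ndarray, curve_y: np.ndarray) -> float:
    """Plateau level: response at the top of the grid, with a plateau
    check (relative slope < 1% per decade over the last interval)."""
    y_max = curve_y[-1]
    if len(curve_x) >= 2 and y_max > 0:
        decades = math.log10(curve_x[-1] / curve_x[-2])
        slope = abs(curve_y[-1] - curve_y[-2]) / max(y_max, 1e-12) / max(decades, 1e-12)
        if slope > PLATEAU_REL_SLOPE:
            # fall back to the grid maximum; the caller may widen the grid
            y_max = float(np.max(curve_y))
    return float(y_max)


def ec_metric(
    kaiA_grid: np.ndarray, response: np.ndarray, x_pct: float, baseline: float | None = None
) -> float:
    """EC_x: smallest stimulus at which the response reaches x% of the
    saturation level above baseline (monotone linear interpolation).

    Returns nan when the level is never attained on the grid.
    """
    x_axis = np.asarray(kaiA_grid, float)
    y = np.asarray(response, float)
    if baseline is None:
        baseline = float(y[0])
    sat = _saturation(x_axis, y)
    level = baseline + (x_pct / 100.0) * (sat - baseline)
    above = np.nonzero(y >= level)[0]
    if len(above) == 0 or sat <= baseline:
        return float("nan")
    i = above[0]
    if i == 0:
        return float(x_axis[0])
    x0, x1 = x_axis[i - 1], x_axis[i]
    y0, y1 = y[i - 1], y[i]
    return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))


def shape_measures(curve: StimulusResponseCurve | tuple) -> dict[str, float]:
    """(EC10, EC90-EC10) plus the hyperbolic reference for a fitted K.

    Returns dict with keys ec10, ec50, ec90, switch (EC90-EC10),
    hyperbola_K (least-squares K of a scaled hyperbola through the same
    points), and the references K/9 and 80K/9.
    """
    if isinstance(curve, StimulusResponseCurve):
        x_axis, y = curve.kaiA_grid, curve.response
    else:
        x_axis, y = curve
    ec10 = ec_metric(x_axis, y, 10.0)
    ec50 = ec_metric(x_axis, y, 50.0)
    ec90 = ec_metric(x_axis, y, 90.0)
    base = float(y[0])
    sat = _saturation(x_axis, y)

    def resid(logk):
        h = base + (sat - base) * x_axis / (10.0 ** logk[0] + x_axis)
        return h - y

    fit = least_squares(resid, x0=[math.log10(max(ec50, 1e-6))])
    k_hyp = float(10.0 ** fit.x[0])
    return {
        "ec10": ec10,
        "ec50": ec50,
        "ec90": ec90,
        "switch": ec90 - ec10,
        "hyperbola_K": k_hyp,
        "hyperbola_ec10": k_hyp / 9.0,
        "hyperbola_switch": 80.0 * k_hyp / 9.0,
    }


# --- phenomenological substrate-competition curve --------------------------

@dataclass
class CompetitionFitParams:
    """Free parameters of the inhibitor-ultrasensitivity curve: maximal
    response Pmax (%), inhibitor level I (uM), response scale K1 (uM),
    inhibitor dissociation constant K2 (uM), basal offset b (%)."""

    Pmax: float
    I: float
    K1: float
    K2: float
    b: float

    def __post_init__(self):
        for f in ("Pmax", "I", "K1", "K2", "b"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


def free_kinase(K_conc, I, K2):
    """Free kinase after one-site binding to the inhibitor (Kd = K2):
    the stable root of Kf^2 + Kf(K2 + I - K) - K*K2 = 0."""
    K_conc = np.asarray(K_conc, float)
    bq = K2 + I - K_conc
    disc = np.sqrt(bq * bq + 4.0 * K2 * K_conc)
    return 0.5 * (-bq + disc)


def competition_curve(K_conc, fit: CompetitionFitParams):
    """%XP([K]) of the inhibitor ultrasensitivity scheme."""
    kf = free_kinase(K_conc, fit.I, fit.K2)
    return fit.Pmax * kf / (fit.K1 + kf) + fit.b


def threshold_hyperbola(K_conc, fit: CompetitionFitParams):
    """The K2 -> 0 limit: Pmax (K-I)/(K1+K-I) H(K-I) + b."""
    K_conc = np.asarray(K_conc, float)
    excess = np.maximum(K_conc - fit.I, 0.0)
    return fit.Pmax * excess / (fit.K1 + excess) + fit.b


def fit_competition(
    K_conc: np.ndarray,
    response: np.ndarray,
    n_starts: int = 8,
    rng: np.random.Generator | None = None,
) -> tuple[CompetitionFitParams, float]:
    """Nonlinear least squares of the competition curve; returns the fit
    and its EC50 (found by root bracketing, since EC50 is not an explicit
    parameter of the scheme).

    Multi-start over log-spaced initializations; needs points on both
    sides of the threshold to be identifiable.
    """
    K_conc = np.asarray(K_conc, float)
    response = np.asarray(response, float)
    if len(K_conc) < 6:
        raise ValueError("need at least 6 points spanning the threshold")
    rng = rng or np.random.default_rng(0)
    span = float(response.max() - response.min())
    x_mid = float(np.median(K_conc))

    def resid(p):
        pmax, i0, k1, k2, b = np.exp(p[:4]).tolist() + [p[4]]
        return competition_curve(K_conc, CompetitionFitParams(pmax, i0, k1, k2, b)) - response

    best = None
    starts = [
        np.array([math.log(max(span, 1e-3)), math.log(x_mid), math.log(x_mid / 3),
                  math.log(x_mid / 100), float(response.min())])
    ]
    for _ in range(n_starts - 1):
        starts.append(starts[0] + rng.normal(0, 1.0, size=5) * np.array([0.3, 1, 1, 2, 0.1]))
    for s in starts:
        try:
            res = least_squares(resid, s, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("competition fit did not converge from any start")
    pmax, i0, k1, k2 = np.exp(best.x[:4])
    fit = CompetitionFitParams(pmax, i0, k1, k2, best.x[4])
    ec50 = ec50_of_fit(fit, K_conc[0], K_conc[-1])
    return fit, ec50


def ec50_of_fit(fit: CompetitionFitParams, lo: float, hi: float) -> float:
    """Numeric EC50 of the fitted curve: stimulus at half the span between
    the basal level and the saturation Pmax + b."""
    target = fit.b + 0.5 * fit.Pmax

    def g(k):
        return float(competition_curve(k, fit)) - target

    lo = max(lo, 1e-12)
    hi_ext = hi
    for _ in range(60):
        if g(hi_ext) > 0:
            break
        hi_ext *= 2.0
    else:
        return float("nan")
    if g(lo) > 0:
        return lo
    return float(brentq(g, lo, hi_ext))
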
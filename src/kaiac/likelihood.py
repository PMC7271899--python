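"""Dataset container and the Gaussian / half-harmonic likelihoods.

Observed phosphoform percentages carry a Gaussian likelihood with a single
global error sigma shared by all (de)phosphorylation points; sigma^2 is a
fitted hyperparameter, quoted in uM^2 and converted to percentage points
through the total KaiC concentration of each reaction.  Dephosphorylation
records are up-weighted by a factor of 4 so that the small
dephosphorylation dataset is not swamped by the phosphorylation data.  The
hydrolysis constraint is an upper bound only, so its log-likelihood is a
half harmonic: zero below the bound and quadratic above it.

The S phosphoform is never a stored observable: percentages sum to 100, so
S is the conservation-constrained variable and datasets store U, T and D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import (
    IntegrationError,
    Protocol,
    SimulationCondition,
    Trajectory,
    observables,
    simulate,
    simulate_dephosphorylation_protocol,
)
from .params import RateParameterSet
from .priors import PriorSpec

DEPHOS_WEIGHT = 4.0
OBSERVED_PHOSPHOFORMS = ("U", "T", "D")

# Upper bound on the mean CII hydrolysis rate: 29.8 +/- 5.1 ADP per KaiC
# per day.  Over the 12 h observation window at total KaiC [C]:
#   bound (uM) = 29.8 * [C] * 0.5, sigma_h (uM) = 5.1 * [C] * 0.5.
HYDROLYSIS_RATE_PER_DAY = 29.8
HYDROLYSIS_RATE_SD_PER_DAY = 5.1
HYDROLYSIS_KAIA_LEVELS = (0.375, 0.75, 1.50)  # uM monomer


@dataclass
class HydrolysisBound:
    value_uM: float
    sigma_uM: float
    condition_ids: tuple

    @classmethod
    def default(cls, kaiC_total: float, condition_ids: tuple) -> "HydrolysisBound":
        return cls(
            value_uM=HYDROLYSIS_RATE_PER_DAY * kaiC_total * 0.5,
            sigma_uM=HYDROLYSIS_RATE_SD_PER_DAY * kaiC_total * 0.5,
            condition_ids=tuple(condition_ids),
        )


@dataclass
class KineticsDataset:
    """Tidy records plus condition metadata and the hydrolysis bound.

    records columns: condition_id, time_h, phosphoform (U/T/D), value_pct,
    weight.  Every condition_id must be present in `conditions`.
    """

    records: pd.DataFrame
    conditions: dict[str, SimulationCondition]
    hydrolysis: HydrolysisBound | None = None
    _compiled: list = field(default=None, repr=False)

    def __post_init__(self):
        unknown = set(self.records["condition_id"]) - set(self.conditions)
        if unknown:
            raise ValueError(f"records reference undefined conditions: {unknown}")
        if "S" in set(self.records["phosphoform"]):
            raise ValueError("S is the conservation-constrained phosphoform; "
                             "datasets store U, T, D only")

    # --- CSV round trip ----------------------------------------------------

    def to_csv(self, path) -> None:
        df = self.records.copy()
        meta = pd.DataFrame(
            [
                {
                    "condition_id": cid,
                    "kaiA_uM": c.kaiA_total_monomer,
                    "pctATP": c.pct_ATP,
                    "protocol": c.protocol.value,
                    "kaiC_uM": c.kaiC_total,
                    "duration_h": c.duration,
                }
                for cid, c in self.conditions.items()
            ]
        )
        df = df.merge(meta, on="condition_id")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, hydrolysis: HydrolysisBound | None = None):
        df = pd.read_csv(path)
        conditions = {}
        for cid, grp in df.groupby("condition_id"):
            row = grp.iloc[0]
            conditions[cid] = SimulationCondition(
                kaiC_total=float(row["kaiC_uM"]),
                kaiA_total_monomer=float(row["kaiA_uM"]),
                pct_ATP=float(row["pctATP"]),
                duration=float(row["duration_h"]),
                protocol=Protocol(row["protocol"]),
            )
        records = df[["condition_id", "time_h", "phosphoform", "value_pct", "weight"]]
        return cls(records=records, conditions=conditions, hydrolysis=hydrolysis)

    # --- compiled per-condition arrays for fast likelihood evaluation ------

    def compiled(self):
        if self._compiled is None:
            groups = []
            for cid, grp in self.records.groupby("condition_id", sort=True):
                cond = self.conditions[cid]
                times = np.unique(grp["time_h"].to_numpy(float))
                t_index = {t: i for i, t in enumerate(times)}
                rows = grp.reset_index(drop=True)
                ti = np.array([t_index[t] for t in rows["time_h"]], dtype=int)
                groups.append(
                    {
                        "condition_id": cid,
                        "condition": cond,
                        "times": times,
                        "time_idx": ti,
                        "phospho": rows["phosphoform"].to_numpy(),
                        "values": rows["value_pct"].to_numpy(float),
                        "weights": rows["weight"].to_numpy(float),
                    }
                )
            self._compiled = groups
        return self._compiled


def _simulate_condition(
    params: RateParameterSet, cond: SimulationCondition, times: np.ndarray
) -> Trajectory:
    t = times if times[0] == 0.0 else np.concatenate([[0.0], times])
    # extend to 12 h when the hydrolysis observable needs it
    if cond.protocol is Protocol.PHOSPHORYLATION and t[-1] < 12.0:
        t = np.concatenate([t, [12.0]])
    if cond.protocol is Protocol.DEPHOSPHORYLATION_TWO_STAGE:
        return simulate_dephosphorylation_protocol(params, t)
    return simulate(params, cond, t)


def _gaussian_block(group, traj: Trajectory, sigma_pct: float) -> float:
    obs = observables(traj)
    model = np.empty_like(group["values"])
    full_times = traj.time_grid
    # map requested times onto the (possibly 0/12h-padded) solver grid
    pos = np.searchsorted(full_times, group["times"])
    for k, p in enumerate(group["phospho"]):
        model[k] = obs.pct[p][pos[group["time_idx"][k]]]
    r = group["values"] - model
    w = group["weights"]
    return float(
        np.sum(w * (-0.5 * (r / sigma_pct) ** 2 - math.log(math.sqrt(2 * math.pi) * sigma_pct)))
    )


def sigma_pct_from_sigma2(sigma2_uM2: float, kaiC_total: float) -> float:
    """Convert the uM^2 error variance to percentage points of total KaiC."""
    return math.sqrt(sigma2_uM2) / kaiC_total * 100.0


def log_likelihood_timeseries(
    params: RateParameterSet,
    dataset: KineticsDataset,
    trajectories: dict | None = None,
) -> float:
    """Gaussian log-likelihood of all (de)phosphorylation records with the
    single global sigma; -inf if any integration fails."""
    total = 0.0
    try:
        for group in dataset.compiled():
            cid = group["condition_id"]
            if trajectories is not None and cid in trajectories:
                traj = trajectories[cid]
            else:
                traj = _simulate_condition(params, group["condition"], group["times"])
                if trajectories is not None:
                    trajectories[cid] = traj
            sigma_pct = sigma_pct_from_sigma2(params.sigma2, traj.kaiC_total)
            total += _gaussian_block(group, traj, sigma_pct)
    except IntegrationError:
        return -math.inf
    return total


def log_likelihood_hydrolysis(
    params: RateParameterSet,
    dataset: KineticsDataset,
    trajectories: dict | None = None,
) -> float:
    """Half-harmonic log-likelihood of the ADP-production upper bound."""
    bound = dataset.hydrolysis
    if bound is None:
        return 0.0
    total = 0.0
    try:
        for cid in bound.condition_ids:
            cond = dataset.conditions[cid]
            if trajectories is not None and cid in trajectories:
                traj = trajectories[cid]
            else:
                group = next(
                    g for g in dataset.compiled() if g["condition_id"] == cid
                )
                traj = _simulate_condition(params, cond, group["times"])
                if trajectories is not None:
                    trajectories[cid] = traj
            adp = observables(traj).adp_produced_12h
            if adp > bound.value_uM:
                total += -0.5 * ((adp - bound.value_uM) / bound.sigma_uM) ** 2
    except IntegrationError:
        return -math.inf
    return total


def log_posterior(
    params: RateParameterSet,
    dataset: KineticsDataset,
    spec: PriorSpec | None = None,
) -> float:
    """log prior + Gaussian log-likelihood + hydrolysis half-harmonic
    (additive constant dropped).  Shares one simulation per condition
    between the two likelihood terms."""
    spec = spec or PriorSpec()
    lp = spec.log_prior(params)
    if not math.isfinite(lp):
        return -math.inf
    cache: dict = {}
    ll = log_likelihood_timeseries(params, dataset, cache)
    if not math.isfinite(ll):
        return -math.inf
    lh = log_likelihood_hydrolysis(params, dataset, cache)
    if not math.isfinite(lh):
        return -math.inf
    return lp + ll + lh


@dataclass
class ReducedPosterior:
    """Posterior over a subset of the 48 coordinates, the rest clamped.

    Used for test-scale fits: `free_idx` selects walker coordinates and
    `base_vector` supplies the clamped values.  Calls return
    (log_likelihood, log_prior) so samplers can temper the likelihood
    alone.
    """

    dataset: KineticsDataset
    spec: PriorSpec
    base_vector: np.ndarray
    free_idx: np.ndarray

    def expand(self, theta: np.ndarray) -> np.ndarray:
        v = self.base_vector.copy()
        v[self.free_idx] = theta
        return v

    def components(self, theta: np.ndarray) -> tuple[float, float]:
        try:
            params = RateParameterSet.from_vector(self.expand(theta))
        except ValueError:
            return -math.inf, -math.inf
        lp = self.spec.log_prior(params)
        if not math.isfinite(lp):
            return -math.inf, lp
        cache: dict = {}
        ll = log_likelihood_timeseries(params, self.dataset, cache)
        if math.isfinite(ll):
            ll += log_likelihood_hydrolysis(params, self.dataset, cache)
        return ll, lp

    def __call__(self, theta: np.ndarray) -> float:
        ll, lp = self.components(theta)
        return ll + lp if math.isfinite(ll) and math.isfinite(lp) else -math.inf
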
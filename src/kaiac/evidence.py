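"""Marginal likelihood by a free-energy-perturbation ladder, Bayes
factors, and reduced model variants with tied KaiA kinetics.

The evidence p(D|M) = Z_1/Z_0 is written as a telescoping product over a
ladder of tempered targets q_lambda = L^lambda * p, 0 = lambda_0 < ... <
lambda_N = 1.  Each ratio is an exponential average over samples of the
next-higher rung,

    Z_{lambda_{n-1}} / Z_{lambda_n} = < L^{lambda_{n-1}-lambda_n} >_{q_{lambda_n}},

so ln p(D|M) is minus the sum of the stage log-averages.  Sampling starts
from a converged posterior ensemble at lambda = 1 and steps the ladder
down; the segment from the lowest sampled rung to lambda = 0 is evaluated
with that rung's own samples, completing the telescope.  The likelihood
must be normalized as a density over the data; the prior normalization
cancels within each ratio.

Bayes factors B_ij = p(D|M_i)/p(D|M_j); values above 3.2 are
conventionally substantial evidence against the weaker model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .params import (
    DELTA_NAMES_EXCHANGE,
    DELTA_NAMES_HYDROLYSIS,
    DELTA_NAMES_HYDROLYSIS_A,
    DELTA_NAMES_PHOS,
    BASE_RATE_NAMES,
    FREE_DELTA_NAMES,
    FREE_INIT_NAMES,
    RateParameterSet,
)
from .sampler import WalkerEnsemble, run_ensemble

BAYES_FACTOR_SUBSTANTIAL = 3.2


# --- tempered ladder -------------------------------------------------------

@dataclass
class LadderConfig:
    """Descending lambda ladder; defaults are the full-scale settings
    (step 0.01 down to 0.01, 2,000 steps per stage, last 1,000 used)."""

    lambda_step: float = 0.01
    lambda_min: float = 0.01
    stage_steps: int = 2_000
    keep_last: int = 1_000
    alpha: float = 1.1
    n_bootstrap: int = 200

    def lambdas(self) -> np.ndarray:
        """Sampled rungs, descending from 1.0 to lambda_min."""
        n = int(round((1.0 - self.lambda_min) / self.lambda_step))
        lam = 1.0 - self.lambda_step * np.arange(n + 1)
        return np.round(lam, 12)

    @classmethod
    def test_scale(cls) -> "LadderConfig":
        return cls(lambda_step=0.05, lambda_min=0.05, stage_steps=300,
                   keep_last=150, n_bootstrap=100)


@dataclass
class EvidenceResult:
    log_evidence: float
    std_error: float
    stage_lambdas: np.ndarray
    stage_log_ratios: np.ndarray
    flagged_stages: list = field(default_factory=list)


def estimate_log_evidence(
    log_prob_fn,
    ensemble: WalkerEnsemble,
    ladder: LadderConfig,
    rng: np.random.Generator | None = None,
) -> EvidenceResult:
    """Estimate ln p(D|M) down the lambda ladder.

    `log_prob_fn(theta) -> (loglike, logprior)` with the likelihood
    normalized as a density; `ensemble` should be a converged posterior
    ensemble (it initializes the lambda = 1 stage).  The Monte Carlo
    standard error is a bootstrap over walkers, which respects the strong
    within-walker autocorrelation.
    """
    rng = rng or ensemble.rng
    lambdas = ladder.lambdas()
    gaps = np.append(-np.diff(lambdas), lambdas[-1])  # gap below each rung
    stage_ll = []  # per stage: (records, walkers) loglike array
    flagged = []
    ens = ensemble
    for lam in lambdas:
        ens, chain = run_ensemble(
            log_prob_fn, ens, ladder.stage_steps, ladder.alpha, beta=float(lam)
        )
        keep = min(ladder.keep_last, chain.loglike.shape[0])
        stage_ll.append(chain.loglike[-keep:])

    log_ratios = np.empty(len(lambdas))
    for i, (lam, gap) in enumerate(zip(lambdas, gaps)):
        ll = stage_ll[i]
        good = np.all(np.isfinite(ll), axis=0)
        if not good.all():
            flagged.append(float(lam))
            ll = ll[:, good]
        # ln < exp(-gap * lnL) > over the retained samples
        log_ratios[i] = logsumexp(-gap * ll) - math.log(ll.size)
    log_z = -float(np.sum(log_ratios))

    # block bootstrap over walkers
    n_walk = stage_ll[0].shape[1]
    reps = np.empty(ladder.n_bootstrap)
    for b in range(ladder.n_bootstrap):
        idx = rng.integers(n_walk, size=n_walk)
        tot = 0.0
        for (lam, gap), ll in zip(zip(lambdas, gaps), stage_ll):
            sub = ll[:, idx % ll.shape[1]]
            tot -= logsumexp(-gap * sub) - math.log(sub.size)
        reps[b] = tot
    return EvidenceResult(
        log_evidence=log_z,
        std_error=float(np.std(reps)),
        stage_lambdas=lambdas,
        stage_log_ratios=log_ratios,
        flagged_stages=flagged,
    )


def bayes_factor(log_evidence_i: float, log_evidence_j: float) -> float:
    """B_ij = p(D|M_i)/p(D|M_j) = exp(ln Z_i - ln Z_j)."""
    return math.exp(log_evidence_i - log_evidence_j)


# --- reduced model variants ------------------------------------------------

# Free KaiA-bound dephosphorylation modifiers retained by every reduced
# variant; the corresponding phosphorylation modifiers become the
# detailed-balance-dependent ones.
_PHOS_A_FREE = ("dkdA_TU", "dkdA_DT", "dkdA_DS", "dkdA_SU")
_SHARED = (
    DELTA_NAMES_EXCHANGE
    + DELTA_NAMES_HYDROLYSIS
    + DELTA_NAMES_HYDROLYSIS_A
    + DELTA_NAMES_PHOS
    + _PHOS_A_FREE
)


def _resolve_cycles(d: dict, ka: dict, kb: dict) -> dict:
    """Fill the four dependent KaiA-bound phosphorylation modifiers so that
    every detailed-balance cycle closes under the tied KaiA-on values.

    `ka[(X, nuc)]` / `kb[(X, nuc)]` give the tied log10 on/off modifiers
    for every state.  The cycle conditions are solved for dkpA_UT,
    dkpA_US, dkpA_TD, dkpA_SD.
    """
    out = dict(d)
    out["dkpA_UT"] = ka[("T", "DP")] - kb[("T", "DP")] + d["dkdA_TU"]
    out["dkpA_US"] = (
        ka[("S", "DP")] - d["dkd_SU"] - kb[("S", "DP")] + d["dkp_US"] + d["dkdA_SU"]
    )
    out["dkpA_TD"] = (
        d["dkp_TD"] + ka[("D", "DP")] + d["dkdA_DT"] + kb[("T", "TP")]
        - d["dkd_DT"] - kb[("D", "DP")] - ka[("T", "TP")]
    )
    out["dkpA_SD"] = (
        d["dkp_SD"] + ka[("D", "DP")] + d["dkdA_DS"] + kb[("S", "TP")]
        - d["dkd_DS"] - kb[("D", "DP")] - ka[("S", "TP")]
    )
    return out


@dataclass(frozen=True)
class ModelVariant:
    """A model with tied KaiA (un)binding kinetics and the same network.

    full      : the unmodified 48-coordinate model.
    minus_n   : on/off rates independent of the nucleotide-bound state
                (one on/off pair per phosphoform).
    minus_p   : independent of the phosphoform (one pair per nucleotide
                state).
    minus_n_p : a single KaiA on/off pair (the base ka, kb only).
    """

    name: str
    free_delta_names: tuple

    @property
    def n_dims(self) -> int:
        # base rates + free modifiers + sigma2 + 7 init fractions
        return len(BASE_RATE_NAMES) + len(self.free_delta_names) + 1 + len(FREE_INIT_NAMES)

    def resolve_deltas(self, reduced: dict[str, float]) -> dict[str, float]:
        """Map the variant's free modifiers to the full 34-name set."""
        if self.name == "full":
            return {n: reduced[n] for n in FREE_DELTA_NAMES}
        d = {n: reduced[n] for n in _SHARED}
        if self.name == "minus_n":
            ka = {(x, nuc): reduced.get(f"dka_{x}", 0.0) for x in "UTSD"
                  for nuc in ("TP", "DP")}
            kb = {(x, nuc): reduced.get(f"dkb_{x}", 0.0) for x in "UTSD"
                  for nuc in ("TP", "DP")}
        elif self.name == "minus_p":
            ka = {(x, nuc): (reduced["dka_DP"] if nuc == "DP" else 0.0)
                  for x in "UTSD" for nuc in ("TP", "DP")}
            kb = {(x, nuc): (reduced["dkb_DP"] if nuc == "DP" else 0.0)
                  for x in "UTSD" for nuc in ("TP", "DP")}
        elif self.name == "minus_n_p":
            ka = {(x, nuc): 0.0 for x in "UTSD" for nuc in ("TP", "DP")}
            kb = dict(ka)
        else:
            raise ValueError(f"unknown variant {self.name!r}")
        d = _resolve_cycles(d, ka, kb)
        # explicit free on/off modifiers of the full naming scheme
        d["dka_U_DP"] = ka[("U", "DP")]
        d["dka_D_DP"] = ka[("D", "DP")]
        d["dka_D_TP"] = ka[("D", "TP")]
        for x in "UTSD":
            for nuc in ("TP", "DP"):
                name = f"dkb_{x}_{nuc}"
                if name in FREE_DELTA_NAMES:
                    d[name] = kb[(x, nuc)]
        return d

    def to_params(self, vector: np.ndarray) -> RateParameterSet:
        """Build a full RateParameterSet from the variant's coordinates."""
        v = np.asarray(vector, float)
        if v.shape != (self.n_dims,):
            raise ValueError(f"expected {self.n_dims} coordinates, got {v.shape}")
        nb = len(BASE_RATE_NAMES)
        nd = len(self.free_delta_names)
        reduced = {n: v[nb + i] for i, n in enumerate(self.free_delta_names)}
        return RateParameterSet(
            base_rates={n: 10.0 ** v[i] for i, n in enumerate(BASE_RATE_NAMES)},
            delta_log10=self.resolve_deltas(reduced),
            sigma2=10.0 ** v[nb + nd],
            init_fractions={n: v[nb + nd + 1 + i] for i, n in enumerate(FREE_INIT_NAMES)},
        )


_VARIANT_DELTAS = {
    "full": FREE_DELTA_NAMES,
    "minus_n": _SHARED + ("dka_T", "dka_S", "dka_D", "dkb_T", "dkb_S", "dkb_D"),
    "minus_p": _SHARED + ("dka_DP", "dkb_DP"),
    "minus_n_p": _SHARED,
}


def build_variant(variant_name: str) -> ModelVariant:
    """Return the named model variant ('full', 'minus_n', 'minus_p',
    'minus_n_p')."""
    if variant_name not in _VARIANT_DELTAS:
        raise ValueError(
            f"unknown variant {variant_name!r}; choose from {sorted(_VARIANT_DELTAS)}"
        )
    return ModelVariant(variant_name, tuple(_VARIANT_DELTAS[variant_name]))


def nucleotide_tied_from(params: RateParameterSet) -> RateParameterSet:
    """A minus_n-style companion of `params`: each phosphoform's KaiA
    on/off modifiers are replaced by the log-mean of its ATP- and
    ADP-bound values (derived modifiers included), with detailed balance
    re-closed.  Used to ask how much of a response shape is due to the
    nucleotide dependence of KaiA binding."""
    variant = build_variant("minus_n")
    derived = params.derived_delta

    def on(x, nuc):
        name = f"dka_{x}_{nuc}"
        if name in params.delta_log10:
            return params.delta_log10[name]
        if name in derived:
            return derived[name]
        return 0.0

    def off(x, nuc):
        name = f"dkb_{x}_{nuc}"
        return params.delta_log10.get(name, 0.0)

    reduced = {n: params.delta_log10[n] for n in _SHARED}
    for x in "TSD":
        reduced[f"dka_{x}"] = 0.5 * (on(x, "TP") + on(x, "DP"))
        reduced[f"dkb_{x}"] = 0.5 * (off(x, "TP") + off(x, "DP"))
    # the U phosphoform folds its mean into the base rates
    dka_u = 0.5 * (on("U", "TP") + on("U", "DP"))
    dkb_u = 0.5 * (off("U", "TP") + off("U", "DP"))
    base = dict(params.base_rates)
    base["ka"] = base["ka"] * 10.0 ** dka_u
    base["kb"] = base["kb"] * 10.0 ** dkb_u
    for x in "TSD":
        reduced[f"dka_{x}"] -= dka_u
        reduced[f"dkb_{x}"] -= dkb_u
    return RateParameterSet(
        base_rates=base,
        delta_log10=variant.resolve_deltas(reduced),
        sigma2=params.sigma2,
        init_fractions=dict(params.init_fractions),
    )
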
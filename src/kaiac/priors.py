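"""Prior distributions for the 48 free parameters.

All rate-like parameters are estimated in base-10 log space, which keeps
them positive.  Base rates carry wide log10-normal priors (sd = 3 decades);
the state-dependent modifiers carry log10-Laplace priors with scale b = 1,
i.e. an l1 penalty that shrinks each modifier toward 1 (no state effect)
unless the data demand otherwise.  Experimental constraints on KaiA
binding kinetics enter through the prior means: the on/off base rates are
centred on measured values, and the off-rate modifiers for the T, S, D
phosphoforms are centred so that the implied dwell times match
single-molecule measurements.  The global error variance sigma2 carries an
inverse-gamma prior and the initial-condition fractions a Dirichlet prior
concentrated on the dephosphorylated ADP-bound state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .params import (
    BASE_RATE_NAMES,
    FREE_DELTA_NAMES,
    FREE_INIT_NAMES,
    RateParameterSet,
)

LN10 = math.log(10.0)

# Measured KaiA binding kinetics used as prior centres.
KA_EXP = 0.0279  # s^-1 uM^-1
KB_EXP = 0.0663  # s^-1
TAU_EXP = {"T": 1.0, "S": 0.43, "D": 0.26}  # KaiA dwell times, s


def _default_laplace_mu() -> dict[str, float]:
    mu = {n: 0.0 for n in FREE_DELTA_NAMES}
    # dwell-time constraints apply to both the ADP- and ATP-bound off-rate
    # modifiers of each phosphoform: kb * dkb ~ 1 / tau
    for p, tau in TAU_EXP.items():
        centre = -math.log10(tau * KB_EXP)
        mu[f"dkb_{p}_DP"] = centre
        mu[f"dkb_{p}_TP"] = centre
    return mu


@dataclass
class PriorSpec:
    """Hyperparameters of every univariate/Dirichlet prior block."""

    normal_mu: dict[str, float] = field(
        default_factory=lambda: {
            "kp": 0.0,
            "kd": 0.0,
            "ka": math.log10(KA_EXP),
            "kb": math.log10(KB_EXP),
            "krDP": 0.0,
            "kh": 0.0,
        }
    )
    normal_sd: float = 3.0
    laplace_mu: dict[str, float] = field(default_factory=_default_laplace_mu)
    laplace_b: float = 1.0
    invgamma_shape: float = 1.0
    invgamma_scale: float = 0.01  # uM^2
    dirichlet_a: tuple = (20.0, 100.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def log_prior(self, params: RateParameterSet) -> float:
        """Sum of log prior densities, evaluated on the sampling coordinates
        (log10 for rates/modifiers/sigma2, natural for fractions)."""
        lp = 0.0
        for n in BASE_RATE_NAMES:
            x = math.log10(params.base_rates[n])
            lp += stats.norm.logpdf(x, loc=self.normal_mu[n], scale=self.normal_sd)
        for n in FREE_DELTA_NAMES:
            x = params.delta_log10[n]
            lp += -abs(x - self.laplace_mu[n]) / self.laplace_b - math.log(
                2.0 * self.laplace_b
            )
        s2 = params.sigma2
        if not (s2 > 0 and math.isfinite(s2)):
            return -math.inf
        # coordinate is log10(sigma2); include the change-of-variables term
        lp += stats.invgamma.logpdf(
            s2, self.invgamma_shape, scale=self.invgamma_scale
        ) + math.log(s2 * LN10)
        fracs = params.all_init_fractions()
        if np.any(fracs <= 0.0) or fracs.sum() > 1.0 + 1e-12:
            return -math.inf
        lp += stats.dirichlet.logpdf(
            fracs / fracs.sum(), np.asarray(self.dirichlet_a)
        )
        return float(lp)

    def sample(self, rng: np.random.Generator) -> RateParameterSet:
        """Draw one parameter set from the prior."""
        base = {
            n: 10.0 ** rng.normal(self.normal_mu[n], self.normal_sd)
            for n in BASE_RATE_NAMES
        }
        delta = {
            n: rng.laplace(self.laplace_mu[n], self.laplace_b)
            for n in FREE_DELTA_NAMES
        }
        s2 = float(stats.invgamma.rvs(
            self.invgamma_shape, scale=self.invgamma_scale, random_state=rng
        ))
        fracs = rng.dirichlet(np.asarray(self.dirichlet_a))
        return RateParameterSet(
            base_rates=base,
            delta_log10=delta,
            sigma2=s2,
            init_fractions={n: fracs[i] for i, n in enumerate(FREE_INIT_NAMES)},
        )


def log_prior(params: RateParameterSet, spec: PriorSpec | None = None) -> float:
    """Module-level convenience wrapper around PriorSpec.log_prior."""
    return (spec or PriorSpec()).log_prior(params)
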
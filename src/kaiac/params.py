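"""Model parameterization: base rates, multiplicative state modifiers, and
the detailed-balance constraints.

Every reaction rate is written as a base rate times a multiplicative
modifier ("delta-k" factor) specific to the molecular states involved,
e.g. the KaiA off rate from the ATP-bound T phosphoform is kb * dkb_T_TP.
Reactions without a listed modifier use the bare base rate (modifier = 1);
the U phosphoform / ATP-bound / KaiA-free combination is the baseline
throughout, and the bare phosphotransfer pair (kp, kd) is anchored to the
U <-> T reaction without KaiA.

The scheme has 38 modifiers, of which 34 are free: thermodynamic detailed
balance around the four reversible cycles that mix phosphotransfer and
KaiA (un)binding eliminates the four KaiA-on modifiers dka_S_TP, dka_T_TP,
dka_T_DP and dka_S_DP.

Free parameter count: 6 base rates + 34 modifiers + the global error
variance sigma2 + 7 free initial-condition fractions = 48 scalars.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

BASE_RATE_NAMES = ("kp", "kd", "ka", "kb", "krDP", "kh")

# The 34 free log10 modifiers, grouped as in the parameter table.
DELTA_NAMES_EXCHANGE = ("dkTPA_T", "dkTPA_S", "dkTPA_D")
DELTA_NAMES_HYDROLYSIS = ("dkh_T", "dkh_S", "dkh_D")
DELTA_NAMES_HYDROLYSIS_A = ("dkhA_U", "dkhA_T", "dkhA_S", "dkhA_D")
DELTA_NAMES_KA_ON = ("dka_U_DP", "dka_D_DP", "dka_D_TP")
DELTA_NAMES_KA_OFF = (
    "dkb_U_DP",
    "dkb_T_DP",
    "dkb_S_DP",
    "dkb_D_DP",
    "dkb_T_TP",
    "dkb_S_TP",
    "dkb_D_TP",
)
DELTA_NAMES_PHOS = ("dkp_US", "dkd_SU", "dkp_TD", "dkd_DT", "dkp_SD", "dkd_DS")
DELTA_NAMES_PHOS_A = (
    "dkpA_UT",
    "dkdA_TU",
    "dkpA_TD",
    "dkdA_DT",
    "dkpA_SD",
    "dkdA_DS",
    "dkpA_US",
    "dkdA_SU",
)

FREE_DELTA_NAMES = (
    DELTA_NAMES_EXCHANGE
    + DELTA_NAMES_HYDROLYSIS
    + DELTA_NAMES_HYDROLYSIS_A
    + DELTA_NAMES_KA_ON
    + DELTA_NAMES_KA_OFF
    + DELTA_NAMES_PHOS
    + DELTA_NAMES_PHOS_A
)

# KaiA-on modifiers fixed by detailed balance, never free.
DERIVED_DELTA_NAMES = ("dka_S_TP", "dka_T_TP", "dka_T_DP", "dka_S_DP")

ALL_DELTA_NAMES = FREE_DELTA_NAMES + DERIVED_DELTA_NAMES

INIT_STATE_NAMES = (
    "init_CTPU",
    "init_CDPU",
    "init_CTPT",
    "init_CDPT",
    "init_CTPS",
    "init_CDPS",
    "init_CTPD",
    "init_CDPD",
)
# The last fraction (CDPD) is fixed by conservation; the first 7 are free.
FREE_INIT_NAMES = INIT_STATE_NAMES[:-1]

N_FREE_PARAMS = len(BASE_RATE_NAMES) + len(FREE_DELTA_NAMES) + 1 + len(FREE_INIT_NAMES)

assert len(FREE_DELTA_NAMES) == 34
assert len(ALL_DELTA_NAMES) == 38
assert N_FREE_PARAMS == 48


def apply_detailed_balance(delta_log10: dict[str, float]) -> dict[str, float]:
    """Solve the four cycle constraints for the dependent KaiA-on modifiers.

    Each reversible cycle of the form C_TP^X -> C_DP^Y -> A-C_DP^Y ->
    A-C_TP^X -> C_TP^X mixes a phosphotransfer step with KaiA binding and
    unbinding; at equilibrium the product of the forward rate constants
    around the cycle must equal that of the reverse ones.  Each cycle
    constraint is solved for the single dependent KaiA-on modifier.

    Parameters
    ----------
    delta_log10 : mapping of the 34 free modifier names to log10 values.

    Returns
    -------
    dict mapping the 4 derived modifier names to log10 values.
    """
    missing = [n for n in FREE_DELTA_NAMES if n not in delta_log10]
    if missing:
        raise ValueError(f"missing free modifiers: {missing}")
    d = {n: float(delta_log10[n]) for n in FREE_DELTA_NAMES}
    for name, v in d.items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite modifier {name}={v}")

    # log10-space sums; the baseline (U,TP) on/off modifiers and the bare
    # U<->T phosphotransfer pair contribute log10(1) = 0 where they appear.
    derived = {
        # cycle C_TP^S, C_DP^D, A-C_DP^D, A-C_TP^S
        "dka_S_TP": (
            d["dkp_SD"] + d["dka_D_DP"] + d["dkdA_DS"] + d["dkb_S_TP"]
            - d["dkd_DS"] - d["dkb_D_DP"] - d["dkpA_SD"]
        ),
        # cycle C_TP^T, C_DP^D, A-C_DP^D, A-C_TP^T
        "dka_T_TP": (
            d["dkp_TD"] + d["dka_D_DP"] + d["dkdA_DT"] + d["dkb_T_TP"]
            - d["dkd_DT"] - d["dkb_D_DP"] - d["dkpA_TD"]
        ),
        # cycle C_TP^U, C_DP^T, A-C_DP^T, A-C_TP^U (U<->T pair is the bare anchor)
        "dka_T_DP": d["dkb_T_DP"] + d["dkpA_UT"] - d["dkdA_TU"],
        # cycle C_TP^U, C_DP^S, A-C_DP^S, A-C_TP^U
        "dka_S_DP": (
            d["dkd_SU"] + d["dkb_S_DP"] + d["dkpA_US"]
            - d["dkp_US"] - d["dkdA_SU"]
        ),
    }
    return derived


@dataclass
class RateParameterSet:
    """The full free parameterization of the kinetic model.

    Attributes
    ----------
    base_rates : natural-scale positive rates.  kp, kd, kb, krDP, kh in
        s^-1; ka in s^-1 uM^-1 (second-order, acting on the KaiA dimer
        concentration).  The reverse-exchange rate krTP is identically 0
        and the nucleotide on-rate ratio Kon is identically 1; neither is
        a parameter.
    delta_log10 : the 34 free log10 modifiers.
    sigma2 : global error variance hyperparameter (uM^2).
    init_fractions : fractions of total KaiC in the first 7 KaiA-free
        states at t=0 (the 8th, CDPD, follows by conservation).  All
        KaiA-bound states start empty in the phosphorylation protocol.
    """

    base_rates: dict[str, float]
    delta_log10: dict[str, float]
    sigma2: float = 1.0e-3
    init_fractions: dict[str, float] = field(
        default_factory=lambda: {n: (1.0 / 8 if i < 7 else 0.0) for i, n in enumerate(FREE_INIT_NAMES)}
    )

    def __post_init__(self) -> None:
        for n in BASE_RATE_NAMES:
            if n not in self.base_rates:
                raise ValueError(f"missing base rate {n}")
            if not (self.base_rates[n] > 0 and math.isfinite(self.base_rates[n])):
                raise ValueError(f"base rate {n} must be positive and finite")
        self._derived = apply_detailed_balance(self.delta_log10)

    @property
    def derived_delta(self) -> dict[str, float]:
        """log10 values of the 4 detailed-balance-derived KaiA-on modifiers."""
        return dict(self._derived)

    def delta(self, name: str) -> float:
        """Natural-scale modifier by name (free, derived, or baseline = 1)."""
        if name in self.delta_log10:
            return 10.0 ** self.delta_log10[name]
        if name in self._derived:
            return 10.0 ** self._derived[name]
        return 1.0

    def all_init_fractions(self) -> np.ndarray:
        """All 8 initial fractions (CDPD reconstructed by conservation)."""
        free = np.array([self.init_fractions[n] for n in FREE_INIT_NAMES])
        return np.append(free, 1.0 - free.sum())

    # --- flat serialization ------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        """Flat key->value dict: natural values for base rates, sigma2 and
        fractions; log10 values for modifiers."""
        out: dict[str, float] = {n: self.base_rates[n] for n in BASE_RATE_NAMES}
        out.update({n: self.delta_log10[n] for n in FREE_DELTA_NAMES})
        out["sigma2"] = self.sigma2
        out.update({n: self.init_fractions[n] for n in FREE_INIT_NAMES})
        return out

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "RateParameterSet":
        return cls(
            base_rates={n: float(d[n]) for n in BASE_RATE_NAMES},
            delta_log10={n: float(d[n]) for n in FREE_DELTA_NAMES},
            sigma2=float(d.get("sigma2", 1.0e-3)),
            init_fractions={n: float(d.get(n, 0.0)) for n in FREE_INIT_NAMES},
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RateParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # --- walker-coordinate mapping -----------------------------------------

    def to_vector(self) -> np.ndarray:
        """48-vector of sampling coordinates: log10 base rates, log10
        modifiers, log10 sigma2, then the 7 init fractions (natural)."""
        v = [math.log10(self.base_rates[n]) for n in BASE_RATE_NAMES]
        v += [self.delta_log10[n] for n in FREE_DELTA_NAMES]
        v.append(math.log10(self.sigma2))
        v += [self.init_fractions[n] for n in FREE_INIT_NAMES]
        return np.array(v)

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "RateParameterSet":
        v = np.asarray(v, dtype=float)
        if v.shape != (N_FREE_PARAMS,):
            raise ValueError(f"expected shape ({N_FREE_PARAMS},), got {v.shape}")
        nb = len(BASE_RATE_NAMES)
        nd = len(FREE_DELTA_NAMES)
        return cls(
            base_rates={n: 10.0 ** v[i] for i, n in enumerate(BASE_RATE_NAMES)},
            delta_log10={n: v[nb + i] for i, n in enumerate(FREE_DELTA_NAMES)},
            sigma2=10.0 ** v[nb + nd],
            init_fractions={n: v[nb + nd + 1 + i] for i, n in enumerate(FREE_INIT_NAMES)},
        )


COORD_NAMES = (
    tuple(f"log10_{n}" for n in BASE_RATE_NAMES)
    + FREE_DELTA_NAMES
    + ("log10_sigma2",)
    + FREE_INIT_NAMES
)
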
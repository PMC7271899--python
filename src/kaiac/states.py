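"""State space of the KaiA-KaiC subsystem.

Each KaiC subunit (CII domain) is tracked by three properties: its
phosphoform (U, T, S, or D), the nucleotide bound in the catalytic pocket
(ATP, written TP, or ADP, written DP), and whether a KaiA dimer is bound.
This gives 4 x 2 x 2 = 16 distinct states.

The enumeration order is fixed and load-bearing throughout the package:
index = 8*kaiA_bound + 2*phosphoform + nucleotide, with phosphoforms
ordered (U, T, S, D) and nucleotides (TP, DP).  Indices 0-7 are therefore
the eight KaiA-free states (CTPU, CDPU, CTPT, CDPT, CTPS, CDPS, CTPD,
CDPD) and 8-15 the corresponding KaiA-bound states; the KaiA-bound partner
of free state i is always i + 8.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Phosphoform(str, Enum):
    U = "U"
    T = "T"
    S = "S"
    D = "D"


class Nucleotide(str, Enum):
    TP = "TP"  # ATP bound
    DP = "DP"  # ADP bound


PHOSPHOFORMS = (Phosphoform.U, Phosphoform.T, Phosphoform.S, Phosphoform.D)
NUCLEOTIDES = (Nucleotide.TP, Nucleotide.DP)

N_STATES = 16
N_FREE_STATES = 8


@dataclass(frozen=True)
class KaiCState:
    """A single KaiC subunit state: phosphoform x nucleotide x KaiA-bound."""

    phosphoform: Phosphoform
    nucleotide: Nucleotide
    kaiA_bound: bool

    @property
    def index(self) -> int:
        return (
            8 * int(self.kaiA_bound)
            + 2 * PHOSPHOFORMS.index(self.phosphoform)
            + NUCLEOTIDES.index(self.nucleotide)
        )

    @property
    def label(self) -> str:
        """Human-readable label, e.g. 'C^T_TP' or 'A-C^D_DP'."""
        prefix = "A-" if self.kaiA_bound else ""
        return f"{prefix}C^{self.phosphoform.value}_{self.nucleotide.value}"


def enumerate_states() -> list[KaiCState]:
    """Return the 16 KaiC states in the fixed enumeration order."""
    states = []
    for bound in (False, True):
        for p in PHOSPHOFORMS:
            for n in NUCLEOTIDES:
                states.append(KaiCState(p, n, bound))
    return states


STATES = enumerate_states()
STATE_LABELS = tuple(s.label for s in STATES)


def state_index(phosphoform: str, nucleotide: str, kaiA_bound: bool) -> int:
    """Index of a state given its identifying triple."""
    return KaiCState(
        Phosphoform(phosphoform), Nucleotide(nucleotide), bool(kaiA_bound)
    ).index


# Phosphotransfer pairs: an ATP-bound X interconverts with an ADP-bound Y,
# transferring the gamma-phosphate (phosphorylation forward, regeneration of
# ATP on dephosphorylation).  Only these four (X, Y) pairs exist.
PHOSPHOTRANSFER_PAIRS = (
    (Phosphoform.U, Phosphoform.T),
    (Phosphoform.U, Phosphoform.S),
    (Phosphoform.T, Phosphoform.D),
    (Phosphoform.S, Phosphoform.D),
)
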
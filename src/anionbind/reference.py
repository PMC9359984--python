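"""Published association constants and standard depth registries.

These numbers are *inputs* to simulations and cross-media comparisons: the
association constants of the trimeric carbazole-urea macrocycle (receptor "1")
and of the reference acyclic bis-urea (receptor "2") in DMSO-d6/0.5% H2O, in
C12E8 micelles and in POPC vesicles, together with lipid-only binding constants
and H+/anion symport rates.  Entries reported only as bounds (">1e5", "<1")
carry the bound and a flag instead of a point value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional


@dataclass(frozen=True)
class Measured:
    """A reported value with its replicate SD, or a one-sided bound."""

    value: Optional[float] = None
    sd: Optional[float] = None
    bound: Optional[str] = None  # ">" lower bound, "<" upper bound

    def __post_init__(self):
        if self.value is None:
            raise ValueError("Measured requires a value")
        if self.bound not in (None, ">", "<"):
            raise ValueError("bound must be '>', '<' or None")

    @property
    def is_bound(self) -> bool:
        return self.bound is not None


@dataclass(frozen=True)
class AnionRecord:
    """One anion's row: hydration free energy, Ka per medium, transport rate."""

    anion: str
    charge: int
    dg_hydr_kj_mol: float
    ka_dmso: Optional[Measured]  # receptor 1, DMSO-d6/0.5% H2O
    ka_dmso_ref: Optional[Measured]  # reference bis-urea 2, same medium
    ka_c12e8: Optional[Measured]  # receptor 1, C12E8 micelles, M^-1
    ka_popc: Optional[Measured]  # receptor 1, POPC vesicles, M^-1
    ka_pc_lipid: Optional[Measured]  # lipid-only binding, M^-1
    transport_rate: Optional[Measured]  # anions s^-1 carrier^-1 at 20 mM


TABLE_BINDING = {
    "SO4": AnionRecord("SO4", -2, -975.0,
                       Measured(7.4e9, 1.1e9), Measured(1e5, bound=">"),
                       Measured(5.4e4, 3e3), Measured(370.0, 10.0),
                       None, Measured(0.042, 0.006)),
    "H2PO4": AnionRecord("H2PO4", -1, -473.0,
                         Measured(1e5, bound=">"), Measured(4.6e4),
                         Measured(140.0, 20.0), Measured(1.0, bound="<"),
                         None, Measured(0.031, 0.010)),
    "Cl": AnionRecord("Cl", -1, -344.0,
                      Measured(2000.0, 100.0), Measured(670.0),
                      Measured(19.0, 1.0), Measured(1.0, bound="<"),
                      Measured(0.2), Measured(0.082, 0.016)),
    "Br": AnionRecord("Br", -1, -318.0,
                      Measured(200.0, 10.0), Measured(70.0),
                      Measured(29.0, 1.0), Measured(2.6, 0.6),
                      Measured(2.0), Measured(0.097, 0.018)),
    "NO3": AnionRecord("NO3", -1, -286.0,
                       Measured(340.0, 10.0), Measured(10.2),
                       Measured(210.0, 10.0), Measured(24.0, 4.0),
                       Measured(2.8), Measured(2.1, 0.1)),
    "I": AnionRecord("I", -1, -280.0,
                     Measured(6.1, 0.6), Measured(3.0),
                     Measured(200.0, 10.0), Measured(24.0, 2.0),
                     Measured(32.0), Measured(2.0, 0.4)),
    "ClO4": AnionRecord("ClO4", -1, -229.0,
                        Measured(1.0, bound="<"), None,
                        Measured(32.0, 1.0), Measured(45.0, 9.0),
                        Measured(115.0), Measured(0.83, 0.10)),
}

# Most probable fluorophore depths from the bilayer centre (distribution
# analysis of spin-label quenching), Angstrom.
DEPTH_ANION_FREE = 19.0  # headgroup region
DEPTH_SULFATE_BOUND = 19.0  # unchanged on sulfate binding
DEPTH_PERCHLORATE_BOUND = 16.0  # carbonyl/glycerol region

# Standard nitroxide quencher depths from the bilayer centre (Angstrom),
# parallax-literature values for PC bilayers; overridable per dataset.
QUENCHER_DEPTHS = {
    "tempo-pc": 19.5,
    "5-doxyl-pc": 12.15,
    "12-doxyl-pc": 5.85,
}


def fold_enhancement(anion: str) -> float:
    """Affinity of the macrocycle over the reference bis-urea in DMSO.

    For nitrate this is the printed ~33-fold enhancement attributed to the
    macrocycle's size/shape complementarity for the planar NO3- ion.
    """
    rec = TABLE_BINDING[anion]
    if rec.ka_dmso is None or rec.ka_dmso_ref is None:
        raise ValueError(f"no paired DMSO constants for {anion}")
    if rec.ka_dmso.is_bound or rec.ka_dmso_ref.is_bound:
        raise ValueError(f"DMSO constant for {anion} reported only as a bound")
    return rec.ka_dmso.value / rec.ka_dmso_ref.value


def log_selectivity(anion_a: str, anion_b: str, medium: str) -> float:
    """log10 selectivity Ka(a)/Ka(b) of the macrocycle in a given medium."""
    field = {"dmso": "ka_dmso", "c12e8": "ka_c12e8", "popc": "ka_popc"}[medium]
    ka_a = getattr(TABLE_BINDING[anion_a], field)
    ka_b = getattr(TABLE_BINDING[anion_b], field)
    if ka_a is None or ka_b is None or ka_a.is_bound or ka_b.is_bound:
        raise ValueError("selectivity undefined for bounded/missing entries")
    return math.log10(ka_a.value / ka_b.value)
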
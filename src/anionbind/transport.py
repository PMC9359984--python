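"""HPTS salt-pulse transport assay: from fluorescence ratios to per-carrier rates.

In the assay, vesicles loaded with an inert gluconate buffer contain the
ratiometric pH probe HPTS; an external salt pulse drives H+/anion symport by
the membrane-embedded carrier, acidifying the vesicle interior.  The chain
implemented here is

    R(t)  ->  pH(t)  ->  intravesicular H+ influx  D[H]in(t)
          ->  initial rate (M s^-1)  ->  anions s^-1 carrier^-1

with the buffer capacity of HEPES handled through its protonation fraction
and the per-carrier normalisation done by per-vesicle counting from the
vesicle geometry (a bulk-concentration shortcut is available as an
alternative mode; results name the mode used).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .constants import (AREA_PER_LIPID, AVOGADRO, BILAYER_THICKNESS, HEPES_PKA,
                        HPTS_PKA, KW, VESICLE_DIAMETER)
from .exceptions import ConfigurationError, DomainError


@dataclass(frozen=True)
class HptsCalibration:
    """Ratiometric calibration of HPTS: limiting ratios and apparent pKa."""

    r_min: float
    r_max: float
    pka: float = HPTS_PKA

    def __post_init__(self):
        if not self.r_min < self.r_max:
            raise DomainError("calibration requires r_min < r_max")


@dataclass(frozen=True)
class VesicleSystem:
    """Buffer and vesicle geometry defining the intravesicular compartment."""

    buffer_conc: float = 0.010  # M HEPES
    buffer_pka: float = HEPES_PKA
    initial_ph: float = 7.0
    diameter: float = VESICLE_DIAMETER  # m
    area_per_lipid: float = AREA_PER_LIPID  # m^2
    bilayer_thickness: float = BILAYER_THICKNESS  # m

    def __post_init__(self):
        for name in ("buffer_conc", "buffer_pka", "initial_ph", "diameter",
                     "area_per_lipid", "bilayer_thickness"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        if abs(self.initial_ph - self.buffer_pka) > 1.5:
            raise DomainError("initial pH outside the buffer range (pKa +/- 1.5)")

    @property
    def outer_radius(self) -> float:
        return self.diameter / 2.0

    @property
    def inner_radius(self) -> float:
        r_in = self.outer_radius - self.bilayer_thickness
        if r_in <= 0:
            raise DomainError("bilayer thicker than the vesicle radius")
        return r_in

    @property
    def lipids_per_vesicle(self) -> float:
        r_out, r_in = self.outer_radius, self.inner_radius
        return 4.0 * math.pi * (r_out ** 2 + r_in ** 2) / self.area_per_lipid

    @property
    def inner_volume_litres(self) -> float:
        return (4.0 / 3.0) * math.pi * self.inner_radius ** 3 * 1e3


@dataclass(frozen=True)
class TransportTrace:
    """Time-stamped HPTS ratio trace with its assay composition."""

    time: Tuple[float, ...]  # s, strictly increasing
    ratio: Tuple[float, ...]  # I(ex 460)/I(ex 403)
    anion: str = ""
    anion_conc: float = 0.020  # M
    lipid_conc: float = 1e-4  # M
    carrier_mole_fraction: float = 0.01

    def __post_init__(self):
        t = np.asarray(self.time, float)
        if t.size != len(self.ratio):
            raise ConfigurationError("time and ratio differ in length")
        if np.any(np.diff(t) <= 0):
            raise DomainError("time must be strictly increasing")


def ratio_to_ph(ratio, calib: HptsCalibration):
    """pH from the HPTS excitation ratio; strictly increasing in R."""
    r = np.asarray(ratio, float)
    if np.any(r <= calib.r_min) or np.any(r >= calib.r_max):
        raise DomainError("ratio outside (r_min, r_max); clip or recalibrate "
                          "before conversion")
    out = calib.pka + np.log10((r - calib.r_min) / (calib.r_max - r))
    return float(out) if np.isscalar(ratio) else out


def ph_to_ratio(ph, calib: HptsCalibration):
    """Inverse of :func:`ratio_to_ph`."""
    p = np.asarray(ph, float)
    q = 10.0 ** (p - calib.pka)
    out = (calib.r_min + calib.r_max * q) / (1.0 + q)
    return float(out) if np.isscalar(ph) else out


def buffer_protonated_fraction(ph, pka: float):
    """Fraction of the buffer in its protonated form, alpha(pH)."""
    return 1.0 / (1.0 + 10.0 ** (np.asarray(ph, float) - pka))


def proton_influx(ph_trace, system: VesicleSystem):
    """Intravesicular H+ influx D[H]in(t) from a pH time course (M).

    D[H]in = C_buf [alpha(pH_t) - alpha(pH_0)] + ([H+]_t - [H+]_0)
             - ([OH-]_t - [OH-]_0);
    acidification gives positive influx.
    """
    ph = np.asarray(ph_trace, float)
    if np.any(np.abs(ph - system.buffer_pka) > 2.0):
        raise DomainError("pH trace leaves the buffer validity range")
    ph0 = ph[0]
    alpha = buffer_protonated_fraction(ph, system.buffer_pka)
    alpha0 = buffer_protonated_fraction(ph0, system.buffer_pka)
    h, h0 = 10.0 ** (-ph), 10.0 ** (-ph0)
    oh, oh0 = KW / h, KW / h0
    return system.buffer_conc * (alpha - alpha0) + (h - h0) - (oh - oh0)


def initial_rate(time, influx, window: float = 30.0,
                 t_start: float = 0.0) -> Tuple[float, float]:
    """Initial influx rate: OLS slope over [t_start, t_start + window].

    Returns (slope, standard error) in M s^-1.
    """
    t = np.asarray(time, float)
    y = np.asarray(influx, float)
    if window <= 0:
        raise ConfigurationError("window must be positive")
    if t_start < t[0]:
        raise ConfigurationError("window begins before the recorded trace "
                                 "(salt pulse not yet applied)")
    mask = (t >= t_start) & (t <= t_start + window)
    if mask.sum() < 5:
        raise ConfigurationError("need >= 5 samples inside the rate window")
    res = stats.linregress(t[mask], y[mask])
    return float(res.slope), float(res.stderr)


def per_carrier_rate(rate: float, system: VesicleSystem,
                     carrier_mole_fraction: float, lipid_conc: float,
                     mode: str = "per_vesicle") -> float:
    """Convert an intravesicular influx rate (M s^-1) to anions s^-1 carrier^-1.

    Per-vesicle mode counts lipids on both leaflets from the vesicle geometry,
    carriers from the carrier mole fraction, and protons from the rate times
    the internal volume; one H+ corresponds to one transported anion under
    the 1:1 symport stoichiometry.  Bulk mode divides the rate scaled by the
    total trapped-volume fraction by the bulk carrier concentration.
    """
    if not carrier_mole_fraction > 0:
        raise DomainError("carrier_mole_fraction must be > 0")
    if not lipid_conc > 0:
        raise DomainError("lipid_conc must be > 0")
    if mode == "per_vesicle":
        lipids = system.lipids_per_vesicle
        carriers = carrier_mole_fraction * lipids
        protons_per_vesicle_s = rate * system.inner_volume_litres * AVOGADRO
        return protons_per_vesicle_s / carriers
    if mode == "bulk":
        vesicles_per_litre = lipid_conc * AVOGADRO / system.lipids_per_vesicle
        vol_fraction = vesicles_per_litre * system.inner_volume_litres
        carrier_conc = carrier_mole_fraction * lipid_conc
        return rate * vol_fraction / carrier_conc
    raise ConfigurationError("mode must be 'per_vesicle' or 'bulk'")


@dataclass
class TransportResults:
    """Initial rate and per-carrier transport rate with diagnostics."""

    initial_rate: float  # M s^-1, intravesicular basis
    se_initial_rate: float
    per_carrier: float  # anions s^-1 carrier^-1
    se_per_carrier: float
    window: float
    mode: str
    anion: str = ""
    assumptions: Dict[str, object] = field(default_factory=dict)

    def summary(self) -> str:
        return "\n".join([
            f"anion: {self.anion or '?'}",
            f"initial H+ influx rate: {self.initial_rate:.4g} "
            f"+/- {self.se_initial_rate:.2g} M/s (window {self.window:g} s)",
            f"per-carrier rate ({self.mode}): {self.per_carrier:.4g} "
            f"+/- {self.se_per_carrier:.2g} anions/s/carrier",
        ] + [f"assumes {k} = {v}" for k, v in self.assumptions.items()])


class TransportRateModel:
    """Full chain from an HPTS ratio trace to a per-carrier transport rate."""

    def __init__(self, trace: TransportTrace, system: VesicleSystem,
                 calibration: HptsCalibration, window: float = 30.0,
                 mode: str = "per_vesicle"):
        self.trace = trace
        self.system = system
        self.calibration = calibration
        self.window = window
        self.mode = mode

    def fit(self) -> TransportResults:
        ph = ratio_to_ph(np.asarray(self.trace.ratio), self.calibration)
        influx = proton_influx(ph, self.system)
        slope, se = initial_rate(self.trace.time, influx, self.window,
                                 t_start=float(self.trace.time[0]))
        scale = per_carrier_rate(1.0, self.system,
                                 self.trace.carrier_mole_fraction,
                                 self.trace.lipid_conc, self.mode)
        return TransportResults(
            initial_rate=slope, se_initial_rate=se,
            per_carrier=slope * scale, se_per_carrier=se * scale,
            window=self.window, mode=self.mode, anion=self.trace.anion,
            assumptions={
                "hpts_pka": self.calibration.pka,
                "buffer_pka": self.system.buffer_pka,
                "vesicle_diameter_m": self.system.diameter,
                "area_per_lipid_m2": self.system.area_per_lipid,
                "bilayer_thickness_m": self.system.bilayer_thickness,
            })
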
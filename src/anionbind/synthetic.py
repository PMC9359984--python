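"""Synthetic experiments with known ground truth for every pipeline stage.

Each generator evaluates the same forward model that the corresponding
analysis fits — exact speciation for titrations (with the Boltzmann surface
correction applied when a surface potential is set), the mirrored-Gaussian
quenching profile for depth analysis, and the ratio/pH/influx chain for
transport traces — then adds i.i.d. Gaussian noise scaled to the signal
range.  Output is deterministic given the seed, and every result carries a
truth echo sufficient to rerun the analysis end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .constants import T_DEFAULT
from .electrostatics import boltzmann_factor
from .exceptions import ConfigurationError, DomainError
from .speciation import (free_sulfate_with_precipitation, solve_1to1,
                         solve_1to2, solve_competition)
from .titration import TitrationSeries
from .transport import (HptsCalibration, TransportTrace, VesicleSystem,
                        ph_to_ratio, proton_influx)

TITRATION_KINDS = ("fluorescence", "nmr_shift", "nmr_integrals", "baso4", "competition")


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters for one synthetic experiment.

    Only the fields relevant to the chosen experiment kind need to be set;
    :func:`simulate_titration` checks consistency.  ``noise`` is the Gaussian
    SD as a fraction of the noiseless signal range; ``seed`` fixes the RNG.
    """

    ka: float = 0.0
    ka2: Optional[float] = None  # stepwise second constant (1:2 model)
    host_total: float = 5e-8
    guest_grid: Tuple[float, ...] = ()
    baseline: float = 1.0
    endpoint: float = 3.0
    endpoint2: Optional[float] = None
    # competition
    competitor: Optional[str] = None
    competitor_total: float = 0.0
    competitor_ka: float = 0.0
    competitor_charge: int = -1
    reporter_charge: int = -2
    surface_potential: float = 0.0  # V
    # BaSO4 precipitation
    sulfate_total: float = 0.0
    ksp: float = 0.0
    counterion_grid: Tuple[float, ...] = ()
    # depth analysis
    depth: float = 0.0
    dispersion: float = 3.0
    strength: float = 0.0
    # transport
    per_carrier_rate: float = 0.0
    temperature: float = T_DEFAULT
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise < 0:
            raise ConfigurationError("noise must be >= 0")

    def echo(self) -> Dict[str, object]:
        """Serializable record of the generating parameters."""
        from dataclasses import asdict
        return asdict(self)


def _rng(truth: SimulationTruth) -> np.random.Generator:
    return np.random.default_rng(truth.seed)


def _add_noise(values: np.ndarray, truth: SimulationTruth,
               rng: np.random.Generator) -> np.ndarray:
    if truth.noise == 0:
        return values
    span = float(values.max() - values.min()) or abs(truth.endpoint - truth.baseline) or 1.0
    return values + rng.normal(0.0, truth.noise * span, size=values.shape)


def simulate_titration(truth: SimulationTruth, kind: str):
    """Generate one titration experiment of the requested kind.

    Returns ``(data, truth)`` where ``data`` is a :class:`TitrationSeries`
    for the fluorescence/NMR-shift/competition kinds, a list of
    ``(guest_total, integral_free, integral_bound)`` triples for the
    slow-exchange kind, and a list of ``(counterion_total, bound_fraction)``
    points for the BaSO4 precipitation kind.
    """
    if kind not in TITRATION_KINDS:
        raise ConfigurationError(f"unknown titration kind {kind!r}")
    if kind != "baso4" and len(truth.guest_grid) == 0:
        raise ConfigurationError("guest_grid must be non-empty")
    if kind != "baso4" and truth.ka < 0:
        raise ConfigurationError("ka must be >= 0")
    rng = _rng(truth)
    if kind in ("fluorescence", "nmr_shift"):
        return _simulate_direct(truth, kind, rng), truth
    if kind == "competition":
        return _simulate_competition(truth, rng), truth
    if kind == "nmr_integrals":
        return _simulate_integrals(truth, rng), truth
    return _simulate_baso4(truth, rng), truth


def _simulate_direct(truth: SimulationTruth, kind: str, rng) -> TitrationSeries:
    obs_kind = "fluorescence_intensity" if kind == "fluorescence" else "nmr_shift_ppm"
    y = np.empty(len(truth.guest_grid))
    for i, g in enumerate(truth.guest_grid):
        if truth.ka2 is not None:
            st = solve_1to2(truth.host_total, g, truth.ka, truth.ka2)
            th1 = st.complexes["HG"] / truth.host_total
            th2 = st.complexes["HG2"] / truth.host_total
            e2 = truth.endpoint2 if truth.endpoint2 is not None else truth.endpoint
            y[i] = truth.baseline + (truth.endpoint - truth.baseline) * th1 \
                + (e2 - truth.baseline) * th2
        else:
            st = solve_1to1(truth.host_total, g, truth.ka)
            th = st.complexes["HG"] / truth.host_total
            y[i] = truth.baseline + (truth.endpoint - truth.baseline) * th
    y = _add_noise(y, truth, rng)
    return TitrationSeries(tuple(truth.guest_grid), tuple(y), obs_kind,
                           truth.host_total, temperature=truth.temperature)


def _simulate_competition(truth: SimulationTruth, rng) -> TitrationSeries:
    """Sulfate titration at fixed competitor; binding happens at the surface.

    With a non-zero surface potential the *surface* concentrations seen by
    the membrane-embedded host are the bulk values scaled by their Boltzmann
    factors; the recorded grid stays on the bulk scale, exactly as measured.
    """
    if truth.competitor is None:
        raise ConfigurationError("competition kind requires a competitor")
    b_s = boltzmann_factor(truth.surface_potential, truth.reporter_charge,
                           truth.temperature)
    b_x = boltzmann_factor(truth.surface_potential, truth.competitor_charge,
                           truth.temperature)
    x_surf = truth.competitor_total * b_x
    y = np.empty(len(truth.guest_grid))
    for i, g in enumerate(truth.guest_grid):
        st = solve_competition(truth.host_total, g * b_s, x_surf,
                               truth.ka, truth.competitor_ka)
        th = st.complexes["HS"] / truth.host_total
        y[i] = truth.baseline + (truth.endpoint - truth.baseline) * th
    y = _add_noise(y, truth, rng)
    return TitrationSeries(tuple(truth.guest_grid), tuple(y),
                           "fluorescence_intensity", truth.host_total,
                           fixed_competitor=(truth.competitor, truth.competitor_total),
                           competitor_charge=truth.competitor_charge,
                           temperature=truth.temperature)


def _simulate_integrals(truth: SimulationTruth, rng) -> List[Tuple[float, float, float]]:
    out = []
    for g in truth.guest_grid:
        st = solve_1to1(truth.host_total, g, truth.ka)
        bound = st.complexes["HG"]
        i_free, i_bound = st.free_host, bound
        if truth.noise:
            scale = truth.noise * truth.host_total
            i_free = max(i_free + rng.normal(0.0, scale), 1e-12 * truth.host_total)
            i_bound = max(i_bound + rng.normal(0.0, scale), 0.0)
        out.append((g, i_free, i_bound))
    return out


def _simulate_baso4(truth: SimulationTruth, rng) -> List[Tuple[float, float]]:
    if not truth.ksp > 0 or not truth.sulfate_total > 0:
        raise ConfigurationError("baso4 kind requires sulfate_total and ksp")
    if len(truth.counterion_grid) == 0:
        raise ConfigurationError("baso4 kind requires a counterion grid")
    thetas = np.empty(len(truth.counterion_grid))
    for i, ba in enumerate(truth.counterion_grid):
        bound = 0.0
        for _ in range(200):
            st = free_sulfate_with_precipitation(
                max(truth.sulfate_total - bound, 0.0), ba, truth.ksp)
            s_free = st.free_guests["SO4"]
            theta = truth.ka * s_free / (1.0 + truth.ka * s_free)
            new_bound = theta * truth.host_total
            if abs(new_bound - bound) <= 1e-15 + 1e-12 * abs(new_bound):
                break
            bound = new_bound
        thetas[i] = theta
    if truth.noise:
        thetas = np.clip(thetas + rng.normal(0.0, truth.noise, size=thetas.shape),
                         0.0, 1.0)
    return list(zip([float(c) for c in truth.counterion_grid],
                    [float(t) for t in thetas]))


def simulate_quenching(depth: float, dispersion: float, strength: float,
                       quencher_depths: Sequence[Tuple[str, float]],
                       density: float, noise: float = 0.0, seed: int = 0):
    """Generate relative-fluorescence values for a set of spin-labelled
    quenchers from the mirrored-Gaussian quenching profile.

    Returns ``(measurements, truth)`` with F/F0 clipped to (0, 1].
    """
    from .depth import QuenchingMeasurement, _gaussian_profile

    if not dispersion > 0:
        raise ConfigurationError("dispersion must be > 0")
    rng = np.random.default_rng(seed)
    d = np.array([dd for _, dd in quencher_depths], float)
    f = np.exp(-_gaussian_profile(d, abs(depth), dispersion, strength))
    if noise:
        f = f + rng.normal(0.0, noise * (float(f.max() - f.min()) or 1.0), size=f.shape)
    f = np.clip(f, 1e-12, 1.0)
    measurements = [QuenchingMeasurement(name, dd, float(ff), density)
                    for (name, dd), ff in zip(quencher_depths, f)]
    truth = SimulationTruth(depth=depth, dispersion=dispersion, strength=strength,
                            noise=noise, seed=seed)
    return measurements, truth


def _invert_influx(target: float, ph0: float, system: VesicleSystem) -> float:
    """pH at which the intravesicular influx equals ``target`` (acidification)."""
    def f(ph):
        return proton_influx(np.array([ph0, ph]), system)[1] - target
    if target <= 0:
        return ph0
    return brentq(f, system.buffer_pka - 1.9, ph0, xtol=1e-13)


def simulate_transport_trace(per_carrier: float, system: VesicleSystem,
                             calib: HptsCalibration, anion: str = "",
                             anion_conc: float = 0.020, lipid_conc: float = 1e-4,
                             carrier_mole_fraction: float = 0.01,
                             duration: float = 60.0, dt: float = 0.1,
                             plateau_delta_ph: float = 0.5,
                             noise: float = 0.0, seed: int = 0):
    """Generate an HPTS ratio trace from a known per-carrier transport rate.

    The influx follows a single-exponential approach A(1 - exp(-kt)) to the
    plateau A set by ``plateau_delta_ph``; the initial slope A*k equals the
    intravesicular molar rate implied by the per-carrier truth, so an
    initial-rate analysis with a window short against 1/k recovers it.
    Returns ``(trace, truth_dict)``.
    """
    from .constants import AVOGADRO

    if per_carrier < 0:
        raise DomainError("per_carrier rate must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    ph0 = system.initial_ph
    carriers = carrier_mole_fraction * system.lipids_per_vesicle
    rate = per_carrier * carriers / (system.inner_volume_litres * AVOGADRO)
    if rate == 0:
        influx = np.zeros_like(t)
    else:
        amp = proton_influx(np.array([ph0, ph0 - plateau_delta_ph]), system)[1]
        k = rate / amp
        influx = amp * (-np.expm1(-k * t))
    ph = np.array([_invert_influx(v, ph0, system) for v in influx])
    ratio = ph_to_ratio(ph, calib)
    if noise:
        span = float(ratio.max() - ratio.min()) or (calib.r_max - calib.r_min) * 0.1
        ratio = ratio + rng.normal(0.0, noise * span, size=ratio.shape)
    eps = 1e-9 * (calib.r_max - calib.r_min)
    ratio = np.clip(ratio, calib.r_min + eps, calib.r_max - eps)
    trace = TransportTrace(tuple(t), tuple(ratio), anion=anion,
                           anion_conc=anion_conc, lipid_conc=lipid_conc,
                           carrier_mole_fraction=carrier_mole_fraction)
    truth = {"per_carrier": per_carrier, "rate_M_per_s": rate,
             "plateau_delta_ph": plateau_delta_ph, "noise": noise, "seed": seed}
    return trace, truth
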
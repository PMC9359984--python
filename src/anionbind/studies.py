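"""Seeded parameter-recovery studies at desk scale.

Each study generates one experiment class with a known ground truth under the
conditions of the corresponding measurement (host concentration, titrant
grid, noise level), analyses every replicate with the production pipeline,
and reports the median estimate with its Monte-Carlo uncertainty.  These are
the end-to-end checks behind the acceptance suite and the reproduction
script; they are also a convenient template for power analyses of new
designs.

Per-replicate seeds are derived deterministically from the base seed via
``numpy.random.SeedSequence`` and kept below 2**31.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .constants import KSP_BASO4
from .depth import fit_depth_distribution
from .electrostatics import ElectrolyteComposition, InterfaceModel
from .reference import QUENCHER_DEPTHS
from .synthetic import SimulationTruth, simulate_quenching, simulate_titration
from .titration import fit_baso4_competition, fit_competition_ka, fit_titration

#: quenchers used in the standard three-depth quenching design
STANDARD_QUENCHERS: Tuple[Tuple[str, float], ...] = tuple(
    sorted(QUENCHER_DEPTHS.items(), key=lambda kv: -kv[1]))


@dataclass
class RecoveryStudy:
    """Median recovered value across seeded replicates, with uncertainties.

    ``se_median`` is the Gaussian large-sample standard error of the median,
    1.2533 * SD / sqrt(n); ``median_se_fit`` is the median of the per-fit
    standard errors, useful for combining with an external replicate SD.
    """

    truth: float
    estimates: np.ndarray
    fit_ses: np.ndarray

    @property
    def median(self) -> float:
        return float(np.median(self.estimates))

    @property
    def sd(self) -> float:
        return float(np.std(self.estimates, ddof=1))

    @property
    def se_median(self) -> float:
        return 1.2533 * self.sd / math.sqrt(len(self.estimates))

    @property
    def median_se_fit(self) -> float:
        return float(np.median(self.fit_ses))

    @property
    def n(self) -> int:
        return len(self.estimates)


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def recover_ka_direct(truth_ka: float, host_total: float, guest_max: float,
                      kind: str = "fluorescence", n_points: int = 15,
                      noise: float = 0.01, n_seeds: int = 50,
                      seed: int = 0, baseline: float = 1.0,
                      endpoint: float = 3.0) -> RecoveryStudy:
    """Recover a 1:1 constant from direct fluorescence or NMR-shift titrations.

    The titrant grid spans [0, guest_max] linearly with ``n_points`` points
    and Gaussian noise of ``noise`` x signal range is added per replicate.
    """
    grid = tuple(np.linspace(0.0, guest_max, n_points))
    est, ses = [], []
    for s in _seeds(seed, n_seeds):
        truth = SimulationTruth(ka=truth_ka, host_total=host_total,
                                guest_grid=grid, baseline=baseline,
                                endpoint=endpoint, noise=noise, seed=int(s))
        series, _ = simulate_titration(truth, kind)
        res = fit_titration(series, "1:1")
        est.append(res.ka)
        ses.append(res.se_ka)
    return RecoveryStudy(truth_ka, np.array(est), np.array(ses))


def recover_ka_competition(truth_ka_s: float, truth_ka_x: float,
                           surface_potential: float, competitor: str = "ClO4",
                           competitor_total: float = 0.2,
                           competitor_charge: int = -1,
                           host_total: float = 5e-8, guest_max: float = 0.5,
                           n_points: int = 15, noise: float = 0.01,
                           n_seeds: int = 50, seed: int = 0) -> RecoveryStudy:
    """Recover a competitor constant through the full Boltzmann-correction
    chain: generate sulfate titrations at a fixed competitor with binding at
    surface-referenced concentrations, then analyse with the same interface
    model (ionic strength 0.2 M, competitor as the Na+ salt)."""
    grid = tuple(np.linspace(0.0, guest_max, n_points))
    elec = ElectrolyteComposition.from_species(
        [("Na", 1, competitor_total), (competitor, competitor_charge,
                                       competitor_total)])
    iface = InterfaceModel(elec, surface_potential=surface_potential)
    est, ses = [], []
    for s in _seeds(seed, n_seeds):
        truth = SimulationTruth(ka=truth_ka_s, host_total=host_total,
                                guest_grid=grid, noise=noise, seed=int(s),
                                competitor=competitor,
                                competitor_total=competitor_total,
                                competitor_ka=truth_ka_x,
                                competitor_charge=competitor_charge,
                                surface_potential=surface_potential)
        series, _ = simulate_titration(truth, "competition")
        res = fit_competition_ka(series, ka_s=truth_ka_s, interface=iface)
        est.append(res.ka_x)
        ses.append(res.standard_errors["ka_x"])
    return RecoveryStudy(truth_ka_x, np.array(est), np.array(ses))


def recover_ka_baso4(truth_ka: float, host_total: float = 3e-4,
                     sulfate_total: float = 5e-4, ksp: float = KSP_BASO4,
                     noise: float = 0.0, n_seeds: int = 1,
                     seed: int = 0) -> RecoveryStudy:
    """Recover a very large sulfate constant via BaSO4-precipitation buffering.

    The counterion grid is log-spaced so that free sulfate, pinned at
    Ksp/[Ba2+], sweeps through 1/Ka; with the aqueous Ksp and Ka ~ 7e9 this
    requires counterion totals up to the molar range.
    """
    grid = tuple(np.logspace(-2, 1, 12))
    est, ses = [], []
    for s in _seeds(seed, n_seeds):
        truth = SimulationTruth(ka=truth_ka, host_total=host_total,
                                sulfate_total=sulfate_total, ksp=ksp,
                                counterion_grid=grid, noise=noise, seed=int(s))
        points, _ = simulate_titration(truth, "baso4")
        res = fit_baso4_competition(points, host_total, sulfate_total, ksp)
        est.append(res.ka)
        ses.append(res.se_ka)
    return RecoveryStudy(truth_ka, np.array(est), np.array(ses))


def recover_depth(truth_depth: float, dispersion: float = 3.0,
                  strength: float = 5.0, noise: float = 0.0,
                  seed: int = 0,
                  quenchers: Sequence[Tuple[str, float]] = STANDARD_QUENCHERS,
                  density: float = 0.075 / 68.0) -> float:
    """Recover the most probable fluorophore depth by distribution analysis
    of a quenching profile over the standard three spin-label depths."""
    ms, _ = simulate_quenching(truth_depth, dispersion, strength,
                               tuple(quenchers), density, noise=noise, seed=seed)
    return fit_depth_distribution(ms).depth
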
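"""Fluorophore penetration depth from quenching by spin-labelled lipids.

Nitroxide groups attached at known positions along lipid acyl chains (or on
the headgroup) quench a membrane-embedded fluorophore in proportion to their
lateral overlap with it.  Two estimators of the fluorophore's transverse
position are provided:

* the two-quencher *parallax* formula, which triangulates the depth from the
  ratio of fluorescence surviving two quenchers at different depths; and
* *distribution analysis*, which fits the quenching profile -ln(F/F0) across
  three or more quencher depths with a mirrored transverse Gaussian and
  reports the most probable depth, its dispersion and the quenching strength.

Depths are in Angstrom measured from the bilayer centre; the Gaussian is
symmetrised across the midplane (images at +z and -z) so that profiles are
invariant under z -> -z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import ConfigurationError, DomainError
from .reference import QUENCHER_DEPTHS

MAX_DEPTH = 30.0  # Angstrom; half-thickness bound for reported depths

#: default quencher surface density: mole fraction / area per lipid
AREA_PER_LIPID_A2 = 68.0  # Angstrom^2 per POPC


def surface_density(mole_fraction: float, area_per_lipid_a2: float = AREA_PER_LIPID_A2) -> float:
    """Quencher surface density C in molecules per Angstrom^2."""
    if not 0 < mole_fraction <= 1:
        raise DomainError("mole_fraction must be in (0, 1]")
    return mole_fraction / area_per_lipid_a2


@dataclass(frozen=True)
class QuenchingMeasurement:
    """Relative fluorescence surviving one spin-labelled quencher."""

    quencher: str
    depth: float  # Angstrom from bilayer centre
    f_over_f0: float
    density: float  # molecules Angstrom^-2

    def __post_init__(self):
        if not 0 < self.f_over_f0 <= 1:
            raise DomainError(f"F/F0 must be in (0, 1], got {self.f_over_f0!r}")
        if self.depth < 0:
            raise DomainError("quencher depth must be >= 0")
        if not self.density > 0:
            raise DomainError("quencher surface density must be > 0")

    @classmethod
    def from_registry(cls, quencher: str, f_over_f0: float, mole_fraction: float,
                      depth: Optional[float] = None) -> "QuenchingMeasurement":
        if depth is None:
            try:
                depth = QUENCHER_DEPTHS[quencher.lower()]
            except KeyError:
                raise ConfigurationError(
                    f"unknown quencher {quencher!r}; known: {sorted(QUENCHER_DEPTHS)}")
        return cls(quencher, depth, f_over_f0, surface_density(mole_fraction))


@dataclass
class DepthResult:
    """Most probable fluorophore depth and, for distribution analysis, the
    transverse dispersion and quenching strength."""

    depth: float  # Angstrom from bilayer centre
    method: str  # "parallax" | "distribution"
    dispersion: Optional[float] = None  # sigma_d, Angstrom
    strength: Optional[float] = None  # S (area of the quenching Gaussian)
    rss: float = 0.0
    flags: tuple = ()

    def summary(self) -> str:
        lines = [f"method: {self.method}",
                 f"most probable depth: {self.depth:.2f} A from bilayer centre"]
        if self.dispersion is not None:
            lines.append(f"dispersion sigma_d: {self.dispersion:.2f} A")
        if self.strength is not None:
            lines.append(f"quenching strength S: {self.strength:.4g}")
        lines.append(f"residual sum of squares: {self.rss:.3g}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def parallax_depth(m1: QuenchingMeasurement, m2: QuenchingMeasurement) -> DepthResult:
    """Two-quencher parallax estimate of the fluorophore depth.

    ``m1`` must be the shallower quencher (larger distance from the centre).
    z = L_c1 + [ -ln(F1/F2)/(pi C) - L21^2 ] / (2 L21), with L21 the depth
    difference; equal quenching puts the fluorophore exactly midway.
    """
    if m1.depth == m2.depth:
        raise DomainError("parallax needs two distinct quencher depths")
    if m1.depth < m2.depth:
        raise DomainError("m1 must be the shallower quencher (depth1 > depth2)")
    c = m1.density
    flags = []
    if not math.isclose(m1.density, m2.density, rel_tol=1e-9):
        import warnings
        warnings.warn("quencher surface densities differ; using their mean", stacklevel=2)
        c = 0.5 * (m1.density + m2.density)
        flags.append("unequal_density_mean_used")
    l21 = m1.depth - m2.depth
    z = m1.depth + (-math.log(m1.f_over_f0 / m2.f_over_f0) / (math.pi * c) - l21 ** 2) \
        / (2.0 * l21)
    if not 0.0 <= z <= MAX_DEPTH:
        flags.append("depth_outside_bilayer_clamped")
        z = min(max(z, 0.0), MAX_DEPTH)
    return DepthResult(z, "parallax", flags=tuple(flags))


def _gaussian_profile(d: np.ndarray, z: float, sigma: float, s: float) -> np.ndarray:
    """-ln(F/F0) at quencher depth d for a mirrored transverse Gaussian."""
    norm = s / (sigma * math.sqrt(2.0 * math.pi))
    return norm * (np.exp(-((d - z) ** 2) / (2.0 * sigma ** 2))
                   + np.exp(-((d + z) ** 2) / (2.0 * sigma ** 2)))


class DepthDistributionModel:
    """Distribution analysis: fit the transverse Gaussian quenching profile.

    The quenching profile -ln(F/F0) observed across >= 3 quencher depths is
    fitted with S/(sigma_d sqrt(2 pi)) * exp(-(d - z)^2 / (2 sigma_d^2)),
    symmetrised across the bilayer midplane.  ``fit()`` multi-starts the
    depth over the bilayer half-width and returns the best run.
    """

    def __init__(self, measurements: Sequence[QuenchingMeasurement]):
        ms = list(measurements)
        if len({m.depth for m in ms}) < 3:
            raise ConfigurationError(
                "distribution analysis needs >= 3 distinct quencher depths; "
                "for two quenchers fall back to parallax_depth")
        self.measurements = ms
        self._d = np.array([m.depth for m in ms])
        self._y = np.array([-math.log(m.f_over_f0) for m in ms])

    def predict(self, z: float, sigma: float, s: float) -> np.ndarray:
        return _gaussian_profile(self._d, z, sigma, s)

    def fit(self, z_starts: Sequence[float] = tuple(range(2, 29, 4))) -> DepthResult:
        y = self._y
        best = None
        for z0 in z_starts:
            x0 = np.array([z0, 3.0, max(float(y.max()) * 3.0 * math.sqrt(2 * math.pi), 1e-3)])
            res = least_squares(
                lambda x: _gaussian_profile(self._d, *x) - y, x0,
                bounds=([0.0, 1e-3, 0.0], [MAX_DEPTH, 30.0, np.inf]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15)
            if best is None or res.cost < best.cost:
                best = res
        z, sigma, s = best.x
        flags = []
        if not best.success:  # pragma: no cover
            flags.append("optimizer_not_converged")
        return DepthResult(float(z), "distribution", float(sigma), float(s),
                           rss=2.0 * float(best.cost), flags=tuple(flags))


def fit_depth_distribution(measurements: Sequence[QuenchingMeasurement]) -> DepthResult:
    """Functional wrapper over :class:`DepthDistributionModel`."""
    return DepthDistributionModel(measurements).fit()
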
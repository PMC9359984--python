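"""Exact equilibrium speciation for host-guest binding models.

Solvers for the equilibria used throughout the package:

* 1:1 association       H + G  <-> HG          (Ka)
* stepwise 1:2          HG + G <-> HG2         (K1, K2)
* two-guest competition H + S <-> HS, H + X <-> HX   (mutually exclusive 1:1)
* solubility-product buffering of a guest by a sparingly soluble salt
  (BaSO4: free sulfate pinned at Ksp/[Ba2+] once saturated)

All concentrations are molar; association constants are M^-1 and treated as
concentration constants (activity coefficients ignored; ionic strength is
fixed experimentally).  Every solver closes its mass balances to <=1e-10
relative, checked by :func:`mass_balance_error`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from scipy.optimize import brentq

from .exceptions import DomainError, NumericalError

# Stoichiometry of every complex label the solvers can emit:
# complex -> {component: count}.  "H" is the host; guest labels are free-form.
_STOICH = {
    "HG": {"H": 1, "G": 1},
    "HG2": {"H": 1, "G": 2},
    "HS": {"H": 1, "S": 1},
    "HX": {"H": 1, "X": 1},
}

#: root-finding tolerances (absolute M / relative), iteration cap
ABS_TOL = 1e-15
REL_TOL = 1e-12
MAX_ITER = 200


@dataclass(frozen=True)
class BindingSystem:
    """Totals and constants defining one binding equilibrium problem.

    ``constants`` is keyed by complex label ("HG", "HG2" for 1:2 stepwise;
    "HS", "HX" for competition).  ``ksp``/``counterion_total`` switch on
    solubility-product buffering of the first guest.
    """

    host_total: float
    guest_totals: Tuple[Tuple[str, float], ...]
    constants: Dict[str, float]
    ksp: Optional[float] = None
    counterion_total: Optional[float] = None

    def __post_init__(self):
        _require_nonneg(host_total=self.host_total)
        for label, c in self.guest_totals:
            _require_nonneg(**{f"guest_total[{label}]": c})
        for label, k in self.constants.items():
            _require_nonneg(**{f"constants[{label}]": k})
        if self.counterion_total is not None:
            _require_nonneg(counterion_total=self.counterion_total)
            if self.ksp is None or not self.ksp > 0:
                raise DomainError("ksp must be > 0 when counterion_total is set")


@dataclass
class SpeciationState:
    """Free and complexed concentrations at equilibrium (all molar).

    ``precipitate`` is mol of solid per litre of solution (0 if none); its
    components are named in ``precipitate_components``.
    """

    free_host: float
    free_guests: Dict[str, float]
    complexes: Dict[str, float] = field(default_factory=dict)
    precipitate: float = 0.0
    precipitate_components: Tuple[str, ...] = ()

    def component_total(self, component: str) -> float:
        """Reconstruct a component's total from the state (mass balance)."""
        total = self.free_host if component == "H" else self.free_guests.get(component, 0.0)
        for label, conc in self.complexes.items():
            total += _STOICH[label].get(component, 0) * conc
        if component in self.precipitate_components:
            total += self.precipitate
        return total

    def bound_host_fraction(self, host_total: float) -> float:
        if host_total == 0:
            return 0.0
        bound = sum(c for c in self.complexes.values())
        return bound / host_total


def mass_balance_error(state: SpeciationState, totals: Dict[str, float]) -> float:
    """Worst relative mass-balance error over the given component totals."""
    worst = 0.0
    for comp, total in totals.items():
        recon = state.component_total(comp)
        scale = max(abs(total), ABS_TOL)
        worst = max(worst, abs(recon - total) / scale)
    return worst


def _require_nonneg(**named):
    for name, value in named.items():
        if not math.isfinite(value):
            raise DomainError(f"{name} must be finite, got {value!r}")
        if value < 0:
            raise DomainError(f"{name} must be >= 0, got {value!r}")


def solve_1to1(host_total: float, guest_total: float, ka: float) -> SpeciationState:
    """Closed-form 1:1 speciation via the stable quadratic root.

    [HG] solves  Ka*(H-hg)*(G-hg) = hg; the root is taken so that
    0 <= [HG] <= min(H, G).
    """
    _require_nonneg(host_total=host_total, guest_total=guest_total, ka=ka)
    if ka == 0 or host_total == 0 or guest_total == 0:
        return SpeciationState(host_total, {"G": guest_total}, {"HG": 0.0})
    b = host_total + guest_total + 1.0 / ka
    prod = host_total * guest_total
    disc = math.sqrt(b * b - 4.0 * prod)
    # citardauq form: numerically stable when hg << b
    hg = 2.0 * prod / (b + disc)
    hg = min(hg, host_total, guest_total)
    return SpeciationState(host_total - hg, {"G": guest_total - hg}, {"HG": hg})


def solve_1to2(host_total: float, guest_total: float, k1: float, k2: float) -> SpeciationState:
    """Stepwise 1:2 speciation: unique free-guest root of the cubic balance.

    With free guest g, free host h = H/(1 + K1*g + K1*K2*g^2) and the guest
    balance g + h*(K1*g + 2*K1*K2*g^2) = G has exactly one root in [0, G].
    """
    _require_nonneg(host_total=host_total, guest_total=guest_total, k1=k1, k2=k2)
    if k2 == 0:
        st = solve_1to1(host_total, guest_total, k1)
        st.complexes["HG2"] = 0.0
        return st
    if guest_total == 0 or host_total == 0:
        return SpeciationState(host_total, {"G": guest_total}, {"HG": 0.0, "HG2": 0.0})

    def residual(g):
        denom = 1.0 + k1 * g * (1.0 + k2 * g)
        h = host_total / denom
        return g + h * (k1 * g + 2.0 * k1 * k2 * g * g) - guest_total

    lo, hi = 0.0, guest_total
    if residual(lo) > 0 or residual(hi) < 0:  # pragma: no cover - impossible by monotonicity
        raise NumericalError("no sign change of 1:2 residual on [0, guest_total]")
    g = brentq(residual, lo, hi, xtol=ABS_TOL, rtol=4 * 2.23e-16, maxiter=MAX_ITER)
    for _ in range(3):  # Newton polish (numerical derivative) for mass balance
        dg = max(1e-9 * g, 1e-18)
        deriv = (residual(g + dg) - residual(g - dg)) / (2 * dg)
        if deriv <= 0:
            break
        step = residual(g) / deriv
        if g - step < 0 or g - step > guest_total:
            break
        g -= step
        if abs(step) <= 1e-17 * g:
            break
    h = host_total / (1.0 + k1 * g * (1.0 + k2 * g))
    hg = k1 * h * g
    hg2 = k2 * hg * g
    return SpeciationState(h, {"G": g}, {"HG": hg, "HG2": hg2})


def solve_competition(host_total: float, s_total: float, x_total: float,
                      ka_s: float, ka_x: float) -> SpeciationState:
    """Two mutually exclusive 1:1 complexes at a single site.

    Solved by bracketing the free-host concentration: given free host h the
    free guests are s = S/(1+Ka_s*h), x = X/(1+Ka_x*h), and the host balance
    h*(1 + Ka_s*s + Ka_x*x) - H is strictly increasing in h.
    """
    _require_nonneg(host_total=host_total, s_total=s_total, x_total=x_total,
                    ka_s=ka_s, ka_x=ka_x)
    if host_total == 0:
        return SpeciationState(0.0, {"S": s_total, "X": x_total}, {"HS": 0.0, "HX": 0.0})

    def residual(h):
        s = s_total / (1.0 + ka_s * h)
        x = x_total / (1.0 + ka_x * h)
        return h * (1.0 + ka_s * s + ka_x * x) - host_total

    try:
        h = brentq(residual, 0.0, host_total, xtol=ABS_TOL, rtol=4 * 2.23e-16,
                   maxiter=MAX_ITER)
    except RuntimeError as exc:  # pragma: no cover - cap is generous
        raise NumericalError("competition solver did not converge",
                             residuals={"host": residual(host_total)}) from exc

    def dresidual(h):
        return 1.0 + ka_s * s_total / (1.0 + ka_s * h) ** 2 \
            + ka_x * x_total / (1.0 + ka_x * h) ** 2

    for _ in range(3):  # Newton polish to machine-level mass balance
        step = residual(h) / dresidual(h)
        if h - step < 0:
            break
        h -= step
        if abs(step) <= 1e-17 * h:
            break
    s = s_total / (1.0 + ka_s * h)
    x = x_total / (1.0 + ka_x * h)
    return SpeciationState(h, {"S": s, "X": x}, {"HS": ka_s * h * s, "HX": ka_x * h * x})


def apparent_ka_under_competition(ka_s: float, ka_x: float, x_free: float) -> float:
    """Apparent reporter constant in the presence of a fixed free competitor.

    Ka_app = Ka_s / (1 + Ka_x * [X]_free) — exact in the excess-competitor
    limit where [X]_free is unperturbed by host binding.
    """
    _require_nonneg(ka_s=ka_s, ka_x=ka_x, x_free=x_free)
    return ka_s / (1.0 + ka_x * x_free)


def invert_competition(ka_s: float, ka_s_app: float, x_free: float) -> float:
    """Competitor constant from the attenuation of the reporter's constant."""
    _require_nonneg(ka_s=ka_s, ka_s_app=ka_s_app)
    if ka_s_app > ka_s:
        raise DomainError("competitor cannot raise apparent affinity under this model "
                          f"(ka_s_app={ka_s_app!r} > ka_s={ka_s!r})")
    if not x_free > 0:
        raise DomainError(f"x_free must be > 0, got {x_free!r}")
    return (ka_s / ka_s_app - 1.0) / x_free


def free_sulfate_with_precipitation(sulfate_total: float, counterion_total: float,
                                    ksp: float) -> SpeciationState:
    """Free sulfate when a sparingly soluble counterion salt may precipitate.

    Below saturation (ion product <= Ksp) everything stays dissolved.  Above
    it, precipitate p solves (S-p)(C-p) = Ksp with 0 <= p <= min(S, C),
    pinning the ion product at Ksp exactly.
    """
    _require_nonneg(sulfate_total=sulfate_total, counterion_total=counterion_total)
    if not ksp > 0:
        raise DomainError(f"ksp must be > 0, got {ksp!r}")
    if sulfate_total * counterion_total <= ksp:
        return SpeciationState(0.0, {"SO4": sulfate_total, "Ba": counterion_total},
                               {}, 0.0, ("SO4", "Ba"))
    s_plus_c = sulfate_total + counterion_total
    disc = math.sqrt((sulfate_total - counterion_total) ** 2 + 4.0 * ksp)
    # smaller quadratic root in stable (citardauq) form
    p = 2.0 * (sulfate_total * counterion_total - ksp) / (s_plus_c + disc)
    free_s = sulfate_total - p
    free_c = counterion_total - p
    # one Newton polish on the ion-product condition keeps (S-p)(C-p) = Ksp
    # at machine precision even after cancellation
    f = free_s * free_c - ksp
    dp = f / (free_s + free_c)
    p += dp
    free_s = sulfate_total - p
    free_c = counterion_total - p
    return SpeciationState(0.0, {"SO4": free_s, "Ba": free_c}, {}, p, ("SO4", "Ba"))
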
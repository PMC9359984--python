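# Methods

This note records the models implemented in `anionbind`, the assumptions and
defaults behind them, the design choices made where the underlying
experimental protocol left the design open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Binding models and speciation

All equilibria are treated with concentration constants (activities ≈
concentrations). This matches practice in the experiments being modelled:
constants are reported as concentration quotients and, where it matters
(competition titrations in water), the ionic strength is fixed at 0.2 M so
activity coefficients are constant across the titration and absorbed into
K_a. Ion pairing of the TBA⁺/Na⁺ counterions is ignored.

* **1:1** — [HG] is the stable (citardauq) root of the quadratic mass
  balance, clamped to [0, min(H_tot, G_tot)].
* **1:2 stepwise** — free guest is the unique root of the cubic balance on
  [0, G_tot], bracketed by Brent's method and Newton-polished; both HG and
  HG₂ are returned. Which anions, if any, warrant the 1:2 model is a user
  decision; both models are available and AIC is exposed on the fit result
  for comparison, but no model choice is asserted by the package.
* **Competition** — two mutually exclusive 1:1 complexes at the single
  macrocycle cavity (the cavity architecture supports single occupancy).
  The free-host concentration is bracketed on [0, H_tot]; the host-balance
  residual is strictly increasing in free host, so the root is unique.
* **BaSO₄ buffering** — below saturation nothing precipitates; above it the
  precipitate is the stable quadratic root of (S−p)(C−p) = K_sp, with one
  Newton polish pinning the ion product at K_sp to machine precision.
  K_sp in the titration medium is not known precisely; the default
  1.08 × 10⁻¹⁰ M² is the aqueous literature value and every report using it
  echoes it as an assumption.

Numerical policy: absolute tolerance 1e−15 M, relative 1e−12, iteration cap
200; all solvers close host and guest mass balances to ≤1e−10 relative
(property-tested against brute-force root scans on random instances).

## Titration fitting

Free-ligand depletion is always handled exactly through the speciation
solvers — host totals span 50 nM (fluorescence) to 0.3 mM (NMR), so the
excess-guest approximation is never safe to assume. Fits are unit-weighted
by default (homoscedastic noise); per-point σ is accepted from input.
K_a is fitted as log₁₀K_a with a multi-start grid over {0..9} to avoid local
minima at extreme constants; estimates at the parameter boundary are
downgraded to bounds via flags (mirroring ">10⁵"/"<1"-style reporting), and
fits where SE(K_a) ≥ K_a are flagged unidentifiable. Standard errors come
from the Jacobian at the optimum; SE(K_a) = ln(10)·K_a·SE(log₁₀K_a).
Replicate aggregation reports mean and sample SD across experiments.

The fluorescence observable is single-wavelength intensity (the titrations
being modelled plot the intensity at one emission wavelength); an integrated
band would fit identically up to an affine rescaling, to which the K_a
estimate is invariant (tested to 1e−9 relative).

Anions that quench the fluorophore dynamically (Br⁻, NO₃⁻, I⁻, ClO₄⁻) cannot
be titrated directly; they are handled only through the competition route.
No Stern–Volmer observable model is implemented.

### Competition route

K_app = K_s/(1 + K_x·[X]_free) assumes the competitor is in large excess over
the host so [X]_free ≈ [X]_tot (warned otherwise). The fit inverts this
exactly; if the apparent constant is not attenuated the competitor constant
is reported as 0 with a `no_detectable_competition` flag (the "<1 M⁻¹"
case). Uncertainty is propagated first-order from both the apparent fit and
the supplied SE of the reporter constant.

### BaSO₄ design

With the aqueous K_sp and K_a(SO₄²⁻) ≈ 7.4 × 10⁹ M⁻¹, half-saturation of the
host requires free sulfate ≈ 1/K_a ≈ 1.4 × 10⁻¹⁰ M, i.e. free Ba²⁺ ≈
K_sp·K_a ≈ 0.8 M. The synthetic design therefore titrates the counterion on
a log grid from 0.01 to 10 M — numerically exact, though a real titration at
molar barium would raise ionic-strength issues the model ignores; the actual
experimental medium (DMSO-d₆) will have a far smaller K_sp, shifting the
grid correspondingly. The host-bound share of sulfate is included in the
balance self-consistently (fixed-point iteration, tolerance 1e−12).

## Interfacial electrostatics

Planar Gouy–Chapman theory throughout: the Debye length at 0.2 M ionic
strength (~0.7 nm) is small against the ~100 nm vesicle radius, and the same
planar treatment is applied to micelles as an approximation. Zeta, measured
at the shear plane, is back-propagated to the surface by integrating the
planar Poisson–Boltzmann decay in inverted form x(ψ) = ∫dψ/|dψ/dx| (which
avoids stiffness near the surface) and solving ψ(x_shear) = ζ for ψ₀ by
bracketing in [ζ, ±0.5 V]. The shear-plane distance is not measurable here;
the default is 2 Å, configurable, and echoed in every report. Defaults:
ε_r = 78.4, T = 298.15 K.

The Grahame relation σ = sign(ψ₀)√(2εε₀RT Σcᵢ[exp(−zᵢFψ₀/RT) − 1]) is
implemented for arbitrary electrolyte mixtures and is mutually consistent
with the profile integration (field at the surface reproduces σ to 1e−8).

Correction policy: concentrations, not constants, are corrected — each ionic
species is scaled by its own Boltzmann factor before fitting. This is exact
in general and reduces to dividing K_app by the reporter's factor in the
excess-competitor regime. By default **all** ionic species are corrected; a
`correct: sulfate_only` switch reproduces the alternative reading in which
only the reporter is re-referenced. Stern-layer/ion-specific adsorption and
mobility→zeta conversions are out of scope (ζ is taken as the instrument
reports it).

## Penetration depth

Parallax: z = L_c1 + [−ln(F₁/F₂)/(πC) − L₂₁²]/(2L₂₁) for a shallow/deep
quencher pair with common surface density C (mean used, with a warning, if
they differ). Distribution analysis fits −ln(F/F₀)(d) =
S/(σ_d√(2π))·exp(−(d−z)²/2σ_d²), symmetrised across the bilayer midplane
(images at ±z), over ≥3 quencher depths by bounded least squares
multi-started in z; it reports the most probable depth z, dispersion σ_d and
strength S. Distribution analysis is the default (it is what "most probable
location" refers to); parallax is retained for two-quencher data.

Default quencher depths from the bilayer centre — Tempo-PC 19.5 Å,
5-doxyl-PC 12.15 Å, 12-doxyl-PC 5.85 Å — are standard parallax-literature
values for PC bilayers and are configurable per dataset; the quencher
surface density defaults to mole fraction/area per lipid (0.68 nm² per
POPC). With exactly three depths the three-parameter Gaussian interpolates
the data, so noiseless recovery is exact but noise propagates strongly into
z (a 2% noise study needs ~5 quencher positions to hold the median depth
error below 0.5 Å). Time-resolved quenching and fluorophore orientation are
not modelled.

## Transport kinetics

pH = pKa + log₁₀((R − R_min)/(R_max − R)) for the HPTS excitation ratio;
calibration constants (R_min, R_max, apparent pKa 7.2) and the buffer pKa
(HEPES, 7.48 at 25 °C) are explicit inputs, never silently hard-coded.
Influx: Δ[H]ᵢₙ = C_buf[α(pH_t) − α(pH₀)] + Δ[H⁺] − Δ[OH⁻] with
α = 1/(1 + 10^(pH−pKa)); acidification is positive. This is verified against
an independent charge-balance titration solver. Initial rates are OLS slopes
over a configurable window (default 30 s) reported with their SE so that
selectivity comparisons are like-for-like.

Per-carrier normalisation counts lipids per vesicle from both leaflets,
4π(r_out² + r_in²)/a_lipid, carriers as mole fraction × lipids, and protons
as rate × V_in × N_A; one H⁺ ≡ one anion under the symport stoichiometry.
Geometry defaults: diameter 200 nm, a_lipid 0.68 nm², bilayer 3.7 nm. A
bulk-concentration shortcut (rate × trapped-volume fraction / carrier
concentration) is available as `mode="bulk"`; with full carrier partitioning
the two normalisations agree exactly, and results always name the mode used.

The synthetic trace generator uses a single-exponential approach of the
influx to a plateau set by a ~0.5 pH-unit acidification — a phenomenological
stand-in, since only initial rates are analysed and the late-time shape is
not load-bearing. One consequence: at Table-scale per-carrier rates
(~2 anions s⁻¹ carrier⁻¹) the implied intravesicular equilibration is fast
(k of order 1 s⁻¹), so rate windows must be short against 1/k; the recovery
tests choose windows of 1/k ÷ 50–100 accordingly, and the window used is
always reported next to the rate.

## Synthetic data and what the tests show

Noise is Gaussian, homoscedastic on the observable, scaled to the noiseless
signal range — matching the unit-weight fitting default. Generators are
deterministic given the seed and echo their full truth. They do **not**
emulate photobleaching, drift, shot noise, activity effects, slow
equilibration or pipetting error; passing recovery tests therefore
demonstrates correctness and statistical calibration of the inference chain
under its own assumptions, not robustness to every artefact of real
instruments.

Recovery-study problem sizes: 15-point titration grids, 50 seeded replicates
per study at 1% noise (medians reported with the Gaussian SE of the median,
1.2533·SD/√n); three-quencher noiseless profiles for the depth checks;
12-point log counterion grids for the precipitation route. These sizes were
chosen as representative of the bench experiments while keeping every study
runnable in seconds.

## Known limitations

* Planar double-layer geometry for micelles is a coarser approximation than
  for vesicles (micelle radius ~ a few Debye lengths).
* The competition model assumes strictly mutually exclusive 1:1 binding;
  ternary complexes or allosteric effects would bias K_x.
* K_sp, shear-plane distance, quencher depths and HPTS/HEPES constants are
  literature defaults, not fitted; every result document echoes the values
  in force.
* The 1:2 observable model attributes independent amplitudes to HG and HG₂;
  strongly correlated amplitudes can make K₂ weakly identified on sparse
  grids (flagged through the SE-based identifiability check).
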
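# Methods

This note documents the physics model, the numerical choices and the
limitations of the `nanoscint` pipeline: what is simulated, which
parameters matter, what the synthetic data emulate, and what passing the
test suite does and does not demonstrate.

## Atomic data

Photon interactions are described by per-element mass attenuation
coefficients (photoelectric, incoherent, coherent) on 0.25–15 keV grids,
and electrons by total mass stopping powers. The shipped tables for H, C,
N, O, Si, Ar and Zn are generated by a compact parameterization
(`nanoscint.shipped_tables`), anchored on published atomic constants:

* K-edge energies (Zn 9.659 keV, Si 1.839 keV, …), Kα line energies,
  K fluorescence yields (Zn ω_K = 0.479, Si 0.050) and K-edge jump ratios
  (Zn 7.8, Si 10.3);
* per-element photoelectric power laws `pe(E) = pe10 · (10/E)^n` with the
  10 keV anchor and exponent fitted per element, divided by the jump ratio
  below the K edge. Only the K edge is resolved as a discontinuity — the
  table carries a *duplicated grid energy* at the edge so log-log
  interpolation never bridges it. L/M structure is smoothed; below the
  mean L-binding energy the law is flattened, so the sub-keV photoelectric
  tail is only indicative (sub-keV photons are rare in these simulations:
  the lowest fluorescence line tracked is Si Kα at 1.74 keV);
* incoherent scattering from the Klein–Nishina total cross section times
  Z/A with a simple low-energy binding damping; coherent scattering from a
  smooth Z^2.9 power law (it only redirects photons, so its absolute scale
  is uncritical at the percent level of these observables);
* electron stopping from the Joy–Luo low-energy modification of the Bethe
  formula with standard mean excitation energies — accurate to ~10% down
  to a few hundred eV, which is the regime of the 1 nm-step transport.

The tables are therefore *compatible with*, not identical to, any specific
evaluated library (EPDL/XCOM); the energy-partition observables carry
tolerances of a few percentage points for this reason. Mixtures use
mass-fraction additivity. Materials: SiO₂ (2.65 g/cm³), ZnO (5.61 g/cm³),
TCPP (C₄₈H₃₀N₄O₈, 1.3 g/cm³) and standard dry air
(N 75.5 / O 23.2 / Ar 1.3 wt%, 1.205 mg/cm³ — the assemblies sit in
ambient air and the composition is an implementation constant).

Interpolation is log-log linear and exact at grid nodes; energies outside
a table raise an error rather than extrapolate, because silent
extrapolation would corrupt partition fractions.

## Geometries

*Code A* places `n_zno` ZnO spheres (5 nm diameter) with centres exactly on
the sphere of radius R_SiO₂ + r_ZnO = 42.5 nm (tangent, not embedded — the
micrographs show surface-decorating particles and no embedding depth is
known), accepted by rejection sampling with a minimum centre distance of
one NP diameter. At n = 215 the occupied surface fraction is ~19%, so
placement succeeds with a large margin (the retry budget is 10⁶ attempts
per particle). The air world is a 500 nm sphere; energy crossing it is
scored as escaped, not as air dose, so the small air percentage depends on
this convention (documented tolerance driver).

*Code B* packs `n_nanosystems` coated spheres — a 40 nm SiO₂ core plus a
ZnO shell whose 0.688 nm thickness makes its volume equal to 215 NPs
(rounds to the nominal 0.7 nm) — uniformly into the air-filled cylinder,
with full containment and hard non-overlap enforced on a uniform cell
grid. The holder is 8.5 µm diameter × 1 µm height by default (the
alternative 8.25 µm diameter that appears elsewhere in the source material
is selectable via `holder_diameter_um`). At the full population of 5×10⁴
the characteristic surface-to-surface spacing is ≈23 nm and the mean
nearest-neighbour gap ≈6 nm; a quoted "mean inter-distance of ∼50 nm" is
consistent with these only as an order-of-magnitude spacing figure and is
not used quantitatively. For CI-scale runs the benchmark suite uses 2×10³
nanosystems — the partition fractions are intensive, so the population can
be scaled down without biasing them.

Point location resolves the innermost containing body (shell over core at
shell radii); ray segmentation solves the sphere/cylinder quadratics in
closed form and merges contiguous same-medium segments.

## Transport

Primaries are parallel monochromatic photons on a uniform disc
circumscribing the target's projected footprint (the beam width is not
otherwise specified), tilted 26° from the cylinder/world axis. When
`air_column` is on, attenuation over the 15 cm source distance is applied;
it matters only for absolute interaction counts, not for conditional
partition fractions, and defaults off.

Photon physics per interaction:

* **channel selection** proportional to the partial linear attenuation
  coefficients;
* **photoelectric**: the target element is sampled by its share of the
  photoelectric coefficient; above the K edge the K shell is ionized with
  probability 1 − 1/jump. The photoelectron (E − binding) is emitted
  isotropically. The K vacancy relaxes radiatively with probability ω_K —
  the Kα photon is tracked like any photon and may escape — otherwise
  non-radiatively. Two non-radiative models are available:
  `relaxation="local"` (default) deposits the vacancy energy at the
  interaction point, matching the behaviour of the reference Geant4
  Livermore configuration in which Auger-electron production is not
  activated; `relaxation="auger"` emits a single KLL-like Auger electron
  of energy k_edge − 2·l̄_L and deposits the residual binding locally.
  The choice is physically consequential at 10 keV: a transported 7.5 keV
  KLL electron leaves a 5 nm ZnO particle almost immediately, moving the
  ZnO share of deposited energy from ≈78% (local) to ≈55% (transported).
  Outer-shell ionization deposits the mean L-binding energy locally.
* **incoherent**: Klein–Nishina on free electrons at rest, sampled with
  Kahn's composition-rejection algorithm; the recoil electron direction
  follows the Compton kinematics. No Doppler broadening or binding — a
  documented deviation from Livermore, acceptable because incoherent
  scattering is a minor channel below 10 keV;
* **coherent**: Thomson angular law (1 + cos²θ), energy unchanged. By
  default a Rayleigh event counts as "the first interaction" for
  conditioning; `rayleigh_counts_as_first=False` moves the tag to the next
  energy-transferring event (the partition is insensitive at these
  energies).

Electrons follow a condensed-history walk: fixed 1 nm steps in solid media
(a 5 nm NP is crossed in ≥5 steps), adaptive steps in air bounded by half
the distance to the nearest body surface (never skipping a particle), the
per-step loss S(E)·Δs deposited at the step midpoint, and local absorption
of the residual energy below the 250 eV cutoff. Angular diffusion applies
a Gaussian polar deflection per step with variance 2t·Δs/R(E), where R is
the residual CSDA range and t solves (1 − e⁻ᵗ)/t = f with detour factor
f = 0.6, so the displacement/path ratio over a full range is ≈0.6.
No bremsstrahlung (negligible below 15 keV in these media).

**Forced first interaction.** In forced mode the primary's first
interaction is sampled on the solid segments of its ray from the piecewise
truncated exponential, and the history weight is the unconditional
probability 1 − exp(−Σ μᵢ lᵢ) (times the air-column survival when
enabled). All subsequent transport is analog; every score is multiplied by
the weight. Per history, weight·E_beam = Σ(deposits) + escaped holds to
float precision and is asserted in the tests at 10⁻⁶ relative.

**Randomness.** A master seed spawns one splitmix64-derived substream per
history, so results are independent of batching and bit-reproducible.

## Scoring

Partition tables normalise the weighted per-medium deposits over
{SiO₂, ZnO, air}; statistical errors come from 20-batch history variance.
Radial profiles histogram the weighted deposits against r = |x − anchor|:
in code A the anchor is the first-interaction body centre (host centre for
SiO₂-first histories → r_SiO₂; NP centre for ZnO-first → r_ZnO), in code B
the centre of the nanosystem nearest to the deposit (the alternative
first-interaction anchoring is one config switch away,
`scoring_anchor="first"`). Bin widths default to 1 nm (code A) and 5 nm
(code B); overflow clamps into the last bin so bin sums remain exhaustive.
Large runs aggregate per-history sums and histograms inside the kernel;
full per-deposit event streams (`record_events=True`) are intended for
small runs and are cross-checked against the aggregated path in the tests.

At the study conditions this model reproduces: a strict SiO₂ majority at
3.3 keV; a monotone increase of the ZnO share across 3.3 → 6.6 → 10 keV
with ≈78% in ZnO at 10 keV (the Zn K-edge effect); first-in-ZnO profiles
whose leakage beyond the NP radius is smaller at 10 keV than at 6.6 keV;
and a per-primary interaction probability that falls monotonically with
beam energy. Problem sizes used by the test suite: 2×10⁵ forced histories
for the 10 keV partition (batch error < 1 pp), 3×10⁴ per energy for the
trend properties.

## RL spectral decomposition

The model class is a sum of area-parameterized Gaussians on the
photon-energy axis, fit over the 1.2–4.5 eV window (the porphyrin
Soret-band tail above ~3 eV is deliberately not modelled). The fit is a
damped least-squares (Levenberg–Marquardt) with analytic Jacobian:
multiplicative damping (×ν on a rejected step, ÷ν on an accepted one,
ν = 3), convergence on a relative chi-square decrease < 10⁻⁸, on a
vanishing step, when no damping yields a downhill step (stationary point),
or when progress stays below 10⁻⁶ relative for 20 consecutive accepted
steps (this last guard terminates the slow zigzag tail of narrow curved
valleys, where the remaining total improvement is negligible compared to
the parameter uncertainties). Uncertainty weighting is used when the
spectrum carries per-point uncertainties, else unweighted.

Constraints are enforced by smooth reparameterization: signed-log or
sigmoid-boxed areas, sigmoid-boxed widths and centers; transformed
coordinates are clamped at their saturation values (|u| = 18) so the
optimizer cannot crawl toward an asymptote. The default component sets
encode prior knowledge of these materials — the same component set fits
every spectrum of a series, so centers are boxed within ±0.05 eV of their
nominal positions, emission widths within 0.02–0.6 eV (the defect band is
broad, the excitonic and dye bands narrow), Q-band dips within
0.02–0.15 eV. Because areas enter the model linearly, initial areas are
seeded by sign-constrained linear least squares (NNLS) at the initial
centers/widths before the nonlinear refinement, which reliably starts the
fit in the correct basin.

Parameter uncertainties come from the Laplace approximation in the
*transformed* space; the credible interval of a center is the sigmoid
image of its ±nσ raw interval (`FitResult.center_interval`), which widens
correctly near a bound instead of collapsing. On synthetic
functionalized-type spectra the 3σ intervals recover all ten component
centers in ≈92% of replicates; the residual misses are marginal and
reflect the intrinsically correlated errors of overlapping mixed-sign
components. Removing the four negative Q-band components strictly worsens
chi-square in every replicate — the negative components are required, not
optional.

## Synthetic data

The spectrum generator draws from a fixed ground truth emulating a
functionalized sample: six positive bands (1.55/0.06, 1.70/0.075,
1.85/0.095, 2.22/0.25, 2.70/0.20, 3.09/0.08 eV centre/σ) and four negative
Q-band components (σ = 0.055 eV, dip amplitudes ≈30% of the local
emission), on an 800-point grid (CCD-like ~4 meV sampling) with
counting-like noise σ = 0.3·√(1 + |model|) — peak SNR ≈ 40–50, comparable
to long-integration CCD spectra. What the generator does *not* emulate:
detector spectral-response residuals, baseline drifts, cosmic-ray spikes,
wavelength-calibration error, and any non-Gaussian band shape. Passing the
recovery study therefore demonstrates the estimator's correctness on
well-calibrated data of the stated SNR, not robustness to instrument
systematics.

The benchmark suite enumerates the 4×3 grid of code A configurations
(n_zno ∈ {0, 10, 100, 215} × {3.3, 6.6, 10} keV) plus one reduced code B
configuration, all with fixed seeds; every fixture is regenerable
bit-identically from (spec, seed).

## Known limitations

* Single-configuration atomic relaxation (no cascade transport); the
  `local` default reproduces Geant4-Livermore-without-Auger behaviour, and
  both bracketing choices are available.
* Free-electron Compton; Thomson (form-factor-free) Rayleigh.
* Sub-keV photoelectric tails are schematic; the transport cutoff is
  250 eV.
* The air percentage of the partition depends on the finite world size.
* Electron transport is condensed-history with a fixed detour factor, not
  track structure; straggling of path lengths is not modelled.
* Polychromatic tube spectra are out of scope — the simulated beams are
  monochromatic at the tube's mean energies, so intensity-vs-voltage
  observations of the physical experiment are not reproduced here.
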
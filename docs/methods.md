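# Methods

## Intensity decay: Lorentzian lifetime distribution

The excited-state decay of a membrane probe is modelled as a continuous
Lorentzian distribution of lifetimes centred at τ_c with full width at half
maximum w, plus one discrete short component fixed at 0.01 ns that absorbs
scattered excitation light. The distribution is truncated to
τ ∈ (0, τ_c + 50 w] — the untruncated Lorentzian puts mass at unphysical
τ ≤ 0 — and renormalised on that support. `width = 0` degenerates exactly
to a single exponential.

**Quadrature.** The truncated density is discretised once per (τ_c, w)
with composite Gauss–Legendre after the arctangent substitution
u = atan((τ − τ_c)/(w/2)), under which the Lorentzian density is constant;
64 panels × 16 nodes (1024 nodes) reproduce adaptive quadrature to ~1e−9
across realistic centres and widths, including arbitrarily narrow
distributions that a fixed log-τ grid would miss. The node weights are
normalised to sum to one, so I(0) = 1 holds to machine precision and every
downstream transform is a closed form over the discrete components.

## Frequency-domain observables

With ω = 2πf (f in MHz, converted to rad/ns via ω = 2πf·10⁻³), each
exponential component contributes ωτ²/(1+ω²τ²) to the sine transform N and
τ/(1+ω²τ²) to the cosine transform D; phase = atan2(N, D), modulation =
√(N²+D²)/Σaτ. Phase is in degrees at every interface, radians internally.

Polarized observables build I_par = ⅓I(t)[1+2r(t)] and
I_perp = ⅓I(t)[1−r(t)]; products of exponentials are exponentials, so both
stay closed-form. Conventions, stated explicitly because instruments and
texts differ:

* **differential phase** Δφ = φ_perp − φ_par, positive while the
  anisotropy is decaying;
* **modulation ratio** Λ = AC_par/AC_perp, the ratio of modulated
  amplitudes (the standard frequency-domain anisotropy observable). Λ is
  *not* DC-normalised: for a time-constant anisotropy r it tends to
  (1+2r)/(1−r), and to 1 only when r = 0. A DC-normalised alternative
  (m_par/m_perp → 1 for shape-identical decays) was considered and
  rejected to stay with the field-standard quantity.

The lifetime-reference correction for a single-exponential standard
(default 1.45 ns, dimethyl-POPOP in ethanol) adds atan(ωτ_ref) to phase
and divides modulation by √(1+ω²τ_ref²); it is the exact inverse of
measuring against that standard.

The default frequency grid is 15 log-spaced points from 2 to 250 MHz,
spanning the phase sensitivity of 0.5–5 ns lifetimes; real instruments'
grids vary and any strictly increasing grid is accepted.

## Fitting

Weighted least squares, χ² = Σ(Δφ/σ_φ)² + Σ(Δm/σ_m)², minimised with
bounded trust-region least squares (lmfit) from five deterministic
multi-starts around the supplied start model — the χ² surface in
(width, main_fraction) is shallow, and the restarts are seeded so runs are
reproducible. Ties are broken by lowest χ², then smallest width (lifetime)
or smallest θ₁ (anisotropy). Datasets without stated uncertainties get
σ_φ = 0.2°, σ_m = σ_Λ = 0.004 — typical multifrequency instrument
precision — both overridable.

Fixed parameters: the scatter lifetime (0.01 ns) in the lifetime fit and
θ₂ (10⁶ ns = 1 ms) in the anisotropy fit; both are exposed but never
varied. The anisotropy fit parameterises r_∞ = r₀·h with h ∈ [0, 1], which
turns the physical ordering 0 ≤ r_∞ ≤ r₀ ≤ 0.4 into box bounds; h at its
upper bound is flagged "fully hindered".

**Confidence limits.** Correlated 67 % intervals by profile scan: the
named parameter is stepped outward (geometric step growth, linear
interpolation at the crossing) while all other free parameters are
re-optimised. The threshold is the one-parameter F-statistic bound
χ² ≤ χ²_min·(1 + F₀.₆₇(1, ν)/ν). For correctly weighted data
(χ²_min ≈ ν) this is numerically the familiar Δχ² ≈ 1 rule; for an exact
fit it collapses the interval to the estimate, which an additive Δχ² = 1
threshold would not do. Intervals that run into a parameter bound are
flagged open-ended.

## GP imaging

GP = (I_blue − I_red)/(I_blue + I_red) per pixel, computed only where the
summed channels exceed an intensity threshold (default 2 % of the joint
maximum — keeps the vesicle ring, rejects dark background; no geometric
circle fit is attempted). The blue (~440 nm) channel is the first TIFF
page by convention, overridable.

The histogram of masked GP values on [−1, 1] (bin width 0.02) is smoothed
with a 5-bin moving average, normalised to peak 1, and fitted with one or
two Gaussians by bounded least squares; the component centre is the
reported GP of that population. Two phases are declared only when the
two-Gaussian fit reduces the residual sum of squares below 50 % of the
one-Gaussian RSS **and** the centres are > 0.15 GP units apart **and**
both amplitudes exceed 0.1 of the peak. The RSS-ratio rule was chosen over
an information criterion for transparency; all five knobs live in
`GPConfig`. Fewer than 50 valid pixels is an error, not a guess.

The transition temperature of a series (≥ 4 temperatures, strictly
increasing) is the midpoint between the highest two-phase temperature and
the lowest one-phase temperature above it; the GP at the transition is the
single-population centre at that one-phase temperature. All-two-phase
series report T_mix = max temperature with an open-ended (censored) flag;
non-monotone call patterns are flagged ambiguous with every candidate
midpoint listed.

## Synthetic data

Generators are pure functions of (recipe, seed); per-element sub-streams
are derived from (seed, element index), so series are reproducible
element-wise and zero-noise outputs are exact fixed points of the analysis.

*Cuvette arm*: forward-model observables plus independent Gaussian noise
on phase and modulation (defaults 0.2° / 0.004), the error model of a
cross-correlation phase fluorometer at good signal. It does not emulate
correlated drifts, colour effects of the reference, or background
luminescence.

*Imaging arm*: a ring (default radius 80 px, width 12 px in a 256² image)
carrying one or two **contiguous angular domains** — matching the
macroscopic domains seen on real vesicles — with per-pixel channel
expectations solving I_b + I_r = N and GP(I_b, I_r) = domain GP, Poisson
noise per channel (how two-channel counting noise actually propagates into
GP; N = 400 counts/pixel gives σ_GP ≈ √((1−GP²)/N) ≈ 0.05), and a dark
background off-ring. No point-spread function, photobleaching,
z-sectioning or dye partitioning between phases is modelled, so passing
tests demonstrate correctness of the estimators under idealised optics,
not robustness to those effects.

*Thermotropic series*: below the onset, two domains at gp_high(T) and
gp_low(T) (defaults 0.61 − 0.005 T and 0.11 − 0.005 T: constant 0.5
separation, ~0.45/−0.05 near a low-30s °C onset); at and above it, one
domain at the fraction-weighted mean. These defaults are the package's
study conditions for end-to-end tests.

## Numerical and design notes

* Rounding for table-style presentation is half-away-from-zero at two
  decimals (three for R₁); stored values are always full precision.
* Dataset rows are sorted by frequency at construction, making fits
  invariant to input row order; duplicate frequencies are rejected.
* Magic-angle modulation may exceed 1 by up to 5σ_m to admit measurement
  noise near the zero-frequency limit.
* Published benchmark tables are rounded from unrounded fit output, so a
  minority of printed derived-parameter cells are internally inconsistent
  by one unit in the last digit; `reference_data.consistent_rows()`
  filters them, and nothing is tuned to reproduce the inconsistent cells.
* Pipeline reports carry provenance (config hash, seed, package version)
  and isolate per-entry failures; reruns with the same config + seed are
  numerically identical.

## Problem sizes

Simulation-based checks use 15-frequency datasets, replicate counts of
40–200, vesicle images of 256² (≈6×10³ ring pixels) for detection-rate
studies and 512² (≈10⁵ ring pixels) for histogram-centre accuracy, and an
11-point 4 °C thermotropic grid — sizes at which every Monte-Carlo bound
asserted in the tests was calibrated.

## Known limitations

* One distributed + one scatter lifetime component only; no Gaussian
  distributions, no multi-component discrete mixtures, no
  species-associated anisotropy.
* No global (linked) analysis across temperatures or cholesterol
  contents; each dataset is fitted independently.
* Time-domain (photon-counting) data are out of scope.
* The coexistence decision is threshold-based; vesicles with domains much
  smaller than the optical resolution, or strongly unequal dye
  partitioning, would violate the generator's assumptions and are not
  covered by the tests.
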
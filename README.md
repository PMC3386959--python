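# memphase

Analysis of lipid–cholesterol membrane structure and dynamics from two
kinds of fluorescence measurement:

* **frequency-domain fluorometry** of probes (DPH, Laurdan) embedded in
  large unilamellar vesicles — phase and modulation versus modulation
  frequency, fitted with a Lorentzian-distributed lifetime plus scatter
  term and a hindered-rotator ("wobble-in-cone") anisotropy decay;
* **Laurdan generalized-polarization (GP) imaging** of giant unilamellar
  vesicles — pixel-wise GP maps from two emission channels, Gaussian fits
  of the GP histogram, liquid–liquid phase-coexistence calls, and the
  immiscibility transition temperature from a thermotropic series.

It is written for membrane biophysicists who have cuvette phase/modulation
data or two-channel vesicle micrographs (or want to simulate them: the
package ships generators for both arms) and want order parameters,
rotational rates and phase diagrams out the other end.

## Models

The intensity decay is a continuous Lorentzian distribution of lifetimes
(centre τ_c, FWHM w, truncated to τ > 0 and renormalised) plus a discrete
0.01 ns component absorbing scattered light:

    I(t) = f_main ∫ L(τ; τ_c, w) e^(−t/τ) dτ + (1 − f_main) e^(−t/0.01)

The anisotropy decays from r₀ to a residual r_∞ with fast correlation time
θ₁ (a second, 1 ms correlation time lets the residual decay far beyond the
fluorescence timescale):

    r(t) = (r₀ − r_∞) e^(−t/θ₁) + r_∞ e^(−t/θ₂)

from which the derived parameters follow in closed form:

    f₁ = 1 − r_∞/r₀,   R₁ = 1/(6 θ₁),   S = √(r_∞/r₀)

Both models are fitted in the frequency domain: per lifetime component the
sine/cosine transforms have closed forms, so phase φ = atan(N/D) and
modulation m = √(N²+D²)/J are exact over the quadrature discretisation.
Polarized observables use I_par = ⅓I(t)[1+2r(t)], I_perp = ⅓I(t)[1−r(t)];
the differential phase is Δφ = φ_perp − φ_par and the modulation ratio is
Λ = AC_par/AC_perp. Fits minimise the σ-weighted χ²; uncertainties are
correlated 67 % profile confidence limits.

Generalized polarization is GP = (I₄₄₀ − I₄₉₀)/(I₄₄₀ + I₄₉₀) per pixel;
one GP population means a homogeneous membrane, two (high/low GP) mean
coexisting ordered and fluid liquid phases, and the temperature at which
two populations merge into one is the immiscibility transition T_mix.

## Worked example

`examples/derive_order_parameters.py` runs published benchmark rows for
DPH through the derived-parameter relations:

```
                system  theta1     f1      R1  r_inf    r0      S
          DPH/DPPC 25C    0.80   0.10   0.208   0.36  0.40   0.95
          DPH/DPPC 50C    0.89   0.80   0.187   0.08  0.40   0.45
          DPH/DOPC 25C    3.45   0.94   0.048   0.02  0.32   0.25
          DPH/DOPC 50C    1.48   0.97   0.113   0.01  0.30   0.18
```

High S with a tiny fast amplitude (gel-phase DPPC at 25 °C) means the
probe is locked in ordered acyl chains; in fluid DOPC the order parameter
collapses and nearly the whole anisotropy decays through the fast wobble.

`examples/fit_frequency_domain.py` simulates one noisy sample and recovers
it (truth τ_c = 3.45 ns, r₀ = 0.32, r_∞ = 0.02, θ₁ = 3.45 ns):

```
lifetime fit:   tau_center = 3.4579   width = 0.3830   reduced chi^2 = 0.60
anisotropy fit: r0 = 0.3197  r_inf = 0.0182  theta1 = 3.4770
                theta1 67% CI = [3.425, 3.530] ns
                derived: f1=0.943  R1=0.0479 rad/ns  S=0.239
```

`examples/gp_imaging.py` and `examples/thermotropic_series.py` do the
imaging arm: a two-domain vesicle is called two-phase with GP centres at
+0.450/−0.050 (truth 0.45/−0.05), and a series with a 33 °C onset on a
4 °C grid yields T_mix = 34 °C — within half a grid step.

There is also a thin CLI (`memphase simulate|fit-lifetime|fit-anisotropy|
derive-params|gp-image|run-series`) for batch runs over CSV/TIFF manifests
described in YAML; see `memphase --help`.

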
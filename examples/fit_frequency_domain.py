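"""Recover decay parameters from simulated multifrequency data.

Simulates one cuvette sample (distributed lifetime + hindered rotator) on a
15-point 2-250 MHz grid with instrument-level Gaussian noise (0.2 deg on
phase, 0.004 on modulation), then runs the two-stage analysis: magic-angle
lifetime fit, then anisotropy fit with the fitted intensity decay held
fixed, then the derived order parameters with profile confidence limits.
"""

from memphase import (
    HinderedRotatorModel,
    LorentzianLifetimeModel,
    confidence_limits,
    fit_anisotropy,
    fit_lifetime,
)
from memphase.simulate import SimulationRecipe, simulate_frequency_dataset

truth_intensity = LorentzianLifetimeModel(tau_center=3.45, width=0.4, main_fraction=0.98)
truth_anisotropy = HinderedRotatorModel(r0=0.32, r_inf=0.02, theta1=3.45)
recipe = SimulationRecipe(truth_intensity=truth_intensity,
                          truth_anisotropy=truth_anisotropy, seed=42)

ds_magic = simulate_frequency_dataset(recipe, "magic_angle")
ds_pol = simulate_frequency_dataset(recipe, "polarized")

lifetime = fit_lifetime(ds_magic, LorentzianLifetimeModel(2.0, 0.2, 0.95), seed=0)
print("lifetime fit (truth tau_c=3.45, width=0.40, fraction=0.98):")
for name, value in lifetime.estimates.items():
    print(f"  {name:>13} = {value:7.4f}")
print(f"  reduced chi^2 = {lifetime.reduced_chi_squared:.2f}")

aniso = fit_anisotropy(ds_pol, lifetime.model(),
                       HinderedRotatorModel(r0=0.35, r_inf=0.1, theta1=2.0), seed=0)
print("\nanisotropy fit (truth r0=0.32, r_inf=0.02, theta1=3.45):")
for name, value in aniso.estimates.items():
    print(f"  {name:>13} = {value:7.4f}")
lo, hi = confidence_limits(aniso, "theta1")
print(f"  theta1 67% CI = [{lo:.3f}, {hi:.3f}] ns")
print(f"  derived: f1={aniso.derived['f1']:.3f}  "
      f"R1={aniso.derived['R1']:.4f} rad/ns  S={aniso.derived['S']:.3f}")
print("\nS near 0.25 marks a disordered fluid bilayer; the CI reflects")
print("the injected measurement noise, not a tabulated uncertainty.")
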
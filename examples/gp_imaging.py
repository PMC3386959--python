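"""GP map and phase-coexistence call on a synthetic two-domain vesicle.

Renders a giant-vesicle equatorial ring whose two angular halves sit at
GP 0.45 (ordered, dehydrated) and -0.05 (fluid, hydrated) with Poisson
photon noise, computes the pixel-wise GP map, and asks whether the GP
histogram is better described by one or two Gaussian populations.
"""

from memphase import detect_phase_coexistence, fit_gp_histogram, gp_image
from memphase.simulate import VesicleImageRecipe, simulate_guv_image

recipe = VesicleImageRecipe(domain_gps=(0.45, -0.05), seed=11)
blue, red, truth = simulate_guv_image(recipe)
image = gp_image(blue, red)
print(f"ring pixels above threshold: {int(image.mask.sum())}")

n_phases, hist = detect_phase_coexistence(image)
print(f"phases detected: {n_phases}")
for center, width, amplitude in hist.fitted_components:
    print(f"  GP population: centre {center:+.3f}, width {width:.3f}, "
          f"amplitude {amplitude:.2f}")

single = fit_gp_histogram(image, n_components=1)
print(f"1- vs 2-Gaussian residual sum of squares: "
      f"{single.fit_rss:.3f} vs {hist.fit_rss:.3f}")
print("\nTwo well-separated centres near the domain truths (0.45 / -0.05)")
print("mean coexisting ordered and fluid liquid phases on one vesicle.")
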
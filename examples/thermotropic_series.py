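"""Immiscibility transition temperature from a thermotropic image series.

Simulates vesicle images every 4 degC from 20 to 60 degC with a liquid-
liquid coexistence onset at 33 degC: below onset each image carries two GP
domains, above it a single mixed phase.  The analysis calls one or two
phases per temperature and places the transition midway between the last
two-phase and first one-phase temperature.
"""

import numpy as np

from memphase import analyze_thermotropic_series, gp_image
from memphase.simulate import VesicleImageRecipe, simulate_thermotropic_series

t_grid = np.arange(20.0, 61.0, 4.0)
entries, truth = simulate_thermotropic_series(
    t_grid, t_onset=33.0, recipe=VesicleImageRecipe(domain_gps=(0.0,), seed=7))

images = [gp_image(blue, red) for _, blue, red in entries]
series = analyze_thermotropic_series(t_grid, images)

print("T (degC)  phases  GP centre(s)")
for t, n, hist in zip(series.temperatures, series.n_phases, series.histograms):
    centers = ", ".join(f"{c:+.3f}" for c in sorted(hist.centers))
    print(f"  {t:5.1f}     {n}     {centers}")

print(f"\ntrue onset: {truth['t_onset']} degC")
print(f"estimated T_mix: {series.transition_temperature} degC "
      f"(midpoint of the 2->1 phase boundary)")
print(f"GP at the transition: {series.gp_at_transition:+.3f}")
print("\nThe estimate lands within half a grid step of the onset; finer")
print("temperature grids tighten it proportionally.")
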
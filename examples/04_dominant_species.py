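"""Map potentially dominant species with cover-abundance calibration.

Softmax observation probabilities say which species a *record* likely
belongs to — a quantity inflated for over-reported species. Reweighting
each species so that its summed probability over survey plots equals its
summed cover-abundance percentage cancels that reporting bias; the
highest weighted probability per wooded pixel is then the potentially
dominant species. This example uses the generator's exact conditional
probabilities to isolate the calibration step itself; a trained network
adds its own fit error on top (see the methods note).
"""

import numpy as np

import multisdm as m
from multisdm.synth import conditional_probability_cube

bundle = m.make_demo_bundle(seed=42, n_species=8, size=32, n_obs=30_000, n_sites=100)

cube = conditional_probability_cube(
    bundle.landscape, bundle.species, np.arange(32, 335, 3)
)
weights = m.bias_correction_weights(bundle.surveys, cube)
print("species  reporting-rate rho  correction weight")
for sp, w in zip(bundle.species, weights.w):
    print(f"{sp.name}  {sp.rho:18.2f}  {w:17.1f}")

wooded = bundle.landscape.wooded
corrected = m.dominance_map(cube, weights, wooded)
raw = m.dominance_map(cube, None, wooded)
truth = bundle.truth_dominant_map()
agree_c = np.mean(corrected.winner[wooded] == truth[wooded])
agree_r = np.mean(raw.winner[wooded] == truth[wooded])
print(f"\nagreement with true dominant on {wooded.sum()} wooded pixels:")
print(f"  bias-corrected: {agree_c:.2f}")
print(f"  raw:            {agree_r:.2f}")
print("-> the correction weights undo the reporting rates (and the species'")
print("   seasonal and range characteristics), so the corrected map recovers the")
print("   true dominant far more often than the raw argmax, which mostly mirrors")
print("   observer preference.")
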
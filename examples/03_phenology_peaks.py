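"""Map the day of peak observation probability and compare with truth.

Daily predictions from March to September are smoothed with a 22-day
running mean per pixel; the day of the highest mode is a proxy for peak
flowering. In the virtual ecosystem the true peak day lags linearly with
elevation, so the recovered map should reproduce that gradient. The
generator's closed-form conditional probabilities act as a perfect-model
reference: they show how much of any shortfall is the trained network's
fit error rather than the mapping procedure.
"""

import numpy as np
from scipy.stats import spearmanr

import multisdm as m
from multisdm.synth import conditional_probability_cube

bundle = m.make_demo_bundle(seed=42, n_species=8, size=32, n_obs=30_000, n_sites=100)
training = m.TrainingConfig(loss="cel", phase1_epochs=5, phase2_max_epochs=10, seed=0)
model, _ = m.fit_model(
    bundle.observations.copy(), bundle.landscape.grid,
    training=training, width=64, n_blocks=2, seed=0,
)

days = np.arange(60, 274)
fitted = m.predict_cube(model, bundle.landscape.grid, days)
perfect = conditional_probability_cube(bundle.landscape, bundle.species, days)


def score(cube, sp):
    peaks = m.phenology_map(cube, sp.name, kernel=22, threshold=0.01)
    truth = m.truth_peak(bundle.landscape, sp)
    ok = ~np.isnan(peaks.t_peak)
    if ok.sum() < 20:
        return None
    return spearmanr(peaks.t_peak[ok], truth[ok]).statistic


print("species  lapse(d/100m)  r (perfect model)  r (trained)")
for sp in bundle.species:
    r_perfect, r_fit = score(perfect, sp), score(fitted, sp)
    print(f"{sp.name}  {sp.lapse:13.1f}  {r_perfect:17.2f}  {r_fit:11.2f}")
print("-> the mapping recovers the elevational phenology gradient essentially")
print("   perfectly from exact probabilities; with a small network and a short")
print("   training budget the trained model recovers it for most species, and")
print("   species with a weak lapse are the hardest to resolve.")
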
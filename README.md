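# multisdm

Multispecies neural distribution models for presence-only species
observations — with phenology mapping, cover-abundance-calibrated
dominance mapping, and climate-scenario projection.

## The problem

Citizen-science platforms produce millions of opportunistic plant
records: one species, one place, one day, and no information about
anything else that grew there. Such single-positive data carry strong
spatial (accessibility), seasonal, and taxonomic (observer-preference)
biases. `multisdm` models all species jointly with one deep network so
that biases shared across species cancel, and turns the fitted
spatiotemporal probabilities into ecological products that single-species
models cannot provide: maps of peak observation timing (a phenology
proxy), maps of potentially dominant species calibrated against
vegetation-plot cover, and projections under changed climate predictors.
It is written for ecologists and methodologists who want a compact,
fully scriptable implementation with a built-in virtual ecosystem whose
ground truth makes every pipeline stage testable end to end.

## The model

A residual multilayer network scores each taxon from the environmental
features of a cell plus two circular seasonal coordinates
`(sin θ, cos θ)`, `θ = 2π·doy/year_length`. The softmax over taxa is the
observation probability `P(taxon | record at x, t)`. Two cost functions
are available:

* cross-entropy (CEL), `−log softmax(s)_o` — strictly proper, so the
  fitted softmax converges to the true conditional probabilities;
* a single-positive lambda-NDCG ranking loss,
  `l(s) = −(1/D_rank(o)) Σ_{j≤n} log2 σ(s_o − s_{π_j})` with
  `D_i = log2(1+i)` and rank cap `n` (default 500) — it only asks the
  observed taxon to rank highly, making no claim about unobserved taxa.

Members trained with the two losses are ensembled by the square root of
the geometric mean. Downstream, daily predictions are smoothed with a
22-day running mean and the day of the highest mode per pixel gives the
phenology map; February–November mean probabilities, reweighted so that
per-taxon sums match summed cover-abundance percentages over survey
plots (`w_s = Σ cover_s / Σ p̄_s`), give the potentially-dominant-species
map; predictor deltas applied in raw units before rescaling, with
out-of-training-range cells flagged, give scenario projections.

## Worked example

`examples/04_dominant_species.py` builds a small virtual ecosystem
(8 species, 32×32 grid, 30,000 records, reporting rates spanning ~7×),
computes reporting-bias weights from 100 simulated vegetation plots,
and compares dominance maps with and without the correction against the
generator's true dominant species:

```
species  reporting-rate rho  correction weight
sp000                0.48              118.3
sp001                0.86               77.9
sp002                0.24              231.7
...
agreement with true dominant on 609 wooded pixels:
  bias-corrected: 0.95
  raw:            0.82
```

Under-reported species (small rho) receive the largest correction
weights, and the corrected argmax recovers the true dominant on 95 % of
wooded pixels versus 82 % for the raw probabilities. The other examples
cover simulation and bias structure (`01`), training and rank-based
evaluation (`02` — e.g. weighted median rank 2.0 of 8 taxa, top-5
accuracy 0.95 on held-out records), phenology-peak recovery (`03`), and
scenario projection with upslope dominance-band shifts (`05`). Each
example prints a closing line saying what its numbers mean.

A thin command-line interface wraps the same library for shell use:

```bash
multisdm --config config.yaml simulate --out sim/
multisdm --config config.yaml train --obs sim/observations.csv \
         --grid sim/predictors.npz --out model/
multisdm --config config.yaml phenology --model model/model.npz \
         --grid sim/predictors.npz --out phen/
```

Every stage writes a manifest (config snapshot, seed, input/output
checksums) next to its outputs.

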
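# c4drought

Quantify differential drought tolerance in two co-dominant C4 prairie
grasses — *Andropogon gerardii* (big bluestem) and *Schizachyrium scoparium*
(little bluestem) — by combining three lines of evidence:

1. **Field resilience** (`c4drought.resilience`). From a multi-decade panel
   of growing-season precipitation and annual flowering-stalk biomass,
   detrend and standardize both series, fit ARX(p) models for p ∈ {0, 1, 2}
   by ordinary least squares, pick p by BIC, and trace the impulse response
   of biomass to a 2σ precipitation deficit. The year-0 response is the
   species' **resistance**; the recovery path gives **return time** and
   **elasticity**.
2. **Gas-exchange physiology** (`c4drought.gas_exchange`). Relative water
   content and relative growth rate of greenhouse plants, plus rapid A–Ci
   response curves fitted with the monomolecular model
   `A = a − (a − b)·exp(−c·Ci)`. Evaluating the fitted demand curve at the
   Ci equivalent of 40 Pa atmospheric CO₂ (i.e., with stomatal drawdown
   removed) splits each drought leaf's photosynthetic loss into **relative
   stomatal limitation (RSL)** and **relative metabolic limitation (RML)**,
   which sum exactly to the total relative loss.
3. **Hierarchical Bayesian ANOVA** (`c4drought.bayes_anova`). A Gibbs
   sampler for `y ~ N(Xb, σ²)` with a shared shrinkage prior
   `b_j ~ N(0, σ_b²)`, `σ_b² ~ Gamma(2, 0.1)` on the non-intercept effects.
   Each effect and any user-defined cell contrast is reported with its
   posterior directional probability: Pr > 0.95 is flagged *significant*,
   Pr > 0.90 *moderate*.

`c4drought.synthetic` generates data from all three designs with known
ground truth, and `c4drought.pipeline` (plus the `drought-limits` CLI) runs
simulate → resilience → aci → anova end to end, deterministically from one
seed, with a provenance-stamped `report.json`.

## Worked example

```bash
drought-limits run-all --out demo_output --seed 42
```

or equivalently `python examples/full_pipeline.py`, which prints:

```
{'simulate': 'ok', 'resilience': 'ok', 'aci': 'ok', 'anova': 'ok'}
Andropogon gerardii: resistance -1.48 (truth -1.50), AR order 0
Schizachyrium scoparium: resistance -0.97 (truth -1.00), AR order 0
mean RSL = 31.3%, mean RML = 0.3% over 8 drought leaves
Andropogon gerardii: Pr(drought effect) = 1.000 [significant]
Schizachyrium scoparium: Pr(drought effect) = 0.746 [none]
```

The demo simulates the drought-sensitive species (*A. gerardii*, β = 0.75)
and the tolerant one (*S. scoparium*, β = 0.5); the pipeline recovers their
resistances (−2β), finds the photosynthetic loss of the simulated drought
leaves to be almost entirely stomatal, and flags a significant drought
effect on relative water content only for the sensitive species. Re-running
with the same seed reproduces every output file byte-for-byte.

Per-capability walkthroughs live in `examples/`:

- `examples/field_resistance.py` — ARX fit, BIC order selection, impulse
  response on one synthetic 38-year panel.
- `examples/aci_limitation.py` — monomolecular A–Ci fit and RSL/RML
  partition for one drought leaf.
- `examples/hierarchical_anova.py` — shrinkage ANOVA with the directional
  decision rule on a treatment × week factorial.
- `examples/full_pipeline.py` — the end-to-end demo above.

From Python:

```python
from c4drought import resilience, synthetic

panel = synthetic.gen_timeseries(
    synthetic.TimeSeriesTruth(n_years=38, beta=0.6, noise_sd=0.8, seed=7)
)
result = resilience.analyze_panel(panel, shock=-2.0, horizon=3)
print(result["order"], result["resistance"], result["return_time"])
```

## Documentation

`docs/methods.md` states the statistical models, estimation procedures,
numerical choices, and known limitations in full.
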
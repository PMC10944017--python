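"""Drought resistance of annual biomass from an ARX impulse response.

Generates a synthetic 38-year panel of growing-season precipitation and
standardized flowering-stalk biomass with a known precipitation coefficient
(beta = 0.6), then runs the field-data stage: detrend and standardize both
series, pick the autoregressive order by BIC, and summarize the impulse
response to a 2-sigma drought.
"""

import json

from c4drought import resilience, synthetic

truth = synthetic.TimeSeriesTruth(n_years=38, beta=0.6, phi=(),
                                  noise_sd=(1 - 0.6**2) ** 0.5,
                                  trend_slope=0.02, seed=7)
panel = synthetic.gen_timeseries(truth)
result = resilience.analyze_panel(panel, shock=-2.0, horizon=3)

print(json.dumps(result, indent=1))
print()
print(f"True beta = {truth.beta}; estimated beta = {result['beta']:.3f}.")
print(
    f"Resistance {result['resistance']:.2f} means a 2-sigma drought suppresses "
    "flowering-stalk biomass by that many standard deviations in the drought "
    f"year; the selected AR({result['order']}) model implies full recovery "
    f"after {result['return_time']} year(s)."
)
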
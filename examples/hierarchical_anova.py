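"""Hierarchical Bayesian two-way ANOVA with the directional decision rule.

Generates a treatment x week factorial for relative water content with a
known drought effect that grows over time, fits y ~ N(Xb, sigma^2) with the
shrinkage prior b ~ N(0, sigma_b^2), sigma_b^2 ~ Gamma(2, 0.1), and reports
the posterior probability that each effect is directional:
Pr > 0.90 is moderate evidence, Pr > 0.95 significant.
"""

from c4drought import synthetic
from c4drought.bayes_anova import MCMCSettings, anova_report

means = {}
for tr in ("control", "drought"):
    for wk in (4, 7):
        means[("Andropogon gerardii", tr, wk)] = (
            0.92 if tr == "control" else 0.92 - 0.05 * wk
        )
truth = synthetic.FactorialTruth(
    species=("Andropogon gerardii",), treatments=("control", "drought"),
    weeks=(4, 7), cell_means=means, n_reps=13, residual_sd=0.08, seed=1,
)
table = synthetic.gen_factorial(truth, response_name="RWC")

report = anova_report(
    table, response="value", factors=["treatment", "week"], interaction=True,
    mcmc=MCMCSettings(n_chains=4, n_warmup=1000, n_samples=1000, seed=11),
    cell_contrasts=[{
        "name": "drought < control | week 7",
        "a": {"treatment": "drought", "week": 7},
        "b": {"treatment": "control", "week": 7},
        "direction": "<0",
    }],
)

for c in report["contrasts"]:
    print(f"{c['label']:35s} Pr({c['direction']}) = {c['pr']:.3f}  [{c['significance']}]")
print(f"converged: {report['converged']} (all split-Rhat <= 1.05)")
print()
print("The drought main effect and its week-7 interaction should be flagged "
      "significant: the simulated water limitation deepens with time, as in "
      "a progressive dry-down.")
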
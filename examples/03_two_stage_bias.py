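"""Show the bias of the two-stage shortcut against the joint model.

Simulates 10 replicate cohorts, estimates the outcome loadings on the
individual mean level, slope and log-variability by (a) the joint model
and (b) the two-stage summary regression, and prints per-method bias and
RMSE.  The headline contrast: with a handful of visits the two-stage
log-variability loading is strongly attenuated toward zero, while the
joint estimate stays close to the truth.
"""

from melsjm import GeneratorConfig
from melsjm.synthetic_data import model_a_params, model_a_spec
from melsjm.two_stage_baseline import bias_experiment

cfg = GeneratorConfig(
    n_individuals=600, spec=model_a_spec(), true_params=model_a_params(),
)
results, summary = bias_experiment(cfg, n_replicates=10, seed=7)

truth = results.groupby("loading")["truth"].first()
print("true loadings:")
print(truth.round(4).to_string())
print("\nbias and RMSE by method:")
print(summary.round(4).to_string(index=False))
print("\nThe log-variability loading (gamma_log_scale) is the one the")
print("two-stage procedure estimates worst: its per-individual variance")
print("summaries carry large sampling noise, which attenuates the")
print("regression coefficient toward zero.")
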
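"""Recovery of the simulated relative damaging rate r by its MLE.

Simulates cohorts of 5000 cases at r = 1, 5 and 10 and compares the mean
maximum-likelihood estimate r_hat against the simulated value.  Close
agreement shows the estimator is usable as an effect-size readout, not just
a test statistic.
"""

from dnmload.simulate import SimulationConfig, recovery_experiment

config = SimulationConfig(seed=51, n_cases=5000, n_reps=200, r_grid=(1, 5, 10))
table = recovery_experiment(config)
print(table.to_string(index=False))
print(
    "\nmean_r_hat should sit within ~15% of r_true; the RMSE reflects the "
    "Poisson noise of small per-cohort mutation counts."
)
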
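"""Why randomized context/target subsampling protects against overfitting.

Trains two CNPs with identical architecture and epochs on the same
synthetic molecular meta-dataset: one samples 5% of each task's
observations as contexts/targets per iteration, the other uses 100%
(with overlap allowed).  Test-task negative log predictive density
(NLPD, lower is better) shows the full-fraction model overfitting.
"""

from molnp.experiments import overfitting_sweep

res = overfitting_sweep(seed=0, n_tasks=12, n_molecules=150, epochs=40)
print(f"test-task NLPD, 5% fraction:   {res[0.05]:.3f}")
print(f"test-task NLPD, 100% fraction: {res[1.0]:.3f}")
# The 100%-fraction model sees every datapoint every epoch (high
# effective epochs), memorizes the training tasks and loses calibration
# on held-out tasks — its NLPD is visibly worse.
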
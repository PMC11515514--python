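"""Uncertainty calibration on a synthetic molecular meta-dataset.

Meta-trains a CNP on synthetic docking-score-like tasks (sparse linear
functions of fingerprint bits with a 70% shared component), then checks
on held-out tasks whether predicted variance tracks realized error:
targets are ranked by predicted variance into confidence percentiles
and the Pearson correlation of log mean MSE vs log mean variance is
reported, before and after fine-tuning.

Takes a few minutes at a reduced problem size.
"""

from molnp.experiments import calibration_study

res = calibration_study(seed=0, n_tasks=20, n_molecules=300, epochs=40,
                        n_test_tasks=3, n_contexts=100)
print(f"calibration correlation before fine-tuning: "
      f"{res['corr_before']:.3f}")
print(f"calibration correlation after fine-tuning:  "
      f"{res['corr_after']:.3f}")
# Correlations near 1 mean the model knows where it is wrong: its most
# confident percentiles really do have the lowest squared error.
# Fine-tuning shifts the weights but should keep this ordering intact.
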
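"""Effective-epoch accounting.

When only C contexts and T targets are subsampled from a task's O
observations each epoch, a given datapoint is seen on average
e_e = e * n_bar / O times over e epochs (n_bar = C + T).  This script
verifies the formula empirically by counting actual views.
"""

from molnp.experiments import effective_epoch_count
from molnp.meta_train import effective_epochs

res = effective_epoch_count(seed=0, O=200, C=20, T=20, epochs=2000)
print(f"predicted effective epochs:  {res['predicted']:.1f}")
print(f"empirical mean views/point:  {res['empirical_mean_views']:.1f}")
print(f"relative error:              {100 * res['relative_error']:.2f}%")
print(f"formula check: e_e(10, 250, 2500) = "
      f"{effective_epochs(10, 250, 2500)}")
# Matching counts confirm the ledger used to compare training budgets
# across tasks of very different sizes, and to size fine-tuning runs.
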
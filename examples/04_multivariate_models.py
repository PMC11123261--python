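"""PLS-DA with permutation validation plus a random-forest classifier.

Fits the multivariate arm on a pretreated table and prints the model
quality panel: R2 (fit), Q2 (7-fold cross-validated prediction),
permutation p-values (99 scrambles here for speed; the workflow default is
1000) and the random forest's out-of-bag AUC, then the top features by
VIP and mean decrease in accuracy.
"""

import pandas as pd

from metabofinger import GeneratorConfig, RunConfig, generate_run, run_pretreatment
from metabofinger.multivariate import evaluate_models, plsda_fit

cfg = GeneratorConfig(
    n_features=400, n_differential=25, n_contaminant=12,
    platform_modes=("hilic_pos",), seed=4,
)
table, truth = generate_run(cfg, batch=1, platform_mode="hilic_pos")
pre = run_pretreatment(table, RunConfig(seed=4))

bio = pre.table.columns_of("biological")
X = pre.table.intensities[bio].T
y = pre.table.samples.loc[bio, "group"].to_numpy()

rc = RunConfig(seed=4, n_permutations=99)
evaluation, model = evaluate_models(X, y, rc)
print({k: round(v, 4) for k, v in evaluation.to_dict().items()})

top = pd.DataFrame({"vip": model.vip_series(), "mda": evaluation.mda})
top["truly_differential"] = top.index.isin(truth.differential_ids)
print("\ntop 8 features by VIP:")
print(top.sort_values("vip", ascending=False).head(8).round(3).to_string())
print("\nhigh R2/Q2 with permutation p-values at the floor (1/(n+1)) and "
      "OOB AUC 1 mean the class separation is real, not overfitting; the "
      "VIP/MDA ranking concentrates on the truly differential features.")
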
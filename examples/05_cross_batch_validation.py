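"""End-to-end cross-batch validated selection scored against ground truth.

Generates two independent replicate batches, analyzes each (pretreatment,
univariate and multivariate arms), matches features across batches by
m/z-RT, and keeps only features selected in both batches with a
consistent fold-change direction. Prints sensitivity and FDR of the
validated set next to the single-batch selections.
"""

import json

from metabofinger import GeneratorConfig, RunConfig, analyze_experiment, generate_run

cfg = GeneratorConfig(
    n_features=300, n_differential=25, n_contaminant=10,
    platform_modes=("hilic_pos",), seed=5,
)
batch1, truth = generate_run(cfg, batch=1, platform_mode="hilic_pos")
batch2, _ = generate_run(cfg, batch=2, platform_mode="hilic_pos")

rc = RunConfig(seed=5, n_permutations=99)
result = analyze_experiment(batch1, batch2, rc)

print(f"matched {result.matches['feature_id_2'].notna().sum()} of "
      f"{len(result.matches)} batch-1 features across batches")
print(f"validated features: {len(result.validated_ids)}")
print(json.dumps(result.metrics(truth), indent=1))
print("\nthe validated set's FDR sits far below either single batch's - "
      "replication is the workflow's main false-positive guard, paid for "
      "with a moderate sensitivity cost.")
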
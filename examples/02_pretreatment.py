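"""Run the full pretreatment chain and inspect what each stage removed.

Drift correction, blank/presence/RSD filtering, random-forest imputation,
log transform, PQN normalization and Pareto scaling, with a per-stage
feature-count report and the drift-correction summary.
"""

from metabofinger import GeneratorConfig, RunConfig, generate_run, run_pretreatment

cfg = GeneratorConfig(
    n_features=400, n_differential=25, n_contaminant=12,
    platform_modes=("hilic_pos",), seed=2,
)
table, _ = generate_run(cfg, batch=1, platform_mode="hilic_pos")
result = run_pretreatment(table, RunConfig(seed=2))

print(result.report.summary().to_string(index=False))

drift = result.drift_model.per_feature
print(f"\ndrift correction applied to {int(drift['applied'].sum())} of "
      f"{len(drift)} features (kept only where it lowers the QC RSD out-of-sample)")
applied = drift[drift["applied"]]
if len(applied):
    print(f"median QC RSD of corrected features: "
          f"{applied['qc_rsd_before'].median():.1f}% -> "
          f"{applied['qc_rsd_after'].median():.1f}%")
print("\nthe contaminant features vanish at the blank filter; the final table "
      "is imputed, normalized and Pareto-scaled, ready for modelling.")
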
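"""Run the whole analysis end to end on a synthetic cohort.

simulate -> diet scoring -> GRS -> case/control classification -> GEE ->
interaction measures, with a case/control comparison table, exclusion log
and reproducibility manifest.
"""

from amdgxe import run_pipeline

bundle = run_pipeline(
    {"simulate": {"n_subjects": 612, "seed": 6}, "bootstrap": {"n_boot": 200, "seed": 6}},
    out_dir="scratch/example_pipeline",
)

print("case/control comparison (first rows):")
print(bundle["table1"].head(8).to_string(index=False))
print("\nadjusted ORs (no interaction term):")
print(bundle["main_ors"].round(3))
print("\nadditive interaction (delta CIs):")
print(bundle["interaction"].additive_delta.round(3))
print("\nmanifest:", {k: bundle["manifest"][k] for k in
                      ("n_subjects_input", "n_subjects_retained", "n_eyes", "n_excluded")})
print("\nOutputs (CSV/JSON) were written to scratch/example_pipeline/.")
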
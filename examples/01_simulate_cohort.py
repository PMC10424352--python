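"""Generate a synthetic AMD case-control cohort and write its input files.

Builds a 612-subject cohort — Hardy-Weinberg genotypes over 52 variants,
food-frequency answers, paired-eye outcomes — and writes the five
pipeline inputs (FFQ, food catalog, variant weights, VCF genotypes,
phenotypes) plus a manifest.
"""

from amdgxe import SimulationConfig, write_cohort

paths = write_cohort(SimulationConfig(n_subjects=612, seed=1), "scratch/example_cohort")
for name, path in paths.items():
    print(f"{name:12s} {path}")
print("\nEach file is one pipeline input; the manifest records the config and "
      "seed so the cohort can be regenerated exactly.")
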
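"""Two-cohort comparison with an injected allele-frequency difference.

The original patient genotypes are not public, so this example emulates a
case/control contrast: a 'shifted' cohort enriched for low-expression MAOA
uVNTR alleles versus a cohort at the published frequencies.  It runs both
through the model and applies the nonparametric battery (Mann-Whitney U,
Cohen's d, post hoc power) to the per-individual species means.
"""

import pandas as pd

from serosim import CALIBRATED_SCALE, CohortSpec, sample_cohort, simulate_cohort
from serosim.stats import compare_groups

control = CohortSpec(n=120, seed=1, group_label="control")
shifted = CohortSpec(
    n=120,
    seed=2,
    group_label="low_maoa",
    allele_freqs={
        **control.resolved_freqs(),
        "uVNTR": {"3R": 0.60, "3.5R": 0.004, "4R": 0.387, "5R": 0.009},
    },
)

records = sample_cohort(control) + sample_cohort(shifted)
means = simulate_cohort(records, scale=CALIBRATED_SCALE)

group_means = means.groupby("group")[["fc5ht_mean", "hiaa5_mean"]].mean()
print("group means (µM):")
print(group_means.round(4), "\n")

results = compare_groups(means, species_cols=["fc5ht_mean", "v5ht_mean", "hiaa5_mean"])
print(results[["species", "statistic", "p_value", "effect_size_d", "power"]].round(4))
print(
    "\nEnriching low-expression MAOA alleles lowers the degradation product\n"
    "5-HIAA and leaves more serotonin in the cell; the p-values and effect\n"
    "sizes quantify how detectable that shift is at this sample size."
)
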
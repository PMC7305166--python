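"""Draw the synthetic study cohorts and summarize their structure.

Emulates the study population: a 678-subject main cohort (BMI mixture
straddling the 30 kg/m² obesity cut, male-majority gender split, log-normal
serum biomarkers with correlated adiponectin isoforms, planted IPFP-volume
generator) and an 80-subject external validation cohort with a
female-majority split and shifted BMI profile.

Full cohort CSVs go to scratch/ (they are regenerable from the seed);
results/ gets the per-stratum summary table.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ipfpvol.pipeline import stratify, split_gender
from ipfpvol.synth import CohortSpec, cohort_to_csv, generate_cohort, generate_validation_cohort

SEED = 0
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    base = CohortSpec(seed=SEED)
    cohort = generate_cohort(base)
    external = generate_validation_cohort(base, seed=SEED + 1)
    cohort_to_csv(cohort, SCRATCH / f"cohort_seed{SEED}.csv")
    cohort_to_csv(external, SCRATCH / f"external_seed{SEED + 1}.csv")

    rows = []
    for name, sub in stratify(cohort).items():
        genders = split_gender(sub)
        rows.append(
            {
                "cohort": name,
                "n": len(sub),
                "n_female": len(genders[0]),
                "n_male": len(genders[1]),
                "bmi_mean": sub["bmi"].mean(),
                "ipfp_volume_mean_mm3": sub["ipfp_volume"].mean(),
            }
        )
    rows.append(
        {
            "cohort": "External",
            "n": len(external),
            "n_female": (external["gender"] == 0).sum(),
            "n_male": (external["gender"] == 1).sum(),
            "bmi_mean": external["bmi"].mean(),
            "ipfp_volume_mean_mm3": external["ipfp_volume"].mean(),
        }
    )
    table = pd.DataFrame(rows).round(1)
    table.to_csv(RESULTS / "cohort_summary.csv", index=False)
    print(table.to_string(index=False))

    r = np.corrcoef(
        np.log(cohort["adiponectin_HMW"]), np.log(cohort["adiponectin_LMW"])
    )[0, 1]
    print(f"\nlog HMW-LMW adiponectin correlation: {r:.2f} (planted 0.58)")
    male_gap = (
        cohort.loc[cohort.gender == 1, "ipfp_volume"].mean()
        - cohort.loc[cohort.gender == 0, "ipfp_volume"].mean()
    )
    print(f"male-female mean IPFP volume gap: {male_gap:.0f} mm³ (positive by construction)")


if __name__ == "__main__":
    main()
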
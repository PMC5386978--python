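"""Generate the two study cohorts and tabulate their programmed structure.

Produces the lifespan sample (29 subjects, 15 female, ages 4-22 y) used to
model healthy brain aging, and the young-adult experimental sample (5/5
female CTR/MNR, 7/6 male) carrying the programmed maternal-nutrient-
restriction GM deficit in females.  Writes metadata and per-sex summary
tables under results/.
"""

from pathlib import Path

import pandas as pd

import primage as pm

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

params = pm.AgingModelParams()
lifespan = pm.generate_cohort(params, n_per_sex=(15, 14), master_seed=SEED)
experiment = pm.generate_experiment_cohort(params, master_seed=SEED + 1)

cols = ["id", "sex", "age", "group", "birth_weight", "weight_at_scan"]
lifespan.metadata[cols].to_csv(OUT / "lifespan_metadata.csv", index=False)
experiment.metadata[cols].to_csv(OUT / "experiment_metadata.csv", index=False)

rows = []
for sex in ("female", "male"):
    sub = lifespan.metadata[lifespan.metadata["sex"] == sex]
    rows.append({
        "sex": sex, "n": len(sub),
        "age_mean": sub["age"].mean(), "age_sd": sub["age"].std(ddof=1),
        "tiv_mean_ml": sub["tiv_true_ml"].mean(),
        "tiv_sd_ml": sub["tiv_true_ml"].std(ddof=1),
        "gm_frac_mean": sub["gm_frac_true"].mean(),
        "gm_frac_sd": sub["gm_frac_true"].std(ddof=1),
    })
summary = pd.DataFrame(rows).round(3)
summary.to_csv(OUT / "lifespan_summary.csv", index=False)

print(f"lifespan cohort: n={lifespan.n} "
      f"({(lifespan.metadata['sex'] == 'female').sum()} female), "
      f"ages {lifespan.metadata['age'].min():.1f}-"
      f"{lifespan.metadata['age'].max():.1f} y")
print(f"experiment cohort: n={experiment.n}, cells "
      f"{experiment.metadata.groupby(['sex', 'group']).size().to_dict()}")
print(summary.to_string(index=False))
print(f"tables written to {OUT}")
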
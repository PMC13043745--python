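"""Regional nonsense constraint on a synthetic cohort.

Simulates a transcriptome in which nonsense variants are strongly removed
from distal regions (90%) and NMD-target regions (70%), calibrates scaled
mutation rates on the synonymous background, and tests each transcript
region for depletion with the Poisson-binomial model.
"""

from nmdconstraint.constraint import compute_constraint
from nmdconstraint.mutation_model import calibrate_scaled_rates
from nmdconstraint.synthetic_data import SimConfig, simulate_cohort, simulate_transcriptome

cfg = SimConfig(
    seed=42,
    n_transcripts=80,
    s_region={"nmd_target": 0.7, "distal": 0.9},  # fraction of nonsense removed
)
study = simulate_transcriptome(cfg)
cohort = simulate_cohort(study)

background = cohort[cohort["consequence"] == "synonymous"]
curve = calibrate_scaled_rates(
    background["raw_rate"].to_numpy(), background["observed"].to_numpy()
)
cohort = cohort.assign(scaled_rate=curve.lookup(cohort["raw_rate"].to_numpy()))

results = compute_constraint(cohort)
print(results.head(8).to_string(index=False))

by_region = results.groupby("region")["classification"].value_counts().unstack(fill_value=0)
print("\nclassification by region:")
print(by_region.to_string())
print(
    "\n-> regions simulated under selection (nmd_target, distal) yield\n"
    "   constrained calls (low O/E, OE95 < 0.6, FDR < 0.05); neutral\n"
    "   regions are unconstrained or indeterminate when small."
)
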
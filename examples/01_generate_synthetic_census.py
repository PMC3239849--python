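"""Generate a small synthetic DA-level census and inspect its structure.

Each row is one dissemination area (DA, ~400-700 residents) with per-sex,
per-indicator aggregate numerators and denominators plus mean employment
incomes — the same aggregate shape a census extract would provide.
"""

from genineq import GeneratorConfig, generate_census

config = GeneratorConfig(n_das=300, n_missing=3, n_single_sex=2,
                         n_zero_labour=2, seed=11)
census = generate_census(config)

print(f"{len(census)} DAs, {census.shape[1]} columns")
print(census[["da_id", "area_type", "pop_f", "pop_m",
              "divorce_num_f", "divorce_den_f",
              "income_mean_f", "income_mean_m"]].head().to_string(index=False))
print("\narea types:", census["area_type"].value_counts().to_dict())
# The num/den pairs are aggregate person counts; filters downstream must
# cope with the 3 missing-data DAs, 2 single-sex DAs and 2 zero-labour DAs
# planted here.
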
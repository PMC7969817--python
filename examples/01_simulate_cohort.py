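"""Generate a multi-study synthetic cohort and inspect its planted truth.

Builds a 3-study cohort with healthy/IBD/MS/RA labels, a shared 15-taxon
autoimmunity signature, per-study batch taxa, and a matched metabolome,
then prints what was planted where.
"""
from autosig.synthetic_data import SimulationConfig, generate_cohort, generate_metabolome

config = SimulationConfig(seed=42)
profile, metadata, truth = generate_cohort(config)
metabolome = generate_metabolome(profile, truth, config)

print(f"cohort: {profile.n_samples} samples x {profile.n_taxa} taxa "
      f"({metadata['study_id'].nunique()} studies)")
print("class sizes:", metadata["disease"].value_counts().to_dict())
print("library sizes:", int(profile.data.sum(axis=1).min()), "-",
      int(profile.data.sum(axis=1).max()), "reads")
for disease, taxa in sorted(truth.disease_taxa.items()):
    print(f"planted {disease} signature: {len(taxa)} taxa")
for study, taxa in sorted(truth.batch_taxa.items()):
    print(f"batch taxa in {study}: {len(taxa)}")
print(f"metabolome: {metabolome.shape[1]} metabolites, "
      f"{len(truth.metabolite_links)} planted links at |rho| ~ {config.link_strength}")
# Every number above is ground truth the downstream stages must recover:
# disease taxa should top the consensus ranking, batch taxa should be
# flagged by the study model, links should survive BH correction.
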
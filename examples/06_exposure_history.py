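"""Exposure-history accounting: colonization, migration, persistence.

Quantifies which soil species established in the gut, how far each
mouse's community moved across the Day-60 environmental shift, and which
birthplace markers persisted with a consistent direction.
"""

import numpy as np

from soiltrace import (
    AbundanceTable,
    SyntheticConfig,
    colonization_report,
    generate_study,
    kruskal_screen,
    marker_set,
    migration_magnitude,
    persistence,
    shared_features,
    source_attribution,
)

study = generate_study(SyntheticConfig(seed=3, n_mice_per_group=15))
recs60 = study.gut_records(60)
gut60 = [r.sample_id for r in recs60]
gut90 = [r.sample_id for r in study.gut_records(90)]
t60 = study.taxa_day60.subset_samples(gut60)
t90 = study.taxa_day90.subset_samples(gut90)

print("colonization (soil species establishing in the gut):")
for env, soil in study.soil_profiles.items():
    group = [r.sample_id for r in recs60 if r.birthplace.value == env]
    rep = colonization_report(soil, t60.subset_samples(group), environment=env)
    print(
        f"  {env:7s}: {rep.established_count}/{rep.soil_species_count} species "
        f"({100 * rep.established_fraction_of_soil_count:.1f}%), carrying "
        f"{100 * rep.mean_gut_abundance_fraction:.1f}% of gut abundance"
    )

mig = migration_magnitude(t60, t90, study.records)
print("\nmean Day-60->90 JSD by birthplace (drift after the environment shift):")
for env, v in sorted(mig.group_means.items(), key=lambda kv: kv[1]):
    print(f"  {env:7s}: {v:.3f}")

def screen(table, labels, name):
    feats = shared_features(table, labels)
    df = table.data[feats]
    sub = AbundanceTable(df.div(df.sum(axis=1), axis=0), "taxon", "relative")
    return marker_set(kruskal_screen(sub, labels), name, 0.05)

bp60 = np.array([r.birthplace.value for r in recs60])
bp90 = np.array([r.birthplace.value for r in study.gut_records(90)])
rep = persistence(screen(t60, bp60, "birthplace@60"), screen(t90, bp90, "birthplace@90"))
print(
    f"\npersistence: {rep.n_consistent} of {rep.n_day60} Day-60 birthplace markers "
    f"({100 * rep.persistence_fraction_day60:.0f}%) still marked birthplace at Day 90 "
    "with the same direction"
)

control = [r for r in study.gut_records(90) if r.birthplace == r.current_env][:3]
print("\nsource attribution for control mice (Day-60 community explains Day-90):")
for r in control:
    a = source_attribution(
        study.taxa_day60.data.loc[f"{r.mouse_id}_d60"],
        study.taxa_day90.data.loc[r.sample_id],
        mouse_id=r.mouse_id,
    )
    print(f"  {r.mouse_id}: {100 * a.fraction_attributed:.2f}%")
print(
    "\nAttribution near 100% in untransferred mice is the contamination "
    "check: their Day-90 communities are explained by what was already "
    "there at Day 60."
)
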
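"""Birthplace-marker screening: rank tests for taxa, NB test for KOs.

Runs the Kruskal-Wallis screen (taxa shared across groups, BH-corrected)
and the negative-binomial count test on a synthetic study with planted
4-fold group effects, then compares the detected markers with the truth.
"""

import numpy as np

from soiltrace import (
    AbundanceTable,
    SyntheticConfig,
    aggregate_to_ko,
    generate_study,
    kruskal_screen,
    marker_set,
    nb_test,
    shared_features,
)

study = generate_study(SyntheticConfig(seed=2, n_mice_per_group=15))
gut60 = [r.sample_id for r in study.gut_records(60)]
taxa = study.taxa_day60.subset_samples(gut60)
labels = np.array([r.birthplace.value for r in study.gut_records(60)])

feats = shared_features(taxa, labels)
df = taxa.data[feats]
shared = AbundanceTable(df.div(df.sum(axis=1), axis=0), "taxon", "relative")
taxa_markers = marker_set(kruskal_screen(shared, labels), "birthplace@60", alpha=0.05)
planted = study.truth.taxon_markers
hits = sum(1 for m in taxa_markers.markers if planted.get(m.feature_id) == m.enriched_group)
print(
    f"taxa: {len(feats)} shared species tested, {len(taxa_markers)} markers at q<0.05; "
    f"{hits}/{len(planted)} planted markers recovered with the right direction"
)

ko_counts, _ = aggregate_to_ko(study.gene_counts_day60, study.catalog)
ko_counts = ko_counts.subset_samples(gut60)  # align rows with the labels
ko_markers = marker_set(nb_test(ko_counts, labels), "birthplace@60", alpha=0.05)
ko_planted = study.truth.ko_markers
ko_hits = sum(1 for m in ko_markers.markers if ko_planted.get(m.feature_id) == m.enriched_group)
print(
    f"KOs:  {len(ko_counts.feature_ids)} tested, {len(ko_markers)} markers at q<0.05; "
    f"{ko_hits}/{len(ko_planted)} planted KO markers recovered"
)
print(
    "\nSensitivity near 1 with few extra detections shows both screens "
    "recover the planted group signals at the configured effect size."
)
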
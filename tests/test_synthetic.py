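"""Synthetic-study generator: determinism, invariants, planted structure."""

import numpy as np
import pandas as pd
import pytest

from soiltrace import SyntheticConfig, generate_study, jsd
from soiltrace.datamodel import ValueKind


def small_config(**kw):
    defaults = dict(seed=3, n_mice_per_group=4, n_kos=200, n_pathways=12,
                    n_planted_enriched_pathways=4)
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        a = generate_study(small_config())
        b = generate_study(small_config())
        pd.testing.assert_frame_equal(a.taxa_day60.data, b.taxa_day60.data)
        pd.testing.assert_frame_equal(a.gene_counts_day90.data, b.gene_counts_day90.data)
        assert a.truth.taxon_markers == b.truth.taxon_markers

    def test_different_seed_differs(self):
        a = generate_study(small_config(seed=3))
        b = generate_study(small_config(seed=4))
        assert not a.taxa_day60.data.equals(b.taxa_day60.data)

    def test_ko_size_does_not_perturb_taxon_stream(self):
        a = generate_study(small_config(n_kos=200))
        b = generate_study(small_config(n_kos=300))
        pd.testing.assert_frame_equal(a.taxa_day60.data, b.taxa_day60.data)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_mice_per_group": 1},
            {"drift_rate": {"desert": 1.5, "steppe": 0.1, "forest": 0.2}},
            {"persistence_fraction_planted": 2.0},
            {"nb_dispersion": 0.0},
            {"n_planted_enriched_pathways": 99},
            {"colonization_fraction": {"desert": 0.1, "steppe": 0.5, "forest": 0.5}},
        ],
    )
    def test_invalid_configs_rejected_before_output(self, kw):
        with pytest.raises(ValueError):
            generate_study(small_config(**kw))


class TestEmittedTables:
    def test_relative_invariants_hold(self):
        st = generate_study(small_config())
        for t in (st.taxa_day60, st.taxa_day90):
            assert t.value_kind is ValueKind.RELATIVE
            assert np.allclose(t.values.sum(axis=1), 1.0, atol=1e-9)
            assert (t.values >= 0).all()

    def test_counts_are_integral(self):
        st = generate_study(small_config())
        assert np.allclose(st.gene_counts_day60.values % 1, 0)

    def test_manifest_matches_design(self):
        st = generate_study(small_config())
        gut90 = st.gut_records(90)
        transferred = [r for r in gut90 if r.birthplace != r.current_env]
        # 2/3 of mice transferred, split between the two other environments
        assert len(transferred) == round(2 / 3 * 4) * 3
        assert len(gut90) == 12

    def test_colonizer_counts_echo_config(self):
        st = generate_study(small_config())
        cfg = st.config
        for env in ("desert", "steppe", "forest"):
            expected = round(cfg.colonization_fraction[env] * cfg.pool_sizes[env])
            assert len(st.truth.colonizers[env]) == expected

    def test_soil_species_pools_have_configured_sizes(self):
        st = generate_study(small_config())
        for env, size in st.config.pool_sizes.items():
            assert (st.soil_profiles[env] > 0).sum() == size


class TestPlantedStructure:
    def test_marker_counts_and_directions(self):
        st = generate_study(small_config())
        counts = {g: 0 for g in ("desert", "steppe", "forest")}
        for g in st.truth.taxon_markers.values():
            counts[g] += 1
        assert counts == st.config.n_planted_taxon_markers
        assert set(st.truth.persistent_taxa) <= set(st.truth.taxon_markers)

    def test_marker_fold_realized_in_group_means(self):
        st = generate_study(small_config(n_mice_per_group=25))
        t = st.taxa_day60
        bp = {r.sample_id: r.birthplace.value for r in st.gut_records(60)}
        labels = np.array([bp[s] for s in t.sample_ids])
        for marker, group in list(st.truth.taxon_markers.items())[:8]:
            col = t.data[marker].to_numpy()
            own = col[labels == group].mean()
            rest = col[labels != group].mean()
            assert own > 2.0 * rest  # 4-fold planted, Dirichlet-noised

    def test_zero_drift_keeps_day90_near_day60(self):
        cfg_still = small_config(
            drift_rate={"desert": 0.0, "steppe": 0.0, "forest": 0.0},
            transfer_fraction=0.0,
            persistence_fraction_planted=1.0,
        )
        st = generate_study(cfg_still)
        jsds = []
        for r60, r90 in zip(st.gut_records(60), st.gut_records(90)):
            jsds.append(
                jsd(
                    st.taxa_day60.data.loc[r60.sample_id].to_numpy(),
                    st.taxa_day90.data.loc[r90.sample_id].to_numpy(),
                )
            )
        # residual JSD is pure Dirichlet resampling noise
        drifted = generate_study(small_config(transfer_fraction=0.0))
        jsds_drift = [
            jsd(
                drifted.taxa_day60.data.loc[r60.sample_id].to_numpy(),
                drifted.taxa_day90.data.loc[r90.sample_id].to_numpy(),
            )
            for r60, r90 in zip(drifted.gut_records(60), drifted.gut_records(90))
            if r60.birthplace.value == "forest"
        ]
        assert np.mean(jsds) < np.mean(jsds_drift)

    def test_null_effect_fold_gives_alpha_level_detections(self, rng):
        # fold 1 plants nothing: the Day-60 screen should fire at ~alpha
        from soiltrace.differential import kruskal_screen, marker_set, shared_features
        from soiltrace.datamodel import AbundanceTable

        st = generate_study(small_config(taxon_effect_fold=1.0, n_mice_per_group=8))
        t = st.taxa_day60
        bp = {r.sample_id: r.birthplace.value for r in st.gut_records(60)}
        labels = np.array([bp[s] for s in t.sample_ids])
        feats = shared_features(t, labels)
        df = t.data[feats]
        sub = AbundanceTable(df.div(df.sum(axis=1), axis=0), t.feature_kind, ValueKind.RELATIVE)
        markers = marker_set(kruskal_screen(sub, labels), "birthplace@60", 0.05)
        # BH at 5% on ~140 null features: a handful of hits at most
        assert len(markers) <= 0.05 * len(feats) + 3
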
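"""Colonization accounting, migration magnitude, persistence, attribution."""

import numpy as np
import pandas as pd
import pytest

from soiltrace import (
    Environment,
    SampleRecord,
    SampleType,
    colonization_report,
    migration_magnitude,
    persistence,
    source_attribution,
)
from soiltrace.differential import DifferentialFeature, MarkerSet

from conftest import make_relative


def mset(name, features, alpha=0.05):
    return MarkerSet(
        grouping_name=name,
        alpha=alpha,
        markers=[DifferentialFeature(f, 0.001, 0.01, d, {}) for f, d in features.items()],
    )


class TestColonization:
    def test_basic_accounting(self):
        soil = pd.Series({"A": 0.5, "B": 0.3, "C": 0.2})
        gut = make_relative([[0.7, 0.3, 0.0]], feature_ids=["A", "B", "C"])
        rep = colonization_report(soil, gut)
        assert rep.established_species == {"A", "B"}
        assert rep.established_fraction_of_soil_count == pytest.approx(2 / 3)
        assert rep.established_soil_abundance_fraction == pytest.approx(0.8)
        assert rep.mean_gut_abundance_fraction == pytest.approx(1.0)

    def test_no_shared_species(self):
        soil = pd.Series({"X": 1.0})
        gut = make_relative([[1.0]], feature_ids=["A"])
        rep = colonization_report(soil, gut)
        assert rep.established_species == set()
        assert rep.established_soil_abundance_fraction == 0.0
        assert rep.mean_gut_abundance_fraction == 0.0

    def test_impossible_threshold_empties_established(self):
        soil = pd.Series({"A": 0.6, "B": 0.4})
        gut = make_relative([[0.5, 0.5]], feature_ids=["A", "B"])
        rep = colonization_report(soil, gut, detection_threshold=1.0)
        assert rep.established_count == 0

    def test_min_samples(self):
        soil = pd.Series({"A": 0.6, "B": 0.4})
        gut = make_relative([[1.0, 0.0], [0.5, 0.5]], feature_ids=["A", "B"])
        rep = colonization_report(soil, gut, min_samples=2)
        assert rep.established_species == {"A"}


class TestPersistence:
    def test_consistent_direction_required(self):
        day60 = mset("birthplace@60", {"A": "steppe", "B": "desert", "C": "forest"})
        day90 = mset("birthplace@90", {"A": "steppe", "B": "forest", "D": "steppe"})
        rep = persistence(day60, day90)
        assert rep.consistent_markers == {"A": "steppe"}
        assert rep.persistence_fraction_day60 == pytest.approx(1 / 3)
        assert rep.persistence_fraction_day90 == pytest.approx(1 / 3)

    def test_empty_day60_flagged_not_error(self):
        rep = persistence(mset("birthplace@60", {}), mset("birthplace@90", {"A": "steppe"}))
        assert rep.persistence_fraction_day60 == 0.0
        assert rep.empty_day60

    def test_mismatched_grouping_rejected(self):
        with pytest.raises(ValueError, match="grouping"):
            persistence(mset("birthplace@60", {}), mset("current_env@90", {}))

    def test_invariant_to_marker_ordering(self):
        f = {"A": "steppe", "B": "desert", "C": "forest"}
        day60a = mset("birthplace@60", f)
        day60b = mset("birthplace@60", dict(reversed(list(f.items()))))
        day90 = mset("birthplace@90", {"B": "desert", "A": "steppe"})
        assert (
            persistence(day60a, day90).n_consistent
            == persistence(day60b, day90).n_consistent
            == 2
        )


class TestAttribution:
    def test_identical_support_full(self):
        p = pd.Series({"A": 0.7, "B": 0.3})
        assert source_attribution(p, p).fraction_attributed == pytest.approx(1.0)

    def test_disjoint_zero(self):
        a = pd.Series({"A": 1.0})
        b = pd.Series({"B": 1.0})
        assert source_attribution(a, b).fraction_attributed == 0.0

    def test_partial(self):
        d60 = pd.Series({"A": 0.5, "B": 0.5})
        d90 = pd.Series({"A": 0.7, "B": 0.2, "C": 0.1})
        assert source_attribution(d60, d90).fraction_attributed == pytest.approx(0.9)


def records_for(n_per_group, groups=("desert", "steppe")):
    recs = []
    for g in groups:
        for i in range(n_per_group):
            m = f"m_{g}_{i}"
            for tp in (60, 90):
                recs.append(
                    SampleRecord(
                        f"{m}_d{tp}", m, SampleType.GUT, Environment(g), Environment(g), tp
                    )
                )
    return recs


class TestMigration:
    def test_identical_profiles_zero_change(self):
        recs = records_for(2)
        rows = np.tile([0.4, 0.6], (4, 1))
        t60 = make_relative(rows, sample_ids=[r.sample_id for r in recs if r.timepoint == 60])
        t90 = make_relative(rows, sample_ids=[r.sample_id for r in recs if r.timepoint == 90])
        cmp_ = migration_magnitude(t60, t90, recs)
        assert all(c.jsd_60_to_90 == 0.0 for c in cmp_.changes)

    def test_missing_pair_skipped(self):
        recs = records_for(2)[:-1]  # drop one Day-90 sample
        ids60 = [r.sample_id for r in recs if r.timepoint == 60]
        ids90 = [r.sample_id for r in recs if r.timepoint == 90]
        t60 = make_relative(np.tile([0.5, 0.5], (len(ids60), 1)), sample_ids=ids60)
        t90 = make_relative(np.tile([0.5, 0.5], (len(ids90), 1)), sample_ids=ids90)
        cmp_ = migration_magnitude(t60, t90, recs)
        assert cmp_.skipped_mice == ["m_steppe_1"]

    def test_planted_drift_group_detected(self, rng):
        # one group stays put, the other drifts strongly: Wilcoxon flags it
        n = 10
        recs = records_for(n)
        base = rng.dirichlet(np.ones(30) * 2)
        target = rng.dirichlet(np.ones(30) * 2)
        rows60, rows90, ids60, ids90 = [], [], [], []
        for r in recs:
            drift = 0.0 if "desert" in r.mouse_id else 0.5
            p = base if r.timepoint == 60 else (1 - drift) * base + drift * target
            noisy = rng.dirichlet(p * 2000)
            (rows60 if r.timepoint == 60 else rows90).append(noisy)
            (ids60 if r.timepoint == 60 else ids90).append(r.sample_id)
        t60 = make_relative(np.array(rows60), sample_ids=ids60)
        t90 = make_relative(np.array(rows90), sample_ids=ids90)
        cmp_ = migration_magnitude(t60, t90, recs)
        assert cmp_.group_means["steppe"] > cmp_.group_means["desert"]
        assert cmp_.pairwise_q[("desert", "steppe")] < 0.05

    def test_null_groups_p_not_degenerate(self, rng):
        # identical drift distributions: pairwise p roughly uniform
        ps = []
        for rep in range(40):
            recs = records_for(6)
            base = rng.dirichlet(np.ones(20))
            rows60 = [rng.dirichlet(base * 500) for _ in range(12)]
            rows90 = [rng.dirichlet(base * 500) for _ in range(12)]
            t60 = make_relative(np.array(rows60), sample_ids=[r.sample_id for r in recs if r.timepoint == 60])
            t90 = make_relative(np.array(rows90), sample_ids=[r.sample_id for r in recs if r.timepoint == 90])
            cmp_ = migration_magnitude(t60, t90, recs)
            ps.append(cmp_.pairwise_p[("desert", "steppe")])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01
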
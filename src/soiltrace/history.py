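"""Exposure-history inference: colonization accounting, migration
magnitude, birthplace-marker persistence and source attribution.

These four analyses quantify, in order: which soil species establish in
the gut and how much abundance they carry; how far each mouse's gut
community moves between Day 60 and Day 90 (Jensen-Shannon distance) and
whether birthplace groups differ in that magnitude; which Day-60
birthplace markers remain markers with the same enrichment direction at
Day 90; and what share of a mouse's Day-90 community was already present
in the same mouse at Day 60.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import jsd
from .datamodel import AbundanceTable, SampleRecord, ValueKind, metadata_frame
from .differential import MarkerSet, bh_adjust

__all__ = [
    "ColonizationReport",
    "MigrationChange",
    "PersistenceReport",
    "AttributionResult",
    "colonization_report",
    "soil_vs_gut_jsd",
    "migration_magnitude",
    "persistence",
    "source_attribution",
]


@dataclass
class ColonizationReport:
    environment: str
    soil_species_count: int
    established_species: set[str]
    established_count: int
    established_fraction_of_soil_count: float
    established_soil_abundance_fraction: float
    mean_gut_abundance_fraction: float


def colonization_report(
    soil_profile: pd.Series,
    gut_table: AbundanceTable,
    environment: str = "",
    detection_threshold: float = 0.0,
    min_samples: int = 1,
) -> ColonizationReport:
    """Account for soil species establishing in the gut.

    A soil species is *established* when its relative abundance exceeds
    ``detection_threshold`` in at least ``min_samples`` gut samples.
    Reported alongside the count are the established species' share of
    the soil community's abundance and their mean share of each gut
    community's abundance.
    """
    if len(gut_table.sample_ids) == 0:
        raise ValueError("empty gut table")
    soil_profile = soil_profile[soil_profile > 0]
    soil_species = set(soil_profile.index)
    gut = gut_table.data.reindex(columns=sorted(soil_species), fill_value=0.0)
    hits = (gut > detection_threshold).sum(axis=0)
    established = set(hits.index[hits >= min_samples])
    soil_total = float(soil_profile.sum())
    soil_frac = (
        float(soil_profile[sorted(established)].sum() / soil_total) if established else 0.0
    )
    if established:
        gut_frac = float(
            gut_table.data.reindex(columns=sorted(established), fill_value=0.0)
            .sum(axis=1)
            .mean()
        )
    else:
        gut_frac = 0.0
    n_soil = len(soil_species)
    return ColonizationReport(
        environment=environment,
        soil_species_count=n_soil,
        established_species=established,
        established_count=len(established),
        established_fraction_of_soil_count=len(established) / n_soil if n_soil else 0.0,
        established_soil_abundance_fraction=soil_frac,
        mean_gut_abundance_fraction=gut_frac,
    )


def soil_vs_gut_jsd(
    soil_profile: pd.Series,
    gut_table: AbundanceTable,
    *,
    against_mean: bool = False,
    sqrt: bool = False,
) -> float:
    """Group-level beta diversity between a soil community and the gut
    communities it seeded.

    Default: mean of the JSD between the soil profile and each gut
    sample.  ``against_mean=True`` instead compares the soil profile to
    the mean gut profile.
    """
    features = sorted(set(soil_profile.index) | set(gut_table.feature_ids))
    soil = soil_profile.reindex(features, fill_value=0.0).to_numpy(dtype=float)
    soil = soil / soil.sum()
    gut = gut_table.data.reindex(columns=features, fill_value=0.0).to_numpy(dtype=float)
    if against_mean:
        mean_gut = gut.mean(axis=0)
        mean_gut = mean_gut / mean_gut.sum()
        return jsd(soil, mean_gut, sqrt=sqrt)
    return float(np.mean([jsd(soil, row, sqrt=sqrt) for row in gut]))


@dataclass
class MigrationChange:
    mouse_id: str
    birthplace: str
    new_env: str
    jsd_60_to_90: float
    layer: str  # "taxon" or "KO"


@dataclass
class MigrationComparison:
    changes: list[MigrationChange]
    group_means: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    pairwise_q: dict[tuple[str, str], float]
    skipped_mice: list[str]


def migration_magnitude(
    day60_table: AbundanceTable,
    day90_table: AbundanceTable,
    records: list[SampleRecord],
    *,
    layer: str = "taxon",
    sqrt: bool = False,
) -> MigrationComparison:
    """Per-mouse Day-60 to Day-90 JSD, compared between birthplace groups
    by pairwise Wilcoxon rank-sum tests with BH correction.

    Mice missing either timepoint are skipped (and listed)."""
    meta = metadata_frame(records)
    gut = meta[meta["sample_type"] == "gut"]
    t60, t90 = day60_table.union_align(day90_table)
    by_mouse: dict[str, dict[int, str]] = {}
    for sid, row in gut.iterrows():
        by_mouse.setdefault(row["mouse_id"], {})[int(row["timepoint"])] = sid
    changes: list[MigrationChange] = []
    skipped: list[str] = []
    for mouse, tp in sorted(by_mouse.items()):
        if 60 not in tp or 90 not in tp:
            skipped.append(mouse)
            continue
        s60, s90 = tp[60], tp[90]
        if s60 not in t60.data.index or s90 not in t90.data.index:
            skipped.append(mouse)
            continue
        d = jsd(
            t60.data.loc[s60].to_numpy(dtype=float),
            t90.data.loc[s90].to_numpy(dtype=float),
            sqrt=sqrt,
        )
        changes.append(
            MigrationChange(
                mouse_id=mouse,
                birthplace=gut.loc[s60, "birthplace"],
                new_env=gut.loc[s90, "current_env"],
                jsd_60_to_90=d,
                layer=layer,
            )
        )
    groups = sorted({c.birthplace for c in changes})
    values = {g: [c.jsd_60_to_90 for c in changes if c.birthplace == g] for g in groups}
    group_means = {g: float(np.mean(v)) for g, v in values.items() if v}
    pairs = [
        (g1, g2) for i, g1 in enumerate(groups) for g2 in groups[i + 1 :]
        if values[g1] and values[g2]
    ]
    p_raw = {
        pair: float(stats.ranksums(values[pair[0]], values[pair[1]]).pvalue)
        for pair in pairs
    }
    q = bh_adjust(list(p_raw.values())) if p_raw else []
    pairwise_q = {pair: float(qv) for pair, qv in zip(p_raw, q)}
    return MigrationComparison(
        changes=changes,
        group_means=group_means,
        pairwise_p=p_raw,
        pairwise_q=pairwise_q,
        skipped_mice=skipped,
    )


@dataclass
class PersistenceReport:
    grouping_name: str
    n_day60: int
    n_day90: int
    consistent_markers: dict[str, str]  # feature_id -> shared direction
    n_consistent: int
    persistence_fraction_day60: float  # vs the Day-60 marker count
    persistence_fraction_day90: float  # vs the Day-90 marker count
    empty_day60: bool = False


def persistence(markers_day60: MarkerSet, markers_day90: MarkerSet) -> PersistenceReport:
    """Markers significant at both timepoints with the same enrichment
    direction.

    The fraction is reported against both denominators (the Day-60 and
    the Day-90 marker counts); an empty Day-60 set yields fraction 0 with
    a flag rather than an error.
    """
    g60 = markers_day60.grouping_name.split("@")[0]
    g90 = markers_day90.grouping_name.split("@")[0]
    if g60 != g90:
        raise ValueError(
            f"marker sets use different grouping variables: {g60!r} vs {g90!r}"
        )
    if markers_day60.alpha != markers_day90.alpha:
        raise ValueError("marker sets computed at different alpha levels")
    dir60 = {m.feature_id: m.enriched_group for m in markers_day60.markers}
    dir90 = {m.feature_id: m.enriched_group for m in markers_day90.markers}
    consistent = {
        fid: d for fid, d in dir60.items() if fid in dir90 and dir90[fid] == d
    }
    n60, n90 = len(dir60), len(dir90)
    return PersistenceReport(
        grouping_name=markers_day60.grouping_name,
        n_day60=n60,
        n_day90=n90,
        consistent_markers=consistent,
        n_consistent=len(consistent),
        persistence_fraction_day60=len(consistent) / n60 if n60 else 0.0,
        persistence_fraction_day90=len(consistent) / n90 if n90 else 0.0,
        empty_day60=n60 == 0,
    )


@dataclass
class AttributionResult:
    mouse_id: str
    fraction_attributed: float


def source_attribution(
    day60_profile: pd.Series,
    day90_profile: pd.Series,
    presence_threshold: float = 0.0,
    mouse_id: str = "",
) -> AttributionResult:
    """Share of a mouse's Day-90 relative abundance carried by taxa that
    were already present (> threshold) in the same mouse at Day 60."""
    present = set(day60_profile.index[day60_profile > presence_threshold])
    attributed = float(day90_profile[day90_profile.index.isin(present)].sum())
    return AttributionResult(mouse_id=mouse_id, fraction_attributed=min(attributed, 1.0))
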
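"""End-to-end orchestration of the exposure-history analysis.

``analyze_study`` runs every stage in dependency order on a
:class:`~soiltrace.synthetic.SyntheticStudy` (or any object with the
same attributes, e.g. one assembled from files): alpha diversity,
Jensen-Shannon distance matrices, PCoA + PERMANOVA, colonization
accounting, taxon and KO differential screens at the three groupings,
reporter-Z pathway enrichment, migration magnitude, marker persistence
and source attribution.  The report is a plain dataclass that can be
serialized to JSON; ``recovery_metrics`` scores a report against the
generator's planted truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, history, ordination, pathways
from .datamodel import (
    AbundanceTable,
    SampleType,
    ValueKind,
    metadata_frame,
)
from .differential import (
    MarkerSet,
    kruskal_screen,
    marker_set,
    nb_test,
    shared_features,
)
from .gene_abundance import aggregate_to_ko, length_normalize_table
from .synthetic import SyntheticStudy, SyntheticTruth

__all__ = [
    "AnalysisParams",
    "StudyReport",
    "analyze_study",
    "recovery_metrics",
    "truth_eval",
    "report_to_json",
]


@dataclass
class AnalysisParams:
    alpha: float = 0.05
    n_permutations: int = 999
    background_samples: int = 10_000
    jsd_sqrt: bool = False
    pathway_threshold: float = 2.0
    seed: int = 0


@dataclass
class StudyReport:
    run_id: str
    params: AnalysisParams
    alpha_diversity: pd.DataFrame
    soil_shannon: dict
    permanova_birthplace_taxa: ordination.PermanovaResult
    permanova_timepoint_taxa: ordination.PermanovaResult
    permanova_timepoint_ko: ordination.PermanovaResult
    pcoa_taxa_day60: ordination.PcoaResult
    colonization: dict  # env -> ColonizationReport
    soil_gut_jsd: dict  # env -> float
    taxa_markers: dict  # grouping -> MarkerSet
    ko_markers: dict  # grouping -> MarkerSet
    pathway_scores: list
    migration_taxa: history.MigrationComparison
    migration_ko: history.MigrationComparison
    persistence_taxa: history.PersistenceReport
    persistence_ko: history.PersistenceReport
    attribution_control: list  # AttributionResult for non-transferred mice


def _screen_taxa(table, labels, grouping, alpha):
    feats = shared_features(table, labels)
    # re-close over shared features so each row is a valid profile again
    df = table.data[feats]
    sub = AbundanceTable(
        df.div(df.sum(axis=1), axis=0), table.feature_kind, ValueKind.RELATIVE
    )
    results = kruskal_screen(sub, labels)
    return marker_set(results, grouping, alpha)


def analyze_study(study: SyntheticStudy, params: AnalysisParams | None = None) -> StudyReport:
    params = params or AnalysisParams()
    meta = metadata_frame(study.records)
    gut60 = [r.sample_id for r in study.gut_records(60)]
    gut90 = [r.sample_id for r in study.gut_records(90)]
    t60 = study.taxa_day60.subset_samples(gut60)
    t90 = study.taxa_day90.subset_samples(gut90)
    bp60 = meta.loc[gut60, "birthplace"].to_numpy()
    bp90 = meta.loc[gut90, "birthplace"].to_numpy()
    env90 = meta.loc[gut90, "current_env"].to_numpy()

    # ---- alpha diversity -------------------------------------------------
    alpha_div = community.shannon_table(t60)
    soil_shannon = {
        env: community.shannon(p / p.sum()) for env, p in study.soil_profiles.items()
    }

    # ---- beta diversity and ordination ----------------------------------
    d60 = community.distance_matrix(t60, sqrt=params.jsd_sqrt)
    pcoa60 = ordination.pcoa(d60)
    perm_bp = ordination.permanova(
        d60,
        bp60,
        n_permutations=params.n_permutations,
        seed=params.seed,
        factor_name="birthplace@60",
    )
    both, both90 = t60.union_align(t90)
    combined = AbundanceTable(
        pd.concat([both.data, both90.data]), t60.feature_kind, ValueKind.RELATIVE
    )
    d_all = community.distance_matrix(combined, sqrt=params.jsd_sqrt)
    tp_labels = np.array(["d60"] * len(gut60) + ["d90"] * len(gut90))
    perm_tp = ordination.permanova(
        d_all,
        tp_labels,
        n_permutations=params.n_permutations,
        seed=params.seed,
        factor_name="timepoint",
    )

    # ---- functional layer: length-normalize, aggregate to KO ------------
    ko60_rel, _ = aggregate_to_ko(
        length_normalize_table(study.gene_counts_day60, study.catalog), study.catalog
    )
    ko90_rel, _ = aggregate_to_ko(
        length_normalize_table(study.gene_counts_day90, study.catalog), study.catalog
    )
    ko_combined = AbundanceTable(
        pd.concat(
            [
                ko60_rel.data.reindex(columns=sorted(set(ko60_rel.feature_ids) | set(ko90_rel.feature_ids)), fill_value=0.0),
                ko90_rel.data.reindex(columns=sorted(set(ko60_rel.feature_ids) | set(ko90_rel.feature_ids)), fill_value=0.0),
            ]
        ),
        ko60_rel.feature_kind,
        ValueKind.RELATIVE,
    )
    d_ko_all = community.distance_matrix(ko_combined, sqrt=params.jsd_sqrt)
    perm_tp_ko = ordination.permanova(
        d_ko_all,
        tp_labels,
        n_permutations=params.n_permutations,
        seed=params.seed,
        factor_name="timepoint",
    )

    # ---- colonization accounting ----------------------------------------
    colonization = {}
    soil_gut = {}
    for env, soil in study.soil_profiles.items():
        group60 = [s for s, b in zip(gut60, bp60) if b == env]
        gut_tab = t60.subset_samples(group60)
        colonization[env] = history.colonization_report(soil, gut_tab, environment=env)
        soil_gut[env] = history.soil_vs_gut_jsd(soil, gut_tab, sqrt=params.jsd_sqrt)

    # ---- differential screens -------------------------------------------
    taxa_markers = {
        "birthplace@60": _screen_taxa(t60, bp60, "birthplace@60", params.alpha),
        "current_env@90": _screen_taxa(t90, env90, "current_env@90", params.alpha),
        "birthplace@90": _screen_taxa(t90, bp90, "birthplace@90", params.alpha),
    }
    ko_counts60, _ = aggregate_to_ko(study.gene_counts_day60, study.catalog)
    ko_counts90, _ = aggregate_to_ko(study.gene_counts_day90, study.catalog)
    ko_counts60 = ko_counts60.subset_samples(gut60)
    ko_counts90 = ko_counts90.subset_samples(gut90)
    ko_res_60 = nb_test(ko_counts60, bp60, alpha=params.alpha)
    ko_res_90_bp = nb_test(ko_counts90, bp90, alpha=params.alpha)
    ko_res_90_env = nb_test(ko_counts90, env90, alpha=params.alpha)
    ko_markers = {
        "birthplace@60": marker_set(ko_res_60, "birthplace@60", params.alpha),
        "current_env@90": marker_set(ko_res_90_env, "current_env@90", params.alpha),
        "birthplace@90": marker_set(ko_res_90_bp, "birthplace@90", params.alpha),
    }

    # ---- pathway enrichment (Day-60 birthplace contrast) ----------------
    pathway_scores = pathways.score_pathways(
        study.pathway_map,
        ko_res_60,
        background_samples=params.background_samples,
        seed=params.seed,
        threshold=params.pathway_threshold,
        alpha=params.alpha,
    )

    # ---- migration magnitude, persistence, attribution ------------------
    migration_taxa = history.migration_magnitude(
        t60, t90, study.records, layer="taxon", sqrt=params.jsd_sqrt
    )
    migration_ko = history.migration_magnitude(
        ko60_rel, ko90_rel, study.records, layer="KO", sqrt=params.jsd_sqrt
    )
    persistence_taxa = history.persistence(
        taxa_markers["birthplace@60"], taxa_markers["birthplace@90"]
    )
    persistence_ko = history.persistence(
        ko_markers["birthplace@60"], ko_markers["birthplace@90"]
    )

    control_mice = sorted(
        {
            r.mouse_id
            for r in study.gut_records(90)
            if r.birthplace == r.current_env
        }
    )
    t60a, t90a = t60.union_align(t90)
    attribution = []
    mouse_samples = {
        (r.mouse_id, r.timepoint): r.sample_id
        for r in study.records
        if r.sample_type is SampleType.GUT
    }
    for mouse in control_mice:
        s60 = mouse_samples.get((mouse, 60))
        s90 = mouse_samples.get((mouse, 90))
        if s60 is None or s90 is None:
            continue
        attribution.append(
            history.source_attribution(
                t60a.data.loc[s60], t90a.data.loc[s90], mouse_id=mouse
            )
        )

    return StudyReport(
        run_id=study.truth.run_id,
        params=params,
        alpha_diversity=alpha_div,
        soil_shannon=soil_shannon,
        permanova_birthplace_taxa=perm_bp,
        permanova_timepoint_taxa=perm_tp,
        permanova_timepoint_ko=perm_tp_ko,
        pcoa_taxa_day60=pcoa60,
        colonization=colonization,
        soil_gut_jsd=soil_gut,
        taxa_markers=taxa_markers,
        ko_markers=ko_markers,
        pathway_scores=pathway_scores,
        migration_taxa=migration_taxa,
        migration_ko=migration_ko,
        persistence_taxa=persistence_taxa,
        persistence_ko=persistence_ko,
        attribution_control=attribution,
    )


# ---------------------------------------------------------------------------
# recovery metrics against planted truth


def _marker_recovery(markers: MarkerSet, planted: dict) -> dict:
    detected = {m.feature_id: m.enriched_group for m in markers.markers}
    hits = sum(
        1 for f, g in detected.items() if planted.get(f) == g
    )
    sensitivity = hits / len(planted) if planted else float("nan")
    fdr = (
        sum(1 for f in detected if f not in planted) / len(detected)
        if detected
        else 0.0
    )
    return {"sensitivity": sensitivity, "fdr": fdr, "n_detected": len(detected)}


def recovery_metrics(report: StudyReport, truth: SyntheticTruth) -> dict:
    """Score pipeline outputs against the planted ground truth of the
    same synthetic run: marker sensitivity/FDR, pathway assignment
    accuracy, persistence-fraction error, and whether the configured
    drift-rate ordering is recovered from the per-mouse JSDs."""
    if report.run_id != truth.run_id:
        raise ValueError(
            f"report run {report.run_id!r} does not match truth run {truth.run_id!r}"
        )
    out = {
        "taxa": _marker_recovery(report.taxa_markers["birthplace@60"], truth.taxon_markers),
        "ko": _marker_recovery(report.ko_markers["birthplace@60"], truth.ko_markers),
    }
    sig = [s for s in report.pathway_scores if s.significant]
    planted_sig = [s for s in sig if s.pathway_id in truth.planted_pathways]
    correct = sum(
        1 for s in planted_sig if s.assigned_group == truth.planted_pathways[s.pathway_id]
    )
    out["pathways"] = {
        "sensitivity": len(planted_sig) / len(truth.planted_pathways),
        "fdr": (len(sig) - len(planted_sig)) / len(sig) if sig else 0.0,
        "assignment_accuracy": correct / len(planted_sig) if planted_sig else float("nan"),
    }
    out["persistence"] = {
        "taxa_recovered": report.persistence_taxa.persistence_fraction_day60,
        "taxa_planted": truth.planted_taxon_persistence_fraction,
        "taxa_error": abs(
            report.persistence_taxa.persistence_fraction_day60
            - truth.planted_taxon_persistence_fraction
        ),
        "ko_recovered": report.persistence_ko.persistence_fraction_day60,
        "ko_planted": truth.planted_ko_persistence_fraction,
        "ko_error": abs(
            report.persistence_ko.persistence_fraction_day60
            - truth.planted_ko_persistence_fraction
        ),
    }
    rate_order = [e for e, _ in sorted(truth.drift_rate.items(), key=lambda kv: kv[1])]
    jsd_order = [
        e for e, _ in sorted(report.migration_taxa.group_means.items(), key=lambda kv: kv[1])
    ]
    out["drift"] = {
        "configured_order": rate_order,
        "recovered_order": jsd_order,
        "order_recovered": rate_order == jsd_order,
        "group_mean_jsd": dict(report.migration_taxa.group_means),
    }
    return out


#: alias: scoring a run against its planted truth
truth_eval = recovery_metrics


# ---------------------------------------------------------------------------
# JSON serialization (CLI / provenance)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    return obj


def report_to_json(report: StudyReport, path: str | Path | None = None) -> dict:
    """Serialize a StudyReport (thresholds, seeds and all stage outputs)
    to a JSON-compatible dict; write it when a path is given."""
    doc = {"schema_version": 1}
    doc.update(
        {
            "run_id": report.run_id,
            "params": _jsonable(report.params),
            "soil_shannon": _jsonable(report.soil_shannon),
            "alpha_diversity": _jsonable(report.alpha_diversity),
            "permanova": {
                "birthplace@60_taxa": _jsonable(report.permanova_birthplace_taxa),
                "timepoint_taxa": _jsonable(report.permanova_timepoint_taxa),
                "timepoint_ko": _jsonable(report.permanova_timepoint_ko),
            },
            "colonization": _jsonable(report.colonization),
            "soil_gut_jsd": _jsonable(report.soil_gut_jsd),
            "taxa_markers": {
                k: {"n": len(v), "features": sorted(v.feature_ids)}
                for k, v in report.taxa_markers.items()
            },
            "ko_markers": {k: {"n": len(v)} for k, v in report.ko_markers.items()},
            "pathways": {
                "n_significant": sum(1 for s in report.pathway_scores if s.significant),
                "scores": _jsonable(report.pathway_scores),
            },
            "migration": {
                "taxa_group_means": _jsonable(report.migration_taxa.group_means),
                "taxa_pairwise_q": {
                    f"{a}|{b}": q for (a, b), q in report.migration_taxa.pairwise_q.items()
                },
                "ko_group_means": _jsonable(report.migration_ko.group_means),
            },
            "persistence": {
                "taxa": _jsonable(report.persistence_taxa),
                "ko": _jsonable(report.persistence_ko),
            },
            "attribution_control": _jsonable(report.attribution_control),
        }
    )
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
    return doc
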
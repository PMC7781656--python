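"""Seeded generator of a full synthetic soil-exposure study.

The generator emulates the design of the mouse housing experiment it
stands in for: three soil environments (desert, steppe, forest) with
species pools of realistic sizes, a gut-selected subset of each pool,
planted group-differential taxa and KOs at known effect sizes, a
Day-60 to Day-90 drift toward a shared developmental attractor at a
birthplace-dependent rate (steppe least), and negative-binomially
dispersed gene counts with gene-length structure.  Every planted signal
is recorded in a :class:`SyntheticTruth` so parameter-recovery tests can
score the pipeline against known ground truth.

Statistical structure
---------------------
* Soil communities: log-normal abundances over environment-specific
  pools; the log-sd differs by environment so that expected soil Shannon
  diversity echoes realistic values (desert most even, steppe least).
* Gut selection: a core of cosmopolitan species establishes in every
  group and carries a base profile *common to all groups*; each
  environment additionally contributes its own minor colonizers at
  ~0.1% total abundance.  Group differences among shared species are
  therefore exactly the planted markers — which makes truth-referenced
  sensitivity and FDR well defined.
* Inter-mouse variation: Dirichlet resampling of the group expectation
  for taxa; NB count noise for the gene/KO layer.
* Day-90: each mouse's expectation moves a fraction ``drift_rate`` of
  the way toward a shared attractor (a perturbed version of the common
  base, closest to the steppe-associated state); transferred mice
  additionally mix in the new environment's minor colonizers.  A
  configured subset of planted markers keeps its effect at Day 90
  (the persistent markers); the rest lose it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceTable,
    Environment,
    FeatureKind,
    GeneCatalog,
    PathwayMap,
    SampleRecord,
    SampleType,
    ValueKind,
)

__all__ = ["SyntheticConfig", "SyntheticTruth", "SyntheticStudy", "generate_study"]

ENVS = ("desert", "steppe", "forest")


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults mirror the housing design
    (30 mice per group, 2/3 transferred at Day 60) and realistic
    community sizes."""

    seed: int = 0
    n_mice_per_group: int = 30
    transfer_fraction: float = 2.0 / 3.0
    pool_sizes: dict = field(
        default_factory=lambda: {"desert": 352, "forest": 290, "steppe": 443}
    )
    # log-sd per environment calibrated so the expected soil Shannon
    # index is ~3.2 (desert), ~2.6 (forest) and ~1.4 (steppe): desert
    # soil most even, steppe dominated by few taxa despite its richness
    soil_sigma: dict = field(
        default_factory=lambda: {"desert": 2.59, "forest": 2.98, "steppe": 5.5}
    )
    colonization_fraction: dict = field(
        default_factory=lambda: {
            "desert": 251 / 352,
            "forest": 211 / 290,
            "steppe": 209 / 443,
        }
    )
    n_core_species: int = 140
    n_universe_extra: int = 560  # non-core species universe shared by pools
    gut_base_sigma: float = 2.4
    env_unique_mass: float = 0.001
    n_planted_taxon_markers: dict = field(
        default_factory=lambda: {"desert": 9, "steppe": 16, "forest": 12}
    )
    taxon_effect_fold: float = 4.0
    # markers are planted in a mid-abundance band: detectable above the
    # floor, and collectively light enough that compositional closure of
    # the folded profiles barely moves non-marker species
    marker_min_abundance: float = 3e-4
    marker_max_abundance: float = 1e-2
    dirichlet_concentration: float = 1000.0
    drift_rate: dict = field(
        default_factory=lambda: {"desert": 0.30, "steppe": 0.10, "forest": 0.40}
    )
    attractor_sigma_taxa: float = 1.0
    attractor_sigma_ko: float = 0.8
    transfer_mix: float = 0.05
    persistence_fraction_planted: float = 0.25
    n_kos: int = 4011
    ko_sigma: float = 1.0
    n_pathways: int = 130
    n_planted_enriched_pathways: int = 31
    pathway_size_range: tuple = (8, 25)
    ko_effect_fold: float = 4.0
    genes_per_ko_max: int = 3
    gene_length_range: tuple = (300, 3000)
    unassigned_gene_fraction: float = 0.05
    nb_dispersion: float = 0.05
    library_size_range: tuple = (150_000, 250_000)

    def validate(self) -> None:
        if self.n_mice_per_group < 3:
            raise ValueError("need at least 3 mice per group")
        for env in ENVS:
            if self.pool_sizes[env] <= 0:
                raise ValueError("pool sizes must be positive")
            if not (0.0 <= self.colonization_fraction[env] <= 1.0):
                raise ValueError("colonization fractions must be in [0, 1]")
            if not (0.0 <= self.drift_rate[env] <= 1.0):
                raise ValueError("drift rates must be in [0, 1]")
            n_col = round(self.colonization_fraction[env] * self.pool_sizes[env])
            if n_col < self.n_core_species:
                raise ValueError(
                    f"{env}: colonizer count {n_col} below core size {self.n_core_species}"
                )
        if not (0.0 <= self.persistence_fraction_planted <= 1.0):
            raise ValueError("persistence fraction must be in [0, 1]")
        if not (0.0 <= self.transfer_fraction <= 1.0):
            raise ValueError("transfer fraction must be in [0, 1]")
        if self.taxon_effect_fold <= 0 or self.ko_effect_fold <= 0:
            raise ValueError("effect folds must be positive")
        if self.n_planted_enriched_pathways > self.n_pathways:
            raise ValueError("more planted pathways than pathways")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("bad library size range")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside the emitted tables."""

    run_id: str
    taxon_markers: dict  # species -> enriched group
    persistent_taxa: list
    ko_markers: dict  # KO -> enriched group
    persistent_kos: list
    planted_pathways: dict  # pathway -> assigned group
    drift_rate: dict
    colonizers: dict  # env -> list of species
    planted_taxon_persistence_fraction: float
    planted_ko_persistence_fraction: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    records: list  # SampleRecord, soils + gut
    soil_profiles: dict  # env -> pd.Series (relative)
    taxa_day60: AbundanceTable
    taxa_day90: AbundanceTable
    gene_counts_day60: AbundanceTable
    gene_counts_day90: AbundanceTable
    catalog: GeneCatalog
    pathway_map: PathwayMap
    truth: SyntheticTruth

    def gut_records(self, timepoint: int) -> list:
        return [
            r
            for r in self.records
            if r.sample_type is SampleType.GUT and r.timepoint == timepoint
        ]


def _lognormal_profile(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return w / w.sum()


def _apply_fold(profile: pd.Series, features: list, fold: float) -> pd.Series:
    out = profile.copy()
    out.loc[features] *= fold
    return out / out.sum()


def _perturb_except(
    profile: pd.Series, pinned: list, sigma: float, rng: np.random.Generator
) -> pd.Series:
    """Multiplicative log-normal perturbation of a profile that leaves the
    ``pinned`` features untouched and preserves the total mass carried by
    the perturbed features (so pinned entries keep their exact values)."""
    out = profile.copy()
    mask = ~out.index.isin(pinned)
    w = out[mask].to_numpy()
    pw = w * np.exp(rng.normal(0.0, sigma, size=mask.sum()))
    out.loc[mask] = pw * (w.sum() / pw.sum())
    return out


def generate_study(config: SyntheticConfig | None = None) -> SyntheticStudy:
    """Generate the complete synthetic study, deterministically from
    ``config.seed``.

    One RNG stream per logical component (pools, soil, gut base, marker
    placement, per-mouse resampling, KO layer, counts, design), all
    spawned from the master seed, so changing e.g. ``n_kos`` does not
    perturb the taxon draws.
    """
    config = config or SyntheticConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (
        ss_pools,
        ss_soil,
        ss_base,
        ss_markers,
        ss_attr,
        ss_dir60,
        ss_dir90,
        ss_design,
        ss_ko,
        ss_pathways,
        ss_catalog,
        ss_counts,
    ) = [np.random.default_rng(c) for c in ss.spawn(12)]

    # ---- species universe and environment pools -------------------------
    n_universe = config.n_core_species + config.n_universe_extra
    species = np.array([f"sp{i:04d}" for i in range(1, n_universe + 1)])
    core = species[: config.n_core_species]
    noncore = species[config.n_core_species :]
    pools: dict[str, np.ndarray] = {}
    colonizers: dict[str, np.ndarray] = {}
    for env in ENVS:
        extra = ss_pools.choice(
            noncore, size=config.pool_sizes[env] - len(core), replace=False
        )
        pools[env] = np.concatenate([core, extra])
        n_col = round(config.colonization_fraction[env] * config.pool_sizes[env])
        unique = ss_pools.choice(extra, size=n_col - len(core), replace=False)
        colonizers[env] = np.concatenate([core, unique])

    # ---- soil communities ------------------------------------------------
    soil_profiles = {
        env: pd.Series(
            _lognormal_profile(ss_soil, len(pools[env]), config.soil_sigma[env]),
            index=pools[env],
        ).sort_index()
        for env in ENVS
    }

    # ---- gut base: common core profile + env-unique minor colonizers ----
    core_w = _lognormal_profile(ss_base, len(core), config.gut_base_sigma)
    base: dict[str, pd.Series] = {}
    unique_profiles: dict[str, pd.Series] = {}
    for env in ENVS:
        unique = [s for s in colonizers[env] if s not in set(core)]
        uw = _lognormal_profile(ss_base, len(unique), 1.0)
        unique_profiles[env] = pd.Series(uw, index=unique)
        prof = pd.concat(
            [
                pd.Series(core_w * (1.0 - config.env_unique_mass), index=core),
                unique_profiles[env] * config.env_unique_mass,
            ]
        )
        base[env] = prof / prof.sum()

    # ---- planted taxon markers ------------------------------------------
    core_base = pd.Series(core_w, index=core) * (1.0 - config.env_unique_mass)
    eligible = list(
        core_base.index[
            (core_base >= config.marker_min_abundance)
            & (core_base <= config.marker_max_abundance)
        ]
    )
    n_markers_total = sum(config.n_planted_taxon_markers[e] for e in ENVS)
    if len(eligible) < n_markers_total:
        raise ValueError(
            f"only {len(eligible)} species above the marker abundance floor; "
            f"{n_markers_total} markers requested"
        )
    chosen = ss_markers.choice(eligible, size=n_markers_total, replace=False)
    # deal markers to groups in descending abundance order so each group
    # carries a comparable planted signal mass; likewise spread each
    # group's persistent subset across the abundance ranks.  Without the
    # stratification the Day-60->90 change contributed by decaying
    # markers varies wildly between groups and masks the drift rates.
    chosen = sorted(chosen, key=lambda s: -core_base[s])
    taxon_markers: dict[str, str] = {}
    remaining = dict(config.n_planted_taxon_markers)
    for s in chosen:
        env = max(ENVS, key=lambda e: remaining[e] / config.n_planted_taxon_markers[e])
        taxon_markers[str(s)] = env
        remaining[env] -= 1
    persistent_taxa: list[str] = []
    for env in ENVS:
        members = [s for s in chosen if taxon_markers[str(s)] == env]  # abundance order
        n_persist = round(config.persistence_fraction_planted * len(members))
        if n_persist:
            idx = np.linspace(0, len(members) - 1, n_persist).round().astype(int)
            persistent_taxa.extend(str(members[i]) for i in idx)

    def with_markers(env: str, marker_ids: list[str]) -> pd.Series:
        own = [s for s in marker_ids if taxon_markers[s] == env]
        return _apply_fold(base[env], own, config.taxon_effect_fold)

    expected60 = {env: with_markers(env, list(taxon_markers)) for env in ENVS}
    base90 = {env: with_markers(env, persistent_taxa) for env in ENVS}

    # attractor: the shared developmental target the communities converge
    # toward — the steppe-associated base reshaped by host selection.
    # Marker species are pinned to the base so that drift neither erases
    # nor fabricates marker signal: planted persistence stays the only
    # dial controlling which markers survive to Day 90.
    attractor = _perturb_except(
        base["steppe"], list(taxon_markers), config.attractor_sigma_taxa, ss_attr
    )

    # ---- design: mice, transfers, metadata ------------------------------
    records: list[SampleRecord] = [
        SampleRecord(
            sample_id=f"soil_{env}",
            mouse_id=f"soil_{env}",
            sample_type=SampleType.SOIL,
            birthplace=Environment(env),
            current_env=Environment(env),
            timepoint=0,
        )
        for env in ENVS
    ]
    mouse_env90: dict[str, tuple[str, str]] = {}  # mouse -> (birthplace, env at 90)
    for env in ENVS:
        n = config.n_mice_per_group
        n_transfer = round(config.transfer_fraction * n)
        others = [e for e in ENVS if e != env]
        order = ss_design.permutation(n)
        for i in range(n):
            mouse = f"m_{env}_{i + 1:02d}"
            rank = int(np.flatnonzero(order == i)[0])
            if rank < n_transfer // 2:
                env90 = others[0]
            elif rank < n_transfer:
                env90 = others[1]
            else:
                env90 = env
            mouse_env90[mouse] = (env, env90)
            for tp in (60, 90):
                records.append(
                    SampleRecord(
                        sample_id=f"{mouse}_d{tp}",
                        mouse_id=mouse,
                        sample_type=SampleType.GUT,
                        birthplace=Environment(env),
                        current_env=Environment(env if tp == 60 else env90),
                        timepoint=tp,
                    )
                )

    # ---- per-mouse taxon tables -----------------------------------------
    all_species = sorted(
        set().union(*(set(colonizers[e]) for e in ENVS)) | set(attractor.index)
    )

    def draw(rng: np.random.Generator, expected: pd.Series) -> pd.Series:
        alpha = expected.to_numpy() * config.dirichlet_concentration
        p = rng.dirichlet(alpha)
        return pd.Series(p, index=expected.index)

    rows60, rows90, ids60, ids90 = [], [], [], []
    for mouse, (bp, env90) in sorted(mouse_env90.items()):
        r = config.drift_rate[bp]
        idx = base90[bp].index.union(attractor.index)
        e90 = (1.0 - r) * base90[bp].reindex(idx, fill_value=0.0) + r * attractor.reindex(
            idx, fill_value=0.0
        )
        if env90 != bp:
            mix = unique_profiles[env90] / unique_profiles[env90].sum()
            idx2 = e90.index.union(mix.index)
            e90 = (1.0 - config.transfer_mix) * e90.reindex(
                idx2, fill_value=0.0
            ) + config.transfer_mix * mix.reindex(idx2, fill_value=0.0)
        e90 = e90 / e90.sum()
        p60 = draw(ss_dir60, expected60[bp])
        p90 = draw(ss_dir90, e90[e90 > 0])
        rows60.append(p60.reindex(all_species, fill_value=0.0).to_numpy())
        rows90.append(p90.reindex(all_species, fill_value=0.0).to_numpy())
        ids60.append(f"{mouse}_d60")
        ids90.append(f"{mouse}_d90")

    def taxa_table(rows, ids) -> AbundanceTable:
        arr = np.vstack(rows)
        arr = arr / arr.sum(axis=1, keepdims=True)
        df = pd.DataFrame(arr, index=ids, columns=all_species)
        return AbundanceTable(df, FeatureKind.TAXON, ValueKind.RELATIVE)

    taxa_day60 = taxa_table(rows60, ids60)
    taxa_day90 = taxa_table(rows90, ids90)

    # ---- KO layer: base profile, planted pathways, markers --------------
    kos = np.array([f"K{i:05d}" for i in range(1, config.n_kos + 1)])
    ko_w = _lognormal_profile(ss_ko, config.n_kos, config.ko_sigma)
    ko_base = pd.Series(ko_w, index=kos)

    lo, hi = config.pathway_size_range
    shuffled = ss_pathways.permutation(kos)
    planted_groups = [ENVS[(i + 1) % 3] for i in range(config.n_planted_enriched_pathways)]
    # cycle starting at steppe so the steppe group dominates when the
    # planted count is not divisible by three
    pathway_members: dict[str, frozenset] = {}
    planted_pathways: dict[str, str] = {}
    ko_markers: dict[str, str] = {}
    cursor = 0
    for i in range(config.n_planted_enriched_pathways):
        size = int(ss_pathways.integers(lo, hi + 1))
        members = shuffled[cursor : cursor + size]
        cursor += size
        pid = f"path{i + 1:04d}"
        group = planted_groups[i]
        pathway_members[pid] = frozenset(str(k) for k in members)
        planted_pathways[pid] = group
        for k in members:
            ko_markers[str(k)] = group
    for i in range(config.n_planted_enriched_pathways, config.n_pathways):
        size = int(ss_pathways.integers(lo, hi + 1))
        members = ss_pathways.choice(kos, size=size, replace=False)
        pathway_members[f"path{i + 1:04d}"] = frozenset(str(k) for k in members)
    pmap = PathwayMap(pathway_members)

    n_persist_ko = round(config.persistence_fraction_planted * len(ko_markers))
    persistent_kos = [
        str(k)
        for k in ss_pathways.choice(sorted(ko_markers), size=n_persist_ko, replace=False)
    ]

    def ko_profile(env: str, marker_ids) -> pd.Series:
        own = [k for k in marker_ids if ko_markers[k] == env]
        return _apply_fold(ko_base, own, config.ko_effect_fold)

    ko60 = {env: ko_profile(env, list(ko_markers)) for env in ENVS}
    ko_base90 = {env: ko_profile(env, persistent_kos) for env in ENVS}
    ko_attractor = _perturb_except(
        ko_base, list(ko_markers), config.attractor_sigma_ko, ss_attr
    )

    # ---- gene catalog ----------------------------------------------------
    genes, lengths, gene_ko = [], [], []
    for k in kos:
        n_genes = int(ss_catalog.integers(1, config.genes_per_ko_max + 1))
        for j in range(n_genes):
            genes.append(f"g_{k}_{j + 1}")
            lengths.append(int(ss_catalog.integers(*config.gene_length_range)))
            gene_ko.append(str(k))
    n_unassigned = round(config.unassigned_gene_fraction * len(genes))
    for j in range(n_unassigned):
        genes.append(f"g_none_{j + 1}")
        lengths.append(int(ss_catalog.integers(*config.gene_length_range)))
        gene_ko.append(None)
    catalog = GeneCatalog(
        pd.DataFrame(
            {"length_bp": lengths, "ko_id": gene_ko}, index=pd.Index(genes, name="gene_id")
        )
    )
    genes_arr = np.array(genes)
    lengths_arr = np.array(lengths, dtype=float)
    ko_of_gene = np.array([k if k is not None else "" for k in gene_ko])
    genes_per_ko = pd.Series(ko_of_gene[ko_of_gene != ""]).value_counts()

    # split each KO's copy-number mass equally over its genes; unassigned
    # genes carry a small fixed copy-number mass
    def gene_copy_numbers(ko_abund: pd.Series) -> np.ndarray:
        per_gene = np.empty(len(genes_arr))
        assigned = ko_of_gene != ""
        per_gene[assigned] = (
            ko_abund.loc[ko_of_gene[assigned]].to_numpy()
            / genes_per_ko.loc[ko_of_gene[assigned]].to_numpy()
        )
        if (~assigned).any():
            per_gene[~assigned] = 0.02 / max((~assigned).sum(), 1)
        return per_gene

    def gene_counts_for(expected_ko: pd.Series, rng: np.random.Generator) -> np.ndarray:
        b = gene_copy_numbers(expected_ko)
        read_weight = b * lengths_arr
        read_frac = read_weight / read_weight.sum()
        lib = int(rng.integers(*config.library_size_range))
        mu = lib * read_frac
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu * config.nb_dispersion)
        return rng.poisson(lam)

    g_rows60, g_rows90 = [], []
    for mouse, (bp, env90) in sorted(mouse_env90.items()):
        r = config.drift_rate[bp]
        e90 = (1.0 - r) * ko_base90[bp] + r * ko_attractor
        e90 = e90 / e90.sum()
        g_rows60.append(gene_counts_for(ko60[bp], ss_counts))
        g_rows90.append(gene_counts_for(e90, ss_counts))

    def gene_table(rows, ids) -> AbundanceTable:
        df = pd.DataFrame(np.vstack(rows), index=ids, columns=genes_arr, dtype=float)
        return AbundanceTable(df, FeatureKind.GENE, ValueKind.COUNT)

    gene_counts_day60 = gene_table(g_rows60, ids60)
    gene_counts_day90 = gene_table(g_rows90, ids90)

    truth = SyntheticTruth(
        run_id=f"seed{config.seed}",
        taxon_markers=taxon_markers,
        persistent_taxa=sorted(persistent_taxa),
        ko_markers=ko_markers,
        persistent_kos=sorted(persistent_kos),
        planted_pathways=planted_pathways,
        drift_rate=dict(config.drift_rate),
        colonizers={env: sorted(str(s) for s in colonizers[env]) for env in ENVS},
        planted_taxon_persistence_fraction=len(persistent_taxa) / max(len(taxon_markers), 1),
        planted_ko_persistence_fraction=len(persistent_kos) / max(len(ko_markers), 1),
    )
    return SyntheticStudy(
        config=config,
        records=records,
        soil_profiles=soil_profiles,
        taxa_day60=taxa_day60,
        taxa_day90=taxa_day90,
        gene_counts_day60=gene_counts_day60,
        gene_counts_day90=gene_counts_day90,
        catalog=catalog,
        pathway_map=pmap,
        truth=truth,
    )
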
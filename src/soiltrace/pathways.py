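"""Reporter-Z pathway enrichment and ternary group assignment.

Each tested KO's p-value maps to a Z-score via the inverse normal CDF,
Z = Phi^-1(1 - p).  A pathway with k scored member KOs gets the raw
aggregate Z_raw = sum(Z) / sqrt(k), which is then corrected against the
background of random size-k KO sets drawn without replacement from all
tested KOs: Z_adj = (Z_raw - mu_k) / sigma_k.  Pathways with Z_adj >= 2
(one-sided 95% on the normal scale) are called significantly enriched,
and each is assigned to the group where most of its individually
significant member KOs are enriched (the ternary / triple-graph rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import PathwayMap
from .differential import TIE, DifferentialFeature

__all__ = [
    "PathwayScore",
    "ko_to_z",
    "background_moments",
    "exact_background_moments",
    "reporter_z",
    "score_pathways",
    "ternary_assign",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"
_P_CLIP = 1e-15
DEFAULT_THRESHOLD = 2.0


@dataclass
class PathwayScore:
    pathway_id: str
    k: int
    z_raw: float
    mu_k: float
    sigma_k: float
    z_adjusted: float
    significant: bool
    assigned_group: str = UNASSIGNED
    member_direction_counts: dict[str, int] = field(default_factory=dict)


def ko_to_z(p_value: float) -> float:
    """Z = Phi^-1(1 - p), with p clipped to [1e-15, 1 - 1e-15]."""
    if not (0.0 < p_value < 1.0):
        if p_value <= 0.0 or p_value >= 1.0:
            p_value = float(np.clip(p_value, _P_CLIP, 1.0 - _P_CLIP))
        if not (0.0 < p_value < 1.0):
            raise ValueError(f"p-value {p_value} outside (0, 1)")
    p_value = float(np.clip(p_value, _P_CLIP, 1.0 - _P_CLIP))
    return float(stats.norm.isf(p_value))


def background_moments(
    all_z: np.ndarray, k: int, background_samples: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo (mu_k, sigma_k) of sum(Z)/sqrt(k) over random size-k
    subsets of the tested KOs, drawn without replacement."""
    all_z = np.asarray(all_z, dtype=float)
    if k > len(all_z):
        raise ValueError(f"pathway size {k} exceeds tested-KO universe {len(all_z)}")
    draws = np.empty(background_samples)
    for i in range(background_samples):
        draws[i] = rng.choice(all_z, size=k, replace=False).sum()
    draws /= np.sqrt(k)
    sigma = float(draws.std(ddof=1))
    if sigma <= 0:
        raise ValueError("degenerate background (zero variance)")
    return float(draws.mean()), sigma


def exact_background_moments(all_z: np.ndarray, k: int) -> tuple[float, float]:
    """Exact without-replacement moments of sum(Z)/sqrt(k) — the finite
    population (simple random sampling) mean and standard deviation.

    mean = k * zbar / sqrt(k); var = k * S^2 * (N-k)/N / k  with
    S^2 the population variance with ddof=1.  Used as the enumeration
    oracle for the Monte-Carlo estimate.
    """
    all_z = np.asarray(all_z, dtype=float)
    n = len(all_z)
    if k > n:
        raise ValueError("k exceeds universe size")
    zbar = all_z.mean()
    s2 = all_z.var(ddof=1)
    mean = float(np.sqrt(k) * zbar)
    var_sum = k * s2 * (n - k) / n  # variance of the subset sum under SRSWOR
    return mean, float(np.sqrt(var_sum / k))


def reporter_z(
    pathway_id: str,
    member_kos: frozenset[str] | set[str],
    ko_z: dict[str, float],
    background_samples: int = 10_000,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    background: tuple[float, float] | None = None,
) -> PathwayScore | None:
    """Score one pathway; returns None (skipped) when no member KO was
    tested.  ``background`` injects precomputed (mu_k, sigma_k)."""
    zs = np.array([ko_z[k] for k in member_kos if k in ko_z])
    k = len(zs)
    if k == 0:
        return None
    z_raw = float(zs.sum() / np.sqrt(k))
    if background is None:
        rng = np.random.default_rng(seed)
        all_z = np.array(list(ko_z.values()))
        mu_k, sigma_k = background_moments(all_z, k, background_samples, rng)
    else:
        mu_k, sigma_k = background
        if sigma_k <= 0:
            raise ValueError("sigma_k must be positive")
    z_adj = (z_raw - mu_k) / sigma_k
    return PathwayScore(
        pathway_id=pathway_id,
        k=k,
        z_raw=z_raw,
        mu_k=mu_k,
        sigma_k=sigma_k,
        z_adjusted=float(z_adj),
        significant=bool(z_adj >= threshold),
    )


def score_pathways(
    pmap: PathwayMap,
    ko_results: list[DifferentialFeature],
    background_samples: int = 10_000,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = 0.05,
) -> list[PathwayScore]:
    """Score every pathway and run the ternary assignment.

    KO Z-scores come from the unadjusted test p-values (the Z transform
    assumes uniform-null p-values; BH q-values would break calibration).
    Background moments for each distinct pathway size are estimated once,
    which keeps the 10,000-draw default affordable for large maps.
    """
    ko_z = {r.feature_id: ko_to_z(r.p_value) for r in ko_results}
    all_z = np.array(list(ko_z.values()))
    rng = np.random.default_rng(seed)
    sizes = sorted(
        {len([k for k in pmap[p] if k in ko_z]) for p in pmap.pathway_ids} - {0}
    )
    moments = {
        k: background_moments(all_z, k, background_samples, rng) for k in sizes
    }
    by_feature = {r.feature_id: r for r in ko_results}
    scores = []
    for pid in pmap.pathway_ids:
        k = len([k for k in pmap[pid] if k in ko_z])
        if k == 0:
            continue
        score = reporter_z(
            pid, pmap[pid], ko_z, threshold=threshold, background=moments[k]
        )
        members = [by_feature[k] for k in pmap[pid] if k in by_feature]
        scores.append(ternary_assign(score, members, alpha=alpha))
    return scores


def ternary_assign(
    score: PathwayScore, members: list[DifferentialFeature], alpha: float = 0.05
) -> PathwayScore:
    """Assign a pathway to the group where most significantly differential
    member KOs point; ``tie`` on equal top counts, ``unassigned`` when no
    member is significant."""
    counts: dict[str, int] = {}
    for m in members:
        if m.q_value < alpha and m.enriched_group != TIE:
            counts[m.enriched_group] = counts.get(m.enriched_group, 0) + 1
    score.member_direction_counts = counts
    if not counts:
        score.assigned_group = UNASSIGNED
        return score
    best = max(counts.values())
    top = [g for g, c in counts.items() if c == best]
    score.assigned_group = top[0] if len(top) == 1 else TIE
    return score
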
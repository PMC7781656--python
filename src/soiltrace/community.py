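"""Alpha and beta diversity: Shannon index, rarefaction, and the
Jensen-Shannon distance.

Shannon entropy is reported in natural-log units (nats).  The
Jensen-Shannon distance uses base-2 logarithms so that values live in
[0, 1]; by default the divergence itself is reported, with its square
root (the true metric) available via ``sqrt=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import AbundanceTable, DistanceMatrix, ValueKind

__all__ = [
    "shannon",
    "shannon_table",
    "observed_richness",
    "jsd",
    "distance_matrix",
    "rarefy_richness",
    "expected_richness_hypergeometric",
    "RarefactionCurve",
]

_SUM_TOL = 1e-9


def _check_profile(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"{name} sums to {p.sum():.9g}, not 1")
    return p


def shannon(profile: np.ndarray | pd.Series) -> float:
    """Shannon diversity H = -sum p ln p over positive entries (nats)."""
    p = _check_profile(np.asarray(profile, dtype=float), "profile")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def observed_richness(profile: np.ndarray | pd.Series) -> int:
    return int((np.asarray(profile, dtype=float) > 0).sum())


def shannon_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon H and observed richness."""
    if table.value_kind is not ValueKind.RELATIVE:
        raise ValueError("alpha diversity requires a relative table")
    rows = {
        sid: {"shannon_H": shannon(row), "observed_richness": observed_richness(row)}
        for sid, row in zip(table.sample_ids, table.values)
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def jsd(p: np.ndarray, q: np.ndarray, *, sqrt: bool = False) -> float:
    """Jensen-Shannon distance between two aligned relative-abundance
    profiles, base-2 logs: JSD = KL(P||M)/2 + KL(Q||M)/2 with M=(P+Q)/2.

    Bounded in [0, 1]; zero-abundance features contribute nothing via the
    0*log 0 := 0 convention (no pseudocounts needed).  ``sqrt=True``
    returns the square root, which satisfies the triangle inequality.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(
            f"misaligned profiles ({p.shape} vs {q.shape}); union-align with zeros first"
        )
    p = _check_profile(p, "P")
    q = _check_profile(q, "Q")
    m = (p + q) / 2.0
    # m >= p/2 wherever p > 0, but halving a subnormal can underflow m
    # to exactly zero; such entries carry ~1e-324 mass and contribute
    # nothing, so guard the denominator
    safe_m = np.where(m > 0, m, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_p = np.where((p > 0) & (m > 0), p * np.log2(np.where(p > 0, p / safe_m, 1.0)), 0.0).sum()
        kl_q = np.where((q > 0) & (m > 0), q * np.log2(np.where(q > 0, q / safe_m, 1.0)), 0.0).sum()
    d = 0.5 * kl_p + 0.5 * kl_q
    d = float(min(max(d, 0.0), 1.0))  # clamp fp wobble at the boundaries
    return float(np.sqrt(d)) if sqrt else d


def distance_matrix(table: AbundanceTable, *, sqrt: bool = False) -> DistanceMatrix:
    """All-pairs Jensen-Shannon distances for a relative table."""
    if table.value_kind is not ValueKind.RELATIVE:
        raise ValueError("distances require a relative table")
    values = table.values
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jsd(values[i], values[j], sqrt=sqrt)
    return DistanceMatrix(list(table.sample_ids), out)


@dataclass
class RarefactionCurve:
    sample_id: str
    depths: np.ndarray
    expected_richness: np.ndarray
    replicate_count: int
    seed: int


def expected_richness_hypergeometric(counts: np.ndarray, depth: int) -> float:
    """Exact expected richness in a without-replacement subsample of size
    ``depth``: sum_i [1 - C(N-c_i, depth)/C(N, depth)].

    Serves as the closed-form check for the Monte-Carlo estimate.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth > total:
        raise ValueError("depth exceeds library size")
    # log-gamma evaluation keeps large binomials stable
    from scipy.special import gammaln

    def log_comb(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    with np.errstate(invalid="ignore"):
        log_ratio = log_comb(total - counts, depth) - log_comb(total, depth)
    p_absent = np.where(total - counts >= depth, np.exp(log_ratio), 0.0)
    return float((1.0 - p_absent).sum())


def rarefy_richness(
    counts: np.ndarray | pd.Series,
    depths: list[int] | np.ndarray,
    replicates: int = 100,
    seed: int = 0,
    sample_id: str = "",
) -> RarefactionCurve:
    """Monte-Carlo rarefaction: mean observed richness over seeded
    subsamples drawn without replacement at each depth."""
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("rarefaction requires integer counts")
        counts = np.round(counts).astype(np.int64)
    if (counts < 0).any():
        raise ValueError("negative counts")
    total = int(counts.sum())
    depths = np.asarray(sorted(int(d) for d in depths))
    if (depths < 1).any():
        raise ValueError("depths must be positive")
    if depths.max() > total:
        raise ValueError(f"depth {depths.max()} exceeds library size {total}")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(counts)), counts)
    richness = np.empty(len(depths))
    for k, depth in enumerate(depths):
        acc = 0
        for _ in range(replicates):
            sub = rng.choice(pool, size=depth, replace=False)
            acc += len(np.unique(sub))
        richness[k] = acc / replicates
    return RarefactionCurve(sample_id, depths, richness, replicates, seed)
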
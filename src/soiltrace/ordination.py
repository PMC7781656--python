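"""Principal coordinates analysis and PERMANOVA on a distance matrix.

Both are implemented directly from their definitions.  PCoA is classical
scaling: eigendecompose the Gower-centered matrix ``-1/2 J D^2 J`` and
scale eigenvectors by the square roots of the positive eigenvalues.
PERMANOVA partitions the sum of squared distances by a single factor and
assesses its pseudo-F against seeded label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import DistanceMatrix

__all__ = ["PcoaResult", "PermanovaResult", "pcoa", "permanova", "permanova_f"]


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues
    negative_eigenvalue_count: int

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distances among the embedded coordinates."""
        x = self.coordinates
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=-1)
        np.fill_diagonal(d2, 0.0)
        return np.sqrt(d2)


def pcoa(dm: DistanceMatrix, *, eps: float = 1e-10) -> PcoaResult:
    """Classical multidimensional scaling of a distance matrix.

    Negative eigenvalues (non-Euclidean input) are reported and their
    axes dropped; no Lingoes/Cailliez correction is applied.
    """
    d = dm.entries
    n = d.shape[0]
    if n < 2:
        raise ValueError("PCoA needs at least two samples")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    positive = eigvals > eps * scale
    negative = int((eigvals < -eps * scale).sum())
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])[None, :]
    pos_sum = eigvals[positive].sum()
    prop = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return PcoaResult(
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
        negative_eigenvalue_count=negative,
    )


@dataclass
class PermanovaResult:
    factor_name: str
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int


def _group_codes(labels: list[str] | np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def permanova_f(d: np.ndarray, codes: np.ndarray) -> float:
    """Pseudo-F for integer group codes on a squared-distance partition.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous terms
    per group; F = (SS_between/(a-1)) / (SS_within/(n-a)).
    """
    n = d.shape[0]
    d2 = d**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    groups = np.unique(codes)
    for g in groups:
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    a = len(groups)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return float((ss_between / (a - 1)) / (ss_within / (n - a)))


def permanova(
    dm: DistanceMatrix,
    labels: list[str] | np.ndarray,
    n_permutations: int = 999,
    seed: int = 0,
    factor_name: str = "factor",
) -> PermanovaResult:
    """One-factor PERMANOVA with seeded label permutations.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations), so the smallest
    attainable p is 1/(n_permutations+1).
    """
    labels = np.asarray(labels)
    if len(labels) != len(dm.sample_ids):
        raise ValueError("label count does not match distance matrix")
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    codes = _group_codes(labels)
    a = len(np.unique(codes))
    if a < 2:
        raise ValueError("constant labels: need at least two groups")
    counts = np.bincount(codes)
    if (counts == 0).any():
        raise ValueError("empty group")
    d = dm.entries
    n = d.shape[0]
    f_obs = permanova_f(d, codes)

    d2 = d**2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within_obs = 0.0
    for g in np.unique(codes):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within_obs += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    r2 = float((ss_total - ss_within_obs) / ss_total) if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if permanova_f(d, codes[perm]) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        factor_name=factor_name,
        pseudo_F=f_obs,
        R2=r2,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
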
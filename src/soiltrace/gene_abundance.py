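"""Length-normalized gene abundance and gene-to-KO aggregation.

Shotgun read counts per gene are converted to per-sample relative gene
abundances in two steps: the copy number of gene *i* is its mapped-read
count divided by its length, ``b_i = x_i / L_i``, and the relative
abundance closes copy numbers over the sample, ``a_i = b_i / sum_j b_j``.
Gene-level tables are then aggregated to KEGG Orthology (KO) groups via
the catalog's KO assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import AbundanceTable, FeatureKind, GeneCatalog, ValueKind

__all__ = [
    "GeneAbundanceVector",
    "length_normalize",
    "length_normalize_table",
    "aggregate_to_ko",
    "UNASSIGNED_KO",
]

#: pooled pseudo-KO for genes with no KEGG assignment; excluded from tests
UNASSIGNED_KO = "unassigned"


@dataclass
class GeneAbundanceVector:
    """Per-sample copy numbers (``b_i``) and relative abundances (``a_i``)."""

    gene_ids: list[str]
    copy_number: np.ndarray
    relative_abundance: np.ndarray
    no_reads: bool = False  # set when every x_i was zero

    def as_series(self) -> pd.Series:
        return pd.Series(self.relative_abundance, index=self.gene_ids)


def length_normalize(
    counts: dict[str, float] | pd.Series, catalog: GeneCatalog
) -> GeneAbundanceVector:
    """Length-normalize one sample's mapped-read counts.

    Counts are accepted as non-negative reals (fractional multi-mapping
    weights occur in practice); non-integer values trigger a warning,
    not an error.  If no reads mapped at all, relative abundances are
    defined as all-zero and ``no_reads`` is flagged.
    """
    series = pd.Series(counts, dtype=float)
    if (series < 0).any():
        bad = series.index[series < 0][0]
        raise ValueError(f"negative read count for gene {bad!r}")
    missing = sorted(set(series.index) - set(catalog.data.index))
    if missing:
        raise KeyError(f"genes absent from catalog: {missing[:10]}")
    frac = series[(series % 1) != 0]
    if len(frac):
        warnings.warn(
            f"{len(frac)} non-integer read counts (multi-mapping weights?); accepted",
            stacklevel=2,
        )
    lengths = catalog.lengths(series.index)
    b = series.to_numpy() / lengths
    total = b.sum()
    if total > 0:
        a = b / total
        return GeneAbundanceVector(list(series.index), b, a, no_reads=False)
    return GeneAbundanceVector(list(series.index), b, np.zeros_like(b), no_reads=True)


def length_normalize_table(table: AbundanceTable, catalog: GeneCatalog) -> AbundanceTable:
    """Apply length normalization to every sample of a gene count table,
    yielding a relative gene-abundance table."""
    if table.feature_kind is not FeatureKind.GENE:
        raise ValueError("length normalization applies to gene-level tables")
    missing = sorted(set(table.feature_ids) - set(catalog.data.index))
    if missing:
        raise KeyError(f"genes absent from catalog: {missing[:10]}")
    lengths = catalog.lengths(table.feature_ids)
    b = table.values / lengths[None, :]
    totals = b.sum(axis=1)
    if (totals == 0).any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"samples with no mapped reads: {bad}")
    a = b / totals[:, None]
    df = pd.DataFrame(a, index=table.data.index, columns=table.data.columns)
    return AbundanceTable(df, FeatureKind.GENE, ValueKind.RELATIVE)


def aggregate_to_ko(
    table: AbundanceTable, catalog: GeneCatalog, *, drop_unassigned: bool = True
) -> tuple[AbundanceTable, dict]:
    """Sum a gene-level table into KO-level features.

    Genes without a KO assignment are pooled into ``unassigned``.  For
    relative tables the output is re-closed to one over assigned KOs when
    ``drop_unassigned`` (the default); the mass dropped per sample is
    recorded in the returned provenance dict.

    Returns ``(ko_table, provenance)`` where provenance holds the
    per-sample assigned fraction and the KO count.
    """
    if table.feature_kind is not FeatureKind.GENE:
        raise ValueError("aggregation applies to gene-level tables")
    kos = [catalog.ko_of(g) or UNASSIGNED_KO for g in table.feature_ids]
    grouped = table.data.T.groupby(pd.Index(kos, name="ko_id")).sum().T
    assigned_cols = [c for c in grouped.columns if c != UNASSIGNED_KO]
    unassigned = (
        grouped[UNASSIGNED_KO] if UNASSIGNED_KO in grouped.columns
        else pd.Series(0.0, index=grouped.index)
    )
    totals = grouped.sum(axis=1)
    with np.errstate(invalid="ignore"):
        assigned_fraction = np.where(totals > 0, 1.0 - unassigned / totals, 0.0)
    provenance = {
        "n_kos": len(assigned_cols),
        "assigned_fraction": dict(zip(grouped.index, assigned_fraction.tolist())),
        "reclosed": False,
    }
    if not assigned_cols:
        warnings.warn("no gene has a KO assignment; KO table is empty", stacklevel=2)
        empty = pd.DataFrame(index=table.data.index)
        return AbundanceTable(empty, FeatureKind.KO, table.value_kind), provenance
    if drop_unassigned:
        out = grouped[assigned_cols]
        if table.value_kind is ValueKind.RELATIVE:
            sums = out.sum(axis=1)
            if (sums == 0).any():
                bad = list(out.index[sums == 0])
                raise ValueError(f"samples with zero assigned abundance: {bad}")
            out = out.div(sums, axis=0)
            provenance["reclosed"] = True
    else:
        out = grouped
    return AbundanceTable(out.copy(), FeatureKind.KO, table.value_kind), provenance
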
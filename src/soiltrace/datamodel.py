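"""Domain types and tabular I/O for the exposure-history pipeline.

Every module in :mod:`soiltrace` consumes the conventions fixed here:
samples are rows, features are columns, tables travel as TSV (UTF-8,
``.`` decimal) with the first column holding sample identifiers and the
header row holding feature identifiers.  Feature identifiers are opaque
strings; no taxonomic parsing is attempted.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FeatureKind",
    "ValueKind",
    "SampleType",
    "Environment",
    "SampleRecord",
    "AbundanceTable",
    "GeneCatalog",
    "PathwayMap",
    "DistanceMatrix",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "read_gene_catalog",
    "read_pathway_map",
    "read_distance_matrix",
    "write_distance_matrix",
    "to_relative",
    "display_filter",
]

#: tolerance for accepting a nominally relative row before renormalizing
RELATIVE_SUM_TOL = 1e-6
#: tolerance for asserting that a relative row sums to one
RELATIVE_STRICT_TOL = 1e-9


class FeatureKind(str, enum.Enum):
    TAXON = "taxon"
    GENE = "gene"
    KO = "KO"


class ValueKind(str, enum.Enum):
    COUNT = "count"
    RELATIVE = "relative"


class SampleType(str, enum.Enum):
    SOIL = "soil"
    GUT = "gut"


class Environment(str, enum.Enum):
    DESERT = "desert"
    STEPPE = "steppe"
    FOREST = "forest"


ENVIRONMENTS = tuple(e.value for e in Environment)


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata for one soil or fecal metagenome.

    ``timepoint`` is days since birth: 0 for soil inputs, 60 or 90 for
    gut samples.  Soil samples and Day-60 gut samples are, by design,
    still in their birthplace environment.
    """

    sample_id: str
    mouse_id: str
    sample_type: SampleType
    birthplace: Environment
    current_env: Environment
    timepoint: int

    def __post_init__(self) -> None:
        if self.timepoint < 0:
            raise ValueError(f"negative timepoint for sample {self.sample_id!r}")
        if self.sample_type is SampleType.SOIL and self.birthplace != self.current_env:
            raise ValueError(
                f"soil sample {self.sample_id!r} has birthplace "
                f"{self.birthplace.value!r} != current_env {self.current_env.value!r}"
            )
        if (
            self.sample_type is SampleType.GUT
            and self.timepoint == 60
            and self.birthplace != self.current_env
        ):
            raise ValueError(
                f"Day-60 gut sample {self.sample_id!r} must still be in its "
                f"birthplace environment"
            )


def validate_records(records: Iterable[SampleRecord]) -> list[SampleRecord]:
    """Check cross-record invariants: unique sample ids and unique
    (mouse_id, timepoint) pairs."""
    records = list(records)
    seen_sid: set[str] = set()
    seen_mt: set[tuple[str, int]] = set()
    for r in records:
        if r.sample_id in seen_sid:
            raise ValueError(f"duplicate sample_id {r.sample_id!r}")
        seen_sid.add(r.sample_id)
        key = (r.mouse_id, r.timepoint)
        if key in seen_mt:
            raise ValueError(f"duplicate (mouse_id, timepoint) pair {key!r}")
        seen_mt.add(key)
    return records


@dataclass
class AbundanceTable:
    """A samples x features matrix of counts or relative abundances.

    The payload is a pandas DataFrame whose index holds sample ids and
    whose columns hold feature ids.  Relative tables keep every row
    summing to one within ``RELATIVE_STRICT_TOL``.
    """

    data: pd.DataFrame
    feature_kind: FeatureKind
    value_kind: ValueKind

    def __post_init__(self) -> None:
        self.feature_kind = FeatureKind(self.feature_kind)
        self.value_kind = ValueKind(self.value_kind)
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at sample {df.index[i]!r}, feature {df.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at sample {df.index[i]!r}, feature {df.columns[j]!r}"
            )
        if self.value_kind is ValueKind.RELATIVE and df.shape[1] > 0:
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > RELATIVE_STRICT_TOL
            if bad.any():
                raise ValueError(
                    f"relative table row {df.index[int(np.argmax(bad))]!r} sums to "
                    f"{sums[int(np.argmax(bad))]:.9g}, not 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return AbundanceTable(self.data.loc[sample_ids].copy(), self.feature_kind, self.value_kind)

    def union_align(self, other: "AbundanceTable") -> tuple["AbundanceTable", "AbundanceTable"]:
        """Align two tables onto the union of their feature sets, padding
        missing features with zeros (the convention all pairwise-distance
        and colonization computations rely on)."""
        features = sorted(set(self.data.columns) | set(other.data.columns))
        a = self.data.reindex(columns=features, fill_value=0.0)
        b = other.data.reindex(columns=features, fill_value=0.0)
        return (
            AbundanceTable(a, self.feature_kind, self.value_kind),
            AbundanceTable(b, other.feature_kind, other.value_kind),
        )


@dataclass
class GeneCatalog:
    """Gene lengths and KO assignments for length normalization.

    ``ko_id`` is NaN/None for genes without a KEGG Orthology assignment.
    """

    data: pd.DataFrame  # index gene_id; columns length_bp, ko_id

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if (df["length_bp"] <= 0).any():
            bad = df.index[df["length_bp"] <= 0][0]
            raise ValueError(f"non-positive length for gene {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def lengths(self, gene_ids: Iterable[str]) -> np.ndarray:
        return self.data.loc[list(gene_ids), "length_bp"].to_numpy(dtype=float)

    def ko_of(self, gene_id: str) -> str | None:
        ko = self.data.loc[gene_id, "ko_id"]
        return None if pd.isna(ko) else str(ko)


@dataclass
class PathwayMap:
    """KO -> pathway membership; a KO may belong to several pathways."""

    members: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for pid, kos in self.members.items():
            if not kos:
                raise ValueError(f"pathway {pid!r} has no member KOs")
            self.members[pid] = frozenset(kos)

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.members)

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self.members[pathway_id]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with an explicit sample ordering."""

    sample_ids: list[str]
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n = len(self.sample_ids)
        if self.entries.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if np.isnan(self.entries).any():
            raise ValueError("NaN in distance matrix")
        if (self.entries < 0).any():
            raise ValueError("negative distance")
        if not np.allclose(self.entries, self.entries.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.entries), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        # exact symmetry/zero diagonal after the tolerance check
        self.entries = (self.entries + self.entries.T) / 2.0
        np.fill_diagonal(self.entries, 0.0)

    def subset(self, sample_ids: Iterable[str]) -> "DistanceMatrix":
        sample_ids = list(sample_ids)
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(sample_ids, self.entries[np.ix_(idx, idx)])

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.sample_ids.index(pair[0])
        j = self.sample_ids.index(pair[1])
        return float(self.entries[i, j])


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path: str | Path | io.StringIO, csv: bool) -> pd.DataFrame:
    sep = "," if csv else "\t"
    # pandas silently de-duplicates header names; check the raw header first
    if isinstance(path, io.StringIO):
        header = path.readline()
        path.seek(0)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
    fields = header.rstrip("\n").split(sep)[1:]
    if len(fields) != len(set(fields)):
        dup = next(f for f in fields if fields.count(f) > 1)
        raise ValueError(f"duplicate feature id {dup!r} in header")
    return pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})


def read_abundance_table(
    path: str | Path | io.StringIO,
    feature_kind: FeatureKind | str,
    value_kind: ValueKind | str,
    *,
    csv: bool = False,
) -> AbundanceTable:
    """Read a samples x features TSV (CSV via ``csv=True``).

    Relative tables whose rows deviate from one by at most
    ``RELATIVE_SUM_TOL`` are silently renormalized; larger deviations are
    rejected.
    """
    df = _read_table(path, csv)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.rename_axis(index=None, columns=None)
    value_kind = ValueKind(value_kind)
    if value_kind is ValueKind.RELATIVE:
        values = df.to_numpy(dtype=float)
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at sample {df.index[i]!r}, feature {df.columns[j]!r}"
            )
        sums = values.sum(axis=1)
        off = np.abs(sums - 1.0)
        if (off > RELATIVE_SUM_TOL).any():
            bad = int(np.argmax(off))
            raise ValueError(
                f"relative table row {df.index[bad]!r} sums to {sums[bad]:.9g}; "
                f"deviation exceeds {RELATIVE_SUM_TOL:g}"
            )
        df = df.div(sums, axis=0)
    return AbundanceTable(df, FeatureKind(feature_kind), value_kind)


def write_abundance_table(table: AbundanceTable, path: str | Path, *, csv: bool = False) -> None:
    table.data.to_csv(path, sep="," if csv else "\t", index_label="sample_id")


def read_metadata(path: str | Path | io.StringIO, *, csv: bool = False) -> list[SampleRecord]:
    df = _read_table(path, csv).reset_index()
    records = [
        SampleRecord(
            sample_id=str(row.sample_id),
            mouse_id=str(row.mouse_id),
            sample_type=SampleType(row.sample_type),
            birthplace=Environment(row.birthplace),
            current_env=Environment(row.current_env),
            timepoint=int(row.timepoint),
        )
        for row in df.itertuples(index=False)
    ]
    return validate_records(records)


def write_metadata(records: Iterable[SampleRecord], path: str | Path, *, csv: bool = False) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "mouse_id": r.mouse_id,
                "sample_type": r.sample_type.value,
                "birthplace": r.birthplace.value,
                "current_env": r.current_env.value,
                "timepoint": r.timepoint,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="," if csv else "\t", index=False)


def metadata_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id (convenience for joins)."""
    rows = [
        {
            "sample_id": r.sample_id,
            "mouse_id": r.mouse_id,
            "sample_type": r.sample_type.value,
            "birthplace": r.birthplace.value,
            "current_env": r.current_env.value,
            "timepoint": r.timepoint,
        }
        for r in records
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def read_gene_catalog(path: str | Path | io.StringIO, *, csv: bool = False) -> GeneCatalog:
    df = _read_table(path, csv)
    df.index = df.index.astype(str)
    df["length_bp"] = df["length_bp"].astype(int)
    return GeneCatalog(df[["length_bp", "ko_id"]])


def write_gene_catalog(catalog: GeneCatalog, path: str | Path, *, csv: bool = False) -> None:
    catalog.data.to_csv(path, sep="," if csv else "\t", index_label="gene_id")


def read_pathway_map(path: str | Path | io.StringIO, *, csv: bool = False) -> PathwayMap:
    """Long-format TSV with columns pathway_id, ko_id."""
    df = pd.read_csv(path, sep="," if csv else "\t", dtype=str)
    members: dict[str, set[str]] = {}
    for pid, ko in zip(df["pathway_id"], df["ko_id"]):
        members.setdefault(pid, set()).add(ko)
    return PathwayMap({p: frozenset(k) for p, k in members.items()})


def write_pathway_map(pmap: PathwayMap, path: str | Path, *, csv: bool = False) -> None:
    rows = [
        {"pathway_id": pid, "ko_id": ko}
        for pid in pmap.pathway_ids
        for ko in sorted(pmap[pid])
    ]
    pd.DataFrame(rows).to_csv(path, sep="," if csv else "\t", index=False)


def read_distance_matrix(path: str | Path | io.StringIO, *, csv: bool = False) -> DistanceMatrix:
    df = _read_table(path, csv)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path, *, csv: bool = False) -> None:
    pd.DataFrame(dm.entries, index=dm.sample_ids, columns=dm.sample_ids).to_csv(
        path, sep="," if csv else "\t", index_label="sample_id"
    )


# ---------------------------------------------------------------------------
# table transforms


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Close each sample row to relative abundances.

    Idempotent on already-relative tables.  A sample with no observed
    features cannot be closed and is reported by id.
    """
    values = table.values
    sums = values.sum(axis=1)
    zero = sums == 0
    if zero.any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"all-zero sample rows cannot be made relative: {bad}")
    df = pd.DataFrame(values / sums[:, None], index=table.data.index, columns=table.data.columns)
    return AbundanceTable(df, table.feature_kind, ValueKind.RELATIVE)


def display_filter(table: AbundanceTable, threshold: float = 0.001) -> AbundanceTable:
    """Collapse per-sample minor features (abundance <= threshold) into an
    ``others`` feature, as done for stacked-bar displays.

    Rows keep their sums exactly; a feature below the threshold in one
    sample but not another is collapsed only where it is minor.  Feature
    columns that end up zero in every sample are dropped.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    if table.value_kind is not ValueKind.RELATIVE:
        raise ValueError("display_filter requires a relative table")
    if "others" in table.data.columns:
        raise ValueError("table already contains an 'others' feature")
    values = table.values.copy()
    minor = values <= threshold
    others = np.where(minor, values, 0.0).sum(axis=1)
    values[minor] = 0.0
    df = pd.DataFrame(values, index=table.data.index, columns=table.data.columns)
    df["others"] = others
    keep = (df.to_numpy() > 0).any(axis=0) | (df.columns == "others")
    df = df.loc[:, keep]
    return AbundanceTable(df, table.feature_kind, ValueKind.RELATIVE)
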
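"""Abundance-table IO, taxonomy aggregation, normalization, filtering, distances.

The pipeline starts at the relative-abundance matrix: samples in rows, taxa in
columns, optionally annotated with Greengenes-style rank-prefixed lineage
strings (``k__...;p__...;...;g__Bacteroides``).  Everything downstream assumes
total-sum-scaled rows (each sample on the probability simplex).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AbundanceTable",
    "DistanceMatrix",
    "read_abundance_table",
    "aggregate_taxonomy",
    "normalize_tss",
    "filter_taxa",
    "remove_dominated",
    "pairwise_distances",
    "METRICS",
    "RANK_PREFIX",
]

METRICS = ("manhattan", "euclidean", "braycurtis", "jensenshannon")

RANK_PREFIX = {"Kingdom": "k__", "Phylum": "p__", "Class": "c__",
               "Order": "o__", "Family": "f__", "Genus": "g__"}

#: name for taxa unclassified at the aggregation level
REST = "Rest"


@dataclass
class AbundanceTable:
    """Samples × taxa nonnegative matrix with ids and optional lineages."""

    sample_ids: list[str]
    taxon_ids: list[str]
    matrix: np.ndarray
    lineages: list[str] | None = None
    level: str = "OTU"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError("matrix shape does not match id lists")
        if (self.matrix < 0).any():
            raise ValueError("abundance matrix has negative entries")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon ids")
        if self.lineages is not None and len(self.lineages) != len(self.taxon_ids):
            raise ValueError("lineages length does not match taxon count")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def d(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.taxon_ids)
        df.index.name = "sample_id"
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class DistanceMatrix:
    metric: str
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric within 1e-12")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12 or (v < -1e-12).any():
            raise ValueError("distance matrix must be nonnegative with zero diagonal")
        np.fill_diagonal(v, 0.0)
        self.values = np.maximum(v, 0.0)


def read_abundance_table(path: str | Path, orientation: str = "samples-in-rows",
                         lineage_column: str | None = None) -> AbundanceTable:
    """Read a TSV/CSV abundance matrix in either orientation.

    ``lineage_column`` names a non-numeric column carrying lineage strings
    (only meaningful for taxa-in-rows input).  Counts or proportions are both
    accepted; call :func:`normalize_tss` afterwards.
    """
    if orientation not in ("samples-in-rows", "taxa-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)

    lineages = None
    if lineage_column is not None:
        if lineage_column not in df.columns:
            raise ValueError(f"lineage column {lineage_column!r} not in file")
        lineages = df[lineage_column].astype(str).tolist()
        df = df.drop(columns=[lineage_column])

    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        raise ValueError(f"non-numeric values in column(s) {list(bad[:3])}")
    df = df.astype(float)
    if (df.values < 0).any():
        i, j = np.argwhere(df.values < 0)[0]
        raise ValueError(f"negative abundance at row {df.index[i]!r}, column {df.columns[j]!r}")

    if orientation == "taxa-in-rows":
        return AbundanceTable(sample_ids=[str(c) for c in df.columns],
                              taxon_ids=list(df.index), matrix=df.values.T,
                              lineages=lineages)
    if lineages is not None:
        raise ValueError("lineage_column is only valid with taxa-in-rows input")
    return AbundanceTable(sample_ids=list(df.index),
                          taxon_ids=[str(c) for c in df.columns],
                          matrix=df.values)


def _rank_name(lineage: str, level: str) -> str:
    """Extract the rank name at ``level`` from a rank-prefixed lineage string."""
    prefix = RANK_PREFIX[level]
    for part in str(lineage).split(";"):
        part = part.strip()
        if part.startswith(prefix):
            name = part[len(prefix):].strip()
            return name if name else REST
    return REST


def aggregate_taxonomy(t: AbundanceTable, level: str) -> AbundanceTable:
    """Sum abundances over taxa sharing the rank name at ``level``.

    Taxa unclassified at that rank pool into the single ``Rest`` taxon.
    Row sums are conserved exactly (pure regrouping of columns).
    """
    if level not in ("Genus", "Family", "Order"):
        raise ValueError(f"unsupported aggregation level {level!r}")
    if t.lineages is None:
        raise ValueError("table has no lineages; taxonomy aggregation is impossible")
    names = [_rank_name(lin, level) for lin in t.lineages]
    order: list[str] = []
    seen: dict[str, int] = {}
    for nm in names:
        if nm not in seen:
            seen[nm] = len(order)
            order.append(nm)
    agg = np.zeros((t.n, len(order)))
    for j, nm in enumerate(names):
        agg[:, seen[nm]] += t.matrix[:, j]
    return AbundanceTable(sample_ids=list(t.sample_ids), taxon_ids=order,
                          matrix=agg, level=level)


def normalize_tss(t: AbundanceTable) -> AbundanceTable:
    """Total-sum scaling: divide each sample by its total abundance."""
    sums = t.matrix.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(f"sample {t.sample_ids[zero[0]]!r} has zero total abundance")
    return replace(t, matrix=t.matrix / sums[:, None])


def filter_taxa(t: AbundanceTable, min_prevalence: float = 0.01,
                min_std: float = 0.001) -> tuple[AbundanceTable, pd.DataFrame]:
    """Drop rare and near-constant taxa.

    A taxon is removed when it is nonzero in fewer than ``min_prevalence``
    of samples, or when the standard deviation of its relative abundance is
    below ``min_std``.  Ties at the thresholds are retained (the rule is
    strictly "less than").  Returns the filtered table and a report of
    dropped taxa with the reason(s).
    """
    prevalence = (t.matrix > 0).mean(axis=0)
    std = t.matrix.std(axis=0)
    low_prev = prevalence < min_prevalence
    low_std = std < min_std
    drop = low_prev | low_std
    if drop.all():
        raise ValueError("all taxa would be removed by the filter")
    report = pd.DataFrame({
        "taxon_id": [t.taxon_ids[j] for j in np.flatnonzero(drop)],
        "prevalence": prevalence[drop],
        "std": std[drop],
        "low_prevalence": low_prev[drop],
        "low_std": low_std[drop],
    })
    keep = ~drop
    kept = AbundanceTable(
        sample_ids=list(t.sample_ids),
        taxon_ids=[tid for tid, k in zip(t.taxon_ids, keep) if k],
        matrix=t.matrix[:, keep],
        lineages=None if t.lineages is None
        else [lin for lin, k in zip(t.lineages, keep) if k],
        level=t.level,
    )
    return kept, report


def remove_dominated(t: AbundanceTable, threshold: float = 0.7,
                     policy: str = "drop-sample") -> AbundanceTable:
    """Sensitivity variant: handle samples dominated by a single taxon.

    ``drop-sample`` (default) removes every sample in which any taxon exceeds
    ``threshold`` relative abundance; ``zero-taxon`` instead zeroes the
    offending entries and re-closes the rows.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if policy not in ("drop-sample", "zero-taxon"):
        raise ValueError(f"unknown policy {policy!r}")
    dominated = t.matrix > threshold
    if policy == "drop-sample":
        keep = ~dominated.any(axis=1)
        if not keep.any():
            raise ValueError("every sample is dominated; nothing left")
        return AbundanceTable(
            sample_ids=[s for s, k in zip(t.sample_ids, keep) if k],
            taxon_ids=list(t.taxon_ids), matrix=t.matrix[keep],
            lineages=t.lineages, level=t.level)
    out = t.matrix.copy()
    out[dominated] = 0.0
    sums = out.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("zeroing the dominant taxon left an empty sample")
    return replace(t, matrix=out / sums[:, None])


def pairwise_distances(t: AbundanceTable | np.ndarray, metric: str) -> DistanceMatrix:
    """Full symmetric distance matrix under one of the four metrics.

    Jensen–Shannon is the metric form: the square root of the JS divergence
    computed with the natural logarithm.  Bray–Curtis and Jensen–Shannon
    expect rows on the simplex.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    X = t.matrix if isinstance(t, AbundanceTable) else np.asarray(t, dtype=float)
    sample_ids = t.sample_ids if isinstance(t, AbundanceTable) else []
    scipy_name = {"manhattan": "cityblock", "euclidean": "euclidean",
                  "braycurtis": "braycurtis", "jensenshannon": "jensenshannon"}[metric]
    vals = squareform(pdist(X, metric=scipy_name))
    vals = np.nan_to_num(vals, nan=0.0)  # JS of identical zero-pattern rows
    vals = 0.5 * (vals + vals.T)
    return DistanceMatrix(metric=metric, values=vals, sample_ids=list(sample_ids))
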
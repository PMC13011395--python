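"""Read-alignment profiling: best-hit resolution, coverage breadth,
length-adjusted relative abundance, and taxonomic aggregation.

Alignments are handled as pandas DataFrames with the columns of
:data:`ALIGNMENT_COLUMNS`; coordinates are 0-based half-open throughout
(SAM's 1-based convention is converted at the reader boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of the tabular alignment representation.
ALIGNMENT_COLUMNS = ["sample_id", "read_id", "votu_id", "start", "end", "score"]

CATALOG_COLUMNS = [
    "votu_id",
    "genome_length",
    "family",
    "lifestyle",
    "completeness",
    "host_genus",
    "host_family",
    "ko_set",
]


@dataclass
class VOTUCatalog:
    """Static per-vOTU annotation table.

    ``df`` is indexed by ``votu_id`` and carries ``genome_length``,
    ``family`` (``"unassigned"`` if unknown), ``lifestyle`` (lytic /
    temperate / unknown), ``completeness`` (percent), ``host_genus``,
    ``host_family`` (``None`` when unpredicted) and ``ko_set``
    (a frozenset of KO identifiers).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.df.index.is_unique:
            dupes = self.df.index[self.df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate votu_id values: {dupes}")
        if (self.df["genome_length"] < 1).any():
            raise ValueError("genome_length must be >= 1")
        comp = self.df["completeness"]
        if ((comp < 0) | (comp > 100)).any():
            raise ValueError("completeness must lie in [0, 100]")

    @property
    def votu_ids(self) -> list[str]:
        return self.df.index.tolist()

    @property
    def genome_lengths(self) -> pd.Series:
        return self.df["genome_length"]

    def __len__(self) -> int:
        return len(self.df)

    def write_tsv(self, path) -> None:
        out = self.df.copy()
        out["ko_set"] = out["ko_set"].map(lambda s: ";".join(sorted(s)))
        out.to_csv(path, sep="\t", index=True, index_label="votu_id")

    @classmethod
    def read_tsv(cls, path) -> "VOTUCatalog":
        df = pd.read_csv(path, sep="\t", index_col="votu_id")
        df["ko_set"] = df["ko_set"].map(
            lambda s: frozenset(str(s).split(";")) if isinstance(s, str) and s else frozenset()
        )
        for col in ("host_genus", "host_family"):
            df[col] = df[col].where(df[col].notna(), None)
        return cls(df)


@dataclass
class AbundanceMatrix:
    """Samples x features relative abundances plus a presence mask.

    Invariants: values >= 0; every non-empty row sums to 1; a feature
    absent by the presence mask has value 0.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    presence: np.ndarray = field(default=None)  # type: ignore[assignment]
    level: str = "votu"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("values shape does not match sample/feature ids")
        if (self.values < 0).any():
            raise ValueError("abundances must be nonnegative")
        if self.presence is None:
            self.presence = self.values > 0
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != self.values.shape:
            raise ValueError("presence mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, presence: pd.DataFrame | None = None, level: str = "votu"
    ) -> "AbundanceMatrix":
        pres = None if presence is None else presence.to_numpy(dtype=bool)
        return cls(
            sample_ids=df.index.tolist(),
            feature_ids=df.columns.tolist(),
            values=df.to_numpy(dtype=float),
            presence=pres,
            level=level,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return AbundanceMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            values=self.values[idx],
            presence=self.presence[idx],
            level=self.level,
        )

    def renormalized(self) -> "AbundanceMatrix":
        """Rescale each row to sum to 1; all-zero rows stay zero."""
        sums = self.values.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(sums > 0, self.values / sums, 0.0)
        return AbundanceMatrix(
            list(self.sample_ids), list(self.feature_ids), vals, self.presence.copy(), self.level
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# level={self.level}\n")
            self.to_frame().to_csv(fh, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path) -> "AbundanceMatrix":
        level = "votu"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# level="):
                level = first.strip().split("=", 1)[1]
                df = pd.read_csv(fh, sep="\t", index_col="sample_id")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", index_col="sample_id")
        return cls.from_frame(df, level=level)


def _validate_alignments(records: pd.DataFrame) -> pd.DataFrame:
    bad = (records["start"] < 0) | (records["end"] <= records["start"])
    if bad.any():
        logger.warning("rejecting %d alignment records with malformed coordinates", int(bad.sum()))
        records = records.loc[~bad]
    return records


def resolve_best_hits(records: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly one alignment per (sample, read).

    Highest score wins; ties are broken by the lexicographically smallest
    ``votu_id`` so the outcome is deterministic.
    """
    records = _validate_alignments(records)
    ordered = records.sort_values(
        ["sample_id", "read_id", "score", "votu_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(["sample_id", "read_id"], keep="first").reset_index(drop=True)


def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total length of the union of [start, end) intervals (interval merge)."""
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    # an interval opens a new run when it starts past the running max end;
    # within a run the running max is driven entirely by that run's ends
    run_end = np.maximum.accumulate(ends)
    new_run = np.empty(len(starts), dtype=bool)
    new_run[0] = True
    new_run[1:] = starts[1:] > run_end[:-1]
    first = np.flatnonzero(new_run)
    last = np.append(first[1:], len(starts)) - 1
    return int((run_end[last] - starts[first]).sum())


def compute_breadth(records: pd.DataFrame, cat: VOTUCatalog) -> pd.DataFrame:
    """Per-(sample, vOTU) genome fraction covered by at least one read.

    Expects best-hit-resolved records.  Returns a DataFrame with columns
    ``sample_id``, ``votu_id``, ``breadth``.
    """
    unknown = set(records["votu_id"]) - set(cat.votu_ids)
    if unknown:
        raise KeyError(f"alignment references unknown vOTU id(s): {sorted(unknown)[:5]}")
    lengths = cat.genome_lengths
    rows = []
    for (sample, votu), grp in records.groupby(["sample_id", "votu_id"], sort=True):
        covered = _union_length(
            grp["start"].to_numpy(dtype=np.int64), grp["end"].to_numpy(dtype=np.int64)
        )
        rows.append((sample, votu, covered / float(lengths[votu])))
    return pd.DataFrame(rows, columns=["sample_id", "votu_id", "breadth"])


def quantify(
    records: pd.DataFrame,
    cat: VOTUCatalog,
    breadth_threshold: float = 0.10,
) -> AbundanceMatrix:
    """Length-adjusted relative abundances from best-hit alignments.

    Per present vOTU (breadth >= threshold): RPK = reads / (kb of genome),
    scaled by the sample's total mapped reads, then each row is
    renormalized to sum to 1.  vOTUs failing the breadth filter are zeroed
    before renormalization.
    """
    records = resolve_best_hits(records)
    samples = sorted(records["sample_id"].unique())
    counts = (
        records.groupby(["sample_id", "votu_id"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=samples, columns=cat.votu_ids, fill_value=0)
    )
    breadth = (
        compute_breadth(records, cat)
        .pivot(index="sample_id", columns="votu_id", values="breadth")
        .reindex(index=samples, columns=cat.votu_ids)
        .fillna(0.0)
    )
    present = breadth.to_numpy() >= breadth_threshold

    kb = cat.genome_lengths.reindex(cat.votu_ids).to_numpy(dtype=float) / 1000.0
    rpk = counts.to_numpy(dtype=float) / kb
    totals = counts.to_numpy().sum(axis=1, keepdims=True).astype(float)
    empty = totals[:, 0] == 0
    if empty.any():
        logger.warning("%d sample(s) have no mapped reads; emitting zero rows", int(empty.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(totals > 0, rpk / totals, 0.0)
    scaled[~present] = 0.0
    row_sums = scaled.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(row_sums > 0, scaled / row_sums, 0.0)
    return AbundanceMatrix(
        sample_ids=samples,
        feature_ids=list(cat.votu_ids),
        values=values,
        presence=present & (values > 0),
        level="votu",
    )


def aggregate_level(m: AbundanceMatrix, cat: VOTUCatalog, level: str) -> AbundanceMatrix:
    """Sum vOTU abundances within a catalog label (family or host genus).

    Unassigned features are pooled into ``"Unclassified"``; row sums are
    preserved exactly.
    """
    if m.level != "votu":
        raise ValueError("aggregation requires a votu-level matrix")
    if level == "family":
        labels = cat.df["family"]
        out_level = "family"
        unassigned_token = "unassigned"
    elif level == "host_genus":
        labels = cat.df["host_genus"]
        out_level = "genus"
        unassigned_token = None
    else:
        raise ValueError(f"unsupported aggregation level: {level!r}")

    mapped = labels.reindex(m.feature_ids)
    mapped = mapped.where(mapped.notna(), "Unclassified")
    if unassigned_token is not None:
        mapped = mapped.where(mapped != unassigned_token, "Unclassified")

    groups = sorted(mapped.unique())
    vals = np.zeros((len(m.sample_ids), len(groups)))
    pres = np.zeros_like(vals, dtype=bool)
    arr = mapped.to_numpy()
    for j, g in enumerate(groups):
        cols = np.flatnonzero(arr == g)
        vals[:, j] = m.values[:, cols].sum(axis=1)
        pres[:, j] = m.presence[:, cols].any(axis=1)
    return AbundanceMatrix(list(m.sample_ids), groups, vals, pres, out_level)


def prevalence(m: AbundanceMatrix, group_mask: np.ndarray | None = None) -> pd.Series:
    """Per-feature fraction of (selected) samples where the feature is present."""
    if group_mask is None:
        group_mask = np.ones(len(m.sample_ids), dtype=bool)
    group_mask = np.asarray(group_mask, dtype=bool)
    if group_mask.sum() == 0:
        raise ValueError("empty sample mask")
    frac = m.presence[group_mask].mean(axis=0)
    return pd.Series(frac, index=m.feature_ids, name="prevalence")


def mean_abundance(m: AbundanceMatrix, group_mask: np.ndarray | None = None) -> pd.Series:
    if group_mask is None:
        group_mask = np.ones(len(m.sample_ids), dtype=bool)
    return pd.Series(m.values[np.asarray(group_mask, dtype=bool)].mean(axis=0), index=m.feature_ids)
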
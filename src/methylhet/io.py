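"""Reading and writing the formats the pipeline touches.

Internal conventions: all coordinates are 0-based half-open; a CpG site is
identified by the position of the C on the plus strand; plus/minus strand
records of the same CpG (positions p and p+1) are merged onto p by default.
Methylation percentages in coverage files are derived values — read counts
are authoritative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: feature classes the pipeline knows about; "promoter" is accepted on input
#: and is resolved to promoter_CGI / promoter_nonCGI during bin annotation.
FEATURE_LABELS = frozenset(
    {
        "CGI",
        "promoter",
        "promoter_CGI",
        "promoter_nonCGI",
        "exon",
        "intron",
        "UTR",
        "LINE",
        "LTR",
        "SINE",
        "H3K4me1",
        "H3K4me3",
        "H3K36me3",
        "intergenic",
    }
)

_SITE_COLUMNS = ["chrom", "pos", "count_meth", "count_unmeth"]


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class CpGCallTable:
    """Per-CpG methylated/unmethylated read counts for one sample.

    ``df`` holds one row per strand-merged CpG site with columns
    ``chrom, pos, count_meth, count_unmeth``; every stored site has
    depth >= 1 and ``(chrom, pos)`` is unique and sorted.
    """

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = _normalize_site_df(self.df)

    @property
    def depth(self) -> pd.Series:
        return self.df["count_meth"] + self.df["count_unmeth"]

    @property
    def level(self) -> pd.Series:
        d = self.depth
        return self.df["count_meth"] / d

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CpGCallTable):
            return NotImplemented
        return self.sample_id == other.sample_id and self.df.reset_index(
            drop=True
        ).equals(other.df.reset_index(drop=True))


def _normalize_site_df(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, _SITE_COLUMNS].copy()
    if len(df):
        if (df["count_meth"] < 0).any() or (df["count_unmeth"] < 0).any():
            raise ValueError("negative read counts")
        depth = df["count_meth"] + df["count_unmeth"]
        df = df[depth > 0]
        df = df.sort_values(["chrom", "pos"], kind="mergesort")
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) records")
    df = df.reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    df["count_meth"] = df["count_meth"].astype(np.int64)
    df["count_unmeth"] = df["count_unmeth"].astype(np.int64)
    return df


def _merge_strands(df: pd.DataFrame) -> pd.DataFrame:
    """Merge plus/minus records of one CpG (0-based positions p, p+1) onto p.

    Greedy left-to-right pairing; CpG starts on the same strand are never
    adjacent, so any adjacent pair is the two strands of one site.
    """
    if not len(df):
        return df
    parts = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        cm = sub["count_meth"].to_numpy()
        cu = sub["count_unmeth"].to_numpy()
        keep_pos, keep_cm, keep_cu = [], [], []
        i = 0
        n = len(pos)
        while i < n:
            if i + 1 < n and pos[i + 1] == pos[i] + 1:
                keep_pos.append(pos[i])
                keep_cm.append(cm[i] + cm[i + 1])
                keep_cu.append(cu[i] + cu[i + 1])
                i += 2
            else:
                keep_pos.append(pos[i])
                keep_cm.append(cm[i])
                keep_cu.append(cu[i])
                i += 1
        parts.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.asarray(keep_pos, dtype=np.int64),
                    "count_meth": np.asarray(keep_cm, dtype=np.int64),
                    "count_unmeth": np.asarray(keep_cu, dtype=np.int64),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def read_bismark_coverage(
    path: str | Path,
    sample_id: str | None = None,
    strand_merge: bool = True,
    assume_zero_based: bool = False,
) -> CpGCallTable:
    """Read a Bismark coverage file into a :class:`CpGCallTable`.

    The file is tab-separated with columns chromosome, start, end,
    methylation percentage, count methylated, count unmethylated, with
    1-based inclusive coordinates (``assume_zero_based`` skips the
    conversion). Sites with zero depth are dropped; strand merging sums
    counts of plus/minus records of the same CpG onto the plus-strand
    position. A methylation percentage inconsistent with the counts by
    more than 0.5 points triggers a warning, counts win.
    """
    path = Path(path)
    names = ["chrom", "start", "end", "pct", "count_meth", "count_unmeth"]
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=names,
            dtype={
                "chrom": str,
                "start": np.int64,
                "end": np.int64,
                "pct": float,
                "count_meth": np.int64,
                "count_unmeth": np.int64,
            },
            comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=names)
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed coverage file: {exc}") from exc
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 1
        raise FormatError(f"{path}: malformed row at line {bad}")
    if len(df):
        depth = df["count_meth"] + df["count_unmeth"]
        with np.errstate(invalid="ignore", divide="ignore"):
            derived = 100.0 * df["count_meth"] / depth
        off = (derived - df["pct"]).abs() > 0.5
        if (off & (depth > 0)).any():
            warnings.warn(
                f"{path}: methylation % column disagrees with counts at "
                f"{int((off & (depth > 0)).sum())} rows; counts used",
                stacklevel=2,
            )
    df["pos"] = df["start"] if assume_zero_based else df["start"] - 1
    df = df[_SITE_COLUMNS]
    df = _normalize_site_df(df)
    if strand_merge:
        df = _merge_strands(df)
    return CpGCallTable(sample_id or path.stem, df)


def write_bismark_coverage(table: CpGCallTable, path: str | Path) -> None:
    """Write a table as single plus-strand Bismark coverage records.

    Round trips through :func:`read_bismark_coverage` losslessly.
    """
    df = table.df
    depth = df["count_meth"] + df["count_unmeth"]
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"] + 1,
            "end": df["pos"] + 1,
            "pct": (100.0 * df["count_meth"] / depth).round(2),
            "count_meth": df["count_meth"],
            "count_unmeth": df["count_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.2f")


@dataclass
class FeatureMap:
    """Labeled genomic intervals with per-chromosome interval trees.

    Intervals are 0-based half-open; overlapping intervals of different
    labels are all retained (feature classes are not mutually exclusive).
    """

    df: pd.DataFrame
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.df.loc[:, ["chrom", "start", "end", "label"]].copy()
        if len(df):
            if (df["start"] >= df["end"]).any():
                bad = df[df["start"] >= df["end"]].iloc[0]
                raise ValueError(
                    f"interval start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
                )
            unknown = set(df["label"]) - FEATURE_LABELS
            if unknown:
                raise ValueError(
                    f"unknown feature label(s) {sorted(unknown)}; "
                    f"known labels: {sorted(FEATURE_LABELS)}"
                )
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.df = df
        self._trees = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            self._trees[chrom] = IntervalTree.from_tuples(
                zip(sub["start"], sub["end"], sub["label"])
            )

    def labels_at(self, chrom: str, start: int, end: int | None = None) -> set[str]:
        """Labels of intervals overlapping [start, end) by >= 1 bp.

        A point query uses [start, start+1). Returns ``{"intergenic"}``
        when no interval overlaps.
        """
        if end is None:
            end = start + 1
        tree = self._trees.get(chrom)
        if tree is None:
            return {"intergenic"}
        hits = {iv.data for iv in tree.overlap(start, end)}
        return hits or {"intergenic"}

    @property
    def labels(self) -> set[str]:
        return set(self.df["label"])


def read_features(path: str | Path) -> FeatureMap:
    """Read BED3+name (chrom, start, end, label) into a :class:`FeatureMap`."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "label"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "label": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "label"])
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: malformed BED file: {exc}") from exc
    return FeatureMap(df)


def write_features(features: FeatureMap, path: str | Path) -> None:
    features.df.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SampleManifest:
    """Sample sheet: sample_id, path, kind (cell|bulk), group, bulk_id."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.loc[:, ["sample_id", "path", "kind", "group", "bulk_id"]].copy()
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids in manifest")
        bad_kind = set(df["kind"]) - {"cell", "bulk"}
        if bad_kind:
            raise ValueError(f"unknown sample kind(s): {sorted(bad_kind)}")
        bulks = set(df.loc[df["kind"] == "bulk", "sample_id"])
        cells = df[df["kind"] == "cell"]
        dangling = set(cells["bulk_id"]) - bulks
        if dangling:
            raise ValueError(f"cells reference missing bulk(s): {sorted(dangling)}")
        self.df = df.reset_index(drop=True)

    @property
    def cells(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "cell"]

    @property
    def bulks(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "bulk"]

    def bulk_of(self, sample_id: str) -> str:
        row = self.df[self.df["sample_id"] == sample_id]
        if not len(row):
            raise KeyError(sample_id)
        return str(row["bulk_id"].iloc[0])


def read_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    return SampleManifest(df)


def write_manifest(manifest: SampleManifest, path: str | Path) -> None:
    manifest.df.to_csv(path, sep="\t", index=False)
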
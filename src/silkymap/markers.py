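"""Ordered marker maps (SNP / microsatellite physical positions)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class MarkerMap:
    """An ordered set of genotyped markers with physical (bp) positions.

    Markers are kept sorted by (chrom, position); ids are unique, and
    positions are unique within a chromosome.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("marker", "chrom", "position_bp")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("no markers")
        if df["marker"].duplicated().any():
            dup = df.loc[df["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id: {dup}")
        if df.duplicated(subset=["chrom", "position_bp"]).any():
            row = df.loc[df.duplicated(subset=["chrom", "position_bp"])].iloc[0]
            raise ValueError(
                f"duplicate position {row['position_bp']} on chrom {row['chrom']}"
            )
        df = df.astype({"marker": str, "chrom": str, "position_bp": np.int64})
        sorted_df = df.sort_values(["chrom", "position_bp"], kind="stable")
        if not sorted_df.index.equals(df.index):
            logger.info("marker map was not position-sorted; sorting")
        self.table = sorted_df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position_bp"].to_numpy()

    @property
    def chroms(self) -> list[str]:
        return self.table["chrom"].tolist()

    def index_of(self, marker_id: str) -> int:
        hits = self.table.index[self.table["marker"] == marker_id]
        if len(hits) == 0:
            raise KeyError(marker_id)
        return int(hits[0])

    def position_of(self, marker_id: str) -> int:
        return int(self.table.loc[self.index_of(marker_id), "position_bp"])

    def within(self, interval: GenomicInterval) -> "MarkerMap":
        df = self.table
        mask = (
            (df["chrom"] == interval.chrom)
            & (df["position_bp"] >= interval.start)
            & (df["position_bp"] <= interval.end)
        )
        sub = df.loc[mask]
        if len(sub) == 0:
            raise ValueError(f"no markers inside {interval}")
        return MarkerMap(sub.reset_index(drop=True))

    def count_within(self, interval: GenomicInterval) -> int:
        df = self.table
        mask = (
            (df["chrom"] == interval.chrom)
            & (df["position_bp"] >= interval.start)
            & (df["position_bp"] <= interval.end)
        )
        return int(mask.sum())

    def span(self, chrom: str | None = None) -> GenomicInterval:
        df = self.table
        if chrom is not None:
            df = df[df["chrom"] == chrom]
        if len(df) == 0:
            raise ValueError(f"no markers on chrom {chrom}")
        c = df["chrom"].iloc[0]
        return GenomicInterval(c, int(df["position_bp"].min()), int(df["position_bp"].max()))

    @classmethod
    def from_records(cls, records) -> "MarkerMap":
        """Build from an iterable of (marker_id, chrom, position_bp)."""
        df = pd.DataFrame(records, columns=["marker", "chrom", "position_bp"])
        return cls(df)


def read_marker_map(path, format: str = "tsv") -> MarkerMap:
    """Read a marker map from a TSV (marker/chrom/position_bp header) or PLINK .map.

    PLINK .map columns are chrom, marker, genetic position (ignored), bp.
    Malformed lines raise with the offending line number; unsorted input is
    sorted with a logged notice.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        rename = {"pos": "position_bp", "position": "position_bp", "id": "marker"}
        df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
        return MarkerMap(df)
    if format == "plink_map":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise ValueError(f"malformed .map line {lineno}: {line!r}")
                try:
                    records.append((fields[1], fields[0], int(fields[3])))
                except ValueError as exc:
                    raise ValueError(f"malformed .map line {lineno}: {line!r}") from exc
        if not records:
            raise ValueError("no markers")
        return MarkerMap.from_records(records)
    raise ValueError(f"unknown marker map format: {format}")
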
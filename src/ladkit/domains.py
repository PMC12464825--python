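"""Ordered LAD/iLAD interval sets.

A :class:`DomainSet` holds the segmentation of a genome into alternating
lamina-associated domains (LADs) and inter-LADs (iLADs): per chromosome the
intervals are sorted, non-overlapping, alternate in state and jointly tile
the covered extent.  Coordinates are 0-based half-open; interval boundaries
fall on bin-size multiples except at chromosome ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

LAD = "LAD"
ILAD = "iLAD"
_STATES = (LAD, ILAD)

__all__ = ["DomainSet", "LAD", "ILAD", "read_bed", "write_bed"]

_COLUMNS = ["chrom", "start", "end", "state", "score", "id"]


@dataclass
class DomainSet:
    """Ordered, non-overlapping LAD/iLAD intervals with optional scores."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in _COLUMNS:
            if col not in df.columns:
                if col == "score":
                    df["score"] = np.nan
                elif col == "id":
                    df["id"] = ""
                else:
                    raise ValueError(f"DomainSet missing column {col!r}")
        df = df[_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad_state = ~df["state"].isin(_STATES)
        if bad_state.any():
            raise ValueError(f"unknown states: {df.loc[bad_state, 'state'].unique()}")
        if (df["start"] >= df["end"]).any():
            raise ValueError("empty or inverted interval")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["start"].values[1:] != sub["end"].values[:-1]).any():
                raise ValueError(f"domains on {chrom} do not tile (gap or overlap)")
            states = sub["state"].values
            if (states[1:] == states[:-1]).any():
                raise ValueError(f"adjacent domains on {chrom} share a state")
        if df["id"].eq("").all():
            df["id"] = [f"D{i:05d}" for i in range(len(df))]
        elif df["id"].duplicated().any():
            raise ValueError("duplicate domain ids")
        self.df = df

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple]) -> "DomainSet":
        """Build from (chrom, start, end, state[, score[, id]]) tuples."""
        rows = []
        for iv in intervals:
            chrom, start, end, state = iv[:4]
            score = iv[4] if len(iv) > 4 else np.nan
            id_ = iv[5] if len(iv) > 5 else ""
            rows.append((chrom, start, end, state, score, id_))
        return cls(pd.DataFrame(rows, columns=_COLUMNS))

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, state: str) -> pd.DataFrame:
        """Intervals of one state, as a plain DataFrame."""
        return self.df[self.df["state"] == state].reset_index(drop=True)

    @property
    def lads(self) -> pd.DataFrame:
        return self.subset(LAD)

    @property
    def ilads(self) -> pd.DataFrame:
        return self.subset(ILAD)

    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def with_scores(self, scores: np.ndarray) -> "DomainSet":
        df = self.df.copy()
        df["score"] = np.asarray(scores, dtype=float)
        return DomainSet(df)

    def state_per_bin(self, grid) -> dict:
        """Per chromosome, an int8 vector: 1 inside a LAD, 0 in an iLAD,
        -1 for bins not covered by any domain."""
        out = {}
        for chrom in grid.chroms:
            labels = np.full(grid.n_bins(chrom), -1, dtype=np.int8)
            sub = self.df[self.df["chrom"] == chrom]
            for r in sub.itertuples():
                b0 = r.start // grid.bin_size
                b1 = -(-r.end // grid.bin_size)  # ceil
                labels[b0:b1] = 1 if r.state == LAD else 0
            out[chrom] = labels
        return out


def write_bed(domains: DomainSet, path, *, score_scale: float = 1000.0) -> None:
    """Write BED6: name = state, score = LAD score x 1000 clipped to [0, 1000]."""
    with open(path, "w") as fh:
        for r in domains.df.itertuples():
            raw = 0.0 if not np.isfinite(r.score) else r.score * score_scale
            bed_score = int(np.clip(raw, 0, 1000))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.state}\t{bed_score}\t.\n")


def read_bed(path) -> DomainSet:
    """Read a BED file whose name column carries the LAD/iLAD state."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "state"]
    return DomainSet(df)
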
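"""Binned genomic signal containers.

The whole pipeline operates on fixed-width genomic bins: integer read counts
per bin (:class:`CountTrack`) and one floating signal value per bin
(:class:`BinnedTrack`, holding log2 antibody:Dam ratios, z-scores or derived
scores).  Bins are 0-based, half-open, tiled from position 0; the final bin of
a chromosome may be partial.  Missing values are NaN and propagate — nothing
in the pipeline imputes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "BinGrid",
    "BinnedTrack",
    "CountTrack",
    "read_chrom_sizes",
    "read_bedgraph",
    "write_bedgraph",
    "read_counts_tsv",
    "write_counts_tsv",
]


@dataclass(frozen=True)
class BinGrid:
    """A fixed-width binning of a genome.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp.  Stored sorted by name so
        two grids over the same genome compare equal.
    bin_size
        Bin width in bp.
    """

    chrom_sizes: Mapping[str, int]
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        ordered = {c: int(l) for c, l in sorted(self.chrom_sizes.items())}
        for chrom, length in ordered.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
        object.__setattr__(self, "chrom_sizes", ordered)

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_sizes[chrom] / self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chroms)

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_size

    def bin_ends(self, chrom: str) -> np.ndarray:
        ends = self.bin_starts(chrom) + self.bin_size
        ends[-1] = min(ends[-1], self.chrom_sizes[chrom])
        return ends

    def bin_index(self, chrom: str, position: int) -> int:
        """Bin containing ``position`` (0-based, half-open bins)."""
        if not 0 <= position < self.chrom_sizes[chrom]:
            raise ValueError(
                f"position {position} outside chromosome {chrom!r} "
                f"(length {self.chrom_sizes[chrom]})"
            )
        return position // self.bin_size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinGrid):
            return NotImplemented
        return (
            self.bin_size == other.bin_size
            and dict(self.chrom_sizes) == dict(other.chrom_sizes)
        )

    def __hash__(self) -> int:
        return hash((self.bin_size, tuple(self.chrom_sizes.items())))


def _validate_data(grid: BinGrid, data: Mapping[str, np.ndarray], dtype) -> Dict[str, np.ndarray]:
    out: Dict[str, np.ndarray] = {}
    if set(data) != set(grid.chroms):
        raise ValueError("data chromosomes do not match grid")
    for chrom in grid.chroms:
        arr = np.asarray(data[chrom], dtype=dtype)
        if arr.ndim != 1 or arr.shape[0] != grid.n_bins(chrom):
            raise ValueError(
                f"chromosome {chrom!r}: expected {grid.n_bins(chrom)} bins, "
                f"got shape {arr.shape}"
            )
        out[chrom] = arr
    return out


@dataclass
class BinnedTrack:
    """Per-bin floating-point signal over a :class:`BinGrid`.

    ``data`` maps chromosome -> float vector of length ``ceil(len/bin_size)``;
    NaN marks missing bins.
    """

    grid: BinGrid
    data: Dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        self.data = _validate_data(self.grid, self.data, np.float64)

    @classmethod
    def from_values(cls, grid: BinGrid, values: np.ndarray) -> "BinnedTrack":
        """Build from a single concatenated vector in grid chromosome order."""
        values = np.asarray(values, dtype=np.float64)
        if values.shape[0] != grid.total_bins:
            raise ValueError("value vector length does not match grid")
        data, offset = {}, 0
        for chrom in grid.chroms:
            n = grid.n_bins(chrom)
            data[chrom] = values[offset : offset + n].copy()
            offset += n
        return cls(grid, data)

    @classmethod
    def full(cls, grid: BinGrid, fill: float = np.nan) -> "BinnedTrack":
        return cls(grid, {c: np.full(grid.n_bins(c), fill) for c in grid.chroms})

    def values(self) -> np.ndarray:
        """All bin values concatenated in grid chromosome order."""
        return np.concatenate([self.data[c] for c in self.grid.chroms])

    def finite_values(self) -> np.ndarray:
        v = self.values()
        return v[np.isfinite(v)]

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(self.grid, {c: v.copy() for c, v in self.data.items()})

    def map(self, fn) -> "BinnedTrack":
        """Apply an elementwise function, preserving NaN."""
        out = {}
        for chrom, v in self.data.items():
            w = np.full_like(v, np.nan)
            m = np.isfinite(v)
            w[m] = fn(v[m])
            out[chrom] = w
        return BinnedTrack(self.grid, out)

    def same_grid(self, other: "BinnedTrack") -> bool:
        return self.grid == other.grid

    def iter_bins(self) -> Iterator[Tuple[str, int, int, float]]:
        for chrom in self.grid.chroms:
            starts = self.grid.bin_starts(chrom)
            ends = self.grid.bin_ends(chrom)
            for s, e, v in zip(starts, ends, self.data[chrom]):
                yield chrom, int(s), int(e), float(v)


@dataclass
class CountTrack:
    """Per-bin non-negative integer read counts for one sample.

    ``role`` distinguishes the antibody-directed sample from the freely
    diffusing Dam-only accessibility control (the log-ratio denominator).
    """

    grid: BinGrid
    data: Dict[str, np.ndarray] = field(repr=False)
    sample: str = ""
    role: str = "antibody"  # "antibody" or "dam"

    def __post_init__(self) -> None:
        if self.role not in ("antibody", "dam"):
            raise ValueError(f"role must be 'antibody' or 'dam', got {self.role!r}")
        self.data = _validate_data(self.grid, self.data, np.int64)
        for chrom, arr in self.data.items():
            if (arr < 0).any():
                raise ValueError(f"negative counts on chromosome {chrom!r}")

    @property
    def library_total(self) -> int:
        return int(sum(arr.sum() for arr in self.data.values()))

    def values(self) -> np.ndarray:
        return np.concatenate([self.data[c] for c in self.grid.chroms])


# ---------------------------------------------------------------------------
# plain-text I/O


def read_chrom_sizes(path) -> Dict[str, int]:
    """Read a two-column chrom.sizes file (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return {str(r.chrom): int(r.size) for r in df.itertuples()}


def write_bedgraph(track: BinnedTrack, path, *, skip_missing: bool = True) -> None:
    """Write a track as 4-column bedGraph; missing bins dropped by default."""
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_bins():
            if skip_missing and not math.isfinite(value):
                continue
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def read_bedgraph(path, chrom_sizes: Mapping[str, int], bin_size: int) -> BinnedTrack:
    """Read a bedGraph whose intervals lie on the given bin grid.

    Bins absent from the file are missing (NaN).
    """
    grid = BinGrid(chrom_sizes, bin_size)
    track = BinnedTrack.full(grid, np.nan)
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
    )
    for r in df.itertuples():
        if r.chrom not in grid.chrom_sizes:
            raise ValueError(f"unknown chromosome {r.chrom!r} in {path}")
        if r.start % bin_size != 0:
            raise ValueError(f"interval start {r.start} not on the {bin_size}-bp grid")
        track.data[r.chrom][r.start // bin_size] = r.value
    return track


def write_counts_tsv(track: CountTrack, path) -> None:
    """Write counts as a headered TSV (chrom, start, end, count)."""
    rows = []
    for chrom in track.grid.chroms:
        starts = track.grid.bin_starts(chrom)
        ends = track.grid.bin_ends(chrom)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends, "count": track.data[chrom],
        }))
    pd.concat(rows).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path, chrom_sizes: Mapping[str, int], bin_size: int,
                    sample: str = "", role: str = "antibody") -> CountTrack:
    grid = BinGrid(chrom_sizes, bin_size)
    df = pd.read_csv(path, sep="\t")
    data = {c: np.zeros(grid.n_bins(c), dtype=np.int64) for c in grid.chroms}
    for r in df.itertuples():
        chrom = str(r.chrom)
        if chrom not in data:
            raise ValueError(f"unknown chromosome {chrom!r} in {path}")
        data[chrom][int(r.start) // bin_size] = int(r.count)
    return CountTrack(grid, data, sample=sample, role=role)
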
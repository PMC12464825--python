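"""Nucleosome linker-length analysis and scaled-region pile-ups.

Linker DNA is the stretch between adjacent nucleosomes.  From dyad (centre)
positions, the distance between consecutive dyads inside the same domain is
computed; a distance over 100 bp is assumed to span a full nucleosome, so
147 bp of nucleosomal DNA is subtracted, while shorter distances are kept
as-is (overlapping/alternative positioning).  Only linkers of 1-100 bp are
retained, grouped by LAD/iLAD state — LADs with longer linkers have a lower
nucleosome density.

The scaled-region pile-up averages a signal track over every domain body
rescaled to a common length, plus fixed-width flanks, with missing data
treated as zero — the deepTools computeMatrix scale-regions convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .domains import DomainSet, LAD, ILAD
from .tracks import BinnedTrack

__all__ = [
    "DyadSet",
    "PileupMatrix",
    "linker_lengths",
    "scaled_region_pileup",
    "read_dyads_bed",
    "write_dyads_bed",
]

NUCLEOSOME_LEN = 147


@dataclass
class DyadSet:
    """Sorted nucleosome centre positions per chromosome."""

    positions: Dict[str, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        out = {}
        for chrom, pos in self.positions.items():
            arr = np.asarray(pos, dtype=np.int64)
            if arr.size and (np.diff(arr) <= 0).any():
                raise ValueError(f"dyads on {chrom} not strictly increasing")
            out[chrom] = arr
        self.positions = out

    def total(self) -> int:
        return sum(len(v) for v in self.positions.values())


def read_dyads_bed(path) -> DyadSet:
    """Read BED3 of dyads; the interval midpoint is the dyad position."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], usecols=[0, 1, 2])
    out: Dict[str, List[int]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.chrom), []).append((int(r.start) + int(r.end)) // 2)
    return DyadSet({c: np.array(sorted(set(v)), dtype=np.int64)
                    for c, v in out.items()})


def write_dyads_bed(dyads: DyadSet, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(dyads.positions):
            for p in dyads.positions[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + 1}\n")


def linker_lengths(
    dyads: DyadSet,
    domains: DomainSet,
    nuc_len: int = NUCLEOSOME_LEN,
    short_cut: int = 100,
    keep_min: int = 1,
    keep_max: int = 100,
) -> Dict[str, np.ndarray]:
    """Retained linker lengths per domain state.

    Both dyads of a pair must lie in the same domain (pairs spanning a
    boundary are ill-defined and dropped).  distance > ``short_cut`` implies
    a full nucleosome between the centres, so ``nuc_len`` is subtracted;
    otherwise the raw distance is the linker.  Only linkers within
    [``keep_min``, ``keep_max``] are kept.
    """
    out: Dict[str, List[int]] = {LAD: [], ILAD: []}
    for chrom, sub in domains.df.groupby("chrom", sort=False):
        pos = dyads.positions.get(chrom)
        if pos is None or pos.size < 2:
            continue
        for r in sub.itertuples():
            inside = pos[(pos >= r.start) & (pos < r.end)]
            if inside.size < 2:
                continue
            dist = np.diff(inside)
            linker = np.where(dist > short_cut, dist - nuc_len, dist)
            kept = linker[(linker >= keep_min) & (linker <= keep_max)]
            out[r.state].extend(int(v) for v in kept)
    return {state: np.array(vals, dtype=np.int64) for state, vals in out.items()}


@dataclass
class PileupMatrix:
    """Domains x positions matrix of mean signal (scale-regions layout)."""

    matrix: np.ndarray
    domain_ids: List[str]
    n_before: int
    n_body: int
    n_after: int
    bs: int

    @property
    def column_labels(self) -> List[str]:
        labels = [f"up{(i - self.n_before) * self.bs}" for i in range(self.n_before)]
        labels += [f"body{i}" for i in range(self.n_body)]
        labels += [f"down{(i + 1) * self.bs}" for i in range(self.n_after)]
        return labels

    def mean_profile(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# scale-regions: bs={self.bs} before={self.n_before * self.bs} "
                     f"body={self.n_body * self.bs} after={self.n_after * self.bs}\n")
            df = pd.DataFrame(self.matrix, columns=self.column_labels)
            df.insert(0, "id", self.domain_ids)
            df.to_csv(fh, sep="\t", index=False)


def _cumulative(track: BinnedTrack, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative integral of the piecewise-constant track (NaN as zero)."""
    vals = np.nan_to_num(track.data[chrom], nan=0.0)
    widths = np.diff(np.append(track.grid.bin_starts(chrom),
                               track.grid.chrom_sizes[chrom]))
    cum = np.concatenate([[0.0], np.cumsum(vals * widths)])
    return vals, cum


def _integral(vals: np.ndarray, cum: np.ndarray, bin_size: int,
              chrom_len: int, x: np.ndarray) -> np.ndarray:
    """Integral of the track from 0 to x (x outside [0, len] clipped)."""
    x = np.clip(x, 0.0, float(chrom_len))
    i = np.minimum((x // bin_size).astype(np.int64), len(vals) - 1)
    return cum[i] + vals[i] * (x - i * bin_size)


def scaled_region_pileup(
    track: BinnedTrack,
    domains,
    bs: int = 10_000,
    before: int = 500_000,
    body: int = 1_000_000,
    after: int = 500_000,
    skip_zeros: bool = False,
) -> PileupMatrix:
    """Mean signal per domain over scaled body plus fixed flanks.

    ``domains`` is a :class:`DomainSet` or any DataFrame of (chrom, start,
    end[, id]) intervals (e.g. the LAD subset alone).  Each output column is
    the area-weighted average of the piecewise-constant track over its span:
    flank columns have native ``bs`` width, body columns divide the domain
    into ``body/bs`` equal parts.  Missing bins and positions outside the
    chromosome count as zero.
    """
    if isinstance(domains, DomainSet):
        dom_df = domains.df
    else:
        dom_df = domains.copy()
        if "id" not in dom_df.columns:
            dom_df["id"] = [f"R{i:05d}" for i in range(len(dom_df))]
    if len(dom_df) == 0:
        raise ValueError("empty domain set")
    for name, value in (("before", before), ("body", body), ("after", after)):
        if value % bs != 0:
            raise ValueError(f"{name} must be a multiple of bs")
    n_before, n_body, n_after = before // bs, body // bs, after // bs
    ncol = n_before + n_body + n_after
    rows, ids = [], []
    grid = track.grid
    cache: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for r in dom_df.itertuples():
        if r.chrom not in cache:
            cache[r.chrom] = _cumulative(track, r.chrom)
        vals, cum = cache[r.chrom]
        chrom_len = grid.chrom_sizes[r.chrom]
        length = r.end - r.start
        if length < bs:
            warnings.warn(
                f"domain {r.id} shorter than one output bin ({length} < {bs} bp); "
                "body columns are degenerate resamples"
            )
        edges = np.concatenate([
            r.start - before + np.arange(n_before + 1) * float(bs),
            r.start + np.arange(1, n_body + 1) * (length / n_body),
            r.end + np.arange(1, n_after + 1) * float(bs),
        ])
        integrals = _integral(vals, cum, grid.bin_size, chrom_len, edges)
        widths = np.diff(edges)
        row = np.diff(integrals) / widths
        rows.append(row)
        ids.append(r.id)
    matrix = np.vstack(rows)
    assert matrix.shape[1] == ncol
    if skip_zeros:
        keep = ~(matrix == 0).all(axis=1)
        matrix = matrix[keep]
        ids = [i for i, k in zip(ids, keep) if k]
    return PileupMatrix(matrix, ids, n_before, n_body, n_after, bs)
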
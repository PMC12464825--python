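"""Consensus signal profiles around LAD borders.

LAD flanks are border points; borders near chromosome ends are not real
borders and are dropped, as are borders touching a domain so short that it
would contribute only one or two bins of noise.  Every genomic bin is then
assigned to its single closest border (so no position is counted twice even
when borders are nearby), given a signed relative position — positive
pointing into the LAD — and the per-position mean and 95% confidence
interval of the mean form the consensus profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .domains import DomainSet, LAD
from .tracks import BinnedTrack

__all__ = ["Border", "BorderProfile", "extract_borders", "border_profile"]

END_EXCLUSION = 50_000
MIN_DOMAIN = 50_000


@dataclass(frozen=True)
class Border:
    """One LAD flank.  orientation +1: the LAD lies right of the position;
    -1: the LAD lies left."""

    chrom: str
    position: int
    orientation: int


@dataclass
class BorderProfile:
    """Mean signal by signed distance from the closest LAD border."""

    rel_pos: np.ndarray    # bp, positive = inside the LAD, on the bin grid
    mean: np.ndarray
    ci_lo: np.ndarray      # NaN where n < 2
    ci_hi: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rel_pos": self.rel_pos, "mean": self.mean,
            "ci_lo": self.ci_lo, "ci_hi": self.ci_hi, "n": self.n,
        })

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# rel_pos sign convention: positive = LAD interior\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def extract_borders(
    domains: DomainSet,
    chrom_sizes: Mapping[str, int],
    end_exclusion: int = END_EXCLUSION,
    min_domain: int = MIN_DOMAIN,
) -> List[Border]:
    """LAD flanks surviving the chromosome-end and short-domain filters.

    A flank within ``end_exclusion`` of a chromosome end is a chromosome
    end, not a border.  A flank adjacent to any domain (the LAD itself or
    the neighbouring iLAD) shorter than ``min_domain`` is dropped: such
    domains span only a couple of bins and would add noise, not signal.
    """
    borders: List[Border] = []
    df = domains.df
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.reset_index(drop=True)
        chrom_len = chrom_sizes[chrom]
        lengths = (sub["end"] - sub["start"]).to_numpy()
        for i, r in sub.iterrows():
            if r["state"] != LAD:
                continue
            for position, orientation, nbr in (
                (int(r["start"]), +1, i - 1),
                (int(r["end"]), -1, i + 1),
            ):
                if position < end_exclusion or position > chrom_len - end_exclusion:
                    continue
                if lengths[i] < min_domain:
                    continue
                if 0 <= nbr < len(sub) and lengths[nbr] < min_domain:
                    continue
                borders.append(Border(chrom, position, orientation))
    return borders


def assign_bins_to_borders(
    track: BinnedTrack, borders: Sequence[Border], window: int = 500_000
):
    """For every bin within ``window`` of some border: (rel_pos, value).

    Each bin goes only to its closest border (by bin-centre distance; an
    exact tie goes to the lower-coordinate border).  The relative position
    is the offset of the bin's LAD-facing edge from the border, signed so
    that positive points into the LAD; adjacent inside bins sit at 0.
    """
    grid = track.grid
    bs = grid.bin_size
    by_chrom: Dict[str, List[Border]] = {}
    for b in borders:
        by_chrom.setdefault(b.chrom, []).append(b)
    rel_all, val_all = [], []
    for chrom, blist in by_chrom.items():
        blist = sorted(blist, key=lambda b: b.position)
        pos = np.array([b.position for b in blist], dtype=np.int64)
        orient = np.array([b.orientation for b in blist], dtype=np.int64)
        n = grid.n_bins(chrom)
        centers = np.arange(n, dtype=np.int64) * bs + bs // 2
        right = np.searchsorted(pos, centers)              # first border >= center
        left = np.clip(right - 1, 0, len(pos) - 1)
        right = np.clip(right, 0, len(pos) - 1)
        d_left = np.abs(centers - pos[left])
        d_right = np.abs(centers - pos[right])
        choose_left = d_left <= d_right                    # tie -> lower coordinate
        nearest = np.where(choose_left, left, right)
        border_pos = pos[nearest]
        border_or = orient[nearest]
        starts = np.arange(n, dtype=np.int64) * bs
        rel = np.where(
            border_or == 1,
            starts - border_pos,
            border_pos - (starts + bs),
        )
        keep = (np.abs(rel) <= window) & np.isfinite(track.data[chrom])
        rel_all.append(rel[keep])
        val_all.append(track.data[chrom][keep])
    if not rel_all:
        return np.array([], dtype=np.int64), np.array([])
    return np.concatenate(rel_all), np.concatenate(val_all)


def border_profile(
    track: BinnedTrack, borders: Sequence[Border], window: int = 500_000
) -> BorderProfile:
    """Consensus profile: mean and normal-theory 95% CI per relative position."""
    if not borders:
        raise ValueError("empty border list")
    rel, vals = assign_bins_to_borders(track, borders, window)
    if rel.size == 0:
        raise ValueError("no bins fall within the window of any border")
    positions = np.unique(rel)
    mean = np.empty(positions.size)
    lo = np.full(positions.size, np.nan)
    hi = np.full(positions.size, np.nan)
    counts = np.empty(positions.size, dtype=np.int64)
    for i, p in enumerate(positions):
        v = vals[rel == p]
        counts[i] = v.size
        mean[i] = v.mean()
        if v.size >= 2:
            se = v.std(ddof=1) / np.sqrt(v.size)
            lo[i] = mean[i] - 1.96 * se
            hi[i] = mean[i] + 1.96 * se
    return BorderProfile(positions, mean, lo, hi, counts)
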
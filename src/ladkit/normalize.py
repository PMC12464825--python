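"""Count binning and log-ratio normalization.

Raw reads are counted in fixed genomic bins (20 kb by default elsewhere),
each library is scaled to 1 million reads, and the antibody signal is
expressed as log2((antibody_cpm + 1) / (dam_cpm + 1)) — the Dam-only sample
in the denominator removes DNA accessibility and amplification bias.
Tracks are z-scaled genome-wide to equalize dynamic range between
experiments, and biological replicates are averaged per bin.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence, Tuple, Union

import numpy as np

from .tracks import BinGrid, BinnedTrack, CountTrack

__all__ = [
    "bin_reads",
    "normalize_log_ratio",
    "zscale_track",
    "average_replicates",
]

ReadTuple = Tuple[str, int, int]   # (chrom, assigned position, mapq)


def bin_reads(
    reads: Union[str, Iterable[ReadTuple]],
    chrom_sizes: Mapping[str, int],
    bin_size: int,
    mapq_min: int = 10,
    sample: str = "",
    role: str = "antibody",
) -> CountTrack:
    """Count reads into fixed bins, discarding low-MAPQ alignments.

    ``reads`` is either an iterable of (chrom, position, mapq) tuples — the
    position being the single assigned coordinate per read (the GATC
    fragment end when ingesting real pA-DamID data) — or a path to a
    SAM/BAM file, in which case the 5' mapped position of each aligned read
    is used.  Reads with MAPQ below ``mapq_min`` are discarded; a position
    outside its declared chromosome raises an error naming the read.
    """
    grid = BinGrid(chrom_sizes, bin_size)
    data = {c: np.zeros(grid.n_bins(c), dtype=np.int64) for c in grid.chroms}

    if isinstance(reads, str):
        reads = _iter_alignment_file(reads)

    for i, (chrom, pos, mapq) in enumerate(reads):
        if mapq < mapq_min:
            continue
        if chrom not in data:
            raise ValueError(f"read {i}: unknown chromosome {chrom!r}")
        if not 0 <= pos < grid.chrom_sizes[chrom]:
            raise ValueError(
                f"read {i}: position {pos} outside chromosome {chrom!r} "
                f"(length {grid.chrom_sizes[chrom]})"
            )
        data[chrom][pos // bin_size] += 1
    return CountTrack(grid, data, sample=sample, role=role)


def _iter_alignment_file(path: str) -> Iterable[ReadTuple]:
    import pysam

    with pysam.AlignmentFile(path) as af:
        for rec in af:
            if rec.is_unmapped:
                continue
            yield rec.reference_name, rec.reference_start, rec.mapping_quality


def normalize_log_ratio(
    ab: CountTrack,
    dam: CountTrack,
    pseudocount: float = 1.0,
    per_million: float = 1e6,
) -> BinnedTrack:
    """log2 ratio of antibody over Dam counts, each scaled to reads-per-million.

    value = log2((ab_cpm + pseudocount) / (dam_cpm + pseudocount)) with
    x_cpm = x * per_million / library_total.
    """
    if ab.grid != dam.grid:
        raise ValueError("antibody and Dam tracks are on different bin grids")
    ab_total, dam_total = ab.library_total, dam.library_total
    if ab_total == 0 or dam_total == 0:
        raise ValueError("zero library total")
    out = {}
    for chrom in ab.grid.chroms:
        ab_cpm = ab.data[chrom] * (per_million / ab_total)
        dam_cpm = dam.data[chrom] * (per_million / dam_total)
        out[chrom] = np.log2((ab_cpm + pseudocount) / (dam_cpm + pseudocount))
    return BinnedTrack(ab.grid, out)


def zscale_track(track: BinnedTrack) -> BinnedTrack:
    """Z-scale genome-wide: (x - mean) / sd over all non-missing bins.

    Keeps the data distribution identical across experiments with different
    dynamic ranges.  Missing bins stay missing.
    """
    finite = track.finite_values()
    if finite.size < 2:
        raise ValueError("need at least 2 non-missing bins to z-scale")
    mean = finite.mean()
    sd = finite.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance track cannot be z-scaled")
    return track.map(lambda v: (v - mean) / sd)


def average_replicates(tracks: Sequence[BinnedTrack]) -> BinnedTrack:
    """Per-bin mean over replicates, skipping missing values.

    A bin is missing in the output only when missing in every replicate.
    """
    if not tracks:
        raise ValueError("no tracks given")
    grid = tracks[0].grid
    for t in tracks[1:]:
        if t.grid != grid:
            raise ValueError("replicate tracks are on different bin grids")
    out = {}
    for chrom in grid.chroms:
        stack = np.stack([t.data[chrom] for t in tracks])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            out[chrom] = np.nanmean(stack, axis=0)
    return BinnedTrack(grid, out)
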
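"""Spike-in calibration of log-ratio tracks.

A fixed admixture of a second species (mouse cells spiked into the human
sample) provides an invariant internal reference: since all spike-ins come
from the same biological material, their log-ratio distribution should be
identical across samples.  Each sample's spike track is converted to a
z-score — offset b = spike mean, scale a = spike SD — and the *same* affine
factors (x - b)/a are applied to the target-species track.  Unlike
per-sample self z-scaling, this preserves genuine global differences in
dynamic range between experiments (a sample whose protein-DNA contacts
weakened genome-wide keeps its reduced contrast).

Spike log-ratios are computed in large bins (250 kb by default) because the
spike read count is limited and larger bins stabilize the scaling estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .tracks import BinnedTrack

__all__ = ["CalibrationFactors", "compute_spikein_scaling", "apply_scaling"]

DEFAULT_SPIKE_BIN_SIZE = 250_000
MIN_SPIKE_BINS = 20


@dataclass
class CalibrationFactors:
    """Per-sample affine calibration: offset b (spike mean), scale a (spike SD)."""

    offset: float
    scale: float
    bin_size: int = DEFAULT_SPIKE_BIN_SIZE
    sample: str = ""

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "CalibrationFactors":
        with open(path) as fh:
            return cls(**json.load(fh))


def compute_spikein_scaling(spike_track: BinnedTrack,
                            sample: str = "") -> CalibrationFactors:
    """Offset and scale that convert the spike log-ratio track to a z-score."""
    vals = spike_track.finite_values()
    if vals.size < MIN_SPIKE_BINS:
        raise ValueError(
            f"only {vals.size} non-missing spike bins (< {MIN_SPIKE_BINS}); "
            "spike reads are too sparse for stable scaling — use larger bins"
        )
    sd = float(vals.std(ddof=0))
    if sd == 0:
        raise ValueError("constant spike track: scale undefined")
    return CalibrationFactors(
        offset=float(vals.mean()), scale=sd,
        bin_size=spike_track.grid.bin_size, sample=sample,
    )


def apply_scaling(target_track: BinnedTrack,
                  factors: CalibrationFactors) -> BinnedTrack:
    """Apply (x - b)/a per bin; the target is never re-centred on itself."""
    b, a = factors.offset, factors.scale
    return target_track.map(lambda v: (v - b) / a)
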
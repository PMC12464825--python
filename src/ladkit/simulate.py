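"""Synthetic pA-DamID data with known ground truth.

The generator emulates the statistical structure of antibody-directed Dam
profiling: a genome tiled by alternating LAD/iLAD domains with geometric
length distributions, a Dam-only accessibility background shared between the
antibody and Dam samples of a pair, negative-binomial read counts whose
antibody mean is the background times 2^(latent log2 contrast), a perturbed
condition that de-partitions and/or shifts the latent contrast, a
second-species spike-in with a contrast fixed across all samples, and
nucleosome dyad positions with state-specific spacing.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Set

import numpy as np
import yaml

from .domains import DomainSet, LAD, ILAD
from .tracks import BinGrid, BinnedTrack, CountTrack

__all__ = [
    "PerturbationSpec",
    "SimulationConfig",
    "GroundTruth",
    "SampleCounts",
    "SimulatedCounts",
    "simulate_genome",
    "simulate_counts",
    "simulate_dyads",
]

CONTROL = "control"
PERTURBED = "perturbed"


@dataclass
class PerturbationSpec:
    """How the perturbed condition differs from control.

    ``departition_factor`` k shrinks every bin's latent contrast toward the
    genome mean by the factor (1 - k): k = 0 leaves the contrast untouched,
    k = 1 flattens it completely (total loss of LAD/iLAD partitioning).
    Fractions of LAD/iLAD domains additionally receive a signed contrast
    shift, giving domain-level differential events with known identity.
    """

    departition_factor: float = 0.0
    affected_lad_fraction: float = 0.0
    affected_ilad_fraction: float = 0.0
    lad_shift: float = 0.0
    ilad_shift: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.departition_factor <= 1.0:
            raise ValueError("departition_factor must be in [0, 1]")
        for frac in (self.affected_lad_fraction, self.affected_ilad_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("affected fractions must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Full generative description of one synthetic experiment."""

    chrom_sizes: Dict[str, int]
    bin_size: int = 20_000
    lad_mean_len: float = 1_000_000.0   # bp, mean of geometric length law
    ilad_mean_len: float = 1_000_000.0
    mu_lad: float = 1.0                 # mean log2 antibody:Dam contrast
    mu_ilad: float = -1.0
    sigma_bin: float = 0.3              # per-bin, per-replicate contrast SD
    dam_depth: float = 1_000_000.0      # expected reads per Dam sample
    ab_depth: float = 1_000_000.0
    dispersion: float = 0.05            # NB dispersion (0 -> Poisson)
    n_replicates: int = 2
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    spike_fraction: float = 0.20
    spike_chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"spike_chr1": 10_000_000}
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes is empty")
        for chrom, length in self.chrom_sizes.items():
            if length < 2 * self.bin_size:
                raise ValueError(
                    f"chromosome {chrom!r} shorter than two bins ({length} bp)"
                )
        if self.mu_lad <= self.mu_ilad:
            raise ValueError("mu_lad must exceed mu_ilad")
        if not 0.0 <= self.spike_fraction < 1.0:
            raise ValueError("spike_fraction must be in [0, 1)")
        for name in ("lad_mean_len", "ilad_mean_len", "dam_depth", "ab_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_bin < 0 or self.dispersion < 0:
            raise ValueError("sigma_bin and dispersion must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        self.perturbation.validate()

    @property
    def grid(self) -> BinGrid:
        return BinGrid(self.chrom_sizes, self.bin_size)

    @property
    def spike_grid(self) -> BinGrid:
        return BinGrid(self.spike_chrom_sizes, self.bin_size)

    # -- YAML round-trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["perturbation"] = PerturbationSpec(**raw.get("perturbation", {}))
        return cls(**raw)


@dataclass
class GroundTruth:
    """True domains, latent per-condition contrast, and perturbed domain ids."""

    domains: DomainSet
    true_contrast: Dict[str, BinnedTrack]   # condition -> latent log2 contrast
    affected_domains: Set[str]


@dataclass
class SampleCounts:
    """One sample pair: antibody + Dam counts, target and spike species."""

    condition: str
    replicate: int
    antibody: CountTrack
    dam: CountTrack
    spike_antibody: CountTrack
    spike_dam: CountTrack


@dataclass
class SimulatedCounts:
    samples: List[SampleCounts]
    spike_contrast: BinnedTrack   # fixed latent spike contrast, all samples

    def get(self, condition: str, replicate: int) -> SampleCounts:
        for s in self.samples:
            if s.condition == condition and s.replicate == replicate:
                return s
        raise KeyError((condition, replicate))


# ---------------------------------------------------------------------------
# genome simulation


def _draw_domains(rng: np.random.Generator, grid: BinGrid,
                  lad_mean_bins: float, ilad_mean_bins: float) -> DomainSet:
    intervals = []
    mean_bins = {LAD: lad_mean_bins, ILAD: ilad_mean_bins}
    for chrom in grid.chroms:
        n = grid.n_bins(chrom)
        chrom_len = grid.chrom_sizes[chrom]
        state = LAD if rng.random() < 0.5 else ILAD
        pos = 0
        while pos < n:
            m = mean_bins[state]
            length = n - pos if not np.isfinite(m) else int(rng.geometric(min(1.0, 1.0 / m)))
            end = min(pos + length, n)
            start_bp = pos * grid.bin_size
            end_bp = min(end * grid.bin_size, chrom_len)
            intervals.append((chrom, start_bp, end_bp, state))
            pos = end
            state = ILAD if state == LAD else LAD
    return DomainSet.from_intervals(intervals)


def simulate_genome(config: SimulationConfig) -> GroundTruth:
    """Draw alternating LAD/iLAD domains and the latent contrast per condition.

    Domain lengths are geometric in units of bins (mean ``lad_mean_len`` /
    ``ilad_mean_len`` bp), matching the Markov segmentation model downstream;
    each chromosome is tiled exactly, and a chromosome shorter than one drawn
    domain becomes a single domain.  The perturbed condition's contrast is the
    control contrast shrunk toward the genome mean by (1 - k) plus additive
    shifts on a randomly chosen subset of domains.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    grid = config.grid
    domains = _draw_domains(
        rng, grid,
        config.lad_mean_len / config.bin_size,
        config.ilad_mean_len / config.bin_size,
    )

    labels = domains.state_per_bin(grid)
    control = {
        c: np.where(labels[c] == 1, config.mu_lad, config.mu_ilad).astype(float)
        for c in grid.chroms
    }
    genome_mean = float(np.mean(np.concatenate(list(control.values()))))

    pert = config.perturbation
    k = pert.departition_factor
    perturbed = {
        c: genome_mean + (1.0 - k) * (v - genome_mean) for c, v in control.items()
    }

    affected: Set[str] = set()
    for state, frac, shift in (
        (LAD, pert.affected_lad_fraction, pert.lad_shift),
        (ILAD, pert.affected_ilad_fraction, pert.ilad_shift),
    ):
        sub = domains.subset(state)
        n_pick = int(round(frac * len(sub)))
        if n_pick == 0:
            continue
        picked = rng.choice(len(sub), size=n_pick, replace=False)
        for idx in np.sort(picked):
            r = sub.iloc[idx]
            affected.add(r["id"])
            b0 = r["start"] // config.bin_size
            b1 = -(-r["end"] // config.bin_size)
            perturbed[r["chrom"]][b0:b1] += shift

    true_contrast = {
        CONTROL: BinnedTrack(grid, control),
        PERTURBED: BinnedTrack(grid, perturbed),
    }
    return GroundTruth(domains, true_contrast, affected)


# ---------------------------------------------------------------------------
# count simulation


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixing; Poisson when dispersion = 0."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def _accessibility_walk(rng: np.random.Generator, n: int, step_sd: float = 0.05) -> np.ndarray:
    """Log-normal random walk along bins, normalized to mean 1."""
    walk = np.cumsum(rng.normal(0.0, step_sd, size=n))
    acc = np.exp(walk - walk.mean())
    return acc / acc.mean()


def _pair_counts(rng: np.random.Generator, grid: BinGrid, contrast: np.ndarray,
                 sigma_bin: float, ab_depth: float, dam_depth: float,
                 dispersion: float, sample: str):
    """Antibody + Dam CountTracks for one sample pair over one genome."""
    n = grid.total_bins
    acc = _accessibility_walk(rng, n)
    dam_mean = dam_depth * acc / acc.sum()
    eps = rng.normal(0.0, sigma_bin, size=n) if sigma_bin > 0 else 0.0
    ab_rel = acc * np.exp2(contrast + eps)
    ab_mean = ab_depth * ab_rel / ab_rel.sum()
    dam_counts = _nb_sample(rng, dam_mean, dispersion)
    ab_counts = _nb_sample(rng, ab_mean, dispersion)

    def split(vec):
        data, off = {}, 0
        for chrom in grid.chroms:
            nb = grid.n_bins(chrom)
            data[chrom] = vec[off:off + nb]
            off += nb
        return data

    ab = CountTrack(grid, split(ab_counts), sample=sample, role="antibody")
    dam = CountTrack(grid, split(dam_counts), sample=sample, role="dam")
    return ab, dam


def simulate_counts(truth: GroundTruth, config: SimulationConfig) -> SimulatedCounts:
    """Generate NB counts for every (condition, replicate) sample pair.

    Dam counts follow the accessibility background alone; antibody counts
    multiply that background by 2^(latent contrast + per-replicate bin noise).
    Spike-in counts are drawn from a single latent spike contrast shared by
    all samples, with expected read fraction ``spike_fraction`` of each
    library.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 23])
    grid = config.grid
    spike_grid = config.spike_grid

    # fixed spike genome: alternating domains + one latent contrast for all
    spike_domains = _draw_domains(
        rng, spike_grid,
        config.lad_mean_len / config.bin_size,
        config.ilad_mean_len / config.bin_size,
    )
    labels = spike_domains.state_per_bin(spike_grid)
    spike_contrast = np.concatenate([
        np.where(labels[c] == 1, config.mu_lad, config.mu_ilad)
        for c in spike_grid.chroms
    ]).astype(float)
    if config.sigma_bin > 0:
        spike_contrast = spike_contrast + rng.normal(
            0.0, config.sigma_bin, size=spike_contrast.size
        )

    f = config.spike_fraction
    spike_scale = f / (1.0 - f) if f > 0 else 0.0

    samples: List[SampleCounts] = []
    for condition in (CONTROL, PERTURBED):
        contrast = truth.true_contrast[condition].values()
        for rep in range(1, config.n_replicates + 1):
            name = f"{condition}_rep{rep}"
            ab, dam = _pair_counts(
                rng, grid, contrast, config.sigma_bin,
                config.ab_depth, config.dam_depth, config.dispersion, name,
            )
            s_ab, s_dam = _pair_counts(
                rng, spike_grid, spike_contrast, 0.0,
                config.ab_depth * spike_scale, config.dam_depth * spike_scale,
                config.dispersion, name + "_spike",
            )
            samples.append(SampleCounts(condition, rep, ab, dam, s_ab, s_dam))

    return SimulatedCounts(
        samples=samples,
        spike_contrast=BinnedTrack.from_values(spike_grid, spike_contrast),
    )


# ---------------------------------------------------------------------------
# nucleosome dyads

NUCLEOSOME_LEN = 147


def simulate_dyads(truth: GroundTruth, nrl_lad: float, nrl_ilad: float,
                   jitter: float, seed: int) -> Dict[str, np.ndarray]:
    """Lay down nucleosome centres with state-specific mean spacing.

    Within each domain, consecutive dyads are spaced by the state's
    nucleosome repeat length plus Gaussian jitter, truncated below at 148 bp
    so nucleosomes never overlap.  Returns sorted, strictly increasing dyad
    positions per chromosome.
    """
    for nrl in (nrl_lad, nrl_ilad):
        if nrl <= NUCLEOSOME_LEN:
            raise ValueError(
                f"repeat length {nrl} <= {NUCLEOSOME_LEN} bp: nucleosomes would overlap"
            )
    rng = np.random.default_rng([seed, 31])
    nrl_of = {LAD: float(nrl_lad), ILAD: float(nrl_ilad)}
    positions: Dict[str, list] = {}
    for r in truth.domains.df.itertuples():
        nrl = nrl_of[r.state]
        pos = int(r.start) + int(round(nrl / 2.0))
        chrom_list = positions.setdefault(r.chrom, [])
        while pos < r.end:
            chrom_list.append(pos)
            spacing = nrl if jitter <= 0 else rng.normal(nrl, jitter)
            pos += max(NUCLEOSOME_LEN + 1, int(round(spacing)))
    out = {}
    for chrom, vals in positions.items():
        arr = np.array(sorted(set(vals)), dtype=np.int64)
        out[chrom] = arr
    return out
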
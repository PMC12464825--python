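"""De-partitioning and cross-condition metrics.

The degree to which a perturbation collapses LAD/iLAD partitioning is
quantified several ways: the slope of the differential signal against the
control signal (a slope of -k means bins lose a fraction k of their
NL-association contrast), the collapse of the bimodal genome-wide signal
distribution into a single mode, shifts in domain-level score distributions
(Welch or Wilcoxon), genomic overlap between domain sets with a Fisher
exact test over genome bins, and Pearson correlation between differential
tracks of different perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .domains import DomainSet
from .hmm import lad_score
from .normalize import zscale_track
from .tracks import BinGrid, BinnedTrack

__all__ = [
    "SlopeResult",
    "OverlapResult",
    "differential_track",
    "departition_slope",
    "bimodality_assess",
    "domain_score_compare",
    "domain_overlap",
    "track_correlation",
]


@dataclass
class SlopeResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


@dataclass
class OverlapResult:
    overlap_mb: float
    total_a_mb: float
    total_b_mb: float
    table: np.ndarray          # 2x2 bin counts: [in A, not in A] x [in B, not in B]
    fisher_p: float
    odds_ratio: float
    fisher_skipped: bool = False


def differential_track(perturbed: BinnedTrack, control: BinnedTrack,
                       zscored: bool = True) -> BinnedTrack:
    """Per-bin difference, perturbed minus control.

    With ``zscored=True`` the inputs are taken to be z-scores already and
    subtracted as given; with ``zscored=False`` each input is z-scaled
    first, so the difference is always on the z scale.
    """
    if perturbed.grid != control.grid:
        raise ValueError("tracks are on different bin grids")
    if not zscored:
        perturbed = zscale_track(perturbed)
        control = zscale_track(control)
    out = {c: perturbed.data[c] - control.data[c] for c in control.grid.chroms}
    return BinnedTrack(control.grid, out)


def departition_slope(control: BinnedTrack,
                      differential: BinnedTrack) -> SlopeResult:
    """OLS slope of the differential signal on the control signal.

    If the perturbation shrinks every bin's contrast toward the mean by a
    factor k, the slope is -k; an intact partition gives slope ~ 0.
    """
    if control.grid != differential.grid:
        raise ValueError("tracks are on different bin grids")
    x = control.values()
    y = differential.values()
    m = np.isfinite(x) & np.isfinite(y)
    x, y = x[m], y[m]
    if x.size < 3:
        raise ValueError("need at least 3 paired non-missing bins")
    if np.ptp(x) == 0:
        raise ValueError("control track has zero variance")
    if np.ptp(y) == 0:
        # perturbed == control everywhere: slope 0, correlation undefined
        return SlopeResult(0.0, float(y[0]), 0.0, 1.0, int(x.size))
    res = stats.linregress(x, y)
    return SlopeResult(float(res.slope), float(res.intercept),
                       float(res.rvalue), float(res.pvalue), int(x.size))


def bimodality_assess(track: BinnedTrack, random_state: int = 0) -> Dict[str, object]:
    """Is the signal distribution bimodal (partitioned) or unimodal?

    Fits 1- and 2-component Gaussian mixtures; ``delta_bic`` > 0 means BIC
    prefers two components.  Ashman's D = sqrt(2)|mu1 - mu2| /
    sqrt(sigma1^2 + sigma2^2) measures mode separation and is scale-free;
    the verdict is "bimodal" only when BIC favours two components *and*
    D > 2 (the classical threshold for a visible dip).  A degenerate fit
    (vanishing component) yields "unimodal" with a flag.
    """
    from sklearn.mixture import GaussianMixture

    x = track.finite_values()
    if x.size < 100:
        raise ValueError("need at least 100 non-missing bins")
    X = x.reshape(-1, 1)
    gm1 = GaussianMixture(1, random_state=random_state).fit(X)
    gm2 = GaussianMixture(2, n_init=3, random_state=random_state).fit(X)
    delta_bic = float(gm1.bic(X) - gm2.bic(X))
    w = gm2.weights_
    mu = gm2.means_.ravel()
    var = gm2.covariances_.ravel()
    degenerate = bool(w.min() < 0.02 or var.min() < 1e-12)
    D = float(np.sqrt(2.0) * abs(mu[0] - mu[1]) / np.sqrt(var.sum()))
    if degenerate:
        verdict = "unimodal"
    else:
        verdict = "bimodal" if (delta_bic > 0 and D > 2.0) else "unimodal"
    return {
        "ashman_D": D,
        "delta_BIC": delta_bic,
        "verdict": verdict,
        "degenerate": degenerate,
        "means": mu.tolist(),
        "weights": w.tolist(),
    }


def _trim(values: np.ndarray, trim_pct: float) -> np.ndarray:
    lo, hi = np.percentile(values, [trim_pct, 100.0 - trim_pct])
    return values[(values >= lo) & (values <= hi)]


def domain_score_compare(
    track: BinnedTrack,
    domains: DomainSet,
    test: str = "welch",
    trim_pct: float = 0.5,
) -> Dict[str, object]:
    """Compare per-domain mean scores between LADs and iLADs.

    The test (Welch's t or two-sided Wilcoxon rank-sum) always runs on the
    full score lists; the top/bottom ``trim_pct`` percentiles are removed
    only from the returned ``*_trimmed`` lists, which exist for plotting.
    """
    if test not in ("welch", "wilcoxon"):
        raise ValueError("test must be 'welch' or 'wilcoxon'")
    scored = lad_score(domains, track)
    lad_scores = scored.lads["score"].dropna().to_numpy()
    ilad_scores = scored.ilads["score"].dropna().to_numpy()
    if len(lad_scores) < 2 or len(ilad_scores) < 2:
        raise ValueError("need at least 2 scored domains per state")
    if test == "welch":
        statistic, p = stats.ttest_ind(lad_scores, ilad_scores, equal_var=False)
    else:
        statistic, p = stats.mannwhitneyu(
            lad_scores, ilad_scores, alternative="two-sided"
        )
    return {
        "lad_scores": lad_scores,
        "ilad_scores": ilad_scores,
        "lad_scores_trimmed": _trim(lad_scores, trim_pct),
        "ilad_scores_trimmed": _trim(ilad_scores, trim_pct),
        "test": test,
        "statistic": float(statistic),
        "p": float(p),
    }


Intervals = Union[pd.DataFrame, DomainSet]


def _as_intervals(x: Intervals) -> pd.DataFrame:
    if isinstance(x, DomainSet):
        return x.df[["chrom", "start", "end"]]
    return x[["chrom", "start", "end"]]


def _bin_membership(df: pd.DataFrame, grid: BinGrid) -> np.ndarray:
    mask = np.zeros(grid.total_bins, dtype=bool)
    offsets = {}
    off = 0
    for chrom in grid.chroms:
        offsets[chrom] = off
        off += grid.n_bins(chrom)
    for r in df.itertuples():
        if r.chrom not in offsets:
            continue
        b0 = r.start // grid.bin_size
        b1 = -(-r.end // grid.bin_size)
        mask[offsets[r.chrom] + b0 : offsets[r.chrom] + b1] = True
    return mask


def _intersection_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    total = 0
    for chrom in set(a["chrom"]).intersection(b["chrom"]):
        ia = a[a["chrom"] == chrom].sort_values("start")
        ib = b[b["chrom"] == chrom].sort_values("start")
        for sa, ea in zip(ia["start"], ia["end"]):
            lo = np.maximum(sa, ib["start"].to_numpy())
            hi = np.minimum(ea, ib["end"].to_numpy())
            total += int(np.clip(hi - lo, 0, None).sum())
    return total


def domain_overlap(
    set_a: Intervals,
    set_b: Intervals,
    bin_size: int,
    chrom_sizes: Mapping[str, int],
) -> OverlapResult:
    """Genomic overlap of two interval sets, with a Fisher exact test.

    The overlap is the exact base-pair intersection reported in Mb; the
    Fisher test is computed on the 2x2 contingency table of fixed-width
    genome bins classified by membership in each set.
    """
    grid = BinGrid(chrom_sizes, bin_size)
    da, db = _as_intervals(set_a), _as_intervals(set_b)
    total_a = int((da["end"] - da["start"]).sum())
    total_b = int((db["end"] - db["start"]).sum())
    overlap = _intersection_bp(da, db)
    in_a = _bin_membership(da, grid)
    in_b = _bin_membership(db, grid)
    table = np.array([
        [np.sum(in_a & in_b), np.sum(in_a & ~in_b)],
        [np.sum(~in_a & in_b), np.sum(~in_a & ~in_b)],
    ], dtype=np.int64)
    if total_a == 0 or total_b == 0:
        return OverlapResult(0.0, total_a / 1e6, total_b / 1e6, table,
                             np.nan, np.nan, fisher_skipped=True)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    if table[0, 1] == 0 or table[1, 0] == 0:
        odds = np.inf
    return OverlapResult(
        overlap_mb=overlap / 1e6,
        total_a_mb=total_a / 1e6,
        total_b_mb=total_b / 1e6,
        table=table,
        fisher_p=float(p),
        odds_ratio=float(odds),
    )


def track_correlation(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    mask: Optional[np.ndarray] = None,
) -> Dict[str, float]:
    """Pearson correlation over pairwise non-missing (and mask-passing) bins.

    ``mask`` is an optional boolean concordance filter over the concatenated
    bin vector (e.g. to drop bins whose control state disagrees between two
    cell lines).  The p-value is the exact t transform of r with n - 2 df.
    """
    if track_a.grid != track_b.grid:
        raise ValueError("tracks are on different bin grids")
    x, y = track_a.values(), track_b.values()
    keep = np.isfinite(x) & np.isfinite(y)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != x.shape:
            raise ValueError("mask length does not match bin count")
        keep &= mask
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired bins")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": int(x.size)}
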
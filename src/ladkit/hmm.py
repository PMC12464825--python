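"""Two-state hidden Markov segmentation of normalized tracks into LADs.

A genome-wide log-ratio (or z-score) track is modelled as a two-state HMM —
an "inside" state with higher signal (lamina-associated) and an "outside"
state — with Gaussian or Student-t emissions.  Parameters are estimated by
Baum-Welch (EM) with scaled forward-backward recursions; missing bins are
skipped by assigning them unit emission likelihood, so the chain propagates
through them on transitions alone.  The Viterbi path segments each
chromosome into alternating LAD/iLAD domains.

The Student-t emission (df fixed at 3) is the robust default: occasional
outlier bins should not drag the state means.  States are identified by
ordering locations — the higher-location state is the LAD state.
"""

from __future__ import annotations

import json
import math
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln

from .domains import DomainSet, LAD, ILAD
from .tracks import BinnedTrack

__all__ = [
    "TwoStateHMM",
    "fit_two_state_hmm",
    "viterbi_path",
    "segment_domains",
    "lad_score",
]

_SCALE_FLOOR = 1e-4
_PROB_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# scaled forward-backward and Viterbi for exactly two states; written with
# scalar arithmetic so numba can compile the sequential recursions.


def _fb2(b0, b1, A00, A01, A10, A11, p0, p1):
    T = b0.shape[0]
    al0 = np.empty(T)
    al1 = np.empty(T)
    c = np.empty(T)
    a0 = p0 * b0[0]
    a1 = p1 * b1[0]
    s = a0 + a1
    if s <= _PROB_FLOOR:
        s = _PROB_FLOOR
    c[0] = s
    al0[0] = a0 / s
    al1[0] = a1 / s
    for t in range(1, T):
        a0 = (al0[t - 1] * A00 + al1[t - 1] * A10) * b0[t]
        a1 = (al0[t - 1] * A01 + al1[t - 1] * A11) * b1[t]
        s = a0 + a1
        if s <= _PROB_FLOOR:
            s = _PROB_FLOOR
        c[t] = s
        al0[t] = a0 / s
        al1[t] = a1 / s
    g0 = np.empty(T)
    g1 = np.empty(T)
    g0[T - 1] = al0[T - 1]
    g1[T - 1] = al1[T - 1]
    be0 = 1.0
    be1 = 1.0
    x00 = 0.0
    x01 = 0.0
    x10 = 0.0
    x11 = 0.0
    for t in range(T - 2, -1, -1):
        bb0 = b0[t + 1] * be0
        bb1 = b1[t + 1] * be1
        ct1 = c[t + 1]
        x00 += al0[t] * A00 * bb0 / ct1
        x01 += al0[t] * A01 * bb1 / ct1
        x10 += al1[t] * A10 * bb0 / ct1
        x11 += al1[t] * A11 * bb1 / ct1
        nbe0 = (A00 * bb0 + A01 * bb1) / ct1
        nbe1 = (A10 * bb0 + A11 * bb1) / ct1
        be0 = nbe0
        be1 = nbe1
        g = al0[t] * be0
        h = al1[t] * be1
        sgh = g + h
        if sgh <= _PROB_FLOOR:
            sgh = _PROB_FLOOR
        g0[t] = g / sgh
        g1[t] = h / sgh
    ll = np.sum(np.log(c))
    return g0, g1, x00, x01, x10, x11, ll


def _vit2(lb0, lb1, lA00, lA01, lA10, lA11, lp0, lp1):
    T = lb0.shape[0]
    back = np.empty((T, 2), dtype=np.int8)
    d0 = lp0 + lb0[0]
    d1 = lp1 + lb1[0]
    for t in range(1, T):
        c00 = d0 + lA00
        c10 = d1 + lA10
        if c00 >= c10:
            nd0 = c00 + lb0[t]
            back[t, 0] = 0
        else:
            nd0 = c10 + lb0[t]
            back[t, 0] = 1
        c01 = d0 + lA01
        c11 = d1 + lA11
        if c01 >= c11:
            nd1 = c01 + lb1[t]
            back[t, 1] = 0
        else:
            nd1 = c11 + lb1[t]
            back[t, 1] = 1
        d0 = nd0
        d1 = nd1
    path = np.empty(T, dtype=np.int8)
    path[T - 1] = 0 if d0 >= d1 else 1
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


try:  # compile the sequential recursions when numba is available
    import numba

    _fb2 = numba.njit(cache=False)(_fb2)
    _vit2 = numba.njit(cache=False)(_vit2)
except ImportError:  # pragma: no cover - numba is normally installed
    pass


# ---------------------------------------------------------------------------
# emission densities


def _emission_likelihood(x: np.ndarray, loc: float, scale: float,
                         emission: str, df: float) -> np.ndarray:
    """Density of observations under one state; 1.0 at missing bins."""
    out = np.ones_like(x)
    m = np.isfinite(x)
    z = (x[m] - loc) / scale
    if emission == "gaussian":
        out[m] = np.exp(-0.5 * z * z) / (scale * math.sqrt(2.0 * math.pi))
    else:  # student-t
        lognorm = (gammaln((df + 1) / 2.0) - gammaln(df / 2.0)
                   - 0.5 * math.log(df * math.pi) - math.log(scale))
        out[m] = np.exp(lognorm - 0.5 * (df + 1) * np.log1p(z * z / df))
    return out


class TwoStateHMM:
    """Two-state HMM over a binned signal track, fit by Baum-Welch.

    Parameters
    ----------
    emission
        "t" (Student-t, robust default) or "gaussian".
    df
        Degrees of freedom of the t emission (fixed, not estimated).
    max_iter, tol
        EM stopping rule: stop when the log-likelihood improves by less
        than ``tol`` or after ``max_iter`` iterations.

    Fitted attributes (state 0 = outside/iLAD, state 1 = inside/LAD, the
    higher-location state): ``locations_``, ``scales_``, ``transmat_``,
    ``startprob_``, ``loglik_history_``, ``converged_``.
    """

    def __init__(self, emission: str = "t", df: float = 3.0,
                 max_iter: int = 500, tol: float = 1e-6,
                 seed: Optional[int] = None):
        if emission not in ("t", "gaussian"):
            raise ValueError("emission must be 't' or 'gaussian'")
        if emission == "t" and df <= 2:
            raise ValueError("t emission requires df > 2")
        self.emission = emission
        self.df = float(df)
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.seed = seed

    # -- fitting -----------------------------------------------------------

    def fit(self, track: BinnedTrack) -> "TwoStateHMM":
        sequences = [track.data[c] for c in track.grid.chroms]
        return self.fit_sequences(sequences)

    def fit_sequences(self, sequences: Sequence[np.ndarray]) -> "TwoStateHMM":
        seqs = [np.asarray(s, dtype=np.float64) for s in sequences if len(s) > 0]
        allx = np.concatenate(seqs) if seqs else np.array([])
        finite = allx[np.isfinite(allx)]
        if finite.size < 50:
            raise ValueError("need at least 50 non-missing bins to fit")
        if finite.std() < 1e-10:
            raise ValueError("near-zero variance track: two states are not identifiable")

        # deterministic init: 25th/75th percentile locations, common scale,
        # sticky transitions (stay probability 0.99)
        q25, q75 = np.percentile(finite, [25.0, 75.0])
        locs = np.array([q25, q75], dtype=float)
        scales = np.full(2, max(finite.std(), _SCALE_FLOOR))
        A = np.array([[0.99, 0.01], [0.01, 0.99]])
        pi = np.array([0.5, 0.5])

        history: List[float] = []
        converged = False
        for _ in range(self.max_iter):
            ll, g_list = 0.0, []
            xi = np.zeros((2, 2))
            pi_acc = np.zeros(2)
            for x in seqs:
                b0 = _emission_likelihood(x, locs[0], scales[0], self.emission, self.df)
                b1 = _emission_likelihood(x, locs[1], scales[1], self.emission, self.df)
                g0, g1, x00, x01, x10, x11, seq_ll = _fb2(
                    b0, b1, A[0, 0], A[0, 1], A[1, 0], A[1, 1], pi[0], pi[1])
                ll += seq_ll
                xi += np.array([[x00, x01], [x10, x11]])
                pi_acc += np.array([g0[0], g1[0]])
                g_list.append((g0, g1))
            history.append(ll)

            # M-step
            new_locs = np.empty(2)
            new_scales = np.empty(2)
            for i in range(2):
                num = den_u = den_g = 0.0
                parts = []
                for x, gpair in zip(seqs, g_list):
                    m = np.isfinite(x)
                    xm = x[m]
                    gm = gpair[i][m]
                    if self.emission == "t":
                        z2 = ((xm - locs[i]) / scales[i]) ** 2
                        u = (self.df + 1.0) / (self.df + z2)
                    else:
                        u = np.ones_like(xm)
                    num += np.sum(gm * u * xm)
                    den_u += np.sum(gm * u)
                    den_g += np.sum(gm)
                    parts.append((xm, gm, u))
                mu = num / max(den_u, _PROB_FLOOR)
                s2 = sum(np.sum(gm * u * (xm - mu) ** 2) for xm, gm, u in parts)
                new_locs[i] = mu
                new_scales[i] = max(math.sqrt(s2 / max(den_g, _PROB_FLOOR)), _SCALE_FLOOR)
            row = xi.sum(axis=1)
            A = xi / np.maximum(row[:, None], _PROB_FLOOR)
            A = A / A.sum(axis=1, keepdims=True)
            pi = pi_acc / pi_acc.sum()
            locs, scales = new_locs, new_scales

            if len(history) >= 2 and abs(history[-1] - history[-2]) < self.tol:
                converged = True
                break

        if not converged:
            warnings.warn(
                f"Baum-Welch did not converge in {self.max_iter} iterations; "
                "returning the best model so far"
            )

        # identifiability: state 1 is the higher-location (LAD) state
        order = np.argsort(locs)
        self.locations_ = locs[order]
        self.scales_ = scales[order]
        self.transmat_ = A[np.ix_(order, order)]
        self.startprob_ = pi[order]
        self.loglik_history_ = history
        self.converged_ = converged
        return self

    # -- inference ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "locations_"):
            raise RuntimeError("model is not fitted")

    def log_likelihood(self, x: np.ndarray) -> float:
        self._check_fitted()
        b0 = _emission_likelihood(x, self.locations_[0], self.scales_[0],
                                  self.emission, self.df)
        b1 = _emission_likelihood(x, self.locations_[1], self.scales_[1],
                                  self.emission, self.df)
        *_, ll = _fb2(b0, b1, self.transmat_[0, 0], self.transmat_[0, 1],
                      self.transmat_[1, 0], self.transmat_[1, 1],
                      self.startprob_[0], self.startprob_[1])
        return float(ll)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Viterbi state path (0 = outside, 1 = inside/LAD) for one sequence.

        Missing observations contribute no emission term; their state is
        inferred from the transition structure alone.
        """
        self._check_fitted()
        x = np.asarray(x, dtype=np.float64)
        with np.errstate(divide="ignore"):
            lb0 = np.log(_emission_likelihood(
                x, self.locations_[0], self.scales_[0], self.emission, self.df))
            lb1 = np.log(_emission_likelihood(
                x, self.locations_[1], self.scales_[1], self.emission, self.df))
            lA = np.log(np.maximum(self.transmat_, _PROB_FLOOR))
            lp = np.log(np.maximum(self.startprob_, _PROB_FLOOR))
        path = _vit2(lb0, lb1, lA[0, 0], lA[0, 1], lA[1, 0], lA[1, 1],
                     lp[0], lp[1])
        return np.asarray(path, dtype=np.int8)

    # -- (de)serialization -------------------------------------------------

    def to_json(self, path=None) -> str:
        self._check_fitted()
        payload = {
            "emission": self.emission,
            "df": self.df,
            "locations": self.locations_.tolist(),
            "scales": self.scales_.tolist(),
            "transmat": self.transmat_.tolist(),
            "startprob": self.startprob_.tolist(),
            "converged": bool(self.converged_),
            "loglik": self.loglik_history_[-1] if self.loglik_history_ else None,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "TwoStateHMM":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(emission=payload["emission"], df=payload["df"])
        model.locations_ = np.array(payload["locations"])
        model.scales_ = np.array(payload["scales"])
        model.transmat_ = np.array(payload["transmat"])
        model.startprob_ = np.array(payload["startprob"])
        model.converged_ = payload["converged"]
        model.loglik_history_ = [payload["loglik"]] if payload["loglik"] else []
        return model


def fit_two_state_hmm(track: BinnedTrack, emission: str = "t",
                      max_iter: int = 500, tol: float = 1e-6,
                      seed: Optional[int] = None) -> TwoStateHMM:
    """Fit a two-state HMM to a normalized track (thin class wrapper)."""
    return TwoStateHMM(emission=emission, max_iter=max_iter, tol=tol,
                       seed=seed).fit(track)


def viterbi_path(track: BinnedTrack, model: TwoStateHMM) -> Dict[str, np.ndarray]:
    """Per-chromosome Viterbi state vectors (0 = iLAD, 1 = LAD)."""
    return {c: model.predict(track.data[c]) for c in track.grid.chroms}


def _enforce_min_bins(path: np.ndarray, min_bins: int) -> np.ndarray:
    """Iteratively absorb runs shorter than ``min_bins`` into neighbours."""
    path = path.copy()
    while True:
        runs = _runs(path)
        short = [(e - s, idx) for idx, (s, e, _) in enumerate(runs)
                 if e - s < min_bins]
        if not short or len(runs) == 1:
            return path
        _, idx = min(short)
        s, e, state = runs[idx]
        path[s:e] = 1 - state


def _runs(path: np.ndarray) -> List[Tuple[int, int, int]]:
    """(start, end, state) runs of a 0/1 vector."""
    change = np.flatnonzero(np.diff(path)) + 1
    bounds = np.concatenate([[0], change, [len(path)]])
    return [(int(bounds[i]), int(bounds[i + 1]), int(path[bounds[i]]))
            for i in range(len(bounds) - 1)]


def segment_domains(track: BinnedTrack, model: TwoStateHMM,
                    min_bins: int = 1) -> DomainSet:
    """Segment a track into alternating LAD/iLAD domains via Viterbi.

    Domains are called once (on the control-condition average track) and the
    coordinates reused for all samples.  Runs shorter than ``min_bins`` are
    absorbed into their neighbours.  A chromosome with no non-missing bins
    emits no domains.
    """
    grid = track.grid
    intervals = []
    for chrom in grid.chroms:
        x = track.data[chrom]
        if not np.isfinite(x).any():
            warnings.warn(f"chromosome {chrom!r} is fully missing; no domains emitted")
            continue
        path = model.predict(x)
        if min_bins > 1:
            path = _enforce_min_bins(path, min_bins)
        chrom_len = grid.chrom_sizes[chrom]
        for s, e, state in _runs(path):
            start_bp = s * grid.bin_size
            end_bp = min(e * grid.bin_size, chrom_len)
            intervals.append((chrom, start_bp, end_bp, LAD if state else ILAD))
    return DomainSet.from_intervals(intervals)


def lad_score(domains: DomainSet, ztrack: BinnedTrack) -> DomainSet:
    """Per-domain LAD score: mean of the z-scaled signal over the domain's bins.

    A domain whose bins are all missing gets a missing score (with a warning).
    """
    grid = ztrack.grid
    scores = np.empty(len(domains))
    for i, r in enumerate(domains.df.itertuples()):
        b0 = r.start // grid.bin_size
        b1 = -(-r.end // grid.bin_size)
        vals = ztrack.data[r.chrom][b0:b1]
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            warnings.warn(f"domain {r.id} has no non-missing bins; score set missing")
            scores[i] = np.nan
        else:
            scores[i] = finite.mean()
    return domains.with_scores(scores)
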
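"""Two-state hidden Markov model for runs of homozygosity.

Each scaffold's windowed heterozygote counts are segmented into an
*inbred* state (autozygous tracts, few heterozygotes) and an *outbred*
state.  Emissions are Poisson with callable-site exposure:

    k_t | state s  ~  Poisson(lambda_s * n_t)

where ``n_t`` is the number of callable (non-N) sites in window ``t``.
The exposure makes masked deserts uninformative rather than ROH-like;
windows flagged missing (callable fraction below the track threshold)
contribute likelihood one in both states.

Parameters are estimated from the data by Baum–Welch (EM); decoding uses
Viterbi with ties broken toward the outbred state so that ROH calls stay
conservative.  Consecutive inbred windows are merged into tracts and
tracts shorter than ``min_length`` (default 2 Mb, the confidence floor
for long-tract calling) are dropped.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import gammaln

from .heterozygosity import HetWindowTrack
from .seqio import Interval, write_bed

INBRED, OUTBRED = 0, 1
DEFAULT_MIN_LENGTH = 2_000_000
_LAMBDA_FLOOR = 1e-12  # per-bp; keeps Poisson log-pmf finite when a state sees no hets


@dataclass
class RohHmmParams:
    """Parameters of the two-state ROH HMM.

    ``lambda_in``/``lambda_out`` are expected heterozygous sites per
    callable bp in the inbred and outbred state; ``trans`` is the 2x2
    per-window transition matrix (row = from-state) and ``init`` the
    initial state distribution, both ordered (inbred, outbred).
    """

    lambda_in: float
    lambda_out: float
    trans: np.ndarray
    init: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, dtype=float)
        self.init = np.asarray(self.init, dtype=float)
        if self.lambda_in < 0 or self.lambda_out < 0:
            raise ValueError("emission rates must be >= 0")
        if not self.degenerate and self.lambda_in > self.lambda_out:
            raise ValueError("lambda_in must not exceed lambda_out")
        if self.trans.shape != (2, 2) or self.init.shape != (2,):
            raise ValueError("trans must be 2x2 and init length 2")
        if ((self.trans < 0) | (self.trans > 1)).any() or ((self.init < 0) | (self.init > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.trans.sum(axis=1), 1.0) or not math.isclose(
            self.init.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValueError("transition rows and init must sum to 1")

    @classmethod
    def from_genome_het(cls, het_rate: float, stay: float = 0.999) -> "RohHmmParams":
        """Default initialization: outbred rate at the genome-wide
        heterozygosity, inbred rate a tenth of it, sticky transitions
        (Mb-scale tracts over 100 kb windows)."""
        return cls(
            lambda_in=max(het_rate / 10.0, _LAMBDA_FLOOR),
            lambda_out=max(het_rate, _LAMBDA_FLOOR),
            trans=np.array([[stay, 1 - stay], [1 - stay, stay]]),
            init=np.array([0.5, 0.5]),
        )

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "lambda_in": float(self.lambda_in),
                    "lambda_out": float(self.lambda_out),
                    "trans": self.trans.tolist(),
                    "init": self.init.tolist(),
                    "degenerate": bool(self.degenerate),
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RohHmmParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            lambda_in=d["lambda_in"],
            lambda_out=d["lambda_out"],
            trans=np.array(d["trans"]),
            init=np.array(d["init"]),
            degenerate=d.get("degenerate", False),
        )


def emission_loglik(
    k: np.ndarray, n: np.ndarray, missing: np.ndarray, params: RohHmmParams
) -> np.ndarray:
    """Log emission matrix, shape (T, 2): Poisson(k; lambda_s * n) per
    window, zero (likelihood one) for missing windows."""
    if params.lambda_in <= 0 or params.lambda_out <= 0:
        raise ValueError("emission rates must be > 0 for likelihood evaluation")
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    out = np.zeros((len(k), 2))
    for s, lam in ((INBRED, params.lambda_in), (OUTBRED, params.lambda_out)):
        mu = lam * n
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = k * np.log(mu) - mu - gammaln(k + 1.0)
        ll = np.where(mu > 0, ll, np.where(k == 0, 0.0, -np.inf))
        out[:, s] = ll
    out[np.asarray(missing, dtype=bool)] = 0.0
    return out


def _forward_scaffold(logB: np.ndarray, params: RohHmmParams) -> float:
    lt = np.log(np.maximum(params.trans, 1e-300))
    a0 = math.log(max(params.init[0], 1e-300)) + logB[0, 0]
    a1 = math.log(max(params.init[1], 1e-300)) + logB[0, 1]
    t00, t01, t10, t11 = lt[0, 0], lt[0, 1], lt[1, 0], lt[1, 1]
    for t in range(1, len(logB)):
        b0, b1 = logB[t, 0], logB[t, 1]
        n0 = np.logaddexp(a0 + t00, a1 + t10) + b0
        n1 = np.logaddexp(a0 + t01, a1 + t11) + b1
        a0, a1 = n0, n1
    return float(np.logaddexp(a0, a1))


def forward_loglik(track: HetWindowTrack, params: RohHmmParams) -> float:
    """Total log-likelihood of a window track (scaffolds independent,
    each restarting from the initial distribution)."""
    total = 0.0
    for _, k, n, missing in track.per_scaffold():
        total += _forward_scaffold(emission_loglik(k, n, missing, params), params)
    return total


def _forward_backward(logB: np.ndarray, params: RohHmmParams):
    """Scaled log-space forward-backward.

    Returns (log_alpha, log_beta, loglik) with alpha/beta unnormalized in
    log space (fine at 2 states and <1e5 windows).
    """
    T = len(logB)
    lt = np.log(np.maximum(params.trans, 1e-300))
    la = np.empty((T, 2))
    la[0] = np.log(np.maximum(params.init, 1e-300)) + logB[0]
    for t in range(1, T):
        la[t, 0] = np.logaddexp(la[t - 1, 0] + lt[0, 0], la[t - 1, 1] + lt[1, 0]) + logB[t, 0]
        la[t, 1] = np.logaddexp(la[t - 1, 0] + lt[0, 1], la[t - 1, 1] + lt[1, 1]) + logB[t, 1]
    lb = np.empty((T, 2))
    lb[T - 1] = 0.0
    for t in range(T - 2, -1, -1):
        x0 = lb[t + 1, 0] + logB[t + 1, 0]
        x1 = lb[t + 1, 1] + logB[t + 1, 1]
        lb[t, 0] = np.logaddexp(lt[0, 0] + x0, lt[0, 1] + x1)
        lb[t, 1] = np.logaddexp(lt[1, 0] + x0, lt[1, 1] + x1)
    ll = float(np.logaddexp(la[T - 1, 0], la[T - 1, 1]))
    return la, lb, ll


def posteriors(logB: np.ndarray, params: RohHmmParams) -> tuple[np.ndarray, float]:
    la, lb, ll = _forward_backward(logB, params)
    g = la + lb - ll
    g = np.exp(g)
    g /= g.sum(axis=1, keepdims=True)
    return g, ll


def viterbi(logB: np.ndarray, params: RohHmmParams) -> np.ndarray:
    """Most probable state path; ties broken toward the outbred state."""
    T = len(logB)
    lt = np.log(np.maximum(params.trans, 1e-300))
    li = np.log(np.maximum(params.init, 1e-300))
    score = np.empty((T, 2))
    back = np.zeros((T, 2), dtype=np.int8)
    score[0] = li + logB[0]
    for t in range(1, T):
        for j in (INBRED, OUTBRED):
            via_in = score[t - 1, INBRED] + lt[INBRED, j]
            via_out = score[t - 1, OUTBRED] + lt[OUTBRED, j]
            # >= prefers the outbred predecessor on ties
            if via_out >= via_in:
                back[t, j] = OUTBRED
                score[t, j] = via_out + logB[t, j]
            else:
                back[t, j] = INBRED
                score[t, j] = via_in + logB[t, j]
    path = np.empty(T, dtype=np.int8)
    path[T - 1] = OUTBRED if score[T - 1, OUTBRED] >= score[T - 1, INBRED] else INBRED
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


@dataclass
class DecodeResult:
    """Per-scaffold Viterbi paths and forward-backward posteriors."""

    paths: dict[str, np.ndarray]
    posteriors: dict[str, np.ndarray]  # shape (T, 2), columns (inbred, outbred)
    loglik: float


def decode(track: HetWindowTrack, params: RohHmmParams) -> DecodeResult:
    """Viterbi path and per-window posteriors for every scaffold."""
    paths: dict[str, np.ndarray] = {}
    posts: dict[str, np.ndarray] = {}
    total_ll = 0.0
    for name, k, n, missing in track.per_scaffold():
        logB = emission_loglik(k, n, missing, params)
        paths[name] = viterbi(logB, params)
        g, ll = posteriors(logB, params)
        posts[name] = g
        total_ll += ll
    return DecodeResult(paths=paths, posteriors=posts, loglik=total_ll)


# ---------------------------------------------------------------------------
# Baum-Welch
# ---------------------------------------------------------------------------

def fit(
    tracks: HetWindowTrack | list[HetWindowTrack],
    init: RohHmmParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    seed: int | None = None,
) -> tuple[RohHmmParams, list[float]]:
    """Estimate HMM parameters by Baum–Welch.

    The M-step is an exposure-weighted Poisson rate update; the
    log-likelihood is non-decreasing across iterations and iteration
    stops when the relative improvement falls below ``tol`` (with
    ``tol=inf`` the initial parameters are returned after a single
    E-step's bookkeeping).  States are re-ordered after convergence so
    that ``lambda_in < lambda_out``.  Returns the fitted parameters and
    the per-iteration log-likelihood history.

    ``seed`` is accepted for interface uniformity; EM itself is
    deterministic given the initialization.
    """
    if isinstance(tracks, HetWindowTrack):
        tracks = [tracks]
    sequences = [
        (k, n, missing)
        for track in tracks
        for _, k, n, missing in track.per_scaffold()
    ]
    total_k = sum(int(k.sum()) for k, _, _ in sequences)
    total_n = sum(int(n[~m].sum()) for _, n, m in sequences)
    if total_k == 0:
        warnings.warn(
            "degenerate input: no heterozygous sites anywhere; returning a flat fit",
            RuntimeWarning,
            stacklevel=2,
        )
        return (
            RohHmmParams(
                lambda_in=0.0,
                lambda_out=0.0,
                trans=np.array([[0.999, 0.001], [0.001, 0.999]]),
                init=np.array([0.5, 0.5]),
                degenerate=True,
            ),
            [],
        )
    if init is None:
        init = RohHmmParams.from_genome_het(total_k / max(total_n, 1))
    params = init
    history: list[float] = []
    if math.isinf(tol):
        ll = sum(
            _forward_scaffold(emission_loglik(k, n, m, params), params)
            for k, n, m in sequences
        )
        return params, [ll]
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E-step
        num_k = np.zeros(2)
        num_n = np.zeros(2)
        xi_sum = np.zeros((2, 2))
        gamma0 = np.zeros(2)
        gamma_sum = np.zeros(2)
        ll = 0.0
        lt = np.log(np.maximum(params.trans, 1e-300))
        for k, n, missing in sequences:
            logB = emission_loglik(k, n, missing, params)
            la, lb, seq_ll = _forward_backward(logB, params)
            ll += seq_ll
            g = np.exp(la + lb - seq_ll)
            g /= g.sum(axis=1, keepdims=True)
            gamma0 += g[0]
            gamma_sum += g[:-1].sum(axis=0) if len(g) > 1 else 0.0
            obs = ~np.asarray(missing, dtype=bool)
            num_k += g[obs].T @ k[obs].astype(float)
            num_n += g[obs].T @ n[obs].astype(float)
            if len(logB) > 1:
                for i in (0, 1):
                    for j in (0, 1):
                        lxi = la[:-1, i] + lt[i, j] + logB[1:, j] + lb[1:, j] - seq_ll
                        xi_sum[i, j] += np.exp(lxi).sum()
        history.append(ll)
        # M-step
        lam = np.maximum(num_k / np.maximum(num_n, 1e-300), _LAMBDA_FLOOR)
        row = xi_sum.sum(axis=1, keepdims=True)
        trans = np.where(row > 0, xi_sum / np.maximum(row, 1e-300), params.trans)
        trans = np.clip(trans, 1e-12, 1.0)
        trans /= trans.sum(axis=1, keepdims=True)
        pi = gamma0 / gamma0.sum()
        if lam[0] <= lam[1]:
            params = RohHmmParams(lambda_in=lam[0], lambda_out=lam[1], trans=trans, init=pi)
        else:
            swap = np.array([1, 0])
            params = RohHmmParams(
                lambda_in=lam[1],
                lambda_out=lam[0],
                trans=trans[np.ix_(swap, swap)],
                init=pi[swap],
            )
        if prev_ll > -np.inf and ll - prev_ll < tol * abs(prev_ll):
            break
        prev_ll = ll
    return params, history


# ---------------------------------------------------------------------------
# Tract extraction
# ---------------------------------------------------------------------------

@dataclass
class RohCallSet:
    """Sorted, non-overlapping ROH intervals for one individual, each
    with the mean inbred-state posterior over its windows."""

    individual_id: str
    tracts: list[Interval]
    posteriors: list[float] = field(default_factory=list)
    min_length: int = DEFAULT_MIN_LENGTH

    def __post_init__(self) -> None:
        by_scaffold: dict[str, list[Interval]] = {}
        for iv in self.tracts:
            iv.validate()
            by_scaffold.setdefault(iv.scaffold, []).append(iv)
        for ivs in by_scaffold.values():
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping tracts {a} and {b}")
        if self.posteriors and len(self.posteriors) != len(self.tracts):
            raise ValueError("posteriors must match tracts one-to-one")
        for iv in self.tracts:
            if iv.length < self.min_length:
                raise ValueError(
                    f"tract {iv} shorter than min_length {self.min_length}"
                )

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.tracts)

    def lengths_mb(self) -> np.ndarray:
        return np.array([iv.length / 1e6 for iv in self.tracts])

    def to_bed(self, path: str | os.PathLike) -> None:
        labels = (
            [f"{p:.4f}" for p in self.posteriors]
            if self.posteriors
            else ["."] * len(self.tracts)
        )
        write_bed(self.tracts, path, labels=labels)

    @classmethod
    def from_intervals(
        cls,
        individual_id: str,
        intervals: list[Interval],
        min_length: int = 0,
    ) -> "RohCallSet":
        """Build a call set from bare intervals (e.g. a truth BED),
        dropping those shorter than ``min_length``."""
        kept = sorted(
            (iv for iv in intervals if iv.length >= min_length),
            key=lambda iv: (iv.scaffold, iv.start),
        )
        return cls(individual_id=individual_id, tracts=kept, min_length=min_length)


def extract_tracts(
    result: DecodeResult,
    track: HetWindowTrack,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> RohCallSet:
    """Merge consecutive inbred-state windows into ROH intervals.

    A tract spans from the start of its first window to the end of its
    last; missing windows inherit their Viterbi state, so single masked
    windows between inbred flanks do not split tracts.  Tracts shorter
    than ``min_length`` are dropped.
    """
    tracts: list[Interval] = []
    posts: list[float] = []
    for name, grp in track.windows.groupby("scaffold", sort=False):
        path = result.paths[name]
        post = result.posteriors[name][:, INBRED]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        t = 0
        while t < len(path):
            if path[t] == INBRED:
                t0 = t
                while t < len(path) and path[t] == INBRED:
                    t += 1
                iv = Interval(name, int(starts[t0]), int(ends[t - 1]))
                if iv.length >= min_length:
                    tracts.append(iv)
                    posts.append(float(post[t0:t].mean()))
            else:
                t += 1
    return RohCallSet(
        individual_id=track.individual_id,
        tracts=tracts,
        posteriors=posts,
        min_length=min_length,
    )


def sample_track(
    params: RohHmmParams,
    n_windows: int,
    exposure: int,
    seed: int = 0,
    scaffold: str = "sim",
    window_size: int | None = None,
) -> tuple[HetWindowTrack, np.ndarray]:
    """Draw a window track from the HMM generative model (for parameter
    recovery studies).  Returns the track and the true state path."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    states = np.empty(n_windows, dtype=np.int8)
    states[0] = rng.choice(2, p=params.init)
    for t in range(1, n_windows):
        states[t] = rng.choice(2, p=params.trans[states[t - 1]])
    lam = np.where(states == INBRED, params.lambda_in, params.lambda_out)
    k = rng.poisson(lam * exposure)
    w = window_size or exposure
    starts = np.arange(n_windows) * w
    df = pd.DataFrame(
        {
            "scaffold": scaffold,
            "start": starts,
            "end": starts + w,
            "het_count": k,
            "callable": exposure,
        }
    )
    return HetWindowTrack(window_size=w, windows=df, individual_id="sim"), states
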
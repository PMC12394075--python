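"""HMM idealization of apparent-FRET traces.

A Gaussian-emission hidden Markov model with a user-fixed state count is fit
by maximum-likelihood EM jointly across all traces of a condition, the most
probable (Viterbi) state path is decoded per trace, and per-frame transition
probabilities are converted to rate constants via k = −ln(1−P)/τ.

EM fitting is delegated to hmmlearn; restarts, initialization, state
relabelling (ascending emission mean, so "high-FRET" is always the last
index) and the Viterbi tie-break convention are owned here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.base import ConvergenceMonitor
from hmmlearn.hmm import GaussianHMM


class _RecordingMonitor(ConvergenceMonitor):
    """Convergence monitor that keeps the whole log-likelihood trace."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)

from .synthetic import FretTrace

__all__ = ["HmmFit", "IdealizedPath", "fit_hmm", "viterbi", "prob_to_rate",
           "dwell_statistics"]


@dataclass
class HmmFit:
    """Result of a shared EM fit over a set of traces."""

    n_states: int
    means: np.ndarray            # ascending
    sds: np.ndarray
    transmat: np.ndarray         # row-stochastic per-frame probabilities
    startprob: np.ndarray
    log_likelihood: float
    n_restarts: int
    converged: bool
    history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def rates(self, frame_period: float) -> np.ndarray:
        """Off-diagonal transition rates in 1/s via −ln(1−P)/τ."""
        out = np.zeros_like(self.transmat)
        for i in range(self.n_states):
            for j in range(self.n_states):
                if i != j:
                    out[i, j] = prob_to_rate(self.transmat[i, j], frame_period)
        return out


@dataclass
class IdealizedPath:
    """Per-frame discrete state assignment with dwell segments."""

    states: np.ndarray
    frame_period: float

    @property
    def dwells(self):
        """List of (state, start_frame, n_frames) partitioning the trace."""
        s = self.states
        change = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [s.size]))
        return [(int(s[a]), int(a), int(b - a)) for a, b in zip(starts, ends)]


def _as_arrays(traces):
    out = []
    for t in traces:
        if isinstance(t, FretTrace):
            e = t.apparent_fret
            out.append(e[np.isfinite(e)])
        else:
            a = np.asarray(t, dtype=float)
            out.append(a[np.isfinite(a)])
    return out


def fit_hmm(traces, n_states: int, n_restarts: int = 10, tol: float = 1e-6,
            max_iter: int = 500, seed: int = 0) -> HmmFit:
    """Maximum-likelihood Gaussian HMM shared across a set of traces.

    Emission means are initialized at data quantiles and jittered per restart
    with a seeded RNG; the best of ``n_restarts`` EM runs is returned with
    states relabelled in ascending order of emission mean.
    """
    arrays = _as_arrays(traces)
    if not arrays or any(a.size < 2 for a in arrays):
        raise ValueError("need at least one trace with >= 2 frames")
    x = np.concatenate(arrays)[:, None]
    lengths = [a.size for a in arrays]

    data_sd = float(np.std(x))
    degenerate = data_sd < 1e-12
    if degenerate:
        warnings.warn("zero-variance data: HMM fit is degenerate", stacklevel=2)
    q = np.quantile(x, (np.arange(n_states) + 0.5) / n_states)
    span = max(np.ptp(x), 1e-6)
    rng = np.random.default_rng(seed)

    best = None
    best_hist = None
    for r in range(n_restarts):
        means0 = q if r == 0 else q + rng.normal(0.0, 0.05 * span, n_states)
        model = GaussianHMM(n_components=n_states, covariance_type="diag",
                            n_iter=max_iter, tol=tol, init_params="",
                            params="stmc", min_covar=1e-8,
                            random_state=np.random.RandomState(seed + r))
        model.startprob_ = np.full(n_states, 1.0 / n_states)
        model.transmat_ = np.full((n_states, n_states),
                                  0.1 / max(n_states - 1, 1))
        np.fill_diagonal(model.transmat_, 0.9)
        model.means_ = np.sort(means0)[:, None]
        model.covars_ = np.full((n_states, 1), max(data_sd, 1e-3) ** 2)
        model.monitor_ = _RecordingMonitor(tol, max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, lengths)
        score = model.monitor_.full_history[-1]
        if best is None or score > best_score:
            best, best_score = model, score
            best_hist = np.asarray(model.monitor_.full_history)

    order = np.argsort(best.means_.ravel())
    means = best.means_.ravel()[order]
    sds = np.sqrt(best.covars_.ravel()[order])
    transmat = best.transmat_[np.ix_(order, order)]
    startprob = best.startprob_[order]

    converged = bool(best.monitor_.converged) and not degenerate
    if n_states > 1:
        gaps = np.diff(means)
        pooled = 0.5 * (sds[:-1] + sds[1:])
        if np.any(gaps < 2.0 * np.maximum(pooled, 1e-12)):
            warnings.warn("poorly separated emission means: state count may "
                          "exceed the data's support", stacklevel=2)
            converged = False
    return HmmFit(n_states, means, sds, transmat, startprob,
                  float(best_score), n_restarts, converged, best_hist)


def viterbi(trace, fit: HmmFit) -> IdealizedPath:
    """Most probable state sequence under a fitted HMM.

    Deterministic; exact ties are broken toward the lowest state index.  With
    a zero-SD emission model a datum off the emission support is an error.
    """
    if isinstance(trace, FretTrace):
        e = trace.apparent_fret
        tau = trace.frame_period
    else:
        e = np.asarray(trace, dtype=float)
        tau = float("nan")
    e = e[np.isfinite(e)]
    n, k = e.size, fit.n_states

    sds = fit.sds.copy()
    zero = sds <= 0
    if zero.any():
        # emission support under zero SD is the exact mean value
        support = np.zeros((n, k), dtype=bool)
        support[:, ~zero] = True
        for i in np.flatnonzero(zero):
            support[:, i] = np.abs(e - fit.means[i]) <= 1e-12
        if np.any(~support.any(axis=1)):
            raise ValueError("datum outside the support of a zero-SD emission model")
        loge = np.where(support, 0.0, -np.inf)
        for i in np.flatnonzero(~zero):
            loge[:, i] = _log_normal(e, fit.means[i], sds[i])
    else:
        loge = _log_normal(e[:, None], fit.means[None, :], sds[None, :])

    with np.errstate(divide="ignore"):
        logt = np.log(fit.transmat)
        logp0 = np.log(fit.startprob)

    delta = logp0 + loge[0]
    back = np.zeros((n, k), dtype=int)
    for t in range(1, n):
        cand = delta[:, None] + logt          # cand[i, j]
        back[t] = np.argmax(cand, axis=0)      # argmax -> lowest index on ties
        delta = cand[back[t], np.arange(k)] + loge[t]
    states = np.empty(n, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(n - 2, -1, -1):
        states[t] = back[t + 1][states[t + 1]]
    return IdealizedPath(states, tau)


def _log_normal(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd * np.sqrt(2.0 * np.pi))


def prob_to_rate(p: float, frame_period: float) -> float:
    """Convert a per-frame transition probability to a rate: −ln(1−P)/τ."""
    if not 0.0 <= p < 1.0:
        raise ValueError("transition probability must lie in [0, 1); P >= 1 "
                         "implies an infinite rate")
    if frame_period <= 0:
        raise ValueError("frame_period must be positive")
    return -np.log1p(-p) / frame_period


def dwell_statistics(paths) -> pd.DataFrame:
    """Censored dwell-time table with maximum-likelihood exponential rates.

    The first and last dwell of every trace are censored (their start/end was
    not observed); for each state the mean uncensored dwell (seconds) and the
    ML exponential escape rate 1/mean are reported.
    """
    durations: dict[int, list[float]] = {}
    for path in paths:
        dwells = path.dwells
        for state, _start, n_frames in dwells[1:-1]:
            durations.setdefault(state, []).append(n_frames * path.frame_period)
    if not durations:
        warnings.warn("no uncensored dwells", stacklevel=2)
        return pd.DataFrame(columns=["state", "n_dwells", "mean_dwell_s",
                                     "rate_per_s"])
    rows = []
    for state in sorted(durations):
        d = np.asarray(durations[state])
        rows.append({"state": state, "n_dwells": d.size,
                     "mean_dwell_s": float(d.mean()),
                     "rate_per_s": float(1.0 / d.mean())})
    return pd.DataFrame(rows)
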
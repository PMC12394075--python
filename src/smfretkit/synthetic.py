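"""Synthetic data generation for the whole analysis chain.

Every downstream stage (QC, HMM idealization, sub-frame kinetic inference,
histogram decomposition, structure metrics, differential HDX) is exercised on
data produced here, with known ground truth.

The central object is a continuous-time Markov chain (CTMC) over a small
number of conformational states, observed through a camera that integrates
over a finite frame period ``tau``.  The apparent FRET efficiency of a frame
is the dwell-time-weighted average of the per-state emission means plus
Gaussian noise — the "time-averaged" signal that makes rates faster than the
frame rate invisible to naive idealization but recoverable from the shape of
the occupancy-fraction distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KineticModel",
    "FretTrace",
    "SyntheticTruth",
    "simulate_trace",
    "simulate_trace_set",
    "simulate_occupancy_windows",
    "simulate_uptake_table",
    "make_toy_frames",
    "pooled_fret",
]

#: Fixed donor+acceptor total intensity before photobleaching (arbitrary
#: units).  Only the acceptor/(donor+acceptor) ratio matters downstream.
TOTAL_INTENSITY = 500.0


@dataclass(frozen=True)
class KineticModel:
    """Emission model and transition rates of a CTMC over FRET states.

    ``emission_means`` are apparent-FRET means per state (unitless), one
    per state; ``noise_sd`` is the per-frame Gaussian SD of the observed
    efficiency; ``rate_matrix`` holds off-diagonal transition rates in 1/s
    (diagonal entries are ignored and recomputed as negative row sums).
    """

    emission_means: np.ndarray
    noise_sd: float
    rate_matrix: np.ndarray

    def __post_init__(self):
        means = np.atleast_1d(np.asarray(self.emission_means, dtype=float))
        rates = np.atleast_2d(np.asarray(self.rate_matrix, dtype=float))
        object.__setattr__(self, "emission_means", means)
        object.__setattr__(self, "rate_matrix", rates)
        n = means.size
        if n < 1:
            raise ValueError("need at least one state")
        if rates.shape != (n, n):
            raise ValueError(
                f"rate_matrix shape {rates.shape} does not match {n} states"
            )
        off = rates[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("transition rates must be finite")
        if np.any(off < 0):
            raise ValueError("transition rates must be non-negative")
        if not np.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError("noise_sd must be finite and non-negative")

    @classmethod
    def two_state(cls, k_f: float, k_r: float, eps_low: float = 0.38,
                  eps_high: float = 0.63, noise_sd: float = 0.05) -> "KineticModel":
        """Two-state model: ``k_f`` = rate low→high, ``k_r`` = high→low."""
        rates = np.array([[0.0, k_f], [k_r, 0.0]])
        return cls(np.array([eps_low, eps_high]), noise_sd, rates)

    @property
    def n_states(self) -> int:
        return self.emission_means.size

    @property
    def generator(self) -> np.ndarray:
        """Infinitesimal generator Q (rows sum to zero)."""
        q = self.rate_matrix.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the chain (sums to 1).

        The two-state case uses the closed form k_r/(k_f+k_r), k_f/(k_f+k_r)
        so that the high-state occupancy is exactly k_f/(k_f+k_r).
        """
        if self.n_states == 2:
            k_f = self.rate_matrix[0, 1]
            k_r = self.rate_matrix[1, 0]
            tot = k_f + k_r
            if tot == 0.0:
                return np.array([0.5, 0.5])
            return np.array([k_r / tot, k_f / tot])
        q = self.generator
        # left null vector of Q: solve pi Q = 0 with sum(pi) = 1
        a = np.vstack([q.T, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


@dataclass
class FretTrace:
    """One donor/acceptor intensity record at fixed frame period."""

    frame_period: float
    donor: np.ndarray
    acceptor: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor and acceptor must be 1-D arrays of equal length")
        if self.donor.size < 1:
            raise ValueError("trace must contain at least one frame")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")

    def __len__(self) -> int:
        return self.donor.size

    @property
    def apparent_fret(self) -> np.ndarray:
        """acceptor/(donor+acceptor); NaN where the total is not positive."""
        total = self.donor + self.acceptor
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(total > 0, self.acceptor / total, np.nan)
        return e


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated trace.

    ``occupancy_fraction`` is the fraction of each frame's exposure spent in
    the highest-emission state, so its long-run mean is the stationary
    occupancy of that state (k_f/(k_f+k_r) for two states).
    ``state_fractions`` holds the full (n_frames, n_states) matrix.
    """

    model: KineticModel
    jump_times: np.ndarray
    jump_states: np.ndarray
    state_fractions: np.ndarray
    bleach_frame: int | None

    @property
    def occupancy_fraction(self) -> np.ndarray:
        high = int(np.argmax(self.model.emission_means))
        return self.state_fractions[:, high]


def _sample_ctmc_path(model: KineticModel, total_time: float,
                      rng: np.random.Generator, start_state: int | None = None):
    """Exact CTMC path: jump times (starting at 0) and visited states."""
    n = model.n_states
    if start_state is None:
        pi = model.stationary_distribution()
        state = int(rng.choice(n, p=pi))
    else:
        state = int(start_state)
    rates = model.rate_matrix.copy()
    np.fill_diagonal(rates, 0.0)
    out_rate = rates.sum(axis=1)

    if n == 2 and out_rate[0] > 0 and out_rate[1] > 0:
        # Alternating dwells: vectorized block generation.
        mean_jumps = total_time * out_rate.mean()
        block = max(16, int(mean_jumps + 6.0 * math.sqrt(mean_jumps + 1.0)))
        times = [0.0]
        states = [state]
        t, s = 0.0, state
        while t < total_time:
            u = rng.exponential(1.0, size=block)
            k_seq = np.where(np.arange(block) % 2 == 0, out_rate[s], out_rate[1 - s])
            dwells = u / k_seq
            jumps = t + np.cumsum(dwells)
            keep = jumps < total_time
            jt = jumps[keep]
            times.extend(jt.tolist())
            seq = (s + 1 + np.arange(jt.size)) % 2
            states.extend(seq.tolist())
            if jt.size < block:
                t = total_time
            else:
                t = jt[-1]
                s = int(seq[-1])
        return np.asarray(times), np.asarray(states, dtype=int)

    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        k_out = out_rate[state]
        if k_out <= 0:
            break
        t += rng.exponential(1.0 / k_out)
        if t >= total_time:
            break
        p = rates[state] / k_out
        state = int(rng.choice(n, p=p))
        times.append(t)
        states.append(state)
    return np.asarray(times), np.asarray(states, dtype=int)


def _frame_fractions(jump_times: np.ndarray, jump_states: np.ndarray,
                     n_states: int, n_frames: int, tau: float) -> np.ndarray:
    """Fraction of each frame spent in each state, from an exact path."""
    edges = np.arange(n_frames + 1) * tau
    # segment boundaries: union of jump times and frame edges
    bounds = np.union1d(jump_times, edges)
    bounds = bounds[(bounds >= 0.0) & (bounds <= n_frames * tau)]
    starts = bounds[:-1]
    ends = bounds[1:]
    seg_state = jump_states[np.searchsorted(jump_times, starts, side="right") - 1]
    seg_frame = np.searchsorted(edges, starts, side="right") - 1
    seg_frame = np.clip(seg_frame, 0, n_frames - 1)
    frac = np.zeros((n_frames, n_states))
    np.add.at(frac, (seg_frame, seg_state), (ends - starts) / tau)
    return np.clip(frac, 0.0, 1.0)


def simulate_trace(model: KineticModel, n_frames: int, frame_period: float,
                   seed, bleach_rate: float | None = None,
                   meta: dict | None = None,
                   start_state: int | None = None) -> tuple[FretTrace, SyntheticTruth]:
    """Simulate one camera-averaged FRET trace with exact CTMC dynamics.

    Per frame the latent path is sampled exactly (exponential waiting times,
    stationary start); the observed efficiency is the dwell-weighted average
    of the state emission means plus ``Normal(0, noise_sd)``.  Donor and
    acceptor are synthesized from a fixed total intensity so that
    acceptor/(donor+acceptor) reproduces the observed efficiency exactly.

    ``bleach_rate`` (1/s), if given, draws a single-step photobleach time from
    an exponential; from that frame onward both channels collapse to baseline
    noise below the standard QC thresholds.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if frame_period <= 0:
        raise ValueError("frame_period must be positive")
    rng = np.random.default_rng(seed)
    total_time = n_frames * frame_period

    jt, js = _sample_ctmc_path(model, total_time, rng, start_state)
    frac = _frame_fractions(jt, js, model.n_states, n_frames, frame_period)
    e_ideal = frac @ model.emission_means
    e_obs = e_ideal + rng.normal(0.0, model.noise_sd, size=n_frames)

    bleach_frame = None
    if bleach_rate is not None and bleach_rate > 0:
        t_bleach = rng.exponential(1.0 / bleach_rate)
        frame = int(t_bleach / frame_period)
        if frame < n_frames:
            bleach_frame = frame

    acceptor = TOTAL_INTENSITY * e_obs
    donor = TOTAL_INTENSITY * (1.0 - e_obs)
    if bleach_frame is not None:
        n_post = n_frames - bleach_frame
        # post-bleach baseline: |N(0,1)| per channel keeps all three QC
        # criteria (acceptor<5, donor<5, sum<10) satisfied essentially always
        donor[bleach_frame:] = np.abs(rng.normal(0.0, 1.0, n_post))
        acceptor[bleach_frame:] = np.abs(rng.normal(0.0, 1.0, n_post))

    info = dict(meta or {})
    info.setdefault("seed", seed)
    trace = FretTrace(frame_period, donor, acceptor, meta=info)
    truth = SyntheticTruth(model, jt, js, frac, bleach_frame)
    return trace, truth


def simulate_trace_set(model: KineticModel, n_traces: int, n_frames: int,
                       frame_period: float, seed: int,
                       bleach_rate: float | None = None,
                       condition: str = "synthetic"):
    """Simulate a reproducible set of traces.

    Per-trace seeds are spawned from one master ``SeedSequence`` so the set is
    identical regardless of generation order.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_traces)
    traces, truths = [], []
    for i, child in enumerate(children):
        meta = {"trace_id": f"{condition}-{i:05d}", "condition": condition,
                "seed": int(child.generate_state(1)[0] % (2**31))}
        tr, th = simulate_trace(model, n_frames, frame_period, child,
                                bleach_rate=bleach_rate, meta=meta)
        traces.append(tr)
        truths.append(th)
    return traces, truths


def pooled_fret(traces) -> np.ndarray:
    """Concatenate finite apparent-FRET values over a set of traces."""
    vals = np.concatenate([t.apparent_fret for t in traces])
    return vals[np.isfinite(vals)]


def simulate_occupancy_windows(k1: float, k2: float, tau: float,
                               n_windows: int, seed) -> np.ndarray:
    """Brute-force Monte-Carlo oracle for the occupancy-fraction distribution.

    Simulates ``n_windows`` independent stationary two-state CTMC windows of
    length ``tau`` and returns the fraction of each window spent in state 1
    (the state with escape rate ``k1``).  This is the in-repo ground truth the
    closed-form Bessel density is validated against.
    """
    if k1 <= 0 or k2 <= 0 or tau <= 0:
        raise ValueError("rates and tau must be positive")
    rng = np.random.default_rng(seed)
    pi1 = k2 / (k1 + k2)
    in1 = rng.random(n_windows) < pi1
    remaining = np.full(n_windows, tau)
    time1 = np.zeros(n_windows)
    while True:
        active = remaining > 0
        if not active.any():
            break
        k = np.where(in1, k1, k2)
        dwell = rng.exponential(1.0, n_windows) / k
        dt = np.minimum(dwell, remaining)
        dt[~active] = 0.0
        time1 += np.where(in1, dt, 0.0)
        remaining -= dt
        flip = active & (dwell < remaining + dt)  # dwell ended inside window
        in1 = np.where(flip, ~in1, in1)
    return time1 / tau


# ---------------------------------------------------------------------------
# HDX uptake table generator


def simulate_uptake_table(protection_map: dict, timepoints, noise_sd: float,
                          replicates: int, seed,
                          conditions=None, max_uptake: float = 90.0,
                          half_time: float = 600.0) -> pd.DataFrame:
    """Synthetic per-peptide deuterium-uptake table with known protection.

    ``protection_map`` maps peptide keys ``(start, end, sequence)`` to a dict
    ``{condition: delta}`` where ``delta`` is the %D reduction relative to the
    reference (first) condition at the longest timepoint; the reduction ramps
    with the uptake curve itself so condition differences equal the map values
    in expectation at the final timepoint.  Mean uptake follows a saturating
    single-exponential and is monotone non-decreasing in time.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not protection_map:
        raise ValueError("empty peptide set")
    timepoints = np.asarray(sorted(timepoints), dtype=float)
    if np.any(np.diff(timepoints) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    rng = np.random.default_rng(seed)
    if conditions is None:
        conditions = sorted({c for v in protection_map.values() for c in v})
        conditions = ["reference"] + [c for c in conditions if c != "reference"]

    base = 1.0 - np.exp(-timepoints / half_time)
    ramp = base / base[-1]
    rows = []
    for (start, end, seq), prot in sorted(protection_map.items()):
        # per-peptide intrinsic-exchange spread, stable across conditions
        pep_rng = np.random.default_rng(abs(hash((start, end, seq))) % (2**31))
        umax = max_uptake * (0.9 + 0.2 * pep_rng.random())
        for cond in conditions:
            delta = float(prot.get(cond, 0.0))
            mean = np.clip(umax * base - delta * ramp, 0.0, 100.0)
            for rep in range(replicates):
                obs = mean + rng.normal(0.0, noise_sd, size=timepoints.size)
                for t, v in zip(timepoints, obs):
                    rows.append({"start": int(start), "end": int(end),
                                 "sequence": seq, "timepoint_s": float(t),
                                 "condition": cond, "replicate": rep,
                                 "percent_d": float(np.clip(v, 0.0, 110.0))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Toy coordinate frames


def make_toy_frames(atoms, n_frames: int = 1, jitter_sd: float = 0.0,
                    seed=0, displacements=None):
    """Build toy multi-frame structures with known geometry.

    ``atoms`` is a sequence of ``(chain, resnum, resname, atom_name, element,
    (x, y, z))`` tuples.  Each frame realizes the base coordinates plus
    optional per-frame ``displacements`` (array of shape
    ``(n_frames, n_atoms, 3)``) plus isotropic Gaussian jitter of SD
    ``jitter_sd`` Å.  Returns a list of :class:`~smfretkit.structures.StructureFrame`.
    """
    from .structures import StructureFrame

    atoms = list(atoms)
    if not atoms:
        raise ValueError("empty atom specification")
    rng = np.random.default_rng(seed)
    base = np.array([a[5] for a in atoms], dtype=float)
    if displacements is not None:
        displacements = np.asarray(displacements, dtype=float)
        if displacements.shape != (n_frames, len(atoms), 3):
            raise ValueError("displacements shape must be (n_frames, n_atoms, 3)")
    frames = []
    for i in range(n_frames):
        xyz = base.copy()
        if displacements is not None:
            xyz = xyz + displacements[i]
        if jitter_sd > 0:
            xyz = xyz + rng.normal(0.0, jitter_sd, size=xyz.shape)
        frames.append(StructureFrame(
            chains=np.array([a[0] for a in atoms]),
            resnums=np.array([a[1] for a in atoms], dtype=int),
            resnames=np.array([a[2] for a in atoms]),
            atom_names=np.array([a[3] for a in atoms]),
            elements=np.array([a[4] for a in atoms]),
            coords=xyz,
            model_index=i,
        ))
    return frames
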
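"""Bayesian inference of two-state rates faster than the camera frame rate.

When a molecule switches states many times within one exposure, the camera
records the time average of the two emission levels, and idealization-based
rate estimates saturate at roughly the frame rate.  The information about the
rates survives, however, in the *shape* of the per-frame signal distribution:
each frame reports ``E = f·ε₁ + (1−f)·ε₂ + noise`` where ``f`` is the
fraction of the exposure spent in the low state, and the distribution of
``f`` for a stationary two-state chain is known in closed form.

For escape rates ``k₁`` (out of the ε₁ state) and ``k₂`` (out of the ε₂
state), stationary weights ``π₁ = k₂/(k₁+k₂)`` and ``π₂ = k₁/(k₁+k₂)``, and
exposure ``τ``, the occupancy fraction has point masses

    P(f=1) = π₁·exp(−k₁τ)        (no transition, spent whole frame in ε₁)
    P(f=0) = π₂·exp(−k₂τ)

plus a continuous part obtained by conditioning on the number of jumps
(a Bessel-function series):

    p(f) = τ·exp(−τ·(√(k₁f) − √(k₂(1−f)))²) · [ (2k₁k₂/(k₁+k₂))·I₀ᵉ(2z)
           + (k₂√(k₁k₂·f/(1−f)) + k₁√(k₁k₂·(1−f)/f))/(k₁+k₂) · I₁ᵉ(2z) ]

with ``z = τ√(k₁k₂f(1−f))`` and ``Iνᵉ`` the exponentially scaled modified
Bessel functions.  The per-frame marginal likelihood integrates the Gaussian
emission model over this distribution; the posterior over
``(ε₁, ε₂, σ, {k₁ᵢ, k₂ᵢ})`` — emission parameters shared across datasets,
rates per dataset — is sampled with an affine-invariant MCMC ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

import emcee

__all__ = [
    "PriorSpec",
    "PosteriorSummary",
    "GlobalInferenceResult",
    "occupancy_point_masses",
    "occupancy_fraction_density",
    "frame_loglik",
    "infer_rates_global",
]


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the sub-resolution model.

    Emission means get normal priors centered on the expected low/high FRET
    levels; the noise SD and each rate get maximum-entropy log-uniform priors
    on wide supports.
    """

    eps1_mean: float = 0.44
    eps1_sd: float = 0.2
    eps2_mean: float = 0.66
    eps2_sd: float = 0.2
    sigma_bounds: tuple = (0.01, 1.0)
    rate_bounds: tuple = (1e-3, 1e3)


@dataclass
class PosteriorSummary:
    """Per-parameter samples with median, central 1σ interval and MAP."""

    names: list
    samples: np.ndarray          # (n_samples, n_params), thinned production
    median: np.ndarray
    ci16: np.ndarray
    ci84: np.ndarray
    map_estimate: np.ndarray
    burn_steps: int
    log_posterior_trace: np.ndarray

    def interval(self, name: str) -> tuple[float, float, float]:
        i = self.names.index(name)
        return float(self.ci16[i]), float(self.median[i]), float(self.ci84[i])


# ---------------------------------------------------------------------------
# Occupancy-fraction distribution


def occupancy_point_masses(k1: float, k2: float, tau: float):
    """Weights of the transitionless frames: (P(f=0), P(f=1))."""
    _check_rates(k1, k2, tau)
    pi1 = k2 / (k1 + k2)
    pi2 = k1 / (k1 + k2)
    return pi2 * np.exp(-k2 * tau), pi1 * np.exp(-k1 * tau)


def occupancy_fraction_density(f, k1: float, k2: float, tau: float):
    """Continuous part of the occupancy-fraction distribution at ``f``.

    ``f`` is the fraction of the exposure spent in the state with escape rate
    ``k1``.  Endpoint point masses are reported separately by
    :func:`occupancy_point_masses`; together the three parts integrate to 1.
    """
    _check_rates(k1, k2, tau)
    f = np.asarray(f, dtype=float)
    out = np.zeros_like(f)
    inside = (f > 0.0) & (f < 1.0)
    fi = f[inside]
    g = 1.0 - fi
    z = tau * np.sqrt(k1 * k2 * fi * g)
    expo = -tau * (np.sqrt(k1 * fi) - np.sqrt(k2 * g)) ** 2
    ksum = k1 + k2
    bracket = (2.0 * k1 * k2 / ksum) * special.i0e(2.0 * z) + (
        (k2 * np.sqrt(k1 * k2 * fi / g) + k1 * np.sqrt(k1 * k2 * g / fi))
        / ksum) * special.i1e(2.0 * z)
    out[inside] = tau * np.exp(expo) * bracket
    return out if out.shape else float(out)


def _check_rates(k1, k2, tau):
    if not (np.isfinite(k1) and np.isfinite(k2)) or k1 <= 0 or k2 <= 0:
        raise ValueError("rates must be positive and finite")
    if tau <= 0:
        raise ValueError("tau must be positive")


def _gauss_legendre(n_nodes: int):
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    return 0.5 * (x + 1.0), 0.5 * w   # mapped to (0, 1)


def frame_loglik(e_values, eps1: float, eps2: float, sigma: float,
                 k1: float, k2: float, tau: float,
                 n_nodes: int = 101) -> np.ndarray:
    """Log marginal density of observed efficiencies under the model.

    ``log ∫₀¹ N(E | f·ε₁+(1−f)·ε₂, σ) dP(f)``, with the endpoint point
    masses added analytically and the continuous part integrated by
    fixed-order Gauss–Legendre quadrature.  Numerically stable for ``E``
    outside ``[ε₁, ε₂]`` (everything is assembled in log space).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    _check_rates(k1, k2, tau)
    e = np.atleast_1d(np.asarray(e_values, dtype=float))

    nodes, weights = _gauss_legendre(n_nodes)
    dens = occupancy_fraction_density(nodes, k1, k2, tau)
    w0, w1 = occupancy_point_masses(k1, k2, tau)

    mu_nodes = nodes * eps1 + (1.0 - nodes) * eps2
    log_norm = -np.log(sigma) - 0.5 * np.log(2.0 * np.pi)

    # (nE, n_nodes + 2) matrix of log contributions
    with np.errstate(divide="ignore"):
        log_wdens = np.log(weights * dens)
        log_w1 = np.log(w1)
        log_w0 = np.log(w0)
    cont = log_wdens[None, :] + log_norm \
        - 0.5 * ((e[:, None] - mu_nodes[None, :]) / sigma) ** 2
    pm1 = log_w1 + log_norm - 0.5 * ((e - eps1) / sigma) ** 2
    pm0 = log_w0 + log_norm - 0.5 * ((e - eps2) / sigma) ** 2
    stacked = np.concatenate([cont, pm1[:, None], pm0[:, None]], axis=1)
    ll = special.logsumexp(stacked, axis=1)
    return ll if np.ndim(e_values) else float(ll[0])


# ---------------------------------------------------------------------------
# Global ensemble MCMC


@dataclass
class GlobalInferenceResult:
    summary: PosteriorSummary
    names: list
    n_datasets: int
    priors: PriorSpec
    tau: float

    def rates(self, dataset: int) -> dict:
        """Median and 16–84% interval for (k1, k2) of one dataset."""
        out = {}
        for key in (f"k1_{dataset}", f"k2_{dataset}"):
            lo, med, hi = self.summary.interval(key)
            out[key] = {"median": med, "ci16": lo, "ci84": hi}
        return out


class _GlobalPosterior:
    """Binned global log-posterior shared by the walker ensemble.

    Each dataset's efficiencies are histogrammed once on a fine grid; the
    log-likelihood is the count-weighted sum of the per-frame marginal at the
    bin centers.  Bin widths are far below any admissible σ, so the binning
    error is negligible next to the quadrature tolerance.
    """

    def __init__(self, datasets, tau, priors, n_nodes=101, n_bins=512):
        self.tau = tau
        self.priors = priors
        self.n_nodes = n_nodes
        self.binned = []
        for data in datasets:
            e = np.asarray(data, dtype=float)
            e = e[np.isfinite(e)]
            if e.size == 0:
                self.binned.append(None)
                continue
            lo, hi = e.min(), e.max()
            pad = 1e-6 * max(hi - lo, 1.0)
            counts, edges = np.histogram(e, bins=n_bins, range=(lo - pad, hi + pad))
            centers = 0.5 * (edges[:-1] + edges[1:])
            keep = counts > 0
            self.binned.append((centers[keep], counts[keep]))
        self.n_datasets = len(datasets)
        self.ndim = 3 + 2 * self.n_datasets
        p = priors
        self._ln_sig_lo, self._ln_sig_hi = np.log(p.sigma_bounds)
        self._ln_k_lo, self._ln_k_hi = np.log(p.rate_bounds)

    def unpack(self, theta):
        eps1, eps2, ln_sigma = theta[0], theta[1], theta[2]
        ks = np.exp(theta[3:]).reshape(self.n_datasets, 2)
        return eps1, eps2, np.exp(ln_sigma), ks

    def log_prior(self, theta):
        p = self.priors
        eps1, eps2, ln_sigma = theta[0], theta[1], theta[2]
        if eps1 > eps2:       # labelling convention: ε₁ is the lower mean
            return -np.inf
        if not (self._ln_sig_lo <= ln_sigma <= self._ln_sig_hi):
            return -np.inf
        lnks = theta[3:]
        if np.any(lnks < self._ln_k_lo) or np.any(lnks > self._ln_k_hi):
            return -np.inf
        lp = -0.5 * ((eps1 - p.eps1_mean) / p.eps1_sd) ** 2 \
            - np.log(p.eps1_sd * np.sqrt(2 * np.pi))
        lp += -0.5 * ((eps2 - p.eps2_mean) / p.eps2_sd) ** 2 \
            - np.log(p.eps2_sd * np.sqrt(2 * np.pi))
        lp += -np.log(self._ln_sig_hi - self._ln_sig_lo)
        lp += -lnks.size * np.log(self._ln_k_hi - self._ln_k_lo)
        return lp

    def __call__(self, theta):
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        eps1, eps2, sigma, ks = self.unpack(theta)
        ll = 0.0
        for binned, (k1, k2) in zip(self.binned, ks):
            if binned is None:
                continue
            centers, counts = binned
            ll += float(counts @ frame_loglik(centers, eps1, eps2, sigma,
                                              k1, k2, self.tau,
                                              n_nodes=self.n_nodes))
        if not np.isfinite(ll):
            return -np.inf
        return lp + ll

    def map_start(self, rng, n_prior_draws: int = 256, n_refine: int = 4):
        """Multistart MAP estimate for walker initialization.

        The marginal-likelihood surface over the rates is multimodal: a
        static two-Gaussian mode competes with the fast-exchange mode, and
        they sit many e-foldings apart in rate.  Candidate starts are probed
        on a log-spaced symmetric-rate grid (emissions at their prior means)
        plus the best of a batch of prior draws; the best few candidates are
        refined by Nelder–Mead on the negative log-posterior.
        """
        from scipy.optimize import minimize

        p = self.priors
        candidates = []
        for k in (0.1, 1.0, 10.0, 100.0, 1000.0):
            theta = np.empty(self.ndim)
            theta[0], theta[1] = p.eps1_mean, p.eps2_mean
            theta[2] = np.log(0.05)
            theta[3:] = np.log(k)
            candidates.append(theta)
        draws = self.sample_prior(rng, n_prior_draws)
        scores = np.array([self(t) for t in draws])
        order = np.argsort(scores)[::-1]
        candidates.extend(draws[order[:3]])

        scored = sorted(candidates, key=self, reverse=True)
        best_theta, best_val = None, -np.inf
        for theta in scored[:n_refine + 3]:
            res = minimize(lambda t: -self(t), theta, method="Nelder-Mead",
                           options={"maxiter": 400, "fatol": 0.01,
                                    "xatol": 1e-4})
            if -res.fun > best_val:
                best_val, best_theta = -res.fun, res.x
        return best_theta

    def laplace_scales(self, center, step: float = 1e-3) -> np.ndarray:
        """Per-parameter posterior SDs from the diagonal curvature at a mode.

        Used only to disperse the initial walker ball on the right scale;
        the MCMC itself determines the reported intervals.
        """
        d = self.ndim
        scales = np.empty(d)
        f0 = self(center)
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = step
            curv = (self(center + ei) - 2.0 * f0 + self(center - ei)) / step**2
            scales[i] = 1.0 / np.sqrt(-curv) if curv < 0 else 0.1
        return np.clip(scales, 1e-4, 1.0)

    def sample_prior(self, rng, n):
        p = self.priors
        draws = np.empty((n, self.ndim))
        draws[:, 0] = rng.normal(p.eps1_mean, p.eps1_sd, n)
        draws[:, 1] = rng.normal(p.eps2_mean, p.eps2_sd, n)
        swap = draws[:, 0] > draws[:, 1]
        draws[swap, 0], draws[swap, 1] = draws[swap, 1], draws[swap, 0].copy()
        draws[:, 2] = rng.uniform(self._ln_sig_lo, self._ln_sig_hi, n)
        draws[:, 3:] = rng.uniform(self._ln_k_lo, self._ln_k_hi,
                                   (n, self.ndim - 3))
        return draws


def infer_rates_global(datasets, tau: float, priors: PriorSpec = PriorSpec(),
                       n_walkers: int | None = None, seed: int = 0,
                       min_burn: int = 300, max_burn: int = 1700,
                       production: int = 100, thin: int = 10,
                       plateau_tol: float = 0.1, n_nodes: int = 101,
                       n_bins: int = 512, init: str = "map"
                       ) -> GlobalInferenceResult:
    """Global ensemble MCMC over shared emissions and per-dataset rates.

    With ``init='map'`` (default) walkers start in a small ball around a
    multistart maximum-a-posteriori estimate; ``init='prior'`` draws them
    from the priors instead (adequate only when the posterior is unimodal —
    the broad log-uniform rate priors otherwise trap the ensemble in the
    static-limit mode).  Burn-in runs in 100-step chunks until the mean
    log-posterior changes by less than ``plateau_tol`` between consecutive
    chunks (at least ``min_burn``, at most ``max_burn`` steps) and is
    discarded; ``production`` further steps are taken, thinned by ``thin``
    for interval summaries; the MAP is located on the full production chain.

    Parameter order: ``eps1, eps2, sigma, k1_0, k2_0, k1_1, k2_1, ...``
    (rates sampled on a log scale internally, reported in 1/s).
    """
    if len(datasets) < 1:
        raise ValueError("need at least one dataset")
    post = _GlobalPosterior(datasets, tau, priors, n_nodes=n_nodes,
                            n_bins=n_bins)
    ndim = post.ndim
    if n_walkers is None:
        n_walkers = 4 * ndim
    if n_walkers < 2 * ndim:
        raise ValueError("walker count must be at least twice the dimension")
    rng = np.random.default_rng(seed)
    if init == "map" and any(b is not None for b in post.binned):
        center = post.map_start(rng)
        scatter = post.laplace_scales(center)
        p0 = center[None, :] + scatter[None, :] * rng.standard_normal(
            (n_walkers, ndim))
        # keep starts inside the prior support (redraw with shrinking jitter)
        for i in range(n_walkers):
            shrink = 1.0
            while not np.isfinite(post.log_prior(p0[i])):
                shrink *= 0.5
                p0[i] = center + shrink * scatter * rng.standard_normal(ndim)
    elif init in ("map", "prior"):
        p0 = post.sample_prior(rng, n_walkers)
    else:
        raise ValueError(f"unknown init scheme {init!r}")

    sampler = emcee.EnsembleSampler(n_walkers, ndim, post)
    sampler.random_state = np.random.RandomState(seed).get_state()

    state = p0
    burn = 0
    prev_mean = None
    chunk = 100
    logpost_trace = []
    while burn < max_burn:
        state = sampler.run_mcmc(state, chunk, progress=False)
        burn += chunk
        lp = sampler.get_log_prob()[-chunk:]
        mean_lp = float(np.mean(lp[np.isfinite(lp)]))
        logpost_trace.append(mean_lp)
        if (prev_mean is not None and burn >= min_burn
                and abs(mean_lp - prev_mean) < plateau_tol):
            break
        prev_mean = mean_lp
    sampler.reset()
    sampler.run_mcmc(state, production, progress=False)

    chain = sampler.get_chain()                  # (production, walkers, ndim)
    logp = sampler.get_log_prob()
    flat_all = chain.reshape(-1, ndim)
    flat_logp = logp.reshape(-1)
    thinned = chain[thin - 1::thin].reshape(-1, ndim)

    names = ["eps1", "eps2", "sigma"]
    for i in range(post.n_datasets):
        names += [f"k1_{i}", f"k2_{i}"]

    def natural(arr):
        out = arr.copy()
        out[:, 2] = np.exp(out[:, 2])
        out[:, 3:] = np.exp(out[:, 3:])
        return out

    thinned_nat = natural(thinned)
    map_theta = natural(flat_all[np.argmax(flat_logp)][None, :])[0]
    summary = PosteriorSummary(
        names=names,
        samples=thinned_nat,
        median=np.median(thinned_nat, axis=0),
        ci16=np.percentile(thinned_nat, 16, axis=0),
        ci84=np.percentile(thinned_nat, 84, axis=0),
        map_estimate=map_theta,
        burn_steps=burn,
        log_posterior_trace=np.asarray(logpost_trace),
    )
    return GlobalInferenceResult(summary, names, post.n_datasets, priors, tau)
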
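"""Equilibrium analysis of FRET distributions.

Histogram decomposition into Gaussian components, the missed-trace occupancy
correction, the independent-subunit cooperativity expectation, linear
gating-scheme occupancies and the Förster distance conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.mixture import GaussianMixture

__all__ = [
    "MixtureFit", "OccupancyEstimate", "fit_mixture", "histogram_with_sem",
    "correct_occupancy", "both_closed_probability", "gating_occupancies",
    "fret_to_distance", "distance_to_fret",
]

DEFAULT_BINS = 40
DEFAULT_RANGE = (-0.1, 1.1)


@dataclass
class MixtureFit:
    """Gaussian mixture decomposition of an efficiency distribution.

    ``fraction_high`` is the weight of the highest-mean component — the
    standard "high-FRET fraction" readout of two-Gaussian histogram fits.
    """

    n_components: int
    means: np.ndarray           # ascending
    sds: np.ndarray
    weights: np.ndarray         # sum to 1
    residual: float
    method: str
    degenerate: bool = False
    fraction_high_se: float | None = None

    @property
    def fraction_high(self) -> float:
        return float(self.weights[-1])


@dataclass
class OccupancyEstimate:
    """Missed-trace-corrected active/inactive occupancies.

    Automated trace selection preferentially drops dim, low-FRET (inactive)
    molecules; with ``c = n/n'`` the observed-to-true trace-count ratio, the
    corrected fractions are ``f'_A = c·f_A`` and ``f'_I = 1 − c·(1 − f_I)``
    (which sum to 1 exactly), giving ``K'_eq = f'_A/f'_I`` and, when the
    reverse rate is trusted, ``k'_f = K'_eq·k_r``.
    """

    f_observed: float
    c: float
    f_active: float
    f_inactive: float
    k_eq: float
    k_r: float | None = None
    k_f: float | None = None


def _mixture_pdf(x, *params):
    k = len(params) // 3
    out = np.zeros_like(x)
    for i in range(k):
        a, mu, sd = params[3 * i:3 * i + 3]
        out = out + a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return out


def fit_mixture(values, n_components: int = 2, method: str = "ml",
                bins: int = DEFAULT_BINS, hist_range=DEFAULT_RANGE,
                seed: int = 0, n_bootstrap: int = 0) -> MixtureFit:
    """Decompose efficiencies into ``n_components`` Gaussians.

    ``method='ml'`` fits the unbinned maximum-likelihood mixture
    (EM, seeded); ``method='binned'`` least-squares-fits a sum of Gaussians
    to the density histogram, mirroring how published histograms are fit.
    Components are reported in ascending order of mean.  ``n_bootstrap`` > 0
    adds a bootstrap standard error on the high-FRET fraction.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if not 1 <= n_components <= 4:
        raise ValueError("n_components must be in 1..4")
    if values.size < 3 * n_components:
        raise ValueError("fewer observations than mixture parameters")

    fit = _fit_once(values, n_components, method, bins, hist_range, seed)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        fracs = []
        for _ in range(n_bootstrap):
            resampled = rng.choice(values, size=values.size, replace=True)
            try:
                fracs.append(_fit_once(resampled, n_components, method, bins,
                                       hist_range, seed).weights[-1])
            except RuntimeError:
                continue
        if fracs:
            fit.fraction_high_se = float(np.std(fracs))
    return fit


def _fit_once(values, n_components, method, bins, hist_range, seed):
    if method == "ml":
        gm = GaussianMixture(n_components=n_components, n_init=5,
                             random_state=seed, covariance_type="full")
        gm.fit(values[:, None])
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        weights = gm.weights_
        residual = float(-gm.score(values[:, None]))
    elif method == "binned":
        hist, edges = np.histogram(values, bins=bins, range=hist_range,
                                   density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        q = np.quantile(values, (np.arange(n_components) + 0.5) / n_components)
        p0 = []
        for mu in q:
            p0 += [hist.max(), mu, max(np.std(values) / n_components, 0.02)]
        lo = [0.0, hist_range[0], 1e-3] * n_components
        hi = [np.inf, hist_range[1], 1.0] * n_components
        popt, _ = curve_fit(_mixture_pdf, centers, hist, p0=p0,
                            bounds=(lo, hi), maxfev=20000)
        amps = popt[0::3]
        means = popt[1::3]
        sds = popt[2::3]
        weights = amps * sds * np.sqrt(2.0 * np.pi)
        weights = weights / weights.sum()
        residual = float(np.sqrt(np.mean(
            (_mixture_pdf(centers, *popt) - hist) ** 2)))
    else:
        raise ValueError(f"unknown method {method!r}")

    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    degenerate = False
    if n_components > 1:
        gaps = np.diff(means)
        if np.any(weights < 1e-3) or np.any(gaps < sds[:-1] + sds[1:]):
            degenerate = True
            warnings.warn("mixture components overlap or vanish: data may "
                          "support fewer states", stacklevel=3)
    return MixtureFit(n_components, means, sds, np.asarray(weights, float),
                      residual, method, degenerate)


def histogram_with_sem(movies, bins: int = DEFAULT_BINS,
                       hist_range=DEFAULT_RANGE) -> pd.DataFrame:
    """Per-movie density histograms averaged with s.e.m. across movies."""
    movies = [np.asarray(m, float) for m in movies]
    densities = []
    for m in movies:
        m = m[np.isfinite(m)]
        d, edges = np.histogram(m, bins=bins, range=hist_range, density=True)
        densities.append(d)
    densities = np.asarray(densities)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mean = densities.mean(axis=0)
    sem = (densities.std(axis=0, ddof=1) / np.sqrt(len(movies))
           if len(movies) > 1 else np.zeros_like(mean))
    return pd.DataFrame({"bin_center": centers, "density": mean, "sem": sem})


def correct_occupancy(f_observed: float, c: float,
                      k_r: float | None = None) -> OccupancyEstimate:
    """Apply the missed-trace correction to an observed active fraction."""
    if not 0.0 <= f_observed <= 1.0:
        raise ValueError("observed active fraction must lie in [0, 1]")
    if not 0.0 < c <= 1.0:
        if c > 1.0:
            warnings.warn(f"correction factor c={c:.3f} > 1 retained",
                          stacklevel=2)
        else:
            raise ValueError("correction factor must be positive")
    f_active = c * f_observed
    # f'_I = 1 - c*(1 - f_I) with f_I = 1 - f_A reduces to 1 - c*f_A;
    # computing it as the complement keeps f'_A + f'_I = 1 exact in floats
    f_inactive = 1.0 - f_active
    if f_inactive <= 0.0:
        raise ZeroDivisionError("corrected inactive fraction is zero: "
                                "equilibrium constant diverges")
    k_eq = f_active / f_inactive
    k_f = k_eq * k_r if k_r is not None else None
    return OccupancyEstimate(f_observed, c, f_active, f_inactive, k_eq,
                             k_r, k_f)


def both_closed_probability(p: float) -> float:
    """Probability both clamshells are closed under independent closure."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("per-subunit closure probability must lie in [0, 1]")
    return p * p


def gating_occupancies(equilibrium_constants) -> np.ndarray:
    """State occupancies of a linear gating scheme.

    ``equilibrium_constants[i]`` is the equilibrium constant between adjacent
    states i and i+1; occupancy of state i is proportional to the product of
    the constants leading to it, normalized to sum to 1.
    """
    ks = np.asarray(equilibrium_constants, dtype=float)
    if np.any(ks <= 0) or not np.all(np.isfinite(ks)):
        raise ValueError("all equilibrium constants must be positive and finite")
    raw = np.concatenate(([1.0], np.cumprod(ks)))
    return raw / raw.sum()


def fret_to_distance(e: float, r0: float) -> float:
    """Dye-pair distance from efficiency: R = R₀·((1−E)/E)^(1/6)."""
    if not 0.0 < e < 1.0:
        raise ValueError("E must lie strictly between 0 and 1 (the distance "
                         "diverges or vanishes at the endpoints)")
    if r0 <= 0:
        raise ValueError("Förster radius must be positive")
    return r0 * ((1.0 - e) / e) ** (1.0 / 6.0)


def distance_to_fret(r: float, r0: float) -> float:
    """Efficiency at distance R: E = 1/(1 + (R/R₀)⁶)."""
    if r <= 0 or r0 <= 0:
        raise ValueError("distances must be positive")
    return 1.0 / (1.0 + (r / r0) ** 6)
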
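"""Stochastic simulation of fitted-model uncertainty.

From a converged fit, ensembles of replicate studies are simulated: each
replicate draws population parameters from the estimated sampling
distribution (multivariate normal on the unconstrained scale), species
effects eta ~ N(0, omega^2), and residual errors from the combined
proportional + additive model.  Percentile envelopes summarise the
ensemble: the confidence band brackets the noise-free mean trajectory
(parameter/eta uncertainty only) and the prediction band brackets simulated
observations including residual error.  Prediction-band limits may be
post-processed with a local-polynomial (Savitzky-Golay) smoother.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import InitialCondition, solve
from .nlme import FitResult, PopulationParameters

__all__ = [
    "Ensemble",
    "SimulationEnvelope",
    "simulate_ensemble",
    "envelope",
    "savitzky_golay",
]

_COL = {"apical": 0, "cellular": 1, "basolateral": 2}


@dataclass
class Ensemble:
    """Replicate simulations for one species on a common time grid.

    noise_free    (n, T, 3) trajectories without residual error
    observations  (n, T, 3) trajectories with residual error applied
    """

    times: np.ndarray
    noise_free: np.ndarray
    observations: np.ndarray
    species: str = ""

    @property
    def n(self) -> int:
        return self.noise_free.shape[0]


@dataclass
class SimulationEnvelope:
    """Simulated mean with confidence and prediction bands."""

    times: np.ndarray
    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    pi_lo: np.ndarray
    pi_hi: np.ndarray
    compartment: str = ""
    species: str = ""
    ci_level: float = 0.95
    pi_level: float = 0.68

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for lo, hi in ((self.ci_lo, self.ci_hi), (self.pi_lo, self.pi_hi)):
            if np.any(lo > self.mean + 1e-12) or np.any(hi < self.mean - 1e-12):
                raise ValueError("envelope bounds must bracket the mean")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_min": self.times,
            "mean": self.mean,
            "ci95_lo": self.ci_lo,
            "ci95_hi": self.ci_hi,
            "pi68_lo": self.pi_lo,
            "pi68_hi": self.pi_hi,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def smoothed_pi(self, degree: int = 2, window_fraction: float = 0.75
                    ) -> "SimulationEnvelope":
        """Return a copy with Savitzky-Golay-filtered prediction limits.

        Only the PI bounds are filtered; the mean and confidence band are
        left untouched.
        """
        pi_lo = savitzky_golay(self.pi_lo, degree, window_fraction)
        pi_hi = savitzky_golay(self.pi_hi, degree, window_fraction)
        # smoothing can nudge a bound across the mean at sharp features;
        # restore the bracketing invariant
        pi_lo = np.minimum(pi_lo, self.mean)
        pi_hi = np.maximum(pi_hi, self.mean)
        return SimulationEnvelope(self.times, self.mean, self.ci_lo, self.ci_hi,
                                  pi_lo, pi_hi, self.compartment, self.species,
                                  self.ci_level, self.pi_level)


def _draw_parameters(fit: FitResult, rng: np.random.Generator,
                     parameter_uncertainty: bool) -> PopulationParameters:
    if not parameter_uncertainty:
        return fit.params
    cov = fit.cov_theta
    if not np.all(np.isfinite(cov)):
        return fit.params
    # symmetrise and clip tiny negative eigenvalues from numerical Hessians
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    cov = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    for _ in range(100):
        theta = rng.multivariate_normal(fit.theta, cov, method="cholesky")
        try:
            return fit.transform.to_params(theta)
        except (ValueError, OverflowError):
            continue
    return fit.params


def _draw_eta(params: PopulationParameters, rng: np.random.Generator) -> float:
    """Additive species effect on phi, truncated so phi + eta stays in (0, 1]."""
    if params.omega2 <= 0:
        return 0.0
    sd = math.sqrt(params.omega2)
    for _ in range(1000):
        eta = rng.normal(0.0, sd)
        if 0.0 < params.phi + eta <= 1.0:
            return eta
    return 0.0


def simulate_ensemble(fit: FitResult, times, species: str = "", n: int = 2000,
                      seed: int = 0, parameter_uncertainty: bool = True) -> Ensemble:
    """Simulate ``n`` replicate studies from a fitted model.

    Each replicate draws parameters (optionally) and a species effect, solves
    the kinetics on ``times`` and applies combined residual error, truncating
    observations at zero.  Bitwise reproducible for a fixed seed.
    """
    if n < 2:
        raise ValueError("need n >= 2 replicates")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0) or np.any(t < 0):
        raise ValueError("invalid simulation time grid")
    grid = t if t[0] == 0.0 else np.concatenate(([0.0], t))
    keep = slice(1, None) if t[0] != 0.0 else slice(None)
    rng = np.random.default_rng(seed)
    noise_free = np.empty((n, t.size, 3))
    observations = np.empty((n, t.size, 3))
    for r in range(n):
        params = _draw_parameters(fit, rng, parameter_uncertainty)
        eta = _draw_eta(params, rng)
        traj = solve(params.rates,
                     InitialCondition(available_fraction=params.phi + eta),
                     grid).fractions[keep]
        noise_free[r] = traj
        eps1 = rng.normal(0.0, 1.0, traj.shape) * params.sigma1
        eps2 = rng.normal(0.0, 1.0, traj.shape) * params.sigma2
        observations[r] = np.clip(traj * (1.0 + eps1) + eps2, 0.0, None)
    return Ensemble(times=t, noise_free=noise_free, observations=observations,
                    species=species)


def envelope(ensemble: Ensemble, compartment: str = "basolateral",
             ci_level: float = 0.95, pi_level: float = 0.68) -> SimulationEnvelope:
    """Percentile envelope of an ensemble for one compartment.

    Confidence limits are percentiles of the noise-free replicate
    trajectories; prediction limits are percentiles of the simulated
    observations.  Linear-interpolation empirical quantiles throughout.
    """
    if ensemble.n == 0:
        raise ValueError("empty ensemble")
    col = _COL[compartment]
    clean = ensemble.noise_free[:, :, col]
    noisy = ensemble.observations[:, :, col]
    mean = clean.mean(axis=0)

    def bounds(arr, level):
        a = (1.0 - level) / 2.0
        lo = np.quantile(arr, a, axis=0)
        hi = np.quantile(arr, 1.0 - a, axis=0)
        return lo, hi

    ci_lo, ci_hi = bounds(clean, ci_level)
    pi_lo, pi_hi = bounds(noisy, pi_level)
    # a PI from noisy observations can sit asymmetrically around the
    # noise-free mean; widen minimally so every band brackets the mean
    pi_lo = np.minimum(pi_lo, mean)
    pi_hi = np.maximum(pi_hi, mean)
    ci_lo = np.minimum(ci_lo, mean)
    ci_hi = np.maximum(ci_hi, mean)
    return SimulationEnvelope(ensemble.times, mean, ci_lo, ci_hi, pi_lo, pi_hi,
                              compartment=compartment, species=ensemble.species,
                              ci_level=ci_level, pi_level=pi_level)


def _window_length(n: int, window_fraction: float, degree: int) -> int:
    w = int(round(window_fraction * n))
    if w % 2 == 0:
        w += 1
    w = max(w, 5)
    if w > n:
        w = n if n % 2 == 1 else n - 1
    if w <= degree:
        raise ValueError(
            f"series of length {n} too short for degree-{degree} smoothing")
    return w


def savitzky_golay(series, degree: int = 2, window_fraction: float = 0.75
                   ) -> np.ndarray:
    """Local least-squares polynomial smoothing on an equally spaced series.

    The window length is the given fraction of the series length, rounded to
    the nearest odd integer (at least 5).  Near the boundaries the window
    shrinks symmetrically and the polynomial is refit on the truncated
    window, so the output has the series' length and any global polynomial
    of order <= ``degree`` is reproduced exactly.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be 1-D")
    n = y.size
    w = _window_length(n, window_fraction, degree)
    half = w // 2
    out = np.empty(n)
    for i in range(n):
        r = min(half, i, n - 1 - i)
        idx = np.arange(i - r, i + r + 1)
        if idx.size <= degree:
            # too few symmetric neighbours for the requested order; the
            # interpolating fit returns the point itself
            out[i] = y[i]
            continue
        x = (idx - i).astype(float)
        # normal equations of the local polynomial fit; the smoothed value
        # is the fitted constant term at the window centre
        V = np.vander(x, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V, y[idx], rcond=None)
        out[i] = coef[0]
    return out
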
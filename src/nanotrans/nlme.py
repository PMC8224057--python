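"""Non-linear mixed-effects estimation of the translocation model.

Observed fractions Y_ij of nanoparticle species i in the apical or
basolateral compartment are modelled as

    Y_ij = A_ij * (1 + eps1_ij) + eps2_ij,      eps_k ~ N(0, sigma_k^2)

where A_ij is the model-predicted fraction from the three-compartment
kinetics with species-level initial available fraction

    Aa_i(t0) = phi + eta_i,                     eta_i ~ N(0, omega^2).

The marginal likelihood integrates the species-level random effects out;
here that integral is approximated by a Laplace expansion about each
species' conditional mode, with the residual variance evaluated at the
conditional prediction (the interaction term of FOCE-I).  Optional
log-normal between-species effects on the transfer constants are supported
through :class:`ModelSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.special import log_ndtr

from .kinetics import (InitialCondition, KineticRates, solve, _decompose,
                       _propagate, _propagate_decomposed)

__all__ = [
    "PopulationParameters",
    "ModelSpec",
    "TranslocationDataset",
    "FitResult",
    "marginal_objective",
    "fit",
    "empirical_bayes",
    "eta_shrinkage",
    "species_anova",
    "anova_by_time",
]

# Penalised objective value used when a parameter vector is unphysical or a
# species-level curvature is not positive definite.
_PENALTY = 1e10

# Random-effect variances below this are reported as collapsed (the data do
# not support between-species variability).
OMEGA2_COLLAPSE = 1e-6

RATE_NAMES = ("k12", "k21", "k23", "k32")
_COMPARTMENT_COLUMN = {"apical": 0, "basolateral": 2}


@dataclass(frozen=True)
class PopulationParameters:
    """Population-level parameters of the mixed-effects translocation model.

    phi       population mean available fraction, in (0, 1)
    omega2    variance of the additive between-species effect on phi
    rates     population transfer constants (1/min)
    sigma1    proportional residual SD (dimensionless)
    sigma2    additive residual SD (fraction units)
    rate_omega2  optional log-normal between-species variances per rate
    """

    phi: float
    rates: KineticRates
    sigma1: float
    sigma2: float
    omega2: float = 0.0
    rate_omega2: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.phi < 1.0):
            raise ValueError(f"phi must be in (0, 1), got {self.phi}")
        if self.omega2 < 0:
            raise ValueError("omega2 must be >= 0")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("residual SDs must be >= 0")
        if self.sigma1 == 0 and self.sigma2 == 0:
            raise ValueError("sigma1 and sigma2 cannot both be zero")
        for name, w2 in self.rate_omega2.items():
            if name not in RATE_NAMES:
                raise ValueError(f"unknown rate name {name!r}")
            if w2 < 0:
                raise ValueError("rate omega2 values must be >= 0")

    def as_dict(self) -> dict[str, float]:
        d = {"phi": self.phi, "omega2": self.omega2, **self.rates.as_dict()}
        d["sigma1"] = self.sigma1
        d["sigma2"] = self.sigma2
        for name, w2 in self.rate_omega2.items():
            d[f"omega2_{name}"] = w2
        return d


@dataclass(frozen=True)
class ModelSpec:
    """Which between-species random effects are active."""

    eta_phi: bool = True
    eta_rates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in self.eta_rates:
            if name not in RATE_NAMES:
                raise ValueError(f"unknown rate name {name!r}")

    @property
    def n_eta(self) -> int:
        return int(self.eta_phi) + len(self.eta_rates)


class TranslocationDataset:
    """Longitudinal observed fractions, one row per observation.

    Columns: species, replicate, time_min, compartment (apical/basolateral),
    fraction (0-1 scale).
    """

    REQUIRED = ("species", "replicate", "time_min", "compartment", "fraction")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if len(frame) == 0:
            raise ValueError("dataset is empty")
        bad = set(frame["compartment"]) - set(_COMPARTMENT_COLUMN)
        if bad:
            raise ValueError(f"unknown compartment labels: {sorted(bad)}")
        if not np.all(np.isfinite(frame["fraction"])):
            raise ValueError("fractions must be finite")
        if np.any(frame["time_min"].to_numpy() < 0):
            raise ValueError("times must be non-negative")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def species(self) -> list:
        return sorted(self.frame["species"].unique().tolist())

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.frame["time_min"].unique())

    def subset(self, species) -> "TranslocationDataset":
        return TranslocationDataset(self.frame[self.frame["species"] == species])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "TranslocationDataset":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# internal per-species layout for fast repeated likelihood evaluation


class _SpeciesData:
    __slots__ = ("name", "y", "time_idx", "col_idx", "grid", "n")

    def __init__(self, name, sub: pd.DataFrame):
        self.name = name
        self.y = sub["fraction"].to_numpy(dtype=float)
        obs_times = sub["time_min"].to_numpy(dtype=float)
        unique = np.unique(obs_times)
        # solve() needs the application time t0 = 0 on the grid
        self.grid = np.concatenate(([0.0], unique)) if unique[0] > 0 else unique
        offset = 1 if unique[0] > 0 else 0
        self.time_idx = np.searchsorted(unique, obs_times) + offset
        self.col_idx = sub["compartment"].map(_COMPARTMENT_COLUMN).to_numpy()
        self.n = self.y.size


def _split(data: TranslocationDataset) -> list[_SpeciesData]:
    return [
        _SpeciesData(name, sub) for name, sub in data.frame.groupby("species", sort=True)
    ]


def _predict(params: PopulationParameters, spec: ModelSpec, eta: np.ndarray,
             sd: _SpeciesData) -> np.ndarray | None:
    """Predicted fractions for one species at its observations, or None if
    the perturbed parameters are unphysical."""
    k = 0
    phi = params.phi
    if spec.eta_phi:
        phi = params.phi + eta[0]
        k = 1
    if not (0.0 < phi <= 1.0):
        return None
    rates = params.rates
    if spec.eta_rates:
        vals = rates.as_dict()
        for j, name in enumerate(spec.eta_rates):
            vals[name] = vals[name] * math.exp(eta[k + j])
        rates = KineticRates(**vals)
    traj = solve(rates, InitialCondition(available_fraction=phi), sd.grid)
    return traj.fractions[sd.time_idx, sd.col_idx]


def _residual_neg2ll(y: np.ndarray, pred: np.ndarray, sigma1: float,
                     sigma2: float) -> float:
    """-2 log residual likelihood with combined error variance.

    Zero observations are treated as left-censored (fractions cannot be
    negative; below-detection results are reported as zero)."""
    var = sigma1 * sigma1 * pred * pred + sigma2 * sigma2
    if np.any(var <= 0):
        return _PENALTY
    cens = y <= 0.0
    r = y[~cens] - pred[~cens]
    vu = var[~cens]
    total = float(np.sum(np.log(2.0 * math.pi * vu) + r * r / vu))
    if cens.any():
        z = -pred[cens] / np.sqrt(var[cens])
        total += float(-2.0 * log_ndtr(z).sum())
    return total


def _omega_vector(params: PopulationParameters, spec: ModelSpec) -> np.ndarray:
    w2 = []
    if spec.eta_phi:
        w2.append(params.omega2)
    for name in spec.eta_rates:
        w2.append(params.rate_omega2.get(name, 0.0))
    return np.asarray(w2)


def _inner_objective(eta, params, spec, sd, omega2):
    """g(eta) = -log p(y | eta) - log p(eta) (up to no constant dropped)."""
    pred = _predict(params, spec, np.atleast_1d(eta), sd)
    if pred is None:
        return _PENALTY
    val = 0.5 * _residual_neg2ll(sd.y, pred, params.sigma1, params.sigma2)
    eta = np.atleast_1d(eta)
    val += 0.5 * float(np.sum(np.log(2.0 * math.pi * omega2) + eta * eta / omega2))
    return val


def _conditional_mode(params, spec, sd, omega2) -> np.ndarray:
    d = omega2.size
    x0 = np.zeros(d)
    res = optimize.minimize(
        _inner_objective, x0, args=(params, spec, sd, omega2),
        method="BFGS", options={"gtol": 1e-10, "maxiter": 200},
    )
    # Nelder-Mead rescue for the rare rough case
    if not res.success and res.fun >= _PENALTY / 2:
        res = optimize.minimize(
            _inner_objective, x0, args=(params, spec, sd, omega2),
            method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-12},
        )
    return np.atleast_1d(res.x)


def _hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    d = x.size
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h
        for j in range(i, d):
            ej = np.zeros(d); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h * h)
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4.0 * h * h)
    return H


def _species_neg2ll_laplace(params, spec, sd, omega2) -> float:
    eta_hat = _conditional_mode(params, spec, sd, omega2)
    g = lambda e: _inner_objective(e, params, spec, sd, omega2)
    g_hat = g(eta_hat)
    if g_hat >= _PENALTY / 2:
        return _PENALTY
    H = _hessian(g, eta_hat)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return _PENALTY
    d = eta_hat.size
    return 2.0 * g_hat - d * math.log(2.0 * math.pi) + logdet


# -- fast path: random effect on phi only ------------------------------------
#
# The kinetic system is linear in its initial state and the initial state is
# (phi + eta, 0, 0), so every prediction factors as (phi + eta) * base(t)
# with base the propagator response to a unit apical fraction.  The inner
# problem then needs no ODE solves at all.


def _base_predictions(rates: KineticRates, split: list[_SpeciesData]) -> list[np.ndarray]:
    """Unit-initial-fraction predictions at each species' observations.

    The rate matrix is shared by all species, so it is decomposed once."""
    out = []
    matrix = rates.matrix()
    decomp = _decompose(matrix)
    e1 = np.array([1.0, 0.0, 0.0])
    for sd in split:
        dts = sd.grid - sd.grid[0]
        if decomp is None:
            fractions = _propagate(matrix, e1, dts)
        else:
            fractions = _propagate_decomposed(decomp, e1, dts)
        out.append(fractions[sd.time_idx, sd.col_idx])
    return out


_LOG_2PI = math.log(2.0 * math.pi)


def _fixed_neg2ll_phi(phi, base, y, sigma1, sigma2) -> float:
    """-2LL of one species' data given available fraction phi.

    Observed fractions cannot be negative (concentrations below the
    detection limit are reported as zero), so zero observations enter as
    left-censored Gaussian terms and the rest as ordinary Gaussian
    densities with the combined error variance.
    """
    pred = phi * base
    var = sigma1 * sigma1 * pred * pred + sigma2 * sigma2
    if var.min() <= 0:
        return _PENALTY
    cens = y <= 0.0
    if not cens.any():
        r = y - pred
        return float(np.log(var).sum() + (r * r / var).sum() + y.size * _LOG_2PI)
    u = ~cens
    r = y[u] - pred[u]
    vu = var[u]
    total = float(np.log(vu).sum() + (r * r / vu).sum() + r.size * _LOG_2PI)
    z = -pred[cens] / np.sqrt(var[cens])
    total += float(-2.0 * log_ndtr(z).sum())
    return total


def _mode_phi_newton(phi: float, omega2: float, s1sq: float, s2sq: float,
                     base: np.ndarray, b2: np.ndarray, y: np.ndarray
                     ) -> float | None:
    """Conditional mode of f = phi + eta via safeguarded Newton on dg/df.

    Returns None when the iteration fails to converge inside (0, 1]."""
    lo, hi = 1e-9, 1.0
    cens = y <= 0.0
    bu, b2u, yu = base[~cens], b2[~cens], y[~cens]
    bc, b2c = base[cens], b2[cens]

    def gp(f: float) -> float:
        v = (s1sq * f * f) * b2u + s2sq
        vp = (2.0 * s1sq * f) * b2u
        r = yu - f * bu
        val = 0.5 * ((vp / v).sum() - 2.0 * (bu * r / v).sum()
                     - (r * r * vp / (v * v)).sum())
        if bc.size:
            vc = (s1sq * f * f) * b2c + s2sq
            vpc = (2.0 * s1sq * f) * b2c
            sq = np.sqrt(vc)
            z = -f * bc / sq
            dz = -bc / sq + f * bc * vpc / (2.0 * vc * sq)
            ratio = np.exp(-0.5 * z * z - 0.5 * _LOG_2PI - log_ndtr(z))
            val -= (ratio * dz).sum()
        return val + (f - phi) / omega2

    f = min(max(phi, lo), hi)
    d = gp(f)
    h = 1e-7
    curv = (gp(f + h) - d) / h  # numeric slope to seed the secant iteration
    for _ in range(40):
        if curv <= 0:
            return None
        step = d / curv
        f_new = min(max(f - step, lo), hi)
        d_new = gp(f_new)
        if abs(f_new - f) < 1e-10:
            return f_new
        if f_new != f:
            curv = (d_new - d) / (f_new - f)
        f, d = f_new, d_new
    return None


def _species_neg2ll_laplace_phi(params: PopulationParameters, sd: _SpeciesData,
                                base: np.ndarray) -> float:
    phi, omega2 = params.phi, params.omega2
    s1, s2 = params.sigma1, params.sigma2
    log_prior_const = math.log(2.0 * math.pi * omega2)
    b2 = base * base
    s1sq, s2sq = s1 * s1, s2 * s2
    y = sd.y

    def g(eta: float) -> float:
        f = phi + eta
        if not (0.0 < f <= 1.0):
            return _PENALTY
        return 0.5 * _fixed_neg2ll_phi(f, base, y, s1, s2) \
            + 0.5 * (log_prior_const + eta * eta / omega2)

    lo, hi = -phi + 1e-9, 1.0 - phi
    f_hat = _mode_phi_newton(phi, omega2, s1sq, s2sq, base, b2, y)
    if f_hat is not None:
        eta_hat = f_hat - phi
        g_hat = g(eta_hat)
    else:
        res = optimize.minimize_scalar(g, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-9})
        eta_hat, g_hat = float(res.x), float(res.fun)
    if g_hat >= _PENALTY / 2:
        return _PENALTY
    h = 1e-6
    if eta_hat - h < lo or eta_hat + h > hi:
        h = 0.25 * min(eta_hat - lo, hi - eta_hat)
        if h <= 0:
            return _PENALTY
    curv = (g(eta_hat + h) - 2.0 * g_hat + g(eta_hat - h)) / (h * h)
    if curv <= 0:
        return _PENALTY
    return 2.0 * g_hat - math.log(2.0 * math.pi) + math.log(curv)


def _conditional_mode_phi(params: PopulationParameters, sd: _SpeciesData,
                          base: np.ndarray) -> float:
    phi, omega2 = params.phi, params.omega2
    s1, s2 = params.sigma1, params.sigma2
    f_hat = _mode_phi_newton(phi, omega2, s1 * s1, s2 * s2,
                             base, base * base, sd.y)
    if f_hat is not None:
        return f_hat - phi

    def g(eta: float) -> float:
        f = phi + eta
        if not (0.0 < f <= 1.0):
            return _PENALTY
        return 0.5 * _fixed_neg2ll_phi(f, base, sd.y, s1, s2) \
            + 0.5 * eta * eta / omega2

    res = optimize.minimize_scalar(g, bounds=(-phi + 1e-9, 1.0 - phi),
                                   method="bounded", options={"xatol": 1e-11})
    return float(res.x)


def marginal_objective(params: PopulationParameters, data: TranslocationDataset,
                       spec: ModelSpec | None = None) -> float:
    """-2 log marginal likelihood of the population parameters.

    Species with active random effects contribute a Laplace-approximated
    integral about their conditional mode; with all random-effect variances
    at zero the objective reduces exactly to the fixed-effects weighted
    least-squares -2 log-likelihood under the combined error model.
    """
    if spec is None:
        spec = ModelSpec(eta_phi=params.omega2 > 0,
                         eta_rates=tuple(n for n, w in params.rate_omega2.items() if w > 0))
    omega2 = _omega_vector(params, spec)
    split = _split(data)
    return _objective_on_split(params, spec, omega2, split)


def _objective_on_split(params: PopulationParameters, spec: ModelSpec,
                        omega2: np.ndarray, split: list[_SpeciesData]) -> float:
    active = omega2 > 0
    total = 0.0
    if spec.n_eta == 0 or not np.any(active):
        try:
            bases = _base_predictions(params.rates, split)
        except ValueError:
            return _PENALTY
        for sd, base in zip(split, bases):
            total += _fixed_neg2ll_phi(params.phi, base, sd.y,
                                       params.sigma1, params.sigma2)
        return total
    eff_spec, eff_omega2 = _effective(spec, omega2)
    if eff_spec.eta_rates == () and eff_spec.eta_phi:
        try:
            bases = _base_predictions(params.rates, split)
        except ValueError:
            return _PENALTY
        for sd, base in zip(split, bases):
            total += _species_neg2ll_laplace_phi(params, sd, base)
        return total
    for sd in split:
        total += _species_neg2ll_laplace(params, eff_spec, sd, eff_omega2)
    return total


def _effective(spec: ModelSpec, omega2: np.ndarray) -> tuple[ModelSpec, np.ndarray]:
    """Drop random effects whose variance is exactly zero."""
    keep_phi = spec.eta_phi and omega2[0] > 0 if spec.eta_phi else False
    names = []
    vals = []
    k = 1 if spec.eta_phi else 0
    if keep_phi:
        vals.append(omega2[0])
    for j, name in enumerate(spec.eta_rates):
        if omega2[k + j] > 0:
            names.append(name)
            vals.append(omega2[k + j])
    return ModelSpec(eta_phi=keep_phi, eta_rates=tuple(names)), np.asarray(vals)


def marginal_objective_quadrature(params: PopulationParameters,
                                  data: TranslocationDataset,
                                  n_nodes: int = 41) -> float:
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    Numerically exact (for practical purposes) alternative to the Laplace
    approximation, available for the single random effect on phi.  The
    nodes are centred on each species' conditional mode and scaled by the
    local curvature.  Intended for validation: the production objective is
    :func:`marginal_objective`.
    """
    if params.rate_omega2:
        raise NotImplementedError("quadrature supports the phi effect only")
    if params.omega2 <= 0:
        raise ValueError("quadrature needs omega2 > 0")
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    omega2 = params.omega2
    log_prior_const = math.log(2.0 * math.pi * omega2)
    total = 0.0
    split = _split(data)
    bases = _base_predictions(params.rates, split)
    for sd, base in zip(split, bases):

        def g(eta: float) -> float:
            f = params.phi + eta
            if not (0.0 < f <= 1.0):
                return _PENALTY
            return 0.5 * _fixed_neg2ll_phi(f, base, sd.y, params.sigma1,
                                           params.sigma2) \
                + 0.5 * (log_prior_const + eta * eta / omega2)

        res = optimize.minimize_scalar(g, bounds=(-params.phi + 1e-9,
                                                  1.0 - params.phi),
                                       method="bounded",
                                       options={"xatol": 1e-11})
        mode, g_mode = float(res.x), float(res.fun)
        h = 1e-6
        curv = (g(mode + h) - 2.0 * g_mode + g(mode - h)) / (h * h)
        scale = 1.0 / math.sqrt(curv) if curv > 0 else math.sqrt(omega2)
        # integral of exp(-g) via substitution eta = mode + sqrt(2)*s*x
        log_terms = np.array([
            -g(mode + math.sqrt(2.0) * scale * x) + x * x + math.log(w)
            for x, w in zip(nodes, weights)
        ])
        m = log_terms.max()
        log_integral = m + math.log(np.exp(log_terms - m).sum()) \
            + 0.5 * math.log(2.0) + math.log(scale)
        total += -2.0 * log_integral
    return total


def empirical_bayes(params: PopulationParameters, data: TranslocationDataset,
                    species) -> np.ndarray:
    """Conditional mode of the random effects for one species (EBE).

    A species absent from the data has no information and returns the prior
    mode, zero.  Undefined when every random-effect variance is zero.
    """
    spec = ModelSpec(eta_phi=params.omega2 > 0,
                     eta_rates=tuple(n for n, w in params.rate_omega2.items() if w > 0))
    if spec.n_eta == 0:
        raise ValueError("EBEs are undefined when all omega2 are zero")
    omega2 = _omega_vector(params, spec)
    if species not in set(data.frame["species"]):
        return np.zeros(spec.n_eta)
    sd = _SpeciesData(species, data.frame[data.frame["species"] == species])
    if spec.eta_rates == () and spec.eta_phi:
        base = _base_predictions(params.rates, [sd])[0]
        return np.array([_conditional_mode_phi(params, sd, base)])
    return _conditional_mode(params, spec, sd, omega2)


def eta_shrinkage(ebes: Sequence[float], omega: float) -> float:
    """1 - SD(eta_hat)/omega, clipped to [0, 1] (sample SD, n-1 denominator).

    Values near 1 mean the individual estimates have collapsed onto the
    population mean: the data carry little species-level information.
    """
    ebes = np.asarray(ebes, dtype=float)
    if omega <= 0:
        raise ValueError("shrinkage undefined for omega <= 0")
    if ebes.size < 2:
        raise ValueError("need at least 2 EBEs")
    return float(np.clip(1.0 - ebes.std(ddof=1) / omega, 0.0, 1.0))


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


def _logit(p):
    return math.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + math.exp(-x))


class _Transform:
    """Bijection between PopulationParameters and an unconstrained vector."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.names = ["phi"] + list(RATE_NAMES) + ["sigma1", "sigma2"]
        if spec.eta_phi:
            self.names.append("omega")
        for name in spec.eta_rates:
            self.names.append(f"omega_{name}")

    def to_vector(self, p: PopulationParameters) -> np.ndarray:
        v = [_logit(p.phi)]
        v += [math.log(max(getattr(p.rates, n), 1e-12)) for n in RATE_NAMES]
        v += [math.log(max(p.sigma1, 1e-12)), math.log(max(p.sigma2, 1e-12))]
        if self.spec.eta_phi:
            v.append(0.5 * math.log(max(p.omega2, 1e-12)))
        for name in self.spec.eta_rates:
            v.append(0.5 * math.log(max(p.rate_omega2.get(name, 1e-8), 1e-12)))
        return np.array(v)

    def to_params(self, v: np.ndarray) -> PopulationParameters:
        phi = _expit(v[0])
        rates = KineticRates(**{n: math.exp(v[1 + i]) for i, n in enumerate(RATE_NAMES)})
        sigma1 = math.exp(v[5])
        sigma2 = math.exp(v[6])
        k = 7
        omega2 = 0.0
        if self.spec.eta_phi:
            omega2 = math.exp(2.0 * v[k]); k += 1
        rate_omega2 = {}
        for name in self.spec.eta_rates:
            rate_omega2[name] = math.exp(2.0 * v[k]); k += 1
        return PopulationParameters(phi=phi, rates=rates, sigma1=sigma1,
                                    sigma2=sigma2, omega2=omega2,
                                    rate_omega2=rate_omega2)


@dataclass
class FitResult:
    """Maximum-likelihood fit of the mixed-effects translocation model."""

    params: PopulationParameters
    se: dict[str, float]
    neg2ll: float
    ebes: dict
    shrinkage: float
    converged: bool
    collapsed: bool
    n_obs: int
    spec: ModelSpec
    theta: np.ndarray
    cov_theta: np.ndarray
    transform: _Transform
    delta_ofv: float = float("nan")

    def summary_frame(self) -> pd.DataFrame:
        est = self.params.as_dict()
        rows = []
        for name, value in est.items():
            rows.append({"parameter": name, "estimate": value,
                         "se": self.se.get(name, float("nan"))})
        return pd.DataFrame(rows)

    def to_yaml(self, path=None):
        doc = {
            "estimates": {k: float(v) for k, v in self.params.as_dict().items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "neg2ll": float(self.neg2ll),
            "eta_shrinkage": None if math.isnan(self.shrinkage) else float(self.shrinkage),
            "converged": bool(self.converged),
            "random_effect_collapsed": bool(self.collapsed),
            "n_obs": int(self.n_obs),
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _default_start(data: TranslocationDataset) -> PopulationParameters:
    apical = data.frame[data.frame["compartment"] == "apical"]
    if len(apical):
        t_min = apical["time_min"].min()
        phi0 = float(np.clip(apical[apical["time_min"] == t_min]["fraction"].mean(),
                             0.05, 0.95))
    else:
        phi0 = 0.5
    return PopulationParameters(
        phi=phi0, rates=KineticRates(0.005, 0.005, 0.005, 0.005),
        sigma1=0.1, sigma2=0.02, omega2=0.01,
    )


def fit(data: TranslocationDataset, spec: ModelSpec | None = None,
        start: PopulationParameters | None = None, n_starts: int = 5,
        seed: int = 0, maxiter: int = 2000, collapse_lrt: bool = True) -> FitResult:
    """Fit the population model by maximising the marginal likelihood.

    Derivative-free simplex exploration from ``n_starts`` jittered starting
    points, followed by a quasi-Newton polish of the best candidate.  The
    between-species effect is reported as collapsed when its variance
    estimate falls below ``OMEGA2_COLLAPSE`` or (with ``collapse_lrt``)
    when it fails a likelihood-ratio comparison against the fixed-effects
    model.
    """
    if spec is None:
        spec = ModelSpec(eta_phi=True)
    if data.times.size < 2:
        raise ValueError("need at least 2 distinct observation times")
    if start is None:
        start = _default_start(data)
    tr = _Transform(spec)
    split = _split(data)

    def objective(v: np.ndarray) -> float:
        if np.any(np.abs(v) > 50):
            return _PENALTY
        try:
            params = tr.to_params(v)
        except (ValueError, OverflowError):
            return _PENALTY
        omega2 = _omega_vector(params, spec)
        return _objective_on_split(params, spec, omega2, split)

    rng = np.random.default_rng(seed)
    v0 = tr.to_vector(start)
    best = None
    for s in range(max(n_starts, 1)):
        v_init = v0 if s == 0 else v0 + rng.normal(0.0, 0.5, size=v0.size)
        res = optimize.minimize(objective, v_init, method="Nelder-Mead",
                                options={"maxiter": maxiter, "xatol": 1e-5,
                                         "fatol": 1e-7, "adaptive": True})
        if best is None or res.fun < best.fun:
            best = res
    polish = optimize.minimize(objective, best.x, method="L-BFGS-B",
                               options={"maxiter": 500})
    if polish.fun <= best.fun:
        best = polish
    converged = bool(best.fun < _PENALTY / 2)

    params = tr.to_params(best.x)
    # Collapse decision: the random effect is dropped either when its
    # variance estimate is numerically zero or when it fails a boundary
    # likelihood-ratio test against the fixed-effects model (dOFV < 3.84,
    # the 5% chi-square(1) criterion used in pharmacometric model building).
    delta_ofv = float("nan")
    collapsed = spec.eta_phi and params.omega2 < OMEGA2_COLLAPSE
    if spec.eta_phi and collapse_lrt and converged and not collapsed:
        fe_spec = ModelSpec(eta_phi=False, eta_rates=spec.eta_rates)
        fe_tr = _Transform(fe_spec)
        fe_omega2 = _omega_vector(params, fe_spec)

        def fe_objective(v: np.ndarray) -> float:
            if np.any(np.abs(v) > 50):
                return _PENALTY
            try:
                fe_params = fe_tr.to_params(v)
            except (ValueError, OverflowError):
                return _PENALTY
            return _objective_on_split(fe_params, fe_spec, fe_omega2, split)

        fe_start = best.x[: 7]
        fe_res = optimize.minimize(fe_objective, fe_start, method="Nelder-Mead",
                                   options={"maxiter": 800, "xatol": 1e-5,
                                            "fatol": 1e-7, "adaptive": True})
        delta_ofv = float(fe_res.fun - best.fun)
        if delta_ofv < 3.84:
            collapsed = True

    # standard errors from the curvature of -2LL on the transformed scale
    se: dict[str, float] = {}
    cov = np.full((best.x.size, best.x.size), np.nan)
    try:
        H = _hessian(objective, best.x, h=1e-4)
        cov = 2.0 * np.linalg.inv(H)
        d = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        phi = params.phi
        se["phi"] = d[0] * phi * (1.0 - phi)
        for i, name in enumerate(RATE_NAMES):
            se[name] = d[1 + i] * getattr(params.rates, name)
        se["sigma1"] = d[5] * params.sigma1
        se["sigma2"] = d[6] * params.sigma2
        k = 7
        if spec.eta_phi:
            se["omega2"] = d[k] * 2.0 * params.omega2
            k += 1
        for name in spec.eta_rates:
            se[f"omega2_{name}"] = d[k] * 2.0 * params.rate_omega2.get(name, 0.0)
            k += 1
    except np.linalg.LinAlgError:
        pass

    ebes: dict = {}
    shrink = float("nan")
    if spec.eta_phi and not collapsed and params.omega2 > 0:
        omega2 = _omega_vector(params, spec)
        if spec.eta_rates == ():
            bases = _base_predictions(params.rates, split)
            for sd, base in zip(split, bases):
                ebes[sd.name] = np.array(
                    [_conditional_mode_phi(params, sd, base)])
        else:
            for sd in split:
                ebes[sd.name] = _conditional_mode(params, spec, sd, omega2)
        phis = [e[0] for e in ebes.values()]
        if len(phis) >= 2:
            shrink = eta_shrinkage(phis, math.sqrt(params.omega2))

    return FitResult(params=params, se=se, neg2ll=float(best.fun), ebes=ebes,
                     shrinkage=shrink, converged=converged, collapsed=collapsed,
                     n_obs=len(data), spec=spec, theta=best.x, cov_theta=cov,
                     transform=tr, delta_ofv=delta_ofv)


# ---------------------------------------------------------------------------
# per-time-point species comparison


def species_anova(data: TranslocationDataset, time: float, compartment: str) -> float:
    """One-way ANOVA p-value for species differences at one time/compartment.

    Degenerate inputs with zero within-group variance but unequal means give
    p = 0; identical constant groups give p = 1.
    """
    sub = data.frame[(data.frame["time_min"] == time)
                     & (data.frame["compartment"] == compartment)]
    groups = [g["fraction"].to_numpy() for _, g in sub.groupby("species")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 species with >= 2 replicates each")
    if all(np.ptp(g) == 0 for g in groups):
        means = [g[0] for g in groups]
        return 1.0 if np.ptp(means) == 0 else 0.0
    stat, p = stats.f_oneway(*groups)
    return float(p)


def anova_by_time(data: TranslocationDataset, compartment: str,
                  adjust: str = "holm") -> pd.DataFrame:
    """Per-time-point one-way species ANOVA with multiplicity adjustment."""
    from statsmodels.stats.multitest import multipletests

    rows = []
    for t in data.times:
        rows.append({"time_min": t, "compartment": compartment,
                     "p_value": species_anova(data, t, compartment)})
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adjusted"] = multipletests(out["p_value"], method=adjust)[1]
    out["significant"] = out.get("p_adjusted", out["p_value"]) < 0.05
    return out
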
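"""Three-compartment translocation kinetics.

An apically applied nanoparticle dose distributes over three compartments of
a Transwell barrier system — apical medium, a lumped cellular compartment
(cells plus the intermediate filter membrane) and basolateral medium — with
first-order exchange between neighbours:

    dAa/dt = -k12*Aa + k21*Ac
    dAc/dt =  k12*Aa - (k21 + k23)*Ac + k32*Ab
    dAb/dt =  k23*Ac - k32*Ab

Aa, Ac, Ab are fractions of the applied particle number (0-1 scale) and the
four transfer constants are in 1/min.  The system is linear and closed, so
the total fraction is conserved along every trajectory and the solution is
a matrix exponential applied to the initial state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticRates",
    "CompartmentState",
    "InitialCondition",
    "Trajectory",
    "derivative",
    "solve",
    "steady_state",
]

COMPARTMENTS = ("apical", "cellular", "basolateral")


class NoFiniteSteadyStateError(ValueError):
    """Raised when a reverse rate is zero and detailed balance is undefined."""


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class KineticRates:
    """First-order transfer rate constants (1/min), all non-negative."""

    k12: float
    k21: float
    k23: float
    k32: float

    def __post_init__(self) -> None:
        _require_finite("rate", self.k12, self.k21, self.k23, self.k32)
        if min(self.k12, self.k21, self.k23, self.k32) < 0:
            raise ValueError(f"rates must be non-negative: {self}")

    def matrix(self) -> np.ndarray:
        """Rate matrix M with d(Aa,Ac,Ab)/dt = M @ (Aa,Ac,Ab)."""
        k12, k21, k23, k32 = self.k12, self.k21, self.k23, self.k32
        return np.array(
            [
                [-k12, k21, 0.0],
                [k12, -(k21 + k23), k32],
                [0.0, k23, -k32],
            ]
        )

    def as_dict(self) -> dict[str, float]:
        return {"k12": self.k12, "k21": self.k21, "k23": self.k23, "k32": self.k32}


@dataclass(frozen=True)
class CompartmentState:
    """Fractions of applied particles in each compartment at time t (min)."""

    Aa: float
    Ac: float
    Ab: float
    t: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("state", self.Aa, self.Ac, self.Ab, self.t)

    @property
    def total(self) -> float:
        return self.Aa + self.Ac + self.Ab

    def as_array(self) -> np.ndarray:
        return np.array([self.Aa, self.Ac, self.Ab])


@dataclass(frozen=True)
class InitialCondition:
    """Initial state: the available fraction sits apically at t0.

    ``available_fraction`` is Aa(t0), the fraction of the applied dose that
    is free to translocate (particles lost to e.g. surface adhesion never
    enter the kinetics).  Cellular and basolateral compartments start empty
    unless stated otherwise.
    """

    available_fraction: float
    cellular: float = 0.0
    basolateral: float = 0.0

    def __post_init__(self) -> None:
        _require_finite(
            "initial fraction", self.available_fraction, self.cellular, self.basolateral
        )
        if not (0.0 < self.available_fraction <= 1.0):
            raise ValueError(
                f"available_fraction must be in (0, 1], got {self.available_fraction}"
            )
        if self.cellular < 0 or self.basolateral < 0:
            raise ValueError("initial cellular/basolateral fractions must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.available_fraction, self.cellular, self.basolateral])


class Trajectory(Sequence):
    """Solution of the kinetic system on a time grid.

    Behaves as a sequence of :class:`CompartmentState` and exposes the raw
    ``times`` (n,) and ``fractions`` (n, 3) arrays for vectorised use.
    """

    def __init__(self, times: np.ndarray, fractions: np.ndarray):
        self.times = np.asarray(times, dtype=float)
        self.fractions = np.asarray(fractions, dtype=float)
        if self.fractions.shape != (self.times.size, 3):
            raise ValueError("fractions must have shape (len(times), 3)")

    def __len__(self) -> int:
        return self.times.size

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.times[i], self.fractions[i])
        Aa, Ac, Ab = self.fractions[i]
        return CompartmentState(Aa=Aa, Ac=Ac, Ab=Ab, t=self.times[i])

    def __iter__(self) -> Iterator[CompartmentState]:
        for i in range(len(self)):
            yield self[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "A_apical": self.fractions[:, 0],
                "A_cellular": self.fractions[:, 1],
                "A_basolateral": self.fractions[:, 2],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Trajectory":
        cols = ["A_apical", "A_cellular", "A_basolateral"]
        return cls(frame["time_min"].to_numpy(), frame[cols].to_numpy())

    @classmethod
    def read_csv(cls, path) -> "Trajectory":
        return cls.from_frame(pd.read_csv(path))


def derivative(state: CompartmentState, rates: KineticRates) -> tuple[float, float, float]:
    """Instantaneous rate of change (dAa/dt, dAc/dt, dAb/dt) in 1/min.

    The three components sum to zero: the system is closed.
    """
    dAa, dAc, dAb = rates.matrix() @ state.as_array()
    return (float(dAa), float(dAc), float(dAb))


def _decompose(matrix: np.ndarray):
    """Eigendecomposition of the rate matrix, or None when near-degenerate.

    Near-degenerate eigenvalues make the eigenbasis ill-conditioned; callers
    fall back to per-time matrix exponentials in that regime.
    """
    eigvals, eigvecs = np.linalg.eig(matrix)
    scale = max(np.max(np.abs(eigvals)), 1.0)
    gaps = np.abs(eigvals[:, None] - eigvals[None, :])
    np.fill_diagonal(gaps, np.inf)
    if np.min(gaps) / scale < 1e-9:
        return None
    return eigvals, eigvecs


def _propagate_decomposed(decomp, x0: np.ndarray, dts: np.ndarray) -> np.ndarray:
    eigvals, eigvecs = decomp
    coeff = np.linalg.solve(eigvecs, x0)
    return np.real(
        (eigvecs[None, :, :] * np.exp(np.outer(dts, eigvals))[:, None, :]) @ coeff
    )


def _propagate(matrix: np.ndarray, x0: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """exp(M*dt) @ x0 for each dt, via eigendecomposition with a robust fallback."""
    decomp = _decompose(matrix)
    if decomp is None:
        from scipy.linalg import expm

        return np.stack([expm(matrix * dt) @ x0 for dt in dts])
    return _propagate_decomposed(decomp, x0, dts)


def solve(rates: KineticRates, init: InitialCondition, times) -> Trajectory:
    """Closed-form solution of the linear kinetic system on a time grid.

    ``times`` must be non-negative and strictly increasing; the first grid
    point is taken as t0, where the state equals ``init`` exactly.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    x0 = init.as_array()
    dts = t - t[0]
    fractions = _propagate(rates.matrix(), x0, dts)
    fractions[dts == 0.0] = x0  # exact identity at the start of the grid
    return Trajectory(t, fractions)


def steady_state(rates: KineticRates, total: float = 1.0) -> CompartmentState:
    """Long-time limit of the closed system.

    The chain satisfies detailed balance, so the stationary distribution is
    proportional to (1, k12/k21, k12*k23/(k21*k32)), scaled to ``total``.
    Requires both reverse rates to be strictly positive.
    """
    if rates.k21 <= 0 or rates.k32 <= 0:
        raise NoFiniteSteadyStateError(
            "steady state requires k21 > 0 and k32 > 0 (otherwise mass drains "
            "irreversibly into a terminal compartment)"
        )
    w = np.array(
        [
            1.0,
            rates.k12 / rates.k21,
            (rates.k12 * rates.k23) / (rates.k21 * rates.k32),
        ]
    )
    frac = total * w / w.sum()
    # t marks the asymptotic limit; kept finite for state validity
    return CompartmentState(Aa=frac[0], Ac=frac[1], Ab=frac[2], t=0.0)
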
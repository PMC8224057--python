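"""EAF4 post-processing: retention shifts -> electrophoretic mobility -> zeta.

Electrical asymmetrical flow field-flow fractionation superimposes an
electrical field on the cross-flow of an AF4 channel.  In the
high-retention limit the retention time of a particle is proportional to
its total transverse drift velocity, so applying a field E shifts the peak
retention time as

    t_r(E) / t_r(0) = 1 + s * mu * E / u_cf

with u_cf the mean cross-flow velocity at the accumulation wall, mu the
electrophoretic mobility and s the polarity sign of the installed
electrodes (with the default polarity a negative mobility increases
retention).  A linear least-squares fit of retention time against field
strength yields mu and its regression uncertainty; the zeta potential
follows from Henry's equation in the Smoluchowski limit,
zeta = 3 eta mu / (2 eps0 epsr f(ka)), with f(ka) = 1.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChannelGeometry",
    "Fractogram",
    "FieldSeries",
    "MediumProperties",
    "MobilityResult",
    "ZetaResult",
    "MOBILITY_TABLE",
    "peak_maximum",
    "mobility_from_field_series",
    "zeta_from_mobility",
]

VACUUM_PERMITTIVITY_F_M = 8.8541878128e-12


class NoPeakError(ValueError):
    """The fractogram has no detectable peak after the void peak."""


@dataclass(frozen=True)
class ChannelGeometry:
    """AF4 channel geometry.

    ``effective_area_cm2`` is the accumulation-wall area carrying the
    cross-flow; for the trapezoidal analytical channel used here it is an
    effective value consistent with the tip-to-tip length.
    """

    tip_to_tip_mm: float = 277.0
    spacer_um: float = 350.0
    effective_area_cm2: float = 31.6

    def cross_flow_velocity_m_s(self, cross_flow_ml_min: float) -> float:
        if cross_flow_ml_min <= 0:
            raise ValueError("cross flow must be positive")
        return (cross_flow_ml_min * 1e-6 / 60.0) / (self.effective_area_cm2 * 1e-4)


@dataclass
class Fractogram:
    """Elution-time trace of detector signal at one field strength."""

    time_min: np.ndarray
    signal: np.ndarray
    field_v_m: float = 0.0
    carrier_conductivity_us_cm: float = 90.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time_min.size != self.signal.size:
            raise ValueError("time and signal must have equal length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("elution times must be strictly increasing")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite")


@dataclass
class FieldSeries:
    """Peak retention times versus applied electrical field strength."""

    fields_v_m: np.ndarray
    retention_min: np.ndarray
    cross_flow_ml_min: float
    detector_flow_ml_min: float = 0.30
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    polarity: float = -1.0

    def __post_init__(self) -> None:
        self.fields_v_m = np.asarray(self.fields_v_m, dtype=float)
        self.retention_min = np.asarray(self.retention_min, dtype=float)
        if self.fields_v_m.size != self.retention_min.size:
            raise ValueError("fields and retention times must align")
        if np.unique(self.fields_v_m).size < 3:
            raise ValueError("need >= 3 distinct field strengths")
        if not np.any(self.fields_v_m == 0.0):
            raise ValueError("the zero-field point must be included")
        if np.any(self.retention_min <= 0):
            raise ValueError("retention times must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"field_v_per_m": self.fields_v_m,
                             "retention_min": self.retention_min})


@dataclass(frozen=True)
class MediumProperties:
    """Carrier-medium constants for the mobility -> zeta conversion."""

    viscosity_pa_s: float = 8.872e-4
    relative_permittivity: float = 78.4
    vacuum_permittivity_f_m: float = VACUUM_PERMITTIVITY_F_M
    temperature_k: float = 298.15
    henry_factor: float = 1.5

    def __post_init__(self) -> None:
        for name in ("viscosity_pa_s", "relative_permittivity",
                     "vacuum_permittivity_f_m", "temperature_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (1.0 <= self.henry_factor <= 1.5):
            raise ValueError("Henry factor must lie in [1, 1.5]")

    @classmethod
    def water_25c(cls) -> "MediumProperties":
        return cls()


@dataclass(frozen=True)
class MobilityResult:
    """Electrophoretic mobility (m^2/(V s)) with regression uncertainty."""

    mobility_m2_v_s: float
    uncertainty_m2_v_s: float
    r_squared: float
    flagged: bool = False


@dataclass(frozen=True)
class ZetaResult:
    """Zeta potential (mV) with linearly propagated uncertainty."""

    zeta_mv: float
    uncertainty_mv: float


def peak_maximum(fractogram: Fractogram, void_time_min: float = 0.0) -> float:
    """Retention time (min) of the signal maximum after void-peak exclusion.

    The apex is refined by fitting a parabola through the maximum sample and
    its two neighbours, giving sub-grid-resolution localisation.
    """
    mask = fractogram.time_min > void_time_min
    t = fractogram.time_min[mask]
    y = fractogram.signal[mask]
    if t.size < 3:
        raise NoPeakError("no samples after the void time")
    if np.ptp(y) == 0:
        raise NoPeakError("flat signal: no peak")
    i = int(np.argmax(y))
    if i == 0 or i == y.size - 1:
        return float(t[i])
    # parabolic vertex through three points on a (locally) uniform grid
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i])
    delta = 0.5 * (y0 - y2) / denom
    dt = 0.5 * (t[i + 1] - t[i - 1])
    return float(t[i] + np.clip(delta, -1.0, 1.0) * dt)


def mobility_from_field_series(series: FieldSeries) -> MobilityResult:
    """Electrophoretic mobility from the retention-time shift with field.

    Ordinary least squares of t_r against E gives slope b and intercept a;
    under the relative-shift model mu = s * b * u_cf / a.  The uncertainty
    is the regression standard error of the slope propagated through the
    same relation.  Poorly conditioned fits (negative intercept or R^2 of
    the non-zero-slope model below 0.2 despite a non-zero slope estimate)
    are flagged rather than rejected.
    """
    E = series.fields_v_m
    t = series.retention_min
    n = E.size
    if n < 3:
        raise ValueError("need at least 3 points")
    X = np.column_stack([np.ones(n), E])
    beta, *_ = np.linalg.lstsq(X, t, rcond=None)
    a, b = beta
    resid = t - X @ beta
    dof = max(n - 2, 1)
    s2 = float(resid @ resid) / dof
    sxx = float(np.sum((E - E.mean()) ** 2))
    se_b = math.sqrt(s2 / sxx)
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    u_cf = series.geometry.cross_flow_velocity_m_s(series.cross_flow_ml_min)
    flagged = a <= 0
    if flagged:
        a = max(a, 1e-9)
    mu = series.polarity * b * u_cf / a
    se_mu = abs(u_cf / a) * se_b
    if abs(b) > 2 * se_b and r2 < 0.2:
        flagged = True
    return MobilityResult(mobility_m2_v_s=float(mu),
                          uncertainty_m2_v_s=float(se_mu),
                          r_squared=float(r2), flagged=bool(flagged))


def zeta_from_mobility(mobility_m2_v_s: float, medium: MediumProperties | None = None,
                       uncertainty_m2_v_s: float = 0.0) -> ZetaResult:
    """Zeta potential (mV) via Henry's equation in the Smoluchowski limit.

    zeta = 3 eta mu / (2 eps0 epsr f(ka)); with f(ka) = 1.5 this reduces to
    the Helmholtz-Smoluchowski form zeta = eta mu / (eps0 epsr).  The
    uncertainty scales linearly with the mobility uncertainty.
    """
    if medium is None:
        medium = MediumProperties.water_25c()
    factor = (3.0 * medium.viscosity_pa_s
              / (2.0 * medium.vacuum_permittivity_f_m
                 * medium.relative_permittivity * medium.henry_factor))
    return ZetaResult(zeta_mv=float(factor * mobility_m2_v_s * 1e3),
                      uncertainty_mv=float(factor * abs(uncertainty_m2_v_s) * 1e3))


# Published EAF4 electrophoretic mobilities (1e-8 m^2/(V s)) for the four
# particle species in ultrapure water and in cell culture medium; these are
# measurement inputs to the zeta conversion.
MOBILITY_TABLE = pd.DataFrame(
    [
        ("AuNRods", "UPW", -2.74, 0.22),
        ("AuNP-30", "UPW", -4.61, 0.39),
        ("AuNP-200", "UPW", -2.36, 0.10),
        ("AgNP", "UPW", -2.99, 0.15),
        ("AuNRods", "CCM", -2.68, 0.14),
        ("AuNP-30", "CCM", -4.41, 0.32),
        ("AuNP-200", "CCM", -1.81, 0.11),
        ("AgNP", "CCM", -5.35, 0.35),
    ],
    columns=["species", "solvent", "mobility_e8_m2_v_s", "mobility_sd_e8_m2_v_s"],
)


def zeta_table(medium: MediumProperties | None = None) -> pd.DataFrame:
    """Convert the shipped mobility table to zeta potentials (mV)."""
    rows = []
    for _, row in MOBILITY_TABLE.iterrows():
        z = zeta_from_mobility(row["mobility_e8_m2_v_s"] * 1e-8, medium,
                               row["mobility_sd_e8_m2_v_s"] * 1e-8)
        rows.append({**row, "zeta_mv": z.zeta_mv, "zeta_sd_mv": z.uncertainty_mv})
    return pd.DataFrame(rows)
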
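"""Sinusoidal tether-bias model for loop-seq cyclizability.

The measured cyclizability of a 50-bp sequence with the tether at base ``n``
is modelled as

    C_n = C_0 + A_n * sin(2*pi*n/period + phi0)

with ``period`` the DNA helical repeat (10.4 bp by default).  With
observations at n = 26, 29, 31 and an assumed set of amplitude ratios
``r_n = A_26 / A_n`` the model is linear in ``(C_0, u, v)`` where
``u = A_26*cos(phi0)`` and ``v = A_26*sin(phi0)``, and can be solved exactly
per sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_PERIOD",
    "TETHER_LOCATIONS",
    "HelixConstants",
    "BiotinObservation",
    "AmplitudeRatioScheme",
    "BiotinFit",
    "SingularSchemeError",
    "bias_term",
    "forward_cn",
    "solve_c0",
    "solve_c0_arrays",
    "approx_c0",
    "q_score",
    "phase_progress",
    "wrap_phase",
]

DEFAULT_PERIOD = 10.4
TETHER_LOCATIONS = (26, 29, 31)

#: amplitude below which the phase direction is numerically undefined
_AMPLITUDE_TOL = 1e-12
#: reciprocal-condition-number threshold for an unsolvable scheme
_RCOND_TOL = 1e-10


class SingularSchemeError(ValueError):
    """The amplitude-ratio scheme yields a (near-)singular linear system."""


@dataclass(frozen=True)
class HelixConstants:
    """DNA helical repeat length in bp per turn."""

    period: float = DEFAULT_PERIOD

    def __post_init__(self) -> None:
        if not (math.isfinite(self.period) and self.period > 0):
            raise ValueError("helical period must be a positive finite number")


@dataclass(frozen=True)
class BiotinObservation:
    """One sequence's measured cyclizability triplet (tether at 26/29/31)."""

    c26: float
    c29: float
    c31: float

    def __post_init__(self) -> None:
        for name in ("c26", "c29", "c31"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.c26, self.c29, self.c31], dtype=float)


@dataclass(frozen=True)
class AmplitudeRatioScheme:
    """Assumed amplitude ratios r_n = A_26 / A_n.

    The anchor is ``ratio_31 = A_26/A_31``; ratios at other tether locations
    follow by linear interpolation/extrapolation in n:

        r_n = 1 - (n - 26) * (1 - ratio_31) / 5

    so ``r_26 = 1`` always and ``ratio_31 = 0.7`` gives ``r_29 = 0.82``.
    An explicit ``ratio_29`` may be supplied to override the interpolation
    (used when scanning ratio grids).
    """

    ratio_31: float = 0.7
    ratio_29: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ratio_31) and self.ratio_31 > 0):
            raise ValueError("ratio_31 must be positive and finite")
        for n in TETHER_LOCATIONS:
            if self.ratio(n) <= 0:
                raise ValueError(
                    f"scheme ratio_31={self.ratio_31} implies non-positive "
                    f"r_{n} = {self.ratio(n)}"
                )

    def ratio(self, n: float) -> float:
        """r_n = A_26 / A_n at tether location *n*."""
        if self.ratio_29 is not None and n == 29:
            return self.ratio_29
        return 1.0 - (n - 26.0) * (1.0 - self.ratio_31) / 5.0

    def ratios(self) -> np.ndarray:
        """Ratios at the three measured tether locations (26, 29, 31)."""
        return np.array([self.ratio(n) for n in TETHER_LOCATIONS])


@dataclass(frozen=True)
class BiotinFit:
    """Exact model fit to one observation under an assumed ratio scheme.

    ``phi0`` is ``None`` when the fitted amplitude is numerically zero, in
    which case the phase direction is undefined.
    """

    c0: float
    a26: float
    phi0: float | None
    scheme: AmplitudeRatioScheme = field(default_factory=AmplitudeRatioScheme)
    period: float = DEFAULT_PERIOD

    def amplitude(self, n: float) -> float:
        """Implied amplitude A_n = A_26 / r_n."""
        return self.a26 / self.scheme.ratio(n)

    def predict(self, n: float) -> float:
        """Forward-model C_n for this fit."""
        phi0 = 0.0 if self.phi0 is None else self.phi0
        return forward_cn(self.c0, self.a26, phi0, self.scheme, n, self.period)


def _check_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value!r}")


def bias_term(
    n: float, phi0: float, amplitude: float, period: float = DEFAULT_PERIOD
) -> float:
    """Tether-bias component ``amplitude * sin(2*pi*n/period + phi0)``."""
    _check_finite(n=n, phi0=phi0, amplitude=amplitude, period=period)
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    return amplitude * math.sin(2.0 * math.pi * n / period + phi0)


def forward_cn(
    c0: float,
    a26: float,
    phi0: float,
    scheme: AmplitudeRatioScheme,
    n: float,
    period: float = DEFAULT_PERIOD,
) -> float:
    """Forward model: ``C_n = c0 + (a26 / r_n) * sin(2*pi*n/period + phi0)``."""
    _check_finite(c0=c0, a26=a26, phi0=phi0)
    if a26 < 0:
        raise ValueError("a26 must be non-negative")
    r_n = scheme.ratio(n)
    if r_n <= 0:
        raise ValueError(f"scheme ratio r_{n} = {r_n} must be positive")
    return c0 + bias_term(n, phi0, a26 / r_n, period)


def design_matrix(
    scheme: AmplitudeRatioScheme, period: float = DEFAULT_PERIOD
) -> np.ndarray:
    """3x3 design for the linear system in (c0, u, v) at n = 26, 29, 31."""
    ns = np.asarray(TETHER_LOCATIONS, dtype=float)
    theta = 2.0 * np.pi * ns / period
    r = scheme.ratios()
    return np.column_stack([np.ones(3), np.sin(theta) / r, np.cos(theta) / r])


def _solver_inverse(scheme: AmplitudeRatioScheme, period: float) -> np.ndarray:
    m = design_matrix(scheme, period)
    if 1.0 / np.linalg.cond(m) < _RCOND_TOL:
        raise SingularSchemeError(
            f"amplitude-ratio scheme {scheme} gives a near-singular system "
            f"at period {period}"
        )
    return np.linalg.inv(m)


def solve_c0(
    obs: BiotinObservation,
    scheme: AmplitudeRatioScheme | None = None,
    period: float = DEFAULT_PERIOD,
) -> BiotinFit:
    """Exact intrinsic-cyclizability solve for one observation triplet.

    Substituting ``u = a26*cos(phi0)``, ``v = a26*sin(phi0)`` turns the
    sinusoidal model into three linear equations in ``(c0, u, v)``; the
    solution reproduces the observations to machine precision.
    """
    scheme = scheme if scheme is not None else AmplitudeRatioScheme()
    inv = _solver_inverse(scheme, period)
    c0, u, v = inv @ obs.as_array()
    a26 = math.hypot(u, v)
    phi0 = wrap_phase(math.atan2(v, u)) if a26 >= _AMPLITUDE_TOL else None
    return BiotinFit(float(c0), float(a26), phi0, scheme, period)


def solve_c0_arrays(
    c26: np.ndarray,
    c29: np.ndarray,
    c31: np.ndarray,
    scheme: AmplitudeRatioScheme | None = None,
    period: float = DEFAULT_PERIOD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`solve_c0` over aligned observation arrays.

    Returns ``(c0, a26, phi0)`` arrays; ``phi0`` is ``NaN`` where the fitted
    amplitude is numerically zero.
    """
    scheme = scheme if scheme is not None else AmplitudeRatioScheme()
    inv = _solver_inverse(scheme, period)
    obs = np.vstack([np.asarray(c26, float), np.asarray(c29, float), np.asarray(c31, float)])
    c0, u, v = inv @ obs
    a26 = np.hypot(u, v)
    phi0 = wrap_phase(np.arctan2(v, u))
    phi0 = np.where(a26 >= _AMPLITUDE_TOL, phi0, np.nan)
    return c0, a26, phi0


def approx_c0(obs: BiotinObservation, f: float = 0.7) -> float:
    """Two-observation approximation ``(c26/f + c31) / (1 + 1/f)``.

    Valid because the tether bias at n = 26 and n = 31 is nearly antiphase
    (5 bp apart, almost half a helical turn), so a suitably weighted sum
    cancels it.
    """
    if not (math.isfinite(f) and f > 0):
        raise ValueError("weight f must be positive and finite")
    return (obs.c26 / f + obs.c31) / (1.0 + 1.0 / f)


def q_score(c26: float, c31: float, f: float) -> float:
    """Ranking score ``c26 + f*c31`` used to tune the amplitude-ratio weight."""
    _check_finite(c26=c26, c31=c31, f=f)
    return c26 + f * c31


def wrap_phase(phi: float | np.ndarray) -> float | np.ndarray:
    """Reduce a phase (radians) to the half-open interval [-pi, pi)."""
    out = np.mod(np.asarray(phi) + np.pi, 2.0 * np.pi) - np.pi
    return float(out) if np.isscalar(phi) or np.asarray(phi).ndim == 0 else out


def phase_progress(
    phi_at_l: float, k: float, period: float = DEFAULT_PERIOD
) -> float:
    """Phase *k* bp downstream: ``phi(l+k) = phi(l) - 2*pi*k/period``.

    Each 1-bp shift of the 50-mer window advances the helix one base, so the
    rotational phase at the tether decreases by one base's worth of twist.
    """
    return float(wrap_phase(phi_at_l - 2.0 * math.pi * k / period))
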
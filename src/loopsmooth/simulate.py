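"""Simulation benchmark for the tether-bias estimators.

Generates C_n tracks (n = 26, 29, 31) from the sinusoidal bias model with
bounded-random-walk parameters under three amplitude-ratio regimes:

* setting ``i``   — A_31 = A_26/0.7, A_29 = A_26/0.82 (the assumed ratios
  are the truth);
* setting ``ii``  — A_31 = 0.7*A_26, A_29 = 0.82*A_26 (inverted ratios);
* setting ``iii`` — A_31 = a*A_26, A_29 = b*A_26 with log(a), log(b)
  evolving as independent bounded random walks (a, b in [0.2, 1.5]).

The benchmark compares the per-position closed-form solve (under assumed
ratios 0.7/0.82) against the k=10.4 smoothed tracks and their average,
reporting Pearson correlations with the true intrinsic signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biotin import (
    DEFAULT_PERIOD,
    AmplitudeRatioScheme,
    SingularSchemeError,
    design_matrix,
    solve_c0_arrays,
)
from .smoothing import mean_tracks, moving_average
from .tracks import PositionTrack, pearson

__all__ = [
    "BoundedWalkSpec",
    "SimulationSetting",
    "SimulationResult",
    "bounded_random_walk",
    "simulate_setting",
    "evaluate_correlations",
    "ratio_heatmap",
    "sensitivity_run",
    "TABLE_ROWS",
]

TABLE_ROWS = (
    "c26",
    "c29",
    "c31",
    "c26_smoothed",
    "c29_smoothed",
    "c31_smoothed",
    "mean_smoothed",
    "c0_solved",
)


@dataclass(frozen=True)
class BoundedWalkSpec:
    """Gaussian random walk reflected into [lower, upper].

    ``init`` is the start value, or ``None`` for a uniform draw in bounds.
    """

    step_sd: float
    lower: float
    upper: float
    init: float | None = None

    def __post_init__(self) -> None:
        if self.step_sd < 0:
            raise ValueError("step_sd must be >= 0")
        if not self.lower < self.upper:
            raise ValueError("require lower < upper")
        if self.init is not None and not (self.lower <= self.init <= self.upper):
            raise ValueError("init must lie within bounds")


def bounded_random_walk(
    spec: BoundedWalkSpec, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate the walk: a step leaving the bounds is retaken in the
    opposite direction with the same magnitude (then clamped if still out)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if (spec.upper - spec.lower) < 4 * spec.step_sd:
        warnings.warn(
            "bounds narrower than 4*step_sd: single-reflection boundary "
            "handling becomes a poor approximation",
            stacklevel=2,
        )
    x = np.empty(length)
    x[0] = rng.uniform(spec.lower, spec.upper) if spec.init is None else spec.init
    if length > 1:
        steps = rng.normal(0.0, spec.step_sd, size=length - 1)
        lo, hi = spec.lower, spec.upper
        for i in range(1, length):
            y = x[i - 1] + steps[i - 1]
            if y < lo or y > hi:
                y = x[i - 1] - steps[i - 1]
                if y < lo:
                    y = lo
                elif y > hi:
                    y = hi
            x[i] = y
    return x


@dataclass(frozen=True)
class SimulationSetting:
    """Generative parameters for one benchmark run."""

    label: str = "i"
    length: int = 100_000
    seed: int = 0
    noise_sd: float = 0.25
    period: float = DEFAULT_PERIOD
    c0_walk: BoundedWalkSpec = field(
        default_factory=lambda: BoundedWalkSpec(1.0 / 12.0, -2.0, 2.0)
    )
    a26_walk: BoundedWalkSpec = field(
        default_factory=lambda: BoundedWalkSpec(1.0 / 5.0, 0.1, 3.0)
    )
    #: step sd of the log-scale ratio walks (setting iii only)
    ratio_step_sd: float = 0.1
    #: bounds of the a, b ratio walks on the value scale (setting iii only)
    ratio_bounds: tuple[float, float] = (0.2, 1.5)
    #: draw the noise once per position and share it across n (the default
    #: draws independently per (n, position))
    shared_noise: bool = False

    def __post_init__(self) -> None:
        if self.label not in ("i", "ii", "iii"):
            raise ValueError("label must be one of 'i', 'ii', 'iii'")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SimulationResult:
    """Ground-truth and observed tracks from one simulation run."""

    setting: SimulationSetting
    c0: PositionTrack
    a26: PositionTrack
    a29: PositionTrack
    a31: PositionTrack
    phi: PositionTrack
    observed: Mapping[int, PositionTrack]  # n -> C_n track

    @property
    def length(self) -> int:
        return len(self.c0)


def _sub_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent sub-streams so parameter overrides perturb only their
    own component.  Spawn order is part of the reproducibility contract."""
    names = ("c0", "a26", "log_a", "log_b", "phi", "eps26", "eps29", "eps31")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(s) for name, s in zip(names, children)}


def simulate_setting(setting: SimulationSetting) -> SimulationResult:
    """Generate C_n = C_0 + A_n*sin(2*pi*n/period + phi) + eps per position."""
    rngs = _sub_rngs(setting.seed)
    length = setting.length
    c0 = bounded_random_walk(setting.c0_walk, length, rngs["c0"])
    a26 = bounded_random_walk(setting.a26_walk, length, rngs["a26"])

    lo, hi = setting.ratio_bounds
    log_walk = BoundedWalkSpec(setting.ratio_step_sd, math.log(lo), math.log(hi))
    # the ratio walks are always drawn so that settings sharing a seed share
    # every other stream; they only enter the model in setting iii
    a_ratio = np.exp(bounded_random_walk(log_walk, length, rngs["log_a"]))
    b_ratio = np.exp(bounded_random_walk(log_walk, length, rngs["log_b"]))

    if setting.label == "i":
        a31, a29 = a26 / 0.7, a26 / 0.82
    elif setting.label == "ii":
        a31, a29 = 0.7 * a26, 0.82 * a26
    else:
        a31, a29 = a_ratio * a26, b_ratio * a26

    phi = rngs["phi"].uniform(0.0, 2.0 * math.pi) - (
        2.0 * math.pi / setting.period
    ) * np.arange(length)

    amplitudes = {26: a26, 29: a29, 31: a31}
    shared = rngs["eps26"].normal(0.0, setting.noise_sd, size=length)
    observed = {}
    for n in (26, 29, 31):
        eps = (
            shared
            if setting.shared_noise
            else rngs[f"eps{n}"].normal(0.0, setting.noise_sd, size=length)
        )
        values = (
            c0
            + amplitudes[n] * np.sin(2.0 * math.pi * n / setting.period + phi)
            + eps
        )
        observed[n] = PositionTrack("sim", 1, values)

    return SimulationResult(
        setting=setting,
        c0=PositionTrack("sim", 1, c0),
        a26=PositionTrack("sim", 1, a26),
        a29=PositionTrack("sim", 1, a29),
        a31=PositionTrack("sim", 1, a31),
        phi=PositionTrack("sim", 1, phi),
        observed=observed,
    )


def evaluate_correlations(
    result: SimulationResult,
    k: float = 10.4,
    assumed_scheme: AmplitudeRatioScheme | None = None,
) -> pd.DataFrame:
    """Pearson correlation of every estimator with the true intrinsic track.

    Rows: raw C_26/C_29/C_31, each k-smoothed track, their mean, and the
    per-position closed-form solve under *assumed_scheme*.
    """
    assumed_scheme = assumed_scheme or AmplitudeRatioScheme(0.7)
    c0 = result.c0
    smoothed = {n: moving_average(result.observed[n], k) for n in (26, 29, 31)}
    mean_smoothed = mean_tracks([smoothed[n] for n in (26, 29, 31)])
    c0_hat, _, _ = solve_c0_arrays(
        result.observed[26].values,
        result.observed[29].values,
        result.observed[31].values,
        assumed_scheme,
        result.setting.period,
    )
    rows = {
        "c26": pearson(result.observed[26], c0),
        "c29": pearson(result.observed[29], c0),
        "c31": pearson(result.observed[31], c0),
        "c26_smoothed": pearson(smoothed[26], c0),
        "c29_smoothed": pearson(smoothed[29], c0),
        "c31_smoothed": pearson(smoothed[31], c0),
        "mean_smoothed": pearson(mean_smoothed, c0),
        "c0_solved": pearson(c0_hat, c0.values),
    }
    return pd.DataFrame(
        {"estimator": list(rows), "correlation": list(rows.values())}
    ).set_index("estimator")


def ratio_heatmap(
    setting: SimulationSetting | SimulationResult,
    ratio31_grid: Sequence[float] | None = None,
    ratio29_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Correlation of the closed-form solve with truth over a ratio grid.

    Rows are assumed A_26/A_31 values, columns assumed A_26/A_29 values (the
    latter override the linear-interpolation rule).  Cells whose scheme is
    numerically singular are NaN.
    """
    if ratio31_grid is None:
        ratio31_grid = np.linspace(0.5, 1.5, 21)
    if ratio29_grid is None:
        ratio29_grid = np.linspace(0.5, 1.5, 21)
    result = (
        setting if isinstance(setting, SimulationResult) else simulate_setting(setting)
    )
    obs = np.vstack([result.observed[n].values for n in (26, 29, 31)])
    truth = result.c0.values
    grid = np.full((len(ratio31_grid), len(ratio29_grid)), np.nan)
    for i, r31 in enumerate(ratio31_grid):
        for j, r29 in enumerate(ratio29_grid):
            try:
                scheme = AmplitudeRatioScheme(ratio_31=r31, ratio_29=r29)
                inv = np.linalg.inv(design_matrix(scheme, result.setting.period))
            except (SingularSchemeError, np.linalg.LinAlgError, ValueError):
                continue
            c0_hat = inv[0] @ obs
            grid[i, j] = pearson(c0_hat, truth)
    return pd.DataFrame(
        grid,
        index=pd.Index(np.round(ratio31_grid, 10), name="ratio_31"),
        columns=pd.Index(np.round(ratio29_grid, 10), name="ratio_29"),
    )


def _scaled(spec: BoundedWalkSpec, variance_multiplier: float) -> BoundedWalkSpec:
    return replace(spec, step_sd=spec.step_sd * math.sqrt(variance_multiplier))


def sensitivity_run(
    base: SimulationSetting,
    overrides: Sequence[Mapping[str, float]],
    k: float = 10.4,
) -> pd.DataFrame:
    """Correlation of the mean-smoothed estimator under variance overrides.

    Each override maps any of ``c0_var``, ``a26_var``, ``ratio_var``,
    ``noise_var`` to a variance multiplier (default 1).  Returns one row per
    override with the multipliers and corr(mean-smoothed, truth).
    """
    rows = []
    for override in overrides:
        unknown = set(override) - {"c0_var", "a26_var", "ratio_var", "noise_var"}
        if unknown:
            raise ValueError(f"unknown sensitivity override(s): {sorted(unknown)}")
        if any(m <= 0 for m in override.values()):
            raise ValueError("variance multipliers must be positive")
        setting = replace(
            base,
            c0_walk=_scaled(base.c0_walk, override.get("c0_var", 1.0)),
            a26_walk=_scaled(base.a26_walk, override.get("a26_var", 1.0)),
            ratio_step_sd=base.ratio_step_sd
            * math.sqrt(override.get("ratio_var", 1.0)),
            noise_sd=base.noise_sd * math.sqrt(override.get("noise_var", 1.0)),
        )
        result = simulate_setting(setting)
        smoothed = [moving_average(result.observed[n], k) for n in (26, 29, 31)]
        corr = pearson(mean_tracks(smoothed), result.c0)
        row = {key: override.get(key, 1.0) for key in ("c0_var", "a26_var", "ratio_var", "noise_var")}
        row["correlation"] = corr
        rows.append(row)
    return pd.DataFrame(rows)
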
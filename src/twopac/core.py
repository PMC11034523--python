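"""Closed-form quantities of the two-phase ("Smurf") ageing model.

The model splits every lifespan into two consecutive phases.  During the
first phase individuals face no mortality but an age-increasing risk of an
abrupt physiological transition (operationally detected in flies as the
"Smurf" phenotype: whole-body spread of an ingested blue dye).  Once past
the transition, individuals die at a constant rate.  Three parameters
describe a cohort:

``a``
    slope of the linear increase of the Smurf fraction among the living,
    in fraction per day;
``t0``
    age at which the first Smurf appears, in days;
``k``
    mortality rate of Smurfs, per day.

The proportion of Smurfs among the living is ``p(t) = clip(a(t - t0), 0, 1)``
and the population hazard is ``k * p(t)``.  Because ``p`` is bounded by 1,
the hazard plateaus at ``k`` once every survivor is a Smurf — a
bounded-heterogeneity route to the late-life deceleration of mortality,
with no unbounded frailty distribution involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_K",
    "SaturationError",
    "TwoPhaseParams",
    "MixtureSignal",
    "smurf_proportion",
    "cumulative_hazard",
    "survival_fraction",
    "population_hazard",
    "subpopulation_split",
    "smurf_peak_age",
    "transition_rate",
    "mean_smurf_remaining_life",
    "mix_signals",
    "deconvolve_mixture",
]

#: Default Smurf mortality rate, per day.  The Smurf phase lasts roughly
#: 2-3 days in female flies, i.e. ``1/k`` of about 3 days; ``k = 0.3/d`` is
#: a package convention for simulations, not a measured constant.
DEFAULT_K = 0.3


class SaturationError(ValueError):
    """Raised when a quantity is requested past Smurf saturation (p = 1)."""


@dataclass(frozen=True)
class TwoPhaseParams:
    """Parameter triple (a, t0, k) of the two-phase survival model.

    Parameters
    ----------
    a
        Smurf-appearance slope, fraction per day.  Must be positive.
    t0
        Age of first Smurf appearance, days.  May be negative: the linear
        Smurf-proportion law is often reported as slope/intercept
        ``p(t) = a t + b``, and a positive intercept ``b`` corresponds to
        ``t0 = -b/a < 0`` (the cohort starts with Smurfs already present).
    k
        Smurf mortality rate, per day.  Must be positive.

    Notes
    -----
    The equivalent line representation ``(a, b)`` with ``b = -a * t0`` is
    available through :meth:`from_line` and the :attr:`b` property; the
    intercept passed to the constructor round-trips exactly.
    """

    a: float
    t0: float
    k: float = DEFAULT_K
    _b: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError(f"a must be finite and > 0, got {self.a}")
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be finite and > 0, got {self.k}")
        if not np.isfinite(self.t0):
            raise ValueError(f"t0 must be finite, got {self.t0}")

    @classmethod
    def from_line(cls, a: float, b: float, k: float = DEFAULT_K) -> "TwoPhaseParams":
        """Build parameters from the line form ``p(t) = a t + b``."""
        a = float(a)
        if not (np.isfinite(a) and a > 0):
            raise ValueError(f"a must be finite and > 0, got {a}")
        return cls(a=a, t0=-float(b) / a, k=float(k), _b=float(b))

    @property
    def b(self) -> float:
        """Intercept of the Smurf-proportion line, ``b = -a * t0``."""
        if self._b is not None:
            return self._b
        return -self.a * self.t0

    @property
    def t_sat(self) -> float:
        """Saturation age ``t0 + 1/a`` at which p(t) reaches 1, days."""
        return self.t0 + 1.0 / self.a


@dataclass(frozen=True)
class MixtureSignal:
    """A population-average signal decomposed into its two subpopulations.

    At a sampling age the living population is a mixture of a fraction
    ``s`` of Smurfs and ``1 - s`` of non-Smurfs, so any per-individual
    signal averages to ``mixed = s * smurf + (1 - s) * nonsmurf``.
    """

    s: float
    smurf_value: float
    nonsmurf_value: float
    mixed_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"mixture weight s must lie in [0, 1], got {self.s}")
        expected = self.s * self.smurf_value + (1.0 - self.s) * self.nonsmurf_value
        scale = max(1.0, abs(self.mixed_value), abs(expected))
        if abs(self.mixed_value - expected) > 1e-9 * scale:
            raise ValueError(
                "mixed_value is inconsistent with s, smurf_value, nonsmurf_value"
            )


def _as_time(t, *, nonnegative: bool = False):
    """Validate ages and return (ndarray, was_scalar)."""
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("ages must be finite")
    if nonnegative and np.any(arr < 0):
        raise ValueError("ages must be non-negative")
    return arr, arr.ndim == 0


def smurf_proportion(t, params: TwoPhaseParams):
    """Proportion of Smurfs among the living at age ``t``.

    Implements the linear law ``p(t) = clip(a (t - t0), 0, 1)``: zero until
    the first Smurf appears at ``t0``, then increasing with slope ``a``
    until every survivor is a Smurf at ``t_sat = t0 + 1/a``.
    """
    arr, scalar = _as_time(t)
    p = np.clip(params.a * (arr - params.t0), 0.0, 1.0)
    return float(p) if scalar else p


def cumulative_hazard(t, params: TwoPhaseParams):
    """Integrated population hazard ``H(t) = k * \\int_0^t p(u) du``."""
    arr, scalar = _as_time(t, nonnegative=True)
    a, t0, k = params.a, params.t0, params.k
    u0 = max(t0, 0.0)
    p0 = min(max(a * (u0 - t0), 0.0), 1.0)  # proportion at the start of exposure
    tsat = params.t_sat
    H = np.zeros_like(arr)
    if p0 >= 1.0:
        # saturated from the start: constant hazard k throughout
        H = k * arr
    else:
        pt = a * (arr - t0)
        mid = (arr > u0) & (arr <= tsat)
        late = arr > tsat
        with np.errstate(over="ignore", invalid="ignore"):
            H[mid] = (k / (2.0 * a)) * (pt[mid] ** 2 - p0**2)
            H[late] = (k / (2.0 * a)) * (1.0 - p0**2) + k * (arr[late] - tsat)
        H = np.nan_to_num(H, nan=np.inf, posinf=np.inf)
    return float(H) if scalar else H


def survival_fraction(t, params: TwoPhaseParams):
    """Fraction of the cohort alive at age ``t`` under the two-phase model.

    Piecewise closed form, continuous and non-increasing:

    * 1 on ``[0, max(t0, 0)]`` (the survival plateau: nobody dies before
      the first Smurf appears);
    * ``exp(-(k a / 2) (t - t0)^2)`` between ``t0`` and ``t_sat`` (for
      ``t0 >= 0``), a Gaussian-shaped shoulder;
    * a pure exponential tail of rate ``k`` beyond ``t_sat``, where the
      population hazard has plateaued.
    """
    H = cumulative_hazard(t, params)
    return np.exp(-np.asarray(H)) if np.ndim(H) else math.exp(-H)


def population_hazard(t, params: TwoPhaseParams):
    """Population-level force of mortality ``k * p(t)``, per day.

    The hazard of the mixed population is the Smurf mortality ``k``
    weighted by the proportion of Smurfs among the living; it is bounded
    above by ``k`` and equals ``k`` exactly for ``t >= t_sat``.
    """
    arr, scalar = _as_time(t)
    h = params.k * np.clip(params.a * (arr - params.t0), 0.0, 1.0)
    return float(h) if scalar else h


def subpopulation_split(t, params: TwoPhaseParams, n0: float):
    """Expected numbers of (non-Smurfs, Smurfs) alive at age ``t``.

    The observed longevity curve of a cohort of ``n0`` individuals is the
    sum of the two components returned here: ``(1 - p) F n0`` non-Smurfs
    and ``p F n0`` Smurfs, with ``p`` the Smurf proportion and ``F`` the
    survival fraction.  The Smurf component rises to a single interior
    maximum at :func:`smurf_peak_age` and the two components are equal
    when ``p = 0.5``.
    """
    if n0 < 0:
        raise ValueError("n0 must be non-negative")
    arr, scalar = _as_time(t, nonnegative=True)
    p = np.clip(params.a * (arr - params.t0), 0.0, 1.0)
    F = np.exp(-np.asarray(cumulative_hazard(arr, params)))
    non = (1.0 - p) * F * n0
    smu = p * F * n0
    if scalar:
        return float(non), float(smu)
    return non, smu


def smurf_peak_age(params: TwoPhaseParams) -> float:
    """Age at which the number of living Smurfs is maximal, days.

    Before saturation the Smurf count is proportional to
    ``a x exp(-(k a / 2) x^2)`` with ``x = t - t0``, maximised at
    ``x = 1 / sqrt(a k)``; the peak therefore sits at
    ``t0 + 1/sqrt(a k)`` (around population mid-life for typical
    parameters), provided that age precedes saturation.
    """
    return params.t0 + 1.0 / math.sqrt(params.a * params.k)


def transition_rate(t, params: TwoPhaseParams):
    """Individual hazard of the Smurf transition at age ``t``, per day.

    The per-individual transition hazard implied jointly by the linear
    proportion law and the constant Smurf mortality is

    ``lambda(t) = a / (1 - p(t)) + k * p(t)``.

    Plugging this rate into the two-type dynamics ``N' = -lambda N``,
    ``S' = lambda N - k S`` reproduces ``p(t) = a (t - t0)`` exactly.  The
    rate diverges as ``p -> 1``; requesting it at or past saturation
    raises :class:`SaturationError` (simulators must force conversion at
    ``t_sat`` instead).
    """
    arr, scalar = _as_time(t)
    p = np.clip(params.a * (arr - params.t0), 0.0, 1.0)
    if np.any(p >= 1.0):
        raise SaturationError(
            "transition rate is unbounded at Smurf saturation (p >= 1)"
        )
    lam = params.a / (1.0 - p) + params.k * p
    return float(lam) if scalar else lam


def mean_smurf_remaining_life(params: TwoPhaseParams) -> float:
    """Mean remaining lifespan after the Smurf transition, ``1/k`` days.

    Smurf deaths are exponential with rate ``k``, so the phase lasts
    ``1/k`` days on average regardless of the age at transition.
    """
    return 1.0 / params.k


def mix_signals(s, smurf_value, nonsmurf_value):
    """Forward mixture: population-average signal at Smurf proportion ``s``."""
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0.0) or np.any(s_arr > 1.0):
        raise ValueError("mixture weight s must lie in [0, 1]")
    out = s_arr * np.asarray(smurf_value, dtype=float) + (1.0 - s_arr) * np.asarray(
        nonsmurf_value, dtype=float
    )
    return float(out) if out.ndim == 0 else out


def deconvolve_mixture(mixed_value, smurf_value, s):
    """Recover the non-Smurf signal from a population average.

    Inverts ``mixed = s * smurf + (1 - s) * nonsmurf`` for the non-Smurf
    component: ``(mixed - s * smurf) / (1 - s)``.  At ``s = 1`` the living
    population contains no non-Smurfs and the component is unidentifiable,
    so ``s`` must lie in ``[0, 1)``.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0.0) or np.any(s_arr >= 1.0):
        raise ValueError("mixture weight s must lie in [0, 1) for deconvolution")
    out = (np.asarray(mixed_value, dtype=float) - s_arr * np.asarray(smurf_value, dtype=float)) / (
        1.0 - s_arr
    )
    return float(out) if out.ndim == 0 else out
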
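"""Gompertz proportional-hazards law: closed forms, sampling, life-expectancy utilities.

The hazard is ``h(x) = a * exp(b*x) * exp(eta)`` where ``eta`` is a linear
predictor (log hazard ratio).  All functions are vectorised over ``age`` and
``eta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .errors import ConfigError

#: Conversion parameters used throughout for hazard-ratio -> life-years summaries.
DEFAULT_A = 3.34e-5
DEFAULT_B = 0.1


@dataclass(frozen=True)
class GompertzParams:
    """Baseline Gompertz parameters: level ``a`` at age 0 and slope ``b`` per year."""

    a: float = DEFAULT_A
    b: float = DEFAULT_B

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and self.a > 0):
            raise ConfigError(f"GompertzParams.a must be a positive finite number, got {self.a}")
        if not (np.isfinite(self.b) and self.b > 0):
            raise ConfigError(f"GompertzParams.b must be a positive finite number, got {self.b}")


def hazard(age, params: GompertzParams, eta=0.0):
    """Hazard rate h(x) = a e^{bx} e^{eta}."""
    age = np.asarray(age, dtype=float)
    return params.a * np.exp(params.b * age + eta)


def cum_hazard(age, params: GompertzParams, eta=0.0):
    """Cumulative hazard H(x) = (a e^{eta}/b) (e^{bx} - 1)."""
    age = np.asarray(age, dtype=float)
    out = np.where(np.isinf(age), np.inf, (params.a / params.b) * np.exp(np.asarray(eta, dtype=float)) * np.expm1(params.b * np.where(np.isinf(age), 0.0, age)))
    return out


def log_survival(age, params: GompertzParams, eta=0.0):
    return -cum_hazard(age, params, eta)


def survival(age, params: GompertzParams, eta=0.0):
    return np.exp(log_survival(age, params, eta))


def cdf(age, params: GompertzParams, eta=0.0):
    # 1 - S computed via expm1 for accuracy near 0
    return -np.expm1(log_survival(age, params, eta))


def log_pdf(age, params: GompertzParams, eta=0.0):
    age = np.asarray(age, dtype=float)
    return np.log(params.a) + params.b * age + np.asarray(eta, dtype=float) - cum_hazard(age, params, eta)


def pdf(age, params: GompertzParams, eta=0.0):
    return np.exp(log_pdf(age, params, eta))


def gompertz_functions(params: GompertzParams, eta, age) -> dict:
    """Evaluate hazard, cumulative hazard, survival, density and CDF at ``age``.

    Returned as a dict keyed ``hazard / cum_hazard / survival / density / cdf``;
    every entry is vectorised over ``age``.
    """
    return {
        "hazard": hazard(age, params, eta),
        "cum_hazard": cum_hazard(age, params, eta),
        "survival": survival(age, params, eta),
        "density": pdf(age, params, eta),
        "cdf": cdf(age, params, eta),
    }


def sample_death_ages(params: GompertzParams, eta, rng: np.random.Generator, size=None):
    """Draw death ages by inversion: T = (1/b) log1p(b E / (a e^{eta})), E ~ Exp(1).

    ``eta`` may be a scalar or an array; if ``size`` is None the shape of
    ``eta`` is used.
    """
    eta = np.asarray(eta, dtype=float)
    if size is None:
        size = eta.shape if eta.shape else None
    e = rng.exponential(size=size)
    return np.log1p(params.b * e / (params.a * np.exp(eta))) / params.b


def remaining_life_expectancy(age: float, params: GompertzParams, hr: float = 1.0, tol: float = 1e-8) -> float:
    """Remaining life expectancy e(age) under hazard ``hr * a e^{bx}``.

    Computed by adaptive quadrature of exp(-H(age, age+t)) over t in [0, inf).
    The closed form (1/b) e^c E1(c) with c = (a hr / b) e^{b age} is used only
    as a test oracle, never here.
    """
    if hr <= 0:
        raise ConfigError(f"hr must be positive, got {hr}")
    c = (params.a * hr / params.b) * np.exp(params.b * age)

    def integrand(t):
        with np.errstate(over="ignore"):  # exp(-inf) -> 0 is the right limit
            return np.exp(-c * np.expm1(params.b * t))

    value, _ = integrate.quad(integrand, 0.0, np.inf, epsabs=tol, epsrel=tol, limit=200)
    return value


def hr_to_e_gain(hr: float, params: GompertzParams | None = None, age: float = 35.0) -> float:
    """Difference in remaining life expectancy at ``age`` for hazard ratio ``hr`` vs 1.

    Positive when ``hr < 1``.  The proportional shift applies to the hazard
    above ``age`` only.
    """
    params = params or GompertzParams()
    if hr == 1.0:
        return 0.0
    return remaining_life_expectancy(age, params, hr=hr) - remaining_life_expectancy(age, params, hr=1.0)


def annualize_hr(hr_high_ed: float, hr_low_ed: float, years_gap: float) -> float:
    """Per-year hazard ratio: (hr_high_ed / hr_low_ed) ** (1 / years_gap)."""
    if hr_high_ed <= 0 or hr_low_ed <= 0:
        raise ConfigError("hazard ratios must be positive")
    if years_gap == 0:
        raise ConfigError("years_gap must be nonzero")
    return float((hr_high_ed / hr_low_ed) ** (1.0 / years_gap))
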
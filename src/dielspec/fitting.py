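"""Simulated-annealing estimation of dielectric model parameters.

The fitter minimises the average relative fitting error

    err_bar = (100/N) * sum_i sqrt( ((Re m_i - Re c_i)/Re c_i)^2
                                  + ((Im m_i - Im c_i)/Im c_i)^2 )

between a measured spectrum ``m`` and the model curve ``c`` (denominators are
the fitted curve), with both imaginary parts taken in the loss-positive
convention. Annealing uses geometric cooling with Gaussian proposals in a
unit-normalised parameter box, followed by an optional derivative-free
simplex polish.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.optimize import minimize

from .models import (
    EPS_0,
    ColeColeParams,
    DielectricSpectrum,
    FrequencyGrid,
    ImprovedColeColeParams,
)

__all__ = [
    "DEFAULT_BOUNDS",
    "FitConfig",
    "FitResult",
    "average_error",
    "r_squared",
    "fit_cole_cole",
    "fit_improved",
]

_PARAM_NAMES_CC = ("eps_inf", "delta_eps", "tau_s", "alpha", "sigma_s")
_PARAM_NAMES_IMPROVED = _PARAM_NAMES_CC + ("a_coef",)

#: Default search box. eps_inf is wider than the 2.4-4.2 tissue-water range
#: because measured lung fits fall below it at large tidal volumes.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "eps_inf": (1.5, 5.0),
    "delta_eps": (0.0, 200.0),
    "tau_s": (0.1e-12, 100e-12),
    "alpha": (0.0, 0.5),
    "sigma_s": (0.0, 1.0),
    "a_coef": (-1e-7, 1e-7),
}


def average_error(measured: DielectricSpectrum, fitted: DielectricSpectrum) -> float:
    """Average fitting error between two spectra, in percent.

    Per-frequency Euclidean norm of the relative errors of the real and loss
    components, averaged over the grid; denominators come from ``fitted``.
    """
    if not np.array_equal(measured.grid.freqs_hz, fitted.grid.freqs_hz):
        raise ValueError("measured and fitted spectra must share the same frequency grid")
    for name, comp in (("real", fitted.eps_real), ("loss", fitted.eps_loss)):
        zero = comp == 0.0
        if np.any(zero):
            f_bad = fitted.grid.freqs_hz[zero][0]
            raise ZeroDivisionError(
                f"fitted {name} component is exactly 0 at f = {f_bad:g} Hz"
            )
    return _err_bar_arrays(
        measured.eps_real, measured.eps_loss, fitted.eps_real, fitted.eps_loss
    )


def _err_bar_arrays(
    m_real: np.ndarray, m_loss: np.ndarray, f_real: np.ndarray, f_loss: np.ndarray
) -> float:
    d = np.hypot((m_real - f_real) / f_real, (m_loss - f_loss) / f_loss)
    return 100.0 * float(np.mean(d))


def r_squared(measured_component: np.ndarray, fitted_component: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot for one spectrum component."""
    m = np.asarray(measured_component, dtype=float)
    f = np.asarray(fitted_component, dtype=float)
    if m.shape != f.shape or m.ndim != 1 or m.size < 2:
        raise ValueError("components must be equal-length 1-D arrays of length >= 2")
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: measured component has zero variance")
    ss_res = float(np.sum((m - f) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class FitConfig:
    """Annealing schedule, search box and reproducibility settings.

    ``initial_temperature=None`` sets T0 to the objective value at the
    starting point of each restart (so the first proposals accept freely).
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    initial_temperature: float | None = None
    cooling_rate: float = 0.95
    iterations_per_temperature: int = 200
    n_restarts: int = 5
    seed: int = 0
    fix_alpha_zero: bool = False
    local_polish: bool = True
    max_evaluations: int = 50_000
    temperature_floor_ratio: float = 1e-6
    step_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling_rate < 1.0:
            raise ValueError("cooling_rate must be in (0, 1)")
        if self.iterations_per_temperature < 1:
            raise ValueError("iterations_per_temperature must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.initial_temperature is not None and not self.initial_temperature > 0:
            raise ValueError("initial_temperature must be positive")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name!r}: lower must be < upper")

    def to_dict(self) -> dict:
        return {
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "initial_temperature": self.initial_temperature,
            "cooling_rate": self.cooling_rate,
            "iterations_per_temperature": self.iterations_per_temperature,
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "fix_alpha_zero": self.fix_alpha_zero,
            "local_polish": self.local_polish,
            "max_evaluations": self.max_evaluations,
            "temperature_floor_ratio": self.temperature_floor_ratio,
            "step_fraction": self.step_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        d = dict(d)
        if "bounds" in d:
            d["bounds"] = {k: tuple(v) for k, v in d["bounds"].items()}
        return cls(**d)


@dataclass(frozen=True)
class FitResult:
    """Best parameters found plus goodness-of-fit and convergence metadata."""

    params: ColeColeParams | ImprovedColeColeParams
    err_bar_pct: float
    r2_real: float
    r2_imag: float
    n_evaluations: int
    seed: int
    converged: bool
    model: str  # "cole_cole" | "improved"

    def to_dict(self) -> dict:
        p = self.params
        pd = {
            "eps_inf": p.eps_inf,
            "delta_eps": p.delta_eps,
            "tau_s": p.tau_s,
            "tau_ps": p.tau_ps,
            "alpha": p.alpha,
            "sigma_s": p.sigma_s,
        }
        if isinstance(p, ImprovedColeColeParams):
            pd["a_coef"] = p.a_coef
        return {
            "model": self.model,
            "params": pd,
            "err_bar_pct": self.err_bar_pct,
            "r2_real": self.r2_real,
            "r2_imag": self.r2_imag,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "converged": self.converged,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# internal machinery


def _forward_components(
    theta: np.ndarray, omega: np.ndarray, improved: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Model real part and loss magnitude for a raw parameter vector."""
    eps_inf, delta_eps, tau_s, alpha, sigma_s = theta[:5]
    with np.errstate(all="ignore"):
        eps = (
            eps_inf
            + delta_eps / (1.0 + (1j * omega * tau_s) ** (1.0 - alpha))
            - 1j * sigma_s / (omega * EPS_0)
        )
        if improved:
            eps = eps + theta[5] * omega
    return eps.real, -eps.imag


class _Objective:
    """Average-error objective over the unit box [0,1]^d; counts evaluations."""

    def __init__(
        self,
        measured: DielectricSpectrum,
        improved: bool,
        bounds: dict[str, tuple[float, float]],
        fix_alpha_zero: bool,
    ):
        self.m_real = measured.eps_real
        self.m_loss = measured.eps_loss
        self.omega = measured.grid.omega
        self.improved = improved
        self.fix_alpha_zero = fix_alpha_zero
        names = _PARAM_NAMES_IMPROVED if improved else _PARAM_NAMES_CC
        self.free_names = tuple(n for n in names if not (fix_alpha_zero and n == "alpha"))
        self.lo = np.array([bounds[n][0] for n in self.free_names])
        self.hi = np.array([bounds[n][1] for n in self.free_names])
        self.n_evaluations = 0

    @property
    def dim(self) -> int:
        return len(self.free_names)

    def theta_from_x(self, x: np.ndarray) -> np.ndarray:
        free = self.lo + np.clip(x, 0.0, 1.0) * (self.hi - self.lo)
        if self.fix_alpha_zero:
            free = np.insert(free, 3, 0.0)  # alpha slot
        return free

    def x_from_theta(self, theta: np.ndarray) -> np.ndarray:
        if self.fix_alpha_zero:
            theta = np.delete(theta, 3)
        return (theta - self.lo) / (self.hi - self.lo)

    def __call__(self, x: np.ndarray) -> float:
        self.n_evaluations += 1
        f_real, f_loss = _forward_components(self.theta_from_x(x), self.omega, self.improved)
        if (
            not (np.all(np.isfinite(f_real)) and np.all(np.isfinite(f_loss)))
            or np.any(f_real == 0.0)
            or np.any(f_loss == 0.0)
        ):
            return math.inf
        return _err_bar_arrays(self.m_real, self.m_loss, f_real, f_loss)


def _anneal(
    objective: _Objective, x0: np.ndarray, rng: np.random.Generator, cfg: FitConfig
) -> tuple[np.ndarray, float, list[float]]:
    """One annealing run from x0.

    Returns the best point, its objective value, and the best-so-far trace
    (one entry per evaluation; non-increasing by construction).
    """
    x = np.clip(x0, 0.0, 1.0)
    fx = objective(x)
    best_x, best_f = x.copy(), fx
    trace = [best_f]
    t0 = cfg.initial_temperature
    if t0 is None:
        t0 = fx if math.isfinite(fx) and fx > 0 else 1.0
    temp = t0
    evals = 1
    while temp > cfg.temperature_floor_ratio * t0 and evals < cfg.max_evaluations:
        scale = cfg.step_fraction * max(temp / t0, 1e-3)
        for _ in range(cfg.iterations_per_temperature):
            if evals >= cfg.max_evaluations:
                break
            prop = np.clip(x + rng.normal(0.0, scale, size=x.shape), 0.0, 1.0)
            fp = objective(prop)
            evals += 1
            delta = fp - fx
            if delta <= 0 or (math.isfinite(fp) and rng.random() < math.exp(-delta / temp)):
                x, fx = prop, fp
                if fx < best_f:
                    best_x, best_f = x.copy(), fx
            trace.append(best_f)
        temp *= cfg.cooling_rate
    return best_x, best_f, trace


def _polish(objective: _Objective, x: np.ndarray, f: float) -> tuple[np.ndarray, float]:
    """Two Nelder-Mead passes in the unit box from the annealing optimum."""
    bounds = [(0.0, 1.0)] * objective.dim
    for _ in range(2):
        res = minimize(
            objective,
            x,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20_000, "maxfev": 20_000},
        )
        if res.fun < f:
            x, f = np.clip(res.x, 0.0, 1.0), float(res.fun)
    return x, f


def _run_fit(
    measured: DielectricSpectrum,
    config: FitConfig,
    improved: bool,
    initial_params: ColeColeParams | ImprovedColeColeParams | None,
) -> FitResult:
    objective = _Objective(measured, improved, config.bounds, config.fix_alpha_zero)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_restarts)

    x_init = None
    if initial_params is not None:
        theta0 = _params_to_theta(initial_params, improved)
        x_init = np.clip(objective.x_from_theta(theta0), 0.0, 1.0)

    best_x: np.ndarray | None = None
    best_f = math.inf
    f_starts = []
    for i, ss in enumerate(seeds):
        rng = np.random.Generator(np.random.PCG64(ss))
        if i == 0 and x_init is not None:
            x0 = x_init
        else:
            x0 = rng.uniform(0.0, 1.0, size=objective.dim)
        f_starts.append(objective(x0))
        x, f, _trace = _anneal(objective, x0, rng, config)
        if config.local_polish:
            x, f = _polish(objective, x, f)
        if f < best_f:  # ties keep the earlier restart
            best_x, best_f = x, f

    def safe_r2(m: np.ndarray, f: np.ndarray) -> float:
        # a flat measured component (zero variance) leaves R^2 undefined
        try:
            return r_squared(m, f)
        except ValueError:
            return math.nan

    theta = objective.theta_from_x(best_x)
    params = _theta_to_params(theta, improved)
    f_real, f_loss = _forward_components(theta, measured.grid.omega, improved)
    return FitResult(
        params=params,
        err_bar_pct=_err_bar_arrays(measured.eps_real, measured.eps_loss, f_real, f_loss),
        r2_real=safe_r2(measured.eps_real, f_real),
        r2_imag=safe_r2(measured.eps_loss, f_loss),
        n_evaluations=objective.n_evaluations,
        seed=config.seed,
        converged=bool(best_f < min(f_starts)),
        model="improved" if improved else "cole_cole",
    )


def _params_to_theta(params, improved: bool) -> np.ndarray:
    vals = [params.eps_inf, params.delta_eps, params.tau_s, params.alpha, params.sigma_s]
    if improved:
        a = params.a_coef if isinstance(params, ImprovedColeColeParams) else 0.0
        vals.append(a)
    return np.array(vals, dtype=float)


def _theta_to_params(theta: np.ndarray, improved: bool):
    base = ColeColeParams(
        eps_inf=float(theta[0]),
        delta_eps=float(theta[1]),
        tau_s=float(theta[2]),
        alpha=float(theta[3]),
        sigma_s=float(theta[4]),
    )
    if improved:
        return ImprovedColeColeParams(base, float(theta[5]))
    return base


def fit_improved(
    measured: DielectricSpectrum,
    config: FitConfig | None = None,
    initial_params: ImprovedColeColeParams | ColeColeParams | None = None,
) -> FitResult:
    """Fit the improved (linear-term) model to a measured spectrum.

    Deterministic given ``config.seed``. If ``initial_params`` is supplied it
    seeds the first restart (Cole-Cole parameters are promoted with a=0).
    """
    return _run_fit(measured, config or FitConfig(), True, initial_params)


def fit_cole_cole(
    measured: DielectricSpectrum,
    config: FitConfig | None = None,
    initial_params: ColeColeParams | None = None,
) -> FitResult:
    """Fit the classical Cole-Cole model to a measured spectrum."""
    return _run_fit(measured, config or FitConfig(), False, initial_params)
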
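"""Forward models for complex relative permittivity of dispersive tissue.

The single-pole Cole-Cole relaxation model and a variant with an extra
linear-in-frequency real term are evaluated on a frequency grid, producing
spectra in a loss-positive convention: the imaginary part of the complex
permittivity is stored as the non-negative magnitude ``eps_loss``.

All frequencies are plain Hz; the models use the angular frequency
``omega = 2*pi*f`` internally (including in the linear term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Vacuum permittivity, F/m (CODATA).
EPS_0: float = 8.8541878128e-12

#: Nominal analysis band, Hz. Grids outside this band warn but are accepted.
BAND_MIN_HZ: float = 1.0e8
BAND_MAX_HZ: float = 1.0e9

__all__ = [
    "EPS_0",
    "BAND_MIN_HZ",
    "BAND_MAX_HZ",
    "FrequencyGrid",
    "DielectricSpectrum",
    "ColeColeParams",
    "ImprovedColeColeParams",
    "ModelEvaluationError",
    "evaluate_cole_cole",
    "evaluate_improved",
    "effective_conductivity",
]


class ModelEvaluationError(ValueError):
    """Raised when a parameter set produces an unphysical or non-finite spectrum."""


@dataclass(frozen=True)
class FrequencyGrid:
    """A strictly increasing grid of positive frequencies in Hz."""

    freqs_hz: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=float)
        object.__setattr__(self, "freqs_hz", f)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(f)):
            raise ValueError("frequency grid contains non-finite values")
        if np.any(f <= 0):
            raise ValueError("all frequencies must be > 0")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if f[0] < BAND_MIN_HZ or f[-1] > BAND_MAX_HZ:
            warnings.warn(
                f"grid [{f[0]:.3g}, {f[-1]:.3g}] Hz extends outside the nominal "
                f"analysis band [{BAND_MIN_HZ:.3g}, {BAND_MAX_HZ:.3g}] Hz",
                UserWarning,
                stacklevel=2,
            )

    def __len__(self) -> int:
        return int(self.freqs_hz.size)

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies, rad/s."""
        return 2.0 * np.pi * self.freqs_hz

    @classmethod
    def default(cls, n_points: int = 101) -> "FrequencyGrid":
        """101 linearly spaced points spanning 100 MHz to 1 GHz inclusive."""
        return cls(np.linspace(BAND_MIN_HZ, BAND_MAX_HZ, n_points))

    @classmethod
    def linear(cls, f_min_hz: float, f_max_hz: float, n_points: int) -> "FrequencyGrid":
        if n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not f_min_hz < f_max_hz:
            raise ValueError("f_min must be < f_max")
        return cls(np.linspace(f_min_hz, f_max_hz, n_points))


@dataclass(frozen=True)
class DielectricSpectrum:
    """Complex relative permittivity sampled on a frequency grid.

    ``eps_real`` is the dielectric constant; ``eps_loss`` is the magnitude of
    the (negative) imaginary part, so the full complex permittivity is
    ``eps_real - 1j * eps_loss``.
    """

    grid: FrequencyGrid
    eps_real: np.ndarray
    eps_loss: np.ndarray

    def __post_init__(self) -> None:
        er = np.asarray(self.eps_real, dtype=float)
        el = np.asarray(self.eps_loss, dtype=float)
        object.__setattr__(self, "eps_real", er)
        object.__setattr__(self, "eps_loss", el)
        n = len(self.grid)
        if er.shape != (n,) or el.shape != (n,):
            raise ValueError("eps_real/eps_loss must match the grid length")
        if not (np.all(np.isfinite(er)) and np.all(np.isfinite(el))):
            raise ValueError("spectrum contains non-finite values")
        if np.any(el < 0):
            raise ValueError("eps_loss must be non-negative (loss-positive convention)")

    def __len__(self) -> int:
        return len(self.grid)

    @property
    def complex_permittivity(self) -> np.ndarray:
        """eps_real - 1j*eps_loss (engineering sign convention)."""
        return self.eps_real - 1j * self.eps_loss


@dataclass(frozen=True)
class ColeColeParams:
    """Single-pole Cole-Cole parameters.

    eps_inf : high-frequency permittivity (dimensionless, > 0)
    delta_eps : dispersion magnitude (dimensionless, >= 0)
    tau_s : relaxation time, seconds (> 0)
    alpha : relaxation-time distribution factor, 0 <= alpha < 1
    sigma_s : static conductivity, S/m (>= 0)
    """

    eps_inf: float
    delta_eps: float
    tau_s: float
    alpha: float
    sigma_s: float

    def __post_init__(self) -> None:
        if not self.eps_inf > 0:
            raise ValueError("eps_inf must be > 0")
        if self.delta_eps < 0:
            raise ValueError("delta_eps must be >= 0")
        if not self.tau_s > 0:
            raise ValueError("tau_s must be > 0")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must be in [0, 1)")
        if self.sigma_s < 0:
            raise ValueError("sigma_s must be >= 0")

    @property
    def tau_ps(self) -> float:
        """Relaxation time in picoseconds (presentation unit)."""
        return self.tau_s * 1e12


@dataclass(frozen=True)
class ImprovedColeColeParams:
    """Cole-Cole parameters plus a linear angular-frequency coefficient.

    ``a_coef`` multiplies omega (rad/s) and adds a purely real contribution
    ``a_coef * omega`` to the permittivity. Physically plausible magnitudes
    are O(1e-9); values above 1e-6 are rejected.
    """

    base: ColeColeParams
    a_coef: float

    A_COEF_MAX_ABS = 1e-6

    def __post_init__(self) -> None:
        if not np.isfinite(self.a_coef):
            raise ValueError("a_coef must be finite")
        if abs(self.a_coef) > self.A_COEF_MAX_ABS:
            raise ValueError(f"|a_coef| must be <= {self.A_COEF_MAX_ABS:g}")

    @classmethod
    def from_values(
        cls,
        eps_inf: float,
        delta_eps: float,
        tau_s: float,
        alpha: float,
        sigma_s: float,
        a_coef: float,
    ) -> "ImprovedColeColeParams":
        return cls(ColeColeParams(eps_inf, delta_eps, tau_s, alpha, sigma_s), a_coef)

    # flat accessors so both parameter types expose the same surface
    @property
    def eps_inf(self) -> float:
        return self.base.eps_inf

    @property
    def delta_eps(self) -> float:
        return self.base.delta_eps

    @property
    def tau_s(self) -> float:
        return self.base.tau_s

    @property
    def tau_ps(self) -> float:
        return self.base.tau_ps

    @property
    def alpha(self) -> float:
        return self.base.alpha

    @property
    def sigma_s(self) -> float:
        return self.base.sigma_s


def _cole_cole_complex(
    eps_inf: float,
    delta_eps: float,
    tau_s: float,
    alpha: float,
    sigma_s: float,
    omega: np.ndarray,
) -> np.ndarray:
    # principal branch of the complex power; reduces to j*omega*tau at alpha=0
    relax = delta_eps / (1.0 + (1j * omega * tau_s) ** (1.0 - alpha))
    conduction = sigma_s / (1j * omega * EPS_0)
    return eps_inf + relax + conduction


def _to_spectrum(eps: np.ndarray, grid: FrequencyGrid, check_real: bool) -> DielectricSpectrum:
    if not np.all(np.isfinite(eps)):
        bad = grid.freqs_hz[~np.isfinite(eps)][0]
        raise ModelEvaluationError(f"non-finite permittivity at f = {bad:g} Hz")
    if check_real and np.any(eps.real <= 0):
        bad = grid.freqs_hz[eps.real <= 0][0]
        raise ModelEvaluationError(f"non-positive real permittivity at f = {bad:g} Hz")
    # physical parameter sets give Im eps <= 0; clamp roundoff noise only
    return DielectricSpectrum(grid, eps.real, np.maximum(-eps.imag, 0.0))


def evaluate_cole_cole(params: ColeColeParams, grid: FrequencyGrid) -> DielectricSpectrum:
    """Evaluate the single-pole Cole-Cole model on ``grid``.

    eps*(omega) = eps_inf + delta_eps / (1 + (j*omega*tau)^(1-alpha))
                  + sigma_s / (j*omega*eps0)
    """
    eps = _cole_cole_complex(
        params.eps_inf, params.delta_eps, params.tau_s, params.alpha, params.sigma_s, grid.omega
    )
    return _to_spectrum(eps, grid, check_real=False)


def evaluate_improved(params: ImprovedColeColeParams, grid: FrequencyGrid) -> DielectricSpectrum:
    """Evaluate the improved model: Cole-Cole plus a real linear term A*omega.

    Raises :class:`ModelEvaluationError` if the real part becomes non-positive
    anywhere on the grid (unphysical parameter combination).
    """
    b = params.base
    eps = _cole_cole_complex(b.eps_inf, b.delta_eps, b.tau_s, b.alpha, b.sigma_s, grid.omega)
    eps = eps + params.a_coef * grid.omega
    return _to_spectrum(eps, grid, check_real=True)


def effective_conductivity(spectrum: DielectricSpectrum) -> np.ndarray:
    """Per-frequency effective conductivity sigma(omega) = omega * eps0 * eps_loss, S/m."""
    return spectrum.grid.omega * EPS_0 * spectrum.eps_loss
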
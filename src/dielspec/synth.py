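"""Synthetic dielectric-spectrum generation across tidal-volume conditions.

Stands in for animal measurements: spectra are produced by the improved
forward model from a packaged tidal-volume parameter table, with independent
multiplicative Gaussian noise per component and per frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    DielectricSpectrum,
    FrequencyGrid,
    ImprovedColeColeParams,
    evaluate_improved,
)

__all__ = [
    "TIDAL_VOLUMES_ML",
    "NoiseModel",
    "TidalVolumeTable",
    "SpectrumRecord",
    "VtDataset",
    "lung_parameter_table",
    "generate_spectrum",
    "generate_vt_dataset",
]

TIDAL_VOLUMES_ML: tuple[int, ...] = (30, 40, 50, 60, 70, 80)

# Fitted lung-tissue parameters by tidal volume (mL):
# (eps_inf, delta_eps, tau in ps, alpha, sigma_s in 1e-3 S/m, a_coef in 1e-9)
_LUNG_TABLE_RAW: dict[int, tuple[float, float, float, float, float, float]] = {
    30: (3.48, 58.52, 6.04, 0.0, 19.96, -3.66),
    40: (3.22, 57.81, 5.91, 0.0, 17.56, -3.74),
    50: (3.63, 58.59, 5.15, 0.0, 10.48, -3.74),
    60: (2.28, 56.43, 4.93, 0.0, 7.90, -3.68),
    70: (3.81, 55.07, 5.31, 0.0, 6.61, -3.82),
    80: (2.13, 54.01, 5.02, 0.0, 4.55, -3.53),
}


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise.

    Each spectrum component value is multiplied by an independent
    ``1 + Normal(0, cv)`` factor; loss values are clipped at zero.
    """

    cv_real: float = 0.02
    cv_loss: float = 0.02
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_real < 0 or self.cv_loss < 0:
            raise ValueError("noise coefficients of variation must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class TidalVolumeTable:
    """Mapping from tidal volume (mL) to improved-model parameters."""

    entries: dict[int, ImprovedColeColeParams]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("table must contain at least one tidal volume")

    def volumes(self) -> tuple[int, ...]:
        return tuple(sorted(self.entries))

    def __getitem__(self, vt_ml: int) -> ImprovedColeColeParams:
        return self.entries[vt_ml]

    def interpolated(self, vt_ml: float) -> ImprovedColeColeParams:
        """Linear-in-VT interpolation of each parameter.

        Extrapolation beyond the tabulated volumes is refused. This is a
        simulation convenience only; intermediate volumes were never measured.
        """
        vts = np.array(self.volumes(), dtype=float)
        if not vts[0] <= vt_ml <= vts[-1]:
            raise ValueError(f"vt_ml={vt_ml} outside tabulated range [{vts[0]}, {vts[-1]}]")
        fields = ["eps_inf", "delta_eps", "tau_s", "alpha", "sigma_s", "a_coef"]
        cols = {
            f: np.array([getattr(self.entries[int(v)], f) for v in vts]) for f in fields
        }
        vals = {f: float(np.interp(vt_ml, vts, cols[f])) for f in fields}
        return ImprovedColeColeParams.from_values(**vals)


def lung_parameter_table() -> TidalVolumeTable:
    """The packaged six-volume lung parameter table (30-80 mL)."""
    entries = {
        vt: ImprovedColeColeParams.from_values(
            eps_inf=ei,
            delta_eps=de,
            tau_s=tau_ps * 1e-12,
            alpha=al,
            sigma_s=sig_m * 1e-3,
            a_coef=a_n * 1e-9,
        )
        for vt, (ei, de, tau_ps, al, sig_m, a_n) in _LUNG_TABLE_RAW.items()
    }
    return TidalVolumeTable(entries)


def _noisy_replicate(
    clean: DielectricSpectrum, noise: NoiseModel, rng: np.random.Generator
) -> DielectricSpectrum:
    real = clean.eps_real * (1.0 + rng.normal(0.0, noise.cv_real, size=len(clean)))
    loss = clean.eps_loss * (1.0 + rng.normal(0.0, noise.cv_loss, size=len(clean)))
    return DielectricSpectrum(clean.grid, real, np.maximum(loss, 0.0))


def generate_spectrum(
    params: ImprovedColeColeParams,
    grid: FrequencyGrid,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> list[DielectricSpectrum]:
    """Generate ``noise.replicates`` noisy spectra from one parameter set.

    Deterministic given ``noise.seed`` (or an explicit ``rng``). Note the
    real-part noise draws for a replicate precede its loss draws.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    clean = evaluate_improved(params, grid)
    return [_noisy_replicate(clean, noise, rng) for _ in range(noise.replicates)]


@dataclass(frozen=True)
class SpectrumRecord:
    """One generated replicate, labelled by condition."""

    vt_ml: int
    replicate: int
    spectrum: DielectricSpectrum
    params: ImprovedColeColeParams


@dataclass(frozen=True)
class VtDataset:
    """Labelled replicate spectra across tidal-volume conditions."""

    records: tuple[SpectrumRecord, ...]
    noise: NoiseModel

    def __len__(self) -> int:
        return len(self.records)

    @property
    def grid(self) -> FrequencyGrid:
        return self.records[0].spectrum.grid

    def volumes(self) -> tuple[int, ...]:
        return tuple(sorted({r.vt_ml for r in self.records}))

    def by_volume(self, vt_ml: int) -> list[SpectrumRecord]:
        return [r for r in self.records if r.vt_ml == vt_ml]


def generate_vt_dataset(
    table: TidalVolumeTable, grid: FrequencyGrid, noise: NoiseModel
) -> VtDataset:
    """One replicate set per tabulated tidal volume, in ascending VT order."""
    rng = np.random.default_rng(noise.seed)
    records: list[SpectrumRecord] = []
    for vt in table.volumes():
        params = table[vt]
        for rep, spec in enumerate(generate_spectrum(params, grid, noise, rng=rng)):
            records.append(SpectrumRecord(vt, rep, spec, params))
    return VtDataset(tuple(records), noise)
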
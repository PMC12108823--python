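"""Plain-text file formats: spectrum CSV, dataset manifests, run configs.

The canonical spectrum file is a CSV with ``# key: value`` comment headers
and columns ``frequency_hz, eps_real, eps_loss`` (or ``conductivity_S_per_m``
in place of the loss column; conversion happens on read). Parameters and
results travel as JSON, run configuration as YAML.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .models import EPS_0, DielectricSpectrum, FrequencyGrid, ImprovedColeColeParams
from .synth import NoiseModel, SpectrumRecord, VtDataset

__all__ = [
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "write_dataset",
    "read_dataset",
    "RunConfig",
    "params_to_dict",
    "params_from_dict",
]

_LOSS_COL = "eps_loss"
_COND_COL = "conductivity_S_per_m"


class SpectrumParseError(ValueError):
    """Malformed spectrum file; message carries the offending line number."""


def write_spectrum(
    path: str | Path,
    spectrum: DielectricSpectrum,
    *,
    loss_as: str = "eps_loss",
    metadata: dict | None = None,
) -> None:
    """Write a spectrum CSV; ``loss_as`` selects the loss or conductivity column."""
    if loss_as not in (_LOSS_COL, "conductivity"):
        raise ValueError("loss_as must be 'eps_loss' or 'conductivity'")
    path = Path(path)
    meta = {"dielspec_version": __version__, "loss_convention": "positive"}
    meta.update(metadata or {})
    with path.open("w", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        writer = csv.writer(fh)
        if loss_as == _LOSS_COL:
            writer.writerow(["frequency_hz", "eps_real", _LOSS_COL])
            third = spectrum.eps_loss
        else:
            writer.writerow(["frequency_hz", "eps_real", _COND_COL])
            third = spectrum.grid.omega * EPS_0 * spectrum.eps_loss
        for f, er, x in zip(spectrum.grid.freqs_hz, spectrum.eps_real, third):
            writer.writerow([repr(float(f)), repr(float(er)), repr(float(x))])


def read_spectrum(path: str | Path) -> DielectricSpectrum:
    """Read a spectrum CSV, converting a conductivity column to loss if present."""
    path = Path(path)
    freqs: list[float] = []
    reals: list[float] = []
    thirds: list[float] = []
    columns: list[str] | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = [c.strip() for c in line.split(",")]
            if columns is None:
                columns = cells
                if len(columns) != 3 or columns[0] != "frequency_hz" or columns[1] != "eps_real":
                    raise SpectrumParseError(
                        f"{path}:{lineno}: expected header "
                        f"'frequency_hz,eps_real,{{{_LOSS_COL}|{_COND_COL}}}', got {line!r}"
                    )
                if columns[2] not in (_LOSS_COL, _COND_COL):
                    raise SpectrumParseError(
                        f"{path}:{lineno}: third column must be {_LOSS_COL} or {_COND_COL}"
                    )
                continue
            if len(cells) != 3:
                raise SpectrumParseError(f"{path}:{lineno}: expected 3 columns, got {len(cells)}")
            try:
                f, er, x = (float(c) for c in cells)
            except ValueError as exc:
                raise SpectrumParseError(f"{path}:{lineno}: {exc}") from None
            if not (math.isfinite(f) and math.isfinite(er) and math.isfinite(x)):
                raise SpectrumParseError(f"{path}:{lineno}: non-finite value")
            if freqs and f <= freqs[-1]:
                raise SpectrumParseError(
                    f"{path}:{lineno}: frequency {f:g} not strictly greater than previous"
                )
            freqs.append(f)
            reals.append(er)
            thirds.append(x)
    if columns is None or not freqs:
        raise SpectrumParseError(f"{path}: no data rows")
    grid = FrequencyGrid(np.asarray(freqs))
    third = np.asarray(thirds)
    loss = third if columns[2] == _LOSS_COL else third / (grid.omega * EPS_0)
    return DielectricSpectrum(grid, np.asarray(reals), loss)


def params_to_dict(params: ImprovedColeColeParams) -> dict:
    return {
        "eps_inf": params.eps_inf,
        "delta_eps": params.delta_eps,
        "tau_s": params.tau_s,
        "alpha": params.alpha,
        "sigma_s": params.sigma_s,
        "a_coef": params.a_coef,
    }


def params_from_dict(d: dict) -> ImprovedColeColeParams:
    return ImprovedColeColeParams.from_values(
        eps_inf=d["eps_inf"],
        delta_eps=d["delta_eps"],
        tau_s=d["tau_s"],
        alpha=d["alpha"],
        sigma_s=d["sigma_s"],
        a_coef=d.get("a_coef", 0.0),
    )


def write_dataset(out_dir: str | Path, dataset: VtDataset) -> Path:
    """Write each replicate as a spectrum CSV plus a manifest.json; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in dataset.records:
        name = f"vt{rec.vt_ml:03d}_rep{rec.replicate}.csv"
        write_spectrum(
            out_dir / name,
            rec.spectrum,
            metadata={"vt_ml": rec.vt_ml, "replicate": rec.replicate},
        )
        entries.append(
            {
                "file": name,
                "vt_ml": rec.vt_ml,
                "replicate": rec.replicate,
                "generator_params": params_to_dict(rec.params),
            }
        )
    manifest = {
        "dielspec_version": __version__,
        "noise": {
            "cv_real": dataset.noise.cv_real,
            "cv_loss": dataset.noise.cv_loss,
            "replicates": dataset.noise.replicates,
            "seed": dataset.noise.seed,
        },
        "spectra": entries,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path


def read_dataset(manifest_path: str | Path) -> VtDataset:
    """Rebuild a labelled dataset from a manifest written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    noise = NoiseModel(**manifest["noise"])
    records = []
    for entry in manifest["spectra"]:
        spec = read_spectrum(manifest_path.parent / entry["file"])
        records.append(
            SpectrumRecord(
                vt_ml=int(entry["vt_ml"]),
                replicate=int(entry["replicate"]),
                spectrum=spec,
                params=params_from_dict(entry["generator_params"]),
            )
        )
    return VtDataset(tuple(records), noise)


@dataclass(frozen=True)
class RunConfig:
    """Resolved run-wide configuration, serialisable to YAML."""

    f_min_hz: float = 1.0e8
    f_max_hz: float = 1.0e9
    n_points: int = 101
    model: str = "improved"  # "cole_cole" | "improved"
    fit: dict = field(default_factory=dict)  # FitConfig overrides
    noise: dict = field(default_factory=dict)  # NoiseModel overrides
    vt_list: tuple[int, ...] = (30, 40, 50, 60, 70, 80)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.f_min_hz < self.f_max_hz:
            raise ValueError("f_min_hz must be < f_max_hz")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.model not in ("cole_cole", "improved"):
            raise ValueError("model must be 'cole_cole' or 'improved'")

    def grid(self) -> FrequencyGrid:
        return FrequencyGrid.linear(self.f_min_hz, self.f_max_hz, self.n_points)

    def to_dict(self) -> dict:
        return {
            "f_min_hz": self.f_min_hz,
            "f_max_hz": self.f_max_hz,
            "n_points": self.n_points,
            "model": self.model,
            "fit": dict(self.fit),
            "noise": dict(self.noise),
            "vt_list": list(self.vt_list),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "vt_list" in d:
            d["vt_list"] = tuple(int(v) for v in d["vt_list"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
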
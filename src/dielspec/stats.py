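"""Nonparametric group comparison of dielectric quantities across conditions.

Observations are replicate-level values of either the dielectric constant or
the effective conductivity, read off at the grid point nearest a requested
frequency (typically the ISM bands 433 and 915 MHz), and compared across
tidal-volume groups with a tie-corrected Kruskal-Wallis test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .models import EPS_0
from .synth import VtDataset

__all__ = [
    "GroupedSamples",
    "GroupComparisonResult",
    "NormalityReport",
    "extract_at_frequency",
    "kruskal_wallis",
    "normality_check",
]

_QUANTITIES = ("permittivity", "conductivity")


@dataclass(frozen=True)
class GroupedSamples:
    """Scalar observations grouped by condition, at one frequency."""

    groups: tuple[tuple[object, np.ndarray], ...]
    quantity: str
    frequency_hz: float
    warning: str | None = None

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        if any(len(obs) == 0 for _, obs in self.groups):
            raise ValueError("every group must be non-empty")
        if self.quantity not in _QUANTITIES:
            raise ValueError(f"quantity must be one of {_QUANTITIES}")


@dataclass(frozen=True)
class GroupComparisonResult:
    h_statistic: float
    df: int
    p_value: float
    tie_corrected: bool

    def to_dict(self) -> dict:
        return {
            "h_statistic": self.h_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "tie_corrected": self.tie_corrected,
        }


def extract_at_frequency(
    dataset: VtDataset, frequency_hz: float, quantity: str
) -> GroupedSamples:
    """One observation per replicate per tidal volume, at the nearest grid point.

    The grid point closest to ``frequency_hz`` is used (no interpolation). If
    it lies farther away than half the local grid spacing — i.e. the request
    is outside the grid — a warning string is recorded on the output.
    """
    if quantity not in _QUANTITIES:
        raise ValueError(f"quantity must be one of {_QUANTITIES}")
    freqs = dataset.grid.freqs_hz
    idx = int(np.argmin(np.abs(freqs - frequency_hz)))
    selected = freqs[idx]
    spacing = np.diff(freqs)
    local = spacing[min(idx, len(spacing) - 1)]
    warning = None
    if abs(selected - frequency_hz) > 0.5 * local:
        warning = (
            f"requested {frequency_hz:g} Hz is {abs(selected - frequency_hz):g} Hz from "
            f"the nearest grid point {selected:g} Hz (grid spacing {local:g} Hz)"
        )

    groups = []
    for vt in dataset.volumes():
        obs = []
        for rec in dataset.by_volume(vt):
            s = rec.spectrum
            if quantity == "permittivity":
                obs.append(s.eps_real[idx])
            else:
                obs.append(2.0 * np.pi * selected * EPS_0 * s.eps_loss[idx])
        groups.append((vt, np.asarray(obs, dtype=float)))
    return GroupedSamples(tuple(groups), quantity, float(selected), warning)


def kruskal_wallis(samples: GroupedSamples) -> GroupComparisonResult:
    """Tie-corrected Kruskal-Wallis H test with the chi-square approximation.

    Midranks are used for ties. A fully tied sample (zero rank variance)
    degenerates to H = 0, p = 1.
    """
    observations = [np.asarray(obs, dtype=float) for _, obs in samples.groups]
    k = len(observations)
    sizes = np.array([len(o) for o in observations])
    n_total = int(sizes.sum())
    if n_total < k + 1:
        raise ValueError("need at least one group with more than one observation")

    pooled = np.concatenate(observations)
    ranks = sps.rankdata(pooled)  # midranks
    h = 12.0 / (n_total * (n_total + 1))
    offset = 0
    rank_sum_term = 0.0
    for n_i in sizes:
        r_i = ranks[offset : offset + n_i].sum()
        rank_sum_term += r_i**2 / n_i
        offset += n_i
    h = h * rank_sum_term - 3.0 * (n_total + 1)

    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n_total**3 - n_total)
    if correction == 0.0:  # every observation identical
        return GroupComparisonResult(0.0, k - 1, 1.0, True)
    h /= correction
    h = max(h, 0.0)  # guard roundoff
    p = float(sps.chi2.sf(h, df=k - 1))
    return GroupComparisonResult(float(h), k - 1, p, True)


@dataclass(frozen=True)
class NormalityReport:
    """Composite normality test plus the matching descriptive summary."""

    statistic: float
    p_value: float
    normal_consistent: bool
    summary: dict

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "normal_consistent": self.normal_consistent,
            "summary": self.summary,
        }


def normality_check(samples: np.ndarray, alpha: float = 0.05) -> NormalityReport:
    """Shapiro-Wilk normality check steering the descriptive summary.

    Normal-consistent data are summarised by mean and SD; otherwise by median
    and quartiles. Constant samples are rejected as degenerate input.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need a 1-D sample with n >= 3")
    if np.ptp(x) == 0.0:
        raise ValueError("normality test undefined for a constant sample")
    stat, p = sps.shapiro(x)
    normal = bool(p > alpha)
    if normal:
        summary = {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
    else:
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        summary = {"median": float(med), "q1": float(q1), "q3": float(q3)}
    return NormalityReport(float(stat), float(p), normal, summary)
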
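"""Methylation-index (MI) quantification.

Two estimators of the fraction of methylated molecules at a CpG unit:

* from an Epityper-style mass-spectrometric peak pair,
  ``MI = methylated / (methylated + unmethylated)`` peak heights;
* from a bisulfite-sequencing clone matrix,
  ``MI = methylated clones / total clones`` at a given CpG site.

A CpG *unit* is one or more CpG sites reported as a single integral
measurement by the mass-spectrometric assay; its MI is carried as one
scalar and is never disaggregated per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "UndefinedMeasurementError",
    "EpityperPeakPair",
    "BisulfiteCloneMatrix",
    "mi_from_peaks",
    "mi_from_clones",
]


class UndefinedMeasurementError(ValueError):
    """Raised when an MI cannot be computed (e.g. both peaks are zero)."""


@dataclass(frozen=True)
class EpityperPeakPair:
    """Heights of the methylated and unmethylated mass peaks of one CpG unit."""

    methylated_peak: float
    unmethylated_peak: float

    def __post_init__(self) -> None:
        for name in ("methylated_peak", "unmethylated_peak"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")


def mi_from_peaks(peaks: EpityperPeakPair, noise_floor: float = 0.0) -> float:
    """MI from a peak pair; peaks below ``noise_floor`` are zeroed first.

    Raises :class:`UndefinedMeasurementError` if no signal remains.
    """
    if noise_floor < 0:
        raise ValueError("noise_floor must be nonnegative")
    meth = peaks.methylated_peak if peaks.methylated_peak >= noise_floor else 0.0
    unmeth = peaks.unmethylated_peak if peaks.unmethylated_peak >= noise_floor else 0.0
    total = meth + unmeth
    if total <= 0:
        raise UndefinedMeasurementError("both peaks are zero (or below the noise floor)")
    return meth / total


class BisulfiteCloneMatrix:
    """Clones x CpG-sites methylation calls from bisulfite sequencing.

    Rows are randomly picked sequenced clones (single molecules), columns
    CpG sites; ``True`` means the site was scored methylated in that
    clone.  ``site_positions`` are 1-based chromosomal coordinates.
    """

    def __init__(self, calls, site_positions=None) -> None:
        arr = np.asarray(calls)
        if arr.ndim != 2:
            raise ValueError("clone matrix must be two-dimensional")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("clone matrix needs at least one clone and one site")
        if arr.dtype != bool:
            if not np.isin(arr, (0, 1)).all():
                raise ValueError("clone calls must be boolean or 0/1")
            arr = arr.astype(bool)
        self.calls = arr
        if site_positions is None:
            site_positions = tuple(range(1, arr.shape[1] + 1))
        self.site_positions = tuple(int(p) for p in site_positions)
        if len(self.site_positions) != arr.shape[1]:
            raise ValueError("need one site position per column")

    @property
    def n_clones(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BisulfiteCloneMatrix):
            return NotImplemented
        return (
            self.site_positions == other.site_positions
            and np.array_equal(self.calls, other.calls)
        )


def mi_from_clones(matrix: BisulfiteCloneMatrix, site_index: int) -> float:
    """MI at one CpG site: methylated clones over total clones sequenced."""
    if not 0 <= site_index < matrix.n_sites:
        raise IndexError(f"site_index {site_index} out of range for {matrix.n_sites} sites")
    return float(matrix.calls[:, site_index].mean())
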
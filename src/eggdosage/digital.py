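"""Digital PCR: well partitioning and Poisson-corrected counting.

A DNA sample is diluted and distributed across the wells of a plate; a
well is positive if it received at least one template.  With templates
Poisson-distributed at mean ``m`` per well, the positive fraction is
``p = 1 - exp(-m)``, so the plug-in maximum-likelihood estimate from a
plate is ``m = -ln(1 - positives/wells)`` and the absolute molecule
count is ``m * wells`` — direct counting of positive wells followed by
Poisson correction.  The classic design point dilutes to about one
template per two wells (m = 0.5); cohort samples are diluted to a
common *reference-marker* concentration so that the chr18/chrY dosage
ratio is compared at matched counting precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seed import child_rng
from .pools import MoleculePool

__all__ = [
    "SaturationError",
    "UnanalyzableSampleError",
    "DigitalPlateResult",
    "PoissonEstimate",
    "poisson_correct",
    "simulate_plate",
    "dilute_to_reference",
]


class SaturationError(ValueError):
    """All wells positive: the Poisson estimate diverges; re-dilute the sample."""


class UnanalyzableSampleError(ValueError):
    """Sample cannot enter dosage analysis (e.g. no reference-marker molecules)."""


@dataclass(frozen=True)
class DigitalPlateResult:
    """Positive-well count of one digital PCR assay on one plate."""

    assay: str
    wells_total: int
    wells_positive: int

    def __post_init__(self) -> None:
        if self.wells_total < 1:
            raise ValueError("wells_total must be >= 1")
        if not 0 <= self.wells_positive <= self.wells_total:
            raise ValueError("wells_positive must lie in [0, wells_total]")


@dataclass(frozen=True)
class PoissonEstimate:
    """Average templates per well (m) and the implied absolute molecule count."""

    m: float
    molecules: float


def poisson_correct(plate: DigitalPlateResult) -> PoissonEstimate:
    """Poisson-corrected absolute count from a positive-well count.

    ``m = -ln(1 - positives/wells)``; ``molecules = m * wells``.  A
    fully positive plate is saturated and raises :class:`SaturationError`
    (the sample must be re-diluted).
    """
    if plate.wells_positive == plate.wells_total:
        raise SaturationError(
            f"{plate.assay}: all {plate.wells_total} wells positive; re-dilute and repeat"
        )
    fraction = plate.wells_positive / plate.wells_total
    m = -math.log1p(-fraction)
    return PoissonEstimate(m=m, molecules=m * plate.wells_total)


def simulate_plate(
    m_true: float, wells_total: int, seed: int, assay: str = "assay"
) -> DigitalPlateResult:
    """Simulate one plate: per-well template counts ~ Poisson(``m_true``).

    A well is positive iff it received >= 1 template; deterministic
    given ``seed``.
    """
    if m_true < 0:
        raise ValueError("m_true must be nonnegative")
    if wells_total < 1:
        raise ValueError("wells_total must be >= 1")
    rng = child_rng(seed, "digital-plate", assay)
    counts = rng.poisson(m_true, size=wells_total)
    return DigitalPlateResult(assay, wells_total, int(np.count_nonzero(counts)))


def dilute_to_reference(
    pool: MoleculePool,
    reference_marker: str,
    target_m: float,
    wells_total: int,
    max_factor: float | None = None,
) -> tuple[MoleculePool, float]:
    """Scale a pool so the reference marker averages ``target_m`` per well.

    Every marker is scaled by the same factor, so dosage ratios are
    preserved.  ``max_factor`` caps the factor (pass 1.0 to forbid
    concentrating a sample that is already below target).  A pool with
    no reference-marker molecules cannot be normalized and raises
    :class:`UnanalyzableSampleError`.
    """
    if target_m <= 0:
        raise ValueError("target_m must be positive")
    if wells_total < 1:
        raise ValueError("wells_total must be >= 1")
    reference_count = pool.total(reference_marker)
    if reference_count <= 0:
        raise UnanalyzableSampleError(
            f"no {reference_marker} molecules; sample cannot be dosage-analyzed"
        )
    factor = target_m * wells_total / reference_count
    if max_factor is not None:
        factor = min(factor, max_factor)
    return pool.scaled(factor), factor
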
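"""Methylation-sensitive digestion and conventional qPCR readout.

HpaII and HinP1I cut their recognition site only when its CpG is
unmethylated.  A template molecule yields an amplifiable PCR signal only
if *no* site within the amplicon was cut, i.e. (at complete digestion)
only if it is methylated at every site — 5 sites for the chr18 marker,
4 for the beta-actin digestion control, 0 for ZFY, which passes through
untouched.  Cuts at distinct unmethylated sites are independent
Bernoulli events with probability ``efficiency``, so the expected
surviving fraction of a molecule with u unmethylated sites is
``(1 - efficiency)^u``.  Digestion is treated as complete by default
(efficiency 1) and the beta-actin control enforces that assumption;
mock digestion (glycerol instead of enzyme) is efficiency 0.

qPCR copy numbers are converted from quantification cycles through a
log-linear calibration curve and censored (not zeroed) below the limit
of detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from numbers import Integral

import numpy as np

from ._seed import child_rng
from .pools import ACTB, AMPLICON_SITE_COUNT, MoleculePool

__all__ = [
    "DigestionConfig",
    "CalibrationCurve",
    "QpcrResult",
    "ControlReport",
    "digest",
    "amplifiable_count",
    "copies_from_cq",
    "cq_from_copies",
    "digestion_controls",
]


@dataclass(frozen=True)
class DigestionConfig:
    """Digestion with a set of methylation-sensitive enzymes.

    ``efficiency`` is the probability that any one unmethylated site is
    cut; 1.0 models the complete digestion the controls enforce, 0.0 a
    mock digestion.
    """

    enzymes: tuple[str, ...] = ("HpaII", "HinP1I")
    efficiency: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        allowed = {"HpaII", "HinP1I"}
        unknown = set(self.enzymes) - allowed
        if unknown:
            raise ValueError(f"unknown enzymes: {sorted(unknown)}")
        if not (0.0 <= self.efficiency <= 1.0):
            raise ValueError("efficiency must lie in [0, 1]")


def digest(pool: MoleculePool, config: DigestionConfig) -> MoleculePool:
    """Digest a molecule pool; a molecule survives iff no site is cut.

    Methylated sites are never cut; each unmethylated site is cut
    independently with probability ``config.efficiency``.  Markers whose
    amplicon spans no enzyme site (ZFY) pass through unchanged.  At
    efficiency 0 or 1 the outcome is deterministic; in between,
    survivor numbers are Binomial(count, (1-efficiency)^u) draws seeded
    from ``config.seed`` (or deterministic expectations for non-integer
    counts, which only arise after in-silico dilution).
    """
    eff = config.efficiency
    rng = child_rng(config.seed, "digestion")
    out = MoleculePool()
    for (marker, origin, pattern), count in pool.entries.items():
        u = sum(1 for methylated in pattern if not methylated)
        if u == 0 or eff == 0.0:
            survivors = count
        elif eff == 1.0:
            survivors = 0
        else:
            p_survive = (1.0 - eff) ** u
            if isinstance(count, Integral) or float(count).is_integer():
                survivors = int(rng.binomial(int(count), p_survive))
            else:
                survivors = count * p_survive
        if survivors:
            out.add(marker, origin, pattern, survivors)
    return out


def amplifiable_count(pool: MoleculePool, marker: str) -> float:
    """Total surviving molecules of one marker, regardless of origin."""
    return pool.total(marker)


@dataclass(frozen=True)
class CalibrationCurve:
    """qPCR standard curve: Cq = intercept + slope * log10(copies).

    ``intercept`` is the Cq at one copy; ``slope`` is negative (about
    -3.3 Cq per decade at 100% amplification efficiency; the study's
    assays ran at -3.77 and -3.53).  ``lod_copies`` is the limit of
    detection below which signals are reported undetectable.
    """

    slope: float
    intercept: float
    lod_copies: float = 3.0

    def __post_init__(self) -> None:
        if not self.slope < 0:
            raise ValueError("calibration slope must be negative")
        if self.lod_copies < 1:
            raise ValueError("lod_copies must be >= 1")


@dataclass(frozen=True)
class QpcrResult:
    """A qPCR quantification: copy number plus detectability flag.

    Below-LOD measurements keep their copy estimate for diagnostics but
    are flagged undetectable.
    """

    copies: float
    detectable: bool


def copies_from_cq(cq: float, curve: CalibrationCurve) -> QpcrResult:
    """Copy number from a quantification cycle via the standard curve."""
    if not math.isfinite(cq):
        raise ValueError("cq must be finite")
    copies = 10.0 ** ((cq - curve.intercept) / curve.slope)
    return QpcrResult(copies=copies, detectable=copies >= curve.lod_copies)


def cq_from_copies(copies: float, curve: CalibrationCurve) -> float:
    """Inverse of :func:`copies_from_cq`; requires a positive copy number."""
    if copies <= 0:
        raise ValueError("copies must be positive (zero copies give no signal)")
    return curve.intercept + curve.slope * math.log10(copies)


@dataclass(frozen=True)
class ControlReport:
    """Outcome of the per-sample digestion/extraction controls."""

    actb_after_digestion: float
    total_before_digestion: float
    passed: bool
    reason: str


def digestion_controls(pre_pool: MoleculePool, post_pool: MoleculePool) -> ControlReport:
    """Check complete digestion and successful extraction for one sample.

    PASS iff the completely-unmethylated beta-actin target is fully
    removed by digestion (amplifiable count 0 afterwards) and the
    pre-digestion aliquot contained detectable DNA at all.  Failing
    samples are excluded from downstream dosage analysis.
    """
    actb_after = amplifiable_count(post_pool, ACTB)
    total_before = pre_pool.total_molecules()
    if total_before <= 0:
        return ControlReport(actb_after, total_before, False, "no DNA before digestion (extraction failure)")
    if actb_after > 0:
        return ControlReport(actb_after, total_before, False, "beta-actin signal after digestion (incomplete digestion)")
    return ControlReport(actb_after, total_before, True, "ok")
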
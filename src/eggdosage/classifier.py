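"""EGG dosage ratio, euploid reference interval, and classification.

The epigenetic-genetic (EGG) ratio of a plasma sample is the
Poisson-corrected count of digestion-resistant chr18-marker molecules
over the count of ZFY (chrY reference) molecules.  Both species are
fetal-specific in maternal plasma, so the ratio tracks the fetal
chr18 : chrY copy ratio — about 2 : 1 for a euploid male fetus and
3 : 1 (a 1.5-fold increase) for trisomy 18.

Classification uses a reference interval built from euploid pregnancies
as mean ± 1.96 SD of their raw ratios; a sample is called trisomy 18
when its ratio is strictly above the upper bound.  Ratios below the
lower bound are a QC signal but are classified negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .digital import UnanalyzableSampleError
from .stats import TestResult, wilcoxon_signed_rank
from .synthetic import EUPLOID, TRISOMY18

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "EggResult",
    "ReferenceInterval",
    "PerformanceReport",
    "egg_ratio",
    "reference_interval",
    "classify",
    "evaluate",
    "clearance_test",
]

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class EggResult:
    """Per-sample corrected molecule counts and chr18/chrY dosage ratio."""

    sample_id: str
    vapa_molecules: float
    zfy_molecules: float
    ratio: float


def egg_ratio(vapa: float, zfy: float, sample_id: str = "") -> EggResult:
    """EGG ratio of digestion-resistant chr18-marker to ZFY molecules.

    A sample without ZFY molecules (female fetus or assay failure) is
    unanalyzable: the ratio is never coerced to zero or infinity.
    """
    if vapa < 0 or zfy < 0:
        raise ValueError("molecule counts must be nonnegative")
    if zfy == 0:
        raise UnanalyzableSampleError(
            f"sample {sample_id or '<unnamed>'}: no ZFY molecules "
            "(female fetus or assay failure)"
        )
    return EggResult(sample_id, vapa, zfy, vapa / zfy)


@dataclass(frozen=True)
class ReferenceInterval:
    """Euploid mean and SD of the EGG ratio; bounds are mean ± z·SD.

    With ``scale='log'`` the mean/SD describe ln-ratios and the bounds
    are exponentiated back to ratio scale (off by default: the study's
    construction is symmetric on raw ratios).
    """

    mean: float
    sd: float
    z: float = 1.96
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.scale not in ("linear", "log"):
            raise ValueError("scale must be 'linear' or 'log'")

    @property
    def lower(self) -> float:
        lo = self.mean - self.z * self.sd
        return math.exp(lo) if self.scale == "log" else lo

    @property
    def upper(self) -> float:
        hi = self.mean + self.z * self.sd
        return math.exp(hi) if self.scale == "log" else hi


def reference_interval(
    euploid_ratios: Sequence[float], z: float = 1.96, log_scale: bool = False
) -> ReferenceInterval:
    """Mean ± z·SD reference interval from euploid-cohort ratios.

    SD uses the n-1 denominator; at least two ratios are required.
    """
    ratios = np.asarray(euploid_ratios, dtype=float)
    if len(ratios) < 2:
        raise ValueError("need at least 2 euploid ratios to build a reference interval")
    if not np.all(np.isfinite(ratios)):
        raise ValueError("ratios must be finite")
    values = np.log(ratios) if log_scale else ratios
    return ReferenceInterval(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        z=z,
        scale="log" if log_scale else "linear",
    )


def classify(result: "EggResult | float", interval: ReferenceInterval) -> str:
    """Call trisomy 18 iff the ratio is strictly above the upper bound."""
    ratio = result.ratio if isinstance(result, EggResult) else float(result)
    if not math.isfinite(ratio):
        raise ValueError("ratio must be finite")
    return POSITIVE if ratio > interval.upper else NEGATIVE


@dataclass(frozen=True)
class PerformanceReport:
    """Confusion counts against karyotype truth, with derived rates."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def sensitivity(self) -> float:
        """tp / (tp + fn); NaN when no affected samples were evaluated."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def specificity(self) -> float:
        """tn / (tn + fp); NaN when no unaffected samples were evaluated."""
        denom = self.tn + self.fp
        return self.tn / denom if denom else math.nan


def evaluate(predictions: Sequence[str], truth: Sequence[str]) -> PerformanceReport:
    """Confusion counts of positive/negative calls against ploidy truth.

    ``predictions`` contains ``positive``/``negative`` labels,
    ``truth`` contains ``trisomy18``/``euploid``, aligned per sample.
    """
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must be aligned and equal length")
    tp = fp = tn = fn = 0
    for pred, true in zip(predictions, truth):
        if pred not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown prediction label {pred!r}")
        if true not in (TRISOMY18, EUPLOID):
            raise ValueError(f"unknown truth label {true!r}")
        if true == TRISOMY18:
            tp += pred == POSITIVE
            fn += pred == NEGATIVE
        else:
            fp += pred == POSITIVE
            tn += pred == NEGATIVE
    return PerformanceReport(tp=tp, fp=fp, tn=tn, fn=fn)


def clearance_test(
    pre_delivery: Sequence[float], post_delivery: Sequence[float]
) -> TestResult:
    """Wilcoxon signed-rank comparison of paired pre/post-delivery levels.

    Tests whether the marker is cleared from maternal plasma after
    delivery (fetal specificity).  Exact enumeration up to 15 informative
    pairs; requires at least 5 pairs.
    """
    if len(pre_delivery) != len(post_delivery):
        raise ValueError("pre- and post-delivery samples must be paired")
    if len(pre_delivery) < 5:
        raise ValueError("need at least 5 pairs")
    return wilcoxon_signed_rank(pre_delivery, post_delivery)
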
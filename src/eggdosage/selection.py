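"""Marker-selection cascade.

From a panel of candidate CpG units measured in placenta and maternal
blood cells down to a single marker region, in four steps:

1. **Tissue contrast criteria** — keep units with blood MI <= 0.20
   (criterion #1) and placenta-minus-blood MI difference >= 0.50
   (criterion #2); both comparisons inclusive.  Low blood methylation
   lets enzyme digestion remove the maternal background; a large
   placental excess makes the surviving signal fetal-specific.
2. **Inter-individual stability** — rank assays by the median
   coefficient of variation (sample SD / mean, per unit) of placental
   MI across individuals and keep the most stable assays; a dosage
   ratio built on an unstable marker would be useless.
3. **Ploidy independence** — confirm (Mann-Whitney) that placental
   methylation does not differ between euploid and trisomy-18 samples,
   so the epigenetic signal reflects copy number, not methylation shift.
4. **Enzyme-site density** — scan candidate regions for HpaII (CCGG)
   and HinP1I (GCGC) recognition sites and choose the region with the
   most sites near it: more methylation-sensitive sites means more
   complete removal of unmethylated maternal DNA.

Tissue summaries use the median across samples, which is robust and
coincides with the mean at the two-sample screening stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, mann_whitney_u
from .synthetic import MATERNAL_BLOOD, PLACENTA

__all__ = [
    "SelectionCriteria",
    "AssayRegion",
    "EnzymeSite",
    "RegionCandidate",
    "ENZYME_MOTIFS",
    "apply_criteria",
    "rank_assays_by_cv",
    "compare_ploidy_groups",
    "scan_enzyme_sites",
    "count_sites_near_region",
    "select_marker",
]

ENZYME_MOTIFS = {"HpaII": "CCGG", "HinP1I": "GCGC"}


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the two tissue-contrast criteria (inclusive)."""

    mi_blood_max: float = 0.20
    mi_diff_min: float = 0.50

    def __post_init__(self) -> None:
        for name in ("mi_blood_max", "mi_diff_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class AssayRegion:
    """A genomic region spanned by one quantitative methylation assay.

    ``start``/``end`` are 1-based inclusive (UCSC text convention).
    """

    assay_id: str
    locus_id: str
    chrom: str
    start: int
    end: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.assay_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class EnzymeSite:
    """One methylation-sensitive enzyme recognition site (0-based motif start)."""

    enzyme: str
    position: int
    motif: str

    def __post_init__(self) -> None:
        expected = ENZYME_MOTIFS.get(self.enzyme)
        if expected is None:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if self.motif != expected:
            raise ValueError(f"{self.enzyme} motif must be {expected}, got {self.motif}")


def _tissue_summaries(measurements: pd.DataFrame) -> pd.DataFrame:
    required = {"tissue", "locus_id", "unit_id", "mi"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns: {sorted(missing)}")
    summary = (
        measurements.groupby(["locus_id", "unit_id", "tissue"], sort=True)["mi"]
        .median()
        .unstack("tissue")
    )
    return summary


def apply_criteria(
    measurements: pd.DataFrame, criteria: SelectionCriteria = SelectionCriteria()
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag CpG units passing both tissue-contrast criteria.

    ``measurements`` holds one row per (sample, unit) with columns
    ``tissue`` (``placenta`` / ``maternal_blood_cells``), ``locus_id``,
    ``unit_id`` and ``mi``.  Per-unit tissue summaries are medians
    across that tissue's samples.  A unit passes iff
    ``blood <= mi_blood_max`` and ``placenta - blood >= mi_diff_min``.
    Units measured in only one tissue are flagged unevaluable and
    excluded from the per-locus counts.

    Returns ``(unit_table, locus_counts)`` where ``unit_table`` has one
    row per unit (``blood_mi``, ``placenta_mi``, ``evaluable``,
    ``passes``) and ``locus_counts`` counts passing units per locus
    (loci with no passing unit omitted).
    """
    summary = _tissue_summaries(measurements)
    for tissue in (PLACENTA, MATERNAL_BLOOD):
        if tissue not in summary.columns:
            summary[tissue] = np.nan
    table = pd.DataFrame(
        {
            "blood_mi": summary[MATERNAL_BLOOD],
            "placenta_mi": summary[PLACENTA],
        }
    )
    table["evaluable"] = table["blood_mi"].notna() & table["placenta_mi"].notna()
    # inclusive thresholds; epsilon keeps boundary cases like 0.7 - 0.2 >= 0.5
    # from failing on float rounding
    eps = 1e-12
    table["passes"] = (
        table["evaluable"]
        & (table["blood_mi"] <= criteria.mi_blood_max + eps)
        & ((table["placenta_mi"] - table["blood_mi"]) >= criteria.mi_diff_min - eps)
    )
    counts = (
        table[table["passes"]].groupby(level="locus_id").size().astype(int)
    )
    counts.name = "passing_units"
    return table.reset_index(), counts


def rank_assays_by_cv(
    placenta_panel: pd.DataFrame, k: int = 4
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Rank assays by median inter-individual CV of placental MI.

    ``placenta_panel`` has one row per (placenta sample, unit) with an
    ``assay_id`` column (falling back to ``locus_id`` if absent).  The
    per-unit CV is sample SD (n-1 denominator) over mean across
    samples; each assay's score is the median CV of its units.  Units
    with mean MI of 0 have no defined CV and are dropped with a warning.

    Returns ``(unit_cv_table, assay_median_cv_sorted, top_k_assay_ids)``.
    """
    panel = placenta_panel.copy()
    if "assay_id" not in panel.columns:
        panel["assay_id"] = panel["locus_id"]
    grouped = panel.groupby(["assay_id", "unit_id"], sort=True)["mi"]
    n_samples = grouped.size()
    if (n_samples < 2).any():
        bad = n_samples[n_samples < 2].index.tolist()
        raise ValueError(f"need >= 2 placenta samples per unit; offending units: {bad}")
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    zero_mean = means == 0
    if zero_mean.any():
        warnings.warn(
            f"{int(zero_mean.sum())} unit(s) with mean MI = 0 excluded from CV ranking",
            stacklevel=2,
        )
    cv = (sds / means)[~zero_mean]
    unit_cv = cv.rename("cv").reset_index()
    assay_cv = cv.groupby(level="assay_id").median().sort_values(kind="stable")
    assay_cv.name = "median_cv"
    top = list(assay_cv.index[:k])
    return unit_cv, assay_cv, top


def compare_ploidy_groups(
    euploid: pd.DataFrame, trisomy: pd.DataFrame
) -> pd.DataFrame:
    """Per-unit two-sided Mann-Whitney comparison of placental MI.

    Both tables hold one row per (sample, unit) with ``unit_id`` and
    ``mi``.  Units with fewer than two samples in either group are
    excluded with a warning.  All values tied across both groups give
    p = 1 by convention.
    """
    rows = []
    eu_groups = dict(tuple(euploid.groupby("unit_id")["mi"]))
    tr_groups = dict(tuple(trisomy.groupby("unit_id")["mi"]))
    for unit_id in sorted(set(eu_groups) | set(tr_groups)):
        eu = eu_groups.get(unit_id)
        tr = tr_groups.get(unit_id)
        if eu is None or tr is None or len(eu) < 2 or len(tr) < 2:
            warnings.warn(
                f"unit {unit_id}: fewer than 2 samples per ploidy group; excluded",
                stacklevel=2,
            )
            continue
        result: TestResult = mann_whitney_u(eu.to_numpy(), tr.to_numpy())
        rows.append({"unit_id": unit_id, "u": result.statistic, "p": result.pvalue})
    return pd.DataFrame(rows, columns=["unit_id", "u", "p"])


def scan_enzyme_sites(sequence: str) -> list[EnzymeSite]:
    """All HpaII (CCGG) and HinP1I (GCGC) sites in a sequence.

    Single-strand scan (both motifs are their own reverse complements),
    overlapping matches included, positions 0-based.  The sequence must
    be over {A, C, G, T, N}; N never matches a motif.
    """
    seq = sequence.upper()
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"sequence contains invalid characters: {sorted(invalid)}")
    sites: list[EnzymeSite] = []
    for i in range(len(seq) - 3):
        window = seq[i : i + 4]
        for enzyme, motif in ENZYME_MOTIFS.items():
            if window == motif:
                sites.append(EnzymeSite(enzyme, i, motif))
    sites.sort(key=lambda s: (s.position, s.enzyme))
    return sites


def count_sites_near_region(
    region: AssayRegion, sites: Iterable[EnzymeSite], window: int = 100
) -> int:
    """Sites whose motif start lies within the region extended by ``window`` bp.

    Caller must supply sites in the same coordinate frame as the region
    (the scanner's 0-based offsets need a +1 shift against a 1-based
    region).
    """
    if window < 0:
        raise ValueError("window must be nonnegative")
    lo, hi = region.start - window, region.end + window
    return sum(1 for s in sites if lo <= s.position <= hi)


@dataclass(frozen=True)
class RegionCandidate:
    """A candidate marker region with its enzyme-site count and stability score."""

    region: AssayRegion
    site_count: int
    median_cv: float | None = None


def select_marker(candidates: Sequence[RegionCandidate]) -> AssayRegion:
    """Region with the most enzyme sites; more sites remove maternal DNA better.

    Ties are broken by the lowest median CV, then lexically by assay id.
    """
    if not candidates:
        raise ValueError("no candidate regions supplied")
    def sort_key(c: RegionCandidate):
        cv = c.median_cv if c.median_cv is not None else float("inf")
        return (-c.site_count, cv, c.region.assay_id)
    return min(candidates, key=sort_key).region
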
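"""Default synthetic study design.

The clinical study's raw measurements are not distributed with the
package, so the analysis drivers, tests and acceptance checks run on a
synthetic study built here with the same structure:

* a 370-CpG-unit screening panel across 26 candidate loci, of which a
  known planted subset of 40 units in 8 loci (19/5/4/4/3/2/2/1 per
  locus) passes the two tissue-contrast criteria;
* six quantitative methylation assays over the five most promising
  loci, with median inter-individual CVs spanning roughly 8–38%;
* four candidate marker regions whose sequences carry 5, 3, 1 and 1
  planted HpaII/HinP1I sites within 100 bp of the assayed region (plus
  decoy sites outside the window), so the enzyme-site scan selects the
  first chr18 intergenic region;
* the default plasma cohort of 27 euploid and 9 trisomy-18 male-fetus
  pregnancies (:class:`~eggdosage.synthetic.PlasmaCohortConfig`).

Everything is deterministic given a seed, and the planted truth is
returned alongside the generated data so recovery can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .selection import AssayRegion, EnzymeSite
from .synthetic import TissueMethylationModel, generate_marker_sequence, generate_tissue_panel

__all__ = [
    "PASSING_UNITS_PER_LOCUS",
    "ASSAY_CV_TARGETS",
    "MarkerRegionDesign",
    "screening_models",
    "cv_assay_models",
    "marker_region_designs",
    "screening_panel",
    "cv_panel",
]

#: Planted criteria-passing unit counts per locus (40 units in 8 loci).
PASSING_UNITS_PER_LOCUS = {
    "MAT.18.0094": 19,
    "MAT.18.0071": 5,
    "MAT.18.0097": 4,
    "MAT.18.0096": 4,
    "TAS.18.1887": 3,
    "TAS.18.0841": 2,
    "MAT.18.0098": 2,
    "TAS.18.0675": 1,
}

#: Six assays over the five most promising loci; target median CV of
#: placental MI across individuals (the observed range was ~8%–38%).
ASSAY_CV_TARGETS = {
    "MAT.18.0094.1": ("MAT.18.0094", 0.08),
    "MAT.18.0094.2": ("MAT.18.0094", 0.12),
    "MAT.18.0071.3": ("MAT.18.0071", 0.16),
    "MAT.18.0097.2": ("MAT.18.0097", 0.20),
    "MAT.18.0096.1": ("MAT.18.0096", 0.30),
    "TAS.18.1887.1": ("TAS.18.1887", 0.38),
}

_N_LOCI = 26
_TOTAL_UNITS = 370

# methylation archetypes (mean, sd) per tissue
_PASS_BLOOD = (0.05, 0.02)
_PASS_PLACENTA = (0.85, 0.05)
_FAIL_HIGH_BLOOD = ((0.45, 0.05), (0.90, 0.05))   # fails criterion #1
_FAIL_LOW_DIFF = ((0.05, 0.02), (0.30, 0.05))     # fails criterion #2


def _locus_unit_counts() -> dict[str, int]:
    """26 loci totalling 370 units; the top locus is large enough for 19 passers."""
    loci = list(PASSING_UNITS_PER_LOCUS) + [f"LOC.18.{i:04d}" for i in range(1, _N_LOCI - len(PASSING_UNITS_PER_LOCUS) + 1)]
    counts = {}
    counts[loci[0]] = 24
    remaining = _TOTAL_UNITS - 24
    others = loci[1:]
    base = remaining // len(others)
    extra = remaining - base * len(others)
    for i, locus in enumerate(others):
        counts[locus] = base + (1 if i < extra else 0)
    assert sum(counts.values()) == _TOTAL_UNITS
    return counts


def screening_models() -> tuple[list[TissueMethylationModel], dict[str, set[str]]]:
    """Screening-panel models plus the planted pass-set (locus -> unit ids)."""
    models: list[TissueMethylationModel] = []
    expected: dict[str, set[str]] = {}
    for locus, n_units in _locus_unit_counts().items():
        n_pass = PASSING_UNITS_PER_LOCUS.get(locus, 0)
        unit_ids, p_mean, p_sd, b_mean, b_sd, positions = [], [], [], [], [], []
        for u in range(n_units):
            unit_ids.append(f"{locus}.u{u + 1:02d}")
            positions.append(10_000_000 + 1000 * len(models) + 10 * u)
            if u < n_pass:
                blood, plac = _PASS_BLOOD, _PASS_PLACENTA
            elif u % 2 == 0:
                (blood, plac) = _FAIL_HIGH_BLOOD
            else:
                (blood, plac) = _FAIL_LOW_DIFF
            b_mean.append(blood[0]); b_sd.append(blood[1])
            p_mean.append(plac[0]); p_sd.append(plac[1])
        models.append(
            TissueMethylationModel(
                locus_id=locus,
                unit_ids=tuple(unit_ids),
                placenta_mean_mi=tuple(p_mean),
                placenta_sd_mi=tuple(p_sd),
                blood_mean_mi=tuple(b_mean),
                blood_sd_mi=tuple(b_sd),
                unit_positions=tuple(positions),
            )
        )
        if n_pass:
            expected[locus] = set(unit_ids[:n_pass])
    return models, expected


def screening_panel(seed: int, n_placenta: int = 2, n_blood: int = 2) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """The 370-unit two-tissue screening panel plus its planted pass-set."""
    models, expected = screening_models()
    panel = generate_tissue_panel(models, n_placenta=n_placenta, n_blood=n_blood, seed=seed)
    return panel, expected


def cv_assay_models() -> list[tuple[str, TissueMethylationModel]]:
    """One model per quantitative assay, tuned to its target inter-individual CV.

    Higher-CV assays get lower placental means so that sampling stays
    inside [0, 1] without distorting the CV ordering.
    """
    out = []
    means = {0.08: 0.85, 0.12: 0.85, 0.16: 0.80, 0.20: 0.80, 0.30: 0.60, 0.38: 0.50}
    for assay_id, (locus, cv) in ASSAY_CV_TARGETS.items():
        mean = means[cv]
        n_units = 6
        out.append(
            (
                assay_id,
                TissueMethylationModel(
                    locus_id=locus,
                    unit_ids=tuple(f"{assay_id}.u{u + 1:02d}" for u in range(n_units)),
                    placenta_mean_mi=(mean,) * n_units,
                    placenta_sd_mi=(cv * mean,) * n_units,
                    blood_mean_mi=(0.05,) * n_units,
                    blood_sd_mi=(0.02,) * n_units,
                ),
            )
        )
    return out


def cv_panel(seed: int, n_placenta: int = 10) -> pd.DataFrame:
    """Placental MI panel of the six assays for CV ranking (10 placentas)."""
    frames = []
    for assay_id, model in cv_assay_models():
        panel = generate_tissue_panel(model, n_placenta=n_placenta, n_blood=1, seed=seed)
        panel = panel[panel["tissue"] == "placenta"].copy()
        panel["assay_id"] = assay_id
        frames.append(panel)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class MarkerRegionDesign:
    """A candidate region with planted enzyme sites in a local sequence frame.

    The synthetic sequence covers the assayed region plus flanks; region
    coordinates are 1-based inclusive within that local frame.  Sites in
    ``hpaii_positions`` / ``hinp1i_positions`` are 0-based motif starts;
    ``decoy`` positions fall outside the region ± 100 bp window.
    """

    region: AssayRegion
    sequence_length: int
    hpaii_positions: tuple[int, ...] = ()
    hinp1i_positions: tuple[int, ...] = ()

    def sequence(self, seed: int) -> str:
        return generate_marker_sequence(
            self.sequence_length, self.hpaii_positions, self.hinp1i_positions, seed=seed
        )

    def planted_sites_one_based(self) -> list[EnzymeSite]:
        """Planted sites shifted into the region's 1-based frame."""
        sites = [EnzymeSite("HpaII", p + 1, "CCGG") for p in self.hpaii_positions]
        sites += [EnzymeSite("HinP1I", p + 1, "GCGC") for p in self.hinp1i_positions]
        return sorted(sites, key=lambda s: s.position)


def marker_region_designs() -> list[MarkerRegionDesign]:
    """The four candidate regions carried into the enzyme-site scan.

    In-window site counts are 5, 3, 1 and 1; each region also carries a
    decoy site well outside the ±100 bp window.
    """
    def region(assay_id: str, locus: str) -> AssayRegion:
        return AssayRegion(assay_id=assay_id, locus_id=locus, chrom="chr18", start=201, end=600)

    return [
        MarkerRegionDesign(
            region=region("MAT.18.0094.1", "MAT.18.0094"), sequence_length=800,
            hpaii_positions=(250, 390, 530, 40), hinp1i_positions=(320, 460, 720),
        ),
        MarkerRegionDesign(
            region=region("MAT.18.0094.2", "MAT.18.0094"), sequence_length=800,
            hpaii_positions=(260, 540), hinp1i_positions=(400, 30),
        ),
        MarkerRegionDesign(
            region=region("MAT.18.0071.3", "MAT.18.0071"), sequence_length=800,
            hpaii_positions=(400,), hinp1i_positions=(30,),
        ),
        MarkerRegionDesign(
            region=region("MAT.18.0097.2", "MAT.18.0097"), sequence_length=800,
            hpaii_positions=(30,), hinp1i_positions=(380,),
        ),
    ]
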
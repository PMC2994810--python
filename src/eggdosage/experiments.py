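"""Reusable in-silico experiments over the pipeline.

These wrap the per-sample analysis into cohort-level measurements that
the analysis drivers, the test suite and the reproduction script all
share: EGG-ratio tables for a configured cohort and the trisomy-vs-
euploid dosage-fold experiment (the expected fold is 3/2, the chr18
copy-number ratio, when both cohorts share the same fetal-fraction
distribution and assay settings).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .digital import UnanalyzableSampleError
from .pipeline import DigitalConfig, PipelineConfig, analyze_sample
from .synthetic import PlasmaCohortConfig, generate_cohort

__all__ = ["cohort_egg_ratios", "DosageFoldResult", "dosage_fold_experiment"]


def cohort_egg_ratios(config: PipelineConfig) -> pd.DataFrame:
    """EGG ratios of every analyzable sample of a simulated cohort."""
    rows = []
    for sample in generate_cohort(config.cohort):
        try:
            egg, _, control = analyze_sample(sample.sample_id, sample.pool, config)
        except UnanalyzableSampleError:  # pragma: no cover - ~exp(-lambda_ZFY) per sample
            continue
        if not control.passed:  # pragma: no cover - not reachable at efficiency 1
            continue
        rows.append(
            {"sample_id": sample.sample_id, "status": sample.status, "egg_ratio": egg.ratio}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DosageFoldResult:
    fold: float
    mean_euploid: float
    mean_trisomy: float
    n_samples: int


def dosage_fold_experiment(
    n_per_group: int = 1000,
    seed: int = 0,
    genome_equivalents: float = 500.0,
    fetal_fraction_range: tuple[float, float] = (0.03, 0.10),
    per_site_methylation: float = 1.0,
    wells_total: int = 376,
) -> DosageFoldResult:
    """Mean trisomy-18 EGG ratio over mean euploid EGG ratio.

    Both cohorts share the fetal-fraction distribution, complete
    digestion, full fetal methylation and identical digital-PCR
    settings, so the only systematic difference is the fetal chr18 copy
    number (3 vs 2) and the fold converges to 1.5.
    """
    cohort = PlasmaCohortConfig(
        n_euploid=n_per_group,
        n_trisomy=n_per_group,
        fetal_fraction_range=fetal_fraction_range,
        genome_equivalents=genome_equivalents,
        per_site_methylation=per_site_methylation,
        wells_per_assay=wells_total,
        seed=seed,
    )
    config = PipelineConfig(
        cohort=cohort, digital=DigitalConfig(wells_total=wells_total), seed=seed
    )
    ratios = cohort_egg_ratios(config)
    mean_eu = float(ratios.loc[ratios.status == "euploid", "egg_ratio"].mean())
    mean_tr = float(ratios.loc[ratios.status == "trisomy18", "egg_ratio"].mean())
    return DosageFoldResult(
        fold=mean_tr / mean_eu,
        mean_euploid=mean_eu,
        mean_trisomy=mean_tr,
        n_samples=len(ratios),
    )
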
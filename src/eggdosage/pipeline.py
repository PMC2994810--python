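"""End-to-end EGG dosage pipeline over a simulated plasma cohort.

Stages: simulate-cohort → digest (+ beta-actin / extraction controls) →
dilute to the reference-marker concentration → digital counting with
Poisson correction → EGG ratio → euploid reference interval →
classification → performance evaluation.  One global seed is split
deterministically per stage and per sample, so identical config + seed
reproduce every intermediate bit-for-bit; samples failing the digestion
controls or lacking reference molecules are excluded and logged, never
silently coerced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._seed import child_seed_sequence
from .assays import ControlReport, DigestionConfig, digest, digestion_controls
from .classifier import (
    EggResult,
    PerformanceReport,
    ReferenceInterval,
    classify,
    egg_ratio,
    evaluate,
    reference_interval,
)
from .digital import (
    DigitalPlateResult,
    SaturationError,
    UnanalyzableSampleError,
    dilute_to_reference,
    poisson_correct,
    simulate_plate,
)
from .pools import ACTB, VAPA_APCDD1, ZFY
from .synthetic import PlasmaCohortConfig, generate_cohort

logger = logging.getLogger("eggdosage")

__all__ = [
    "StageError",
    "DigitalConfig",
    "ClassifierConfig",
    "PipelineConfig",
    "PipelineResult",
    "run_end_to_end",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage}: {message}")


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    coerced = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in coerced and isinstance(coerced[f.name], list):
            coerced[f.name] = tuple(coerced[f.name])
    return cls(**coerced)


@dataclass(frozen=True)
class DigitalConfig:
    """Digital-PCR stage settings.

    ``wells_total`` defaults to 376 usable wells (a 384-well plate minus
    8 no-template controls).  ``target_m`` is the reference-marker
    dilution target; with ``cap_dilution`` the scaling factor never
    exceeds 1, since a plasma aliquot cannot be concentrated — samples
    below target simply run at their native concentration.
    """

    target_m: float = 0.5
    wells_total: int = 376
    cap_dilution: bool = True

    def __post_init__(self) -> None:
        if self.target_m <= 0:
            raise ValueError("target_m must be positive")
        if self.wells_total < 1:
            raise ValueError("wells_total must be >= 1")


@dataclass(frozen=True)
class ClassifierConfig:
    z: float = 1.96
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """Nested stage configs plus the global seed and output directory."""

    cohort: PlasmaCohortConfig = field(default_factory=PlasmaCohortConfig)
    digestion: DigestionConfig = field(default_factory=DigestionConfig)
    digital: DigitalConfig = field(default_factory=DigitalConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0
    outdir: str = "results/pipeline"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"PipelineConfig: unknown config keys {sorted(unknown)}")
        kwargs: dict = {}
        for key, sub in (
            ("cohort", PlasmaCohortConfig),
            ("digestion", DigestionConfig),
            ("digital", DigitalConfig),
            ("classifier", ClassifierConfig),
        ):
            if key in data:
                kwargs[key] = _from_dict(sub, data[key])
        for key in ("seed", "outdir"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: PipelineConfig
    egg_results: pd.DataFrame
    interval: ReferenceInterval
    performance: PerformanceReport
    excluded: pd.DataFrame
    outdir: Path


def _child_seed(seed: int, *keys) -> int:
    ss = child_seed_sequence(seed, *keys)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def analyze_sample(
    sample_id: str,
    pool,
    config: PipelineConfig,
) -> tuple[EggResult, dict, ControlReport]:
    """Run one sample through digest → controls → dilute → digital count.

    Returns the EGG result, a per-assay diagnostics dict, and the
    control report.  Raises :class:`UnanalyzableSampleError` or
    :class:`SaturationError` where the sample cannot be counted.
    """
    dig_cfg = dataclasses.replace(
        config.digestion, seed=_child_seed(config.seed, "digest", sample_id)
    )
    post = digest(pool, dig_cfg)
    control = digestion_controls(pool, post)
    wells = config.digital.wells_total
    diluted, factor = dilute_to_reference(
        post,
        ZFY,
        config.digital.target_m,
        wells,
        max_factor=1.0 if config.digital.cap_dilution else None,
    )
    diagnostics: dict = {"dilution_factor": factor}
    estimates = {}
    for marker in (VAPA_APCDD1, ZFY, ACTB):
        m_expected = diluted.total(marker) / wells
        plate = simulate_plate(
            m_expected,
            wells,
            seed=_child_seed(config.seed, "plate", sample_id, marker),
            assay=marker,
        )
        estimate = poisson_correct(plate)
        estimates[marker] = estimate
        diagnostics[marker] = {
            "m_expected": m_expected,
            "wells_positive": plate.wells_positive,
            "m_estimated": estimate.m,
            "molecules": estimate.molecules,
        }
    egg = egg_ratio(
        estimates[VAPA_APCDD1].molecules, estimates[ZFY].molecules, sample_id
    )
    return egg, diagnostics, control


def run_end_to_end(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute the whole pipeline and write all intermediates + a manifest."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    try:
        samples = generate_cohort(config.cohort)
    except Exception as err:
        raise StageError("simulate-cohort", str(err)) from err

    rows: list[dict] = []
    excluded: list[dict] = []
    for sample in samples:
        try:
            egg, diagnostics, control = analyze_sample(sample.sample_id, sample.pool, config)
        except (UnanalyzableSampleError, SaturationError) as err:
            logger.warning("sample %s excluded: %s", sample.sample_id, err)
            excluded.append({"sample_id": sample.sample_id, "status": sample.status, "reason": str(err)})
            continue
        except Exception as err:
            raise StageError("digital-count", f"sample {sample.sample_id}: {err}") from err
        if not control.passed:
            logger.warning("sample %s failed controls: %s", sample.sample_id, control.reason)
            excluded.append({"sample_id": sample.sample_id, "status": sample.status, "reason": control.reason})
            continue
        rows.append(
            {
                "sample_id": sample.sample_id,
                "status": sample.status,
                "vapa_molecules": egg.vapa_molecules,
                "zfy_molecules": egg.zfy_molecules,
                "egg_ratio": egg.ratio,
                "m_zfy": diagnostics[ZFY]["m_estimated"],
                "dilution_factor": diagnostics["dilution_factor"],
            }
        )
    egg_df = pd.DataFrame(rows)
    excluded_df = pd.DataFrame(excluded, columns=["sample_id", "status", "reason"])

    try:
        euploid_ratios = egg_df.loc[egg_df["status"] == "euploid", "egg_ratio"]
        interval = reference_interval(
            euploid_ratios.to_numpy(),
            z=config.classifier.z,
            log_scale=config.classifier.log_scale,
        )
        egg_df["call"] = [classify(r, interval) for r in egg_df["egg_ratio"]]
        egg_df["qc_below_lower"] = egg_df["egg_ratio"] < interval.lower
    except Exception as err:
        raise StageError("egg-classify", str(err)) from err

    try:
        performance = evaluate(list(egg_df["call"]), list(egg_df["status"]))
    except Exception as err:
        raise StageError("evaluate", str(err)) from err

    # outputs
    egg_path = outdir / "egg_results.tsv"
    egg_df.to_csv(egg_path, sep="\t", index=False)
    excluded_path = outdir / "excluded_samples.tsv"
    excluded_df.to_csv(excluded_path, sep="\t", index=False)
    perf_path = outdir / "performance.json"
    perf_path.write_text(
        json.dumps(
            {
                "tp": performance.tp,
                "fp": performance.fp,
                "tn": performance.tn,
                "fn": performance.fn,
                "sensitivity": performance.sensitivity,
                "specificity": performance.specificity,
                "reference_interval": {
                    "mean": interval.mean,
                    "sd": interval.sd,
                    "lower": interval.lower,
                    "upper": interval.upper,
                    "scale": interval.scale,
                },
            },
            indent=2,
        )
        + "\n"
    )
    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package": "eggdosage",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "started_utc": started,
        "finished_utc": datetime.now(timezone.utc).isoformat(),
        "outputs": {
            p.name: _sha256(p) for p in (egg_path, excluded_path, perf_path)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    return PipelineResult(
        config=config,
        egg_results=egg_df,
        interval=interval,
        performance=performance,
        excluded=excluded_df,
        outdir=outdir,
    )
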
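"""Synthetic cohort generation.

Everything downstream of the wet lab is driven by three kinds of input:
per-CpG-unit methylation indices (MI) measured in placenta and maternal
blood cells, candidate-region DNA sequences, and maternal-plasma DNA.
This module generates all three with the statistical structure the
analysis assumes:

* **Tissue panels** — per-unit MI drawn from a tissue-specific normal
  clamped to [0, 1] (placenta hypermethylated, blood essentially
  unmethylated, with inter-individual variation).
* **Marker sequences** — random DNA with HpaII (CCGG) / HinP1I (GCGC)
  recognition sites planted at known positions and nowhere else, for
  round-trip testing of the enzyme-site scanner.
* **Plasma samples** — maternal plasma modelled at molecule level: a
  large maternal background (unmethylated chr18 marker, no Y sequence)
  plus a small fetal fraction (3–10% by default) contributing 2 (euploid)
  or 3 (trisomy 18) chr18 marker copies and 1 ZFY copy per genome
  equivalent, with per-molecule per-site methylation.  Molecule numbers
  are Poisson, emulating sampling of cell-free DNA into an aliquot.

All generators are deterministic given their seed; one cohort seed is
expanded into per-sample child seeds so that growing a cohort never
changes earlier samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seed import child_rng, child_seed_sequence
from .pools import ACTB, AMPLICON_SITE_COUNT, FETAL, MATERNAL, MoleculePool, VAPA_APCDD1, ZFY

__all__ = [
    "EUPLOID",
    "TRISOMY18",
    "TissueMethylationModel",
    "PlasmaCohortConfig",
    "PlasmaSample",
    "generate_tissue_panel",
    "generate_plasma_sample",
    "generate_cohort",
    "generate_marker_sequence",
]

EUPLOID = "euploid"
TRISOMY18 = "trisomy18"

PLACENTA = "placenta"
MATERNAL_BLOOD = "maternal_blood_cells"


def _check_fraction_array(name: str, values: Sequence[float], lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"{name} must lie in [{lo}, {hi}]")
    return arr


@dataclass(frozen=True)
class TissueMethylationModel:
    """Population MI structure of one candidate locus in two tissues.

    Each CpG unit has a mean and SD of its methylation index in placenta
    and in maternal blood cells; sampled MIs are clamped to [0, 1].
    """

    locus_id: str
    unit_ids: tuple[str, ...]
    placenta_mean_mi: tuple[float, ...]
    placenta_sd_mi: tuple[float, ...]
    blood_mean_mi: tuple[float, ...]
    blood_sd_mi: tuple[float, ...]
    unit_positions: tuple[int, ...] = ()  # 1-based chromosomal coordinate per unit

    def __post_init__(self) -> None:
        n = len(self.unit_ids)
        if n == 0:
            raise ValueError("model must contain at least one CpG unit")
        for name in ("placenta_mean_mi", "blood_mean_mi"):
            vals = _check_fraction_array(name, getattr(self, name))
            if len(vals) != n:
                raise ValueError(f"{name} must have one value per unit")
        for name in ("placenta_sd_mi", "blood_sd_mi"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if len(vals) != n:
                raise ValueError(f"{name} must have one value per unit")
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise ValueError(f"{name} must be finite and nonnegative")
        if self.unit_positions and len(self.unit_positions) != n:
            raise ValueError("unit_positions must have one value per unit")

    @property
    def positions(self) -> tuple[int, ...]:
        return self.unit_positions or tuple(range(1, len(self.unit_ids) + 1))


def _sample_tissue(
    rng: np.random.Generator, means: Sequence[float], sds: Sequence[float]
) -> np.ndarray:
    mi = rng.normal(np.asarray(means, float), np.asarray(sds, float))
    return np.clip(mi, 0.0, 1.0)


def generate_tissue_panel(
    models: TissueMethylationModel | Iterable[TissueMethylationModel],
    n_placenta: int,
    n_blood: int,
    seed: int,
    assay_ids: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Simulate an Epityper-style MI panel for one or more loci.

    Returns one row per (sample, CpG unit) with columns
    ``sample_id, tissue, locus_id, unit_id, chrom_position, mi`` (plus
    ``assay_id`` when a locus→assay mapping is supplied).  Placenta
    samples are named ``PL01..`` and blood samples ``BL01..``; the draw
    for sample *i* depends only on (seed, tissue, i, locus), so panels
    are reproducible and extensible.
    """
    if n_placenta < 1 or n_blood < 1:
        raise ValueError("need at least one sample per tissue")
    if isinstance(models, TissueMethylationModel):
        models = [models]
    rows: list[dict] = []
    for model in models:
        for tissue, prefix, n, means, sds in (
            (PLACENTA, "PL", n_placenta, model.placenta_mean_mi, model.placenta_sd_mi),
            (MATERNAL_BLOOD, "BL", n_blood, model.blood_mean_mi, model.blood_sd_mi),
        ):
            for i in range(n):
                rng = child_rng(seed, tissue, i, model.locus_id)
                mi = _sample_tissue(rng, means, sds)
                for unit_id, pos, m in zip(model.unit_ids, model.positions, mi):
                    row = {
                        "sample_id": f"{prefix}{i + 1:02d}",
                        "tissue": tissue,
                        "locus_id": model.locus_id,
                        "unit_id": unit_id,
                        "chrom_position": pos,
                        "mi": float(m),
                    }
                    if assay_ids is not None:
                        row["assay_id"] = assay_ids.get(model.locus_id, model.locus_id)
                    rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PlasmaCohortConfig:
    """Study conditions for a simulated maternal-plasma cohort.

    Defaults mirror the clinical study design: 27 euploid and 9
    trisomy-18 male-fetus pregnancies, a fetal fraction uniform on
    3–10%, and a per-aliquot input of ``genome_equivalents`` total
    genomes.  ``per_site_methylation`` is the probability that a fetal
    chr18-marker molecule is methylated at any one enzyme site;
    ``maternal_marker_methylation`` is the (normally ~0) maternal
    counterpart, exposed to stress-test specificity.
    """

    n_euploid: int = 27
    n_trisomy: int = 9
    fetal_fraction_range: tuple[float, float] = (0.03, 0.10)
    genome_equivalents: float = 500.0
    chr18_copies_euploid: int = 2
    chr18_copies_trisomy: int = 3
    zfy_copies_per_fetal_genome: int = 1
    per_site_methylation: float = 0.9
    maternal_marker_methylation: float = 0.0
    digestion_efficiency: float = 1.0
    wells_per_assay: int = 376
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fetal_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("fetal_fraction_range must satisfy 0 <= lo <= hi <= 1")
        for name in ("per_site_methylation", "maternal_marker_methylation", "digestion_efficiency"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_euploid < 0 or self.n_trisomy < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if self.genome_equivalents < 0:
            raise ValueError("genome_equivalents must be nonnegative")
        if self.chr18_copies_trisomy <= self.chr18_copies_euploid:
            raise ValueError("trisomy chr18 copy number must exceed the euploid one")
        if self.zfy_copies_per_fetal_genome < 0:
            raise ValueError("zfy_copies_per_fetal_genome must be nonnegative")
        if self.wells_per_assay < 1:
            raise ValueError("wells_per_assay must be >= 1")

    def with_(self, **kwargs) -> "PlasmaCohortConfig":
        return replace(self, **kwargs)


def _pattern_counts(
    rng: np.random.Generator, n: int, n_sites: int, p_methylated: float
) -> dict[tuple[bool, ...], int]:
    """Counts of per-site methylation patterns for ``n`` molecules."""
    if n == 0:
        return {}
    if n_sites == 0:
        return {(): n}
    if p_methylated == 0.0:
        return {(False,) * n_sites: n}
    if p_methylated == 1.0:
        return {(True,) * n_sites: n}
    states = rng.random((n, n_sites)) < p_methylated
    out: dict[tuple[bool, ...], int] = {}
    for row in states:
        key = tuple(bool(b) for b in row)
        out[key] = out.get(key, 0) + 1
    return out


def generate_plasma_sample(
    config: PlasmaCohortConfig, status: str, seed: int
) -> MoleculePool:
    """Draw one maternal-plasma aliquot as a :class:`MoleculePool`.

    The fetal fraction is drawn uniformly from the configured range.
    Molecule counts are Poisson with means given by origin-specific
    genome equivalents times the locus copy number; fetal chr18-marker
    molecules carry independent per-site methylation, the maternal
    background is (by default) fully unmethylated, and beta-actin is
    unmethylated from both origins.  Maternal plasma contributes no ZFY.
    """
    if status == EUPLOID:
        chr18_copies = config.chr18_copies_euploid
    elif status == TRISOMY18:
        chr18_copies = config.chr18_copies_trisomy
    else:
        raise ValueError(f"status must be {EUPLOID!r} or {TRISOMY18!r}, got {status!r}")

    rng = np.random.default_rng(child_seed_sequence(seed))
    lo, hi = config.fetal_fraction_range
    ff = float(rng.uniform(lo, hi))
    ge = config.genome_equivalents
    fetal_ge = ff * ge
    maternal_ge = (1.0 - ff) * ge

    pool = MoleculePool()
    n_sites_marker = AMPLICON_SITE_COUNT[VAPA_APCDD1]
    n_sites_actb = AMPLICON_SITE_COUNT[ACTB]

    # fetal molecules
    n_fetal_marker = int(rng.poisson(fetal_ge * chr18_copies))
    for pattern, n in _pattern_counts(
        rng, n_fetal_marker, n_sites_marker, config.per_site_methylation
    ).items():
        pool.add(VAPA_APCDD1, FETAL, pattern, n)
    n_fetal_zfy = int(rng.poisson(fetal_ge * config.zfy_copies_per_fetal_genome))
    pool.add(ZFY, FETAL, (), n_fetal_zfy)
    pool.add(ACTB, FETAL, (False,) * n_sites_actb, int(rng.poisson(fetal_ge * 2)))

    # maternal background: 2 chr18 copies, no Y chromosome
    n_maternal_marker = int(rng.poisson(maternal_ge * 2))
    for pattern, n in _pattern_counts(
        rng, n_maternal_marker, n_sites_marker, config.maternal_marker_methylation
    ).items():
        pool.add(VAPA_APCDD1, MATERNAL, pattern, n)
    pool.add(ACTB, MATERNAL, (False,) * n_sites_actb, int(rng.poisson(maternal_ge * 2)))

    return pool


@dataclass(frozen=True)
class PlasmaSample:
    sample_id: str
    status: str
    pool: MoleculePool
    seed_keys: tuple = ()


def generate_cohort(config: PlasmaCohortConfig) -> list[PlasmaSample]:
    """Simulate the full cohort (euploid samples first, then trisomy 18).

    Each sample gets a child seed derived from ``config.seed`` and its
    (status, index) pair; samples are therefore independent and stable
    under changes to the cohort sizes.
    """
    samples: list[PlasmaSample] = []
    for status, n, prefix in (
        (EUPLOID, config.n_euploid, "EU"),
        (TRISOMY18, config.n_trisomy, "T18"),
    ):
        for i in range(n):
            ss = child_seed_sequence(config.seed, "plasma", status, i)
            sample_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
            pool = generate_plasma_sample(config, status, seed=sample_seed)
            samples.append(
                PlasmaSample(f"{prefix}{i + 1:02d}", status, pool, ("plasma", status, i))
            )
    return samples


_MOTIFS = {"HpaII": "CCGG", "HinP1I": "GCGC"}
_MOTIF_LEN = 4


def generate_marker_sequence(
    length: int,
    hpaii_positions: Sequence[int] = (),
    hinp1i_positions: Sequence[int] = (),
    seed: int = 0,
) -> str:
    """Random DNA containing CCGG/GCGC exactly at the planted positions.

    The background is uniform over {A,C,G,T} with accidental motif
    occurrences repaired by point mutation, so an exhaustive scan of the
    returned sequence recovers exactly the planted sites.  Planted sites
    must be in-bounds and non-overlapping.
    """
    planted = [(int(p), _MOTIFS["HpaII"]) for p in hpaii_positions] + [
        (int(p), _MOTIFS["HinP1I"]) for p in hinp1i_positions
    ]
    planted.sort()
    for pos, motif in planted:
        if pos < 0 or pos + _MOTIF_LEN > length:
            raise ValueError(f"planted site at {pos} out of bounds for length {length}")
    for (p1, m1), (p2, _m2) in zip(planted, planted[1:]):
        if p2 < p1 + _MOTIF_LEN:
            raise ValueError(f"planted sites at {p1} and {p2} overlap")

    rng = child_rng(seed, "marker-sequence")
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length))
    footprint = set()
    for pos, motif in planted:
        seq[pos : pos + _MOTIF_LEN] = list(motif)
        footprint.update(range(pos, pos + _MOTIF_LEN))
    planted_set = {(pos, motif) for pos, motif in planted}

    # repair accidental occurrences without touching planted footprints
    for _ in range(100 * max(length, 1)):
        accidental = None
        for i in range(length - _MOTIF_LEN + 1):
            window = "".join(seq[i : i + _MOTIF_LEN])
            if window in ("CCGG", "GCGC") and (i, window) not in planted_set:
                accidental = i
                break
        if accidental is None:
            return "".join(seq)
        mutable = [j for j in range(accidental, accidental + _MOTIF_LEN) if j not in footprint]
        if not mutable:  # pragma: no cover - cannot arise for non-overlapping plants
            raise RuntimeError("accidental motif fully inside planted footprints")
        j = int(rng.choice(mutable))
        choices = [b for b in "ACGT" if b != seq[j]]
        seq[j] = str(rng.choice(choices))
    raise RuntimeError("failed to repair accidental enzyme motifs")  # pragma: no cover
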
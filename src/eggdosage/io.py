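"""File formats: TSV tables, FASTA, BED / 1-based region tables, configs.

Conventions
-----------
* TSV is the native tabular format throughout.
* Region coordinates: BED files are 0-based half-open; the ``onebased``
  TSV dialect (as in genome-browser text tables) is 1-based inclusive.
  An explicit dialect flag selects between them; internally regions are
  1-based inclusive :class:`~eggdosage.selection.AssayRegion` objects.
* Molecule pools serialize one row per (marker, origin, pattern) entry,
  with the methylation pattern as a 0/1 string (empty for ZFY).
* Configs are JSON or YAML by file extension; unknown keys are rejected
  so that typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digital import DigitalPlateResult
from .methylation import BisulfiteCloneMatrix
from .pools import MoleculePool
from .selection import AssayRegion

__all__ = [
    "FormatError",
    "read_table",
    "write_table",
    "read_pool",
    "write_pool",
    "read_fasta",
    "write_fasta",
    "read_regions",
    "write_regions",
    "read_clone_matrix",
    "write_clone_matrix",
    "read_plates",
    "write_plates",
    "load_config_dict",
    "save_config_dict",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------- tables

def read_table(path, required: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------- molecule pools

def write_pool(pool: MoleculePool, path) -> None:
    rows = [
        {
            "marker": marker,
            "origin": origin,
            "pattern": "".join("1" if b else "0" for b in pattern),
            "count": count,
        }
        for (marker, origin, pattern), count in sorted(pool.entries.items())
    ]
    write_table(pd.DataFrame(rows, columns=["marker", "origin", "pattern", "count"]), path)


def read_pool(path) -> MoleculePool:
    df = pd.read_csv(path, sep="\t", dtype={"pattern": str}, keep_default_na=False)
    missing = {"marker", "origin", "pattern", "count"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    pool = MoleculePool()
    for i, row in df.iterrows():
        raw = str(row["pattern"])
        if raw and set(raw) - {"0", "1"}:
            raise FormatError(f"{path}: line {i + 2}: bad pattern {raw!r}")
        pattern = tuple(c == "1" for c in raw)
        count = float(row["count"])
        pool.add(row["marker"], row["origin"], pattern, int(count) if count.is_integer() else count)
    return pool


# ----------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Sequences by record id; raises :class:`FormatError` on malformed input."""
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FormatError(f"{path}: line {lineno}: expected FASTA header ('>')")
            break
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: dict[str, str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------- regions

def read_regions(path, dialect: str = "bed") -> list[AssayRegion]:
    """Read assay regions; ``dialect`` is ``bed`` (0-based half-open) or
    ``onebased`` (1-based inclusive TSV with a header)."""
    if dialect == "bed":
        regions = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: BED needs chrom/start/end/name")
            chrom, start, end, name = fields[:4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as err:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from err
            regions.append(
                AssayRegion(assay_id=name, locus_id=name, chrom=chrom,
                            start=start_i + 1, end=end_i)
            )
        return regions
    if dialect == "onebased":
        df = read_table(path, required=("assay_id", "locus_id", "chrom", "start", "end"))
        return [
            AssayRegion(
                assay_id=row["assay_id"], locus_id=row["locus_id"], chrom=row["chrom"],
                start=int(row["start"]), end=int(row["end"]),
            )
            for _, row in df.iterrows()
        ]
    raise ValueError(f"unknown region dialect {dialect!r}")


def write_regions(regions: Iterable[AssayRegion], path, dialect: str = "bed") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    if dialect == "bed":
        lines = [
            f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.assay_id}" for r in regions
        ]
        Path(path).write_text("\n".join(lines) + "\n")
        return
    if dialect == "onebased":
        df = pd.DataFrame(
            [
                {"assay_id": r.assay_id, "locus_id": r.locus_id, "chrom": r.chrom,
                 "start": r.start, "end": r.end}
                for r in regions
            ]
        )
        write_table(df, path)
        return
    raise ValueError(f"unknown region dialect {dialect!r}")


# ----------------------------------------------------------- clone matrices

def write_clone_matrix(matrix: BisulfiteCloneMatrix, path) -> None:
    """0/1 TSV; the header row carries the 1-based CpG site coordinates."""
    df = pd.DataFrame(matrix.calls.astype(int), columns=[str(p) for p in matrix.site_positions])
    write_table(df, path)


def read_clone_matrix(path) -> BisulfiteCloneMatrix:
    df = pd.read_csv(path, sep="\t")
    try:
        positions = [int(c) for c in df.columns]
    except ValueError as err:
        raise FormatError(f"{path}: header must hold integer site coordinates") from err
    return BisulfiteCloneMatrix(df.to_numpy(), positions)


# ------------------------------------------------------------ digital plates

def write_plates(rows: Iterable[tuple[str, DigitalPlateResult]], path) -> None:
    """One row per (sample, assay) plate result."""
    df = pd.DataFrame(
        [
            {"sample_id": sample_id, "assay": p.assay,
             "wells_total": p.wells_total, "wells_positive": p.wells_positive}
            for sample_id, p in rows
        ]
    )
    write_table(df, path)


def read_plates(path) -> list[tuple[str, DigitalPlateResult]]:
    df = read_table(path, required=("sample_id", "assay", "wells_total", "wells_positive"))
    return [
        (row["sample_id"],
         DigitalPlateResult(row["assay"], int(row["wells_total"]), int(row["wells_positive"])))
        for _, row in df.iterrows()
    ]


# ----------------------------------------------------------------- configs

def load_config_dict(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise FormatError(f"{path}: config must be .json, .yaml or .yml")
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config root must be a mapping")
    return data


def save_config_dict(data: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        raise FormatError(f"{path}: config must be .json, .yaml or .yml")
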
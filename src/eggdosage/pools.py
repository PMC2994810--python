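"""Molecule pools: the in-silico substrate of the plasma assays.

A :class:`MoleculePool` counts cell-free DNA template molecules by

* **marker** — which PCR amplicon the molecule would feed
  (``VAPA_APCDD1`` on chr18, ``ZFY`` on chrY, ``ACTB`` the digestion control),
* **origin** — ``fetal`` (placental) or ``maternal`` (blood-cell),
* **methylation pattern** — one boolean per methylation-sensitive enzyme
  recognition site inside the amplicon (``True`` = CpG methylated).

The chr18 marker amplicon spans 5 HpaII/HinP1I sites, the beta-actin
control spans 4, and the ZFY amplicon spans none, so a ZFY molecule's
pattern is the empty tuple and ZFY always survives digestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from numbers import Real

__all__ = [
    "VAPA_APCDD1",
    "ZFY",
    "ACTB",
    "MARKERS",
    "FETAL",
    "MATERNAL",
    "ORIGINS",
    "AMPLICON_SITE_COUNT",
    "Pattern",
    "PoolKey",
    "MoleculePool",
]

VAPA_APCDD1 = "VAPA_APCDD1"
ZFY = "ZFY"
ACTB = "ACTB"
MARKERS = (VAPA_APCDD1, ZFY, ACTB)

FETAL = "fetal"
MATERNAL = "maternal"
ORIGINS = (FETAL, MATERNAL)

#: Methylation-sensitive HpaII/HinP1I sites spanned by each amplicon.
AMPLICON_SITE_COUNT = {VAPA_APCDD1: 5, ZFY: 0, ACTB: 4}

Pattern = tuple[bool, ...]
PoolKey = tuple[str, str, Pattern]


def _validate_key(key: PoolKey) -> None:
    marker, origin, pattern = key
    if marker not in AMPLICON_SITE_COUNT:
        raise ValueError(f"unknown marker {marker!r}; expected one of {MARKERS}")
    if origin not in ORIGINS:
        raise ValueError(f"unknown origin {origin!r}; expected one of {ORIGINS}")
    expected = AMPLICON_SITE_COUNT[marker]
    if len(pattern) != expected:
        raise ValueError(
            f"{marker} patterns must have {expected} sites, got {len(pattern)}"
        )
    if not all(isinstance(b, (bool,)) or b in (0, 1) for b in pattern):
        raise ValueError("methylation patterns must contain booleans")


@dataclass
class MoleculePool:
    """Counts of template molecules keyed by (marker, origin, pattern).

    Counts generated by the cohort simulator are nonnegative integers;
    after in-silico dilution they may be nonnegative reals (expected
    molecule numbers), which is what the digital-PCR stage consumes.
    """

    entries: dict[PoolKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, count in self.entries.items():
            _validate_key(key)
            if not isinstance(count, Real) or count < 0:
                raise ValueError(f"molecule count for {key} must be nonnegative")

    def add(self, marker: str, origin: str, pattern: Pattern, count: float) -> None:
        """Add ``count`` molecules to a pool entry (creating it if needed)."""
        key = (marker, origin, tuple(bool(b) for b in pattern))
        _validate_key(key)
        if count < 0:
            raise ValueError("molecule count must be nonnegative")
        if count:
            self.entries[key] = self.entries.get(key, 0) + count

    def total(self, marker: str, origin: str | None = None) -> float:
        """Total molecules of ``marker`` (optionally restricted to one origin)."""
        if marker not in AMPLICON_SITE_COUNT:
            raise ValueError(f"unknown marker {marker!r}; expected one of {MARKERS}")
        return sum(
            n
            for (mk, og, _), n in self.entries.items()
            if mk == marker and (origin is None or og == origin)
        )

    def total_molecules(self) -> float:
        return sum(self.entries.values())

    def scaled(self, factor: float) -> "MoleculePool":
        """Pool with every count multiplied by ``factor`` (expected molecules)."""
        if factor < 0:
            raise ValueError("scaling factor must be nonnegative")
        return MoleculePool({k: n * factor for k, n in self.entries.items()})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MoleculePool):
            return NotImplemented
        a = {k: n for k, n in self.entries.items() if n}
        b = {k: n for k, n in other.entries.items() if n}
        return a == b
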
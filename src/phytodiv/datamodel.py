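"""Core domain types for species-compound-region diversity analysis.

The atomic input is a :class:`CompoundOccurrence`: one report that a
standardized compound structure, assigned to one of the seven NPClassifier
biosynthetic pathways, occurs in a species native to one or more WGSRPD
Level-3 botanical regions ("botanical countries").  Occurrences are
aggregated into per-region :class:`RegionGroup` objects on which all
diversity metrics operate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import FrozenSet, NamedTuple, Optional

logger = logging.getLogger("phytodiv")

#: The seven NPClassifier biosynthetic pathway classes.
PATHWAYS: tuple[str, ...] = (
    "fatty acids",
    "polyketides",
    "shikimates-phenylpropanoids",
    "terpenoids",
    "alkaloids",
    "amino acids/peptides",
    "carbohydrates",
)

_PATHWAY_SET = frozenset(PATHWAYS)


@lru_cache(maxsize=1)
def known_region_codes() -> frozenset[str]:
    """Bundled WGSRPD Level-3 region codes (curated, not exhaustive)."""
    text = resources.files("phytodiv.data").joinpath("wgsrpd_l3.txt").read_text()
    codes = {line.strip() for line in text.splitlines()}
    return frozenset(c for c in codes if c and not c.startswith("#"))


def validate_region_code(code: str) -> bool:
    """Return True if ``code`` is a known WGSRPD L3 code; warn otherwise.

    Unknown codes are passed through (the bundled list is a curated subset
    and user schemes may extend it), so validation never rejects a record.
    """
    if code in known_region_codes():
        return True
    logger.warning("unknown WGSRPD Level-3 region code: %r", code)
    return False


@dataclass(frozen=True)
class Fingerprint:
    """Binary molecular fingerprint as a set of "on" bit indices.

    Parameters
    ----------
    bits
        Indices of set bits; must all be ``< n_bits``.
    n_bits
        Size of the bit space (e.g. 2048 for hashed circular fingerprints).
    """

    bits: FrozenSet[int]
    n_bits: int = 2048

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", frozenset(self.bits))
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        if any((b < 0 or b >= self.n_bits) for b in self.bits):
            raise ValueError("fingerprint bit index out of range")
        if not self.bits:
            logger.warning("empty fingerprint (no bits set)")

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class CompoundOccurrence:
    """One (taxon, structure, pathway, native regions) record."""

    taxon: str
    structure: str
    pathway: str
    regions: FrozenSet[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", frozenset(self.regions))
        if not self.structure:
            raise ValueError("structure must be non-empty")
        if self.pathway not in _PATHWAY_SET:
            raise ValueError(
                f"unknown pathway {self.pathway!r}; expected one of {sorted(_PATHWAY_SET)}"
            )
        if not self.regions:
            raise ValueError("regions must be non-empty")


class Compound(NamedTuple):
    """A deduplicated compound inside a region group."""

    structure: str
    pathway: str
    fingerprint: Optional[Fingerprint]


@dataclass
class RegionGroup:
    """All unique compounds and contributing species for one region.

    Compound uniqueness is by standardized structure string; ``compounds``
    is kept in first-encountered order so metric evaluation is
    deterministic given the input record order.
    """

    region: str
    compounds: tuple[Compound, ...]
    species: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        structures = [c.structure for c in self.compounds]
        if len(structures) != len(set(structures)):
            raise ValueError(f"duplicate structures in group {self.region!r}")
        if len(self.compounds) < 1:
            raise ValueError(f"region group {self.region!r} is empty")
        self.species = frozenset(self.species)

    def __len__(self) -> int:
        return len(self.compounds)

    @property
    def pathways(self) -> list[str]:
        return [c.pathway for c in self.compounds]

    @property
    def fingerprints(self) -> list[Optional[Fingerprint]]:
        return [c.fingerprint for c in self.compounds]

    def subset(self, indices) -> "RegionGroup":
        """Sub-group of the compounds at ``indices`` (used by rarefaction)."""
        comps = tuple(self.compounds[i] for i in indices)
        return RegionGroup(region=self.region, compounds=comps, species=self.species)
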
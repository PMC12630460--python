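"""Aggregation of occurrence records into per-region compound groups.

A species' compounds are attributed to every region the species is native
to, so one record fans out to all its region codes.  Within a region,
compounds are deduplicated by their standardized structure string, and the
species set collects every taxon contributing at least one compound.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Mapping, Optional, Union

from .datamodel import Compound, CompoundOccurrence, Fingerprint, RegionGroup

logger = logging.getLogger("phytodiv")

FingerprintSource = Union[Mapping[str, Fingerprint], Callable[[str], Fingerprint]]


def _lookup(fingerprints: Optional[FingerprintSource], structure: str) -> Optional[Fingerprint]:
    if fingerprints is None:
        return None
    if callable(fingerprints):
        return fingerprints(structure)
    return fingerprints.get(structure)


def build_region_groups(
    records: Iterable[CompoundOccurrence],
    fingerprints: Optional[FingerprintSource] = None,
) -> list[RegionGroup]:
    """Group records by region, deduplicating compounds by structure.

    Parameters
    ----------
    records
        Standardized occurrence records; each fans out to all its regions.
    fingerprints
        Either a mapping ``structure -> Fingerprint`` or a callable
        producing one (e.g. a chemistry backend's ``fingerprint``).  May be
        omitted when only pathway-level metrics are needed.

    Returns one group per region code, sorted by code.  If the same
    structure appears with two different pathway labels, the first label
    encountered wins and a conflict warning is logged.
    """
    compounds: dict[str, dict[str, Compound]] = {}
    species: dict[str, set[str]] = {}
    pathway_of: dict[str, str] = {}
    for rec in records:
        prev = pathway_of.setdefault(rec.structure, rec.pathway)
        if prev != rec.pathway:
            logger.warning(
                "pathway conflict for %r: keeping %r, ignoring %r",
                rec.structure, prev, rec.pathway,
            )
        for region in rec.regions:
            by_structure = compounds.setdefault(region, {})
            if rec.structure not in by_structure:
                by_structure[rec.structure] = Compound(
                    structure=rec.structure,
                    pathway=prev,
                    fingerprint=_lookup(fingerprints, rec.structure),
                )
            species.setdefault(region, set()).add(rec.taxon)
    return [
        RegionGroup(
            region=region,
            compounds=tuple(compounds[region].values()),
            species=frozenset(species[region]),
        )
        for region in sorted(compounds)
    ]


def filter_groups(groups: list[RegionGroup], min_size: int = 7) -> list[RegionGroup]:
    """Drop groups with fewer than ``min_size`` compounds, preserving order.

    The default of 7 is the minimum group size admitting rarefaction
    subsamples of size 7.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [g for g in groups if len(g) >= min_size]
    dropped = len(groups) - len(kept)
    if dropped:
        logger.info("discarded %d groups with fewer than %d compounds", dropped, min_size)
    if groups and not kept:
        logger.warning("all %d groups fell below min_size=%d", len(groups), min_size)
    return kept
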
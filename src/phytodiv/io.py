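"""Readers and writers for the pipeline's plain-text table formats.

All tables are UTF-8 CSV with a header row:

* occurrence table  — ``taxon,structure,pathway,regions`` with region codes
  pipe-separated in one cell; rows with an empty pathway cell
  (uncategorised compounds) are dropped with a logged count;
* distribution table — ``taxon,region_code``, one row per native region;
* fingerprint table — ``structure,bits,n_bits`` with bit indices
  pipe-separated;
* diversity table — one row per region with every computed metric; null
  metric values (e.g. Pielou's J when only one pathway is present)
  serialize as empty cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .datamodel import CompoundOccurrence, Fingerprint, validate_region_code

logger = logging.getLogger("phytodiv")

#: Column order of the per-region output table.
DIVERSITY_COLUMNS = [
    "region", "N", "SR", "FAD", "MFAD", "APWD", "H", "Hbc", "G", "J",
    "PD", "PD_resid",
    "rarefied_FAD", "rarefied_MFAD", "rarefied_APWD",
    "rarefied_H", "rarefied_Hbc", "rarefied_G", "rarefied_J",
]


@dataclass
class DiversityProfile:
    """All computed metrics for one region (plain and rarefied)."""

    region: str
    N: int
    SR: Optional[int] = None
    FAD: Optional[float] = None
    MFAD: Optional[float] = None
    APWD: Optional[float] = None
    H: Optional[float] = None
    Hbc: Optional[float] = None
    G: Optional[float] = None
    J: Optional[float] = None
    PD: Optional[float] = None
    PD_resid: Optional[float] = None
    rarefied_FAD: Optional[float] = None
    rarefied_MFAD: Optional[float] = None
    rarefied_APWD: Optional[float] = None
    rarefied_H: Optional[float] = None
    rarefied_Hbc: Optional[float] = None
    rarefied_G: Optional[float] = None
    rarefied_J: Optional[float] = None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")


def read_occurrence_table(path, validate_regions: bool = True) -> list[CompoundOccurrence]:
    """Read compound occurrence records from CSV.

    Rows with a missing pathway label are dropped (uncategorised
    compounds); the dropped count is logged.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["taxon", "structure", "pathway", "regions"], path)
    n_uncat = int((df["pathway"].str.strip() == "").sum())
    if n_uncat:
        logger.info("%s: dropped %d uncategorised rows (empty pathway)", path, n_uncat)
        df = df[df["pathway"].str.strip() != ""]
    records = []
    for row in df.itertuples(index=False):
        regions = frozenset(r for r in str(row.regions).split("|") if r)
        if validate_regions:
            for code in sorted(regions):
                validate_region_code(code)
        records.append(
            CompoundOccurrence(
                taxon=row.taxon, structure=row.structure,
                pathway=row.pathway, regions=regions,
            )
        )
    return records


def write_occurrence_table(records: Iterable[CompoundOccurrence], path) -> None:
    rows = [
        {
            "taxon": r.taxon,
            "structure": r.structure,
            "pathway": r.pathway,
            "regions": "|".join(sorted(r.regions)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["taxon", "structure", "pathway", "regions"]).to_csv(
        path, index=False
    )


def read_distribution_table(path, validate_regions: bool = True) -> dict[str, set[str]]:
    """Read the species -> native-region mapping; returns taxon -> set of codes."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["taxon", "region_code"], path)
    dist: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        if validate_regions:
            validate_region_code(row.region_code)
        dist.setdefault(row.taxon, set()).add(row.region_code)
    return dist


def write_distribution_table(dist: Mapping[str, Iterable[str]], path) -> None:
    rows = [
        {"taxon": taxon, "region_code": code}
        for taxon in sorted(dist)
        for code in sorted(dist[taxon])
    ]
    pd.DataFrame(rows, columns=["taxon", "region_code"]).to_csv(path, index=False)


def read_fingerprint_table(path) -> dict[str, Fingerprint]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["structure", "bits", "n_bits"], path)
    out = {}
    for row in df.itertuples(index=False):
        bits = frozenset(int(b) for b in row.bits.split("|") if b)
        out[row.structure] = Fingerprint(bits=bits, n_bits=int(row.n_bits))
    return out


def write_fingerprint_table(fps: Mapping[str, Fingerprint], path) -> None:
    rows = [
        {
            "structure": s,
            "bits": "|".join(str(b) for b in sorted(fp.bits)),
            "n_bits": fp.n_bits,
        }
        for s, fp in sorted(fps.items())
    ]
    pd.DataFrame(rows, columns=["structure", "bits", "n_bits"]).to_csv(path, index=False)


def write_diversity_table(profiles, path) -> None:
    """Write per-region diversity profiles to CSV.

    Accepts a DataFrame or an iterable of :class:`DiversityProfile`.
    Floats are written with 12 significant digits so reruns with identical
    inputs produce byte-identical files.
    """
    if isinstance(profiles, pd.DataFrame):
        df = profiles
    else:
        df = pd.DataFrame([p.to_dict() for p in profiles])
    cols = [c for c in DIVERSITY_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, float_format="%.12g")


def read_diversity_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
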
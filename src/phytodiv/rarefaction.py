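"""Size-based rarefaction of diversity metrics.

To compare groups sampled with very different effort, each metric is also
reported as its mean over repeated uniform subsamples of a fixed size
drawn without replacement from the group's compounds.  Defaults follow the
study design this package implements: 1000 replicates of size 7, the
subsample size matching the number of biosynthetic pathway classes.

Replicates on which a metric is undefined (e.g. Pielou's J when a
subsample happens to contain a single pathway) are excluded from the mean;
if every replicate is undefined the rarefied value itself is null.  One
random stream is derived per region from the master seed and the region
code, so results do not depend on the order regions are processed in, and
the same subsamples are shared by all metrics within a region.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import pathway_metrics as pm
from .compound_metrics import distance_matrix
from .datamodel import PATHWAYS, RegionGroup

logger = logging.getLogger("phytodiv")


@dataclass(frozen=True)
class RarefactionConfig:
    subsample_size: int = 7
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subsample_size < 2:
            raise ValueError("subsample_size must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def region_rng(seed: int, region: str) -> np.random.Generator:
    """Deterministic per-region random stream from (master seed, region code)."""
    code_hash = int.from_bytes(hashlib.sha256(region.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, code_hash]))


def draw_subsamples(group: RegionGroup, cfg: RarefactionConfig) -> np.ndarray:
    """(replicates x m) matrix of compound indices, sampled without replacement."""
    n = len(group)
    m = cfg.subsample_size
    if n < m:
        raise ValueError(
            f"group {group.region!r} has {n} compounds, fewer than subsample size {m}"
        )
    rng = region_rng(cfg.seed, group.region)
    return np.stack([rng.choice(n, size=m, replace=False) for _ in range(cfg.replicates)])


def rarefied_metric(
    group: RegionGroup,
    metric: Callable[[RegionGroup], Optional[float]],
    cfg: RarefactionConfig,
) -> Optional[float]:
    """Mean of ``metric`` over random fixed-size subsamples of ``group``.

    ``metric`` maps a RegionGroup to a float or None; None replicates are
    dropped from the mean.  Returns None (with a warning) if all
    replicates are null.  Reproducible for a fixed config seed.
    """
    idx = draw_subsamples(group, cfg)
    values = [metric(group.subset(row)) for row in idx]
    kept = [v for v in values if v is not None and np.isfinite(v)]
    if not kept:
        logger.warning("all %d rarefaction replicates null for %r", cfg.replicates, group.region)
        return None
    return float(np.mean(kept))


def rarefy_group(
    group: RegionGroup,
    cfg: RarefactionConfig,
    dist: Optional[np.ndarray] = None,
) -> dict[str, Optional[float]]:
    """Rarefied FAD/MFAD/APWD/H/Hbc/G/J for one group, sharing subsamples.

    Vectorized equivalent of calling :func:`rarefied_metric` once per
    metric with the same replicate draws.  ``dist`` optionally supplies
    the group's precomputed Tanimoto distance matrix.  Also reports the
    fraction of null replicates per metric under ``null_frac_*``.
    """
    idx = draw_subsamples(group, cfg)
    m = cfg.subsample_size

    out: dict[str, Optional[float]] = {}

    if dist is None:
        dist = distance_matrix(group.fingerprints)
    fad = np.array([dist[np.ix_(row, row)].sum() for row in idx])
    out["rarefied_FAD"] = float(fad.mean())
    out["rarefied_MFAD"] = float(fad.mean()) / m
    out["rarefied_APWD"] = float(fad.mean()) / (m * m - m)

    codes = np.array([PATHWAYS.index(p) for p in group.pathways])
    counts = np.zeros((cfg.replicates, len(PATHWAYS)), dtype=np.int64)
    rows = np.repeat(np.arange(cfg.replicates), m)
    np.add.at(counts, (rows, codes[idx].ravel()), 1)

    for name, fn in [
        ("rarefied_H", pm.shannon_rows),
        ("rarefied_Hbc", pm.shannon_bias_controlled_rows),
        ("rarefied_G", pm.gini_simpson_rows),
        ("rarefied_J", pm.pielou_rows),
    ]:
        vals = fn(counts)
        ok = np.isfinite(vals)
        out["null_frac_" + name.removeprefix("rarefied_")] = float(1.0 - ok.mean())
        if ok.any():
            out[name] = float(vals[ok].mean())
        else:
            logger.warning("all rarefaction replicates null for %s in %r", name, group.region)
            out[name] = None
    return out
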
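"""Compound-level (functional attribute) diversity from fingerprint distances.

Disparity between compounds is the Tanimoto (Jaccard) distance between
their binary fingerprints.  Three group-level summaries are computed from
the pairwise distance matrix d_ij:

* FAD  = sum_i sum_j d_ij over the full N x N double sum (richness and
  disparity; the diagonal contributes zero, so FAD is twice the
  unordered-pair sum),
* MFAD = FAD / N (partial correction for compound count),
* APWD = FAD / (N^2 - N), the mean pairwise distance (pure disparity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datamodel import Fingerprint, RegionGroup

logger = logging.getLogger("phytodiv")


@dataclass(frozen=True)
class CompoundDiversityResult:
    N: int
    FAD: float
    MFAD: float
    APWD: Optional[float]  # null for N == 1


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto distance 1 - |A n B| / |A u B| between two fingerprints.

    Two empty fingerprints are defined as identical (distance 0) with a
    logged warning.
    """
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprints have different bit-space sizes")
    union = len(a.bits | b.bits)
    if union == 0:
        logger.warning("Tanimoto distance of two empty fingerprints defined as 0")
        return 0.0
    return 1.0 - len(a.bits & b.bits) / union


def distance_matrix(fingerprints: Sequence[Fingerprint]) -> np.ndarray:
    """Symmetric zero-diagonal matrix of pairwise Tanimoto distances.

    Computed via a dense bit matrix: O(N^2) memory per call, nothing is
    cached across calls.
    """
    n = len(fingerprints)
    if n == 0:
        return np.zeros((0, 0))
    n_bits = fingerprints[0].n_bits
    if any(fp is None for fp in fingerprints):
        raise ValueError("missing fingerprint: cannot compute distances")
    if any(fp.n_bits != n_bits for fp in fingerprints):
        raise ValueError("fingerprints have different bit-space sizes")
    bitmat = np.zeros((n, n_bits), dtype=np.float64)
    for i, fp in enumerate(fingerprints):
        if fp.bits:
            bitmat[i, list(fp.bits)] = 1.0
    inter = bitmat @ bitmat.T
    sizes = bitmat.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - inter / union
    dist[union == 0] = 0.0  # pair of empty fingerprints
    np.fill_diagonal(dist, 0.0)
    return dist


def write_distance_cache(labels: Sequence[str], dist: np.ndarray, path) -> None:
    """Persist pairwise distances as CSV (struct_a,struct_b,distance).

    One row per unordered pair with struct_a < struct_b, so the cache is
    independent of compound order.
    """
    import pandas as pd

    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = sorted((labels[i], labels[j]))
            d = dist[i, j]
            rows.append({"struct_a": a, "struct_b": b, "distance": d})
    rows.sort(key=lambda r: (r["struct_a"], r["struct_b"]))
    pd.DataFrame(rows, columns=["struct_a", "struct_b", "distance"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_distance_cache(path) -> dict[tuple[str, str], float]:
    """Load a distance cache; keys are sorted (struct_a, struct_b) pairs."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"struct_a": str, "struct_b": str})
    return {
        (row.struct_a, row.struct_b): float(row.distance)
        for row in df.itertuples(index=False)
    }


def distance_matrix_from_cache(
    labels: Sequence[str], cache: dict[tuple[str, str], float]
) -> np.ndarray:
    """Rebuild the symmetric distance matrix for ``labels`` from a cache."""
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((labels[i], labels[j])))
            dist[i, j] = dist[j, i] = cache[key]
    return dist


def compound_diversity(
    group: RegionGroup, dist: Optional[np.ndarray] = None
) -> CompoundDiversityResult:
    """FAD, MFAD and APWD for one region group.

    ``dist`` may supply a precomputed distance matrix (e.g. shared with
    rarefaction); otherwise it is computed from the group's fingerprints
    and released on return.
    """
    n = len(group)
    if n == 0:
        raise ValueError("empty group")
    if n == 1:
        return CompoundDiversityResult(N=1, FAD=0.0, MFAD=0.0, APWD=None)
    if dist is None:
        dist = distance_matrix(group.fingerprints)
    fad = float(dist.sum())
    return CompoundDiversityResult(N=n, FAD=fad, MFAD=fad / n, APWD=fad / (n * n - n))
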
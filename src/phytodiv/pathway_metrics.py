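"""Pathway-level diversity: richness/evenness metrics over the seven
NPClassifier biosynthetic pathway classes.

With presence-only compound data, relative abundance of a pathway within a
group is the fraction of the group's compounds assigned to it.  From the
resulting count vector we compute:

* Shannon index                 H   = -sum p_i ln p_i
* sample coverage               C   = 1 - f1/N       (f1: singleton pathways)
* bias-controlled Shannon       Hbc = -sum (p_i C ln(p_i C)) / (1 - (1 - p_i C)^N)
  (the Chao-Shen coverage-adjusted entropy estimator)
* Gini-Simpson index            G   = 1 - sum p_i^2
* Pielou's evenness             J   = H / ln P       (null when P = 1)

Sums run over pathways with p_i > 0 (the 0 ln 0 = 0 convention).  Nulls
propagate as ``None`` so region rows keep explicit missing cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np

logger = logging.getLogger("phytodiv")


@dataclass(frozen=True)
class PathwayCounts:
    """Per-pathway compound counts for one group."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative pathway count")
        if self.N < 1:
            raise ValueError("need at least one compound")

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "PathwayCounts":
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        return cls(counts=counts)

    @property
    def N(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def P(self) -> int:
        """Number of pathways present (count > 0)."""
        return sum(1 for v in self.counts.values() if v > 0)

    @property
    def p(self) -> np.ndarray:
        """Relative abundances of the pathways present, in stable order."""
        vals = np.array([v for v in self.counts.values() if v > 0], dtype=float)
        return vals / vals.sum()

    @property
    def f1(self) -> int:
        """Number of singleton pathways (exactly one compound)."""
        return sum(1 for v in self.counts.values() if v == 1)


def shannon(pc: PathwayCounts) -> float:
    """Shannon index H of the pathway relative abundances."""
    p = pc.p
    return float(-(p * np.log(p)).sum())


def sample_coverage(pc: PathwayCounts) -> float:
    """Estimated sample coverage C = 1 - f1/N."""
    return 1.0 - pc.f1 / pc.N


def shannon_bias_controlled(pc: PathwayCounts) -> Optional[float]:
    """Coverage-adjusted Shannon index Hbc; null when coverage is zero.

    When every pathway present is a singleton C = 0, all adjusted
    abundances vanish and the estimator is undefined.
    """
    c = sample_coverage(pc)
    if c == 0.0:
        logger.warning("sample coverage 0 (all pathways singletons): Hbc undefined")
        return None
    x = pc.p * c
    return float(-np.sum(x * np.log(x) / (1.0 - (1.0 - x) ** pc.N)))


def gini_simpson(pc: PathwayCounts) -> float:
    """Gini-Simpson index G = 1 - sum p_i^2."""
    p = pc.p
    return float(1.0 - (p * p).sum())


def pielou(pc: PathwayCounts) -> Optional[float]:
    """Pielou's evenness J = H / ln P; null when a single pathway is present."""
    if pc.P == 1:
        return None
    return shannon(pc) / float(np.log(pc.P))


# -- vectorized forms over a (replicates x pathways) count matrix ----------
# Used by rarefaction, where the same metrics are evaluated on thousands of
# subsample count vectors at once.  Null becomes NaN here.

def shannon_rows(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1)


def gini_simpson_rows(counts: np.ndarray) -> np.ndarray:
    p = counts / counts.sum(axis=1, keepdims=True)
    return 1.0 - (p * p).sum(axis=1)


def pielou_rows(counts: np.ndarray) -> np.ndarray:
    P = (counts > 0).sum(axis=1).astype(float)
    h = shannon_rows(counts)
    with np.errstate(divide="ignore", invalid="ignore"):
        j = h / np.log(P)
    j[P == 1] = np.nan
    return j


def shannon_bias_controlled_rows(counts: np.ndarray) -> np.ndarray:
    n = counts.sum(axis=1, keepdims=True).astype(float)
    f1 = (counts == 1).sum(axis=1, keepdims=True).astype(float)
    c = 1.0 - f1 / n
    x = counts / n * c
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(x) / (1.0 - (1.0 - x) ** n), 0.0)
    out = -terms.sum(axis=1)
    out[c[:, 0] == 0.0] = np.nan
    return out
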
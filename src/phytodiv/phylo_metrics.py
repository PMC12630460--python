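"""Faith's phylogenetic diversity and richness-independent residual PD.

Faith's PD of a species set is the total branch length of the minimal
subtree spanning the set.  Two root conventions are supported:

* MRCA convention (default): branches from the most recent common
  ancestor of the set down to its leaves; a singleton set has PD 0.
* root convention (``include_root=True``): additionally counts the stem
  path from the MRCA up to the tree root.

Because PD grows mechanically with species richness (SR), a
richness-independent score PD' is computed as the residual of PD after a
robust LOWESS regression of PD on SR (local linear fits, robust to
outliers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

logger = logging.getLogger("phytodiv")


@dataclass(frozen=True)
class PDRecord:
    """Per-region species richness, Faith PD and its LOWESS residual."""

    region: str
    SR: int
    PD: float
    PD_resid: Optional[float] = None


class Phylogeny:
    """Rooted tree with branch lengths over uniquely-labelled leaves.

    Thin wrapper over a dendropy tree; polytomies are preserved, missing
    branch lengths are treated as 0 with a warning, and duplicate leaf
    labels are a hard error.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels in tree")
        n_missing = 0
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                edge.length = 0.0
                n_missing += 1
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")
        if n_missing:
            logger.warning("%d missing branch lengths treated as 0", n_missing)
        self._leaves = frozenset(labels)

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        from dendropy.dataio.newickreader import NewickReader

        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate leaf labels in tree: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True)

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self._leaves

    def __len__(self) -> int:
        return len(self._leaves)

    def faith_pd(self, species: Iterable[str], include_root: bool = False) -> Optional[float]:
        """Faith's PD of ``species``; see module docstring for conventions.

        Names absent from the tree are dropped with a logged count; an
        empty intersection yields None with a warning.
        """
        wanted = set(species)
        missing = wanted - self._leaves
        if missing:
            logger.info("%d species not in tree dropped from PD", len(missing))
            wanted -= missing
        if not wanted:
            logger.warning("no species in tree: PD undefined")
            return None
        k = len(wanted)
        # Postorder count of retained leaves below each edge.  Under the
        # MRCA convention an edge is spanned iff its subtree holds some
        # but not all retained leaves; edges holding all k lie on the
        # MRCA-to-root stem and count only under the root convention.
        total = 0.0
        counts: dict[int, int] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                cnt = 1 if (node.taxon and node.taxon.label in wanted) else 0
            else:
                cnt = sum(counts[id(ch)] for ch in node.child_nodes())
            counts[id(node)] = cnt
            if node is self._tree.seed_node or node.edge.length is None:
                continue
            if (1 <= cnt <= k - 1) or (include_root and cnt == k):
                total += node.edge.length
        return total


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (bifurcating or multifurcating) into a Phylogeny."""
    return Phylogeny.from_newick(text)


def faith_pd(
    tree: Phylogeny, species: Iterable[str], include_root: bool = False
) -> Optional[float]:
    return tree.faith_pd(species, include_root=include_root)


def lowess_fit(
    x: np.ndarray, y: np.ndarray, frac: float = 2.0 / 3.0, it: int = 3
) -> np.ndarray:
    """Robust LOWESS fitted values of y on x at the observed x.

    Tied x values receive identical fitted values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return _sm_lowess(y, x, frac=frac, it=it, return_sorted=False)


def sr_independent_pd(
    records: Sequence[PDRecord], frac: float = 2.0 / 3.0, it: int = 3
) -> list[PDRecord]:
    """Fill PD_resid = PD - LOWESS(PD ~ SR) for a set of region records.

    Requires at least 10 records: residualizing a smoother fitted to fewer
    points is not meaningful.
    """
    if len(records) < 10:
        raise ValueError(
            f"need >= 10 records to residualize PD on SR, got {len(records)}"
        )
    sr = np.array([r.SR for r in records], dtype=float)
    pd_ = np.array([r.PD for r in records], dtype=float)
    fitted = lowess_fit(sr, pd_, frac=frac, it=it)
    return [replace(r, PD_resid=float(p - f)) for r, p, f in zip(records, pd_, fitted)]
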
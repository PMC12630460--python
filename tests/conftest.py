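"""Shared fixtures: random group factories, toy trees, and small studies."""

from __future__ import annotations

import numpy as np
import pytest

import phytodiv as pv
from phytodiv.datamodel import PATHWAYS, Compound, Fingerprint, RegionGroup


def make_fingerprint(rng: np.random.Generator, n_bits: int = 128, n_on: int = 16) -> Fingerprint:
    bits = rng.choice(n_bits, size=min(n_on, n_bits), replace=False)
    return Fingerprint(bits=frozenset(int(b) for b in bits), n_bits=n_bits)


def make_group(
    rng: np.random.Generator,
    n: int,
    region: str = "FIJ",
    n_bits: int = 128,
    n_on: int = 16,
    pathways=None,
) -> RegionGroup:
    """Random region group with sparse random fingerprints."""
    if pathways is None:
        pathways = [PATHWAYS[int(i)] for i in rng.integers(0, len(PATHWAYS), size=n)]
    comps = tuple(
        Compound(
            structure=f"S{i:04d}",
            pathway=pathways[i],
            fingerprint=make_fingerprint(rng, n_bits=n_bits, n_on=n_on),
        )
        for i in range(n)
    )
    return RegionGroup(region=region, compounds=comps,
                       species=frozenset({f"sp{i}" for i in range(max(2, n // 3))}))


def fad_bruteforce(group: RegionGroup) -> float:
    """Independent double-loop oracle for the FAD double sum."""
    total = 0.0
    fps = group.fingerprints
    for a in fps:
        for b in fps:
            union = a.bits | b.bits
            if union:
                total += 1.0 - len(a.bits & b.bits) / len(union)
    return total


def faith_pd_bruteforce(newick: str, species: set[str]) -> float:
    """Mark edges on each leaf-to-MRCA path and sum their lengths.

    Built directly on dendropy parent pointers, independent of the
    package's postorder-count implementation.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    nodes = [leaves[s] for s in species if s in leaves]
    if not nodes:
        return float("nan")
    ancestor_sets = []
    for node in nodes:
        anc = {id(node)}
        for a in node.ancestor_iter():
            anc.add(id(a))
        ancestor_sets.append(anc)
    common = set.intersection(*ancestor_sets)
    marked = {}
    for node in nodes:
        cur = node
        while id(cur) not in common:
            marked[id(cur)] = cur.edge.length or 0.0
            cur = cur.parent_node
    return float(sum(marked.values()))


def balanced_newick(labels: list[str], branch_length: float = 1.0) -> str:
    """Balanced binary Newick subtree over labels, all branch lengths equal."""

    def rec(names):
        if len(names) == 1:
            return f"{names[0]}:{branch_length}"
        mid = len(names) // 2
        return f"({rec(names[:mid])},{rec(names[mid:])}):{branch_length}"

    inner = rec(labels)
    return f"({inner});" if not inner.startswith("(") else inner[: inner.rfind(":")] + ";"


@pytest.fixture()
def toy_tree() -> pv.Phylogeny:
    return pv.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def small_study() -> pv.SimulatedStudy:
    cfg = pv.ScenarioConfig(n_species=150, n_regions=15, n_compounds=600, seed=11)
    return pv.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_profiles(small_study) -> "pd.DataFrame":  # noqa: F821
    tree = pv.parse_newick(small_study.tree_newick)
    return pv.compute_profiles(
        small_study.occurrences,
        tree=tree,
        distributions=small_study.distributions,
        fingerprints=small_study.fingerprints,
        config=pv.PipelineConfig(seed=11, rarefy_reps=200),
    )
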
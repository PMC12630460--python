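"""Synthetic species-compound-region studies with realistic structure.

Real compiled phytochemical occurrence data have three salient features
this generator emulates:

* a heavily right-skewed compounds-per-species distribution — most
  species carry 1-3 recorded compounds while a handful of intensively
  studied species carry over a hundred.  Counts are drawn from a
  log-series distribution with a small admixture of "superproducer"
  species whose counts are geometric with a large mean;
* seven biosynthetic pathway classes with very uneven global frequencies,
  and per-species pathway specialisation controlled by a Dirichlet
  concentration (low concentration = pathway-specialist species = uneven
  regional pathway mixtures = low evenness J);
* botanical regions of very different sizes (island-like small regions
  through mainland-sized ones), with species natively spanning one to
  several regions, and a Yule (pure-birth) phylogeny over all species.

Everything is reproducible from the master seed; fingerprints are
deterministic hashes of the synthetic structure IDs (see
:class:`~phytodiv.chem.HashedFingerprinter`), so no chemistry is needed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import random as _random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy import stats

from .chem import HashedFingerprinter
from .datamodel import PATHWAYS, CompoundOccurrence, Fingerprint, known_region_codes
from .io import (
    write_distribution_table,
    write_fingerprint_table,
    write_occurrence_table,
)
from .pathway_metrics import PathwayCounts

logger = logging.getLogger("phytodiv")

#: Global pathway frequencies, skewed like compiled phytochemical datasets
#: (terpenoids and alkaloids dominate; carbohydrates are rare).
DEFAULT_BASE_MIXTURE: tuple[float, ...] = (
    0.07,  # fatty acids
    0.12,  # polyketides
    0.18,  # shikimates-phenylpropanoids
    0.30,  # terpenoids
    0.25,  # alkaloids
    0.05,  # amino acids/peptides
    0.03,  # carbohydrates
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the synthetic study; defaults are the standard scenario."""

    n_species: int = 500
    n_regions: int = 30
    n_compounds: int = 1500
    #: compounds-per-species model: "logseries" or "ztnb" (zero-truncated
    #: negative binomial with shape ztnb_r and mean ztnb_mean)
    count_dist: str = "logseries"
    logser_p: float = 0.9
    ztnb_r: float = 0.5
    ztnb_mean: float = 4.0
    #: fraction of intensively-studied species and mean of their
    #: geometric compound counts (the >100-compound tail)
    superproducer_frac: float = 0.02
    superproducer_mean: float = 80.0
    base_mixture: tuple[float, ...] = DEFAULT_BASE_MIXTURE
    #: Dirichlet concentration of per-region pathway mixtures; large =
    #: every region mirrors the global mixture, small = regions dominated
    #: by one or two pathways (uneven regions, low evenness J)
    dirichlet_alpha: float = 20.0
    n_bits: int = 2048
    bits_per_compound: int = 64
    birth_rate: float = 1.0
    #: species span 1 + Poisson(mean_regions_per_species - 1) regions
    mean_regions_per_species: float = 2.0
    #: SD of the log-normal region attractiveness weights (region-size skew)
    region_weight_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_regions, self.n_compounds) < 1:
            raise ValueError("counts must be positive")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be > 0")
        if not np.isclose(sum(self.base_mixture), 1.0):
            raise ValueError("base_mixture must sum to 1")
        if self.count_dist not in ("logseries", "ztnb"):
            raise ValueError("count_dist must be 'logseries' or 'ztnb'")


@dataclass
class SimulatedStudy:
    """In-memory result of :func:`simulate_study`."""

    occurrences: list[CompoundOccurrence]
    distributions: dict[str, set[str]]
    tree_newick: str
    fingerprints: dict[str, Fingerprint]
    library: pd.DataFrame
    config: ScenarioConfig


def simulate_library(
    cfg: ScenarioConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, dict[str, Fingerprint]]:
    """Global compound pool: structure IDs, pathway labels, fingerprints.

    Pathways are multinomial draws from ``cfg.base_mixture``; each
    compound also gets a log-normal "popularity" weight governing how
    often species share it.  Fingerprints are deterministic sparse hashes
    of the structure ID.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_compounds
    structures = [f"SYN{i:06d}" for i in range(n)]
    pathway_idx = rng.choice(len(PATHWAYS), size=n, p=np.asarray(cfg.base_mixture))
    popularity = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    fper = HashedFingerprinter(n_bits=cfg.n_bits, n_on=cfg.bits_per_compound)
    fps = {s: fper.fingerprint(s) for s in structures}
    lib = pd.DataFrame(
        {
            "structure": structures,
            "pathway": [PATHWAYS[i] for i in pathway_idx],
            "popularity": popularity,
        }
    )
    return lib, fps


def _species_compound_counts(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_species
    if cfg.count_dist == "logseries":
        counts = stats.logser.rvs(cfg.logser_p, size=n, random_state=rng)
    else:
        # zero-truncated NB via rejection (resample zeros)
        p = cfg.ztnb_r / (cfg.ztnb_r + cfg.ztnb_mean)
        counts = stats.nbinom.rvs(cfg.ztnb_r, p, size=n, random_state=rng)
        while (counts == 0).any():
            zeros = counts == 0
            counts[zeros] = stats.nbinom.rvs(
                cfg.ztnb_r, p, size=int(zeros.sum()), random_state=rng
            )
    boosted = rng.random(n) < cfg.superproducer_frac
    counts = counts.astype(int)
    counts[boosted] = 1 + rng.geometric(1.0 / cfg.superproducer_mean, size=int(boosted.sum()))
    return np.minimum(counts, cfg.n_compounds)


def _yule_tree(species: list[str], birth_rate: float, seed: int) -> str:
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=len(species),
        rng=_random.Random(seed),
    )
    for leaf, name in zip(tree.leaf_node_iter(), species):
        leaf.taxon.label = name
    return tree.as_string(schema="newick", suppress_rooting=True)


def simulate_study(cfg: ScenarioConfig) -> SimulatedStudy:
    """Full synthetic study: occurrences, native ranges, and a Yule tree.

    Each region draws a pathway mixture from Dirichlet(alpha * base
    mixture).  Species are assigned native regions by
    attractiveness-weighted draws (log-normal weights make a few
    mainland-like regions and many small ones) and inherit the mixture of
    their first-drawn native region; their compound set is then sampled
    from the global library weighted by compound popularity times that
    mixture's weight for the compound's pathway.  Region pathway
    composition therefore tracks its own mixture, and the concentration
    parameter is an evenness dial.
    """
    rng = np.random.default_rng(cfg.seed)
    lib, fps = simulate_library(cfg, rng)
    pathway_code = np.array([PATHWAYS.index(p) for p in lib["pathway"]])
    popularity = lib["popularity"].to_numpy()

    species = [f"Taxon_{i:04d}" for i in range(cfg.n_species)]
    codes = sorted(known_region_codes())
    region_codes = list(rng.choice(codes, size=min(cfg.n_regions, len(codes)), replace=False))
    region_weights = rng.lognormal(0.0, cfg.region_weight_sigma, size=len(region_codes))
    region_weights /= region_weights.sum()

    counts = _species_compound_counts(cfg, rng)
    alpha = cfg.dirichlet_alpha * np.clip(np.asarray(cfg.base_mixture), 1e-9, None)
    region_mixtures = rng.dirichlet(alpha, size=len(region_codes))

    occurrences: list[CompoundOccurrence] = []
    distributions: dict[str, set[str]] = {}
    for s_idx, taxon in enumerate(species):
        n_reg = 1 + rng.poisson(max(cfg.mean_regions_per_species - 1.0, 0.0))
        n_reg = min(n_reg, len(region_codes))
        drawn = rng.choice(
            len(region_codes), size=n_reg, replace=False, p=region_weights
        )
        native = frozenset(region_codes[i] for i in drawn)
        distributions[taxon] = set(native)
        theta = region_mixtures[drawn[0]]
        w = popularity * np.clip(theta[pathway_code], 1e-12, None)
        chosen = rng.choice(cfg.n_compounds, size=counts[s_idx], replace=False, p=w / w.sum())
        for c in chosen:
            occurrences.append(
                CompoundOccurrence(
                    taxon=taxon,
                    structure=lib["structure"].iat[c],
                    pathway=lib["pathway"].iat[c],
                    regions=native,
                )
            )

    tree_seed = int(rng.integers(0, 2**31 - 1))
    newick = _yule_tree(species, cfg.birth_rate, tree_seed)
    return SimulatedStudy(
        occurrences=occurrences,
        distributions=distributions,
        tree_newick=newick,
        fingerprints=fps,
        library=lib,
        config=cfg,
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write the study as the plain-text files the pipeline reads.

    Emits occurrences.csv, distributions.csv, tree.nwk, fingerprints.csv
    and scenario.json (the resolved config) under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrences": outdir / "occurrences.csv",
        "distributions": outdir / "distributions.csv",
        "tree": outdir / "tree.nwk",
        "fingerprints": outdir / "fingerprints.csv",
        "scenario": outdir / "scenario.json",
    }
    write_occurrence_table(study.occurrences, paths["occurrences"])
    write_distribution_table(study.distributions, paths["distributions"])
    paths["tree"].write_text(study.tree_newick)
    write_fingerprint_table(study.fingerprints, paths["fingerprints"])
    paths["scenario"].write_text(
        json.dumps(dataclasses.asdict(study.config), indent=2) + "\n"
    )
    return paths


def sample_pathway_counts(
    mixture, n: int, rng: np.random.Generator
) -> PathwayCounts:
    """Multinomial pathway counts of size ``n`` from a mixture over the 7 classes.

    Convenience for constructing regions with a prescribed pathway
    composition (e.g. uniform vs 90/10) in simulation studies.
    """
    mixture = np.asarray(mixture, dtype=float)
    mixture = mixture / mixture.sum()
    draws = rng.multinomial(n, mixture)
    labels = PATHWAYS[: len(mixture)]
    return PathwayCounts(counts={lab: int(c) for lab, c in zip(labels, draws) if c > 0})
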
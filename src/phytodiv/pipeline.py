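"""End-to-end orchestration: records -> per-region diversity table -> analysis.

``compute_profiles`` runs the full metric stage: group occurrence records
by region, discard under-sampled groups, compute the compound-level
(FAD/MFAD/APWD), pathway-level (H/Hbc/G/J) and rarefied metrics per
region, then species richness, Faith PD and the richness-independent PD
residual.  ``associate_profiles`` runs the analysis stage: Yeo-Johnson
normalization, the Spearman correlation matrix, and LOWESS residual
outlier flags for each metric against PD.

All randomness flows from a single master seed; per-region streams are
derived from (seed, region code), so results are independent of
processing order and adding a region never perturbs another's numbers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from . import association as assoc
from .compound_metrics import compound_diversity, distance_matrix
from .datamodel import CompoundOccurrence
from .grouping import FingerprintSource, build_region_groups, filter_groups
from .io import DIVERSITY_COLUMNS, write_diversity_table
from .pathway_metrics import (
    PathwayCounts,
    gini_simpson,
    pielou,
    shannon,
    shannon_bias_controlled,
)
from .phylo_metrics import PDRecord, Phylogeny, sr_independent_pd
from .rarefaction import RarefactionConfig, rarefy_group

logger = logging.getLogger("phytodiv")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (JSON-serializable)."""

    min_group_size: int = 7
    rarefy_m: int = 7
    rarefy_reps: int = 1000
    lowess_frac: float = 2.0 / 3.0
    lowess_it: int = 3
    pd_include_root: bool = False
    outlier_k: float = 2.0
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def compute_profiles(
    records: Iterable[CompoundOccurrence],
    tree: Optional[Phylogeny] = None,
    distributions: Optional[Mapping[str, set]] = None,
    fingerprints: Optional[FingerprintSource] = None,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Per-region diversity table (one row per retained region).

    Parameters
    ----------
    records
        Standardized occurrence records.
    tree
        Rooted phylogeny for SR/PD; omit to skip the phylogenetic columns.
    distributions
        ``taxon -> native region codes``; defines the species pool per
        region for SR/PD.  Defaults to the species observed contributing
        compounds to each region.
    fingerprints
        Structure -> fingerprint mapping or callable.
    """
    cfg = config or PipelineConfig()
    groups = filter_groups(
        build_region_groups(records, fingerprints=fingerprints),
        min_size=cfg.min_group_size,
    )
    rare_cfg = RarefactionConfig(
        subsample_size=cfg.rarefy_m, replicates=cfg.rarefy_reps, seed=cfg.seed
    )

    species_by_region: dict[str, set] = {}
    if distributions is not None:
        for taxon, codes in distributions.items():
            for code in codes:
                species_by_region.setdefault(code, set()).add(taxon)

    rows = []
    for group in groups:
        dist = distance_matrix(group.fingerprints)
        cd = compound_diversity(group, dist)
        pc = PathwayCounts.from_labels(group.pathways)
        row: dict = {
            "region": group.region,
            "N": cd.N,
            "FAD": cd.FAD,
            "MFAD": cd.MFAD,
            "APWD": cd.APWD,
            "H": shannon(pc),
            "Hbc": shannon_bias_controlled(pc),
            "G": gini_simpson(pc),
            "J": pielou(pc),
        }
        row.update(rarefy_group(group, rare_cfg, dist))
        del dist  # O(N^2) memory released before the next group

        if tree is not None:
            pool = species_by_region.get(group.region, group.species)
            in_tree = set(pool) & set(tree.leaf_labels)
            row["SR"] = len(in_tree)
            row["PD"] = (
                tree.faith_pd(in_tree, include_root=cfg.pd_include_root)
                if in_tree
                else None
            )
        rows.append(row)

    df = pd.DataFrame(rows)
    if df.empty:
        logger.warning("no region groups survived filtering: empty diversity table")
        return pd.DataFrame(columns=DIVERSITY_COLUMNS)

    if tree is not None:
        ok = df["PD"].notna()
        if int(ok.sum()) >= 10:
            pd_records = [
                PDRecord(region=r.region, SR=int(r.SR), PD=float(r.PD))
                for r in df[ok].itertuples(index=False)
            ]
            fitted = sr_independent_pd(pd_records, frac=cfg.lowess_frac, it=cfg.lowess_it)
            resid = {rec.region: rec.PD_resid for rec in fitted}
            df["PD_resid"] = df["region"].map(resid)
        else:
            logger.warning("fewer than 10 regions with PD: skipping residualization")
            df["PD_resid"] = np.nan

    cols = [c for c in DIVERSITY_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    return df[cols].sort_values("region", kind="stable").reset_index(drop=True)


def associate_profiles(
    profiles: pd.DataFrame, config: Optional[PipelineConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analysis stage: correlations among metrics, and outlier flags.

    Variables are Yeo-Johnson transformed (Spearman correlations are
    unaffected by the monotone transform; the LOWESS outlier step uses
    the transformed scale).  Returns ``(correlations, outliers)`` tidy
    frames.
    """
    cfg = config or PipelineConfig()
    if len(profiles) < 10:
        raise ValueError("need >= 10 profile rows for the association analysis")

    variables = [
        v
        for v in assoc.METRIC_VARIABLES + assoc.PHYLO_VARIABLES
        if v in profiles.columns and profiles[v].notna().sum() >= 3
    ]
    dropped = [
        v
        for v in assoc.METRIC_VARIABLES + assoc.PHYLO_VARIABLES
        if v in profiles.columns and v not in variables
    ]
    for v in dropped:
        logger.warning("variable %r dropped from analysis (too few non-null values)", v)

    transformed = profiles[["region"]].copy()
    for v in variables:
        transformed[v] = assoc.yeo_johnson(profiles[v])[0]

    correlations = assoc.correlation_matrix(transformed, variables=variables)

    out_rows = []
    if "PD" in variables:
        for metric in assoc.METRIC_VARIABLES:
            if metric not in variables:
                continue
            pair = transformed[["region", "PD", metric]].dropna()
            if len(pair) < 10:
                continue
            for rep in assoc.flag_outliers(
                pair, x_var="PD", y_var=metric, k=cfg.outlier_k,
                frac=cfg.lowess_frac, it=cfg.lowess_it,
            ):
                out_rows.append(dataclasses.asdict(rep))
    outliers = pd.DataFrame(
        out_rows, columns=["region", "metric", "residual", "z", "direction"]
    )
    return correlations, outliers


def write_analysis(
    correlations: pd.DataFrame, outliers: pd.DataFrame, outdir
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "correlations": outdir / "correlations.csv",
        "outliers": outdir / "outliers.csv",
    }
    correlations.to_csv(paths["correlations"], index=False, float_format="%.12g")
    outliers.to_csv(paths["outliers"], index=False, float_format="%.12g")
    return paths


def write_profiles(profiles: pd.DataFrame, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "diversity.csv"
    write_diversity_table(profiles, path)
    return path
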
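"""Derivation of gene features and genetic-interaction degrees from generic inputs.

Only features computable from generic resources are derived here:
multifunctionality (distinct GO terms), conservation counts (23 Ascomycota
species or 86 broader eukaryotes), paralog copy number, physical-interaction
degree over a whitelist of evidence types, expression variation (average
per-study variance percentile), and co-expression degree from a sparsified
weighted network.  Sequence-tool features (CAI, Nc, disorder, dN/dS, protein
length, domain counts) and lab measurements (single-mutant fitness defect,
expression level) are consumed as precomputed columns and never computed.

GI degree is derived from screen score tables by thresholding: negative
interactions at epsilon <= -0.08 with p < 0.05 (strict variant -0.12), or
S-score <= -2.5 for screens on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import Parameters
from .tables import (
    AnnotationSet,
    DegreeTable,
    InteractionScoreTable,
    ThresholdRecord,
    WeightedGeneNetwork,
)

__all__ = [
    "PHYSICAL_EVIDENCE",
    "ExpressionDataset",
    "ParalogClusters",
    "multifunctionality",
    "conservation_count",
    "copy_number",
    "ppi_degree",
    "preprocess_expression",
    "expression_variation",
    "coexpression_degree",
    "degrees_from_interaction_scores",
    "midrank_percentiles",
]

#: BioGRID evidence types counted as physical interactions.
PHYSICAL_EVIDENCE: frozenset[str] = frozenset(
    {
        "Affinity Capture-MS",
        "Affinity Capture-RNA",
        "Affinity Capture-Western",
        "Biochemical Activity",
        "Co-crystal Structure",
        "Co-fractionation",
        "Co-localization",
        "Co-purification",
        "Far Western",
        "FRET",
        "PCA",
        "Protein-peptide",
        "Protein-RNA",
        "Reconstituted Complex",
        "Two-hybrid",
    }
)


@dataclass
class ExpressionDataset:
    """One expression study: genes x samples matrix plus its measurement scale."""

    study_id: str
    matrix: pd.DataFrame  # genes x samples
    scale: str = "log_ratio"  # or "intensity"

    def __post_init__(self) -> None:
        if self.scale not in ("intensity", "log_ratio"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.matrix.shape[1] < 1:
            raise ValueError("expression dataset needs at least one sample")
        if self.matrix.index.has_duplicates:
            raise ValueError("duplicate genes in expression matrix")


@dataclass
class ParalogClusters:
    """Disjoint within-species paralog clusters (InParanoid-style)."""

    clusters: list[frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cl in self.clusters:
            if seen & cl:
                raise ValueError("paralog clusters must be disjoint")
            seen |= cl


def multifunctionality(annotations: AnnotationSet) -> pd.Series:
    """Number of distinct canonical GO terms annotated to each gene."""
    counts = {g: len(ts) for g, ts in annotations.annotations.items()}
    return pd.Series(counts, dtype=int, name="multifunctionality")


def conservation_count(presence: pd.DataFrame, mode: str = "yeast") -> pd.Series:
    """Count species (columns) in which each gene (row) has an ortholog.

    ``mode="yeast"`` expects 23 Ascomycota species columns, ``mode="broad"``
    expects 86 non-yeast species columns.
    """
    expected = {"yeast": 23, "broad": 86}
    if mode not in expected:
        raise ValueError("mode must be 'yeast' or 'broad'")
    if presence.shape[1] != expected[mode]:
        raise ValueError(
            f"{mode} conservation needs {expected[mode]} species columns, "
            f"got {presence.shape[1]}"
        )
    name = "yeast_conservation" if mode == "yeast" else "broad_conservation"
    return presence.astype(bool).sum(axis=1).astype(int).rename(name)


def copy_number(clusters: ParalogClusters) -> pd.Series:
    """Number of paralogs per gene: cluster size minus one; unclustered -> 0."""
    out: dict[str, int] = {}
    for cl in clusters.clusters:
        for g in cl:
            out[g] = len(cl) - 1
    return pd.Series(out, dtype=int, name="copy_number")


def ppi_degree(
    edges: Iterable[tuple[str, str, str]],
    whitelist: Optional[Iterable[str]] = None,
) -> pd.Series:
    """Distinct physical-interaction partners per gene.

    Edges are (gene_a, gene_b, evidence_type) records; only whitelisted
    evidence types count, duplicate partners collapse, self-edges are
    excluded.
    """
    wl = PHYSICAL_EVIDENCE if whitelist is None else frozenset(whitelist)
    partners: dict[str, set[str]] = {}
    for a, b, ev in edges:
        if ev not in wl or a == b:
            continue
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    return pd.Series(
        {g: len(p) for g, p in partners.items()}, dtype=int, name="ppi_degree"
    )


def preprocess_expression(
    ds: ExpressionDataset, max_missing_frac: float = 0.30, k_neighbors: int = 10
) -> ExpressionDataset:
    """Filter, log-transform and KNN-impute one expression study.

    Genes missing in more than ``max_missing_frac`` of samples are dropped;
    intensity-scale data are log2-transformed; remaining missing cells are
    imputed as the mean, at that sample, of the ``k_neighbors`` complete
    genes most Pearson-correlated with the target gene over their shared
    observed samples.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    mat = ds.matrix.astype(float).copy()
    frac_missing = mat.isna().mean(axis=1)
    mat = mat.loc[frac_missing <= max_missing_frac]
    if mat.shape[0] == 0:
        raise ValueError(f"{ds.study_id}: no genes left after missingness filter")
    if ds.scale == "intensity":
        mat = np.log2(mat)
    if not mat.isna().any().any():
        return ExpressionDataset(ds.study_id, mat, "log_ratio")

    complete = mat.dropna(axis=0)
    values = mat.to_numpy()
    comp_vals = complete.to_numpy()
    for ridx, gene in enumerate(mat.index):
        row = values[ridx]
        miss = np.isnan(row)
        if not miss.any() or gene in complete.index:
            continue
        obs = ~miss
        if obs.sum() < 2 or len(complete) == 0:
            # cannot correlate: fall back to the gene's own observed mean
            values[ridx, miss] = np.nanmean(row)
            continue
        x = row[obs]
        xc = x - x.mean()
        ref = comp_vals[:, obs]
        refc = ref - ref.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum() * (refc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (refc @ xc) / denom
        corr = np.nan_to_num(corr, nan=-np.inf)
        k = min(k_neighbors, len(complete))
        nbrs = np.argsort(-corr, kind="stable")[:k]
        values[ridx, miss] = comp_vals[nbrs][:, miss].mean(axis=0)
    out = pd.DataFrame(values, index=mat.index, columns=mat.columns)
    return ExpressionDataset(ds.study_id, out, "log_ratio")


def midrank_percentiles(values: pd.Series) -> pd.Series:
    """Midrank percentiles in [0, 1]: (rank - 0.5)/n with ties averaged."""
    v = values.dropna()
    ranks = stats.rankdata(v.to_numpy(), method="average")
    out = pd.Series((ranks - 0.5) / len(v), index=v.index)
    return out.reindex(values.index)


def expression_variation(datasets: Sequence[ExpressionDataset]) -> pd.Series:
    """Average per-study variance percentile of each gene's expression.

    Within each (preprocessed) study, the variance of each gene across
    samples is converted to a midrank percentile among that study's genes;
    a gene's final value averages its percentiles over the studies that
    contain it.  Genes in no study are absent from the result.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one expression dataset")
    per_study = []
    for ds in datasets:
        var = ds.matrix.var(axis=1, ddof=1)
        per_study.append(midrank_percentiles(var))
    merged = pd.concat(per_study, axis=1)
    return merged.mean(axis=1, skipna=True).rename("expression_variation")


def coexpression_degree(net: WeightedGeneNetwork, density: float = 0.05) -> pd.Series:
    """Number of retained partners per gene after percentile sparsification."""
    from .coexpr import sparsify_network  # shared cutoff convention

    edges = sparsify_network(net, density=density)
    deg = {g: 0 for g in net.genes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    return pd.Series(deg, dtype=int, name="coexpression_degree")


def degrees_from_interaction_scores(
    scores: InteractionScoreTable,
    params: Parameters = Parameters(),
    mode: str = "epsilon",
    species: str = "unknown",
    array_side_only: bool = False,
) -> DegreeTable:
    """Count negative genetic interactions per gene from a screen score table.

    mode="epsilon": score <= eps_cutoff and p < p_cutoff;
    mode="epsilon_strict": score <= eps_strict and p < p_cutoff;
    mode="s_score": score <= s_cutoff (no p-value filter).
    A passing record counts toward both the query and the array gene unless
    ``array_side_only`` restricts degrees to array-side genes (screens where
    only a fixed query panel was crossed).
    """
    df = scores.records
    if mode in ("epsilon", "epsilon_strict"):
        if df["p_value"].isna().all() and len(df) > 0:
            raise ValueError("epsilon modes require p-values, all are missing")
        cutoff = params.eps_cutoff if mode == "epsilon" else params.eps_strict
        passing = (df["score"] <= cutoff) & (df["p_value"] < params.p_cutoff)
        prov = ThresholdRecord("epsilon", cutoff, params.p_cutoff)
    elif mode == "s_score":
        cutoff = params.s_cutoff
        passing = df["score"] <= cutoff
        prov = ThresholdRecord("s_score", cutoff, None)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if array_side_only:
        universe = pd.Index(df["array_gene"].unique())
    else:
        universe = pd.Index(
            pd.concat([df["query_gene"], df["array_gene"]]).unique()
        )
    hit = df.loc[passing]
    counts = pd.Series(0, index=universe, dtype=int)
    if len(hit):
        arr = hit["array_gene"].value_counts()
        counts = counts.add(arr.reindex(universe, fill_value=0), fill_value=0)
        if not array_side_only:
            qry = hit["query_gene"].value_counts()
            counts = counts.add(qry.reindex(universe, fill_value=0), fill_value=0)
    return DegreeTable(species=species, degrees=counts.astype(int), provenance=prov)
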
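"""Two-species synthetic data with the statistical structure the analysis assumes.

The generator stands in for real screen data so every pipeline stage runs
without downloads.  It emulates, at their published scale where one is
stated: two species whose one-to-one ortholog features are only modestly
correlated (single-mutant fitness defect rho = 0.2 across ~1,100 ortholog
pairs), GI degree produced by a shared monotone rule on the features plus
overdispersed (negative-binomial) noise, screen score tables whose
thresholded degrees reproduce planted degrees exactly, and paired
co-expression networks in which planted rewired genes' edges are conserved
at a reduced rate.

Feature marginals use a Gaussian copula: a latent standard-normal draw per
(gene, feature) -- correlated across species for orthologs -- is pushed
through a monotone, feature-appropriate transform (binomial counts for
conservation, lognormal lengths, unit-interval percentiles, ...), so the
cross-species correlation is controlled independently of the marginal
shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import Parameters
from .rewiring import GeneGroup, GeneGroupCatalog
from .tables import (
    CANONICAL_FEATURES,
    DegreeTable,
    FeatureTable,
    InteractionScoreTable,
    OrthologyMap,
    WeightedGeneNetwork,
)

__all__ = [
    "SimulationConfig",
    "SimulatedPair",
    "simulate_species_pair",
    "simulate_interaction_screen",
    "simulate_coexpression_pair",
    "simulate_group_catalog",
]

# Cross-species latent correlations.  Sequence-derived features are strongly
# conserved; physiological features only modestly (fitness defect r = 0.2).
_DEFAULT_RHO: dict[str, float] = {
    "sm_fitness_defect": 0.2,
    "multifunctionality": 0.3,
    "yeast_conservation": 0.7,
    "broad_conservation": 0.7,
    "ppi_degree": 0.2,
    "expression_level": 0.4,
    "disorder": 0.7,
    "cai": 0.7,
    "protein_length": 0.9,
    "coexpression_degree": 0.2,
    "n_domains": 0.9,
    "n_unique_domains": 0.9,
    "nc": 0.7,
    "dn_ds": 0.7,
    "copy_number": 0.5,
    "expression_variation": 0.3,
}

# Shared feature -> log-degree rule; signs follow the observed feature/degree
# correlations (fitness defect dominant and positive, expression variation
# and copy number negative).
_DEFAULT_COEFFS: dict[str, float] = {
    "sm_fitness_defect": 0.55,
    "multifunctionality": 0.18,
    "yeast_conservation": 0.10,
    "broad_conservation": 0.10,
    "ppi_degree": 0.10,
    "expression_level": 0.07,
    "disorder": 0.08,
    "cai": 0.06,
    "protein_length": 0.03,
    "coexpression_degree": 0.03,
    "n_domains": 0.0,
    "n_unique_domains": 0.0,
    "nc": -0.05,
    "dn_ds": -0.07,
    "copy_number": -0.08,
    "expression_variation": -0.12,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic world; defaults emulate the published setting."""

    n_genes: int = 2000
    ortholog_fraction: float = 0.55  # ~1,100 one-to-one pairs at n = 2,000
    rho: dict = field(default_factory=lambda: dict(_DEFAULT_RHO))
    coeffs: dict = field(default_factory=lambda: dict(_DEFAULT_COEFFS))
    intercept: float = 3.0  # log mean degree ~ e^3 ~ 20 interactions
    dispersion: float = 8.0  # negative-binomial size; math.inf = noise-free
    shared_rule: bool = True  # same coefficients in both species
    missing_frac: float = 0.02  # sporadic missing feature cells
    essential_frac: float = 0.15  # top fitness-defect tail flagged essential
    other_ortholog_frac: float = 0.05  # extra many-to-many ("other") pairs
    n_queries: int = 8
    # co-expression generator
    coexpr_genes: int = 832
    coexpr_density: float = 0.05
    n_modules: int = 20
    module_strength: float = 1.5  # latent-weight boost for same-module pairs
    edge_correlation: float = 0.1  # cross-species latent weight correlation
    conservation_deficit: float = 0.8  # P(rewired gene's module reassigned in sp2)
    n_rewired: int = 200  # planted rewired gene-set size
    # group catalog generator
    n_groups: int = 40
    group_size_range: tuple[int, int] = (4, 12)
    planted_shift: float = 0.4
    percentile_correlation: float = 0.9  # ortholog percentile conservation under H0

    def __post_init__(self) -> None:
        for f, r in self.rho.items():
            if not -1 <= r <= 1:
                raise ValueError(f"rho[{f}] must lie in [-1, 1]")
        if not (0 < self.coexpr_density < 1):
            raise ValueError("coexpr_density must lie in (0, 1)")
        if self.n_genes < 1 or self.coexpr_genes < 2:
            raise ValueError("sizes must be positive")


@dataclass
class SimulatedPair:
    """Everything one run of the pipeline consumes, plus generating truth."""

    features1: FeatureTable
    features2: FeatureTable
    degrees1: DegreeTable
    degrees2: DegreeTable
    orthology: OrthologyMap
    essential1: set[str]
    essential2: set[str]
    truth: dict


def _transform_feature(name: str, z: np.ndarray) -> np.ndarray:
    """Monotone map from a standard-normal latent to the feature's marginal."""
    u = stats.norm.cdf(z)
    u = np.clip(u, 1e-9, 1 - 1e-9)
    if name == "sm_fitness_defect":
        return u**2  # most genes near zero defect, few severe
    if name == "multifunctionality":
        return stats.poisson.ppf(u, 6).astype(float)
    if name == "yeast_conservation":
        return stats.binom.ppf(u, 23, 0.7).astype(float)
    if name == "broad_conservation":
        return stats.binom.ppf(u, 86, 0.4).astype(float)
    if name == "ppi_degree":
        return stats.nbinom.ppf(u, 2, 2 / (2 + 20)).astype(float)
    if name == "expression_level":
        return np.exp(2.0 + z)
    if name == "disorder":
        return 100 * u**1.5
    if name == "cai":
        return 0.1 + 0.8 * u
    if name == "protein_length":
        return np.round(np.exp(6.0 + 0.5 * z))
    if name == "coexpression_degree":
        return stats.nbinom.ppf(u, 2, 2 / (2 + 8)).astype(float)
    if name == "n_domains":
        return 1 + stats.poisson.ppf(u, 1.5).astype(float)
    if name == "n_unique_domains":
        return 1 + stats.poisson.ppf(u, 1.2).astype(float)
    if name == "nc":
        return 25 + 30 * u
    if name == "dn_ds":
        return np.exp(-2.5 + 0.8 * z)
    if name == "copy_number":
        return stats.nbinom.ppf(u, 1, 1 / (1 + 0.6)).astype(float)
    if name == "expression_variation":
        return u
    raise KeyError(name)


def simulate_species_pair(
    cfg: SimulationConfig = SimulationConfig(), seed: int = 0
) -> SimulatedPair:
    """Generate matched feature/degree tables, orthology and essentiality.

    Ortholog latent features are bivariate-normal with per-feature
    correlation ``cfg.rho``; species-specific genes draw independently.
    Degree for gene i is a negative-binomial draw with mean
    ``exp(intercept + sum_f coeffs[f] * z_if)`` over the latent
    (standardized) features; with ``shared_rule`` both species use the same
    coefficients, otherwise species 2 gets an independently reshuffled,
    sign-flipped rule.  ``truth`` returns latents and coefficients for
    recovery tests.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_genes
    n_orth = int(round(cfg.ortholog_fraction * n))
    genes1 = [f"g1_{i:05d}" for i in range(n)]
    genes2 = [f"g2_{i:05d}" for i in range(n)]

    z1 = np.empty((n, len(CANONICAL_FEATURES)))
    z2 = np.empty((n, len(CANONICAL_FEATURES)))
    for j, feat in enumerate(CANONICAL_FEATURES):
        rho = float(cfg.rho.get(feat, 0.0))
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        z1[:, j] = a
        z2[:, j] = a.copy()
        # species-specific genes decorrelate fully; orthologs partially
        z2[:n_orth, j] = rho * a[:n_orth] + math.sqrt(1 - rho**2) * b[:n_orth]
        z2[n_orth:, j] = b[n_orth:]

    coeffs1 = np.array([cfg.coeffs.get(f, 0.0) for f in CANONICAL_FEATURES])
    if cfg.shared_rule:
        coeffs2 = coeffs1.copy()
    else:
        # fully decorrelated species-2 rule: a random direction orthogonal
        # to the species-1 coefficients, at the same overall effect size
        g = rng.standard_normal(len(coeffs1))
        norm1 = np.linalg.norm(coeffs1)
        g -= (g @ coeffs1) / norm1**2 * coeffs1
        coeffs2 = g / np.linalg.norm(g) * norm1

    def draw_degrees(z: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
        mu = np.exp(cfg.intercept + z @ coeffs)
        if math.isinf(cfg.dispersion):
            return np.round(mu).astype(int)
        k = cfg.dispersion
        return rng.negative_binomial(k, k / (k + mu)).astype(int)

    deg1 = draw_degrees(z1, coeffs1)
    deg2 = draw_degrees(z2, coeffs2)

    def build_features(z: np.ndarray, genes: list[str]) -> FeatureTable:
        cols = {
            feat: _transform_feature(feat, z[:, j])
            for j, feat in enumerate(CANONICAL_FEATURES)
        }
        df = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
        if cfg.missing_frac > 0:
            mask = rng.random(df.shape) < cfg.missing_frac
            df = df.mask(mask)
        return df

    df1 = build_features(z1, genes1)
    df2 = build_features(z2, genes2)
    ft1 = FeatureTable(species="species1", data=df1)
    ft2 = FeatureTable(species="species2", data=df2)
    dt1 = DegreeTable(species="species1", degrees=pd.Series(deg1, index=genes1))
    dt2 = DegreeTable(species="species2", degrees=pd.Series(deg2, index=genes2))

    pairs = [
        {"gene_species1": genes1[i], "gene_species2": genes2[i],
         "relation": "one_to_one", "curated": False}
        for i in range(n_orth)
    ]
    # many-to-many pairs among species-specific genes ("other" relation)
    n_other = int(cfg.other_ortholog_frac * (n - n_orth))
    spare1 = genes1[n_orth:]
    spare2 = genes2[n_orth:]
    for t in range(min(n_other, len(spare1), len(spare2))):
        pairs.append(
            {"gene_species1": spare1[t], "gene_species2": spare2[t],
             "relation": "other", "curated": bool(t % 2)}
        )
    orth = OrthologyMap(pairs=pd.DataFrame(pairs))

    def essentials(fd: pd.Series) -> set[str]:
        k = int(cfg.essential_frac * len(fd))
        if k == 0:
            return set()
        return set(fd.fillna(-np.inf).sort_values(ascending=False).index[:k])

    ess1 = essentials(df1["sm_fitness_defect"])
    ess2 = essentials(df2["sm_fitness_defect"])
    truth = {
        "coeffs1": dict(zip(CANONICAL_FEATURES, coeffs1)),
        "coeffs2": dict(zip(CANONICAL_FEATURES, coeffs2)),
        "latent1": z1,
        "latent2": z2,
        "n_orthologs": n_orth,
    }
    return SimulatedPair(ft1, ft2, dt1, dt2, orth, ess1, ess2, truth)


def simulate_interaction_screen(
    dt: DegreeTable,
    n_queries: int = 8,
    seed: int = 0,
    params: Parameters = Parameters(),
) -> InteractionScoreTable:
    """Emit a full query-by-array score table realizing planted degrees.

    Every array gene of ``dt`` is paired with each of ``n_queries`` query
    strains (one record per pair, so len = n_queries * n_genes).  Exactly
    ``degree`` of each gene's pairs get an epsilon below the negative
    cutoff with p < 0.05; the rest get near-zero epsilon, or a
    non-significant p when the noise dips below the cutoff.  Thresholding
    the output at (epsilon <= -0.08, p < 0.05) therefore reproduces the
    planted degrees exactly.
    """
    if n_queries < 1:
        raise ValueError("n_queries must be >= 1")
    if (dt.degrees > n_queries).any():
        bad = dt.degrees[dt.degrees > n_queries].index[:3].tolist()
        raise ValueError(f"planted degree exceeds n_queries for genes {bad}")
    rng = np.random.default_rng(seed)
    queries = [f"query_{q + 1}" for q in range(n_queries)]
    n = len(dt.degrees)
    rows_q, rows_a, rows_s, rows_p = [], [], [], []
    for gene, d in dt.degrees.items():
        hits = set(rng.choice(n_queries, size=int(d), replace=False).tolist())
        eps = rng.normal(0.0, 0.03, size=n_queries)
        pvals = rng.uniform(0.0, 1.0, size=n_queries)
        for q in range(n_queries):
            if q in hits:
                score = params.eps_cutoff - rng.uniform(0.005, 0.25)
                p = rng.uniform(0.0, params.p_cutoff * 0.98)
            else:
                score = float(eps[q])
                p = float(pvals[q])
                if score <= params.eps_cutoff and p < params.p_cutoff:
                    p = rng.uniform(params.p_cutoff, 1.0)  # keep non-significant
            rows_q.append(queries[q])
            rows_a.append(gene)
            rows_s.append(score)
            rows_p.append(p)
    records = pd.DataFrame(
        {"query_gene": rows_q, "array_gene": rows_a, "score": rows_s, "p_value": rows_p}
    )
    return InteractionScoreTable(records=records)


def simulate_coexpression_pair(
    orth: OrthologyMap,
    rewired_set: set[str],
    cfg: SimulationConfig = SimulationConfig(),
    seed: int = 0,
    genes: Optional[Sequence[str]] = None,
) -> tuple[WeightedGeneNetwork, WeightedGeneNetwork, dict]:
    """Paired weighted networks with planted low-conservation rewired genes.

    A shared module assignment generates high latent weights for same-module
    pairs in both species; each planted rewired gene's module membership is
    reassigned in species 2 with probability ``cfg.conservation_deficit``,
    so its sparsified edges overlap less across species.  Latent pair
    weights are cross-species correlated (``cfg.edge_correlation``) and
    rank-normalized to (0, 1), so percentile sparsification at
    ``cfg.coexpr_density`` recovers the planted top-density edge sets.

    Returns both networks (species-2 genes labeled by their species-1
    ortholog id) and a truth dict with the planted edge sets and class-wise
    conservation rates (NN/NR/RR by membership in ``rewired_set``).
    """
    if genes is None:
        genes = sorted(orth.one_to_one_map("1to2"))[: cfg.coexpr_genes]
    genes = list(genes)
    missing = rewired_set - set(genes)
    if missing:
        raise ValueError(f"rewired genes not in the network gene set: {sorted(missing)[:3]}")
    rng = np.random.default_rng(seed)
    n = len(genes)
    mod1 = rng.integers(0, cfg.n_modules, size=n)
    mod2 = mod1.copy()
    rew_idx = np.array([i for i, g in enumerate(genes) if g in rewired_set], dtype=int)
    if len(rew_idx):
        move = rng.random(len(rew_idx)) < cfg.conservation_deficit
        for i in rew_idx[move]:
            new = rng.integers(0, cfg.n_modules - 1)
            mod2[i] = new if new < mod1[i] else new + 1  # force a different module

    iu, ju = np.triu_indices(n, k=1)
    shared = rng.standard_normal(len(iu))
    rho = cfg.edge_correlation
    noise1 = rng.standard_normal(len(iu))
    noise2 = rng.standard_normal(len(iu))
    s1 = math.sqrt(rho) * shared + math.sqrt(1 - rho) * noise1
    s2 = math.sqrt(rho) * shared + math.sqrt(1 - rho) * noise2
    s1 = s1 + cfg.module_strength * (mod1[iu] == mod1[ju])
    s2 = s2 + cfg.module_strength * (mod2[iu] == mod2[ju])

    def to_network(score: np.ndarray) -> tuple[WeightedGeneNetwork, set]:
        ranks = stats.rankdata(score, method="ordinal")
        w = (ranks - 0.5) / len(score)
        mat = np.full((n, n), np.nan)
        mat[iu, ju] = w
        mat[ju, iu] = w
        k = int(math.floor(cfg.coexpr_density * len(score)))
        top = np.argsort(-score, kind="stable")[:k]
        edges = {
            (genes[iu[t]], genes[ju[t]]) if genes[iu[t]] <= genes[ju[t]]
            else (genes[ju[t]], genes[iu[t]])
            for t in top
        }
        return WeightedGeneNetwork(genes, mat), edges

    net1, edges1 = to_network(s1)
    net2, edges2 = to_network(s2)

    def class_of(e) -> str:
        r = (e[0] in rewired_set) + (e[1] in rewired_set)
        return ("NN", "NR", "RR")[r]

    union = edges1 | edges2
    inter = edges1 & edges2
    rates = {}
    for cls in ("NN", "NR", "RR"):
        tot = sum(1 for e in union if class_of(e) == cls)
        con = sum(1 for e in inter if class_of(e) == cls)
        rates[cls] = con / tot if tot else float("nan")
    truth = {"edges1": edges1, "edges2": edges2, "class_rates": rates,
             "modules1": mod1, "modules2": mod2}
    return net1, net2, truth


def simulate_group_catalog(
    genes1: Sequence[str],
    orth: OrthologyMap,
    n_groups: int = 40,
    n_planted: int = 10,
    shift: float = 0.4,
    seed: int = 0,
    size_range: tuple[int, int] = (4, 12),
    perc1: Optional[pd.Series] = None,
    perc2: Optional[pd.Series] = None,
    overlap_max: float = 0.50,
    percentile_correlation: float = 0.9,
) -> tuple[GeneGroupCatalog, pd.Series, pd.Series, pd.Series]:
    """Random gene-group catalog with planted rewired groups.

    Groups draw their species-1 members from ``genes1`` (restricted to
    one-to-one-mapped genes so both sides are scored) with sizes inside the
    GO-group band; the greedy overlap invariant (<= 50% of either group) is
    enforced by rejection.  The first ``n_planted`` groups are planted
    rewired: their species-2 members' percentiles are lowered by ``shift``
    (clipped to [0, 1]).

    When no percentile maps are supplied, paired percentiles are drawn from
    a Gaussian copula with correlation ``percentile_correlation``: the null
    world has strongly conserved module degrees, and the planted shift is
    the rewiring signal on top of it.

    Returns (catalog, truth labels per group_id, perc1, perc2-after-shift).
    """
    rng = np.random.default_rng(seed)
    mapping = orth.one_to_one_map("1to2")
    universe = [g for g in genes1 if g in mapping]
    if len(universe) < size_range[1]:
        raise ValueError("not enough ortholog-mapped genes for the group sizes")
    if perc1 is None or perc2 is None:
        rho = percentile_correlation
        z1 = rng.standard_normal(len(universe))
        z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(len(universe))
        if perc1 is None:
            perc1 = pd.Series(stats.norm.cdf(z1), index=universe)
        if perc2 is None:
            genes2 = [mapping[g] for g in universe]
            perc2 = pd.Series(stats.norm.cdf(z2), index=genes2)
    perc2 = perc2.copy()

    groups: list[GeneGroup] = []
    truth = {}
    attempts = 0
    while len(groups) < n_groups and attempts < 200 * n_groups:
        attempts += 1
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members1 = frozenset(
            rng.choice(universe, size=size, replace=False).tolist()
        )
        if any(
            len(members1 & g.members1) > overlap_max * min(len(members1), len(g.members1))
            for g in groups
        ):
            continue
        members2 = frozenset(mapping[g] for g in members1)
        gid = f"grp{len(groups):03d}"
        planted = len(groups) < n_planted
        if planted:
            vals = perc2.loc[sorted(members2)] - shift
            perc2.loc[sorted(members2)] = vals.clip(lower=0.0, upper=1.0)
        groups.append(GeneGroup(gid, gid, "complex", members1, members2))
        truth[gid] = planted
    if len(groups) < n_groups:
        raise RuntimeError("could not place the requested number of groups")
    return (
        GeneGroupCatalog(groups=groups),
        pd.Series(truth, name="planted_rewired"),
        perc1,
        perc2,
    )
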
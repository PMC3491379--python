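"""Conservation of co-expression edges for rewired vs non-rewired genes.

Both species' weighted co-expression networks are restricted to one-to-one
orthologs non-essential in both species, sparsified to their top-density
edges, and every edge in the union of the two edge sets is classified by the
rewiring status of its endpoints: NN (neither rewired), NR (exactly one),
RR (both).  A conserved edge appears in both networks; the per-class
conservation rate is conserved/union with a binomial 95% CI, and classes
are compared with Fisher's exact test.  The chance level is estimated by
degree-preserving randomization (repeated double-edge swaps) of one network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .model import PredictionTable
from .tables import DegreeTable, OrthologyMap, WeightedGeneNetwork

__all__ = [
    "EdgeClassSummary",
    "RewiredLabeling",
    "sparsify_network",
    "restrict_to_orthologs",
    "label_rewired",
    "conservation_by_class",
    "compare_classes",
    "degree_preserving_randomize",
    "background_conservation",
    "conservation_rate",
]

Edge = tuple[str, str]


def _edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass
class EdgeClassSummary:
    """Conservation of one endpoint class of co-expression edges."""

    edge_class: str  # "NN", "NR" or "RR"
    conserved: int
    total: int  # union edges in the class
    rate: float
    ci_low: float
    ci_high: float
    threshold: Optional[int] = None  # rewiring threshold tau, in interactions


@dataclass
class RewiredLabeling:
    """Gene labels at rewiring threshold tau.

    rewired: |degree difference| > tau; non_rewired: |difference| < the
    non-rewired band (30); in between (when tau > 30): unlabeled.
    """

    labels: pd.Series  # values in {"rewired", "non_rewired", "unlabeled"}
    tau: int

    def genes(self, label: str) -> set[str]:
        return set(self.labels.index[self.labels == label])


def sparsify_network(net: WeightedGeneNetwork, density: float = 0.05) -> set[Edge]:
    """Retain the highest-weighted fraction ``density`` of stored pairs.

    The cutoff is the (1 - density) percentile of all stored pair weights;
    pairs strictly above it are kept, so ties at the threshold drop out and
    the realized density never exceeds the target.
    """
    if not (0 <= density <= 1):
        raise ValueError("density must lie in [0, 1]")
    iu, ju, w = net.pair_weights()
    if len(w) == 0 or density == 0:
        return set()
    cutoff = float(np.quantile(w, 1 - density))
    keep = w > cutoff
    if not keep.any():
        warnings.warn("no edges above the sparsification cutoff (all weights tied)")
        return set()
    return {
        _edge(net.genes[i], net.genes[j]) for i, j in zip(iu[keep], ju[keep])
    }


def restrict_to_orthologs(
    net1: WeightedGeneNetwork,
    net2: WeightedGeneNetwork,
    orth: OrthologyMap,
    essential1: Iterable[str] = (),
    essential2: Iterable[str] = (),
) -> tuple[WeightedGeneNetwork, WeightedGeneNetwork, dict[str, str]]:
    """Reindex both networks to one-to-one orthologs non-essential in both species.

    Returns the two restricted networks (species-2 genes relabeled by their
    species-1 ortholog so both share one gene index) and the species-1 ->
    species-2 mapping actually used.  Sparsification should happen after
    this restriction.
    """
    ess1, ess2 = set(essential1), set(essential2)
    mapping = {
        g1: g2
        for g1, g2 in orth.one_to_one_map("1to2").items()
        if g1 in net1._index and g2 in net2._index
        and g1 not in ess1 and g2 not in ess2
    }
    if not mapping:
        raise ValueError("no shared non-essential one-to-one orthologs between networks")
    genes1 = sorted(mapping)
    sub1 = net1.subnetwork(genes1)
    sub2_raw = net2.subnetwork([mapping[g] for g in genes1])
    sub2 = WeightedGeneNetwork(genes1, sub2_raw.weights)  # relabel to species-1 ids
    return sub1, sub2, mapping


def label_rewired(
    pred2: PredictionTable,
    dt1: DegreeTable,
    orth: OrthologyMap,
    tau: int,
    nonrewired_band: int = 30,
) -> RewiredLabeling:
    """Label ortholog pairs rewired/non-rewired by predicted-vs-observed degree.

    For each one-to-one pair, the degree difference is the species-2
    predicted degree minus the species-1 observed degree.  |difference| >
    tau -> rewired; |difference| < ``nonrewired_band`` -> non_rewired;
    otherwise unlabeled.  Labels are indexed by the species-1 gene id.
    """
    labels = {}
    mapping = orth.one_to_one_map("1to2")
    for g1, g2 in mapping.items():
        if g1 not in dt1.degrees.index or g2 not in pred2.predictions.index:
            continue
        pred = pred2.predictions[g2]
        if np.isnan(pred):
            continue
        diff = abs(float(pred) - float(dt1.degrees[g1]))
        if diff > tau:
            labels[g1] = "rewired"
        elif diff < nonrewired_band:
            labels[g1] = "non_rewired"
        else:
            labels[g1] = "unlabeled"
    return RewiredLabeling(labels=pd.Series(labels, dtype=object), tau=int(tau))


def conservation_by_class(
    edges1: set[Edge],
    edges2: set[Edge],
    labeling: RewiredLabeling,
    ci_method: str = "normal",
) -> list[EdgeClassSummary]:
    """Per-class conserved/union edge counts and rates with binomial 95% CIs.

    Classes by endpoint labels: NN both non-rewired, NR exactly one rewired
    and the other non-rewired, RR both rewired; edges touching unlabeled or
    absent genes are excluded.  Conserved = intersection edges of the class;
    total = union edges.  ``ci_method`` is the Wald interval by default
    ("wilson" available).
    """
    lab = labeling.labels
    def classify(e: Edge) -> Optional[str]:
        la, lb = lab.get(e[0]), lab.get(e[1])
        if la is None or lb is None or "unlabeled" in (la, lb):
            return None
        n_rew = (la == "rewired") + (lb == "rewired")
        return ("NN", "NR", "RR")[n_rew]

    out = []
    union = edges1 | edges2
    inter = edges1 & edges2
    for cls in ("NN", "NR", "RR"):
        total = sum(1 for e in union if classify(e) == cls)
        conserved = sum(1 for e in inter if classify(e) == cls)
        if total == 0:
            out.append(
                EdgeClassSummary(cls, 0, 0, np.nan, np.nan, np.nan, labeling.tau)
            )
            continue
        rate = conserved / total
        lo, hi = proportion_confint(conserved, total, alpha=0.05, method=ci_method)
        out.append(
            EdgeClassSummary(
                cls, conserved, total, rate,
                float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)),
                labeling.tau,
            )
        )
    return out


def compare_classes(
    rr: EdgeClassSummary, nn: EdgeClassSummary
) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for conserved-vs-not by class.

    The 2x2 table is [[rr.conserved, rr.total - rr.conserved],
    [nn.conserved, nn.total - nn.conserved]]; a zero margin makes the test
    degenerate (p = 1).
    """
    if rr.total <= 0 or nn.total <= 0:
        raise ValueError("both classes need a positive edge total")
    table = np.array(
        [[rr.conserved, rr.total - rr.conserved],
         [nn.conserved, nn.total - nn.conserved]]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, 1.0
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def degree_preserving_randomize(
    edges: set[Edge], swap_multiplier: int = 20, seed: int = 0
) -> set[Edge]:
    """Shuffle an edge set by attempted double-edge swaps, preserving degrees.

    ``swap_multiplier * |edges|`` swap attempts are made; an attempt picks
    two distinct edges and exchanges endpoints, and is rejected (still
    consuming an attempt) if it would create a self-loop or duplicate edge.
    The degree sequence is invariant by construction.
    """
    if len(edges) < 2:
        return set(edges)
    rng = np.random.default_rng(seed)
    edge_list = sorted(edges)
    n_edges = len(edge_list)
    edge_set = set(edge_list)
    attempts = int(swap_multiplier * n_edges)
    pick = rng.integers(0, n_edges, size=(attempts, 2))
    orient = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        i, j = pick[t]
        if i == j:
            continue
        a, b = edge_list[i]
        c, d = edge_list[j]
        if orient[t]:
            c, d = d, c
        # propose (a, d) and (c, b)
        new1, new2 = _edge(a, d), _edge(c, b)
        if a == d or c == b or new1 == new2:
            continue
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edge_list[i])
        edge_set.discard(edge_list[j])
        edge_set.add(new1)
        edge_set.add(new2)
        edge_list[i], edge_list[j] = new1, new2
    return edge_set


def conservation_rate(edges1: set[Edge], edges2: set[Edge]) -> float:
    """Fraction of union edges present in both networks."""
    union = edges1 | edges2
    if not union:
        return np.nan
    return len(edges1 & edges2) / len(union)


def background_conservation(
    edges1: set[Edge],
    edges2: set[Edge],
    swap_multiplier: int = 20,
    seed: int = 0,
    n_reps: int = 10,
) -> float:
    """Expected conservation if species-1 edges are randomized.

    Randomizes ``edges1`` by degree-preserving swaps and measures its
    conservation (intersection over union) against ``edges2``, averaged
    over ``n_reps`` randomizations.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)
    rates = [
        conservation_rate(
            degree_preserving_randomize(edges1, swap_multiplier, int(s)), edges2
        )
        for s in seeds
    ]
    return float(np.mean(rates))
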
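"""Cross-species rewiring test for gene modules.

A module (protein complex or GO biological-process group) is called rewired
when the difference between the median GI-degree percentile of its genes in
one species and the median percentile of the orthologous genes in the other
species is larger than expected for random gene groups of the same sizes.
Species-1 percentiles come from observed degrees; species-2 percentiles from
whole-genome model predictions, which makes the comparison possible even
though only a sliver of the second species' network has been screened.

The null distribution is built from random ortholog groups: draw as many
species-1 genes as the query group has scored members, requiring exactly the
query group's number of ortholog-mapped members, and recompute |delta|.
Backgrounds are cached per size pair.  Empirical p-values use the add-one
convention p = (1 + #{background >= observed}) / (1 + N), so p is never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .params import Parameters
from .tables import AnnotationSet, DegreeTable, OrthologyMap

__all__ = [
    "GeneGroup",
    "GeneGroupCatalog",
    "build_go_groups",
    "group_statistic",
    "BackgroundSampler",
    "empirical_pvalue",
    "rewiring_scan",
    "within_species_control",
    "read_group_catalog",
    "write_group_catalog",
]


@dataclass(frozen=True)
class GeneGroup:
    """A gene module with members on both species' sides."""

    group_id: str
    label: str
    origin: str  # "complex", "go_species1" or "go_species2"
    members1: frozenset[str]
    members2: frozenset[str]


@dataclass
class GeneGroupCatalog:
    """Retained gene groups after size and overlap filtering."""

    groups: list[GeneGroup]

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self):
        return iter(self.groups)


def _overlap_exceeds(a: frozenset, b: frozenset, max_frac: float) -> bool:
    if not a or not b:
        return False
    inter = len(a & b)
    return inter > max_frac * len(a) or inter > max_frac * len(b)


def build_go_groups(
    ann1: AnnotationSet,
    ann2: AnnotationSet,
    orth: OrthologyMap,
    dt1: DegreeTable,
    fitness2: pd.Series,
    params: Parameters = Parameters(),
) -> GeneGroupCatalog:
    """Build GO-process gene groups mapped across species.

    One candidate group per (GO term, seeding species): the seed side's
    members are the genes annotated with the term, the other side's members
    are their one-to-one orthologs.  A term qualifies when its annotated
    gene count lies strictly between the size bounds in the seeding species.
    Groups need >= 2 species-1 genes of known GI degree and >= 2 species-2
    genes of known fitness defect.  Redundant groups are removed by a
    greedy overlap filter: process groups in descending size and keep one
    only if it overlaps every kept group by <= the overlap bound on both
    species' member sets.
    """
    lo, hi = params.group_size_min_exclusive, params.group_size_max_exclusive
    map12 = orth.one_to_one_map("1to2")
    map21 = orth.one_to_one_map("2to1")
    known_deg = set(dt1.degrees.index)
    known_fit = set(fitness2.dropna().index)

    candidates: list[GeneGroup] = []
    for origin, ann, fwd in (("go_species1", ann1, map12), ("go_species2", ann2, map21)):
        for term in sorted(ann.all_terms()):
            seed_members = frozenset(ann.genes_for_term(term))
            if not (lo < len(seed_members) < hi):
                continue
            mapped = frozenset(fwd[g] for g in seed_members if g in fwd)
            if origin == "go_species1":
                m1, m2 = seed_members, mapped
            else:
                m1, m2 = mapped, seed_members
            if len(m1 & known_deg) < 2 or len(m2 & known_fit) < 2:
                continue
            tag = "c" if origin == "go_species1" else "p"
            candidates.append(
                GeneGroup(f"({tag}){term}", term, origin, m1, m2)
            )

    # greedy overlap filter, largest groups first (deterministic)
    candidates.sort(key=lambda g: (-(len(g.members1) + len(g.members2)), g.group_id))
    kept: list[GeneGroup] = []
    for g in candidates:
        clash = any(
            _overlap_exceeds(g.members1, k.members1, params.group_overlap_max)
            or _overlap_exceeds(g.members2, k.members2, params.group_overlap_max)
            for k in kept
        )
        if not clash:
            kept.append(g)
    if not kept:
        warnings.warn("no GO groups retained after filtering")
    return GeneGroupCatalog(groups=kept)


def group_statistic(
    group: GeneGroup, perc1: pd.Series, perc2: pd.Series
) -> Optional[tuple[float, float, float, int, int]]:
    """(delta, median1, median2, n1, n2) for a group, or None if a side is unscored.

    delta = median species-1 percentile - median species-2 percentile;
    significance is assessed on |delta|.
    """
    side1 = perc1.reindex(sorted(group.members1)).dropna()
    side2 = perc2.reindex(sorted(group.members2)).dropna()
    if len(side1) == 0 or len(side2) == 0:
        warnings.warn(f"group {group.group_id}: a side has no scored genes; skipped")
        return None
    m1, m2 = float(side1.median()), float(side2.median())
    return m1 - m2, m1, m2, len(side1), len(side2)


class BackgroundSampler:
    """Size-matched random-ortholog-group null for |delta|, cached per size key.

    The species-1 universe is every gene with a species-1 percentile; a gene
    is "mapped" when its one-to-one ortholog has a species-2 percentile.
    Sampling n1 distinct genes conditional on exactly n2 mapped members is
    equivalent to drawing n2 from the mapped stratum and n1 - n2 from the
    unmapped stratum uniformly, which is done directly.
    """

    def __init__(
        self,
        orth_or_map,
        perc1: pd.Series,
        perc2: pd.Series,
        n_samples: int = 10_000,
        seed: int = 0,
    ):
        if isinstance(orth_or_map, OrthologyMap):
            self.mapping = orth_or_map.one_to_one_map("1to2")
        else:
            self.mapping = dict(orth_or_map)
        self.perc1 = perc1.dropna()
        self.perc2 = perc2.dropna()
        self.n_samples = int(n_samples)
        self.rng = np.random.default_rng(seed)
        scored2 = set(self.perc2.index)
        universe = list(self.perc1.index)
        self.mapped = np.array(
            [g for g in universe if self.mapping.get(g) in scored2], dtype=object
        )
        self.unmapped = np.array(
            [g for g in universe if self.mapping.get(g) not in scored2], dtype=object
        )
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def distribution(self, n1: int, n2: int) -> np.ndarray:
        """|delta| values for ``n_samples`` random groups of sizes (n1, n2)."""
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        key = (int(n1), int(n2))
        if key in self._cache:
            return self._cache[key]
        if n2 > len(self.mapped) or (n1 - n2) > len(self.unmapped) or n2 > n1 or n2 < 1:
            raise ValueError(
                f"cannot sample background groups of sizes (n1={n1}, n2={n2}): "
                f"{len(self.mapped)} mapped / {len(self.unmapped)} unmapped genes available"
            )
        p1 = self.perc1
        p2 = self.perc2
        mapped_p1 = p1.loc[self.mapped].to_numpy()
        mapped_p2 = p2.loc[[self.mapping[g] for g in self.mapped]].to_numpy()
        unmapped_p1 = p1.loc[self.unmapped].to_numpy() if len(self.unmapped) else np.empty(0)
        out = np.empty(self.n_samples)
        n_extra = n1 - n2
        for s in range(self.n_samples):
            sel = self.rng.choice(len(self.mapped), size=n2, replace=False)
            side1 = mapped_p1[sel]
            if n_extra:
                sel_u = self.rng.choice(len(self.unmapped), size=n_extra, replace=False)
                side1 = np.concatenate([side1, unmapped_p1[sel_u]])
            out[s] = abs(np.median(side1) - np.median(mapped_p2[sel]))
        self._cache[key] = out
        return out


def empirical_pvalue(observed: float, background: np.ndarray) -> float:
    """Add-one empirical p: (1 + #{background >= |observed|}) / (1 + N)."""
    background = np.asarray(background)
    if background.size == 0:
        raise ValueError("background distribution is empty")
    return float((1 + (background >= abs(observed)).sum()) / (1 + background.size))


def _scan(
    catalog: GeneGroupCatalog,
    perc1: pd.Series,
    perc2: pd.Series,
    mapping,
    params: Parameters,
    seed: int,
) -> pd.DataFrame:
    sampler = BackgroundSampler(
        mapping, perc1, perc2, n_samples=params.background_samples, seed=seed
    )
    rows = []
    for g in catalog:
        stat = group_statistic(g, perc1, perc2)
        if stat is None:
            continue
        delta, m1, m2, n1, n2 = stat
        bg = sampler.distribution(n1, n2)
        p = empirical_pvalue(delta, bg)
        rows.append(
            {
                "group_id": g.group_id,
                "label": g.label,
                "origin": g.origin,
                "n1": n1,
                "n2": n2,
                "median1": m1,
                "median2": m2,
                "delta": delta,
                "p": p,
                "rewired": p < params.module_alpha,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "group_id", "label", "origin", "n1", "n2",
            "median1", "median2", "delta", "p", "rewired",
        ],
    )
    df.attrs["n_tested"] = len(df)
    df.attrs["expected_false_positives"] = int(params.module_alpha * len(df))
    return df


def rewiring_scan(
    catalog: GeneGroupCatalog,
    perc1: pd.Series,
    perc2: pd.Series,
    orth: OrthologyMap,
    params: Parameters = Parameters(),
    seed: int = 0,
) -> pd.DataFrame:
    """Test every evaluable group for cross-species degree rewiring.

    ``perc1`` are observed-degree percentiles over species-1 genes; ``perc2``
    are predicted-degree percentiles over all species-2 genes.  The result
    DataFrame carries one row per group with medians, delta, the empirical p
    and the rewired flag at ``params.module_alpha``; ``attrs`` record the
    number tested and the expected false-positive count at alpha.
    """
    return _scan(catalog, perc1, perc2, orth, params, seed)


def within_species_control(
    perc_observed1: pd.Series,
    perc_predicted1: pd.Series,
    catalog: GeneGroupCatalog,
    params: Parameters = Parameters(),
    seed: int = 0,
    cross_results: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Observed-vs-predicted rewiring scan within one species.

    Runs the identical machinery on (observed, predicted) percentiles of the
    same species, with the identity gene mapping.  Groups significant here
    are poorly predicted rather than genuinely rewired; if ``cross_results``
    is given, a ``suspect`` column is added to a returned copy flagging
    those groups.
    """
    # identity mapping on species-1 genes; compare each group's species-1
    # members' observed percentiles with the same genes' predicted ones
    identity = {g: g for g in perc_observed1.index}
    mirrored = GeneGroupCatalog(
        groups=[
            GeneGroup(g.group_id, g.label, g.origin, g.members1, g.members1)
            for g in catalog
        ]
    )
    control = _scan(mirrored, perc_observed1, perc_predicted1, identity, params, seed)
    if cross_results is not None:
        suspects = set(control.loc[control["rewired"], "group_id"])
        out = cross_results.copy()
        out["suspect"] = out["group_id"].isin(suspects)
        control.attrs["annotated_cross_results"] = out
    return control


# ---------------------------------------------------------------------------
# Catalog TSV
# ---------------------------------------------------------------------------

def write_group_catalog(catalog: GeneGroupCatalog, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "group_id": g.group_id,
            "label": g.label,
            "origin": g.origin,
            "members_species1": "|".join(sorted(g.members1)),
            "members_species2": "|".join(sorted(g.members2)),
        }
        for g in catalog
    ]
    pd.DataFrame(
        rows,
        columns=["group_id", "label", "origin", "members_species1", "members_species2"],
    ).to_csv(path, sep="\t", index=False)


def read_group_catalog(path) -> GeneGroupCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    groups = [
        GeneGroup(
            row["group_id"],
            row["label"],
            row["origin"],
            frozenset(x for x in row["members_species1"].split("|") if x),
            frozenset(x for x in row["members_species2"].split("|") if x),
        )
        for _, row in df.iterrows()
    ]
    return GeneGroupCatalog(groups=groups)
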
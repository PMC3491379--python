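"""Pipeline-wide constants and tunable thresholds.

All score cutoffs, ensemble sizes and randomization settings used anywhere in
the pipeline live in a single :class:`Parameters` record so that robustness
sweeps can override them in one place.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Parameters:
    """Analysis-wide thresholds and settings.

    Attributes
    ----------
    eps_cutoff : float
        Epsilon score at or below which a gene pair is called a negative
        genetic interaction (together with ``p_cutoff``).
    eps_strict : float
        Stricter epsilon cutoff for the high-confidence interaction network.
    p_cutoff : float
        P-value cutoff accompanying the epsilon thresholds.
    s_cutoff : float
        S-score cutoff for screens reported on the S-score scale.
    n_trees : int
        Number of bagged regression trees per ensemble.
    n_repeats : int
        Number of refit/evaluate repetitions used to report predictive
        ability as mean +/- sd of the Pearson correlation.
    min_split : int
        Minimum node size eligible for splitting when growing a tree.
    coexpr_density : float
        Fraction of highest-scoring co-expression pairs retained when a
        weighted network is sparsified to an edge set.
    swap_multiplier : int
        Number of attempted double-edge swaps, as a multiple of the edge
        count, used by degree-preserving randomization.
    rewiring_thresholds : tuple of int
        Degree-difference magnitudes at which ortholog pairs are labeled
        rewired for the co-expression conservation analysis.
    nonrewired_band : int
        Ortholog pairs with an absolute degree difference strictly below
        this value are labeled non-rewired.
    group_size_min_exclusive, group_size_max_exclusive : int
        GO-derived gene groups must be annotated to more than the former and
        fewer than the latter genes in at least one species.
    group_overlap_max : float
        Maximum allowed overlap between two retained gene groups, as a
        fraction of either group's members.
    module_alpha : float
        Significance level for calling a gene module rewired.
    background_samples : int
        Random size-matched ortholog groups drawn per group-size key when
        building the empirical null for the rewiring test.
    """

    eps_cutoff: float = -0.08
    eps_strict: float = -0.12
    p_cutoff: float = 0.05
    s_cutoff: float = -2.5
    n_trees: int = 100
    n_repeats: int = 25
    min_split: int = 10
    coexpr_density: float = 0.05
    swap_multiplier: int = 20
    rewiring_thresholds: tuple[int, ...] = (30, 55, 80, 105)
    nonrewired_band: int = 30
    group_size_min_exclusive: int = 3
    group_size_max_exclusive: int = 50
    group_overlap_max: float = 0.50
    module_alpha: float = 0.05
    background_samples: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("eps_cutoff", "eps_strict", "p_cutoff", "s_cutoff"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        thr = self.rewiring_thresholds
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError("rewiring_thresholds must be strictly increasing")
        if self.n_trees < 1 or self.n_repeats < 1:
            raise ValueError("n_trees and n_repeats must be positive")
        if not (0 <= self.coexpr_density <= 1):
            raise ValueError("coexpr_density must lie in [0, 1]")

    def replace(self, **overrides) -> "Parameters":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **overrides)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


#: Known Parameters field names, for config validation.
PARAMETER_FIELDS = tuple(f.name for f in dataclasses.fields(Parameters))
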
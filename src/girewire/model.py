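"""Bagged regression-tree model of genetic-interaction degree.

The model follows the estimator/results convention: :class:`GIDegreeModel`
is constructed from a feature table and a degree table, ``fit`` grows an
ensemble of bootstrap-sampled regression trees, and the returned
:class:`GIDegreeResults` exposes predictions and diagnostics.

Two prediction modes mirror the two uses of the model.  Within-species
predictions are out-of-bag: the prediction for a gene is the median over
exactly the trees whose bootstrap sample excluded it, which makes held-out
evaluation honest without a separate test split.  Cross-species predictions
apply every tree to the other species' feature table and take the median,
since no gene of the second species ever entered training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import Parameters
from .tables import CANONICAL_FEATURES, DegreeTable, FeatureTable, OrthologyMap
from .tree import RegressionTree, TreeNode, grow_tree

__all__ = [
    "GIDegreeModel",
    "GIDegreeResults",
    "TreeEnsemble",
    "PredictionTable",
    "EvaluationResult",
    "bootstrap_sample",
    "fit_ensemble",
    "predict_within",
    "predict_cross",
    "evaluate",
    "feature_degree_correlations",
    "ortholog_baseline",
    "ablation_variants",
    "degree_percentiles",
    "write_ensemble",
    "read_ensemble",
]


def bootstrap_sample(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one bootstrap sample of size ``n`` with replacement.

    Returns ``(counts, oob)`` where ``counts[i]`` is how often index ``i``
    was drawn (the in-bag multiset) and ``oob`` lists the indices never
    drawn.  For large ``n`` the out-of-bag fraction approaches
    ``(1 - 1/n)^n ~ 36.8%``, so each tree trains on ~63.2% of genes.
    """
    if n < 1:
        raise ValueError("bootstrap sample size must be >= 1")
    draws = rng.integers(0, n, size=n)
    counts = np.bincount(draws, minlength=n)
    oob = np.flatnonzero(counts == 0)
    return counts, oob


@dataclass
class TreeEnsemble:
    """Fitted bag of regression trees plus per-tree in-bag multisets."""

    trees: list[RegressionTree]
    in_bag: np.ndarray  # (n_trees, n_genes) draw counts
    gene_ids: list[str]
    species: str
    seed: int
    feature_names: list[str] = field(default_factory=lambda: list(CANONICAL_FEATURES))

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def oob_mask(self) -> np.ndarray:
        """(n_trees, n_genes) boolean: True where the gene is out-of-bag."""
        return self.in_bag == 0


@dataclass
class PredictionTable:
    """Per-gene predicted degree with the count of contributing trees.

    Within-species (out-of-bag) predictions are missing (NaN) for genes that
    were in-bag in every tree; cross-species predictions are never missing.
    """

    species: str
    predictions: pd.Series
    n_trees_used: pd.Series

    def __post_init__(self) -> None:
        self.predictions = self.predictions.astype(float).rename("predicted_degree")
        self.n_trees_used = self.n_trees_used.astype(int).rename("n_trees_used")
        miss = self.predictions.isna()
        if not (miss == (self.n_trees_used == 0)).all():
            raise ValueError("prediction missing iff zero contributing trees")

    def __len__(self) -> int:
        return len(self.predictions)


@dataclass
class EvaluationResult:
    """Predictive ability over refit repetitions: mean +/- sd Pearson r."""

    mean_r: float
    sd_r: float
    per_repeat_r: list[float]
    p_value: float
    n_pairs: float  # mean gene count per repeat

    def summary(self) -> str:
        return (
            f"Pearson r = {self.mean_r:.3f} +/- {self.sd_r:.3f} "
            f"({len(self.per_repeat_r)} repeats, ~{self.n_pairs:.0f} genes, "
            f"p = {self.p_value:.3g})"
        )


def _feature_matrix(ft: FeatureTable, feature_names: Sequence[str]) -> np.ndarray:
    return ft.data.loc[:, list(feature_names)].to_numpy(dtype=float)


class GIDegreeModel:
    """Bagged regression-tree model relating gene features to GI degree.

    Parameters
    ----------
    features : FeatureTable
        The 16 canonical gene features of the training species.
    degrees : DegreeTable or pandas.Series
        Observed negative GI degrees (or any real-valued target, e.g.
        residual degrees for the ablation variant).  Only genes present in
        both tables are used; at least 20 are required.
    params : Parameters
        n_trees, min_split and n_repeats come from here.
    exclude : sequence of str
        Feature columns withheld from the model (e.g. the single-mutant
        fitness defect for the no-fitness ablation).
    include : sequence of str, optional
        If given, train on exactly these features instead.
    """

    def __init__(
        self,
        features: FeatureTable,
        degrees,
        params: Parameters = Parameters(),
        exclude: Sequence[str] = (),
        include: Optional[Sequence[str]] = None,
    ):
        if include is not None:
            names = [f for f in CANONICAL_FEATURES if f in set(include)]
        else:
            names = [f for f in CANONICAL_FEATURES if f not in set(exclude)]
        if not names:
            raise ValueError("no features left to train on")
        self.feature_names = names
        self.features = features
        self.params = params
        target = degrees.degrees if isinstance(degrees, DegreeTable) else degrees
        target = pd.Series(target).astype(float)
        common = features.genes.intersection(target.dropna().index)
        if len(common) < 20:
            raise ValueError(
                f"feature/degree overlap too small ({len(common)} genes, need >= 20)"
            )
        self.gene_ids = list(common)
        self._X = features.data.loc[common, names].to_numpy(dtype=float)
        self._y = target.loc[common].to_numpy(dtype=float)
        self.species = features.species

    @classmethod
    def from_tables(cls, features: FeatureTable, degrees: DegreeTable, **kw):
        return cls(features, degrees, **kw)

    def fit(self, seed: int = 0) -> "GIDegreeResults":
        """Grow ``params.n_trees`` trees on bootstrap samples; deterministic in seed."""
        rng = np.random.default_rng(seed)
        n = len(self.gene_ids)
        trees: list[RegressionTree] = []
        in_bag = np.zeros((self.params.n_trees, n), dtype=int)
        for t in range(self.params.n_trees):
            counts, _ = bootstrap_sample(n, rng)
            idx = np.repeat(np.arange(n), counts)
            trees.append(
                grow_tree(
                    self._X[idx],
                    self._y[idx],
                    min_split=self.params.min_split,
                    feature_names=self.feature_names,
                )
            )
            in_bag[t] = counts
        ens = TreeEnsemble(
            trees=trees,
            in_bag=in_bag,
            gene_ids=list(self.gene_ids),
            species=self.species,
            seed=seed,
            feature_names=list(self.feature_names),
        )
        return GIDegreeResults(self, ens)

    def evaluate(
        self,
        actual: Optional[DegreeTable] = None,
        mode: str = "within",
        test_features: Optional[FeatureTable] = None,
        n_repeats: Optional[int] = None,
        seed: int = 0,
        restrict_to: Optional[Sequence[str]] = None,
    ) -> EvaluationResult:
        """Refit the model ``n_repeats`` times and correlate predictions with degrees.

        mode="within" correlates out-of-bag predictions with the training
        degrees; mode="cross" applies each refit ensemble to
        ``test_features`` and correlates with ``actual`` (the other
        species' observed degrees).  ``restrict_to`` optionally limits the
        evaluation to a gene subset (e.g. genes with no ortholog in the
        training species).
        """
        n_rep = n_repeats if n_repeats is not None else self.params.n_repeats
        seeds = np.random.SeedSequence(seed).generate_state(n_rep) % (2**31)
        rs: list[float] = []
        ns: list[int] = []
        for s in seeds:
            res = self.fit(int(s))
            if mode == "within":
                pred = res.predict_within()
                truth = pd.Series(self._y, index=pd.Index(self.gene_ids))
            elif mode == "cross":
                if test_features is None or actual is None:
                    raise ValueError("cross mode needs test_features and actual")
                pred = res.predict_cross(test_features)
                truth = actual.degrees.astype(float)
            else:
                raise ValueError("mode must be 'within' or 'cross'")
            p = pred.predictions
            if restrict_to is not None:
                p = p.loc[p.index.intersection(pd.Index(restrict_to))]
            r, n_used = _pairwise_pearson(p, truth)
            rs.append(r)
            ns.append(n_used)
        mean_r = float(np.mean(rs))
        sd_r = float(np.std(rs, ddof=1)) if n_rep > 1 else 0.0
        n_mean = float(np.mean(ns))
        p_value = _pearson_pvalue(mean_r, n_mean)
        return EvaluationResult(mean_r, sd_r, rs, p_value, n_mean)

    def evaluate_paired(
        self,
        test_features: FeatureTable,
        test_degrees: DegreeTable,
        n_repeats: Optional[int] = None,
        seed: int = 0,
    ) -> tuple[EvaluationResult, EvaluationResult]:
        """Within- and cross-species evaluation sharing the same refits.

        Each repeat fits one ensemble and records both the out-of-bag
        within-species correlation and the cross-species correlation
        against ``test_degrees``, halving the cost of reporting the pair.
        """
        n_rep = n_repeats if n_repeats is not None else self.params.n_repeats
        seeds = np.random.SeedSequence(seed).generate_state(n_rep) % (2**31)
        truth_w = pd.Series(self._y, index=pd.Index(self.gene_ids))
        truth_c = test_degrees.degrees.astype(float)
        rw_, rc_, nw_, nc_ = [], [], [], []
        for s in seeds:
            res = self.fit(int(s))
            r, n_used = _pairwise_pearson(res.predict_within().predictions, truth_w)
            rw_.append(r)
            nw_.append(n_used)
            r, n_used = _pairwise_pearson(
                res.predict_cross(test_features).predictions, truth_c
            )
            rc_.append(r)
            nc_.append(n_used)

        def pack(rs, ns):
            mean_r = float(np.mean(rs))
            sd_r = float(np.std(rs, ddof=1)) if n_rep > 1 else 0.0
            return EvaluationResult(
                mean_r, sd_r, rs, _pearson_pvalue(mean_r, np.mean(ns)), float(np.mean(ns))
            )

        return pack(rw_, nw_), pack(rc_, nc_)


class GIDegreeResults:
    """Fitted ensemble with prediction and summary methods."""

    def __init__(self, model: GIDegreeModel, ensemble: TreeEnsemble):
        self.model = model
        self.ensemble = ensemble

    def predict_within(self, ft: Optional[FeatureTable] = None) -> PredictionTable:
        """Out-of-bag predictions for the training species.

        For each gene the median is taken over exactly the trees whose
        in-bag multiset excludes it; genes in-bag in every tree get NaN.
        Genes of ``ft`` that never entered training are out-of-bag for all
        trees.
        """
        ens = self.ensemble
        if ft is None:
            genes = list(ens.gene_ids)
            X = self.model._X
        else:
            if ft.species != ens.species:
                raise ValueError(
                    f"within-species prediction: table species {ft.species!r} "
                    f"!= ensemble species {ens.species!r}"
                )
            genes = list(ft.genes)
            X = _feature_matrix(ft, ens.feature_names)
        train_pos = {g: i for i, g in enumerate(ens.gene_ids)}
        preds = np.vstack([tree.predict(X) for tree in ens.trees])
        oob = np.ones((ens.n_trees, len(genes)), dtype=bool)
        for col, g in enumerate(genes):
            i = train_pos.get(g)
            if i is not None:
                oob[:, col] = ens.in_bag[:, i] == 0
        preds = np.where(oob, preds, np.nan)
        n_used = oob.sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            med = np.nanmedian(preds, axis=0)
        med = np.where(n_used == 0, np.nan, med)
        idx = pd.Index(genes, name="gene_id")
        return PredictionTable(
            species=ens.species,
            predictions=pd.Series(med, index=idx),
            n_trees_used=pd.Series(n_used, index=idx),
        )

    def predict_cross(self, ft_other: FeatureTable) -> PredictionTable:
        """Median over all trees applied to another species' features."""
        ens = self.ensemble
        X = _feature_matrix(ft_other, ens.feature_names)
        preds = np.vstack([tree.predict(X) for tree in ens.trees])
        med = np.median(preds, axis=0)
        idx = pd.Index(list(ft_other.genes), name="gene_id")
        return PredictionTable(
            species=ft_other.species,
            predictions=pd.Series(med, index=idx),
            n_trees_used=pd.Series(ens.n_trees, index=idx),
        )

    def summary(self) -> str:
        ens = self.ensemble
        leaves = [t.n_leaves for t in ens.trees]
        oob_frac = float((ens.in_bag == 0).mean())
        lines = [
            "Bagged regression-tree degree model",
            "===================================",
            f"species:            {ens.species}",
            f"training genes:     {len(ens.gene_ids)}",
            f"trees:              {ens.n_trees}",
            f"features:           {len(ens.feature_names)}",
            f"mean leaves/tree:   {np.mean(leaves):.1f}",
            f"mean OOB fraction:  {oob_frac:.3f}",
            f"seed:               {ens.seed}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional convenience surface
# ---------------------------------------------------------------------------

def fit_ensemble(
    ft: FeatureTable,
    dt: DegreeTable,
    params: Parameters = Parameters(),
    seed: int = 0,
    **model_kw,
) -> GIDegreeResults:
    """Fit a bagged ensemble on the genes shared by ``ft`` and ``dt``."""
    return GIDegreeModel(ft, dt, params=params, **model_kw).fit(seed)


def predict_within(results: GIDegreeResults, ft: Optional[FeatureTable] = None) -> PredictionTable:
    return results.predict_within(ft)


def predict_cross(results: GIDegreeResults, ft_other: FeatureTable) -> PredictionTable:
    return results.predict_cross(ft_other)


def _pairwise_pearson(pred: pd.Series, actual: pd.Series) -> tuple[float, int]:
    df = pd.concat([pred.rename("p"), actual.rename("a")], axis=1, join="inner").dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 genes with both values, have {len(df)}")
    if df["p"].std() == 0 or df["a"].std() == 0:
        raise ValueError("zero variance in predictions or degrees")
    r, _ = stats.pearsonr(df["p"], df["a"])
    return float(r), len(df)


def _pearson_pvalue(r: float, n: float) -> float:
    if n <= 3 or abs(r) >= 1:
        return 0.0 if abs(r) >= 1 else 1.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def evaluate(
    refit_fn: Callable[[int], PredictionTable],
    actual,
    n_repeats: int = 25,
    seed: int = 0,
) -> EvaluationResult:
    """Generic repeat-evaluation: call ``refit_fn(seed_r)`` per repeat.

    Each repeat refits with a fresh seed and yields a PredictionTable whose
    Pearson correlation with ``actual`` (a DegreeTable or Series) is
    recorded; missing predictions are excluded pairwise.
    """
    truth = actual.degrees.astype(float) if isinstance(actual, DegreeTable) else pd.Series(actual, dtype=float)
    seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    rs, ns = [], []
    for s in seeds:
        pred = refit_fn(int(s))
        r, n_used = _pairwise_pearson(pred.predictions, truth)
        rs.append(r)
        ns.append(n_used)
    mean_r = float(np.mean(rs))
    sd_r = float(np.std(rs, ddof=1)) if n_repeats > 1 else 0.0
    return EvaluationResult(mean_r, sd_r, rs, _pearson_pvalue(mean_r, np.mean(ns)), float(np.mean(ns)))


def feature_degree_correlations(ft: FeatureTable, dt) -> pd.DataFrame:
    """Pearson r of each feature with GI degree, with Fisher-z 95% CIs.

    Returns a DataFrame (feature, r, p, ci_low, ci_high, n) ordered by |r|
    descending.  Constant features get NaN correlations.
    """
    target = dt.degrees.astype(float) if isinstance(dt, DegreeTable) else pd.Series(dt, dtype=float)
    rows = []
    for feat in CANONICAL_FEATURES:
        pair = pd.concat(
            [ft.data[feat].rename("x"), target.rename("y")], axis=1, join="inner"
        ).dropna()
        n = len(pair)
        if n < 4 or pair["x"].std() == 0 or pair["y"].std() == 0:
            rows.append((feat, np.nan, np.nan, np.nan, np.nan, n))
            continue
        r, p = stats.pearsonr(pair["x"], pair["y"])
        if abs(r) < 1:
            z = np.arctanh(r)
            half = 1.959963984540054 / np.sqrt(n - 3)
            lo, hi = np.tanh(z - half), np.tanh(z + half)
        else:
            lo = hi = r
        rows.append((feat, float(r), float(p), float(lo), float(hi), n))
    out = pd.DataFrame(rows, columns=["feature", "r", "p", "ci_low", "ci_high", "n"])
    return out.reindex(out["r"].abs().sort_values(ascending=False, kind="stable").index).reset_index(
        drop=True
    )


def ortholog_baseline(
    dt_source: DegreeTable, orth: OrthologyMap, target_side: int = 2
) -> PredictionTable:
    """Predict a gene's degree as its one-to-one ortholog's observed degree.

    ``target_side`` selects which species' genes receive predictions (the
    other side supplies the observed degrees).  Genes without a one-to-one
    ortholog of known degree are missing.
    """
    if target_side not in (1, 2):
        raise ValueError("target_side must be 1 or 2")
    mapping = orth.one_to_one_map("2to1" if target_side == 2 else "1to2")
    preds = {}
    for gene, ortho in mapping.items():
        if ortho in dt_source.degrees.index:
            preds[gene] = float(dt_source.degrees[ortho])
    idx = pd.Index(sorted(preds), name="gene_id")
    values = pd.Series([preds[g] for g in idx], index=idx, dtype=float)
    return PredictionTable(
        species=f"species{target_side}",
        predictions=values,
        n_trees_used=pd.Series(1, index=idx, dtype=int),
    )


def ablation_variants(
    ft: FeatureTable,
    dt: DegreeTable,
    params: Parameters = Parameters(),
    seed: int = 0,
) -> dict:
    """Fitness-ablation companions to the full model.

    Returns a dict with:

    - ``"no_fitness"``: results of an ensemble trained on the 15 features
      other than the single-mutant fitness defect;
    - ``"fitness_only"``: results of a single-feature fitness ensemble;
    - ``"residual"``: results of a 15-feature ensemble trained on the
      residual degree (actual minus the fitness-only model's out-of-bag
      prediction), plus ``"residual_target"`` with those residuals.
    """
    if ft.data["sm_fitness_defect"].dropna().empty:
        raise ValueError("fitness column entirely missing")
    seeds = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    no_fit = GIDegreeModel(
        ft, dt, params=params, exclude=("sm_fitness_defect",)
    ).fit(int(seeds[0]))
    fit_only = GIDegreeModel(
        ft, dt, params=params, include=("sm_fitness_defect",)
    ).fit(int(seeds[1]))
    oob = fit_only.predict_within().predictions
    residual = (dt.degrees.astype(float) - oob).dropna()
    resid_model = GIDegreeModel(
        ft, residual, params=params, exclude=("sm_fitness_defect",)
    ).fit(int(seeds[2]))
    return {
        "no_fitness": no_fit,
        "fitness_only": fit_only,
        "residual": resid_model,
        "residual_target": residual,
    }


def degree_percentiles(values) -> pd.Series:
    """Midrank percentiles of degrees (or predictions) in [0, 1]."""
    from .features import midrank_percentiles

    s = values.degrees.astype(float) if isinstance(values, DegreeTable) else pd.Series(values, dtype=float)
    if s.dropna().empty:
        raise ValueError("need at least one value")
    return midrank_percentiles(s)


# ---------------------------------------------------------------------------
# Ensemble text serialization (versioned)
# ---------------------------------------------------------------------------

_FORMAT_TAG = "girewire-ensemble v1"


def write_ensemble(ens: TreeEnsemble, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {_FORMAT_TAG}\n")
        fh.write(f"# species: {ens.species}\n")
        fh.write(f"# seed: {ens.seed}\n")
        fh.write("# features: " + "\t".join(ens.feature_names) + "\n")
        fh.write("# genes: " + "\t".join(ens.gene_ids) + "\n")
        for t, tree in enumerate(ens.trees):
            fh.write(f"TREE {t}\n")
            for i, nd in enumerate(tree.nodes):
                fh.write(
                    f"NODE\t{i}\t{nd.feature}\t{nd.threshold!r}\t{nd.left}\t"
                    f"{nd.right}\t{nd.value!r}\t{nd.n_samples}\t{int(nd.missing_to_left)}\n"
                )
            counts = ens.in_bag[t]
            pairs = [
                f"{ens.gene_ids[i]}:{counts[i]}" for i in np.flatnonzero(counts)
            ]
            fh.write("INBAG\t" + "\t".join(pairs) + "\n")


def read_ensemble(path) -> TreeEnsemble:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != f"# {_FORMAT_TAG}":
        raise ValueError(f"{path}: not a {_FORMAT_TAG} file")
    species = lines[1].split(":", 1)[1].strip()
    seed = int(lines[2].split(":", 1)[1])
    feature_names = lines[3].split(":", 1)[1].strip().split("\t")
    gene_ids = lines[4].split(":", 1)[1].strip().split("\t")
    pos = {g: i for i, g in enumerate(gene_ids)}
    trees: list[RegressionTree] = []
    in_bag_rows: list[np.ndarray] = []
    nodes: list[TreeNode] = []
    for line in lines[5:]:
        if line.startswith("TREE"):
            if nodes:
                trees.append(RegressionTree(nodes, feature_names))
            nodes = []
        elif line.startswith("NODE"):
            _, _i, f, thr, left, right, value, n, mleft = line.split("\t")
            nodes.append(
                TreeNode(
                    int(f), float(thr), int(left), int(right), float(value),
                    int(n), bool(int(mleft)),
                )
            )
        elif line.startswith("INBAG"):
            counts = np.zeros(len(gene_ids), dtype=int)
            for pair in line.split("\t")[1:]:
                g, c = pair.rsplit(":", 1)
                counts[pos[g]] = int(c)
            in_bag_rows.append(counts)
    if nodes:
        trees.append(RegressionTree(nodes, feature_names))
    return TreeEnsemble(
        trees=trees,
        in_bag=np.vstack(in_bag_rows),
        gene_ids=gene_ids,
        species=species,
        seed=seed,
        feature_names=feature_names,
    )
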
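"""Stage orchestration: configuration, provenance, and artifact flow.

The pipeline runs on a directory of TSV artifacts.  ``simulate`` writes a
complete synthetic input bundle; downstream stages (features, degrees, fit,
predict-within, predict-cross, evaluate, rewire, coexpr) each read the
artifacts of their producer stages and write their own, with a provenance
header recording the stage, the seed substream and the parameters.  A
single global seed is expanded into independent per-stage substreams by
hashing the stage name, so rerunning any stage with the same config and
seed reproduces its outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import coexpr as cx
from . import features as feat
from . import model as mdl
from . import rewiring as rw
from . import simulate as sim
from .params import PARAMETER_FIELDS, Parameters
from .tables import (
    DegreeTable,
    read_network,
    read_table,
    write_network,
    write_table,
)

__all__ = ["RunConfig", "load_config", "run_stage", "STAGES"]

log = logging.getLogger("girewire")

STAGES = (
    "simulate",
    "features",
    "degrees",
    "fit",
    "predict-within",
    "predict-cross",
    "evaluate",
    "rewire",
    "coexpr",
)

#: artifact -> producing stage, for dependency error messages
_PRODUCERS = {
    "features1.tsv": "simulate",
    "features2.tsv": "simulate",
    "degrees1.tsv": "simulate",
    "degrees2.tsv": "simulate",
    "orthology.tsv": "simulate",
    "essential1.txt": "simulate",
    "essential2.txt": "simulate",
    "scores2.tsv": "simulate",
    "coexpr1.tsv": "simulate",
    "coexpr2.tsv": "simulate",
    "catalog.tsv": "simulate",
    "ensemble.txt": "fit",
    "pred_within1.tsv": "predict-within",
    "pred_cross2.tsv": "predict-cross",
}


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    out_dir: Path = Path("girewire_out")
    seed: int = 0
    verbosity: str = "INFO"
    params: Parameters = field(default_factory=Parameters)
    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream of the global seed."""
        return int((self.seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31))


_TOP_KEYS = {"out_dir", "seed", "verbosity", "parameters", "simulation"}


def load_config(path: Optional[str] = None, **overrides) -> RunConfig:
    """Load a YAML config; unknown keys are rejected with the valid list.

    An empty (or absent) file yields all defaults: epsilon cutoff -0.08,
    100 trees, 25 evaluation repeats, and so on from :class:`Parameters`.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; valid keys: {sorted(_TOP_KEYS)}"
        )
    p_over = raw.get("parameters", {}) or {}
    bad = set(p_over) - set(PARAMETER_FIELDS)
    if bad:
        raise ValueError(
            f"unknown parameter(s) {sorted(bad)}; valid: {sorted(PARAMETER_FIELDS)}"
        )
    if "rewiring_thresholds" in p_over:
        p_over["rewiring_thresholds"] = tuple(p_over["rewiring_thresholds"])
    params = Parameters(**p_over)
    s_over = raw.get("simulation", {}) or {}
    sim_fields = {f.name for f in dataclasses.fields(sim.SimulationConfig)}
    bad = set(s_over) - sim_fields
    if bad:
        raise ValueError(
            f"unknown simulation key(s) {sorted(bad)}; valid: {sorted(sim_fields)}"
        )
    if "group_size_range" in s_over:
        s_over["group_size_range"] = tuple(s_over["group_size_range"])
    cfg = RunConfig(
        out_dir=Path(raw.get("out_dir", "girewire_out")),
        seed=int(raw.get("seed", 0)),
        verbosity=str(raw.get("verbosity", "INFO")),
        params=params,
        sim=sim.SimulationConfig(**s_over),
    )
    for k, v in overrides.items():
        if v is not None:
            setattr(cfg, k, Path(v) if k == "out_dir" else v)
    log.info("resolved config: %s", cfg)
    return cfg


def _require(cfg: RunConfig, *names: str) -> None:
    for name in names:
        if not (cfg.out_dir / name).exists():
            raise FileNotFoundError(
                f"missing artifact {name!r}; run the "
                f"{_PRODUCERS.get(name, '?')!r} stage first"
            )


def _provenance(cfg: RunConfig, stage: str) -> list[str]:
    return [
        f"# stage: {stage}",
        f"# seed: {cfg.stage_seed(stage)}",
        f"# params: {json.dumps(cfg.params.asdict(), sort_keys=True)}",
    ]


def _write_df(df: pd.DataFrame, cfg: RunConfig, stage: str, name: str) -> None:
    path = cfg.out_dir / name
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance(cfg, stage):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_stage(cfg: RunConfig, stage: str) -> list[Path]:
    """Run one pipeline stage; returns the artifacts written."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; stages: {STAGES}")
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), logging.INFO))
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    seed = cfg.stage_seed(stage)
    fn = {
        "simulate": _stage_simulate,
        "features": _stage_features,
        "degrees": _stage_degrees,
        "fit": _stage_fit,
        "predict-within": _stage_predict_within,
        "predict-cross": _stage_predict_cross,
        "evaluate": _stage_evaluate,
        "rewire": _stage_rewire,
        "coexpr": _stage_coexpr,
    }[stage]
    arts = fn(cfg, seed)
    log.info("stage %s wrote %d artifact(s)", stage, len(arts))
    return arts


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, seed: int) -> list[Path]:
    out = cfg.out_dir
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    pair = sim.simulate_species_pair(cfg.sim, seed=int(seeds[0]))
    write_table(pair.features1, out / "features1.tsv")
    write_table(pair.features2, out / "features2.tsv")
    write_table(pair.degrees1, out / "degrees1.tsv")
    write_table(pair.degrees2, out / "degrees2.tsv")
    write_table(pair.orthology, out / "orthology.tsv")
    for name, ess in (("essential1.txt", pair.essential1), ("essential2.txt", pair.essential2)):
        (out / name).write_text("\n".join(sorted(ess)) + "\n")

    # validation screen for species 2: planted query-degrees scale with the
    # gene's degree percentile over the fixed query panel
    perc2 = mdl.degree_percentiles(pair.degrees2)
    qdeg = np.floor(cfg.sim.n_queries * perc2).astype(int)
    qdt = DegreeTable(species="species2", degrees=qdeg)
    screen = sim.simulate_interaction_screen(
        qdt, n_queries=cfg.sim.n_queries, seed=int(seeds[1]), params=cfg.params
    )
    write_table(screen, out / "scores2.tsv")

    # paired co-expression networks with planted rewired genes: the genes
    # whose cross-species degree difference is largest
    mapping = pair.orthology.one_to_one_map("1to2")
    common = [
        g for g in sorted(mapping)
        if g not in pair.essential1 and mapping[g] not in pair.essential2
    ][: cfg.sim.coexpr_genes]
    d1 = pair.degrees1.degrees
    d2 = pair.degrees2.degrees
    diffs = pd.Series(
        {g: abs(float(d2[mapping[g]]) - float(d1[g])) for g in common}
    )
    n_rew = max(1, min(cfg.sim.n_rewired, len(common) // 2))
    rewired = set(diffs.sort_values(ascending=False).index[:n_rew])
    net1, net2, truth = sim.simulate_coexpression_pair(
        pair.orthology, rewired, cfg.sim, seed=int(seeds[2]), genes=common
    )
    write_network(net1, out / "coexpr1.tsv")
    write_network(net2, out / "coexpr2.tsv")

    perc1_obs = mdl.degree_percentiles(pair.degrees1)
    catalog, truth_groups, _, _ = sim.simulate_group_catalog(
        list(d1.index), pair.orthology,
        n_groups=cfg.sim.n_groups, n_planted=0, seed=int(seeds[3]),
        size_range=cfg.sim.group_size_range, perc1=perc1_obs,
    )
    rw.write_group_catalog(catalog, out / "catalog.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "rewired_coexpr_genes": sorted(rewired),
                "class_rates": truth["class_rates"],
                "coeffs1": pair.truth["coeffs1"],
                "coeffs2": pair.truth["coeffs2"],
            },
            fh, indent=1,
        )
    return [out / n for n in _PRODUCERS if _PRODUCERS[n] == "simulate"]


def _stage_features(cfg: RunConfig, seed: int) -> list[Path]:
    """Recompute the derivable feature columns from bundle inputs and log coverage."""
    _require(cfg, "features1.tsv", "coexpr1.tsv")
    ft1 = read_table(cfg.out_dir / "features1.tsv", "features")
    net1 = read_network(cfg.out_dir / "coexpr1.tsv")
    coex_deg = feat.coexpression_degree(net1, density=cfg.params.coexpr_density)
    df = coex_deg.rename("coexpression_degree_recomputed").reset_index()
    df.columns = ["gene_id", "coexpression_degree_recomputed"]
    log.info("features: %d/%d genes with recomputed co-expression degree",
             len(df), len(ft1))
    _write_df(df, cfg, "features", "derived_features.tsv")
    return [cfg.out_dir / "derived_features.tsv"]


def _stage_degrees(cfg: RunConfig, seed: int) -> list[Path]:
    _require(cfg, "scores2.tsv")
    scores = read_table(cfg.out_dir / "scores2.tsv", "scores")
    dt = feat.degrees_from_interaction_scores(
        scores, cfg.params, mode="epsilon", species="species2", array_side_only=True
    )
    log.info("degrees: %d score records -> %d gene degrees", len(scores), len(dt))
    write_table(dt, cfg.out_dir / "screen_degrees2.tsv")
    return [cfg.out_dir / "screen_degrees2.tsv"]


def _load_model(cfg: RunConfig) -> mdl.GIDegreeModel:
    ft1 = read_table(cfg.out_dir / "features1.tsv", "features")
    dt1 = read_table(cfg.out_dir / "degrees1.tsv", "degrees")
    return mdl.GIDegreeModel(ft1, dt1, params=cfg.params)


def _stage_fit(cfg: RunConfig, seed: int) -> list[Path]:
    _require(cfg, "features1.tsv", "degrees1.tsv")
    res = _load_model(cfg).fit(seed)
    mdl.write_ensemble(res.ensemble, cfg.out_dir / "ensemble.txt")
    log.info("fit: %s", res.summary().replace("\n", " | "))
    return [cfg.out_dir / "ensemble.txt"]


def _results(cfg: RunConfig) -> mdl.GIDegreeResults:
    _require(cfg, "ensemble.txt", "features1.tsv", "degrees1.tsv")
    ens = mdl.read_ensemble(cfg.out_dir / "ensemble.txt")
    return mdl.GIDegreeResults(_load_model(cfg), ens)


def _write_predictions(pred: mdl.PredictionTable, cfg: RunConfig, stage: str, name: str) -> None:
    df = pd.concat([pred.predictions, pred.n_trees_used], axis=1).reset_index()
    _write_df(df, cfg, stage, name)


def _stage_predict_within(cfg: RunConfig, seed: int) -> list[Path]:
    res = _results(cfg)
    pred = res.predict_within()
    _write_predictions(pred, cfg, "predict-within", "pred_within1.tsv")
    return [cfg.out_dir / "pred_within1.tsv"]


def _stage_predict_cross(cfg: RunConfig, seed: int) -> list[Path]:
    _require(cfg, "features2.tsv")
    res = _results(cfg)
    ft2 = read_table(cfg.out_dir / "features2.tsv", "features")
    pred = res.predict_cross(ft2)
    _write_predictions(pred, cfg, "predict-cross", "pred_cross2.tsv")
    return [cfg.out_dir / "pred_cross2.tsv"]


def _stage_evaluate(cfg: RunConfig, seed: int) -> list[Path]:
    _require(cfg, "features1.tsv", "degrees1.tsv", "features2.tsv", "degrees2.tsv")
    model = _load_model(cfg)
    ft2 = read_table(cfg.out_dir / "features2.tsv", "features")
    dt2 = read_table(cfg.out_dir / "degrees2.tsv", "degrees")
    within, cross = model.evaluate_paired(ft2, dt2, seed=seed)
    rows = pd.DataFrame(
        [
            {"scenario": "within_species1", "mean_r": within.mean_r, "sd_r": within.sd_r,
             "n_repeats": len(within.per_repeat_r), "p": within.p_value, "n_genes": within.n_pairs},
            {"scenario": "cross_1_to_2", "mean_r": cross.mean_r, "sd_r": cross.sd_r,
             "n_repeats": len(cross.per_repeat_r), "p": cross.p_value, "n_genes": cross.n_pairs},
        ]
    )
    _write_df(rows, cfg, "evaluate", "evaluation.tsv")
    log.info("evaluate: within %s | cross %s", within.summary(), cross.summary())
    return [cfg.out_dir / "evaluation.tsv"]


def _stage_rewire(cfg: RunConfig, seed: int) -> list[Path]:
    _require(cfg, "degrees1.tsv", "pred_cross2.tsv", "pred_within1.tsv",
             "orthology.tsv", "catalog.tsv")
    out = cfg.out_dir
    dt1 = read_table(out / "degrees1.tsv", "degrees")
    orth = read_table(out / "orthology.tsv", "orthology")
    catalog = rw.read_group_catalog(out / "catalog.tsv")
    pred2 = pd.read_csv(out / "pred_cross2.tsv", sep="\t", comment="#").set_index("gene_id")
    pred1 = pd.read_csv(out / "pred_within1.tsv", sep="\t", comment="#").set_index("gene_id")
    perc1 = mdl.degree_percentiles(dt1)
    perc2 = mdl.degree_percentiles(pred2["predicted_degree"])
    results = rw.rewiring_scan(catalog, perc1, perc2, orth, cfg.params, seed)
    perc1_pred = mdl.degree_percentiles(pred1["predicted_degree"])
    control = rw.within_species_control(
        perc1, perc1_pred, catalog, cfg.params, seed, cross_results=results
    )
    annotated = control.attrs["annotated_cross_results"]
    log.info(
        "rewire: %d groups tested, %d flagged (expected false positives at "
        "alpha=%.2f: %d)",
        results.attrs["n_tested"], int(results["rewired"].sum()),
        cfg.params.module_alpha, results.attrs["expected_false_positives"],
    )
    _write_df(annotated, cfg, "rewire", "rewiring.tsv")
    _write_df(control, cfg, "rewire", "rewiring_control.tsv")
    return [out / "rewiring.tsv", out / "rewiring_control.tsv"]


def _stage_coexpr(cfg: RunConfig, seed: int) -> list[Path]:
    _require(cfg, "coexpr1.tsv", "coexpr2.tsv", "orthology.tsv",
             "degrees1.tsv", "pred_cross2.tsv", "essential1.txt", "essential2.txt")
    out = cfg.out_dir
    net1 = read_network(out / "coexpr1.tsv")
    net2 = read_network(out / "coexpr2.tsv")
    orth = read_table(out / "orthology.tsv", "orthology")
    dt1 = read_table(out / "degrees1.tsv", "degrees")
    ess1 = set((out / "essential1.txt").read_text().split())
    ess2 = set((out / "essential2.txt").read_text().split())
    pred_df = pd.read_csv(out / "pred_cross2.tsv", sep="\t", comment="#").set_index("gene_id")
    pred2 = mdl.PredictionTable(
        species="species2",
        predictions=pred_df["predicted_degree"],
        n_trees_used=pred_df["n_trees_used"],
    )
    # networks are already on a common (species-1-labeled) index in the
    # simulated bundle; restriction still drops essentials and non-orthologs
    identity_pairs = pd.DataFrame(
        {"gene_species1": net1.genes, "gene_species2": net1.genes,
         "relation": "one_to_one", "curated": False}
    )
    map21 = orth.one_to_one_map("2to1")
    ess2_as_sp1 = {map21[g] for g in ess2 if g in map21}
    sub1, sub2, _ = cx.restrict_to_orthologs(
        net1, net2, type(orth)(pairs=identity_pairs), ess1, ess2_as_sp1
    )
    edges1 = cx.sparsify_network(sub1, cfg.params.coexpr_density)
    edges2 = cx.sparsify_network(sub2, cfg.params.coexpr_density)
    overall = cx.conservation_rate(edges1, edges2)
    bg = cx.background_conservation(
        edges1, edges2, cfg.params.swap_multiplier, seed, n_reps=3
    )
    rows = []
    n_classified_total = 0
    for tau in cfg.params.rewiring_thresholds:
        labeling = cx.label_rewired(
            pred2, dt1, orth, tau, cfg.params.nonrewired_band
        )
        summaries = {s.edge_class: s for s in cx.conservation_by_class(edges1, edges2, labeling)}
        odds, p = (np.nan, np.nan)
        if summaries["RR"].total > 0 and summaries["NN"].total > 0:
            odds, p = cx.compare_classes(summaries["RR"], summaries["NN"])
        for cls in ("NN", "NR", "RR"):
            s = summaries[cls]
            n_classified_total += s.total
            rows.append(
                {"threshold": tau, "class": cls, "conserved": s.conserved,
                 "total": s.total, "rate": s.rate, "ci_low": s.ci_low,
                 "ci_high": s.ci_high, "fisher_p_RR_vs_NN": p,
                 "overall_conservation": overall, "background_conservation": bg}
            )
        log.info("coexpr tau=%d: classified union edges per class %s",
                 tau, {c: summaries[c].total for c in ("NN", "NR", "RR")})
    log.info("coexpr: %d union edges, overall conservation %.4f, background %.4f, "
             "sum of class totals %d", len(edges1 | edges2), overall, bg,
             n_classified_total)
    _write_df(pd.DataFrame(rows), cfg, "coexpr", "coexpr_summary.tsv")
    return [out / "coexpr_summary.tsv"]
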
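"""Typed tables and networks used throughout the pipeline, with TSV readers/writers.

Every on-disk artifact is a plain-text table: TSV with a header row for gene
tables, GAF 2.x for annotations, and either a three-column edge list or a
comma-delimited lower-triangle matrix for weighted networks.  Metadata that
does not fit a column (species label, thresholds that produced a degree
table) is carried in ``# key: value`` comment lines before the header and
round-trips through :func:`write_table` / :func:`read_table`.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_FEATURES",
    "FeatureTable",
    "DegreeTable",
    "ThresholdRecord",
    "InteractionScoreTable",
    "OrthologyMap",
    "AnnotationSet",
    "WeightedGeneNetwork",
    "read_table",
    "write_table",
    "read_annotations",
    "read_network",
    "write_network",
]

#: The 16 gene features the degree model consumes, in canonical order.
#: Order matters: it is the deterministic tie-break order for tree splits.
CANONICAL_FEATURES: tuple[str, ...] = (
    "sm_fitness_defect",
    "multifunctionality",
    "yeast_conservation",
    "broad_conservation",
    "ppi_degree",
    "expression_level",
    "disorder",
    "cai",
    "protein_length",
    "coexpression_degree",
    "n_domains",
    "n_unique_domains",
    "nc",
    "dn_ds",
    "copy_number",
    "expression_variation",
)


class TableValidationError(ValueError):
    """Raised when a table violates its schema invariants."""


class TableParseError(ValueError):
    """Raised when a file cannot be parsed as the requested table kind."""


def _check_unique_genes(genes: Iterable[str]) -> None:
    idx = pd.Index(genes)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise TableValidationError(f"duplicate gene_id(s): {dups[:5]}")


@dataclass
class FeatureTable:
    """Per-gene values of the 16 canonical features for one species.

    ``data`` is a DataFrame indexed by gene_id with exactly the canonical 16
    columns; missing values stay NaN (imputation is the model's business).
    """

    species: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        got = list(self.data.columns)
        extra = [c for c in got if c not in CANONICAL_FEATURES]
        missing = [c for c in CANONICAL_FEATURES if c not in got]
        if extra:
            raise TableValidationError(f"unknown feature column(s): {extra}")
        if missing:
            raise TableValidationError(f"missing feature column(s): {missing}")
        _check_unique_genes(self.data.index)
        self.data = self.data.loc[:, list(CANONICAL_FEATURES)].astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "gene_id"
        self._check_ranges()

    def _check_ranges(self) -> None:
        bounded = {
            "yeast_conservation": (0, 23, True),
            "broad_conservation": (0, 86, True),
            "expression_variation": (0.0, 1.0, False),
        }
        for col, (lo, hi, integral) in bounded.items():
            vals = self.data[col].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise TableValidationError(f"{col} out of range [{lo}, {hi}]")
            if integral and not np.allclose(vals, np.round(vals)):
                raise TableValidationError(f"{col} must be integer-valued")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class ThresholdRecord:
    """Provenance of a degree table derived from interaction scores."""

    score_kind: str  # "epsilon" or "s_score"
    score_cutoff: float
    p_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.score_kind not in ("epsilon", "s_score"):
            raise TableValidationError(f"unknown score_kind {self.score_kind!r}")


@dataclass
class DegreeTable:
    """Per-gene negative genetic-interaction degree for one species."""

    species: str
    degrees: pd.Series
    provenance: Optional[ThresholdRecord] = None

    def __post_init__(self) -> None:
        _check_unique_genes(self.degrees.index)
        s = self.degrees.astype(float)
        if (s < 0).any() or not np.allclose(s, np.round(s)):
            raise TableValidationError("degrees must be nonnegative integers")
        self.degrees = s.round().astype(int)
        self.degrees.index = self.degrees.index.astype(str)
        self.degrees.index.name = "gene_id"
        self.degrees.name = "degree"

    @property
    def genes(self) -> pd.Index:
        return self.degrees.index

    def __len__(self) -> int:
        return len(self.degrees)


@dataclass
class InteractionScoreTable:
    """Raw screen scores: one record per (query, array) gene pair."""

    records: pd.DataFrame  # columns: query_gene, array_gene, score, p_value

    def __post_init__(self) -> None:
        cols = ["query_gene", "array_gene", "score", "p_value"]
        df = self.records
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise TableValidationError(f"score table missing column(s): {missing}")
        df = df.loc[:, cols].copy()
        df["query_gene"] = df["query_gene"].astype(str)
        df["array_gene"] = df["array_gene"].astype(str)
        df["score"] = df["score"].astype(float)
        df["p_value"] = df["p_value"].astype(float)
        if df.duplicated(["query_gene", "array_gene"]).any():
            raise TableValidationError("duplicate (query, array) pair in score table")
        pv = df["p_value"].dropna()
        if ((pv < 0) | (pv > 1)).any():
            raise TableValidationError("p_value outside [0, 1]")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class OrthologyMap:
    """Cross-species gene pairs with their orthology relation.

    ``pairs`` columns: gene_species1, gene_species2, relation
    ("one_to_one" or "other") and a boolean ``curated`` source flag.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.pairs.copy()
        for col in ("gene_species1", "gene_species2", "relation"):
            if col not in df.columns:
                raise TableValidationError(f"orthology map missing column {col!r}")
            df[col] = df[col].astype(str)
        if "curated" not in df.columns:
            df["curated"] = False
        df["curated"] = df["curated"].astype(bool)
        bad = set(df["relation"]) - {"one_to_one", "other"}
        if bad:
            raise TableValidationError(f"unknown relation value(s): {sorted(bad)}")
        one = df[df["relation"] == "one_to_one"]
        for col in ("gene_species1", "gene_species2"):
            if one[col].duplicated().any():
                raise TableValidationError(
                    f"gene appears in more than one one_to_one pair ({col})"
                )
        self.pairs = df.reset_index(drop=True)

    def one_to_one(self) -> pd.DataFrame:
        return self.pairs[self.pairs["relation"] == "one_to_one"]

    def one_to_one_map(self, direction: str = "1to2") -> dict[str, str]:
        """Dict mapping genes of one species to their unique ortholog."""
        one = self.one_to_one()
        if direction == "1to2":
            return dict(zip(one["gene_species1"], one["gene_species2"]))
        if direction == "2to1":
            return dict(zip(one["gene_species2"], one["gene_species1"]))
        raise ValueError("direction must be '1to2' or '2to1'")

    def genes_with_any_ortholog(self, side: int) -> set[str]:
        """All genes of species ``side`` (1 or 2) appearing in any pair."""
        col = "gene_species1" if side == 1 else "gene_species2"
        return set(self.pairs[col])

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AnnotationSet:
    """Canonicalized per-gene GO term sets plus the alt-id map that produced them."""

    annotations: dict[str, frozenset[str]]
    alt_ids: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = {}
        for gene, terms in self.annotations.items():
            resolved = frozenset(self._canonicalize(t) for t in terms)
            canon[str(gene)] = resolved
        self.annotations = canon

    def _canonicalize(self, term: str) -> str:
        seen = set()
        while term in self.alt_ids and term not in seen:
            seen.add(term)
            term = self.alt_ids[term]
        return term

    def terms(self, gene: str) -> frozenset[str]:
        return self.annotations.get(gene, frozenset())

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, ts in self.annotations.items() if term in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.annotations.values():
            out |= ts
        return out

    def __len__(self) -> int:
        return len(self.annotations)


class WeightedGeneNetwork:
    """Symmetric gene-gene score matrix, sparsifiable at a percentile cutoff.

    Weights are stored as a dense symmetric matrix with NaN for absent pairs
    and a NaN diagonal (self-pairs carry no weight).
    """

    def __init__(self, genes: Iterable[str], weights: np.ndarray):
        self.genes = list(map(str, genes))
        _check_unique_genes(self.genes)
        w = np.asarray(weights, dtype=float)
        n = len(self.genes)
        if w.shape != (n, n):
            raise TableValidationError(f"weight matrix shape {w.shape} != ({n}, {n})")
        if not np.array_equal(np.isnan(w), np.isnan(w.T)) or not np.allclose(
            np.nan_to_num(w), np.nan_to_num(w.T)
        ):
            raise TableValidationError("weight matrix must be symmetric")
        w = w.copy()
        np.fill_diagonal(w, np.nan)
        self.weights = w
        self._index = {g: i for i, g in enumerate(self.genes)}

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]], genes: Optional[Iterable[str]] = None
    ) -> "WeightedGeneNetwork":
        edges = list(edges)
        if genes is None:
            genes = sorted({g for a, b, _ in edges for g in (a, b)})
        genes = list(genes)
        idx = {g: i for i, g in enumerate(genes)}
        w = np.full((len(genes), len(genes)), np.nan)
        for a, b, wt in edges:
            if a == b:
                raise TableValidationError(f"self-pair for gene {a!r}")
            i, j = idx[a], idx[b]
            for x, y in ((i, j), (j, i)):
                if not np.isnan(w[x, y]) and w[x, y] != wt:
                    raise TableValidationError(
                        f"conflicting weights for pair ({a!r}, {b!r})"
                    )
                w[x, y] = wt
        return cls(genes, w)

    def weight(self, a: str, b: str) -> float:
        return self.weights[self._index[a], self._index[b]]

    def pair_weights(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle (i, j, weight) arrays over stored (non-NaN) pairs."""
        iu, ju = np.triu_indices(len(self.genes), k=1)
        w = self.weights[iu, ju]
        keep = ~np.isnan(w)
        return iu[keep], ju[keep], w[keep]

    def subnetwork(self, genes: Iterable[str]) -> "WeightedGeneNetwork":
        genes = [g for g in genes if g in self._index]
        sel = [self._index[g] for g in genes]
        return WeightedGeneNetwork(genes, self.weights[np.ix_(sel, sel)])

    def n_pairs(self) -> int:
        return len(self.pair_weights()[2])

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

_SCHEMAS = ("features", "degrees", "scores", "orthology")


def _read_metadata(path: Path) -> tuple[dict[str, str], int]:
    """Leading '# key: value' comment lines and how many to skip."""
    meta: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
    return meta, skip


def read_table(path, schema: str, species: Optional[str] = None):
    """Read a typed TSV table.

    Parameters
    ----------
    path : path-like
        TSV file with a header row; leading ``# key: value`` lines carry
        metadata (species, degree-threshold provenance).
    schema : {"features", "degrees", "scores", "orthology"}
        Which table kind to parse; invariants of that kind are enforced.
    species : str, optional
        Species label override; otherwise taken from file metadata.
    """
    path = Path(path)
    if schema not in _SCHEMAS:
        raise ValueError(f"schema must be one of {_SCHEMAS}")
    if not path.exists():
        raise FileNotFoundError(path)
    meta, skip = _read_metadata(path)
    try:
        df = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableParseError(f"{path}: {exc}") from exc
    sp = species or meta.get("species", "unknown")

    if schema == "features":
        if "gene_id" not in df.columns:
            raise TableParseError(f"{path}: feature table needs a gene_id column")
        df = df.set_index("gene_id")
        data = df.apply(_to_float_column)
        return FeatureTable(species=sp, data=data)

    if schema == "degrees":
        for col in ("gene_id", "degree"):
            if col not in df.columns:
                raise TableParseError(f"{path}: degree table needs column {col!r}")
        degrees = pd.Series(
            _to_float_column(df["degree"]).values, index=df["gene_id"].values
        )
        prov = None
        if "score_kind" in meta:
            prov = ThresholdRecord(
                score_kind=meta["score_kind"],
                score_cutoff=float(meta["score_cutoff"]),
                p_cutoff=(
                    float(meta["p_cutoff"])
                    if meta.get("p_cutoff", "none") != "none"
                    else None
                ),
            )
        return DegreeTable(species=sp, degrees=degrees, provenance=prov)

    if schema == "scores":
        need = ["query_gene", "array_gene", "score"]
        for col in need:
            if col not in df.columns:
                raise TableParseError(f"{path}: score table needs column {col!r}")
        out = df.copy()
        out["score"] = _to_float_column(df["score"])
        out["p_value"] = (
            _to_float_column(df["p_value"]) if "p_value" in df.columns else np.nan
        )
        return InteractionScoreTable(records=out)

    # orthology
    for col in ("gene_species1", "gene_species2", "relation"):
        if col not in df.columns:
            raise TableParseError(f"{path}: orthology map needs column {col!r}")
    if "curated" in df.columns:
        df["curated"] = df["curated"].map(
            {"True": True, "true": True, "1": True, "False": False, "false": False, "0": False}
        )
    return OrthologyMap(pairs=df)


def _to_float_column(col: pd.Series) -> pd.Series:
    def conv(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return np.nan
        s = str(v).strip()
        if s in ("", "NA", "NaN", "nan"):
            return np.nan
        try:
            return float(s)
        except ValueError as exc:
            raise TableParseError(f"cannot parse value {v!r} as number") from exc

    return col.map(conv).astype(float)


def write_table(obj, path) -> None:
    """Write a typed table as TSV with metadata comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []
    if isinstance(obj, FeatureTable):
        lines.append(f"# species: {obj.species}")
        body = obj.data.reset_index()
    elif isinstance(obj, DegreeTable):
        lines.append(f"# species: {obj.species}")
        if obj.provenance is not None:
            pr = obj.provenance
            lines.append(f"# score_kind: {pr.score_kind}")
            lines.append(f"# score_cutoff: {pr.score_cutoff!r}")
            lines.append(f"# p_cutoff: {pr.p_cutoff if pr.p_cutoff is not None else 'none'}")
        body = obj.degrees.reset_index()
    elif isinstance(obj, InteractionScoreTable):
        body = obj.records
    elif isinstance(obj, OrthologyMap):
        body = obj.pairs
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    buf = io.StringIO()
    body.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# GAF annotations
# ---------------------------------------------------------------------------

def read_annotations(gaf_path, alt_map_path=None) -> AnnotationSet:
    """Read a GAF 2.x gene-association file into canonical per-gene term sets.

    Gene identifiers come from the DB Object ID column (2nd), term ids from
    the GO ID column (5th).  Terms are replaced via the two-column alt-id map
    (alt_id <tab> canonical_id) before sets are formed, so a gene annotated
    with a term and one of its alternative ids counts that term once.
    Malformed term ids are skipped with a warning.
    """
    alt: dict[str, str] = {}
    if alt_map_path is not None:
        with open(alt_map_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("!", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) >= 2:
                    alt[parts[0]] = parts[1]
    ann: dict[str, set[str]] = {}
    with open(gaf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                warnings.warn(f"{gaf_path}:{lineno}: short GAF row skipped")
                continue
            gene, term = parts[1].strip(), parts[4].strip()
            if not term.startswith("GO:"):
                warnings.warn(f"{gaf_path}:{lineno}: malformed term {term!r} skipped")
                continue
            ann.setdefault(gene, set()).add(term)
    return AnnotationSet(annotations={g: frozenset(t) for g, t in ann.items()}, alt_ids=alt)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def read_network(path, kind: str = "edge_list") -> WeightedGeneNetwork:
    """Read a weighted gene network.

    kind="edge_list": TSV with header (gene_a, gene_b, weight).
    kind="lower_triangle_matrix": first line is the comma-separated gene
    list; line i (1-based thereafter) holds the i weights linking gene i to
    genes 0..i-1.  Empty cells are missing pairs.
    """
    path = Path(path)
    if kind == "edge_list":
        meta, skip = _read_metadata(path)
        df = pd.read_csv(path, sep="\t", skiprows=skip)
        need = ("gene_a", "gene_b", "weight")
        for col in need:
            if col not in df.columns:
                raise TableParseError(f"{path}: edge list needs column {col!r}")
        edges = [
            (str(a), str(b), float(w))
            for a, b, w in zip(df["gene_a"], df["gene_b"], df["weight"])
        ]
        return WeightedGeneNetwork.from_edges(edges)
    if kind == "lower_triangle_matrix":
        with open(path) as fh:
            rows = fh.read().split("\n")
        if rows and rows[-1] == "":
            rows.pop()  # trailing newline; inner blank rows are 1-cell NaN rows
        genes = [g.strip() for g in rows[0].split(",")]
        n = len(genes)
        if len(rows) - 1 != n - 1:
            raise TableParseError(
                f"{path}: expected {n - 1} triangle rows, found {len(rows) - 1}"
            )
        w = np.full((n, n), np.nan)
        for i, row in enumerate(rows[1:], start=1):
            cells = row.split(",")
            if len(cells) != i:
                raise TableParseError(f"{path}: row {i} has {len(cells)} cells, expected {i}")
            for j, cell in enumerate(cells):
                cell = cell.strip()
                if cell in ("", "NA", "NaN", "nan"):
                    continue
                w[i, j] = w[j, i] = float(cell)
        return WeightedGeneNetwork(genes, w)
    raise ValueError("kind must be 'edge_list' or 'lower_triangle_matrix'")


def write_network(net: WeightedGeneNetwork, path, kind: str = "edge_list") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if kind == "edge_list":
        iu, ju, w = net.pair_weights()
        df = pd.DataFrame(
            {
                "gene_a": [net.genes[i] for i in iu],
                "gene_b": [net.genes[j] for j in ju],
                "weight": w,
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        return
    if kind == "lower_triangle_matrix":
        with open(path, "w") as fh:
            fh.write(",".join(net.genes) + "\n")
            for i in range(1, len(net.genes)):
                cells = []
                for j in range(i):
                    v = net.weights[i, j]
                    cells.append("" if np.isnan(v) else f"{v:.17g}")
                fh.write(",".join(cells) + "\n")
        return
    raise ValueError("kind must be 'edge_list' or 'lower_triangle_matrix'")
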
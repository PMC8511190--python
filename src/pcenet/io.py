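"""Readers, writers and set-overlap summaries for the pipeline's external formats.

All tabular formats are TSV (UTF-8, header row); gene sets are GMT. The
expression input is a protein x sample matrix of non-negative spectral
counts, the semiquantitative abundance proxy produced by label-free
shotgun proteomics.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TraitTable",
    "InteractionNetwork",
    "AnnotationCollection",
    "VennSummary",
    "read_expression",
    "read_traits",
    "read_edge_list",
    "read_gene_sets",
    "venn_summary",
    "write_table",
]


@dataclass
class ExpressionMatrix:
    """Protein x sample grid of non-negative expression values.

    ``data`` is indexed by protein ID (rows) and sample ID (columns).
    Raw spectral counts are integers; transformed values are reals.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        dup_p = idx[idx.duplicated()].unique().tolist()
        if dup_p:
            raise ValueError(f"duplicate protein IDs: {dup_p}")
        dup_s = cols[cols.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample IDs: {dup_s}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = [
                (idx[i], cols[j])
                for i, j in zip(*np.where(~np.vectorize(_is_number)(values)))
            ]
            raise ValueError(f"non-numeric cells at (protein, sample): {bad[:10]}")
        neg = np.asarray(values, dtype=float) < 0
        if neg.any():
            coords = [(idx[i], cols[j]) for i, j in zip(*np.where(neg))]
            raise ValueError(f"negative cells at (protein, sample): {coords[:10]}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def log2p1(self) -> "ExpressionMatrix":
        """Return a copy transformed elementwise to log2(v + 1)."""
        return ExpressionMatrix(np.log2(self.data.astype(float) + 1.0))

    def subset(self, proteins) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(proteins)])


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


@dataclass
class TraitTable:
    """Per-sample binary trait indicators plus optional real covariates."""

    traits: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        idx = self.traits.index
        dup = idx[idx.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate sample IDs: {dup}")
        vals = self.traits.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = self.traits.columns[
                [not np.isin(self.traits[c], (0, 1)).all() for c in self.traits.columns]
            ].tolist()
            raise ValueError(f"trait columns with values outside {{0,1}}: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.traits.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    def usable_traits(self) -> list[str]:
        """Traits with at least one sample in each class (testable)."""
        return [c for c in self.traits.columns if self.traits[c].nunique() == 2]

    def aligned_to(self, X: ExpressionMatrix) -> "TraitTable":
        missing = [s for s in X.sample_ids if s not in self.traits.index]
        if missing:
            raise ValueError(f"samples missing from trait table: {missing}")
        cov = None
        if self.covariates is not None:
            cov = self.covariates.loc[X.sample_ids]
        return TraitTable(self.traits.loc[X.sample_ids], cov)


@dataclass
class InteractionNetwork:
    """Undirected protein interaction network with confidence in [0, 1]."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u}")
            s = d.get("confidence", 1.0)
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"confidence out of [0,1] on edge {u}-{v}: {s}")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class AnnotationCollection:
    """Named protein sets (terms) over a common background universe."""

    terms: dict[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.terms.items():
            if not members:
                raise ValueError(f"empty term: {name}")
            stray = members - self.background
            if stray:
                raise ValueError(
                    f"term {name!r} has members outside the background: {sorted(stray)}"
                )


@dataclass(frozen=True)
class VennSummary:
    """Two-set identification overlap: counts and union percentages."""

    n_only_a: int
    n_only_b: int
    n_shared: int
    pct_only_a: float
    pct_only_b: float
    pct_shared: float

    @property
    def n_total(self) -> int:
        return self.n_only_a + self.n_only_b + self.n_shared

    @property
    def n_a(self) -> int:
        return self.n_only_a + self.n_shared

    @property
    def n_b(self) -> int:
        return self.n_only_b + self.n_shared


def read_expression(path, transform: str = "none") -> ExpressionMatrix:
    """Read a protein x sample TSV (first column protein IDs, header samples).

    ``transform='log2p1'`` maps each value v to log2(v + 1). Protein order is
    canonicalized by sorting IDs so that downstream results do not depend on
    file row order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    X = ExpressionMatrix(df.sort_index())
    if transform == "none":
        return X
    if transform == "log2p1":
        return X.log2p1()
    raise ValueError(f"unknown transform: {transform!r}")


def read_traits(path, trait_columns: list[str] | None = None) -> TraitTable:
    """Read a sample trait TSV (first column sample ID).

    Columns whose values all lie in {0, 1} are treated as binary traits,
    the rest as numeric covariates; ``trait_columns`` overrides the
    inference and errors on non-binary values in a declared trait.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if trait_columns is None:
        trait_columns = [c for c in df.columns if np.isin(df[c], (0, 1)).all()]
    else:
        for c in trait_columns:
            if c not in df.columns:
                raise ValueError(f"declared trait column not in file: {c}")
    covar_columns = [c for c in df.columns if c not in trait_columns]
    covariates = df[covar_columns].astype(float) if covar_columns else None
    return TraitTable(df[trait_columns], covariates)


def read_edge_list(path, min_confidence: float = 0.400) -> InteractionNetwork:
    """Read a proteinA/proteinB/combined_score TSV into a filtered network.

    Scores on the STRING 0-1000 integer scale (detected by max > 1) are
    rescaled to [0, 1]. Edges below ``min_confidence`` (strictly) and
    self-loops are dropped; duplicate edges keep the maximum score.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header is None or not header.strip():
            raise ValueError("empty edge list file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed edge row at line {lineno}: {line!r}")
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric score at line {lineno}: {raw!r}"
                ) from exc
            rows.append((a, b, score))
    if rows:
        max_score = max(s for _, _, s in rows)
        if max_score > 1.0:
            rows = [(a, b, s / 1000.0) for a, b, s in rows]
    g = nx.Graph()
    for a, b, s in rows:
        if a == b:
            continue
        if s < min_confidence:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], s)
        else:
            g.add_edge(a, b, confidence=s)
    return InteractionNetwork(g)


def read_gene_sets(path, background: set[str] | None = None) -> AnnotationCollection:
    """Read a GMT file (term, description, members...).

    The background defaults to the union of all term members; an explicit
    background must contain every member.
    """
    terms: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not any(p for p in parts[2:]):
                raise ValueError(f"empty term at line {lineno}")
            name = parts[0]
            members = frozenset(p for p in parts[2:] if p)
            terms[name] = members
    if background is None:
        bg = frozenset().union(*terms.values()) if terms else frozenset()
    else:
        bg = frozenset(background)
    return AnnotationCollection(terms, bg)


def _pct(numer: int, denom: int) -> float:
    """Percentage to one decimal, round-half-up (the reporting convention)."""
    if denom == 0:
        return 0.0
    q = decimal.Decimal(numer * 100) / decimal.Decimal(denom)
    return float(q.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


def venn_summary(set_a, set_b) -> VennSummary:
    """Two-set overlap counts and union percentages (one decimal)."""
    a, b = set(set_a), set(set_b)
    shared = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    total = shared + only_a + only_b
    return VennSummary(
        n_only_a=only_a,
        n_only_b=only_b,
        n_shared=shared,
        pct_only_a=_pct(only_a, total),
        pct_only_b=_pct(only_b, total),
        pct_shared=_pct(shared, total),
    )


def write_table(rows: pd.DataFrame, path) -> None:
    """Write a result table as TSV with stable column order.

    Floats are written with 17 significant digits so a read-back round-trip
    reproduces the values.
    """
    rows.to_csv(path, sep="\t", index=False, float_format="%.17g")
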
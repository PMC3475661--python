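"""Core gene-level data structures, rank normalization and ortholog-loss conventions.

The analyses in this package operate on per-gene properties (Ka/Ks evolutionary
rate, mRNA expression, codon adaptation index, ortholog presence in one or more
comparison species) normalized into genome-wide midranks.  Genes lacking an
ortholog in the comparison species carry no measurable Ka/Ks; they are assigned
a single value strictly above the fastest-evolving ortholog-bearing gene so that
they occupy the top of the rank distribution, and median/rank statistics
downstream are insensitive to the exact constant used.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "GeneTable",
    "PPINetwork",
    "AnnotationMap",
    "rank_transform",
    "assign_missing_ortholog_rate",
]

#: canonical gene-table columns in on-disk order
GENE_TABLE_COLUMNS = [
    "gene_id",
    "ka_ks",
    "expression",
    "cai",
    "is_tf",
    "ortholog_par",
    "ortholog_mik",
]

_BOOL_COLUMNS = ("is_tf", "ortholog_par", "ortholog_mik")


def rank_transform(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Normalized ascending midranks in (0, 1].

    Ties receive the average of the ranks they span (midranks), so the sum of
    un-normalized ranks is exactly N(N+1)/2 and Spearman statistics computed on
    these ranks agree with their conventional definitions.  NaN entries are
    excluded: a gene with no measurement for a property simply has no rank for
    it (pairwise exclusion downstream).

    Raises
    ------
    ValueError
        If no non-missing values are supplied.
    """
    s = pd.Series(values, dtype=float)
    s = s.dropna()
    if s.empty:
        raise ValueError("rank_transform: no non-missing values supplied")
    ranks = rankdata(s.to_numpy(), method="average") / len(s)
    return pd.Series(ranks, index=s.index, name=getattr(values, "name", None))


@dataclass
class GeneTable:
    """Per-gene property table, indexed by unique gene id.

    Wraps a :class:`pandas.DataFrame` whose index is ``gene_id`` and whose
    columns include ``ka_ks`` (NaN when the gene has no ortholog in the primary
    comparison species), ``expression``, ``cai``, the boolean flags ``is_tf``
    and ``ortholog_<species>``, and, once derived, ``assigned_ka_ks`` and
    ``rank_<property>`` columns.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene_id: {dups[:5]}")
        for col in ("ka_ks", "expression", "assigned_ka_ks"):
            if col in df.columns:
                vals = df[col].to_numpy(dtype=float)
                if np.any(vals[~np.isnan(vals)] < 0):
                    raise ValueError(f"negative values in column {col!r}")
        if "cai" in df.columns:
            cai = df["cai"].to_numpy(dtype=float)
            ok = np.isnan(cai) | ((cai >= 0.0) & (cai <= 1.0))
            if not ok.all():
                raise ValueError("cai values must lie in [0, 1]")

    # -- construction / IO --------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneTable":
        df = df.copy()
        if "gene_id" in df.columns:
            df = df.set_index("gene_id")
        df.index = df.index.astype(str)
        df.index.name = "gene_id"
        for col in _BOOL_COLUMNS:
            if col in df.columns:
                df[col] = df[col].astype(int).astype(bool)
        # a gene flagged as lacking the primary-species ortholog carries no
        # measurable ka_ks, whatever the file says
        if "ortholog_par" in df.columns and "ka_ks" in df.columns:
            df.loc[~df["ortholog_par"], "ka_ks"] = np.nan
        elif "ka_ks" in df.columns:
            df["ortholog_par"] = df["ka_ks"].notna()
        return cls(df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "NA"],
                          keep_default_na=False)
        if "gene_id" not in raw.columns:
            raise ValueError("gene table must have a 'gene_id' column")
        if raw["gene_id"].duplicated().any():
            dups = raw["gene_id"][raw["gene_id"].duplicated()].tolist()
            raise ValueError(f"duplicate gene_id: {dups[:5]}")
        df = raw.set_index("gene_id")
        for col in df.columns:
            if col in _BOOL_COLUMNS:
                df[col] = pd.to_numeric(df[col], errors="raise").astype(bool)
            else:
                try:
                    # float() is correctly rounded, so written values re-load
                    # bit-identically (pandas' fast parser is not)
                    df[col] = df[col].map(
                        lambda v: float(v) if isinstance(v, str) else np.nan
                    )
                except ValueError as exc:
                    raise ValueError(f"unparseable numeric field in column {col!r}: {exc}")
        return cls.from_frame(df.reset_index())

    def to_tsv(self, path: str | Path) -> None:
        df = self.df.copy()
        for col in _BOOL_COLUMNS:
            if col in df.columns:
                df[col] = df[col].astype(int)
        cols = [c for c in GENE_TABLE_COLUMNS if c != "gene_id" and c in df.columns]
        cols += [c for c in df.columns if c not in cols]
        df[cols].to_csv(path, sep="\t", index=True, index_label="gene_id")

    # -- accessors -----------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def genes(self) -> pd.Index:
        return self.df.index

    @property
    def tf_ids(self) -> pd.Index:
        return self.df.index[self.df["is_tf"]]

    def has_ortholog(self, comparison: str = "par") -> pd.Series:
        col = f"ortholog_{comparison}"
        if col not in self.df.columns:
            raise KeyError(f"no ortholog flags for comparison species {comparison!r}")
        return self.df[col]

    # -- derived columns -----------------------------------------------------
    def with_ranks(self, properties: Iterable[str]) -> "GeneTable":
        """Return a copy with ``rank_<prop>`` columns added.

        Each property is ranked over the genes that carry it; genes missing
        the property get NaN rank and are excluded pairwise downstream.
        """
        df = self.df.copy()
        for prop in properties:
            if prop not in df.columns:
                raise KeyError(f"unknown property {prop!r}")
            df[f"rank_{prop}"] = rank_transform(df[prop])
        return GeneTable(df)


def assign_missing_ortholog_rate(
    table: GeneTable,
    comparison: str = "par",
    multiplier: float = 1.1,
) -> GeneTable:
    """Assign a shared top Ka/Ks value to genes lacking an ortholog.

    Genes with no ortholog in ``comparison`` (lost there or lineage-specifically
    gained) have no measurable substitution rate but are, by construction,
    at least as diverged as the fastest ortholog-bearing gene.  They all
    receive ``max(ka_ks) * multiplier`` in a new ``assigned_ka_ks`` column;
    ortholog-bearing genes keep their measured value.  Because every
    downstream statistic is rank- or median-based, results do not depend on
    the multiplier as long as it places these genes above the maximum.
    """
    if multiplier <= 1.0:
        raise ValueError("multiplier must exceed 1 to keep assigned values strictly above the maximum")
    df = table.df.copy()
    has = table.has_ortholog(comparison) & df["ka_ks"].notna()
    if not has.any():
        raise ValueError("no ortholog-bearing genes with a Ka/Ks value")
    maxv = float(df.loc[has, "ka_ks"].max())
    assigned_value = maxv * multiplier if maxv > 0 else multiplier - 1.0
    df["assigned_ka_ks"] = np.where(has, df["ka_ks"], assigned_value)
    return GeneTable(df)


class PPINetwork:
    """Undirected protein-protein interaction network with report counts."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        allow_self_loops: bool = False,
    ) -> "PPINetwork":
        g = nx.Graph()
        for a, b, n_reports in edges:
            if a == b and not allow_self_loops:
                continue
            if not isinstance(n_reports, numbers.Integral) or n_reports < 1:
                raise ValueError(f"n_reports must be a positive integer, got {n_reports!r}")
            if g.has_edge(a, b):
                g[a][b]["n_reports"] += int(n_reports)
            else:
                g.add_edge(a, b, n_reports=int(n_reports))
        return cls(g)

    @classmethod
    def from_tsv(cls, path: str | Path, **kw) -> "PPINetwork":
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        return cls.from_edges(
            zip(df["gene_a"], df["gene_b"], df["n_reports"].astype(int)), **kw
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(
            (min(a, b), max(a, b), d["n_reports"]) for a, b, d in self.graph.edges(data=True)
        )
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_reports"]).to_csv(
            path, sep="\t", index=False
        )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degree(self) -> pd.Series:
        """Distinct-partner count per gene."""
        return pd.Series(dict(self.graph.degree()), dtype=int).sort_index()

    def neighbors(self, gene: str) -> list[str]:
        return list(self.graph.neighbors(gene)) if gene in self.graph else []

    def median_neighbor_value(self, values: pd.Series) -> pd.Series:
        """Median of ``values`` over each gene's interaction partners."""
        out = {}
        for gene in self.graph.nodes:
            vals = values.reindex(self.neighbors(gene)).dropna()
            if len(vals):
                out[gene] = float(vals.median())
        return pd.Series(out, dtype=float).sort_index()


@dataclass
class AnnotationMap:
    """Flat gene -> set-of-category annotation (GO-like terms, no graph propagation)."""

    gene_to_terms: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationMap":
        m: dict[str, set[str]] = {}
        for gene, term in pairs:
            m.setdefault(str(gene), set()).add(str(term))
        return cls(m)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_pairs(zip(df["gene_id"], df["term_id"]))

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(
            (g, t) for g, terms in self.gene_to_terms.items() for t in terms
        )
        pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)

    @property
    def terms(self) -> set[str]:
        return {t for terms in self.gene_to_terms.values() for t in terms}

    def genes_in(self, term: str) -> set[str]:
        return {g for g, terms in self.gene_to_terms.items() if term in terms}

    def term_sizes(self) -> pd.Series:
        sizes: dict[str, int] = {}
        for terms in self.gene_to_terms.values():
            for t in terms:
                sizes[t] = sizes.get(t, 0) + 1
        return pd.Series(sizes, dtype=int).sort_index()

    def terms_of(self, gene: str) -> set[str]:
        return self.gene_to_terms.get(gene, set())
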
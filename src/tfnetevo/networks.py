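"""Directed TF->target regulatory networks and per-TF target aggregates.

A regulatory network is an aggregated edge list: multiple experiment records
for the same (TF, target, source) pair collapse to one edge whose ``support``
is the number of distinct experiments reporting it.  Edges come in two
dialects — high-throughput binding assays (``chip``) and literature-curated
small-scale studies (``curated``) — which are never mixed within a statistic.
Edges supported by two or more independent binding experiments form the
"confirmed" network used as a false-positive control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .core import AnnotationMap, GeneTable, PPINetwork

__all__ = [
    "RegulatoryNetwork",
    "build_regulatory_network",
    "confirmed_edges",
    "load_edge_records",
    "tf_target_profiles",
    "partner_annotation_enrichment",
]


def load_edge_records(path: str | Path) -> pd.DataFrame:
    """Read raw experiment records (tf_id, target_id, experiment_id, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    ren = {"tf_id": "tf", "target_id": "target"}
    df = df.rename(columns=ren)
    required = {"tf", "target", "experiment_id", "source"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edge record file missing columns {sorted(missing)}")
    return df

EDGE_COLUMNS = ["tf", "target", "support", "source", "sign"]
VALID_SIGNS = ("A", "R", "U")  # activating / repressive / unsigned


@dataclass
class RegulatoryNetwork:
    """Aggregated directed regulatory edge list.

    ``edges`` has one row per distinct (tf, target, source) with columns
    ``tf, target, support, source, sign``; ``sign`` is 'U' until knockout-based
    sign inference has run.  ``dropped`` records edge records whose endpoints
    were outside the supplied gene universe.
    """

    edges: pd.DataFrame
    dropped: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in EDGE_COLUMNS if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table missing columns {missing}")
        bad = set(self.edges["sign"]) - set(VALID_SIGNS)
        if bad:
            raise ValueError(f"invalid edge signs {bad}")
        if len(self.edges) and (self.edges["support"] < 1).any():
            raise ValueError("edge support must be >= 1")
        dup = self.edges.duplicated(subset=["tf", "target", "source"])
        if dup.any():
            raise ValueError("duplicate (tf, target, source) edges after aggregation")

    # -- basic accessors ----------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def tfs(self) -> pd.Index:
        return pd.Index(sorted(self.edges["tf"].unique()))

    @property
    def out_degree(self) -> pd.Series:
        """Distinct-target count per TF."""
        if self.edges.empty:
            return pd.Series(dtype=int)
        return self.edges.groupby("tf")["target"].nunique().sort_index()

    @property
    def in_degree(self) -> pd.Series:
        """Distinct-regulator count per target gene."""
        if self.edges.empty:
            return pd.Series(dtype=int)
        return self.edges.groupby("target")["tf"].nunique().sort_index()

    def targets_of(self, tf: str) -> list[str]:
        return sorted(self.edges.loc[self.edges["tf"] == tf, "target"].unique())

    def select_source(self, source: str) -> "RegulatoryNetwork":
        return RegulatoryNetwork(
            self.edges[self.edges["source"] == source].reset_index(drop=True)
        )

    def with_signs(self, signs: pd.Series) -> "RegulatoryNetwork":
        """Copy with per-edge signs set from a (tf, target)-indexed Series."""
        edges = self.edges.copy()
        key = pd.MultiIndex.from_frame(edges[["tf", "target"]])
        edges["sign"] = signs.reindex(key).fillna("U").to_numpy()
        return RegulatoryNetwork(edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.tf, row.target, support=row.support,
                       source=row.source, sign=row.sign)
        return g

    # -- IO ------------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegulatoryNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str, "source": str,
                                                "sign": str})
        if "sign" not in df.columns:
            df["sign"] = "U"
        return cls(df[EDGE_COLUMNS])

    def to_tsv(self, path: str | Path) -> None:
        self.edges.sort_values(["tf", "target", "source"]).to_csv(path, sep="\t", index=False)


def build_regulatory_network(
    edge_records: pd.DataFrame | Iterable[tuple],
    universe: Sequence[str] | None = None,
) -> RegulatoryNetwork:
    """Aggregate raw (tf, target, experiment_id, source) records into a network.

    Records sharing (tf, target, source) collapse to one edge whose support is
    the number of distinct experiment ids.  When a gene ``universe`` is given,
    records with endpoints outside it are dropped with a warning and reported
    in the result's ``dropped`` table.
    """
    if not isinstance(edge_records, pd.DataFrame):
        edge_records = pd.DataFrame(
            list(edge_records), columns=["tf", "target", "experiment_id", "source"]
        )
    records = edge_records.copy()
    required = {"tf", "target", "experiment_id", "source"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"edge records missing columns {sorted(missing)}")

    dropped = None
    if universe is not None:
        uni = set(universe)
        bad = ~(records["tf"].isin(uni) & records["target"].isin(uni))
        if bad.any():
            dropped = records[bad].reset_index(drop=True)
            warnings.warn(
                f"dropping {int(bad.sum())} edge records with endpoints outside the "
                f"gene universe",
                stacklevel=2,
            )
            records = records[~bad]

    if records.empty:
        edges = pd.DataFrame(columns=EDGE_COLUMNS).astype({"support": int})
    else:
        edges = (
            records.groupby(["tf", "target", "source"], as_index=False)["experiment_id"]
            .nunique()
            .rename(columns={"experiment_id": "support"})
        )
        edges["sign"] = "U"
        edges = edges[EDGE_COLUMNS].sort_values(["tf", "target", "source"]).reset_index(drop=True)
    return RegulatoryNetwork(edges, dropped=dropped)


def confirmed_edges(net: RegulatoryNetwork, min_support: int = 2) -> RegulatoryNetwork:
    """Keep edges reported by at least ``min_support`` independent experiments."""
    keep = net.edges["support"] >= min_support
    return RegulatoryNetwork(net.edges[keep].reset_index(drop=True))


def tf_target_profiles(
    net: RegulatoryNetwork,
    genes: GeneTable,
    min_targets: int = 3,
    comparison: str = "par",
    min_targets_missing: int = 3,
) -> pd.DataFrame:
    """Per-TF aggregates over distinct target genes.

    Emits one row per TF with at least ``min_targets`` distinct targets found
    in the gene table: the median assigned Ka/Ks of targets (genes lacking an
    ortholog enter at their assigned top value), the fraction of targets
    missing an ortholog in ``comparison`` (only when the TF has at least
    ``min_targets_missing`` targets, since ortholog loss affects only ~10% of
    genes), the fraction of targets in the genome-wide top 20% by conservation
    (Ka/Ks rank <= 0.2), interaction-partner count and expression (rank >=
    0.8), the median target expression, and the TF's regulatory in-degree.
    """
    df = genes.df
    if "assigned_ka_ks" not in df.columns:
        raise ValueError("gene table lacks 'assigned_ka_ks'; run assign_missing_ortholog_rate first")
    has_ortho = genes.has_ortholog(comparison)
    in_deg = net.in_degree

    rank_cols = {
        "conserved": "rank_assigned_ka_ks",
        "interactive": "rank_ppi_degree",
        "expressed": "rank_expression",
    }

    rows = []
    for tf in net.tfs:
        targets = [t for t in net.targets_of(tf) if t in df.index]
        n = len(targets)
        if n < min_targets:
            continue
        sub = df.loc[targets]
        row = {
            "tf_id": tf,
            "n_targets": n,
            "median_target_ka_ks": float(sub["assigned_ka_ks"].median()),
            "median_target_expression": float(sub["expression"].median())
            if "expression" in sub.columns and sub["expression"].notna().any()
            else np.nan,
            "in_degree": int(in_deg.get(tf, 0)),
        }
        if n >= min_targets_missing:
            row["fraction_targets_missing"] = float((~has_ortho.loc[targets]).mean())
        else:
            row["fraction_targets_missing"] = np.nan
        for name, col in rank_cols.items():
            key = f"fraction_targets_top20_{name}"
            if col in sub.columns and sub[col].notna().any():
                r = sub[col].dropna()
                if name == "conserved":
                    row[key] = float((r <= 0.2).mean())
                else:
                    row[key] = float((r >= 0.8).mean())
            else:
                row[key] = np.nan
        rows.append(row)

    cols = [
        "tf_id", "n_targets", "median_target_ka_ks", "fraction_targets_missing",
        "fraction_targets_top20_conserved", "fraction_targets_top20_interactive",
        "fraction_targets_top20_expressed", "median_target_expression", "in_degree",
    ]
    out = pd.DataFrame(rows, columns=cols)
    return out.set_index("tf_id")


def partner_annotation_enrichment(
    ppi: PPINetwork,
    subset: set[str] | Sequence[str],
    ann: AnnotationMap,
    term: str,
) -> tuple[float, float]:
    """Enrichment of an annotation among the PPI partners of a gene subset.

    Every edge contributes two directed incidences (protein, partner).  The
    2x2 table crosses "protein in subset" with "partner annotated with term";
    fold is the ratio of annotated-partner fractions in vs out of the subset
    and p comes from a 1-df chi-square test without continuity correction
    (counts are large in realistic use; a warning is issued when any expected
    count falls below 5).
    """
    subset = set(subset)
    if not subset:
        raise ValueError("empty subset")
    if term not in ann.terms:
        raise ValueError(f"term {term!r} not present in the annotation map")
    term_genes = ann.genes_in(term)

    counts = np.zeros((2, 2), dtype=int)  # rows: subset yes/no; cols: partner in term yes/no
    for a, b in ppi.graph.edges():
        for protein, partner in ((a, b), (b, a)):
            i = 0 if protein in subset else 1
            j = 0 if partner in term_genes else 1
            counts[i, j] += 1
    if counts[0].sum() == 0:
        raise ValueError("subset has no PPI incidences")
    if counts[:, 0].sum() == 0:
        raise ValueError(f"term {term!r} annotates zero PPI partners")

    frac_in = counts[0, 0] / counts[0].sum()
    frac_out = counts[1, 0] / counts[1].sum()
    if frac_out == 0:
        raise ValueError("term annotates no partners outside the subset; fold undefined")
    fold = frac_in / frac_out

    expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
    if (expected < 5).any():
        warnings.warn("chi-square 2x2 table has an expected count below 5", stacklevel=2)
    if frac_in == frac_out:
        return fold, 1.0
    stat, p, _, _ = chi2_contingency(counts, correction=False)
    return float(fold), float(p)
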
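"""Knockout-based inference of activating vs repressive regulatory edges.

A TF-knockout experiment reports, per target gene, an X score: a
confidence-weighted log expression ratio of the knockout strain versus wild
type.  If deleting a TF lowers a bound target's expression (X well below
zero) the TF was activating it; if expression rises (X well above zero) the
TF was repressing it.  Scores of small magnitude, or bound targets with no
knockout measurement, leave the edge unsigned.  The ratio orientation
(knockout/wild-type vs the reverse) is a convention of the source assay and
is therefore a flag rather than a hard-coded assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .networks import RegulatoryNetwork

__all__ = ["KnockoutMatrix", "assign_edge_signs", "split_by_sign"]


@dataclass
class KnockoutMatrix:
    """X scores indexed by (target gene row, knocked-out TF column); NaN = missing."""

    x: pd.DataFrame

    def __post_init__(self) -> None:
        self.x = self.x.astype(float)
        if self.x.index.has_duplicates or self.x.columns.has_duplicates:
            raise ValueError("duplicate gene or TF identifiers in knockout matrix")

    @property
    def tfs(self) -> pd.Index:
        """TFs with knockout data (coverage)."""
        return self.x.columns

    def get(self, tf: str, target: str) -> float:
        if tf not in self.x.columns or target not in self.x.index:
            return float("nan")
        return float(self.x.at[target, tf])

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, float]],
        combine: Literal["max_abs", "mean"] = "max_abs",
    ) -> "KnockoutMatrix":
        """Build from (tf, target, x) triples; replicate scores for one pair are
        combined by the most confident call (largest |X|) by default."""
        df = pd.DataFrame(list(records), columns=["tf", "target", "x"])
        if combine == "max_abs":
            df = df.loc[df.groupby(["tf", "target"])["x"].transform(
                lambda s: s.abs() == s.abs().max()
            )]
            df = df.drop_duplicates(subset=["tf", "target"], keep="first")
        elif combine == "mean":
            df = df.groupby(["tf", "target"], as_index=False)["x"].mean()
        else:
            raise ValueError(f"unknown combine rule {combine!r}")
        wide = df.pivot(index="target", columns="tf", values="x")
        return cls(wide.sort_index().sort_index(axis=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnockoutMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.x.to_csv(path, sep="\t", index=True, index_label="gene_id")


def assign_edge_signs(
    net: RegulatoryNetwork,
    ko: KnockoutMatrix,
    threshold: float = 1.0,
    orientation: Literal["ko_over_wt", "wt_over_ko"] = "ko_over_wt",
) -> RegulatoryNetwork:
    """Sign edges whose knockout X score magnitude strictly exceeds the threshold.

    With the knockout/wild-type orientation, X < -threshold means the target
    dropped when its TF was removed (activating edge, 'A') and X > +threshold
    means it rose (repressive, 'R').  |X| <= threshold, or a TF absent from
    the knockout data, leaves the edge unsigned ('U').  Unsigned edges are
    retained; the operation is idempotent and order-independent.
    """
    edges = net.edges.copy()
    if edges.empty:
        return RegulatoryNetwork(edges)
    xs = np.full(len(edges), np.nan)
    cols = ko.x.columns
    idx = ko.x.index
    tf_pos = edges["tf"].map({t: i for i, t in enumerate(cols)})
    tg_pos = edges["target"].map({g: i for i, g in enumerate(idx)})
    have = tf_pos.notna() & tg_pos.notna()
    mat = ko.x.to_numpy()
    xs[have.to_numpy()] = mat[
        tg_pos[have].astype(int).to_numpy(), tf_pos[have].astype(int).to_numpy()
    ]
    if orientation == "wt_over_ko":
        xs = -xs
    elif orientation != "ko_over_wt":
        raise ValueError(f"unknown orientation {orientation!r}")
    sign = np.where(xs < -threshold, "A", np.where(xs > threshold, "R", "U"))
    edges["sign"] = sign
    return RegulatoryNetwork(edges)


def split_by_sign(
    net: RegulatoryNetwork,
) -> tuple[RegulatoryNetwork, RegulatoryNetwork]:
    """Partition signed edges into (activating, repressive) subnetworks.

    Unsigned edges belong to neither; counts are conserved:
    ``|A| + |R| + |U| == |edges|``.
    """
    act = net.edges[net.edges["sign"] == "A"].reset_index(drop=True)
    rep = net.edges[net.edges["sign"] == "R"].reset_index(drop=True)
    return RegulatoryNetwork(act), RegulatoryNetwork(rep)
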
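"""Correlation, enrichment and spread statistics relating TF and target properties.

Covers: Spearman correlations between gene-level and network-level
properties for the TF set and the all-protein set; the sign-stratified
co-evolution table (TF rate vs the evolutionary properties of activated and
repressed targets separately); a co-regulation spread test comparing the
pairwise closeness of a TF's targets to in-degree-matched random "target"
sets; term enrichment of fast-TF targets by Fisher's exact test; and
equal-count binned-median profiles with bootstrap standard errors for
plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AnnotationMap, GeneTable, PPINetwork
from .networks import RegulatoryNetwork, tf_target_profiles

__all__ = [
    "CorrelationResult",
    "SpreadTestResult",
    "spearman",
    "tf_target_correlation_panel",
    "sign_stratified_correlations",
    "coregulation_spread_test",
    "target_set_enrichment",
    "fast_slow_target_sets",
    "binned_median_profile",
]


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    x_label: str = ""
    y_label: str = ""

    def to_dict(self) -> dict:
        return {"rho": self.rho, "p": self.p, "n": self.n,
                "x_label": self.x_label, "y_label": self.y_label}


def spearman(
    x: Mapping[str, float] | pd.Series | Sequence[float],
    y: Mapping[str, float] | pd.Series | Sequence[float],
    x_label: str = "",
    y_label: str = "",
) -> CorrelationResult:
    """Spearman's rank correlation on complete pairs (midranks for ties)."""
    if isinstance(x, (pd.Series, Mapping)) and isinstance(y, (pd.Series, Mapping)):
        xs = pd.Series(x, dtype=float)
        ys = pd.Series(y, dtype=float)
        common = xs.index.intersection(ys.index)
        xs, ys = xs[common], ys[common]
    else:
        xs = pd.Series(np.asarray(x, dtype=float))
        ys = pd.Series(np.asarray(y, dtype=float))
    keep = xs.notna() & ys.notna()
    xs, ys = xs[keep], ys[keep]
    if len(xs) < 3:
        raise ValueError("spearman requires at least 3 complete pairs")
    if xs.nunique() < 2 or ys.nunique() < 2:
        raise ValueError("zero variance in one of the inputs")
    rho, p = sps.spearmanr(xs, ys)
    return CorrelationResult(float(rho), float(p), int(len(xs)), x_label, y_label)


def _safe_spearman(x: pd.Series, y: pd.Series, xl: str, yl: str, set_name: str) -> dict:
    """One tidy panel row; correlates with <3 complete pairs are emitted as absent."""
    try:
        r = spearman(x, y, xl, yl)
        return {"set": set_name, "x_label": xl, "y_label": yl, "rho": r.rho,
                "abs_rho": abs(r.rho), "p": r.p, "n": r.n}
    except ValueError:
        n = int((pd.Series(x, dtype=float).notna()
                 & pd.Series(y, dtype=float).reindex(pd.Series(x).index).notna()).sum())
        return {"set": set_name, "x_label": xl, "y_label": yl, "rho": np.nan,
                "abs_rho": np.nan, "p": np.nan, "n": n}


def tf_target_correlation_panel(
    profiles: pd.DataFrame,
    genes: GeneTable,
    ppi: PPINetwork | None = None,
    net: RegulatoryNetwork | None = None,
) -> pd.DataFrame:
    """Spearman panel of Ka/Ks correlates for the TF set and the all-protein set.

    For both sets the same correlate list is evaluated: expression, CAI, PPI
    degree, regulatory in-degree, median interactor Ka/Ks, median regulator
    Ka/Ks, and — defined only for profiled TFs, hence absent rows for
    non-TF-only strata — median target Ka/Ks, fraction of targets missing an
    ortholog, plus TF-vs-target cross-correlations.
    """
    df = genes.df
    ka = df["assigned_ka_ks"]
    feats = pd.DataFrame(index=df.index)
    feats["expression"] = df.get("expression")
    feats["cai"] = df.get("cai")
    if ppi is not None:
        feats["ppi_degree"] = ppi.degree.reindex(df.index)
        feats["median_interactor_ka_ks"] = ppi.median_neighbor_value(ka).reindex(df.index)
    if net is not None:
        feats["in_degree"] = net.in_degree.reindex(df.index)
        # median assigned Ka/Ks of the TFs regulating each gene
        e = net.edges.copy()
        e["tf_ka"] = e["tf"].map(ka)
        feats["median_regulator_ka_ks"] = e.groupby("target")["tf_ka"].median().reindex(df.index)
    for col in ("median_target_ka_ks", "fraction_targets_missing",
                "median_target_expression"):
        if col in profiles.columns:
            feats[col] = profiles[col].reindex(df.index)

    sets = {"tf": df["is_tf"].to_numpy(), "all": np.ones(len(df), dtype=bool)}
    rows = []
    for set_name, mask in sets.items():
        sub_ka = ka[mask]
        for col in feats.columns:
            rows.append(_safe_spearman(sub_ka, feats.loc[mask, col],
                                       "assigned_ka_ks", col, set_name))
        # cross-correlations between TF-level and aggregated target properties
        if "median_target_expression" in feats.columns:
            rows.append(_safe_spearman(feats.loc[mask, "expression"],
                                       feats.loc[mask, "median_target_expression"],
                                       "expression", "median_target_expression", set_name))
        if "fraction_targets_missing" in feats.columns and "in_degree" in feats.columns:
            rows.append(_safe_spearman(feats.loc[mask, "in_degree"],
                                       feats.loc[mask, "fraction_targets_missing"],
                                       "in_degree", "fraction_targets_missing", set_name))
    return pd.DataFrame(rows)


def sign_stratified_correlations(
    net: RegulatoryNetwork,
    genes: GeneTable,
    min_same_sign_targets: int = 5,
    comparison: str = "par",
) -> pd.DataFrame:
    """TF Ka/Ks vs activated- and repressed-target evolutionary properties.

    A TF enters the activated (repressed) stratum only with at least
    ``min_same_sign_targets`` targets of that sign, making the correlations
    robust to sign-inference uncertainty.  Returns a tidy table with one row
    per (sign, property): median target Ka/Ks and fraction of targets missing
    an ortholog in the comparison species.
    """
    df = genes.df
    if "assigned_ka_ks" not in df.columns:
        raise ValueError("gene table lacks 'assigned_ka_ks'")
    rows = []
    for sign, label in (("A", "activated"), ("R", "repressed")):
        sub = RegulatoryNetwork(
            net.edges[net.edges["sign"] == sign].reset_index(drop=True)
        )
        prof = tf_target_profiles(sub, genes, min_targets=min_same_sign_targets,
                                  comparison=comparison,
                                  min_targets_missing=min_same_sign_targets)
        if prof.empty:
            continue
        tf_ka = df["assigned_ka_ks"].reindex(prof.index)
        for prop in ("median_target_ka_ks", "fraction_targets_missing"):
            row = _safe_spearman(tf_ka, prof[prop], "tf_ka_ks", prop, label)
            row["sign"] = label
            row["n_tfs"] = len(prof)
            rows.append(row)
    cols = ["sign", "x_label", "y_label", "rho", "abs_rho", "p", "n", "n_tfs"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# co-regulation spread
# ---------------------------------------------------------------------------

@dataclass
class SpreadTestResult:
    """Observed vs expected median pairwise differences of co-regulated genes."""

    per_tf: pd.DataFrame  # columns: n_targets, observed, expected
    n_null_sets: int
    p: float
    alternative: str

    def to_dict(self) -> dict:
        return {
            "n_tfs": int(len(self.per_tf)),
            "n_null_sets": self.n_null_sets,
            "p": self.p,
            "alternative": self.alternative,
            "median_observed": float(self.per_tf["observed"].median()),
            "median_expected": float(self.per_tf["expected"].median()),
        }


def degree_weighted_sample(
    n_pool: int, size: int, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a weighted sample without replacement (probability ∝ weights)."""
    return rng.choice(n_pool, size=size, replace=False, p=weights)


def _median_pairwise_diff(v: np.ndarray) -> float:
    d = np.abs(v[:, None] - v[None, :])
    iu = np.triu_indices(len(v), k=1)
    return float(np.median(d[iu]))


def coregulation_spread_test(
    net: RegulatoryNetwork,
    values: Mapping[str, float] | pd.Series,
    n_null: int = 100,
    rng: np.random.Generator | int | None = None,
    min_targets: int = 3,
    alternative: str = "two-sided",
    test: str = "ranksums",
) -> SpreadTestResult:
    """Are a TF's targets closer in ``values`` than in-degree-matched random sets?

    For each TF with at least ``min_targets`` targets carrying a value
    (ortholog-bearing genes, for Ka/Ks), the observed statistic is the median
    absolute difference over all unordered target pairs.  The expected
    statistic is the mean of the same median over ``n_null`` equally sized
    random "target" sets drawn without replacement with selection probability
    proportional to regulatory in-degree (genes that are regulated more are
    more likely to appear in any target list, so a uniform null would be
    biased).  Significance is a Wilcoxon rank-sum test across the per-TF
    observed and expected distributions.
    """
    rng = np.random.default_rng(rng)
    values = pd.Series(values, dtype=float).dropna()
    in_deg = net.in_degree
    pool = values.index.intersection(in_deg.index[in_deg > 0]).sort_values()
    if len(pool) == 0:
        raise ValueError("no genes with both a value and a positive in-degree")
    pool_vals = values[pool].to_numpy()
    weights = in_deg[pool].to_numpy(dtype=float)
    weights = weights / weights.sum()

    rows = []
    for tf in net.tfs:
        targ_vals = values.reindex(net.targets_of(tf)).dropna()
        m = len(targ_vals)
        if m < min_targets:
            continue
        observed = _median_pairwise_diff(targ_vals.to_numpy())
        null_medians = np.empty(n_null)
        for b in range(n_null):
            pick = degree_weighted_sample(len(pool), m, weights, rng)
            null_medians[b] = _median_pairwise_diff(pool_vals[pick])
        rows.append({"tf_id": tf, "n_targets": m, "observed": observed,
                     "expected": float(null_medians.mean())})
    if not rows:
        raise ValueError("no TFs qualify for the spread test")
    per_tf = pd.DataFrame(rows).set_index("tf_id")
    if test == "ranksums":
        stat, p = sps.ranksums(per_tf["observed"], per_tf["expected"],
                               alternative=alternative)
    elif test == "signed_rank":
        # paired alternative: the per-TF observed/expected values are natural pairs
        diff = per_tf["observed"] - per_tf["expected"]
        if np.allclose(diff, 0.0):
            p = 1.0
        else:
            _, p = sps.wilcoxon(diff, alternative=alternative)
    else:
        raise ValueError(f"unknown test {test!r}")
    return SpreadTestResult(per_tf, n_null, float(p), alternative)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def fast_slow_target_sets(
    net: RegulatoryNetwork,
    tf_rates: Mapping[str, float] | pd.Series,
    fast_fraction: float = 0.25,
    precedence: str = "fast",
) -> tuple[set[str], set[str]]:
    """Split distinct targets by whether a top-``fast_fraction`` TF regulates them.

    TFs (restricted to those with targets in the network) are ranked by rate;
    quartile-boundary ties break deterministically by gene id.  Genes targeted
    by both fast and slow TFs go to the fast set by default ('fast'
    precedence) or are dropped from both ('exclusive').
    """
    rates = pd.Series(tf_rates, dtype=float).dropna()
    with_targets = rates.index.intersection(net.tfs)
    if len(with_targets) == 0:
        raise ValueError("no TFs with both a rate and targets")
    r = rates[with_targets]
    # descending by rate; ties broken deterministically by gene id
    order = r.iloc[np.lexsort((r.index.to_numpy(), -r.to_numpy()))]
    n_fast = max(1, int(round(fast_fraction * len(order))))
    fast_tfs = set(order.index[:n_fast])
    slow_tfs = set(order.index[n_fast:])
    fast_targets = {t for tf in fast_tfs for t in net.targets_of(tf)}
    slow_targets = {t for tf in slow_tfs for t in net.targets_of(tf)}
    if precedence == "fast":
        slow_targets -= fast_targets
    elif precedence == "exclusive":
        both = fast_targets & slow_targets
        fast_targets -= both
        slow_targets -= both
    else:
        raise ValueError(f"unknown precedence rule {precedence!r}")
    return fast_targets, slow_targets


def target_set_enrichment(
    fast_targets: set[str],
    other_targets: set[str],
    ann: AnnotationMap,
    min_term_size: int = 50,
) -> pd.DataFrame:
    """Fisher-exact term enrichment in fast-TF targets versus other targets.

    Terms must annotate at least ``min_term_size`` genes among the union of
    the two (disjoint) target sets.  The test is one-sided for enrichment;
    fold is the ratio of within-set annotated fractions.  All qualifying rows
    are emitted, with ``significant`` flagging raw p < 0.05 (no
    multiple-testing correction; raw p-values are reported by convention
    here).
    """
    fast_targets, other_targets = set(fast_targets), set(other_targets)
    if not fast_targets or not other_targets:
        raise ValueError("both target sets must be non-empty")
    if fast_targets & other_targets:
        raise ValueError("target sets must be disjoint; resolve overlaps first")
    union = fast_targets | other_targets
    n_fast, n_other = len(fast_targets), len(other_targets)
    rows = []
    for term in sorted(ann.terms):
        members = ann.genes_in(term) & union
        if len(members) < min_term_size:
            continue
        a = len(members & fast_targets)
        c = len(members) - a
        table = [[a, n_fast - a], [c, n_other - c]]
        _, p = sps.fisher_exact(table, alternative="greater")
        frac_fast = a / n_fast
        frac_other = c / n_other
        fold = frac_fast / frac_other if frac_other > 0 else np.inf
        rows.append({"term_id": term, "n_genes": len(members), "fold": fold,
                     "p": float(p), "significant": p < 0.05})
    cols = ["term_id", "n_genes", "fold", "p", "significant"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols].sort_values("p", kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# binned-median profiles
# ---------------------------------------------------------------------------

def binned_median_profile(
    x: Mapping[str, float] | pd.Series | Sequence[float],
    y: Mapping[str, float] | pd.Series | Sequence[float],
    n_bins: int,
    n_boot: int = 100,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Equal-count bins on x with median y, bootstrap SE of the median, and counts.

    The median (robust to outliers and to the value assigned to
    missing-ortholog genes) is reported per bin with a standard error
    estimated from ``n_boot`` bootstrap resamples of the bin members.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    rng = np.random.default_rng(rng)
    xs = pd.Series(x, dtype=float)
    ys = pd.Series(y, dtype=float)
    if not xs.index.equals(ys.index):
        common = xs.index.intersection(ys.index)
        xs, ys = xs[common], ys[common]
    keep = xs.notna() & ys.notna()
    xs, ys = xs[keep], ys[keep]
    if len(xs) < n_bins:
        raise ValueError("fewer points than bins")
    order = np.lexsort((xs.index.to_numpy(), xs.to_numpy()))
    splits = np.array_split(order, n_bins)
    rows = []
    for i, pos in enumerate(splits):
        bin_x = xs.to_numpy()[pos]
        bin_y = ys.to_numpy()[pos]
        med = float(np.median(bin_y))
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = np.median(rng.choice(bin_y, size=len(bin_y), replace=True))
        se = float(boots.std(ddof=1)) if len(bin_y) > 1 else 0.0
        rows.append({
            "bin": i,
            "label": f"[{bin_x.min():.3g}, {bin_x.max():.3g}]",
            "median_y": med,
            "bootstrap_se": se,
            "count": len(pos),
        })
    return pd.DataFrame(rows)
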
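"""End-to-end analysis orchestration with a machine-readable report.

``run_full_analysis`` wires the stages together: load (or synthesize) the
input tables, apply the missing-ortholog rate convention and genome-wide
rank normalization, build the binding-assay and confirmed networks, run
the subset-slope tests for the TF set against each rate correlate (plus
CAI-substituted controls and confirmed-edge variants), infer edge signs
from knockout data, compute the TF-target correlation panel and the
sign-stratified table, the co-regulation spread test, the two-species
divergence test and the target-set term enrichment, and write tidy TSV
outputs, binned-median profile figures and a validated JSON report.

Stages whose inputs are absent are skipped with a recorded reason.  All
randomness is derived from one master seed: each stage hashes
(master_seed, stage_name) into its own substream, so adding a stage never
perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import divergence as dv
from . import networks as nw
from . import signs as sg
from . import slope as sl
from . import stats as st
from .core import AnnotationMap, GeneTable, PPINetwork, assign_missing_ortholog_rate, rank_transform
from .synth import GeneratorConfig, SyntheticBundle, generate_bundle

__all__ = ["AnalysisReport", "run_full_analysis", "DEFAULT_ANALYSIS"]

DEFAULT_ANALYSIS: dict[str, Any] = {
    "seed": 0,
    "n_samples": 10_000,
    "tolerance": 0.01,
    "method": "swap",
    "direction": "auto",
    "missing_multiplier": 1.1,
    "min_targets": 3,
    "min_targets_confirmed": 2,
    "min_same_sign_targets": 5,
    "xscore_threshold": 1.0,
    "spread_n_null": 100,
    "fast_fraction": 0.25,
    "min_term_size": 50,
    "n_bins": 6,
    "comparison": "par",
}


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------

class SlopeTestReport(BaseModel):
    name: str
    dialect: str
    x_label: str
    y_label: str
    observed_slope: float
    p_value: float
    p_is_bound: bool
    direction: str
    n_samples: int
    tolerance: float
    null_slope_mean: float
    null_slope_sd: float
    subset_size: int
    universe_size: int


class CorrelationRow(BaseModel):
    set: str
    x_label: str
    y_label: str
    rho: float | None = None
    p: float | None = None
    n: int


class SignStratifiedRow(BaseModel):
    sign: str
    y_label: str
    rho: float | None = None
    p: float | None = None
    n_tfs: int


class SpreadReport(BaseModel):
    values: str
    n_tfs: int
    n_null_sets: int
    p: float
    alternative: str
    median_observed: float
    median_expected: float


class DivergenceReport(BaseModel):
    t: float
    p: float
    mean_fast: float
    mean_slow: float
    n_fast: int
    n_slow: int


class EnrichmentReportRow(BaseModel):
    term_id: str
    n_genes: int
    fold: float | None = None  # None when the comparison fraction is zero
    p: float
    significant: bool


class StageStatus(BaseModel):
    name: str
    status: str  # "ok" | "skipped"
    reason: str = ""


class SignedEdgeCounts(BaseModel):
    activating: int
    repressive: int
    unsigned: int


class AnalysisReport(BaseModel):
    """Validated, machine-readable record of one full analysis run."""

    version: str = "1"
    seed: int
    config_hash: str
    dialect_thresholds: dict[str, int]
    stages: list[StageStatus] = Field(default_factory=list)
    slope_tests: list[SlopeTestReport] = Field(default_factory=list)
    correlation_panel: list[CorrelationRow] = Field(default_factory=list)
    sign_stratified: list[SignStratifiedRow] = Field(default_factory=list)
    signed_edge_counts: SignedEdgeCounts | None = None
    spread: list[SpreadReport] = Field(default_factory=list)
    divergence: DivergenceReport | None = None
    enrichment: list[EnrichmentReportRow] = Field(default_factory=list)
    provenance: dict[str, str] = Field(default_factory=dict)


def _stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _nan_to_none(v: float) -> float | None:
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)


# ---------------------------------------------------------------------------
# input handling
# ---------------------------------------------------------------------------

@dataclass
class _Inputs:
    genes: GeneTable
    edge_records: pd.DataFrame | None
    ppi: pd.DataFrame | None  # tidy edge list (gene_a, gene_b, n_reports)
    knockout: sg.KnockoutMatrix | None
    counts: pd.DataFrame | None
    annotations: AnnotationMap | None
    digests: dict[str, str]


def _load_inputs(config: Mapping) -> _Inputs:
    if "synthetic" in config:
        syn = config["synthetic"]
        gcfg = GeneratorConfig.from_mapping(syn.get("generator", {}))
        bundle: SyntheticBundle = generate_bundle(gcfg, seed=int(syn.get("seed", 0)))
        return _Inputs(
            genes=bundle.genes,
            edge_records=bundle.edge_records,
            ppi=bundle.ppi_edges,
            knockout=bundle.knockout,
            counts=bundle.counts,
            annotations=bundle.annotations,
            digests={"synthetic_seed": str(bundle.seed)},
        )
    paths = config.get("inputs", {})
    if "genes" not in paths:
        raise ValueError("config must provide either a 'synthetic' block or inputs.genes")
    digests = {}
    for key, p in paths.items():
        if p and Path(p).exists():
            digests[key] = hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]

    def maybe(key, loader):
        return loader(paths[key]) if paths.get(key) and Path(paths[key]).exists() else None

    return _Inputs(
        genes=GeneTable.from_tsv(paths["genes"]),
        edge_records=maybe("edges", nw.load_edge_records),
        ppi=maybe("ppi", lambda p: pd.read_csv(p, sep="\t", dtype={"gene_a": str, "gene_b": str})),
        knockout=maybe("knockout", sg.KnockoutMatrix.from_tsv),
        counts=maybe("counts", lambda p: pd.read_csv(p, sep="\t", dtype={"gene_id_a": str, "gene_id_b": str})),
        annotations=maybe("annotations", AnnotationMap.from_tsv),
        digests=digests,
    )


# ---------------------------------------------------------------------------
# main driver
# ---------------------------------------------------------------------------

def run_full_analysis(
    config: Mapping | str | Path,
    outdir: str | Path,
    make_figures: bool = True,
) -> AnalysisReport:
    """Run every applicable stage and write outputs under ``outdir``.

    ``config`` is a mapping (or a YAML file path) with an optional
    ``synthetic`` block (generator seed and parameter overrides), an
    optional ``inputs`` block of file paths, and an optional ``analysis``
    block overriding :data:`DEFAULT_ANALYSIS`.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    config = dict(config)
    ana = {**DEFAULT_ANALYSIS, **config.get("analysis", {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(ana["seed"])
    comparison = ana["comparison"]

    inputs = _load_inputs(config)
    report = AnalysisReport(
        seed=seed,
        config_hash=_config_hash(config),
        dialect_thresholds={
            "chip_min_targets": ana["min_targets"],
            "confirmed_min_targets": ana["min_targets_confirmed"],
            "confirmed_min_support": 2,
            "min_same_sign_targets": ana["min_same_sign_targets"],
        },
        provenance={"inputs": json.dumps(inputs.digests, sort_keys=True)},
    )
    stages = report.stages

    # ---- preparation ------------------------------------------------------
    genes = assign_missing_ortholog_rate(
        inputs.genes, comparison=comparison, multiplier=ana["missing_multiplier"]
    )
    ppi = (
        PPINetwork.from_edges(
            zip(inputs.ppi["gene_a"], inputs.ppi["gene_b"], inputs.ppi["n_reports"].astype(int))
        )
        if inputs.ppi is not None and len(inputs.ppi)
        else None
    )
    chip_net = conf_net = None
    if inputs.edge_records is not None and len(inputs.edge_records):
        net_all = nw.build_regulatory_network(inputs.edge_records, universe=genes.genes)
        chip_net = net_all.select_source("chip")
        conf_net = nw.confirmed_edges(chip_net, min_support=2)

    df = genes.df
    if ppi is not None:
        df["ppi_degree"] = ppi.degree.reindex(df.index)
        df["median_interactor_ka_ks"] = ppi.median_neighbor_value(
            df["assigned_ka_ks"]
        ).reindex(df.index)
    if chip_net is not None:
        df["in_degree"] = chip_net.in_degree.reindex(df.index).fillna(0).astype(int)
        df["in_degree_confirmed"] = conf_net.in_degree.reindex(df.index).fillna(0).astype(int)
    rank_props = ["assigned_ka_ks", "expression", "cai"] + [
        c for c in ("ppi_degree", "in_degree", "in_degree_confirmed", "median_interactor_ka_ks")
        if c in df.columns
    ]
    genes = genes.with_ranks(rank_props)
    df = genes.df
    tf_subset = set(genes.tf_ids)
    stages.append(StageStatus(name="prepare", status="ok"))

    # ---- subset-slope tests ----------------------------------------------
    slope_specs = [
        ("ka_vs_ppi_degree", "chip", "rank_ppi_degree", "rank_assigned_ka_ks"),
        ("ka_vs_in_degree", "chip", "rank_in_degree", "rank_assigned_ka_ks"),
        ("ka_vs_expression", "chip", "rank_expression", "rank_assigned_ka_ks"),
        ("ka_vs_cai", "chip", "rank_cai", "rank_assigned_ka_ks"),
        ("ka_vs_interactor_ka", "chip", "rank_median_interactor_ka_ks", "rank_assigned_ka_ks"),
        # CAI-substituted controls for the degree trends
        ("cai_vs_ppi_degree", "control", "rank_ppi_degree", "rank_cai"),
        ("cai_vs_in_degree", "control", "rank_in_degree", "rank_cai"),
        # confirmed-edge variant
        ("ka_vs_in_degree_ce", "confirmed", "rank_in_degree_confirmed", "rank_assigned_ka_ks"),
    ]
    for name, dialect, xcol, ycol in slope_specs:
        if xcol not in df.columns or ycol not in df.columns:
            stages.append(StageStatus(name=f"slope:{name}", status="skipped",
                                      reason=f"missing property {xcol}"))
            continue
        x = df[xcol].dropna()
        y = df[ycol].dropna()
        universe = x.index.intersection(y.index)
        subset = tf_subset & set(universe)
        if len(subset) < 3 or len(universe) <= len(subset):
            stages.append(StageStatus(name=f"slope:{name}", status="skipped",
                                      reason="subset or universe too small"))
            continue
        res = sl.slope_pvalue(
            x, y, subset,
            n_samples=int(ana["n_samples"]), tolerance=float(ana["tolerance"]),
            rng=_stage_seed(seed, f"slope:{name}"), method=ana["method"],
            direction=ana["direction"], x_label=xcol, y_label=ycol,
        )
        report.slope_tests.append(SlopeTestReport(
            name=name, dialect=dialect, x_label=xcol, y_label=ycol,
            observed_slope=res.observed_slope, p_value=res.p_value,
            p_is_bound=res.p_is_bound, direction=res.direction,
            n_samples=res.n_samples, tolerance=res.tolerance,
            null_slope_mean=float(res.null_slopes.mean()),
            null_slope_sd=float(res.null_slopes.std(ddof=1)),
            subset_size=len(subset), universe_size=len(universe),
        ))
        stages.append(StageStatus(name=f"slope:{name}", status="ok"))

    # ---- sign inference ---------------------------------------------------
    signed_net = None
    if chip_net is not None and inputs.knockout is not None:
        signed_net = sg.assign_edge_signs(
            chip_net, inputs.knockout, threshold=float(ana["xscore_threshold"])
        )
        act, rep = sg.split_by_sign(signed_net)
        report.signed_edge_counts = SignedEdgeCounts(
            activating=act.n_edges, repressive=rep.n_edges,
            unsigned=signed_net.n_edges - act.n_edges - rep.n_edges,
        )
        signed_net.to_tsv(outdir / "signed_edges.tsv")
        stages.append(StageStatus(name="sign_inference", status="ok"))
    else:
        stages.append(StageStatus(name="sign_inference", status="skipped",
                                  reason="no knockout data" if chip_net is not None
                                  else "no regulatory network"))

    # ---- profiles and correlation panel ----------------------------------
    profiles = None
    if chip_net is not None:
        profiles = nw.tf_target_profiles(
            chip_net, genes, min_targets=int(ana["min_targets"]), comparison=comparison
        )
        profiles.to_csv(outdir / "profiles_chip.tsv", sep="\t")
        prof_ce = nw.tf_target_profiles(
            conf_net, genes, min_targets=int(ana["min_targets_confirmed"]),
            comparison=comparison,
        )
        prof_ce.to_csv(outdir / "profiles_confirmed.tsv", sep="\t")
        panel = st.tf_target_correlation_panel(profiles, genes, ppi=ppi, net=chip_net)
        panel.to_csv(outdir / "correlation_panel.tsv", sep="\t", index=False)
        for row in panel.itertuples(index=False):
            report.correlation_panel.append(CorrelationRow(
                set=row.set, x_label=row.x_label, y_label=row.y_label,
                rho=_nan_to_none(row.rho), p=_nan_to_none(row.p), n=int(row.n),
            ))
        stages.append(StageStatus(name="correlation_panel", status="ok"))
    else:
        stages.append(StageStatus(name="correlation_panel", status="skipped",
                                  reason="no regulatory network"))

    # ---- sign-stratified table -------------------------------------------
    if signed_net is not None:
        strat = st.sign_stratified_correlations(
            signed_net, genes, min_same_sign_targets=int(ana["min_same_sign_targets"]),
            comparison=comparison,
        )
        strat.to_csv(outdir / "sign_stratified.tsv", sep="\t", index=False)
        for row in strat.itertuples(index=False):
            report.sign_stratified.append(SignStratifiedRow(
                sign=row.sign, y_label=row.y_label,
                rho=_nan_to_none(row.rho), p=_nan_to_none(row.p), n_tfs=int(row.n_tfs),
            ))
        stages.append(StageStatus(name="sign_stratified", status="ok"))
    else:
        stages.append(StageStatus(name="sign_stratified", status="skipped",
                                  reason="no knockout data"))

    # ---- co-regulation spread test ---------------------------------------
    if conf_net is not None and conf_net.n_edges:
        has = genes.has_ortholog(comparison)
        spread_inputs = {
            "ka_ks": df.loc[has, "ka_ks"],
            "log2_expression": np.log2(df.loc[has, "expression"].clip(lower=1e-9)),
        }
        for label, values in spread_inputs.items():
            try:
                res = st.coregulation_spread_test(
                    conf_net, values, n_null=int(ana["spread_n_null"]),
                    rng=_stage_seed(seed, f"spread:{label}"),
                )
            except ValueError as exc:
                stages.append(StageStatus(name=f"spread:{label}", status="skipped",
                                          reason=str(exc)))
                continue
            res.per_tf.to_csv(outdir / f"spread_{label}.tsv", sep="\t")
            report.spread.append(SpreadReport(
                values=label, n_tfs=len(res.per_tf), n_null_sets=res.n_null_sets,
                p=res.p, alternative=res.alternative,
                median_observed=float(res.per_tf["observed"].median()),
                median_expected=float(res.per_tf["expected"].median()),
            ))
            stages.append(StageStatus(name=f"spread:{label}", status="ok"))
    else:
        stages.append(StageStatus(name="spread", status="skipped",
                                  reason="no confirmed-edge network"))

    # ---- expression divergence -------------------------------------------
    if inputs.counts is not None and conf_net is not None and conf_net.n_edges:
        counts = inputs.counts
        rpm_a = dv.rpm_normalize(pd.Series(counts["count_a"].to_numpy(),
                                           index=counts["gene_id_a"]))
        rpm_b = dv.rpm_normalize(pd.Series(counts["count_b"].to_numpy(),
                                           index=counts["gene_id_b"]))
        orthologs = dict(zip(counts["gene_id_a"], counts["gene_id_b"]))
        div = dv.log2_fold_changes(rpm_a, rpm_b, orthologs)
        tf_rates = df.loc[df["is_tf"], "assigned_ka_ks"]
        try:
            dres = dv.divergence_ttest(
                div, conf_net, tf_rates, fast_fraction=float(ana["fast_fraction"])
            )
            report.divergence = DivergenceReport(**dres.to_dict())
            stages.append(StageStatus(name="divergence", status="ok"))
        except ValueError as exc:
            stages.append(StageStatus(name="divergence", status="skipped", reason=str(exc)))
        div.df.to_csv(outdir / "divergence_table.tsv", sep="\t")
    else:
        stages.append(StageStatus(name="divergence", status="skipped",
                                  reason="no two-species counts"))

    # ---- target-set enrichment -------------------------------------------
    if inputs.annotations is not None and chip_net is not None:
        tf_rates = df.loc[df["is_tf"], "assigned_ka_ks"]
        fast_t, slow_t = st.fast_slow_target_sets(
            chip_net, tf_rates, fast_fraction=float(ana["fast_fraction"])
        )
        enr = st.target_set_enrichment(
            fast_t, slow_t, inputs.annotations, min_term_size=int(ana["min_term_size"])
        )
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        for row in enr.itertuples(index=False):
            fold = None if not np.isfinite(row.fold) else float(row.fold)
            report.enrichment.append(EnrichmentReportRow(
                term_id=row.term_id, n_genes=int(row.n_genes), fold=fold,
                p=float(row.p), significant=bool(row.significant),
            ))
        stages.append(StageStatus(name="enrichment", status="ok"))
    else:
        stages.append(StageStatus(name="enrichment", status="skipped",
                                  reason="no annotations"))

    # ---- binned-median profiles ------------------------------------------
    profile_specs = [
        ("ka_by_in_degree", "rank_in_degree", "rank_assigned_ka_ks"),
        ("ka_by_cai", "rank_cai", "rank_assigned_ka_ks"),
        ("ka_by_interactor_ka", "rank_median_interactor_ka_ks", "rank_assigned_ka_ks"),
    ]
    for name, xcol, ycol in profile_specs:
        if xcol not in df.columns:
            continue
        for set_name, mask in (("tf", df["is_tf"]), ("all", pd.Series(True, index=df.index))):
            x = df.loc[mask, xcol]
            y = df.loc[mask, ycol]
            try:
                prof = st.binned_median_profile(
                    x, y, n_bins=int(ana["n_bins"]),
                    rng=_stage_seed(seed, f"profile:{name}:{set_name}"),
                )
            except ValueError:
                continue
            prof.to_csv(outdir / f"profile_{name}_{set_name}.tsv", sep="\t", index=False)
            if make_figures:
                _plot_profile(prof, f"{name} ({set_name})", xcol, ycol,
                              outdir / f"profile_{name}_{set_name}.png")
    stages.append(StageStatus(name="binned_profiles", status="ok"))

    # ---- report -----------------------------------------------------------
    (outdir / "report.json").write_text(report.model_dump_json(indent=2))
    return report


def _plot_profile(prof: pd.DataFrame, title: str, xlabel: str, ylabel: str,
                  path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    xs = np.arange(len(prof))
    ax.bar(xs, prof["median_y"], yerr=prof["bootstrap_se"], capsize=3,
           color="#7c9fcf", edgecolor="black", linewidth=0.5)
    for i, row in prof.iterrows():
        ax.text(xs[i], row["median_y"] + row["bootstrap_se"] + 0.01,
                str(int(row["count"])), ha="center", fontsize=7)
    ax.set_xticks(xs)
    ax.set_xticklabels(prof["label"], rotation=30, fontsize=6, ha="right")
    ax.set_xlabel(xlabel, fontsize=8)
    ax.set_ylabel(f"median {ylabel}", fontsize=8)
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)


def report_json_schema() -> dict:
    """JSON schema of the analysis report (published alongside the package)."""
    return AnalysisReport.model_json_schema()
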
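"""Synthetic gene/network/knockout/expression generator with recorded ground truth.

The generator emulates the statistical structure the analyses in this
package assume, at a desk-testable scale, with every coupling configurable
and recorded as ground truth so that each analysis stage can be tested as a
parameter-recovery problem:

* gene properties drawn through a Gaussian copula (latent correlated
  normals mapped through the marginal quantile transforms), so configured
  Spearman couplings are achieved without distorting marginals: expression
  log-normal, CAI a noisy monotone transform of expression, Ka/Ks coupled
  to expression and to PPI-degree propensity with configurable rank-space
  slopes (for bivariate ranks the OLS slope equals the Spearman
  correlation, so "slope" and "rank correlation" are interchangeable
  targets here);
* a TF subset with its own trend multipliers and a downward expression
  shift (TFs are lowly expressed);
* a directed TF->target network with heavy-tailed out-degree, per-edge
  activating/repressive signs, per-edge experiment support, and a TF-level
  coupling between TF Ka/Ks and the Ka/Ks of activated (not repressed)
  targets.  The ``activated_coupling`` parameter is calibrated at the TF
  level: the copula loading of each coupled target is attenuated according
  to how many of its owner TF's targets are coupled, so that the Spearman
  correlation between TF rate and *median activated-target rate* recovered
  by the analysis matches the configured value (a fixed per-edge loading
  would be amplified by median aggregation);
* ortholog-loss flags whose probability increases with the regulating TF's
  rate; knockout X scores consistent with edge signs; two-species read
  counts whose divergence scale is larger for targets of fast TFs; and
  GO-like annotation terms biased toward (niche) or away from (core)
  fast-TF targets.

Ground truth (true signs, coupling owners, fast-TF set, term classes) is
emitted alongside the data and is never consumed by analysis stages.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm, spearmanr

from .core import AnnotationMap, GeneTable
from .signs import KnockoutMatrix

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticBundle",
    "generate_genes",
    "generate_ppi",
    "generate_regulatory_network",
    "generate_knockout_xscores",
    "generate_two_species_counts",
    "generate_annotations",
    "generate_bundle",
]

# sub-stream tags so adding a stage never perturbs another stage's randomness
_STREAMS = {"genes": 1, "ppi": 2, "network": 3, "knockout": 4, "counts": 5,
            "annotations": 6}

# The TF-level coupling is recovered through the *median* of target rates,
# whose noise exceeds the mean's (asymptotically by pi/2 for normal noise);
# part of the coupled signal is also replaced by the assigned top value when
# a coupled target loses its ortholog.  This constant inflates the noise
# term of the attenuation formula to compensate; it is a property of the
# median-aggregation geometry, fixed once, not a per-draw fit.
_MEDIAN_NOISE_INFLATION = 1.55


def _spearman_to_pearson(rho_s: float) -> float:
    """Latent normal correlation achieving a given Spearman correlation."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass
class GeneratorConfig:
    """All generator parameters; none of them appear anywhere else.

    Defaults are the package's study conditions: a 2,000-gene genome with a
    174-member TF subset, a genome-wide rank-space slope of -0.5 between
    Ka/Ks and expression (and -0.3 against PPI degree), TF trends flattened
    to 0.3x the genome slope with expression shifted one standard deviation
    down, 65% activating edges, a TF-level activated-target coupling of
    0.30 with repressed targets uncoupled, and ~10% baseline ortholog loss
    rising with regulator rate.
    """

    n_genes: int = 2000
    n_tfs: int = 174

    # gene-property marginals and couplings
    expr_log_mean: float = 3.0
    expr_log_sd: float = 1.5
    tf_expression_shift: float = 1.0  # TFs drawn this many latent SDs lower
    cai_expression_coupling: float = 0.8
    ka_log_mean: float = -2.6
    ka_log_sd: float = 0.8
    slope_ka_expression: float = -0.5  # genome rank-space slope (== Spearman)
    slope_ka_ppi: float = -0.3
    tf_trend_multiplier_expression: float = 0.3
    tf_trend_multiplier_ppi: float = 0.3

    # PPI degree law (propensity; realized network via Chung-Lu sampling)
    ppi_degree_exponent: float = 2.2
    ppi_degree_max: int = 150
    ppi_redetect_prob: float = 0.3

    # regulatory network
    out_degree_exponent: float = 2.0
    out_degree_min: int = 3
    out_degree_max: int | None = None  # defaults to n_genes // 10
    tf_on_tf_weight: float = 2.0
    fast_tf_on_tf_bias: float = 1.5
    sign_split: float = 0.65
    activated_coupling: float = 0.30
    repressed_coupling: float = 0.0
    n_experiments: int = 3
    redetect_prob: float = 0.4

    # ortholog loss
    missing_fraction_base: float = 0.10
    missing_vs_tf_rate_coupling: float = 0.8

    # knockout X scores
    ko_mu: float = 2.0
    xscore_noise_sd: float = 0.5
    ko_background_sd: float = 0.3
    ko_coverage: float = 1.0

    # two-species counts
    read_depth_factor: float = 20.0  # library depth multiplier on expression
    # (total library ~2-3M reads at the default genome size, matching
    # early RNA-seq depths; low depth makes Poisson noise on log2 fold
    # changes expression-dependent and confounds the divergence test)
    divergence_scale: float = 0.4
    divergence_rate_coupling: float = 1.0
    fast_fraction: float = 0.25

    # annotations
    n_terms: int = 20
    term_size_min: int = 40
    term_size_max: int = 120
    niche_fraction: float = 0.5
    niche_term_bias: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.n_tfs < self.n_genes):
            raise ValueError("need 0 < n_tfs < n_genes")
        for name in ("sign_split", "missing_fraction_base", "ko_coverage",
                     "fast_fraction", "niche_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for me, md in ((1.0, 1.0), (self.tf_trend_multiplier_expression,
                                    self.tf_trend_multiplier_ppi)):
            ce = _spearman_to_pearson(self.slope_ka_expression * me)
            cd = _spearman_to_pearson(self.slope_ka_ppi * md)
            if ce ** 2 + cd ** 2 >= 1.0:
                raise ValueError(
                    "infeasible slope combination: the implied latent loadings of "
                    "expression and PPI degree on Ka/Ks exceed unit variance"
                )

    @classmethod
    def from_mapping(cls, m: Mapping) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(m) - known
        if unknown:
            raise ValueError(f"unknown generator parameters: {sorted(unknown)}")
        return cls(**m)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Per-draw ground truth; emitted next to the data, never fed to analyses."""

    edge_signs: pd.DataFrame  # tf, target, sign
    owner_tf: dict[str, str]  # coupled target -> owning TF
    fast_tfs: list[str]
    niche_terms: list[str] = field(default_factory=list)
    core_terms: list[str] = field(default_factory=list)
    true_ka: dict[str, float] = field(default_factory=dict)
    realized: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "edge_signs": self.edge_signs.values.tolist(),
            "owner_tf": self.owner_tf,
            "fast_tfs": self.fast_tfs,
            "niche_terms": self.niche_terms,
            "core_terms": self.core_terms,
            "true_ka": self.true_ka,
            "realized": self.realized,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            edge_signs=pd.DataFrame(d["edge_signs"], columns=["tf", "target", "sign"]),
            owner_tf=d["owner_tf"],
            fast_tfs=d["fast_tfs"],
            niche_terms=d["niche_terms"],
            core_terms=d["core_terms"],
            true_ka=d["true_ka"],
            realized=d["realized"],
        )


# ---------------------------------------------------------------------------
# gene properties
# ---------------------------------------------------------------------------

def _gene_ids(config: GeneratorConfig) -> tuple[list[str], np.ndarray]:
    wt = len(str(config.n_tfs))
    wg = len(str(config.n_genes))
    ids = [f"TF{i + 1:0{wt}d}" for i in range(config.n_tfs)]
    ids += [f"G{i + 1:0{wg}d}" for i in range(config.n_genes - config.n_tfs)]
    is_tf = np.zeros(config.n_genes, dtype=bool)
    is_tf[: config.n_tfs] = True
    return ids, is_tf


def generate_genes(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[GeneTable, dict[str, np.ndarray]]:
    """Draw the gene-property table plus the latent variables later stages need.

    Returns the table and a dict of latents: ``z_ka`` (Ka/Ks latent),
    ``z_deg`` (PPI-degree propensity latent) and ``ppi_propensity`` (integer
    expected degrees for Chung-Lu sampling).
    """
    n = config.n_genes
    ids, is_tf = _gene_ids(config)

    z_expr = rng.standard_normal(n)
    z_expr[is_tf] -= config.tf_expression_shift
    expression = np.exp(config.expr_log_mean + config.expr_log_sd * z_expr)

    c_cai = config.cai_expression_coupling
    z_cai = c_cai * z_expr + np.sqrt(1 - c_cai ** 2) * rng.standard_normal(n)
    cai = norm.cdf(z_cai)

    z_deg = rng.standard_normal(n)
    ce = _spearman_to_pearson(config.slope_ka_expression)
    cd = _spearman_to_pearson(config.slope_ka_ppi)
    ce_v = np.where(is_tf, _spearman_to_pearson(
        config.slope_ka_expression * config.tf_trend_multiplier_expression), ce)
    cd_v = np.where(is_tf, _spearman_to_pearson(
        config.slope_ka_ppi * config.tf_trend_multiplier_ppi), cd)
    resid = np.sqrt(1.0 - ce_v ** 2 - cd_v ** 2)
    # TF trends attach to the centered expression latent so that the TF
    # expression shift moves TFs' expression, not their Ka/Ks
    z_expr_centered = z_expr + is_tf * config.tf_expression_shift
    z_ka = ce_v * z_expr_centered + cd_v * z_deg + resid * rng.standard_normal(n)
    ka = np.exp(config.ka_log_mean + config.ka_log_sd * z_ka)

    u = norm.cdf(z_deg)
    alpha = config.ppi_degree_exponent
    prop = np.floor((1.0 - u) ** (-1.0 / (alpha - 1.0))).astype(int)
    prop = np.clip(prop, 1, config.ppi_degree_max)

    df = pd.DataFrame(
        {
            "gene_id": ids,
            "ka_ks": ka,
            "expression": expression,
            "cai": cai,
            "is_tf": is_tf,
            "ortholog_par": True,
            "ortholog_mik": True,
        }
    )
    genes = GeneTable.from_frame(df)
    latents = {"z_ka": z_ka, "z_deg": z_deg, "ppi_propensity": prop,
               "z_expr_centered": z_expr_centered}
    return genes, latents


def generate_ppi(
    config: GeneratorConfig,
    genes: GeneTable,
    latents: Mapping[str, np.ndarray],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Chung-Lu PPI edge list from the per-gene degree propensities.

    Edge (i, j) appears with probability ``min(1, d_i d_j / sum(d))`` so the
    realized degree tracks the propensity and inherits its negative rank
    coupling to Ka/Ks.  Returns a tidy edge table (gene_a, gene_b, n_reports).
    """
    ids = genes.genes.to_numpy()
    d = latents["ppi_propensity"].astype(float)
    s = d.sum()
    rows_a, rows_b = [], []
    n = len(ids)
    for i in range(n - 1):
        p = np.minimum(1.0, d[i] * d[i + 1:] / s)
        hit = np.nonzero(rng.random(n - 1 - i) < p)[0]
        if hit.size:
            rows_a.append(np.full(hit.size, i))
            rows_b.append(hit + i + 1)
    if rows_a:
        a = np.concatenate(rows_a)
        b = np.concatenate(rows_b)
    else:
        a = b = np.empty(0, dtype=int)
    n_reports = 1 + rng.binomial(2, config.ppi_redetect_prob, size=a.size)
    return pd.DataFrame(
        {"gene_a": ids[a], "gene_b": ids[b], "n_reports": n_reports}
    )


# ---------------------------------------------------------------------------
# regulatory network
# ---------------------------------------------------------------------------

def _powerlaw_choice(
    rng: np.random.Generator, kmin: int, kmax: int, exponent: float, size: int
) -> np.ndarray:
    ks = np.arange(kmin, kmax + 1)
    p = ks.astype(float) ** (-exponent)
    p /= p.sum()
    return rng.choice(ks, size=size, p=p)


def generate_regulatory_network(
    config: GeneratorConfig,
    genes: GeneTable,
    latents: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw edges, signs, experiment support; couple activated targets; flag orphans.

    Mutates ``genes`` (Ka/Ks of coupled targets redrawn; ortholog-loss flags
    set) and ``latents['z_ka']`` consistently.  Returns the raw experiment
    records (tf, target, experiment_id, source) and the ground truth.
    """
    df = genes.df
    ids = df.index.to_numpy()
    n = len(ids)
    is_tf = df["is_tf"].to_numpy()
    tf_ids = ids[is_tf]
    n_tfs = len(tf_ids)
    z_ka = latents["z_ka"]

    kmax = config.out_degree_max or max(config.out_degree_min + 1, n // 10)
    if kmax >= n:
        raise ValueError("out-degree demand exceeds the gene pool")
    out_deg = _powerlaw_choice(rng, config.out_degree_min, kmax,
                               config.out_degree_exponent, n_tfs)

    # fast TFs (by latent rate, upper quartile) preferentially regulate TFs
    tf_z = z_ka[is_tf]
    fast_reg = tf_z >= np.quantile(tf_z, 0.75)
    pos = {g: i for i, g in enumerate(ids)}
    base_w = np.ones(n)
    edge_tf, edge_tg = [], []
    for ti, tf in enumerate(tf_ids):
        w = base_w.copy()
        w[is_tf] = config.tf_on_tf_weight * (
            config.fast_tf_on_tf_bias if fast_reg[ti] else 1.0
        )
        w[pos[tf]] = 0.0
        w /= w.sum()
        picks = rng.choice(n, size=out_deg[ti], replace=False, p=w)
        edge_tf.extend([tf] * out_deg[ti])
        edge_tg.extend(ids[picks])
    edges = pd.DataFrame({"tf": edge_tf, "target": edge_tg})
    edges["sign"] = np.where(rng.random(len(edges)) < config.sign_split, "A", "R")

    # --- TF-level coupling of activated-target Ka/Ks ------------------------
    # Each non-TF target with at least one edge of the coupled sign is "owned"
    # by one such regulator and its rate latent is redrawn around the owner's.
    # The copula loading is attenuated per owner so that the Spearman between
    # TF rate and *median* target rate (what the analysis measures, over the
    # TF's k same-sign targets of which m are owned) equals the configured
    # coupling: a^2 = rho^2 * k / (m * (m - rho^2 * (m - 1))).
    tf_latent = pd.Series(z_ka[is_tf], index=tf_ids)
    tf_latent_std = (tf_latent - tf_latent.mean()) / tf_latent.std(ddof=0)
    # redraws keep the genome loadings on expression and degree so the
    # genome-wide trends survive; the TF component is added on top
    ce = _spearman_to_pearson(config.slope_ka_expression)
    cd = _spearman_to_pearson(config.slope_ka_ppi)
    a_cap = float(np.sqrt(max(1.0 - ce ** 2 - cd ** 2, 0.0))) - 1e-6
    z_expr_c = latents["z_expr_centered"]
    z_deg = latents["z_deg"]

    owner: dict[str, str] = {}
    for sign, rho in (("A", config.activated_coupling),
                      ("R", config.repressed_coupling)):
        if rho == 0.0:
            continue
        sub = edges[edges["sign"] == sign]
        free = ~sub["target"].map(lambda g: g in owner or is_tf[pos[g]]).to_numpy()
        by_target = sub[free].groupby("target")["tf"].apply(list)
        owned_by_tf: dict[str, list[str]] = {}
        for target in by_target.index:  # groupby index is sorted => deterministic
            tfs_here = by_target[target]
            tf = tfs_here[int(rng.integers(len(tfs_here)))]
            owner[target] = tf
            owned_by_tf.setdefault(tf, []).append(target)
        counts_all = sub.groupby("tf")["target"].nunique()
        for tf, owned in sorted(owned_by_tf.items()):
            k = int(counts_all[tf])
            m = len(owned)
            a2 = rho ** 2 * k * _MEDIAN_NOISE_INFLATION / (m * (m - rho ** 2 * (m - 1)))
            a = min(float(np.sqrt(a2)), a_cap)
            zt = float(tf_latent_std[tf])
            resid = float(np.sqrt(1.0 - a ** 2 - ce ** 2 - cd ** 2))
            for tgt in owned:
                j = pos[tgt]
                z_ka[j] = (a * zt + ce * z_expr_c[j] + cd * z_deg[j]
                           + resid * rng.standard_normal())
    ka_new = np.exp(config.ka_log_mean + config.ka_log_sd * z_ka)
    df["ka_ks"] = ka_new
    true_ka = dict(zip(ids, ka_new))

    # --- ortholog-loss flags (non-TF genes only) ----------------------------
    u_owner = np.full(n, 0.5)
    for tgt, tf in owner.items():
        u_owner[pos[tgt]] = norm.cdf(float(tf_latent_std[tf]))
    p_missing = np.clip(
        config.missing_fraction_base
        * (1.0 + config.missing_vs_tf_rate_coupling * (2.0 * u_owner - 1.0)),
        0.0, 0.95,
    )
    p_missing[is_tf] = 0.0
    missing = rng.random(n) < p_missing
    missing_mik = (~is_tf) & (rng.random(n) < config.missing_fraction_base)
    df["ortholog_par"] = ~missing
    df["ortholog_mik"] = ~missing_mik
    df.loc[missing, "ka_ks"] = np.nan

    # --- experiment support -------------------------------------------------
    n_det = 1 + rng.binomial(config.n_experiments - 1, config.redetect_prob,
                             size=len(edges))
    rec_tf, rec_tg, rec_exp = [], [], []
    for row, nd in zip(edges.itertuples(index=False), n_det):
        exps = rng.choice(config.n_experiments, size=nd, replace=False)
        for e in sorted(exps):
            rec_tf.append(row.tf)
            rec_tg.append(row.target)
            rec_exp.append(f"E{e + 1}")
    records = pd.DataFrame(
        {"tf": rec_tf, "target": rec_tg, "experiment_id": rec_exp, "source": "chip"}
    )

    # fast TFs among TFs with targets, by final true rate (top quartile)
    tf_rate = pd.Series({tf: true_ka[tf] for tf in tf_ids})
    with_targets = sorted(set(edges["tf"]))
    r = tf_rate[with_targets]
    order = r.iloc[np.lexsort((r.index.to_numpy(), -r.to_numpy()))]
    n_fast = max(1, int(round(config.fast_fraction * len(order))))
    fast_tfs = sorted(order.index[:n_fast])

    truth = GroundTruth(
        edge_signs=edges[["tf", "target", "sign"]].copy(),
        owner_tf=owner,
        fast_tfs=fast_tfs,
        true_ka={g: float(v) for g, v in true_ka.items()},
    )
    return records, truth


# ---------------------------------------------------------------------------
# knockout X scores
# ---------------------------------------------------------------------------

def generate_knockout_xscores(
    config: GeneratorConfig,
    genes: GeneTable,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> KnockoutMatrix:
    """X scores (log knockout/wild-type) consistent with the true edge signs.

    Activating edges center at -ko_mu (target drops when its activator is
    deleted), repressive at +ko_mu, both with ``xscore_noise_sd`` noise;
    non-edge cells carry near-zero background.  Only a ``ko_coverage``
    fraction of TFs has knockout data.
    """
    ids = genes.genes
    tf_ids = genes.tf_ids
    n_cov = int(round(config.ko_coverage * len(tf_ids)))
    covered = sorted(rng.choice(tf_ids.to_numpy(), size=n_cov, replace=False))
    mat = rng.normal(0.0, config.ko_background_sd, size=(len(ids), len(covered))) \
        if config.ko_background_sd > 0 else np.zeros((len(ids), len(covered)))
    x = pd.DataFrame(mat, index=ids, columns=covered)
    col_pos = {t: i for i, t in enumerate(covered)}
    row_pos = {g: i for i, g in enumerate(ids)}
    vals = x.to_numpy()
    for row in truth.edge_signs.itertuples(index=False):
        if row.tf not in col_pos:
            continue
        mu = -config.ko_mu if row.sign == "A" else config.ko_mu
        noise = rng.normal(0.0, config.xscore_noise_sd) if config.xscore_noise_sd > 0 else 0.0
        vals[row_pos[row.target], col_pos[row.tf]] = mu + noise
    return KnockoutMatrix(pd.DataFrame(vals, index=ids, columns=covered))


# ---------------------------------------------------------------------------
# two-species counts
# ---------------------------------------------------------------------------

def generate_two_species_counts(
    config: GeneratorConfig,
    genes: GeneTable,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson read counts for both species with rate-coupled divergence.

    Species-A counts are Poisson around each gene's expression; species-B
    rates are multiplied by 2**delta with delta ~ Normal(0, s) where s is
    ``divergence_scale`` for ordinary genes and ``divergence_scale * (1 +
    divergence_rate_coupling)`` for targets of fast-evolving TFs.  Genes
    lacking the comparison-species ortholog are omitted from the pairing.
    """
    df = genes.df
    paired = df.index[df["ortholog_par"]]
    fast_tf_set = set(truth.fast_tfs)
    fast_targets = {
        row.target for row in truth.edge_signs.itertuples(index=False)
        if row.tf in fast_tf_set
    }
    lam = df.loc[paired, "expression"].to_numpy() * config.read_depth_factor
    is_fast_t = np.array([g in fast_targets for g in paired])
    scale = config.divergence_scale * (1.0 + config.divergence_rate_coupling * is_fast_t)
    delta = rng.normal(0.0, 1.0, size=len(paired)) * scale
    count_a = rng.poisson(lam)
    count_b = rng.poisson(lam * np.exp2(delta))
    return pd.DataFrame(
        {
            "gene_id_a": paired,
            "count_a": count_a,
            "gene_id_b": [f"{g}_par" for g in paired],
            "count_b": count_b,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def generate_annotations(
    config: GeneratorConfig,
    genes: GeneTable,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[AnnotationMap, dict[str, list[str]]]:
    """GO-like terms: niche terms biased toward fast-TF targets, core terms away.

    With ``niche_term_bias`` = 1 the assignment is unbiased and enrichment
    tests should be null-calibrated.
    """
    ids = genes.genes.to_numpy()
    fast_targets = {
        row.target for row in truth.edge_signs.itertuples(index=False)
        if row.tf in set(truth.fast_tfs)
    }
    in_fast = np.array([g in fast_targets for g in ids], dtype=float)
    n_niche = int(round(config.niche_fraction * config.n_terms))
    pairs: list[tuple[str, str]] = []
    niche_terms, core_terms = [], []
    for t in range(config.n_terms):
        term = f"T{t + 1:03d}"
        size = int(rng.integers(config.term_size_min, config.term_size_max + 1))
        if t < n_niche:
            w = 1.0 + (config.niche_term_bias - 1.0) * in_fast
            niche_terms.append(term)
        else:
            w = 1.0 + (config.niche_term_bias - 1.0) * (1.0 - in_fast)
            core_terms.append(term)
        w = w / w.sum()
        members = rng.choice(len(ids), size=size, replace=False, p=w)
        pairs.extend((ids[i], term) for i in sorted(members))
    return AnnotationMap.from_pairs(pairs), {"niche": niche_terms, "core": core_terms}


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """One full synthetic draw: every input table the pipeline consumes, plus truth."""

    config: GeneratorConfig
    seed: int
    genes: GeneTable
    edge_records: pd.DataFrame
    ppi_edges: pd.DataFrame
    knockout: KnockoutMatrix
    counts: pd.DataFrame
    annotations: AnnotationMap
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.tsv",
            "edges": outdir / "edges.tsv",
            "ppi": outdir / "ppi.tsv",
            "knockout": outdir / "knockout.tsv",
            "counts": outdir / "counts.tsv",
            "annotations": outdir / "annotations.tsv",
            "truth": outdir / "truth.json",
        }
        self.genes.to_tsv(paths["genes"])
        self.edge_records.rename(
            columns={"tf": "tf_id", "target": "target_id"}
        ).to_csv(paths["edges"], sep="\t", index=False)
        self.ppi_edges.to_csv(paths["ppi"], sep="\t", index=False)
        self.knockout.to_tsv(paths["knockout"])
        self.counts.to_csv(paths["counts"], sep="\t", index=False)
        self.annotations.to_tsv(paths["annotations"])
        self.truth.to_json(paths["truth"])
        return paths


def generate_bundle(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticBundle:
    """Generate every input table from one (config, seed) pair, deterministically.

    Each stage uses its own seed stream derived from (seed, stage tag), so
    outputs are byte-identical across runs and adding a stage never perturbs
    the randomness of the others.
    """
    config = config or GeneratorConfig()

    def stream(name: str) -> np.random.Generator:
        return np.random.default_rng([int(seed), _STREAMS[name]])

    genes, latents = generate_genes(config, stream("genes"))
    ppi_edges = generate_ppi(config, genes, latents, stream("ppi"))
    edge_records, truth = generate_regulatory_network(
        config, genes, latents, stream("network")
    )
    knockout = generate_knockout_xscores(config, genes, truth, stream("knockout"))
    counts = generate_two_species_counts(config, genes, truth, stream("counts"))
    annotations, term_classes = generate_annotations(
        config, genes, truth, stream("annotations")
    )
    truth.niche_terms = term_classes["niche"]
    truth.core_terms = term_classes["core"]

    # realized couplings of this draw, for diagnostics and recovery tests
    df = genes.df
    ok = df["ka_ks"].notna()
    rho_e = spearmanr(df.loc[ok, "ka_ks"], df.loc[ok, "expression"])[0]
    truth.realized = {"spearman_ka_expression": float(rho_e)}

    return SyntheticBundle(
        config=config, seed=int(seed), genes=genes, edge_records=edge_records,
        ppi_edges=ppi_edges, knockout=knockout, counts=counts,
        annotations=annotations, truth=truth,
    )
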
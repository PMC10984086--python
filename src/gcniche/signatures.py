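"""Differential expression, signature scoring, enrichment and cohort analysis.

The DZ/LZ spatial signature is derived from matched dark-zone/light-zone
region pairs by a paired empirical-Bayes moderated t-test: per-gene
within-pair differences are summarized by a one-sample t whose variance is
shrunk toward a common prior, ``s̃² = (d0·s0² + d_g·s_g²) / (d0 + d_g)``,
with the prior (d0, s0²) estimated by method-of-moments on the log sample
variances.  Genes pass at a Benjamini–Hochberg adjusted p below alpha
(optionally with an |logFC| cutoff, the convention used for single-cell
rank-sum comparisons).

Signatures are scored per sample either as the mean of per-gene z-scores
(``mean_z``) or as the summed log2 expression (``total``); samples are
stratified by score tertiles.  Set enrichment in a ranked gene list uses
the weighted Kolmogorov–Smirnov running sum with a gene-label permutation
null.  The cross-cohort analysis asks, for each signature gene, in how many
tumor cohorts its expression correlates significantly and negatively with a
T-cell signature score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSignature

__all__ = [
    "DEResult",
    "EnrichmentResult",
    "CohortCorrelationSummary",
    "moderated_t_paired_de",
    "score_signature",
    "tertile_stratify",
    "enrichment_score",
    "cross_cohort_gene_correlations",
    "dz_lz_group_assignment",
]


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t on paired differences
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    table: pd.DataFrame          # logFC, s2, t, pvalue, adj_pvalue, direction, significant
    d0: float                    # prior degrees of freedom (inf = full pooling)
    s0_sq: float                 # prior variance
    df_residual: float
    method: str
    alpha: float
    lfc_cutoff: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def _squeeze_var(s2: np.ndarray, df: float, trim: float = 0.0) -> tuple[float, float]:
    """Estimate (d0, s0²) of the scaled inverse-chi² variance prior.

    Method-of-moments on ``z = log(s²)``: the excess variance of ``z`` over
    the trigamma sampling variance identifies d0; the mean identifies s0².
    A trimmed mean/variance (fraction ``trim`` per tail) is available for
    heavy-tailed variance mixtures.  Returns ``d0 = inf`` when the observed
    log-variances are no more dispersed than sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    if trim > 0:
        e_mean = float(stats.trim_mean(e, trim))
        lo, hi = np.quantile(e, [trim, 1 - trim])
        e_var = float(np.var(e[(e >= lo) & (e <= hi)], ddof=1))
    else:
        e_mean = float(e.mean())
        e_var = float(np.var(e, ddof=1))
    excess = e_var - float(_trigamma(df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _paired_differences(expr: ExpressionMatrix) -> pd.DataFrame:
    design = expr.design
    for col in ("pair", "zone"):
        if col not in design.columns:
            raise ValueError(f"design needs a {col!r} column for the paired analysis")
    diffs = {}
    for pair_id, grp in design.groupby("pair"):
        zones = set(grp["zone"])
        if zones != {"DZ", "LZ"}:
            raise ValueError(f"incomplete pair {pair_id!r}: zones present {sorted(zones)}")
        dz = grp.index[grp["zone"] == "DZ"][0]
        lz = grp.index[grp["zone"] == "LZ"][0]
        diffs[pair_id] = expr.values[dz] - expr.values[lz]
    return pd.DataFrame(diffs)


def moderated_t_paired_de(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
    method: str = "moderated_t",
    lfc_cutoff: float = 0.0,
    d0_override: float | None = None,
    trim: float = 0.0,
) -> DEResult:
    """Differential expression between matched DZ and LZ regions.

    ``moderated_t`` (default): one-sample empirical-Bayes moderated t on
    the within-pair DZ−LZ differences, BH adjustment, significance at
    ``adj p < alpha`` and ``|logFC| > lfc_cutoff``.  ``d0_override`` forces
    the prior degrees of freedom (0 recovers the ordinary paired t).

    ``rank_sum``: per-gene two-sided rank-sum between the DZ and LZ sample
    groups (unpaired), BH adjustment and the same cutoffs — the convention
    used for single-cell contrasts, where ``lfc_cutoff`` is typically 0.25.
    """
    if method == "rank_sum":
        return _rank_sum_de(expr, alpha=alpha, lfc_cutoff=lfc_cutoff)
    if method != "moderated_t":
        raise ValueError(f"unknown method {method!r}")

    diffs = _paired_differences(expr)
    n = diffs.shape[1]
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    logfc = diffs.mean(axis=1).to_numpy()
    s2 = diffs.var(axis=1, ddof=1).to_numpy()
    df_g = float(n - 1)

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2[s2 > 0])) if d0 > 0 else 0.0
    else:
        d0, s0_sq = _squeeze_var(s2, df_g, trim=trim)

    # total df capped at the pooled residual df, as in the eBayes convention
    df_cap = len(s2) * df_g
    if np.isinf(d0):
        var_post = np.full_like(s2, s0_sq)
        df_total = df_cap
    elif d0 == 0:
        var_post = s2
        df_total = df_g
    else:
        var_post = (d0 * s0_sq + df_g * s2) / (d0 + df_g)
        df_total = min(d0 + df_g, df_cap)
    se = np.sqrt(var_post / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj = multipletests(pvals, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": s2,
            "t": t,
            "pvalue": pvals,
            "adj_pvalue": adj,
            "direction": np.where(logfc >= 0, "up", "down"),
        },
        index=diffs.index.rename("gene"),
    )
    table["significant"] = (table["adj_pvalue"] < alpha) & (
        table["logFC"].abs() > lfc_cutoff
    )
    return DEResult(
        table=table,
        d0=float(d0),
        s0_sq=float(s0_sq),
        df_residual=df_g,
        method="moderated_t",
        alpha=alpha,
        lfc_cutoff=lfc_cutoff,
    )


def _rank_sum_de(expr: ExpressionMatrix, alpha: float, lfc_cutoff: float) -> DEResult:
    design = expr.design
    if "zone" not in design.columns:
        raise ValueError("design needs a 'zone' column")
    g1 = design.index[design["zone"] == "DZ"]
    g2 = design.index[design["zone"] == "LZ"]
    if len(g1) < 3 or len(g2) < 3:
        raise ValueError("need at least 3 samples per group for the rank-sum variant")
    a = expr.values[g1].to_numpy()
    b = expr.values[g2].to_numpy()
    logfc = a.mean(axis=1) - b.mean(axis=1)
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    pvals = np.asarray(res.pvalue, dtype=float)
    adj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "s2": np.nan,
            "t": np.nan,
            "pvalue": pvals,
            "adj_pvalue": adj,
            "direction": np.where(logfc >= 0, "up", "down"),
        },
        index=expr.genes.rename("gene"),
    )
    table["significant"] = (table["adj_pvalue"] < alpha) & (
        table["logFC"].abs() > lfc_cutoff
    )
    return DEResult(
        table=table,
        d0=float("nan"),
        s0_sq=float("nan"),
        df_residual=float("nan"),
        method="rank_sum",
        alpha=alpha,
        lfc_cutoff=lfc_cutoff,
    )


# ---------------------------------------------------------------------------
# signature scoring and stratification
# ---------------------------------------------------------------------------

def score_signature(
    expr: ExpressionMatrix, signature: GeneSignature, method: str = "mean_z"
) -> pd.Series:
    """Per-sample signature score.

    ``mean_z`` averages per-gene z-scores (robust to per-gene scale;
    invariant to gene-wise affine rescaling); ``total`` sums the log2
    values over the signature genes, the convention used for "total
    expression" tertile splits.  Genes absent from the matrix are reported
    via a warning; zero overlap or (for ``mean_z``) zero-variance signature
    genes are errors.
    """
    present = [g for g in signature.genes if g in expr.values.index]
    missing = [g for g in signature.genes if g not in expr.values.index]
    if not present:
        raise ValueError(f"no signature gene of {signature.name!r} found in the matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} signature gene(s) missing from the matrix: {missing[:5]}...",
            stacklevel=2,
        )
    sub = expr.values.loc[present]
    if method == "total":
        score = sub.sum(axis=0)
    elif method == "mean_z":
        sd = sub.std(axis=1, ddof=0)
        if (sd == 0).any():
            bad = list(sd.index[sd == 0])[:5]
            raise ValueError(f"zero-variance signature gene(s), mean_z undefined: {bad}")
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        score = z.mean(axis=0)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    score.name = f"{signature.name}_{method}"
    return score


def tertile_stratify(scores: pd.Series | np.ndarray) -> pd.Series:
    """Split samples at the empirical 1/3 and 2/3 score quantiles.

    Boundary ties go to the lower stratum: ``low`` is ``s ≤ q1/3``, ``mid``
    is ``q1/3 < s ≤ q2/3``, ``high`` is ``s > q2/3``.
    """
    s = pd.Series(scores)
    if len(s) < 3:
        raise ValueError("need at least 3 samples to form tertiles")
    if s.nunique() == 1:
        raise ValueError("all scores identical: tertiles undefined")
    q1, q2 = np.quantile(s.to_numpy(dtype=float), [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(s <= q1, "low", np.where(s <= q2, "mid", "high"))
    return pd.Series(labels, index=s.index, name="tertile")


# ---------------------------------------------------------------------------
# set enrichment (weighted KS running sum)
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    es: float
    p: float
    n_perm: int
    leading_edge: list[str]
    seed: int
    weight: float


def _running_sum_es(
    order_stats: np.ndarray, hit_mask: np.ndarray, weight: float
) -> tuple[float, int]:
    """Signed extremum of the weighted KS running sum and its position."""
    n = len(order_stats)
    n_hit = int(hit_mask.sum())
    w = np.abs(order_stats) ** weight
    w_hit = np.where(hit_mask, w, 0.0)
    denom = w_hit.sum()
    if denom == 0:  # unweighted fallback: every hit counts equally
        w_hit = hit_mask.astype(float)
        denom = float(n_hit)
    inc = w_hit / denom
    dec = np.where(~hit_mask, 1.0 / (n - n_hit), 0.0)
    running = np.cumsum(inc - dec)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if abs(running[i_max]) >= abs(running[i_min]):
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


def enrichment_score(
    ranked_stats: pd.Series,
    signature: GeneSignature,
    n_perm: int = 999,
    seed: int = 0,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Weighted KS enrichment of a gene set in a ranked list.

    ``ranked_stats`` maps gene → ranking statistic; genes are sorted by
    decreasing statistic.  Hits increment the running sum proportionally to
    ``|stat|^weight``, misses decrement uniformly; the enrichment score ES
    is the signed extremum.  The null permutes the hit labels over the
    ranked genes; the two-sided p uses the add-one estimator on |ES|.
    """
    if ranked_stats.index.duplicated().any():
        raise ValueError("ranked list contains duplicate gene ids")
    in_set = ranked_stats.index.isin(signature.genes)
    if not in_set.any():
        raise ValueError("signature does not overlap the ranked list")
    if in_set.all():
        raise ValueError("signature covers the whole ranked list")

    order = np.argsort(-ranked_stats.to_numpy(dtype=float), kind="mergesort")
    stats_sorted = ranked_stats.to_numpy(dtype=float)[order]
    genes_sorted = ranked_stats.index.to_numpy()[order]
    hits = in_set[order]

    es, i_ext = _running_sum_es(stats_sorted, hits, weight)
    if es >= 0:
        leading = [g for g, h in zip(genes_sorted[: i_ext + 1], hits[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes_sorted[i_ext:], hits[i_ext:]) if h]

    rng = np.random.default_rng(seed)
    n = len(genes_sorted)
    n_hit = int(hits.sum())
    count = 0
    for _ in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_hit, replace=False)] = True
        es_star, _ = _running_sum_es(stats_sorted, mask, weight)
        if abs(es_star) >= abs(es) - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return EnrichmentResult(
        es=float(es), p=float(p), n_perm=n_perm, leading_edge=leading, seed=seed, weight=weight
    )


# ---------------------------------------------------------------------------
# cross-cohort gene / T-cell correlation analysis
# ---------------------------------------------------------------------------

@dataclass
class CohortCorrelationSummary:
    per_cohort: pd.DataFrame        # gene × cohort r and adj p (MultiIndex columns)
    negative_counts: pd.Series      # gene -> #cohorts with significant negative r
    selected: list[str]             # genes with count >= min_datasets
    min_datasets: int
    alpha: float
    n_cohorts: int
    excluded_cohorts: list[str] = field(default_factory=list)


def cross_cohort_gene_correlations(
    cohorts: dict[str, ExpressionMatrix],
    dz_signature: GeneSignature,
    tcell_signature: GeneSignature,
    min_datasets: int = 3,
    alpha: float = 0.05,
) -> CohortCorrelationSummary:
    """Count, per DZ-signature gene, the cohorts where it anti-correlates
    with T-cell content.

    In each cohort, every DZ gene's expression is correlated (Pearson)
    against the cohort's mean-z T-cell signature score; p-values are BH
    adjusted within the cohort, and a gene is flagged when the adjusted p
    is below ``alpha`` with a negative coefficient.  Genes flagged in at
    least ``min_datasets`` cohorts form the selected set.  Cohorts with
    fewer than 10 samples are excluded with a warning.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    excluded = [name for name, em in cohorts.items() if em.values.shape[1] < 10]
    if excluded:
        warnings.warn(f"excluding cohorts with < 10 samples: {excluded}", stacklevel=2)
    usable = {k: v for k, v in cohorts.items() if k not in excluded}
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable cohorts after the size filter")

    frames = {}
    flags = {}
    for name, em in usable.items():
        tscore = score_signature(em, tcell_signature, method="mean_z").to_numpy()
        genes = [g for g in dz_signature.genes if g in em.values.index]
        if not genes:
            raise ValueError(f"DZ signature does not overlap cohort {name!r}")
        X = em.values.loc[genes].to_numpy()
        n = X.shape[1]
        tz = (tscore - tscore.mean()) / tscore.std()
        Xm = X - X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xm @ tz) / (n * np.where(sd > 0, sd, np.nan))
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-15, None))
        p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
        p = np.where(np.isnan(r), 1.0, p)
        adj = multipletests(p, method="fdr_bh")[1]
        frames[name] = pd.DataFrame({"r": r, "adj_pvalue": adj}, index=pd.Index(genes, name="gene"))
        flags[name] = pd.Series((adj < alpha) & (r < 0), index=frames[name].index)

    per_cohort = pd.concat(frames, axis=1)
    flag_df = pd.concat(flags, axis=1).fillna(False)
    counts = flag_df.sum(axis=1).astype(int)
    counts = counts.reindex(dz_signature.genes, fill_value=0)
    selected = list(counts.index[counts >= min_datasets])
    return CohortCorrelationSummary(
        per_cohort=per_cohort,
        negative_counts=counts,
        selected=selected,
        min_datasets=min_datasets,
        alpha=alpha,
        n_cohorts=len(usable),
        excluded_cohorts=excluded,
    )


def dz_lz_group_assignment(
    dz_scores: pd.Series, lz_scores: pd.Series
) -> pd.Series:
    """Classify samples as DZ-like, LZ-like or Intermediate.

    The difference score Δ = standardized(DZ score) − standardized(LZ
    score) is split into tertiles: top third → ``DZ-like``, middle →
    ``Intermediate``, bottom → ``LZ-like``.  A reproducible, declared rule
    for a three-way grouping on two signature scores.
    """
    if len(dz_scores) != len(lz_scores):
        raise ValueError("score vectors have different lengths")
    dz = pd.Series(dz_scores)
    lz = pd.Series(lz_scores).reindex(dz.index)
    if lz.isna().any():
        raise ValueError("score vectors cover different samples")

    def z(s: pd.Series) -> pd.Series:
        sd = s.std(ddof=0)
        return (s - s.mean()) / sd if sd > 0 else s * 0.0

    delta = z(dz) - z(lz)
    tert = tertile_stratify(delta)
    mapping = {"high": "DZ-like", "mid": "Intermediate", "low": "LZ-like"}
    out = tert.map(mapping)
    out.name = "dz_lz_group"
    return out
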
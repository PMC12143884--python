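"""Comparative-translatome statistics for uORF-mediated buffering.

Works on tidy per-feature count tables (one row per feature x species x
sample [x replicate]) with columns::

    feature_id gene_id feature_type species sample mrna_count rpf_count
    len_nt mrna_libsize rpf_libsize

Translational efficiency (TE) of a feature is RPKM(Ribo-Seq P-sites) /
RPKM(mRNA). Between two species, ``beta = TE_sp2 / TE_sp1`` for a uORF
(beta_u) or its CDS (beta_c), and ``gamma = beta_c / beta_u``; on the log2
scale each is a difference of log2 TEs whose standard error propagates as a
root-sum-of-squares, giving Wald z tests with Benjamini-Hochberg FDR
control. ``|log2 gamma|`` large with ``log2 beta_c`` near zero while
``log2 beta_u`` moves is the signature of a buffered uORF-CDS pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "compute_rpkm",
    "compute_te",
    "add_te_columns",
    "estimate_se_log2te",
    "SESurface",
    "fit_se_surface",
    "beta_test",
    "gamma_test",
    "interspecies_divergence",
    "adjust_fdr",
    "screen_buffered_pairs",
    "find_dominant_uorf",
    "dominant_consistency_shuffle",
    "assign_gene_classes",
    "group_by_uorf_length",
    "cv_across_samples",
    "filter_expressed_genes",
    "high_expression_filter",
]

LN2 = np.log(2.0)
PSEUDOCOUNT = 0.1
EXPRESSED_RPKM = 0.1  # gene expressed: CDS mRNA RPKM > 0.1 in both species
TRANSLATED_TE = 0.1  # uORF translated: TE > 0.1


# ---------------------------------------------------------------------------
# TE primitives


def compute_rpkm(count, len_nt, libsize):
    """Reads per kilobase per million mapped reads: count * 1e9 / (len * libsize)."""
    count = np.asarray(count, dtype=float)
    len_nt = np.asarray(len_nt, dtype=float)
    libsize = np.asarray(libsize, dtype=float)
    if np.any(len_nt <= 0) or np.any(libsize <= 0):
        raise ValueError("len_nt and libsize must be positive")
    return count * 1e9 / (len_nt * libsize)


def compute_te(rpkm_rpf, rpkm_mrna):
    """TE = RPKM_rpf / RPKM_mrna with the zero-mRNA pseudocount rule.

    When the mRNA RPKM is 0 but the P-site RPKM is positive, 0.1 is added
    to both before dividing; when both are 0 the TE is undefined (NaN).
    """
    rpf = np.asarray(rpkm_rpf, dtype=float)
    mrna = np.asarray(rpkm_mrna, dtype=float)
    te = np.full(np.broadcast(rpf, mrna).shape, np.nan)
    rpf, mrna = np.broadcast_arrays(rpf, mrna)
    regular = mrna > 0
    te[regular] = rpf[regular] / mrna[regular]
    rescue = (mrna == 0) & (rpf > 0)
    te[rescue] = (rpf[rescue] + PSEUDOCOUNT) / PSEUDOCOUNT
    return te if te.ndim else float(te)


def add_te_columns(counts: pd.DataFrame) -> pd.DataFrame:
    """Append rpkm_mrna, rpkm_rpf, te and log2te columns to a counts table."""
    out = counts.copy()
    out["rpkm_mrna"] = compute_rpkm(out["mrna_count"], out["len_nt"], out["mrna_libsize"])
    out["rpkm_rpf"] = compute_rpkm(out["rpf_count"], out["len_nt"], out["rpf_libsize"])
    out["te"] = compute_te(out["rpkm_rpf"], out["rpkm_mrna"])
    with np.errstate(divide="ignore"):
        out["log2te"] = np.where(out["te"] > 0, np.log2(out["te"]), np.nan)
    return out


# ---------------------------------------------------------------------------
# log2TE standard errors


def _moment_dispersion(counts: np.ndarray, min_mean: float = 5.0) -> float:
    """Method-of-moments NB dispersion of one replicate set (unclipped).

    ``(s^2 - m) / m^2`` is unbiased for the dispersion under the NB
    mean-variance law; individual estimates are extremely noisy with few
    replicates (and often negative), so they are only meaningful averaged
    across many features. Low-count features are excluded.
    """
    m = counts.mean()
    if m < min_mean or len(counts) < 2:
        return np.nan
    v = counts.var(ddof=1)
    return (v - m) / m**2


def estimate_se_log2te(
    counts: pd.DataFrame,
    group_cols=("feature_id", "species", "sample"),
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-feature log2TE and its standard error from replicated counts.

    Replicate rows (a ``replicate`` column) are pooled per group. The
    variance follows a delta-method count model:
    ``Var(log2 TE) = (1/ln2)^2 (1/S_rpf + 1/S_mrna + 2 phi / R)`` with
    ``S`` the pooled counts, ``R`` the replicate number and ``phi`` a common
    negative-binomial dispersion (median of per-feature moment estimates
    over both channels unless supplied). Features with zero counts in every
    replicate of both channels are returned flagged with NaN estimates.
    """
    if "replicate" not in counts.columns:
        raise ValueError("replicated counts required: no 'replicate' column")
    group_cols = list(group_cols)
    n_rep = counts.groupby(group_cols)["replicate"].nunique()
    if (n_rep < 2).any():
        raise ValueError("every feature needs >= 2 replicates to estimate an SE")

    if dispersion is None:
        disps = []
        for _, g in counts.groupby(group_cols):
            disps.append(_moment_dispersion(g["mrna_count"].to_numpy(float)))
            disps.append(_moment_dispersion(g["rpf_count"].to_numpy(float)))
        disps = np.asarray(disps, dtype=float)
        disps = disps[np.isfinite(disps)]
        # mean across features keeps the estimator unbiased; clip the
        # aggregate (not the per-feature values) at zero
        dispersion = float(max(0.0, disps.mean())) if disps.size else 0.0

    agg = counts.groupby(group_cols).agg(
        mrna_count=("mrna_count", "sum"),
        rpf_count=("rpf_count", "sum"),
        mrna_libsize=("mrna_libsize", "sum"),
        rpf_libsize=("rpf_libsize", "sum"),
        len_nt=("len_nt", "first"),
        gene_id=("gene_id", "first") if "gene_id" in counts.columns else ("len_nt", "size"),
        n_rep=("replicate", "nunique"),
    ).reset_index()
    agg = add_te_columns(agg)
    s_rpf = agg["rpf_count"].to_numpy(float)
    s_mrna = agg["mrna_count"].to_numpy(float)
    r = agg["n_rep"].to_numpy(float)
    with np.errstate(divide="ignore"):
        var = (1.0 / LN2) ** 2 * (1.0 / s_rpf + 1.0 / s_mrna + 2.0 * dispersion / r)
    agg["se_log2te"] = np.sqrt(var)
    agg["flag_zero"] = (s_rpf == 0) & (s_mrna == 0)
    agg.loc[agg["flag_zero"], ["log2te", "se_log2te"]] = np.nan
    agg.attrs["dispersion"] = dispersion
    return agg


@dataclass
class SESurface:
    """Smooth additive SE predictor fitted on replicated samples.

    Predicts SE(log2 TE) from the mean normalized mRNA count and the log2 TE
    of a feature; used to impute SEs for samples without biological
    replicates. The fit is a Gaussian additive model with a log link over
    B-spline bases, so predictions are strictly positive. Inputs outside
    the training range are clipped to the boundary (``clipped`` flag).
    """

    _result: object
    _smoother: object
    lo: np.ndarray
    hi: np.ndarray

    def predict(self, mean_count, log2te, return_clipped: bool = False):
        x = np.column_stack(
            [np.log10(np.asarray(mean_count, dtype=float) + 1.0),
             np.asarray(log2te, dtype=float)]
        )
        clipped = (x < self.lo) | (x > self.hi)
        x = np.clip(x, self.lo, self.hi)
        basis = self._smoother.transform(x)
        exog = np.column_stack([np.ones(len(x)), basis])
        pred = np.exp(np.asarray(self._result.predict(exog)))
        if return_clipped:
            return pred, clipped.any(axis=1)
        return pred


def fit_se_surface(train: pd.DataFrame, min_features: int = 50) -> SESurface:
    """Fit log SE ~ s(log10 mean count) + s(log2 TE) over B-spline bases.

    Modeling the SE on the log scale keeps predictions strictly positive
    and makes the fit robust to the strongly right-skewed SE distribution.
    """
    from statsmodels.gam.api import BSplines
    import statsmodels.api as sm

    need = {"mean_count", "log2te", "se_log2te"}
    missing = need - set(train.columns)
    if missing:
        raise ValueError(f"training frame lacks columns {sorted(missing)}")
    train = train.dropna(subset=list(need))
    if len(train) < min_features:
        raise ValueError(f"need >= {min_features} training features, got {len(train)}")
    x = np.column_stack(
        [np.log10(train["mean_count"].to_numpy(float) + 1.0),
         train["log2te"].to_numpy(float)]
    )
    if np.ptp(x[:, 0]) == 0 or np.ptp(x[:, 1]) == 0:
        raise ValueError("degenerate training data: constant predictor")
    smoother = BSplines(x, df=[6, 6], degree=[3, 3], include_intercept=False)
    exog = np.column_stack([np.ones(len(x)), smoother.basis])
    y = train["se_log2te"].to_numpy(float)
    if np.any(y <= 0):
        raise ValueError("training SEs must be positive")
    result = sm.OLS(np.log(y), exog).fit()
    return SESurface(
        _result=result,
        _smoother=smoother,
        lo=x.min(axis=0),
        hi=x.max(axis=0),
    )


# ---------------------------------------------------------------------------
# Wald tests and FDR


def _wald(log2_effect: np.ndarray, se: np.ndarray):
    z = log2_effect / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    return z, p


def beta_test(log2te_1, se_1, log2te_2, se_2) -> pd.DataFrame:
    """Interspecific TE fold-change test for one feature set.

    log2 beta = log2 TE(species 2) - log2 TE(species 1);
    SE = sqrt(se_1^2 + se_2^2); two-sided Wald p from the standard normal.
    """
    se_1 = np.atleast_1d(np.asarray(se_1, dtype=float))
    se_2 = np.atleast_1d(np.asarray(se_2, dtype=float))
    if np.any(se_1 <= 0) or np.any(se_2 <= 0):
        raise ValueError("standard errors must be positive")
    log2_beta = np.atleast_1d(
        np.asarray(log2te_2, dtype=float) - np.asarray(log2te_1, dtype=float)
    )
    se = np.sqrt(se_1**2 + se_2**2)
    z, p = _wald(log2_beta, se)
    return pd.DataFrame({"log2_beta": log2_beta, "se_log2_beta": se, "z": z, "p": p})


def gamma_test(
    log2te_uorf_1, se_uorf_1, log2te_uorf_2, se_uorf_2,
    log2te_cds_1, se_cds_1, log2te_cds_2, se_cds_2,
) -> pd.DataFrame:
    """Differential-buffering test: is the CDS TE shift smaller than the uORF's?

    log2 gamma = log2 beta_c - log2 beta_u with the four-term
    root-sum-of-squares SE; gamma < 1 with beta_u > 1 means the CDS moved
    less than the uORF (buffering).
    """
    ses = [
        np.atleast_1d(np.asarray(s, dtype=float))
        for s in (se_uorf_1, se_uorf_2, se_cds_1, se_cds_2)
    ]
    if any(np.any(s <= 0) for s in ses):
        raise ValueError("standard errors must be positive")
    log2_beta_u = np.atleast_1d(
        np.asarray(log2te_uorf_2, dtype=float) - np.asarray(log2te_uorf_1, dtype=float)
    )
    log2_beta_c = np.atleast_1d(
        np.asarray(log2te_cds_2, dtype=float) - np.asarray(log2te_cds_1, dtype=float)
    )
    log2_gamma = log2_beta_c - log2_beta_u
    se = np.sqrt(sum(s**2 for s in ses))
    z, p = _wald(log2_gamma, se)
    return pd.DataFrame(
        {
            "log2_beta_u": log2_beta_u,
            "log2_beta_c": log2_beta_c,
            "log2_gamma": log2_gamma,
            "se_log2_gamma": se,
            "z": z,
            "p": p,
            "beta_u_gt_1": log2_beta_u > 0,
            "gamma_gt_1": log2_gamma > 0,
        }
    )


def interspecies_divergence(
    est: pd.DataFrame, species1: str = "sp1", species2: str = "sp2"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full two-species divergence analysis from per-feature TE estimates.

    ``est`` has one row per (feature_id, species) with columns feature_id,
    gene_id, feature_type, species, log2te, se_log2te (the output of
    :func:`estimate_se_log2te` joined with feature_type, or SE-surface
    imputations). Returns ``(beta, gamma)``:

    * ``beta`` — one row per feature present in both species: log2_beta,
      se, Wald z/p and BH q (adjusted within uORFs and CDSs separately);
    * ``gamma`` — one row per uORF-CDS pair (uORFs joined to their gene's
      CDS): log2_beta_u, log2_beta_c, log2_gamma, four-term SE, z, p, q
      and a ``pair_id`` ("<uorf>|<cds>").
    """
    need = {"feature_id", "gene_id", "feature_type", "species", "log2te", "se_log2te"}
    missing = need - set(est.columns)
    if missing:
        raise ValueError(f"estimate frame lacks columns {sorted(missing)}")
    wide = est.pivot_table(
        index=["feature_id", "gene_id", "feature_type"],
        columns="species",
        values=["log2te", "se_log2te"],
    )
    for sp in (species1, species2):
        if ("log2te", sp) not in wide.columns:
            raise ValueError(f"species {sp!r} absent from estimate frame")
    wide = wide.dropna(
        subset=[(v, sp) for v in ("log2te", "se_log2te") for sp in (species1, species2)]
    )
    res = beta_test(
        wide[("log2te", species1)], wide[("se_log2te", species1)],
        wide[("log2te", species2)], wide[("se_log2te", species2)],
    )
    res.index = wide.index
    beta = res.reset_index()
    beta["q"] = np.nan
    for _, sub in beta.groupby("feature_type"):
        beta.loc[sub.index, "q"] = adjust_fdr(sub["p"])

    flat = wide.reset_index()
    flat.columns = ["feature_id", "gene_id", "feature_type"] + [
        f"{v}_{sp}" for v, sp in wide.columns
    ]
    uorf = flat[flat["feature_type"] == "uORF"]
    cds = flat[flat["feature_type"] == "CDS"].set_index("gene_id")
    pairs = uorf.join(cds, on="gene_id", rsuffix="_cds", how="inner")
    gamma = gamma_test(
        pairs[f"log2te_{species1}"], pairs[f"se_log2te_{species1}"],
        pairs[f"log2te_{species2}"], pairs[f"se_log2te_{species2}"],
        pairs[f"log2te_{species1}_cds"], pairs[f"se_log2te_{species1}_cds"],
        pairs[f"log2te_{species2}_cds"], pairs[f"se_log2te_{species2}_cds"],
    )
    gamma.insert(
        0,
        "pair_id",
        (pairs["feature_id"].astype(str) + "|" + pairs["feature_id_cds"].astype(str)).to_numpy(),
    )
    gamma.insert(1, "gene_id", pairs["gene_id"].to_numpy())
    gamma.insert(2, "uorf_id", pairs["feature_id"].to_numpy())
    gamma["q"] = adjust_fdr(gamma["p"]) if len(gamma) else np.nan
    return beta, gamma


def adjust_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Buffered-pair screen


def screen_buffered_pairs(
    beta_u: pd.DataFrame,
    beta_c: pd.DataFrame,
    gamma: pd.DataFrame,
    lfc_u: float = 1.5,
    lfc_c: float = 0.05,
    lfc_gamma: float = 1.5,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Select uORF-CDS pairs where the uORF shifted but the CDS did not.

    Criteria (all on FDR-adjusted q): |log2 beta_u| > 1.5 with q < 0.05;
    |log2 beta_c| < 0.05 with q > 0.05; |log2 gamma| > 1.5 with q < 0.05.
    Inputs must each carry ``pair_id``, the effect column and ``q``.
    Returns (selected pairs, per-criterion pass counts).
    """
    for name, df in (("beta_u", beta_u), ("beta_c", beta_c), ("gamma", gamma)):
        if "pair_id" not in df.columns:
            raise ValueError(f"{name} frame lacks 'pair_id'")
    merged = (
        beta_u.rename(columns={"log2_beta": "log2_beta_u", "q": "q_u"})[
            ["pair_id", "log2_beta_u", "q_u"]
        ]
        .merge(
            beta_c.rename(columns={"log2_beta": "log2_beta_c", "q": "q_c"})[
                ["pair_id", "log2_beta_c", "q_c"]
            ],
            on="pair_id",
            how="outer",
            indicator=True,
        )
    )
    unmatched = merged.loc[merged["_merge"] != "both", "pair_id"].tolist()
    if unmatched:
        raise ValueError(f"unmatched pair ids between beta_u and beta_c: {unmatched}")
    merged = merged.drop(columns="_merge").merge(
        gamma.rename(columns={"q": "q_g"})[["pair_id", "log2_gamma", "q_g"]],
        on="pair_id",
        how="inner",
    )
    crit_u = (merged["log2_beta_u"].abs() > lfc_u) & (merged["q_u"] < alpha)
    crit_c = (merged["log2_beta_c"].abs() < lfc_c) & (merged["q_c"] > alpha)
    crit_g = (merged["log2_gamma"].abs() > lfc_gamma) & (merged["q_g"] < alpha)
    counts = {
        "uorf_shifted": int(crit_u.sum()),
        "cds_stable": int(crit_c.sum()),
        "gamma_significant": int(crit_g.sum()),
        "all_three": int((crit_u & crit_c & crit_g).sum()),
    }
    return merged[crit_u & crit_c & crit_g].reset_index(drop=True), counts


# ---------------------------------------------------------------------------
# Dominance, classes, grouping, CV


def find_dominant_uorf(te_by_uorf: pd.Series, starts: pd.Series | None = None):
    """The uORF with the highest TE in one sample; 5'-most start wins ties.

    ``te_by_uorf`` is indexed by uORF id; ``starts`` optionally maps ids to
    transcript start coordinates (without it, index order is the tie rule).
    Returns None when every TE is undefined.
    """
    te = te_by_uorf.dropna()
    if te.empty:
        return None
    best = te.max()
    winners = te.index[te == best]
    if len(winners) > 1 and starts is not None:
        return starts.loc[winners].idxmin()
    return winners[0]


def dominant_consistency_shuffle(
    te: pd.DataFrame,
    translated_te: float = TRANSLATED_TE,
    min_translated_samples: int = 5,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> dict:
    """Consistently dominant uORF usage vs a within-sample shuffle null.

    ``te`` is tidy: (gene_id, uorf_id, sample, te). Eligible genes have >= 2
    uORFs and at least one uORF translated (TE > threshold) in at least
    ``min_translated_samples`` samples. Observed statistic: eligible genes
    whose per-sample argmax-TE uORF is the same in every sample. Null: the
    same count after independently permuting each gene's uORF TEs within
    each sample, ``n_shuffles`` times; reported with its mean and 2.5/97.5
    percentile envelope.
    """
    import warnings

    if n_shuffles < 100:
        warnings.warn(f"n_shuffles={n_shuffles} < 100; null envelope will be coarse")
    wide = te.pivot_table(index=["gene_id", "uorf_id"], columns="sample", values="te")
    arrs, genes = [], []
    for gene, g in wide.groupby(level="gene_id"):
        if len(g) < 2:
            continue
        mat = g.to_numpy(float)  # uorfs x samples
        if (np.nansum(mat > translated_te, axis=1) >= min_translated_samples).any():
            arrs.append(mat)
            genes.append(gene)
    if not genes:
        return {"n_eligible": 0, "observed": 0, "null_mean": np.nan,
                "null_lo": np.nan, "null_hi": np.nan, "genes": []}

    def consistent(mats):
        count = 0
        flags = []
        for mat in mats:
            filled = np.where(np.isnan(mat), -np.inf, mat)
            valid = ~np.all(np.isnan(mat), axis=0)
            if not valid.any():
                flags.append(False)
                continue
            dom = filled[:, valid].argmax(axis=0)  # first max = 5'-most row
            ok = bool((dom == dom[0]).all())
            flags.append(ok)
            count += ok
        return count, flags

    observed, flags = consistent(arrs)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for b in range(n_shuffles):
        shuffled = []
        for mat in arrs:
            sh = mat.copy()
            for j in range(sh.shape[1]):
                rng.shuffle(sh[:, j])
            shuffled.append(sh)
        null[b] = consistent(shuffled)[0]
    return {
        "n_eligible": len(genes),
        "observed": observed,
        "null_mean": float(null.mean()),
        "null_lo": float(np.percentile(null, 2.5)),
        "null_hi": float(np.percentile(null, 97.5)),
        "genes": [g for g, ok in zip(genes, flags) if ok],
    }


def assign_gene_classes(uorf_flags: pd.DataFrame) -> pd.Series:
    """Class I/II/III labels from per-uORF conservation/translation/dominance.

    ``uorf_flags``: one row per (gene_id, uorf_id) with boolean columns
    conserved, translated_sp1, translated_sp2, dominant_sp1, dominant_sp2.
    Class I: some conserved uORF dominant in both species. Class II: some
    conserved uORF translated in both species, but no Class-I uORF.
    Class III: everything else (including genes without uORFs, passed as
    rows with uorf_id NA and flags False).
    """
    def classify(g: pd.DataFrame) -> str:
        cons = g["conserved"].fillna(False)
        if (cons & g["dominant_sp1"] & g["dominant_sp2"]).any():
            return "I"
        if (cons & g["translated_sp1"] & g["translated_sp2"]).any():
            return "II"
        return "III"

    return uorf_flags.groupby("gene_id").apply(classify, include_groups=False)


def group_by_uorf_length(total_translated_len: pd.Series) -> pd.Series:
    """Split genes into No / short / long translated-uORF length groups.

    Genes with zero total translated-uORF length are "No"; the rest split
    at their median (values at the median go to "short").
    """
    labels = pd.Series("No", index=total_translated_len.index, dtype=object)
    has = total_translated_len > 0
    if has.any():
        med = total_translated_len[has].median()
        labels[has & (total_translated_len <= med)] = "short"
        labels[has & (total_translated_len > med)] = "long"
    return labels


def cv_across_samples(
    te_wide: pd.DataFrame, group: pd.Series, paired: bool = False
) -> tuple[pd.DataFrame, dict]:
    """Per-gene CV of CDS TE across samples, compared between gene groups.

    ``te_wide``: genes x samples CDS TE. ``group``: boolean per gene (e.g.
    carries a translated uORF). Genes with fewer than 2 defined TEs or zero
    mean are excluded (tallied). Group CVs are compared by Wilcoxon
    rank-sum; with ``paired=True`` (ortholog pairs in matching row order)
    by signed-rank.
    """
    n_def = te_wide.notna().sum(axis=1)
    mean = te_wide.mean(axis=1)
    ok = (n_def >= 2) & (mean > 0)
    cv = te_wide[ok].std(axis=1, ddof=1) / mean[ok]
    res = pd.DataFrame({"cv": cv, "group": group[ok.index[ok]]})
    a = res.loc[res["group"], "cv"].to_numpy()
    b = res.loc[~res["group"], "cv"].to_numpy()
    if paired:
        stat, p = sps.wilcoxon(a, b)
        test = "signed-rank"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "rank-sum"
    summary = {
        "test": test,
        "statistic": float(stat),
        "p": float(p),
        "median_cv_with": float(np.median(a)) if a.size else np.nan,
        "median_cv_without": float(np.median(b)) if b.size else np.nan,
        "n_excluded": int((~ok).sum()),
    }
    return res, summary


# ---------------------------------------------------------------------------
# Expression filters


def filter_expressed_genes(te_table: pd.DataFrame, rpkm_thresh: float = EXPRESSED_RPKM):
    """Genes whose CDS mRNA RPKM exceeds the threshold in *both* species."""
    cds = te_table[te_table["feature_type"] == "CDS"]
    ok = (
        cds.groupby(["gene_id", "species"])["rpkm_mrna"].max().unstack()
        > rpkm_thresh
    )
    return set(ok.index[ok.all(axis=1).fillna(False)])


def high_expression_filter(te_table: pd.DataFrame) -> pd.DataFrame:
    """Keep features of genes with mRNA and RPF RPKM above the 50th percentile.

    The percentile is taken per species over CDS rows; a gene passes if its
    CDS clears both medians in every species present.
    """
    cds = te_table[te_table["feature_type"] == "CDS"]
    keep: set = set()
    by_species = []
    for sp, g in cds.groupby("species"):
        m_med = g["rpkm_mrna"].median()
        r_med = g["rpkm_rpf"].median()
        by_species.append(set(g.loc[(g["rpkm_mrna"] > m_med) & (g["rpkm_rpf"] > r_med), "gene_id"]))
    keep = set.intersection(*by_species) if by_species else set()
    return te_table[te_table["gene_id"].isin(keep)].reset_index(drop=True)
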
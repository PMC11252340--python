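"""Differential engines for count omics, proteomics and methylation.

Count layers (RNA-seq, ATAC-seq, ChIP-seq quantified on consensus peaks) are
tested with a negative-binomial GLM (log link, library-size offsets) and
two-sided Wald tests; dispersion is estimated by a transparent
method-of-moments estimator with a mean-dispersion trend and fixed 50/50
shrinkage.  Proteomics (log2 abundances) uses empirical-Bayes moderated
linear tests in the limma style, with technical replicates averaged first.
Methylation supports the pooled-CpG coverage filters and per-region mean
beta summaries.

The contrast battery mirrors a 4-group young/old x control/enriched design:

=================  ==========================================================
``ee_young``       YC vs YE (young samples only)
``ee_old``         OC vs OE (old samples only)
``ee_all_adj_age`` YC+OC vs YE+OE, age as additive covariate
``aging_ctrl``     YC vs OC (control samples only)
``aging_all_adj_env``  YC+YE vs OC+OE, environment as additive covariate
``oc_vs_rest``     OC vs YC+YE+OE (single indicator)
=================  ==========================================================

log2 fold changes are signed so that positive means higher in old (aging
contrasts), higher under enrichment (EE contrasts) or higher in old-control
(``oc_vs_rest``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

CONTRASTS = ["ee_young", "ee_old", "ee_all_adj_age", "aging_ctrl",
             "aging_all_adj_env", "oc_vs_rest"]

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Normalization and filtering
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_s = median over features (nonzero in all samples) of
    count_is / geometric-mean_i.
    """
    arr = counts.to_numpy(dtype=float)
    keep = (arr > 0).all(axis=1)
    if not keep.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; filter the matrix "
            "before computing size factors")
    logg = np.log(arr[keep]).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(arr[keep]) - logg)
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def filter_low_expression(counts: pd.DataFrame, samples: pd.DataFrame,
                          min_count_cpm_basis: float = 10.0
                          ) -> tuple[pd.DataFrame, dict]:
    """Drop features that are too weakly observed to test.

    A feature is kept when its CPM is at least
    ``min_count_cpm_basis / (median library size in millions)`` in at least
    as many samples as the size of the smallest design cell.  Returns the
    filtered matrix and a report with kept/dropped counts.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    med_lib_millions = np.median(lib) / 1e6
    cpm_cut = min_count_cpm_basis / med_lib_millions
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    groups = samples.groupby(["age", "env"])["sample"].count()
    min_group = int(groups.min())
    keep = (cpm >= cpm_cut).sum(axis=1) >= min_group
    if not keep.any():
        raise ValueError("expression filter removed all features")
    out = counts.loc[keep]
    return out, {"kept": int(keep.sum()), "dropped": int((~keep).sum()),
                 "cpm_cutoff": float(cpm_cut), "min_samples": min_group}


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionModel:
    raw: np.ndarray       # per-feature method-of-moments alpha
    trend_coef: tuple[float, float]   # alpha(mu) = a0 + a1/mu
    final: np.ndarray     # shrunk, floored at 1e-8
    base_mean: np.ndarray

    def trend(self, mu: np.ndarray) -> np.ndarray:
        a0, a1 = self.trend_coef
        return np.maximum(0.0, a0 + a1 / np.maximum(mu, 1e-8))


def estimate_dispersions(counts: pd.DataFrame, sf: pd.Series,
                         samples: pd.DataFrame | None = None) -> DispersionModel:
    """Method-of-moments NB dispersion with a mean trend and 50/50 shrinkage.

    Per-feature raw alpha is the df-weighted pooled estimate of
    max(0, (s^2 - mu) / mu^2) over the design cells (age x env groups when a
    sample sheet is given, otherwise all samples as one group) on normalized
    counts.  The trend alpha(mu) = a0 + a1/mu is fit by least squares on
    features with raw alpha > 0; final alpha = max(1e-8,
    0.5*raw + 0.5*trend(mu)).
    """
    q = counts.to_numpy(dtype=float) / sf.to_numpy()
    if samples is not None:
        key = samples.set_index("sample").loc[list(counts.columns)]
        labels = (key["age"].astype(str) + "/" + key["env"].astype(str)).to_numpy()
    else:
        labels = np.zeros(q.shape[1], dtype=int)
    num = np.zeros(q.shape[0])
    den = np.zeros(q.shape[0])
    for g in np.unique(labels):
        cols = labels == g
        n_g = int(cols.sum())
        if n_g < 2:
            continue
        mu_g = q[:, cols].mean(axis=1)
        s2_g = q[:, cols].var(axis=1, ddof=1)
        w = n_g - 1
        num += w * (s2_g - mu_g)
        den += w * np.maximum(mu_g, 1e-8) ** 2
    if not den.any():
        raise ValueError("need at least 2 samples in some group")
    raw = np.maximum(0.0, num / np.maximum(den, 1e-12))
    mu = q.mean(axis=1)
    pos = raw > 0
    if pos.sum() >= 2:
        X = np.column_stack([np.ones(pos.sum()), 1.0 / np.maximum(mu[pos], 1e-8)])
        coef, *_ = np.linalg.lstsq(X, raw[pos], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        a0, a1 = float(raw.mean()), 0.0
    model = DispersionModel(raw, (a0, a1), np.empty_like(raw), mu)
    model.final = np.maximum(1e-8, 0.5 * raw + 0.5 * model.trend(mu))
    return model


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def design_matrix(samples: pd.DataFrame, contrast: str
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Model matrix and sample mask for a named contrast.

    The coefficient of interest is always column 1; adjusted contrasts carry
    the other factor as an additive covariate.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {CONTRASTS}")
    age = (samples["age"] == "old").to_numpy(dtype=float)
    env = (samples["env"] == "ee").to_numpy(dtype=float)
    if contrast == "ee_young":
        mask = samples["age"].to_numpy() == "young"
        X = np.column_stack([np.ones(mask.sum()), env[mask]])
    elif contrast == "ee_old":
        mask = samples["age"].to_numpy() == "old"
        X = np.column_stack([np.ones(mask.sum()), env[mask]])
    elif contrast == "ee_all_adj_age":
        mask = np.ones(len(samples), dtype=bool)
        X = np.column_stack([np.ones(len(samples)), env, age])
    elif contrast == "aging_ctrl":
        mask = samples["env"].to_numpy() == "ctrl"
        X = np.column_stack([np.ones(mask.sum()), age[mask]])
    elif contrast == "aging_all_adj_env":
        mask = np.ones(len(samples), dtype=bool)
        X = np.column_stack([np.ones(len(samples)), age, env])
    else:  # oc_vs_rest
        mask = np.ones(len(samples), dtype=bool)
        oc = ((samples["age"] == "old") & (samples["env"] == "ctrl")).to_numpy(float)
        X = np.column_stack([np.ones(len(samples)), oc])
    groups = X[:, 1]
    for v in np.unique(groups):
        if (groups == v).sum() < 2:
            raise ValueError(
                f"contrast {contrast!r} needs >=2 samples per compared cell")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"model matrix for {contrast!r} is rank deficient")
    return X, mask


# ---------------------------------------------------------------------------
# NB GLM Wald test
# ---------------------------------------------------------------------------

def _nb_irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
             tol: float = 1e-8, max_iter: int = 100
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for NB GLMs with log link and per-feature dispersion.

    y: (F, n) counts; X: (n, p); offset: (n,); alpha: (F,).
    Returns (beta (F, p), se (F, p), converged (F,)).  Iterations use
    Fisher-scoring (expected-information) weights mu/(1+alpha*mu); standard
    errors come from the observed Fisher information at the final estimate.
    """
    F, n = y.shape
    p = X.shape[1]
    a = alpha[:, None]
    # weighted least squares init on log counts
    z0 = np.log(y + 0.5) - offset[None, :]
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ z0.T).T  # (F, p)
    converged = np.zeros(F, dtype=bool)
    active = np.ones(F, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        eta = offset[None, :] + beta[idx] @ X.T
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + a[idx] * mu)              # (f, n)
        z = eta - offset[None, :] + (y[idx] - mu) / mu
        XtWX = np.einsum("ni,fn,nj->fij", X, W, X)
        XtWz = np.einsum("ni,fn,fn->fi", X, W, z)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        new = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        delta = np.abs(new - beta[idx]).max(axis=1)
        beta[idx] = new
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    # observed information: w_obs = mu (1 + alpha y) / (1 + alpha mu)^2
    eta = np.clip(offset[None, :] + beta @ X.T, -30.0, 30.0)
    mu = np.exp(eta)
    w_obs = mu * (1.0 + a * y) / (1.0 + a * mu) ** 2
    H = np.einsum("ni,fn,nj->fij", X, w_obs, X) + 1e-10 * np.eye(p)[None, :, :]
    cov = np.linalg.inv(H)
    var = np.einsum("fii->fi", cov)
    se = np.sqrt(np.maximum(var, 0.0))
    return beta, se, converged


def nb_wald_test(counts: pd.DataFrame, samples: pd.DataFrame, contrast: str,
                 dispersions: DispersionModel | None = None,
                 sf: pd.Series | None = None) -> pd.DataFrame:
    """Two-sided NB GLM Wald test for one contrast.

    Returns a DiffResult table indexed by feature_id with columns
    ``base_mean``, ``log2fc``, ``se``, ``stat``, ``p``, ``padj``,
    ``converged``, ``contrast``.  Non-converged features keep their estimate
    but get missing p-values and are excluded from BH.
    """
    if sf is None:
        sf = size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, sf, samples)
    X, mask = design_matrix(samples, contrast)
    sub = counts.loc[:, samples.loc[mask, "sample"]]
    y = sub.to_numpy(dtype=float)
    offset = np.log(sf.to_numpy()[mask])
    beta, se, conv = _nb_irls(y, X, offset, dispersions.final)
    b1, s1 = beta[:, 1], se[:, 1]
    stat = np.where(s1 > 0, b1 / np.maximum(s1, 1e-300), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(stat))
    p = np.where(conv, p, np.nan)
    res = pd.DataFrame({
        "base_mean": (y / np.exp(offset)[None, :]).mean(axis=1),
        "log2fc": b1 / LN2,
        "se": s1 / LN2,
        "stat": stat,
        "p": p,
        "padj": bh_adjust(p),
        "converged": conv,
        "contrast": contrast,
    }, index=counts.index.rename("feature_id"))
    return res.sort_index()


def run_contrasts(counts: pd.DataFrame, samples: pd.DataFrame,
                  contrasts: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Run the full contrast battery on a count matrix (shared size factors
    and dispersions)."""
    sf = size_factors(counts)
    disp = estimate_dispersions(counts, sf, samples)
    out = {}
    for c in contrasts or CONTRASTS:
        out[c] = nb_wald_test(counts, samples, c, disp, sf)
    return out


# ---------------------------------------------------------------------------
# Moderated linear tests (proteomics)
# ---------------------------------------------------------------------------

def average_techreps(matrix: pd.DataFrame, samples: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average technical replicates into biological replicates (log2 scale).

    The sample sheet must carry a ``techrep_group`` column covering every
    matrix column; the returned sheet is collapsed to one row per group.
    """
    if "techrep_group" not in samples.columns:
        raise ValueError("sample sheet lacks a techrep_group column")
    key = samples.set_index("sample")
    missing = [c for c in matrix.columns if c not in key.index]
    if missing:
        raise ValueError(f"samples missing from sheet: {missing}")
    groups = key.loc[list(matrix.columns), "techrep_group"]
    counts = groups.value_counts()
    if (counts < 1).any():
        raise ValueError("technical replicate group with zero members")
    collapsed = matrix.T.groupby(groups.to_numpy()).mean().T
    sheet = (samples.drop_duplicates("techrep_group")
             .drop(columns=["sample"])
             .rename(columns={"techrep_group": "sample"})
             [["sample", "age", "env", "replicate"]]
             .reset_index(drop=True))
    collapsed = collapsed[sheet["sample"].tolist()]
    return collapsed, sheet


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0^2) by moment matching of log s^2
    (digamma/trigamma inversion as in moderated-t practice).

    Returns (d0, s0sq); d0 = inf when the observed spread of log s^2 is no
    larger than the chi^2 sampling spread.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    n = len(e)
    var_e = ((e - ebar) ** 2).sum() / (n - 1) if n > 1 else 0.0
    excess = var_e - special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(ebar))
    # invert trigamma(d0/2) = excess by Newton on x = d0/2
    x = 0.5 + 1.0 / excess
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (tri - excess) / special.polygamma(2, x)
        x = max(x - step, 1e-8)
        if abs(tri - excess) < 1e-12:
            break
    d0 = 2.0 * x
    s0sq = float(np.exp(ebar + special.digamma(x) - np.log(x)))
    return float(d0), s0sq


def moderated_linear_test(matrix: pd.DataFrame, samples: pd.DataFrame,
                          contrast: str, d0_override: float | None = None
                          ) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test on a log2 abundance matrix.

    Per-protein OLS for the contrast; residual variances are shrunk toward a
    moment-matched prior, and the moderated t is referred to a t distribution
    with d0 + d_i degrees of freedom.  ``d0_override`` fixes the prior df
    (useful for checking the d0 -> 0 / d0 -> inf limits).
    """
    X, mask = design_matrix(samples, contrast)
    sub = matrix.loc[:, samples.loc[mask, "sample"]]
    Y = sub.to_numpy(dtype=float)
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise ValueError("insufficient replication: zero residual df")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv.T          # (F, p)
    resid = Y - B @ X.T
    s2 = (resid ** 2).sum(axis=1) / df
    if d0_override is not None:
        d0 = float(d0_override)
        _, s0sq = _squeeze_var(s2, df)
    else:
        d0, s0sq = _squeeze_var(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = d0 + df
    c11 = XtX_inv[1, 1]
    se = np.sqrt(np.maximum(s2_post * c11, 1e-300))
    t = B[:, 1] / se
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    res = pd.DataFrame({
        "base_mean": Y.mean(axis=1),
        "log2fc": B[:, 1],
        "se": se,
        "stat": t,
        "p": pvals,
        "padj": bh_adjust(pvals),
        "d0": d0,
        "contrast": contrast,
    }, index=matrix.index.rename("feature_id"))
    return res.sort_index()


def halflife_normalize(matrix: pd.DataFrame, halflives: pd.Series
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Divide log2 protein measurements by the protein half-life.

    Proteins with missing or non-positive half-life are dropped; their ids
    are returned alongside the normalized matrix.
    """
    hl = halflives.reindex(matrix.index)
    bad = hl.isna() | ~np.isfinite(hl) | (hl <= 0)
    dropped = matrix.index[bad].tolist()
    keep = matrix.loc[~bad]
    out = keep.div(hl.loc[~bad], axis=0)
    return out, dropped


# ---------------------------------------------------------------------------
# Methylation summaries
# ---------------------------------------------------------------------------

def filter_cpgs(meth: pd.DataFrame, min_total: int = 10,
                max_quantile: float = 0.999) -> pd.DataFrame:
    """Coverage filters on pooled CpG counts.

    Keeps rows with total >= ``min_total`` and total <= that sample's
    ``max_quantile`` coverage percentile, and adds a ``beta`` column
    (methylated / total, on [0, 1]).
    """
    out = []
    for sid, sub in meth.groupby("sample", sort=True):
        # smallest observed coverage with cumulative fraction >= the cutoff,
        # so only sites strictly above the empirical percentile are removed
        hi = sub["total"].quantile(max_quantile, interpolation="higher")
        keep = sub[(sub["total"] >= min_total) & (sub["total"] <= hi)].copy()
        keep["beta"] = keep["meth"] / keep["total"]
        out.append(keep)
    return pd.concat(out, ignore_index=True)


def region_methylation(cpgs: pd.DataFrame, regions) -> tuple[pd.DataFrame, list[str]]:
    """Per-region, per-sample unweighted mean beta of covered CpGs.

    Returns a regions x samples DataFrame (NaN where no CpG is covered) and
    the list of region ids with no covered CpG in any sample.
    """
    rdf = regions.df
    ids = (rdf["name"].astype(str).to_numpy() if "name" in rdf.columns
           else np.array([f"r{i}" for i in range(len(rdf))], dtype=object))
    samples = sorted(cpgs["sample"].unique())
    out = pd.DataFrame(np.nan, index=pd.Index(ids, name="region_id"), columns=samples)
    by_chrom = {c: g for c, g in cpgs.groupby("chrom")}
    for (chrom, s, e), rid in zip(
            rdf[["chrom", "start", "end"]].itertuples(index=False, name=None), ids):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        inside = sub[(sub["pos"] >= s) & (sub["pos"] < e)]
        if inside.empty:
            continue
        means = inside.groupby("sample")["beta"].mean()
        out.loc[rid, means.index] = means.to_numpy()
    empty = out.index[out.isna().all(axis=1)].tolist()
    return out, empty


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals, family: str | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up with enforced monotonicity.

    Missing values are ignored and returned missing; the ``family`` label is
    provenance only (adjustment is always confined to the vector given).
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    vals = np.empty(m)
    vals[order] = adj
    out[ok] = vals
    return out


def diffresult_to_tsv(res: pd.DataFrame, path) -> None:
    """Write a DiffResult in the package's column order, sorted by id."""
    cols = ["base_mean", "log2fc", "se", "stat", "p", "padj", "contrast"]
    res.sort_index()[[c for c in cols if c in res.columns]].to_csv(path, sep="\t")
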
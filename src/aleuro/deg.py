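"""Paired-design consensus differential expression by two testing paths.

Aleurone vs starchy endosperm contrasts are tested per timepoint with two
independently implemented methods and only genes called by both are kept:

1. A negative-binomial generalized linear model with log link and a
   likelihood-ratio test on the tissue coefficient.  The NB dispersion phi
   (Var = mu + phi mu^2) is estimated in three stages: a common value
   maximizing the summed Cox-Reid adjusted profile likelihood (APL), a
   lowess trend of per-gene estimates against average log-CPM, and tagwise
   values that shrink each gene's APL toward a locally shared APL with a
   fixed prior df.
2. A precision-weighted linear model on log2-CPM: observation-level inverse
   variance weights are read off a lowess fit of sqrt residual standard
   deviation against log-count abundance, followed by empirical-Bayes
   moderation of the gene-wise variances (method of moments on log residual
   variances) and a moderated t-test.

Both paths share trimmed-mean-of-M-values (TMM) normalization factors and
Benjamini-Hochberg FDR control.  The consensus rule requires FDR <= alpha,
|log2 fold change| > log2(min_fold) and agreeing direction in *both* paths;
consensus genes whose mean TPM is zero in either tissue at the tested
timepoint are then eliminated as too sparsely sampled to trust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from aleuro.containers import CountMatrix
from aleuro.expression import TpmTable

_MAX_IRLS = 50
_IRLS_TOL = 1e-8
_PHI_GRID = np.concatenate(([1e-6], np.logspace(-4, 0.7, 24)))


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """Paired two-condition design: intercept + block dummies + condition.

    The condition column codes AL = 1, ST = 0, so positive coefficients mean
    higher expression in aleurone.  ``reduced`` drops the condition column.
    """

    matrix: np.ndarray
    reduced: np.ndarray
    condition_index: int
    sample_ids: pd.Index
    condition: pd.Series

    @classmethod
    def from_samples(cls, samples: pd.DataFrame) -> "DesignSpec":
        blocks = samples["replicate_block"]
        tissue = samples["tissue"]
        for b, sub in samples.groupby("replicate_block"):
            tset = sorted(sub["tissue"])
            if tset != ["AL", "ST"]:
                raise ValueError(
                    f"block {b!r} must pair one AL with one ST sample, "
                    f"got {tset}")
        block_levels = sorted(blocks.unique())
        n = len(samples)
        cols = [np.ones(n)]
        for b in block_levels[1:]:
            cols.append((blocks == b).to_numpy(float))
        cond = (tissue == "AL").to_numpy(float)
        cols.append(cond)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is not full rank")
        return cls(matrix=X, reduced=X[:, :-1], condition_index=X.shape[1] - 1,
                   sample_ids=samples.index,
                   condition=pd.Series(cond, index=samples.index))

    @property
    def residual_df(self) -> int:
        return self.matrix.shape[0] - self.matrix.shape[1]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormFactors:
    """Per-sample TMM scaling factors with geometric mean 1."""

    factors: pd.Series
    library_sizes: pd.Series

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.factors * self.library_sizes


def tmm_factors(cm: CountMatrix, log_ratio_trim: float = 0.3,
                abs_expr_trim: float = 0.05) -> NormFactors:
    """Trimmed mean of M-values normalization factors.

    The reference sample is the column whose upper quartile of scaled counts
    is closest to the mean upper quartile.  For every other sample, gene-wise
    log ratios M and average abundances A (both vs the reference, on the
    library-scaled counts) are doubly trimmed (30% on M, 5% on A by default)
    and the factor is 2 to the precision-weighted mean of the surviving M
    values.  Factors are rescaled to geometric mean 1.
    """
    y = cm.counts.to_numpy(float)
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = cm.sample_ids[lib == 0]
        raise ValueError(f"all-zero sample(s): {list(bad)}")
    scaled = y / lib
    uq = np.array([np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0
                   for col in scaled.T])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(y.shape[1])
    yr, nr = y[:, ref], lib[ref]
    for i in range(y.shape[1]):
        if i == ref:
            continue
        yi, ni = y[:, i], lib[i]
        ok = (yi > 0) & (yr > 0)
        if ok.sum() == 0:
            continue
        pi, pr = yi[ok] / ni, yr[ok] / nr
        m = np.log2(pi / pr)
        a = 0.5 * np.log2(pi * pr)
        fin = np.isfinite(m) & np.isfinite(a)
        m, a = m[fin], a[fin]
        w = (ni - yi[ok][fin]) / (ni * yi[ok][fin]) \
            + (nr - yr[ok][fin]) / (nr * yr[ok][fin])
        lo_m, hi_m = np.quantile(m, [log_ratio_trim, 1 - log_ratio_trim])
        lo_a, hi_a = np.quantile(a, [abs_expr_trim, 1 - abs_expr_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if keep.sum() == 0 or not np.isfinite(m[keep]).any():
            continue
        with np.errstate(divide="ignore"):
            wk = 1.0 / w[keep]
        factors[i] = 2.0 ** (np.sum(wk * m[keep]) / np.sum(wk))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        factors=pd.Series(factors, index=cm.sample_ids, name="tmm_factor"),
        library_sizes=pd.Series(lib, index=cm.sample_ids,
                                name="library_size"))


def average_log_cpm(cm: CountMatrix,
                    factors: NormFactors | None = None) -> pd.Series:
    """log2 CPM of the pooled counts (abundance axis for trend fits)."""
    lib = (factors.effective_library_sizes if factors is not None
           else cm.library_sizes)
    pooled = cm.counts.sum(axis=1) + 0.5
    return np.log2(pooled / (float(lib.sum()) + 1.0) * 1e6)


def filter_expressed(cm: CountMatrix, min_count: int = 10,
                     min_samples: int | None = None) -> CountMatrix:
    """Drop genes too sparsely observed to test.

    Keeps genes with at least ``min_count`` reads in at least ``min_samples``
    samples (default: the smallest tissue group size).
    """
    if min_samples is None:
        min_samples = int(cm.samples.groupby("tissue").size().min())
    keep = (cm.counts >= min_count).sum(axis=1) >= min_samples
    return CountMatrix(cm.counts.loc[keep], cm.gene_lengths, cm.samples)


# ---------------------------------------------------------------------------
# NB GLM machinery
# ---------------------------------------------------------------------------

def _nb_loglik(y, mu, phi):
    """Row-wise NB log likelihood; phi may be scalar or (G, 1)."""
    mu = np.clip(mu, 1e-10, None)
    phi = np.asarray(phi, float)
    if phi.ndim == 1:
        phi = phi[:, None]
    out = np.empty_like(mu)
    pois = np.broadcast_to(phi == 0, mu.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        out_p = y * np.log(mu) - mu - special.gammaln(y + 1.0)
        r = np.where(phi > 0, 1.0 / np.where(phi > 0, phi, 1.0), 1.0)
        out_nb = (special.gammaln(y + r) - special.gammaln(r)
                  - special.gammaln(y + 1.0)
                  + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    out = np.where(pois, out_p, out_nb)
    return out.sum(axis=1)


def _irls_nb(y, X, offset, phi):
    """Vectorized IRLS NB log-link fit for all genes at once.

    Parameters: y (G, n), X (n, p), offset (n,) or (G, n),
    phi scalar or (G,).  Returns (beta (G, p), mu (G, n), converged (G,)).
    """
    G, n = y.shape
    p = X.shape[1]
    phi_col = np.broadcast_to(np.asarray(phi, float), (G,))[:, None]
    offset = np.broadcast_to(offset, (G, n))

    # initialize from a log-linear fit on shifted counts
    z0 = np.log(np.maximum(y, 0.5)) - offset
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, p)

    eye = np.eye(p) * 1e-10
    dev_old = np.full(G, np.inf)
    converged = np.zeros(G, dtype=bool)
    for _ in range(_MAX_IRLS):
        eta = offset + beta @ X.T
        eta = np.clip(eta, offset - 30.0, offset + 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi_col * mu)
        z = (eta - offset) + (y - mu) / mu
        A = np.einsum("gn,ni,nj->gij", w, X, X) + eye
        b = np.einsum("gn,ni->gi", w * z, X)
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        dev = -2.0 * _nb_loglik(y, mu, phi_col)
        delta = np.abs(dev - dev_old) / (np.abs(dev) + 0.1)
        newly = delta < _IRLS_TOL
        converged |= newly
        if converged.all():
            break
        dev_old = dev
    eta = np.clip(offset + beta @ X.T, offset - 30.0, offset + 30.0)
    mu = np.exp(eta)
    return beta, mu, converged


def _adjusted_profile_loglik(y, X, offset, phi):
    """Cox-Reid adjusted profile log likelihood per gene at dispersion phi."""
    G = y.shape[0]
    phi_col = np.broadcast_to(np.asarray(phi, float), (G,))[:, None]
    _, mu, _ = _irls_nb(y, X, offset, phi)
    ll = _nb_loglik(y, mu, phi_col)
    w = mu / (1.0 + phi_col * mu)
    A = np.einsum("gn,ni,nj->gij", w, X, X) + np.eye(X.shape[1]) * 1e-10
    _, logdet = np.linalg.slogdet(A)
    return ll - 0.5 * logdet


def _parabolic_argmax(xs, ys):
    """Refine a grid argmax with one parabolic interpolation step."""
    i = int(np.argmax(ys))
    if i == 0 or i == len(xs) - 1:
        return xs[i]
    x0, x1, x2 = xs[i - 1], xs[i], xs[i + 1]
    y0, y1, y2 = ys[i - 1], ys[i], ys[i + 1]
    num = (x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)
    den = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if den == 0 or not np.isfinite(den):
        return x1
    x_star = x1 - 0.5 * num / den
    return float(np.clip(x_star, x0, x2))


@dataclass
class DispersionEstimates:
    common: float
    trended: pd.Series
    tagwise: pd.Series
    ave_log_cpm: pd.Series


def estimate_dispersion(cm: CountMatrix, design: DesignSpec,
                        factors: NormFactors | None = None,
                        prior_df: float = 10.0,
                        trend_span: float = 0.5) -> DispersionEstimates:
    """Common, trended and tagwise NB dispersions via Cox-Reid APL.

    The common value maximizes the APL summed over genes; the trend is a
    lowess of per-gene APL maximizers against average log-CPM; tagwise
    values maximize each gene's APL plus ``prior_df / residual_df`` times a
    locally shared APL (moving average over abundance-sorted neighbours),
    squeezing noisy per-gene estimates toward their neighbourhood.
    """
    if design.residual_df < 1:
        raise ValueError(
            "zero residual degrees of freedom: pool replicates or simplify "
            "the design")
    if factors is None:
        factors = tmm_factors(cm)
    y = cm.counts.loc[:, design.sample_ids].to_numpy(float)
    nonzero = y.sum(axis=1) > 0
    offset = np.log(factors.effective_library_sizes
                    .loc[design.sample_ids].to_numpy())
    X = design.matrix

    yz = y[nonzero]
    grid = _PHI_GRID
    apl = np.column_stack([
        _adjusted_profile_loglik(yz, X, offset, g) for g in grid])

    log_grid = np.log(grid)
    common = float(np.exp(_parabolic_argmax(log_grid, apl.sum(axis=0))))

    alc = average_log_cpm(cm, factors)
    alc_z = alc.to_numpy()[nonzero]

    per_gene = np.exp([_parabolic_argmax(log_grid, row) for row in apl])
    fit = lowess(np.log(per_gene), alc_z, frac=trend_span,
                 return_sorted=False)
    trended_z = np.exp(fit)

    # locally shared APL: moving average over abundance-sorted genes
    order = np.argsort(alc_z, kind="mergesort")
    window = min(len(order), max(5, int(round(0.1 * len(order)))))
    sorted_apl = apl[order]
    kernel = np.ones(window) / window
    shared_sorted = np.apply_along_axis(
        lambda col: np.convolve(col, kernel, mode="same"), 0, sorted_apl)
    shared = np.empty_like(sorted_apl)
    shared[order] = shared_sorted
    prior_n = prior_df / design.residual_df
    weighted = apl + prior_n * shared
    tagwise_z = np.exp([_parabolic_argmax(log_grid, row) for row in weighted])

    genes = cm.genes
    trended = pd.Series(common, index=genes, name="trended", dtype=float)
    tagwise = pd.Series(common, index=genes, name="tagwise", dtype=float)
    trended.iloc[np.flatnonzero(nonzero)] = trended_z
    tagwise.iloc[np.flatnonzero(nonzero)] = tagwise_z
    return DispersionEstimates(common=common, trended=trended,
                               tagwise=tagwise, ave_log_cpm=alc)


def nb_glm_lrt(cm: CountMatrix, design: DesignSpec, dispersion,
               factors: NormFactors | None = None) -> pd.DataFrame:
    """Likelihood-ratio test of the tissue coefficient per gene.

    ``dispersion`` may be a scalar or a per-gene Series (held fixed during
    fitting, as in the usual two-stage scheme).  Returns a DataFrame with
    columns log2fc, dispersion, lr_stat, p_nb and converged; non-converged
    genes get p = NaN.
    """
    if factors is None:
        factors = tmm_factors(cm)
    y = cm.counts.loc[:, design.sample_ids].to_numpy(float)
    offset = np.log(factors.effective_library_sizes
                    .loc[design.sample_ids].to_numpy())
    if np.isscalar(dispersion):
        phi = np.full(y.shape[0], float(dispersion))
    else:
        phi = pd.Series(dispersion).loc[cm.genes].to_numpy(float)

    beta_full, mu_full, conv_full = _irls_nb(y, design.matrix, offset, phi)
    _, mu_red, conv_red = _irls_nb(y, design.reduced, offset, phi)
    ll_full = _nb_loglik(y, mu_full, phi)
    ll_red = _nb_loglik(y, mu_red, phi)
    lr = np.clip(2.0 * (ll_full - ll_red), 0.0, None)
    p = stats.chi2.sf(lr, df=1)
    converged = conv_full & conv_red
    p = np.where(converged, p, np.nan)
    log2fc = beta_full[:, design.condition_index] / np.log(2.0)
    return pd.DataFrame({"log2fc": log2fc, "dispersion": phi,
                         "lr_stat": lr, "p_nb": p, "converged": converged},
                        index=cm.genes)


# ---------------------------------------------------------------------------
# log-CPM + precision weights path
# ---------------------------------------------------------------------------

def voom_transform(cm: CountMatrix, design: DesignSpec,
                   factors: NormFactors | None = None,
                   span: float = 0.5):
    """log2-CPM with observation-level inverse-variance precision weights.

    log-CPM = log2((count + 0.5) / (effective libsize + 1) * 1e6).  Gene-wise
    linear models give residual standard deviations; a lowess of sqrt(sd)
    against average log2 count yields the mean-variance trend, and each
    observation's weight is the inverse of the trend's predicted variance at
    its fitted log-count.
    """
    if factors is None:
        factors = tmm_factors(cm)
    y = cm.counts.loc[:, design.sample_ids].to_numpy(float)
    lib = factors.effective_library_sizes.loc[design.sample_ids].to_numpy()
    logcpm = np.log2((y + 0.5) / (lib + 1.0) * 1e6)

    X = design.matrix
    H, *_ = np.linalg.lstsq(X, logcpm.T, rcond=None)
    fitted = (X @ H).T
    resid = logcpm - fitted
    d = X.shape[0] - X.shape[1]
    sigma = np.sqrt((resid ** 2).sum(axis=1) / d)

    # abundance axis in log2 counts
    sx = logcpm.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    ok = np.isfinite(sx) & np.isfinite(sy) & (sigma > 0)
    trend = lowess(sy[ok], sx[ok], frac=span)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)

    fitted_counts = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_counts, tx, ty)
    weights = 1.0 / pred_sqrt_sd ** 4
    logcpm_df = pd.DataFrame(logcpm, index=cm.genes,
                             columns=design.sample_ids)
    weights_df = pd.DataFrame(weights, index=cm.genes,
                              columns=design.sample_ids)
    return logcpm_df, weights_df


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-8:
            break
    return float(y)


def moderated_t_test(logcpm: pd.DataFrame, weights: pd.DataFrame,
                     design: DesignSpec) -> pd.DataFrame:
    """Weighted least squares plus empirical-Bayes variance moderation.

    Hyperparameters (prior df d0, prior variance s0^2) come from a closed
    form method of moments on the log residual variances; the posterior
    variance is ``(d0 s0^2 + d s^2) / (d0 + d)`` and the moderated t has
    ``d0 + d`` degrees of freedom.  If the moments imply no excess spread
    (d0 non-finite), all posterior variances equal the prior.
    """
    X = design.matrix
    n, p = X.shape
    d = n - p
    if d < 1:
        raise ValueError("residual df must be >= 1")
    Y = logcpm.to_numpy(float)
    W = weights.to_numpy(float)
    G = Y.shape[0]
    ci = design.condition_index

    A = np.einsum("gn,ni,nj->gij", W, X, X)
    b = np.einsum("gn,ni->gi", W * Y, X)
    Ainv = np.linalg.inv(A)
    beta = np.einsum("gij,gj->gi", Ainv, b)
    fitted = beta @ X.T
    s2 = (W * (Y - fitted) ** 2).sum(axis=1) / d
    unscaled = np.sqrt(Ainv[:, ci, ci])
    coef = beta[:, ci]

    # method of moments on log residual variances (F-distribution fit)
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = e.mean()
    n_ok = len(e)
    e_var = (e - e_mean) @ (e - e_mean) / (n_ok - 1) if n_ok > 1 else 0.0
    excess = e_var - special.polygamma(1, d / 2.0)
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))

    if np.isfinite(d0):
        s2_safe = np.where(ok, s2, 0.0)
        post_var = (d0 * s0_sq + d * s2_safe) / (d0 + d)
        df_total = d0 + d
    else:
        post_var = np.full(G, s0_sq)
        df_total = np.inf
    t = coef / (unscaled * np.sqrt(post_var))
    if np.isfinite(df_total):
        p_lm = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p_lm = 2.0 * stats.norm.sf(np.abs(t))
    return pd.DataFrame({"coef": coef, "t_moderated": t, "p_lm": p_lm,
                         "s2_post": post_var, "prior_df": d0,
                         "prior_var": s0_sq}, index=logcpm.index)


# ---------------------------------------------------------------------------
# FDR and consensus
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN passes through."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def call_consensus_degs(nb_results: pd.DataFrame, lm_results: pd.DataFrame,
                        tpm: TpmTable, timepoint: int,
                        alpha: float = 0.05, min_fold: float = 2.0,
                        elimination: str = "tissue_mean") -> pd.DataFrame:
    """Intersect the two testing paths and apply the zero-TPM elimination.

    consensus requires, in both paths: FDR <= alpha, |log2fc| > log2(min_fold)
    and agreeing sign.  ``elimination='tissue_mean'`` (default) drops
    consensus genes whose mean TPM is 0 in either tissue at the tested
    timepoint; ``'any_replicate'`` uses the stricter reading that any single
    zero-TPM replicate disqualifies.  Returns the full per-gene record table;
    final DEGs are rows with ``deg == True``.
    """
    if not nb_results.index.equals(lm_results.index):
        if set(nb_results.index) != set(lm_results.index):
            raise ValueError("the two paths cover different gene sets")
        lm_results = lm_results.loc[nb_results.index]
    rec = pd.DataFrame(index=nb_results.index)
    rec["log2fc"] = nb_results["log2fc"]
    rec["log2fc_lm"] = lm_results["coef"]
    rec["dispersion"] = nb_results["dispersion"]
    rec["lr_stat"] = nb_results["lr_stat"]
    rec["p_nb"] = nb_results["p_nb"]
    rec["p_lm"] = lm_results["p_lm"]
    rec["fdr_nb"] = bh_adjust(rec["p_nb"])
    rec["fdr_lm"] = bh_adjust(rec["p_lm"])
    thr = np.log2(min_fold)
    sig_nb = (rec["fdr_nb"] <= alpha) & (rec["log2fc"].abs() > thr)
    sig_lm = (rec["fdr_lm"] <= alpha) & (rec["log2fc_lm"].abs() > thr)
    same_sign = np.sign(rec["log2fc"]) == np.sign(rec["log2fc_lm"])
    rec["consensus"] = (sig_nb & sig_lm & same_sign).fillna(False)
    rec["direction"] = np.where(rec["log2fc"] > 0, "up_AL", "up_ST")

    if tpm.mean_tpm is None:
        raise ValueError("tpm summary missing: call summarize_expression")
    if elimination == "tissue_mean":
        al = tpm.mean_tpm[("AL", timepoint)].reindex(rec.index)
        st = tpm.mean_tpm[("ST", timepoint)].reindex(rec.index)
        zero = (al == 0) | (st == 0)
    elif elimination == "any_replicate":
        cols = tpm.samples.index[tpm.samples["timepoint"] == timepoint]
        zero = (tpm.tpm[cols].reindex(rec.index) == 0).any(axis=1)
    else:
        raise ValueError(f"unknown elimination rule {elimination!r}")
    rec["eliminated_zero_tpm"] = (rec["consensus"] & zero).fillna(False)
    rec["deg"] = rec["consensus"] & ~rec["eliminated_zero_tpm"]
    return rec


def deg_overlap_summary(per_timepoint: dict) -> pd.DataFrame:
    """Up/down counts per timepoint plus pairwise overlap of final DEG sets."""
    rows = []
    sets = {}
    for tp, rec in per_timepoint.items():
        final = rec.index[rec["deg"]]
        sets[tp] = set(final)
        up = int((rec.loc[final, "direction"] == "up_AL").sum())
        rows.append({"timepoint": tp, "n_deg": len(final),
                     "up_AL": up, "up_ST": len(final) - up})
    summary = pd.DataFrame(rows)
    tps = sorted(sets)
    for i, a in enumerate(tps):
        for b in tps[i + 1:]:
            inter = len(sets[a] & sets[b])
            rows_ov = {"timepoint": f"{a}&{b}", "n_deg": inter,
                       "up_AL": np.nan, "up_ST": np.nan}
            summary = pd.concat(
                [summary, pd.DataFrame([rows_ov])], ignore_index=True)
    return summary


def run_deg(cm: CountMatrix, timepoint: int, tpm: TpmTable | None = None,
            alpha: float = 0.05, min_fold: float = 2.0,
            min_count: int = 10) -> pd.DataFrame:
    """Full two-path consensus analysis for one timepoint.

    Convenience wrapper: subsets the samples, filters sparse genes, runs TMM
    -> dispersion -> NB-GLM LRT and voom -> moderated t, and applies the
    consensus and elimination rules.
    """
    sub = cm.at_timepoint(timepoint)
    sub = filter_expressed(sub, min_count=min_count)
    design = DesignSpec.from_samples(sub.samples)
    factors = tmm_factors(sub)
    disp = estimate_dispersion(sub, design, factors)
    nb = nb_glm_lrt(sub, design, disp.tagwise, factors)
    logcpm, weights = voom_transform(sub, design, factors)
    lm = moderated_t_test(logcpm, weights, design)
    if tpm is None:
        from aleuro.expression import compute_tpm, summarize_expression
        tpm = summarize_expression(compute_tpm(cm))
    return call_consensus_degs(nb, lm, tpm, timepoint,
                               alpha=alpha, min_fold=min_fold)
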
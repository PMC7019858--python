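"""Marker-trait association on adjusted cultivar means.

Covers marker quality control, the realized-relationship (kinship) matrix,
PCA + k-means population-structure covariates, a kinship-adjusted
mixed-model scan (single spectral decomposition, per-marker GLS at the
null-model variance ratio), Bonferroni / Benjamini-Hochberg thresholds,
pairwise LD r2, and allele-burden summaries over a genomic region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans

from .synthetic_data import GenotypeMatrix

__all__ = [
    "QCReport",
    "StructureCovariates",
    "SignificanceThresholds",
    "marker_qc",
    "kinship",
    "population_structure",
    "association_scan",
    "significance_thresholds",
    "ld_r2",
    "mean_ld",
    "allele_burden",
    "genomic_control_lambda",
]


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_monomorphic: int
    n_high_missing: int
    n_low_maf: int
    n_retained: int


@dataclass(frozen=True)
class StructureCovariates:
    """Group assignments from PCA + k-means, as model covariates."""

    groups: np.ndarray  # per-cultivar group label, 0..k-1
    pc_scores: np.ndarray  # n x n_components
    explained_variance_ratio: np.ndarray
    k: int

    def indicators(self) -> np.ndarray:
        """k-1 group indicator columns (first group as reference)."""
        if self.k <= 1:
            return np.empty((len(self.groups), 0))
        out = np.zeros((len(self.groups), self.k - 1))
        for g in range(1, self.k):
            out[self.groups == g, g - 1] = 1.0
        return out


@dataclass(frozen=True)
class SignificanceThresholds:
    alpha: float
    fdr_rate: float
    n_markers: int
    bonferroni_p: float
    bonferroni_neglog10: float
    bh_p_cutoff: float | None  # largest p rejected by BH; None if no rejection
    n_bh_rejected: int


def _maf(col: np.ndarray) -> float:
    ok = ~np.isnan(col)
    if ok.sum() == 0:
        return np.nan
    freq = col[ok].sum() / (2.0 * ok.sum())
    return float(min(freq, 1.0 - freq))


def marker_qc(
    g: GenotypeMatrix, max_missing: float = 0.10, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop monomorphic markers, high missingness, and low MAF.

    Retains markers that are polymorphic, have a missing fraction
    <= ``max_missing`` and a minor allele frequency >= ``min_maf``; raises
    if nothing survives, quoting the per-rule counts.
    """
    d = g.dosages
    n = d.shape[0]
    miss = np.isnan(d).sum(axis=0) / n
    mafs = np.array([_maf(d[:, j]) for j in range(d.shape[1])])
    with np.errstate(invalid="ignore"):
        poly = np.array([len(np.unique(d[~np.isnan(d[:, j]), j])) > 1 for j in range(d.shape[1])])
    keep = poly & (miss <= max_missing) & (mafs >= min_maf)
    report = QCReport(
        n_input=d.shape[1],
        n_monomorphic=int((~poly).sum()),
        n_high_missing=int((miss > max_missing).sum()),
        n_low_maf=int((poly & (mafs < min_maf)).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        raise ValueError(
            f"no markers pass QC (of {report.n_input}: {report.n_monomorphic} "
            f"monomorphic, {report.n_high_missing} high-missing, {report.n_low_maf} low-MAF)"
        )
    kept = [m for m, k in zip(g.markers, keep) if k]
    return g.subset_markers(kept), report


def _imputed_centered(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed dosages and per-marker allele frequencies."""
    d = g.dosages.copy()
    means = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = np.take(means, idx[1])
    return d, means / 2.0


def kinship(g: GenotypeMatrix) -> np.ndarray:
    """Realized-relationship matrix from centered, frequency-scaled dosages.

    VanRaden-style: K = W W' / (2 * sum p_j (1 - p_j)) with W the
    mean-imputed dosage matrix centered at 2p. Symmetric PSD by
    construction.
    """
    if g.n_markers < 2:
        raise ValueError("need at least 2 markers for a kinship matrix")
    d, p = _imputed_centered(g)
    W = d - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; kinship undefined")
    K = W @ W.T / denom
    return (K + K.T) / 2.0


def population_structure(
    g: GenotypeMatrix,
    k: int = 5,
    n_components: int | None = None,
    explained_target: float = 0.80,
    seed: int = 0,
) -> StructureCovariates:
    """PCA of the dosage matrix + k-means grouping on leading components.

    ``n_components`` defaults to the smallest number of PCs explaining
    ``explained_target`` of the variance (capped at 20). The group labels
    are relabelled by first occurrence so permuting cultivar order changes
    assignments only up to label names.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > g.n_cultivars:
        raise ValueError("k exceeds the number of cultivars")
    d, _ = _imputed_centered(g)
    Xc = d - d.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    evr = var / var.sum() if var.sum() > 0 else var
    if n_components is None:
        n_components = int(np.searchsorted(np.cumsum(evr), explained_target) + 1)
        n_components = int(min(n_components, 20, len(S)))
    n_components = max(1, min(n_components, len(S)))
    scores = U[:, :n_components] * S[:n_components]

    if k == 1:
        groups = np.zeros(g.n_cultivars, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=20, random_state=seed)
        raw = km.fit_predict(scores)
        # canonical labels: order of first appearance
        remap, nxt = {}, 0
        groups = np.empty_like(raw)
        for i, lab in enumerate(raw):
            if lab not in remap:
                remap[lab] = nxt
                nxt += 1
            groups[i] = remap[lab]
    return StructureCovariates(
        groups=groups, pc_scores=scores, explained_variance_ratio=evr[:n_components], k=k
    )


def _null_variance_ratio(yr: np.ndarray, Xr: np.ndarray, lam: np.ndarray) -> float:
    """REML estimate of delta = sigma2_e / sigma2_g on rotated data.

    ``lam`` are kinship eigenvalues; data already rotated by eigenvectors.
    """
    n, p = Xr.shape

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (lam + delta)
        XtWX = (Xr * w[:, None]).T @ Xr
        try:
            beta = np.linalg.solve(XtWX, (Xr * w[:, None]).T @ yr)
        except np.linalg.LinAlgError:
            return np.inf
        r = yr - Xr @ beta
        rss = float(r @ (w * r))
        sign, logdetX = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            (n - p) * np.log(rss / (n - p))
            + np.sum(np.log(lam + delta))
            + logdetX
            + (n - p)
        )
        return -ll

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-10.0, 10.0), method="bounded")
    return float(np.exp(res.x))


def association_scan(
    blues: pd.DataFrame,
    g: GenotypeMatrix,
    K: np.ndarray,
    covariates: StructureCovariates | None = None,
    trait: str | None = None,
    value_col: str = "blue",
) -> pd.DataFrame:
    """Kinship-adjusted single-marker scan of one trait's adjusted means.

    The polygenic/residual variance ratio is estimated once on the null
    model (structure covariates only) via the spectral decomposition of K;
    each marker is then tested by GLS at that ratio. Missing dosages drop
    the affected cultivars from that marker's test. Returns one row per
    marker with effect, p, -log10 p, MAF and explained variance (squared
    correlation between dosage and the covariate-adjusted phenotype, %).
    """
    b = blues
    if "trait" in b.columns and trait is not None:
        b = b[b["trait"] == trait]
    if "season" in b.columns and b["season"].isna().any():
        b = b[b["season"].isna()]
    b = b.dropna(subset=[value_col]).drop_duplicates("cultivar").set_index("cultivar")
    common = [cv for cv in g.cultivars if cv in b.index]
    if len(common) < 3:
        raise ValueError("phenotype and genotype cultivar sets barely overlap")
    idx = [g.cultivars.index(cv) for cv in common]
    y = b.loc[common, value_col].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype; scan undefined")
    D = g.dosages[idx, :]
    Ksub = K[np.ix_(idx, idx)]

    cov_cols = [np.ones((len(common), 1))]
    if covariates is not None:
        ind = covariates.indicators()
        if ind.shape[1]:
            cov_cols.append(ind[idx, :])
    X0 = np.hstack(cov_cols)

    lam, Q = np.linalg.eigh(Ksub)
    lam = np.maximum(lam, 0.0)
    yr = Q.T @ y
    X0r = Q.T @ X0
    delta = _null_variance_ratio(yr, X0r, lam)
    w = 1.0 / (lam + delta)

    # covariate-adjusted phenotype for the explained-variance statistic
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    y_adj = y - X0 @ beta0

    n, p0 = X0.shape
    means = np.nanmean(D, axis=0)
    Dimp = np.where(np.isnan(D), means, D)
    Dr = Q.T @ Dimp

    sw = np.sqrt(w)
    Xw0 = X0r * sw[:, None]
    yw = yr * sw
    # residualise marker columns against the null design under the GLS metric
    Q0, _ = np.linalg.qr(Xw0)
    yw_res = yw - Q0 @ (Q0.T @ yw)
    rss0 = float(yw_res @ yw_res)

    effects = np.full(D.shape[1], np.nan)
    pvals = np.full(D.shape[1], np.nan)
    mafs = np.full(D.shape[1], np.nan)
    explained = np.full(D.shape[1], np.nan)
    df_resid = n - p0 - 1

    has_missing = np.isnan(D).any(axis=0)
    # fast path: complete markers share the rotation and null projection
    complete = ~has_missing
    if complete.any():
        Gw = (Dr[:, complete] * sw[:, None])
        Gw_res = Gw - Q0 @ (Q0.T @ Gw)
        gg = np.einsum("ij,ij->j", Gw_res, Gw_res)
        gy = Gw_res.T @ yw_res
        with np.errstate(divide="ignore", invalid="ignore"):
            bhat = np.where(gg > 0, gy / gg, np.nan)
            rss1 = rss0 - np.where(gg > 0, gy**2 / gg, 0.0)
            se = np.sqrt(rss1 / df_resid / gg)
            tstat = bhat / se
        pv = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
        effects[complete] = bhat
        pvals[complete] = np.where(gg > 0, pv, np.nan)

    for j in np.nonzero(has_missing)[0]:
        ok = ~np.isnan(D[:, j])
        if ok.sum() <= p0 + 2:
            continue
        # exact sub-scan: re-rotate on the subset's kinship
        lam_j, Q_j = np.linalg.eigh(Ksub[np.ix_(ok, ok)])
        lam_j = np.maximum(lam_j, 0.0)
        w_j = 1.0 / (lam_j + delta)
        sw_j = np.sqrt(w_j)
        Xj = np.column_stack([X0[ok], D[ok, j]])
        Xjw = (Q_j.T @ Xj) * sw_j[:, None]
        yjw = (Q_j.T @ y[ok]) * sw_j
        beta_j, res_j, rank_j, _ = np.linalg.lstsq(Xjw, yjw, rcond=None)
        resid = yjw - Xjw @ beta_j
        dfj = ok.sum() - Xj.shape[1]
        if dfj <= 0 or rank_j < Xj.shape[1]:
            continue
        sigma2 = float(resid @ resid) / dfj
        cov = sigma2 * np.linalg.inv(Xjw.T @ Xjw)
        tj = beta_j[-1] / np.sqrt(cov[-1, -1])
        effects[j] = beta_j[-1]
        pvals[j] = 2.0 * stats.t.sf(abs(tj), dfj)

    for j in range(D.shape[1]):
        mafs[j] = _maf(D[:, j])
        ok = ~np.isnan(D[:, j])
        if ok.sum() >= 3 and np.ptp(D[ok, j]) > 0 and np.ptp(y_adj[ok]) > 0:
            r = np.corrcoef(D[ok, j], y_adj[ok])[0, 1]
            explained[j] = 100.0 * r**2

    out = g.marker_map.copy()
    out["effect"] = effects
    out["p_value"] = pvals
    with np.errstate(divide="ignore"):
        out["neglog10_p"] = -np.log10(out["p_value"])
    out["maf"] = mafs
    out["explained_pct"] = explained
    out.attrs["delta"] = delta
    out.attrs["n"] = len(common)
    return out


def significance_thresholds(
    n_markers: int,
    alpha: float = 0.05,
    fdr_rate: float = 0.10,
    pvalues=None,
) -> SignificanceThresholds:
    """Bonferroni family-wise cutoff and Benjamini-Hochberg step-up cutoff."""
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    bonf_p = alpha / n_markers
    bh_cut, n_rej = None, 0
    if pvalues is not None:
        p = np.asarray([v for v in np.asarray(pvalues, dtype=float) if not np.isnan(v)])
        if len(p) == 0:
            raise ValueError("empty p-value list for FDR")
        order = np.sort(p)
        m = len(order)
        crit = fdr_rate * np.arange(1, m + 1) / m
        passing = np.nonzero(order <= crit)[0]
        if len(passing):
            n_rej = int(passing[-1] + 1)
            bh_cut = float(order[passing[-1]])
    return SignificanceThresholds(
        alpha=alpha,
        fdr_rate=fdr_rate,
        n_markers=n_markers,
        bonferroni_p=bonf_p,
        bonferroni_neglog10=float(-np.log10(bonf_p)),
        bh_p_cutoff=bh_cut,
        n_bh_rejected=n_rej,
    )


def ld_r2(g: GenotypeMatrix, markers=None, cultivars=None) -> pd.DataFrame:
    """Pairwise LD as squared Pearson correlation of dosages.

    Pairwise-complete over missing values; symmetric with unit diagonal.
    Pairs involving a marker monomorphic within the (optional) cultivar
    subset are reported missing.
    """
    marker_list = list(markers) if markers is not None else list(g.markers)
    if len(marker_list) < 2:
        raise ValueError("need at least 2 markers for LD")
    sub = g.subset_markers(marker_list)
    d = sub.dosages
    if cultivars is not None:
        rows = [sub.cultivars.index(c) for c in cultivars]
        d = d[rows, :]
    m = d.shape[1]
    out = np.full((m, m), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(m):
        for j in range(i + 1, m):
            ok = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            if ok.sum() < 2:
                continue
            xi, xj = d[ok, i], d[ok, j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            out[i, j] = out[j, i] = r**2
    # monomorphic-within-subset markers get a missing diagonal too
    for i in range(m):
        ok = ~np.isnan(d[:, i])
        if ok.sum() < 2 or np.ptp(d[ok, i]) == 0:
            out[i, :] = np.nan
            out[:, i] = np.nan
    return pd.DataFrame(out, index=marker_list, columns=marker_list)


def mean_ld(g: GenotypeMatrix, markers, cultivars) -> float:
    """Mean off-diagonal r2 among the markers within a cultivar subset."""
    mat = ld_r2(g, markers=markers, cultivars=cultivars).to_numpy()
    iu = np.triu_indices(mat.shape[0], k=1)
    vals = mat[iu]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no valid marker pairs in subset")
    return float(vals.mean())


def allele_burden(
    g: GenotypeMatrix,
    region: tuple[str, float, float],
    blues: pd.DataFrame,
    trait: str | None = None,
    value_col: str = "blue",
) -> dict:
    """Minor-allele burden over a region vs a trait's adjusted means.

    Counts minor alleles per cultivar across the region's markers, reports
    the per-count group means, and compares a linear (additive) regression
    of trait on count against the saturated group-mean model by an F test
    for lack of fit (``additive_p`` small = departure from additivity).
    """
    chrom, lo, hi = region
    mm = g.marker_map
    sel = mm[(mm["chromosome"] == chrom) & (mm["position_mbp"] >= lo) & (mm["position_mbp"] <= hi)]
    if sel.empty:
        raise ValueError(f"no markers in region {chrom}:{lo}-{hi} Mbp")
    cols = [g.markers.index(m) for m in sel["marker"]]
    d = g.dosages[:, cols]
    # orient each marker to count its minor allele
    flip = np.nanmean(d, axis=0) > 1.0
    d = np.where(flip, 2.0 - d, d)
    burden = np.nansum(d, axis=1)

    b = blues
    if "trait" in b.columns and trait is not None:
        b = b[b["trait"] == trait]
    if "season" in b.columns and b["season"].isna().any():
        b = b[b["season"].isna()]
    b = b.dropna(subset=[value_col]).drop_duplicates("cultivar").set_index("cultivar")
    common = [cv for cv in g.cultivars if cv in b.index]
    y = b.loc[common, value_col].to_numpy(dtype=float)
    cnt = burden[[g.cultivars.index(c) for c in common]]

    tbl = (
        pd.DataFrame({"burden": cnt.astype(int), "value": y})
        .groupby("burden")
        .agg(mean=("value", "mean"), n=("value", "size"))
        .reset_index()
    )
    slope = intercept = np.nan
    additive_p = np.nan
    if tbl.shape[0] >= 2 and np.ptp(cnt) > 0:
        reg = stats.linregress(cnt, y)
        slope, intercept = float(reg.slope), float(reg.intercept)
        if tbl.shape[0] >= 3:
            # lack-of-fit F: saturated group means vs the line
            fitted_line = intercept + slope * cnt
            groups = pd.Series(y).groupby(cnt).transform("mean").to_numpy()
            rss_line = float(((y - fitted_line) ** 2).sum())
            rss_sat = float(((y - groups) ** 2).sum())
            df_lof = tbl.shape[0] - 2
            df_pe = len(y) - tbl.shape[0]
            if df_pe > 0 and rss_sat > 0:
                F = ((rss_line - rss_sat) / df_lof) / (rss_sat / df_pe)
                additive_p = float(stats.f.sf(F, df_lof, df_pe))
    return {
        "region_markers": list(sel["marker"]),
        "burden": pd.Series(cnt, index=common, name="burden"),
        "group_summary": tbl,
        "slope_per_allele": slope,
        "intercept": intercept,
        "additive_lack_of_fit_p": additive_p,
    }


def genomic_control_lambda(pvalues) -> float:
    """Genomic-control inflation factor from the median test statistic."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) == 0:
        raise ValueError("no p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
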
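"""Mixed-model analysis of plot-level phenotype tables.

The observation model decomposes each plot value into a general mean,
cultivar and season effects with their interaction, design terms for
season x replication and season x replication x sub-group, and a residual:

    P_ijkl = mu + c_i + y_j + cy_ij + YR_jk + YRG_jkl + e_ijkl

Two variants are used: cultivar/season/interaction fixed (for adjusted
cultivar means, BLUEs) and everything random except the mean (for variance
components and broad-sense heritability

    H2 = sigma2_C / (sigma2_C + sigma2_CY / n + sigma2_e / (n r)) ).

Variance components are estimated by average-information REML with
non-negativity enforced by boundary pinning; fixed effects by GLS at the
converged variances. The random structure here is small (2-4 crossed
terms), which keeps the dense implementation exact and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "MixedModelFit",
    "fit_mixed_model",
    "estimate_blues",
    "heritability",
    "factor_significance",
]

_CANONICAL = {
    "cultivar": "sigma2_c",
    "cultivar:season": "sigma2_cy",
    "season:rep": "sigma2_yr",
    "season:rep:subgroup": "sigma2_yrg",
    "residual": "sigma2_e",
}


@dataclass(frozen=True)
class ModelSpec:
    """Names the response trait and the fixed/random factor terms."""

    trait: str
    fixed: tuple[str, ...] = ("cultivar", "season", "cultivar:season")
    random: tuple[str, ...] = ("season:rep", "season:rep:subgroup")

    @classmethod
    def blue_model(cls, trait: str) -> "ModelSpec":
        """Cultivar, season and interaction fixed; design terms random."""
        return cls(trait=trait)

    @classmethod
    def fully_random(cls, trait: str) -> "ModelSpec":
        """All terms random except the general mean (variance components)."""
        return cls(
            trait=trait,
            fixed=(),
            random=("cultivar", "cultivar:season", "season:rep", "season:rep:subgroup"),
        )

    def restrict_to(self, columns) -> "ModelSpec":
        """Drop terms whose factor columns are absent from ``columns``.

        Lets the default specs run on tables without optional design
        columns (e.g. no sub-group recorded).
        """
        cols = set(columns)
        keep = lambda t: all(c in cols for c in t.split(":"))
        return ModelSpec(
            trait=self.trait,
            fixed=tuple(t for t in self.fixed if keep(t)),
            random=tuple(t for t in self.random if keep(t)),
        )


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components; design terms do not enter heritability."""

    sigma2_c: float = 0.0
    sigma2_cy: float = 0.0
    sigma2_yr: float = 0.0
    sigma2_yrg: float = 0.0
    sigma2_e: float = 0.0
    method: str = "ai-reml"
    converged: bool = True
    n_iter: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in ("sigma2_c", "sigma2_cy", "sigma2_yr", "sigma2_yrg", "sigma2_e")
        }


@dataclass
class MixedModelFit:
    spec: ModelSpec
    vc: VarianceComponents
    variance_by_term: dict[str, float]
    loglik: float
    beta: np.ndarray
    beta_cov: np.ndarray
    beta_labels: list[tuple]
    n_obs: int
    data: pd.DataFrame = field(repr=False, default=None)
    iteration_trace: list = field(default_factory=list, repr=False)


def _term_codes(df: pd.DataFrame, term: str) -> np.ndarray:
    cols = term.split(":")
    for c in cols:
        if c not in df.columns:
            raise KeyError(f"factor column {c!r} missing from table")
    if len(cols) == 1:
        key = df[cols[0]].astype(str)
    else:
        key = df[cols[0]].astype(str)
        for c in cols[1:]:
            key = key + "\x1f" + df[c].astype(str)
    codes, _ = pd.factorize(key, sort=True)
    return codes


def _reml_ai(
    y: np.ndarray,
    X: np.ndarray,
    term_codes: dict[str, np.ndarray],
    max_iter: int = 200,
    rtol: float = 1e-10,
):
    """Average-information REML for iid crossed random terms + residual.

    Returns (variances dict incl. 'residual', restricted loglik, n_iter,
    converged, trace).
    """
    n = len(y)
    terms = list(term_codes)
    # relationship matrices G_r = Z_r Z_r' as dense 0/1 indicators of shared level
    G = {t: (term_codes[t][:, None] == term_codes[t][None, :]).astype(float) for t in terms}

    ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    tot = float(np.var(y - X @ ols_beta, ddof=X.shape[1])) or 1.0
    k = len(terms) + 1
    var = {t: tot / k for t in terms}
    var["residual"] = tot / k
    pinned: set[str] = set()

    def build(varmap):
        V = np.eye(n) * varmap["residual"]
        for t in terms:
            if varmap[t] > 0:
                V += varmap[t] * G[t]
        return V

    def restricted_ll(varmap):
        V = build(varmap)
        c, low = cho_factor(V, lower=True)
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        VinvX = cho_solve((c, low), X)
        XtVinvX = X.T @ VinvX
        sign, logdetX = np.linalg.slogdet(XtVinvX)
        Vinvy = cho_solve((c, low), y)
        beta = np.linalg.solve(XtVinvX, X.T @ Vinvy)
        Py = Vinvy - VinvX @ beta
        ll = -0.5 * (logdetV + logdetX + float(y @ Py))
        return ll, (c, low), VinvX, XtVinvX, Py

    ll, chol, VinvX, XtVinvX, Py = restricted_ll(var)
    trace = [dict(var, loglik=ll)]
    converged = False
    for it in range(1, max_iter + 1):
        Vinv = cho_solve(chol, np.eye(n))
        A = np.linalg.solve(XtVinvX, VinvX.T)
        P = Vinv - VinvX @ A

        active = [t for t in terms if t not in pinned] + ["residual"]
        u = {}
        score = {}
        for t in active:
            Gt = G[t] if t != "residual" else None
            ut = (Gt @ Py) if Gt is not None else Py.copy()
            u[t] = ut
            trPG = float(np.einsum("ij,ij->", P, Gt)) if Gt is not None else float(np.trace(P))
            score[t] = -0.5 * (trPG - float(Py @ ut))
        AI = np.empty((len(active), len(active)))
        Pu = {t: P @ u[t] for t in active}
        for i, t in enumerate(active):
            for j, s in enumerate(active):
                if j < i:
                    AI[i, j] = AI[j, i]
                else:
                    AI[i, j] = 0.5 * float(u[t] @ Pu[s])
        g = np.array([score[t] for t in active])
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(len(active)), g)
        except np.linalg.LinAlgError:
            delta = g / (np.diag(AI) + 1e-10)

        # step-halve until the restricted likelihood does not decrease
        accepted = False
        for half in range(14):
            new = dict(var)
            for t, d in zip(active, delta):
                new[t] = var[t] + d / (2**half)
            floor = max(tot * 1e-12, 1e-300)
            newly_pinned = {t for t in active if new[t] < 0}
            for t in new:
                new[t] = max(new[t], 0.0)
            if new["residual"] <= 0:
                new["residual"] = floor
            try:
                ll_new, chol_new, VinvX_new, XtVinvX_new, Py_new = restricted_ll(new)
            except np.linalg.LinAlgError:
                continue
            if ll_new >= ll - 1e-12:
                var, chol, VinvX, XtVinvX, Py = new, chol_new, VinvX_new, XtVinvX_new, Py_new
                pinned |= {t for t in newly_pinned if t != "residual"}
                accepted = True
                break
        trace.append(dict(var, loglik=ll_new if accepted else ll))
        if not accepted:
            converged = True  # no uphill step found: at a (boundary) optimum
            break
        if abs(ll_new - ll) < rtol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    else:
        it = max_iter
    return var, ll, it, converged, trace


def fit_mixed_model(table: pd.DataFrame, spec: ModelSpec) -> MixedModelFit:
    """REML variance components + GLS fixed effects for one trait.

    The fixed part is parameterised as cell means over the crossing of all
    fixed factors (full rank on observed cells); missing plots are simply
    absent rows. Deterministic given the table.
    """
    df = table[table["trait"] == spec.trait].copy()
    if df.empty:
        raise ValueError(f"trait {spec.trait!r} not found in table")
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    y = df["value"].to_numpy(dtype=float)
    n = len(y)

    for term in spec.fixed + spec.random:
        for c in term.split(":"):
            if c not in df.columns:
                raise KeyError(f"factor column {c!r} missing from table")
            if df[c].nunique() < 1:
                raise ValueError(f"factor {c!r} has no levels")

    # fixed design: cell means over the crossed fixed factors (or intercept)
    fixed_cols = sorted({c for t in spec.fixed for c in t.split(":")})
    if fixed_cols:
        cells = df[fixed_cols].astype(str).agg("\x1f".join, axis=1)
        labels_str, codes = np.unique(cells, return_inverse=True)
        X = np.zeros((n, len(labels_str)))
        X[np.arange(n), codes] = 1.0
        beta_labels = [tuple(s.split("\x1f")) for s in labels_str]
    else:
        X = np.ones((n, 1))
        beta_labels = [("intercept",)]
        fixed_cols = []

    if n <= X.shape[1]:
        raise ValueError(
            f"singular design: {n} observations for {X.shape[1]} fixed-effect cells "
            "(no residual degrees of freedom)"
        )

    term_codes = {t: _term_codes(df, t) for t in spec.random}
    var, ll, n_iter, converged, trace = _reml_ai(y, X, term_codes)

    # GLS fixed effects at converged variances
    V = np.eye(n) * var["residual"]
    for t in spec.random:
        if var[t] > 0:
            G = (term_codes[t][:, None] == term_codes[t][None, :]).astype(float)
            V += var[t] * G
    c, low = cho_factor(V, lower=True)
    VinvX = cho_solve((c, low), X)
    XtVinvX = X.T @ VinvX
    beta_cov = np.linalg.inv(XtVinvX)
    beta = beta_cov @ (X.T @ cho_solve((c, low), y))

    by_term = {t: float(var[t]) for t in spec.random}
    by_term["residual"] = float(var["residual"])
    kw = {}
    for term, attr in _CANONICAL.items():
        if term in by_term:
            kw[attr] = by_term[term]
    kw["sigma2_e"] = by_term["residual"]
    vc = VarianceComponents(**kw, converged=converged, n_iter=n_iter)

    fit = MixedModelFit(
        spec=spec,
        vc=vc,
        variance_by_term=by_term,
        loglik=float(ll),
        beta=beta,
        beta_cov=beta_cov,
        beta_labels=beta_labels,
        n_obs=n,
        data=df,
        iteration_trace=trace,
    )
    fit._fixed_cols = fixed_cols
    return fit


def estimate_blues(fit: MixedModelFit) -> pd.DataFrame:
    """Adjusted cultivar means (and per-season means) with standard errors.

    The per-cultivar BLUE averages that cultivar's season cell means with
    equal weight per season (the estimated-marginal-means convention, not
    weighting by cell counts); per-cultivar-per-season values are the cell
    means themselves. Standard errors come from the GLS fixed-effect
    covariance.
    """
    cols = getattr(fit, "_fixed_cols", None)
    if not cols or "cultivar" not in cols:
        raise ValueError("cultivar must be a fixed factor to compute BLUEs")
    lab = pd.DataFrame(fit.beta_labels, columns=cols)
    lab["_idx"] = np.arange(len(lab))

    rows = []
    for cv, grp in lab.groupby("cultivar", sort=True):
        L = np.zeros(len(fit.beta))
        L[grp["_idx"].to_numpy()] = 1.0 / len(grp)
        est = float(L @ fit.beta)
        se = float(np.sqrt(L @ fit.beta_cov @ L))
        rows.append({"cultivar": cv, "trait": fit.spec.trait, "blue": est, "se": se})
        if "season" in cols:
            for _, r in grp.iterrows():
                i = int(r["_idx"])
                rows.append(
                    {
                        "cultivar": cv,
                        "season": r["season"],
                        "trait": fit.spec.trait,
                        "blue": float(fit.beta[i]),
                        "se": float(np.sqrt(fit.beta_cov[i, i])),
                    }
                )
    out = pd.DataFrame(rows)
    if "season" not in out.columns:
        out["season"] = np.nan
    meta_cols = [c for c in ("year_of_release", "subgroup") if c in fit.data.columns]
    if meta_cols:
        meta = fit.data[["cultivar", *meta_cols]].drop_duplicates("cultivar")
        out = out.merge(meta, on="cultivar", how="left")
    return out


def heritability(vc, n_env: int, n_reps: int) -> float:
    """Broad-sense heritability on an entry-mean basis.

    ``H2 = s2C / (s2C + s2CY/n + s2e/(n*r))`` with genetic, genotype x
    environment and residual components; design-term variances do not enter.
    """
    if n_env < 1 or n_reps < 1:
        raise ValueError("n_env and n_reps must be >= 1")
    if isinstance(vc, VarianceComponents):
        s2c, s2cy, s2e = vc.sigma2_c, vc.sigma2_cy, vc.sigma2_e
    else:
        s2c, s2cy, s2e = vc["sigma2_c"], vc["sigma2_cy"], vc["sigma2_e"]
    denom = s2c + s2cy / n_env + s2e / (n_env * n_reps)
    if denom == 0:
        raise ZeroDivisionError("all variance components are zero")
    return float(s2c / denom)


def factor_significance(table: pd.DataFrame, spec: ModelSpec | str) -> pd.DataFrame:
    """Sequential F-tests for cultivar, season and their interaction.

    The response is whitened with the REML covariance of the random terms,
    then nested fixed-effect models (mean, +cultivar, +season,
    +interaction) are compared by sequential sums of squares. Terms with
    zero added rank (e.g. season in a single-season table) are reported as
    not testable.
    """
    if isinstance(spec, str):
        spec = ModelSpec.blue_model(spec)
    fit = fit_mixed_model(table, spec)
    df = fit.data
    y = df["value"].to_numpy(dtype=float)
    n = len(y)

    V = np.eye(n) * fit.variance_by_term["residual"]
    for t in spec.random:
        if fit.variance_by_term[t] > 0:
            codes = _term_codes(df, t)
            V += fit.variance_by_term[t] * (codes[:, None] == codes[None, :]).astype(float)
    # whiten: W y has iid unit-variance errors under the fitted covariance
    c, low = cho_factor(V, lower=True)
    from scipy.linalg import solve_triangular

    yw = solve_triangular(c, y, lower=low)

    def design(terms):
        mats = [np.ones((n, 1))]
        for t in terms:
            codes = _term_codes(df, t)
            Z = np.zeros((n, codes.max() + 1))
            Z[np.arange(n), codes] = 1.0
            mats.append(Z)
        X = np.hstack(mats)
        return solve_triangular(c, X, lower=low)

    seq = [(), ("cultivar",), ("cultivar", "season"), ("cultivar", "season", "cultivar:season")]
    names = ["cultivar", "season", "cultivar:season"]
    rss, rank = [], []
    for terms in seq:
        Xw = design(terms)
        beta, res, r, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        rss.append(float(resid @ resid))
        rank.append(int(np.linalg.matrix_rank(Xw)))
    df_resid = n - rank[-1]
    if df_resid <= 0:
        raise ValueError("insufficient residual degrees of freedom for F-tests")
    mse = rss[-1] / df_resid

    rows = []
    for i, name in enumerate(names):
        ddf = rank[i + 1] - rank[i]
        if ddf <= 0:
            rows.append({"term": name, "df": 0, "F": np.nan, "p_value": np.nan,
                         "significant": False, "testable": False})
            continue
        F = ((rss[i] - rss[i + 1]) / ddf) / mse
        p = float(stats.f.sf(F, ddf, df_resid))
        rows.append({"term": name, "df": ddf, "F": float(F), "p_value": p,
                     "significant": p < 0.05, "testable": True})
    return pd.DataFrame(rows)
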
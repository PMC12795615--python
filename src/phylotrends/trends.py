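"""Gaussian trend models for assemblage-level ses.MPD.

The response is the ses.MPD z-score per assemblage. Fixed effects follow
the macroecological question — absolute latitude, (centered/scaled)
sampling year, hemisphere, optional site environment (temperature,
precipitation, elevation, land cover) and their interactions with year.
Spatial dependence is absorbed by a Matérn-correlated Gaussian random
field over great-circle distances plus an i.i.d. random effect per
decade/site combination; all models are fitted by maximum likelihood
(never REML) so AIC comparisons across fixed-effect menus are valid.

Marginal covariance of the mixed model:

    Σ = σ²_sp · K_Matérn(D; ρ, ν) + σ²_grp · G Gᵀ + σ²_res · I

with D the haversine distance matrix (km), G the group indicator matrix
and ν fixed at 0.5 (exponential) or 1.5. Variance parameters are profiled
against the residual scale and optimized on the log scale from three
fixed starting points.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt
from scipy import stats

from ._util import pairwise_haversine

__all__ = [
    "TrendDesign",
    "MaternParams",
    "FitResult",
    "CorrelogramResult",
    "prepare_trend_frame",
    "vif",
    "fit_lm",
    "matern_corr",
    "fit_spatial_mixed",
    "aic_select",
    "morans_correlogram",
    "marginal_effects",
    "model_menu",
    "run_regions",
]

CONTINUOUS_TERMS = ("abs_latitude", "year_s", "temperature", "precipitation", "elevation")
CATEGORICAL_TERMS = ("hemisphere", "land_cover")


def prepare_trend_frame(pd_results: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Derive model columns from a per-assemblage diversity table.

    Adds abs_latitude, hemisphere (N for latitude ≥ 0), year_s (year
    centered and scaled by its SD) and the decade/site grouping factor;
    drops rows whose ses.MPD is degenerate/missing and returns how many
    were dropped.
    """
    df = pd_results.copy()
    n0 = len(df)
    bad = df["z"].isna()
    if "degenerate" in df.columns:
        bad |= df["degenerate"].astype(bool)
    df = df.loc[~bad].reset_index(drop=True)
    df["abs_latitude"] = df["lat_2dp"].abs()
    df["hemisphere"] = np.where(df["lat_2dp"] >= 0, "N", "S")
    year = df["year"].astype(float)
    sd = float(year.std(ddof=0)) or 1.0
    df["year_s"] = (year - year.mean()) / sd
    df.attrs["year_mean"] = float(year.mean())
    df.attrs["year_sd"] = sd
    decade = (np.floor(df["year"] / 10) * 10).astype(int)
    df["decade_site"] = [
        f"{d}_{la:.2f}_{lo:.2f}" for d, la, lo in zip(decade, df["lat_2dp"], df["lon_2dp"])
    ]
    return df, n0 - len(df)


class TrendDesign:
    """Fixed-effect design builder bound to one data frame.

    Encodes continuous terms as-is, categorical terms as treatment dummies
    (first level is the reference), and ``a:b`` interactions as products of
    the encoded columns. Encoding choices (category levels, year scaling,
    reference values for predictions) are frozen at construction so the
    same design can build matrices for new data on a marginal-effect grid.
    """

    def __init__(self, frame: pd.DataFrame, response: str = "z"):
        self.frame = frame.reset_index(drop=True)
        self.response = response
        self.levels: Dict[str, list] = {}
        for cat in CATEGORICAL_TERMS:
            if cat in self.frame.columns:
                vals = self.frame[cat].dropna().astype(str)
                self.levels[cat] = sorted(vals.unique())
        self.reference: Dict[str, object] = {}
        for cont in CONTINUOUS_TERMS:
            if cont in self.frame.columns:
                self.reference[cont] = float(pd.to_numeric(self.frame[cont], errors="coerce").mean())
        for cat, levels in self.levels.items():
            if levels:
                mode = self.frame[cat].astype(str).mode()
                self.reference[cat] = str(mode.iloc[0]) if len(mode) else levels[0]
        self.year_mean = frame.attrs.get("year_mean")
        self.year_sd = frame.attrs.get("year_sd")

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.response].to_numpy(dtype=float)

    def response_hash(self) -> str:
        return hashlib.sha256(self.y.tobytes()).hexdigest()[:16]

    def _encode(self, term: str, data: pd.DataFrame) -> Tuple[np.ndarray, List[str]]:
        if ":" in term:
            left, right = term.split(":", 1)
            xl, nl = self._encode(left, data)
            xr, nr = self._encode(right, data)
            cols, names = [], []
            for i, a in enumerate(nl):
                for j, b in enumerate(nr):
                    cols.append(xl[:, i] * xr[:, j])
                    names.append(f"{a}:{b}")
            return np.column_stack(cols), names
        if term in self.levels:
            levels = self.levels[term]
            vals = data[term].astype(str)
            cols = [(vals == lev).to_numpy(dtype=float) for lev in levels[1:]]
            if not cols:  # single-level factor carries no information
                return np.zeros((len(data), 0)), []
            return np.column_stack(cols), [f"{term}[{lev}]" for lev in levels[1:]]
        return (
            pd.to_numeric(data[term], errors="coerce").to_numpy(dtype=float)[:, None],
            [term],
        )

    def matrix(
        self, terms: Sequence[str], data: Optional[pd.DataFrame] = None
    ) -> Tuple[np.ndarray, List[str], Dict[str, List[int]]]:
        """Design matrix with intercept; returns (X, column names, term → cols)."""
        data = self.frame if data is None else data
        blocks = [np.ones((len(data), 1))]
        names = ["(Intercept)"]
        term_cols: Dict[str, List[int]] = {}
        for term in terms:
            x, n = self._encode(term, data)
            term_cols[term] = list(range(len(names), len(names) + len(n)))
            blocks.append(x)
            names.extend(n)
        X = np.column_stack(blocks) if len(blocks) > 1 else blocks[0]
        if np.isnan(X).any():
            bad = [names[j] for j in np.where(np.isnan(X).any(axis=0))[0]]
            raise ValueError(f"missing values in design columns: {bad}")
        return X, names, term_cols

    def grid(self, lat_values: Sequence[float], year_values: Sequence[float]) -> pd.DataFrame:
        """Prediction lattice: |latitude| × year, other predictors at reference."""
        rows = []
        for la in lat_values:
            for yr in year_values:
                row = dict(self.reference)
                row["abs_latitude"] = float(la)
                if self.year_mean is not None:
                    row["year_s"] = (float(yr) - self.year_mean) / self.year_sd
                else:
                    row["year_s"] = float(yr)
                row["year"] = float(yr)
                rows.append(row)
        return pd.DataFrame(rows)


def vif(design: TrendDesign, terms: Sequence[str]) -> Dict[str, float]:
    """(Generalized) variance inflation factor per model term.

    Single-column terms get the classical VIF = 1/(1 − R²_j); multi-column
    (categorical) terms get the generalized VIF
    det(R_11)·det(R_22)/det(R) computed from the correlation matrix of the
    centered design columns. Perfectly collinear terms are reported as
    ``inf`` with a warning naming the columns involved.
    """
    X, names, term_cols = design.matrix(terms)
    Xc = X[:, 1:] - X[:, 1:].mean(axis=0)
    sd = Xc.std(axis=0)
    zero_var = sd == 0
    sd[zero_var] = 1.0
    Z = Xc / sd
    R = (Z.T @ Z) / len(Z)
    out: Dict[str, float] = {}
    det_R = float(np.linalg.det(R))
    for term in terms:
        cols = [c - 1 for c in term_cols[term]]
        if not cols:
            out[term] = np.nan
            continue
        others = [i for i in range(R.shape[0]) if i not in cols]
        if any(zero_var[c] for c in cols):
            out[term] = np.inf
            continue
        if det_R <= 1e-12:
            # Singular overall: decide per term via its auxiliary R²
            r2 = _aux_r2(Z, cols, others)
            if r2 >= 1 - 1e-10:
                warnings.warn(
                    f"perfect collinearity: term {term!r} "
                    f"(columns {[names[c + 1] for c in cols]}) is aliased"
                )
                out[term] = np.inf
                continue
        d11 = float(np.linalg.det(R[np.ix_(cols, cols)]))
        d22 = float(np.linalg.det(R[np.ix_(others, others)])) if others else 1.0
        out[term] = np.inf if det_R <= 1e-12 else d11 * d22 / det_R
    return out


def _aux_r2(Z: np.ndarray, cols: List[int], others: List[int]) -> float:
    if not others:
        return 0.0
    y = Z[:, cols].mean(axis=1) if len(cols) > 1 else Z[:, cols[0]]
    Xo = Z[:, others]
    beta, *_ = np.linalg.lstsq(Xo, y, rcond=None)
    resid = y - Xo @ beta
    tot = float((y**2).sum())
    return 1.0 - float((resid**2).sum()) / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class MaternParams:
    """Variance components of the spatial mixed model (response-scale units)."""

    sigma2_spatial: float
    range_rho: float  # km
    smoothness_nu: float
    sigma2_group: float
    sigma2_resid: float


@dataclass
class FitResult:
    """One fitted trend model: coefficients, ML log-likelihood, AIC.

    ``aic = 2k − 2·loglik`` where k counts the intercept, every slope/dummy
    column, the residual variance, and any free spatial/group variance
    parameters.
    """

    kind: str  # "ols" | "matern"
    terms: Tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    converged: bool
    cov_params: np.ndarray
    design: TrendDesign
    response_hash: str
    matern: Optional[MaternParams] = None
    dropped_columns: Tuple[str, ...] = ()

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "p": self.pvalues}
        )


def _drop_aliased(X: np.ndarray, names: List[str]) -> Tuple[np.ndarray, List[str], List[str]]:
    """Drop linearly dependent columns, keeping the earliest independent set.

    Left-to-right greedy selection (intercept first) so which term gets
    dropped is deterministic and reported by name.
    """
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return X, names, []
    keep: List[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > rank:
            keep.append(j)
            rank += 1
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    warnings.warn(f"design is rank deficient; dropping aliased columns {dropped}")
    return X[:, keep], [names[j] for j in keep], dropped


def _gaussian_loglik(n: int, rss: float) -> float:
    sigma2 = rss / n
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def fit_lm(design: TrendDesign, terms: Sequence[str]) -> FitResult:
    """Ordinary least squares with Gaussian ML log-likelihood and AIC."""
    X, names, _ = design.matrix(terms)
    y = design.y
    if len(y) <= X.shape[1]:
        raise ValueError("more parameters than observations")
    X, names, dropped = _drop_aliased(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    n, p = X.shape
    loglik = _gaussian_loglik(n, rss)
    sigma2_unbiased = rss / (n - p)
    XtX_inv = np.linalg.inv(X.T @ X)
    cov = sigma2_unbiased * XtX_inv
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=n - p)
    k = p + 1
    return FitResult(
        kind="ols",
        terms=tuple(terms),
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        n_params=k,
        n_obs=n,
        converged=True,
        cov_params=cov,
        design=design,
        response_hash=design.response_hash(),
        dropped_columns=tuple(dropped),
    )


_SQRT3 = np.sqrt(3.0)


def matern_corr(distance_km, rho: float, nu: float = 1.5):
    """Matérn correlation at great-circle distance (km).

    ν = 0.5 is the exponential model exp(−d/ρ); ν = 1.5 is
    (1 + √3·d/ρ)·exp(−√3·d/ρ). Both equal 1 at distance 0.
    """
    if rho <= 0:
        raise ValueError("range rho must be positive")
    d = np.asarray(distance_km, dtype=float)
    if nu == 0.5:
        out = np.exp(-d / rho)
    elif nu == 1.5:
        s = _SQRT3 * d / rho
        out = (1.0 + s) * np.exp(-s)
    else:
        raise ValueError("smoothness nu must be 0.5 or 1.5")
    return float(out) if np.isscalar(distance_km) else out


def _group_matrix(groups: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(groups, sort=True)
    G = np.zeros((len(codes), codes.max() + 1))
    G[np.arange(len(codes)), codes] = 1.0
    return G


def fit_spatial_mixed(
    design: TrendDesign,
    terms: Sequence[str],
    nu: float = 1.5,
    fix_zero: Sequence[str] = (),
    n_starts: int = 3,
    tol: float = 1e-8,
    max_iter: int = 4000,
) -> FitResult:
    """ML fit of the Gaussian model with Matérn spatial + group random effects.

    The covariance is profiled on the residual scale,
    Σ = σ²_res·[I + φ_sp·K(ρ) + φ_grp·GGᵀ]; the variance ratios and range
    are optimized on the log scale (Nelder–Mead, three fixed multi-starts
    seeded from the median pairwise distance), and σ²_res and β have
    closed-form profile solutions. ``fix_zero`` may pin "spatial" and/or
    "group" variances to exactly zero; with both pinned the fit reduces to
    OLS exactly. Never fails silently: if no start converges the result is
    returned with ``converged=False``.
    """
    X, names, _ = design.matrix(terms)
    y = design.y
    X, names, dropped = _drop_aliased(X, names)
    n, p = X.shape
    lat = design.frame["lat_2dp"].to_numpy(dtype=float)
    lon = design.frame["lon_2dp"].to_numpy(dtype=float)
    D = pairwise_haversine(lat, lon)
    G = _group_matrix(design.frame["decade_site"]) if "decade_site" in design.frame else None
    use_spatial = "spatial" not in fix_zero
    use_group = "group" not in fix_zero and G is not None
    if use_group and G.shape[1] == n:
        # every decade/site combination observed once: G G' = I exactly, so
        # the group variance is indistinguishable from the residual
        warnings.warn(
            "all decade/site groups are singletons; group variance is not "
            "identifiable and is pinned to 0"
        )
        use_group = False
    GGt = G @ G.T if use_group else None

    def build_V(phi_sp, rho, phi_g):
        V = np.eye(n)
        if use_spatial and phi_sp > 0:
            V = V + phi_sp * matern_corr(D, rho, nu)
        if use_group and phi_g > 0:
            V = V + phi_g * GGt
        return V

    def profile(phi_sp, rho, phi_g):
        V = build_V(phi_sp, rho, phi_g)
        try:
            c, low = sla.cho_factor(V, lower=True)
        except sla.LinAlgError:
            return None
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        Vi_X = sla.cho_solve((c, low), X)
        Vi_y = sla.cho_solve((c, low), y)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        q = float(r @ sla.cho_solve((c, low), r))
        sigma2 = q / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)
        return ll, beta, sigma2, XtViX

    # ---- parameterization of the free log-parameters
    free: List[str] = []
    if use_spatial:
        free += ["log_phi_sp", "log_rho"]
    if use_group:
        free += ["log_phi_g"]

    if not free:
        # Both variance components pinned to zero: Σ = σ²I and the ML fit
        # is exactly OLS, so reuse it rather than running the optimizer.
        ols = fit_lm(design, terms)
        Xf, _, _ = design.matrix(terms)
        beta0, *_ = np.linalg.lstsq(Xf, design.y, rcond=None)
        rss0 = float(np.sum((design.y - Xf @ beta0) ** 2))
        matern = MaternParams(0.0, np.nan, nu, 0.0, rss0 / len(design.y))
        return FitResult(
            kind="matern",
            terms=ols.terms,
            params=ols.params,
            bse=ols.bse,
            pvalues=ols.pvalues,
            loglik=ols.loglik,
            aic=ols.aic,
            n_params=ols.n_params,
            n_obs=ols.n_obs,
            converged=True,
            cov_params=ols.cov_params,
            design=design,
            response_hash=ols.response_hash,
            matern=matern,
            dropped_columns=ols.dropped_columns,
        )

    def unpack(theta):
        vals = dict(zip(free, theta))
        phi_sp = np.exp(vals.get("log_phi_sp", -np.inf)) if use_spatial else 0.0
        rho = np.exp(vals.get("log_rho", 0.0)) if use_spatial else 1.0
        phi_g = np.exp(vals.get("log_phi_g", -np.inf)) if use_group else 0.0
        return phi_sp, rho, phi_g

    def negll(theta):
        if np.any(np.abs(theta) > 25):
            return 1e10
        res = profile(*unpack(theta))
        if res is None or not np.isfinite(res[0]):
            return 1e10
        return -res[0]

    pos = D[np.triu_indices(n, 1)]
    pos = pos[pos > 0]
    dmed = float(np.median(pos)) if pos.size else 1.0
    start_sets = [
        {"log_phi_sp": 0.0, "log_rho": np.log(max(dmed / 2, 1e-3)), "log_phi_g": np.log(0.5)},
        {"log_phi_sp": np.log(0.1), "log_rho": np.log(max(dmed, 1e-3)), "log_phi_g": np.log(0.1)},
        {"log_phi_sp": np.log(10.0), "log_rho": np.log(max(dmed / 5, 1e-3)), "log_phi_g": 0.0},
    ][: max(1, n_starts)]

    best = None
    converged = False
    for s in start_sets:
        theta0 = np.array([s[name] for name in free])
        res = sopt.minimize(
            negll,
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": tol, "maxiter": max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    phi_sp, rho, phi_g = unpack(best.x)
    prof = profile(phi_sp, rho, phi_g)
    if prof is None:
        raise RuntimeError("covariance factorization failed at the optimum")
    loglik, beta, sigma2, XtViX = prof
    cov = sigma2 * np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))
    zvals = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zvals))
    k = p + 1 + len(free)
    matern = MaternParams(
        sigma2_spatial=float(sigma2 * phi_sp),
        range_rho=float(rho) if use_spatial else np.nan,
        smoothness_nu=nu,
        sigma2_group=float(sigma2 * phi_g),
        sigma2_resid=float(sigma2),
    )
    return FitResult(
        kind="matern",
        terms=tuple(terms),
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        loglik=float(loglik),
        aic=2 * k - 2 * float(loglik),
        n_params=k,
        n_obs=n,
        converged=converged,
        cov_params=cov,
        design=design,
        response_hash=design.response_hash(),
        matern=matern,
        dropped_columns=tuple(dropped),
    )


def aic_select(fits: Sequence[FitResult]) -> Tuple[pd.DataFrame, FitResult]:
    """Rank fits by AIC; ties within 2 units resolve toward fewer parameters.

    All candidates must have been fitted to the identical response rows.
    """
    if not fits:
        raise ValueError("no fits to select from")
    ref = (fits[0].n_obs, fits[0].response_hash)
    for f in fits[1:]:
        if (f.n_obs, f.response_hash) != ref:
            raise ValueError("fits were not computed on identical response rows")
    table = pd.DataFrame(
        {
            "terms": [" + ".join(f.terms) if f.terms else "(intercept)" for f in fits],
            "kind": [f.kind for f in fits],
            "n_params": [f.n_params for f in fits],
            "loglik": [f.loglik for f in fits],
            "aic": [f.aic for f in fits],
        }
    ).sort_values("aic", kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    best_aic = min(f.aic for f in fits)
    candidates = [f for f in fits if f.aic - best_aic <= 2.0]
    selected = min(candidates, key=lambda f: (f.n_params, f.aic))
    return table, selected


@dataclass
class CorrelogramResult:
    """Binned Moran's I of model residuals with permutation p-values."""

    bin_edges_km: np.ndarray
    morans_i: np.ndarray  # NaN where a bin is empty or residuals constant
    p_perm: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_km": self.bin_edges_km[:-1],
                "bin_hi_km": self.bin_edges_km[1:],
                "morans_i": self.morans_i,
                "p_perm": self.p_perm,
                "n_pairs": self.n_pairs,
            }
        )


def morans_correlogram(
    residuals,
    coords,
    bin_edges_km: Sequence[float],
    n_perm: int = 199,
    seed: int = 0,
) -> CorrelogramResult:
    """Moran's I per distance bin with binary weights and a permutation null.

    ``coords`` is an (n, 2) array of (lat, lon) in degrees. For each bin
    [lo, hi) the weight matrix marks pairs whose great-circle distance
    falls in the bin; I = (n/S0)·(zᵀWz)/(zᵀz) with z the centered
    residuals. The two-sided permutation p-value is
    (1 + #{|I_perm| ≥ |I_obs|})/(n_perm + 1), invariant to residual
    scaling. Empty bins and zero-variance residuals report missing I.
    """
    edges = np.asarray(bin_edges_km, dtype=float)
    if len(edges) < 3:
        raise ValueError("need at least 2 distance bins")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    r = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = len(r)
    D = pairwise_haversine(coords[:, 0], coords[:, 1])
    z = r - r.mean()
    s2 = float(z @ z)
    nb = len(edges) - 1
    I = np.full(nb, np.nan)
    p = np.full(nb, np.nan)
    n_pairs = np.zeros(nb, dtype=int)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)
    Zp = z[perms]  # (n, n_perm) — same centered values, shuffled labels
    for b in range(nb):
        W = (D >= edges[b]) & (D < edges[b + 1])
        np.fill_diagonal(W, False)
        S0 = int(W.sum())
        n_pairs[b] = S0 // 2
        if S0 == 0 or s2 <= 0:
            continue
        Wf = W.astype(float)
        i_obs = (n / S0) * float(z @ (Wf @ z)) / s2
        i_perm = (n / S0) * np.einsum("ij,ij->j", Zp, Wf @ Zp) / s2
        I[b] = i_obs
        p[b] = (1 + np.sum(np.abs(i_perm) >= abs(i_obs))) / (n_perm + 1)
    return CorrelogramResult(bin_edges_km=edges, morans_i=I, p_perm=p, n_pairs=n_pairs)


def marginal_effects(
    fit: FitResult,
    lat_values: Sequence[float],
    year_values: Sequence[float],
) -> pd.DataFrame:
    """Predicted response with SEs on an |latitude| × year lattice.

    Non-focal continuous predictors sit at their training mean and
    categorical ones at their training mode. Grid points outside the
    observed range of |latitude| or year are flagged as extrapolation.
    """
    if not fit.converged:
        raise ValueError("cannot compute marginal effects from a non-converged fit")
    design = fit.design
    grid = design.grid(lat_values, year_values)
    X, names, _ = design.matrix(fit.terms, data=grid)
    keep = [j for j, nm in enumerate(names) if nm in fit.params.index]
    X = X[:, keep]
    pred = X @ fit.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_params, X))
    obs_lat = design.frame["abs_latitude"]
    obs_year = design.frame["year"] if "year" in design.frame else design.frame["year_s"]
    out = grid[["abs_latitude", "year"]].copy()
    out["predicted"] = pred
    out["se"] = se
    out["extrapolated"] = (
        (out["abs_latitude"] < obs_lat.min())
        | (out["abs_latitude"] > obs_lat.max())
        | (out["year"] < float(obs_year.min()))
        | (out["year"] > float(obs_year.max()))
    )
    return out


def model_menu(include_env: bool = False, include_hemisphere: bool = True) -> List[List[str]]:
    """Candidate fixed-effect menus: full model plus drop-one-family subsets.

    A family is a predictor together with its year interaction, so dropping
    "temperature" removes both temperature and temperature:year_s. The menu
    always ends with the minimal latitude × year models.
    """
    core = ["abs_latitude", "year_s"]
    inter = ["abs_latitude:year_s"]
    hemis = ["hemisphere"] if include_hemisphere else []
    envs = ["temperature", "precipitation", "elevation", "land_cover"] if include_env else []
    env_inter = [f"{v}:year_s" for v in ("temperature", "precipitation", "elevation")] if include_env else []
    full = core + hemis + envs + inter + env_inter
    menu = [full]
    families: Dict[str, List[str]] = {}
    if hemis:
        families["hemisphere"] = hemis
    for v in envs:
        fam = [v] + ([f"{v}:year_s"] if f"{v}:year_s" in env_inter else [])
        families[v] = fam
    families["interactions"] = inter + env_inter
    for fam in families.values():
        menu.append([t for t in full if t not in fam])
    menu.append(core + inter)
    menu.append(core)
    seen, unique = set(), []
    for m in menu:
        key = tuple(m)
        if key not in seen:
            seen.add(key)
            unique.append(list(m))
    return unique


def run_regions(
    frame: pd.DataFrame,
    menu: Sequence[Sequence[str]],
    fitter: str = "ols",
    min_rows: int = 30,
    nu: float = 1.5,
) -> Tuple[Dict[str, dict], Dict[str, str]]:
    """Replicate the candidate-menu fit and AIC selection per region.

    ``frame`` is a prepared trend frame with a ``region`` column. Regions
    with fewer than ``min_rows`` assemblages are skipped with a recorded
    reason. Returns ({region: {"selected", "table"}}, {region: skip reason}).
    """
    results: Dict[str, dict] = {}
    skipped: Dict[str, str] = {}
    for region in sorted(frame["region"].dropna().unique()):
        sub = frame.loc[frame["region"] == region].reset_index(drop=True)
        sub.attrs = dict(frame.attrs)
        if region == "unassigned":
            skipped[region] = f"unassigned points ({len(sub)} rows) not analyzed"
            continue
        if len(sub) < min_rows:
            skipped[region] = f"only {len(sub)} rows (< {min_rows})"
            continue
        design = TrendDesign(sub)
        fits = []
        for terms in menu:
            usable = [t for t in terms if _term_available(design, t)]
            if fitter == "matern":
                fits.append(fit_spatial_mixed(design, usable, nu=nu))
            else:
                fits.append(fit_lm(design, usable))
        table, selected = aic_select(fits)
        results[region] = {"selected": selected, "table": table}
    return results, skipped


def _term_available(design: TrendDesign, term: str) -> bool:
    parts = term.split(":")
    for p in parts:
        if p in design.levels:
            if len(design.levels[p]) < 2:
                return False
        elif p not in design.frame.columns:
            return False
        elif design.frame[p].isna().any():
            return False
    return True
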
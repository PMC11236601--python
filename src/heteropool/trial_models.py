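"""Single-trial linear mixed models with in-repo REML.

Each trial site is analysed with a stage-wise model: design factors (row,
column, block) and genetic effects random, check cultivars fixed, residual
either iid or separable AR1(row)⊗AR1(column). Hybrid effects can be fitted
as a single identity-indexed term or partitioned into an additive part
(male GCA + female GCA, optionally with a relationship matrix over parents)
and a non-additive (SCA) part indexed by hybrid identity.

Variance components are estimated by average-information REML with an EM
fallback: an AI step that would decrease the restricted likelihood (or push
a component negative) is replaced by the EM update, which is an ascent step.
Dense linear algebra throughout — trials are a few hundred plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .synthetic import CrossPlan

logger = logging.getLogger(__name__)

__all__ = [
    "RelationshipMatrix",
    "TrialModelSpec",
    "TrialFit",
    "RandomTerm",
    "build_hybrid_additive_design",
    "fit_mixed_model",
    "reml_fit",
    "compare_spatial",
    "fit_all_sites",
    "parent_blup_table",
]

VAR_FLOOR = 1e-8


@dataclass
class RelationshipMatrix:
    """Symmetric PSD relationship matrix over named levels."""

    values: np.ndarray
    ids: np.ndarray
    provenance: str = "identity"    # identity | pedigree | genomic

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relationship matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")
        w = np.linalg.eigvalsh(0.5 * (v + v.T))
        if w.min() < -1e-6 * max(1.0, w.max()):
            raise ValueError("relationship matrix is not PSD")
        self.values = 0.5 * (v + v.T)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.ids.shape[0] != v.shape[0]:
            raise ValueError("ids length mismatch")


@dataclass
class TrialModelSpec:
    """What to fit at one trial site.

    ``genetic`` is either "hybrid" (one identity-indexed genetic term) or
    "additive+sca" (parent-transmitted GCA term plus hybrid-identity SCA).
    """

    genetic: str = "additive+sca"
    design_terms: tuple = ("row", "col", "block")
    residual: str = "iid"           # "iid" | "ar1xar1"
    relationship: str = "identity"  # label only; matrix passed separately

    def __post_init__(self) -> None:
        if self.genetic not in ("hybrid", "additive+sca"):
            raise ValueError("genetic must be 'hybrid' or 'additive+sca'")
        if self.residual not in ("iid", "ar1xar1"):
            raise ValueError("residual must be 'iid' or 'ar1xar1'")


@dataclass
class RandomTerm:
    name: str
    Z: np.ndarray                  # n × q incidence
    levels: np.ndarray             # q level labels
    G: np.ndarray | None = None    # q × q relationship (None ⇒ identity)


@dataclass
class TrialFit:
    varcomp: dict                  # name -> estimate
    varcomp_se: dict               # name -> approximate SE (may be nan)
    loglik: float
    converged: bool
    n_iter: int
    beta: pd.Series
    blups: dict                    # name -> DataFrame(level, blup, pev, reliability)
    residual: str
    rho: tuple | None = None       # (rho_row, rho_col) when residual=ar1xar1
    aic: float = np.nan
    spec: TrialModelSpec | None = None

    def reliability_summary(self, term: str = "additive") -> float:
        """Mean reliability of a random term's effects (levels with data)."""
        t = self.blups[term]
        used = t["n_obs"] > 0 if "n_obs" in t else np.ones(len(t), bool)
        return float(t.loc[used, "reliability"].mean())


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_hybrid_additive_design(plan: CrossPlan,
                                 parents: list | None = None) -> pd.DataFrame:
    """Hybrid → parent incidence: one row per hybrid with a unit entry in its
    male- and female-parent columns (for F1s of inbreds the additive effect is
    the sum of the two parental GCAs)."""
    if parents is None:
        parents = plan.parents
    pidx = {p: i for i, p in enumerate(parents)}
    H = np.zeros((len(plan.crosses), len(parents)))
    for r, (_, row) in enumerate(plan.crosses.iterrows()):
        for p in (row["male"], row["female"]):
            if p not in pidx:
                raise ValueError(f"unknown parent {p!r} in cross plan")
            H[r, pidx[p]] += 1.0
    return pd.DataFrame(H, index=plan.crosses["hybrid"].to_numpy(),
                        columns=parents)


def _indicator(labels: pd.Series, levels: np.ndarray) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for r, v in enumerate(labels):
        Z[r, lookup[v]] = 1.0
    return Z


def _check_rank(X: np.ndarray, names: list) -> None:
    from scipy.linalg import qr
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"singular fixed-effect design; aliased columns: {aliased}")


def build_site_design(pheno: pd.DataFrame, spec: TrialModelSpec,
                      H: pd.DataFrame | None = None,
                      rel: RelationshipMatrix | None = None):
    """Assemble y, X and random-term matrices for a single-site PhenoTable."""
    df = pheno.reset_index(drop=True)
    y = df["yield"].to_numpy(float)
    n = len(df)
    # fixed: intercept + one column per check cultivar
    checks = sorted(df.loc[df["is_check"], "entry"].unique())
    X = [np.ones((n, 1))]
    names = ["intercept"]
    for c in checks:
        X.append((df["entry"].eq(c) & df["is_check"]).to_numpy(float)[:, None])
        names.append(f"check:{c}")
    X = np.hstack(X)
    _check_rank(X, names)

    terms: list[RandomTerm] = []
    for t in spec.design_terms:
        levels = np.sort(df[t].unique())
        terms.append(RandomTerm(name=t, Z=_indicator(df[t], levels),
                                levels=levels.astype(object)))
    hyb_mask = ~df["is_check"]
    hybrids = np.array(sorted(df.loc[hyb_mask, "entry"].unique()), dtype=object)
    Zh = np.zeros((n, len(hybrids)))
    hl = {h: i for i, h in enumerate(hybrids)}
    for r in np.flatnonzero(hyb_mask.to_numpy()):
        Zh[r, hl[df.at[r, "entry"]]] = 1.0
    if spec.genetic == "hybrid":
        terms.append(RandomTerm(name="hybrid", Z=Zh, levels=hybrids))
    else:
        if H is None:
            raise ValueError("additive+sca model needs the hybrid→parent incidence")
        Hm = H.reindex(hybrids)
        if Hm.isna().any().any():
            missing = list(Hm.index[Hm.isna().any(axis=1)][:3])
            raise ValueError(f"hybrids absent from cross plan: {missing}")
        parents = np.asarray(H.columns, dtype=object)
        Za = Zh @ Hm.to_numpy()
        G = None
        if rel is not None:
            order = {p: i for i, p in enumerate(rel.ids)}
            if not all(p in order for p in parents):
                raise ValueError("relationship matrix does not cover all parents")
            sel = [order[p] for p in parents]
            G = rel.values[np.ix_(sel, sel)]
        terms.append(RandomTerm(name="additive", Z=Za, levels=parents, G=G))
        terms.append(RandomTerm(name="sca", Z=Zh, levels=hybrids))
    return y, X, names, terms, df


# ---------------------------------------------------------------------------
# REML core
# ---------------------------------------------------------------------------

def _ar1(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _residual_corr(df: pd.DataFrame, rho_row: float, rho_col: float) -> np.ndarray:
    rows = df["row"].to_numpy(int)
    cols = df["col"].to_numpy(int)
    Rr = _ar1(rows.max(), rho_row)[np.ix_(rows - 1, rows - 1)]
    Rc = _ar1(cols.max(), rho_col)[np.ix_(cols - 1, cols - 1)]
    return Rr * Rc


@dataclass
class _REMLState:
    theta: np.ndarray
    loglik: float
    P: np.ndarray
    Py: np.ndarray
    Vinv_chol = None


def _reml_loglik(y, X, A_list, R, theta):
    n = len(y)
    V = theta[-1] * R
    for t, A in zip(theta[:-1], A_list):
        V = V + t * A
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return None
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    C = XtVinv @ X
    sign, logdetC = np.linalg.slogdet(C)
    if sign <= 0:
        return None
    Cinv = np.linalg.inv(C)
    P = Vinv - XtVinv.T @ Cinv @ XtVinv
    Py = P @ y
    ll = -0.5 * (logdetV + logdetC + float(y @ Py))
    return ll, P, Py, Vinv, Cinv


def fit_mixed_model(y: np.ndarray, X: np.ndarray, terms: list[RandomTerm],
                    R: np.ndarray | None = None, theta0: np.ndarray | None = None,
                    tol_ll: float = 1e-6, tol_theta: float = 1e-5,
                    max_iter: int = 200):
    """AI-REML with EM fallback for a dense multi-component mixed model.

    Returns (theta, se, loglik, converged, n_iter, P, Py) where theta holds
    one variance per random term followed by the residual variance.
    """
    n = len(y)
    if R is None:
        R = np.eye(n)
    A_list = []
    for t in terms:
        if t.G is None:
            A_list.append(t.Z @ t.Z.T)
        else:
            A_list.append(t.Z @ t.G @ t.Z.T)
    k = len(A_list) + 1
    vy = float(np.var(y)) or 1.0
    theta = (np.full(k, vy / k) if theta0 is None
             else np.asarray(theta0, float).copy())
    theta = np.maximum(theta, VAR_FLOOR)
    q_list = [t.Z.shape[1] for t in terms] + [n - X.shape[1]]
    full_A = A_list + [R]

    out = _reml_loglik(y, X, A_list, R, theta)
    if out is None:
        raise np.linalg.LinAlgError("initial V not positive definite")
    ll, P, Py, _, _ = out
    converged = False
    AI = None
    it = 0
    for it in range(1, max_iter + 1):
        APy = [A @ Py for A in full_A]
        score = np.array([-0.5 * (np.sum(P * A) - Py @ aPy)
                          for A, aPy in zip(full_A, APy)])
        PAPy = [P @ aPy for aPy in APy]
        AI = 0.5 * np.array([[APy[i] @ PAPy[j] for j in range(k)]
                             for i in range(k)])
        # EM update (ascent step, used as fallback)
        em = np.array([theta[i] + theta[i] ** 2 *
                       (Py @ APy[i] - np.sum(P * full_A[i])) / q_list[i]
                       for i in range(k)])
        em = np.maximum(em, VAR_FLOOR)
        cand = None
        # active-set AI step: components pinned at the floor whose gradient
        # points further down are held fixed, the Newton-like step is taken
        # in the free components only
        pinned = (theta <= VAR_FLOOR * 1.01) & (score < 0)
        free = np.flatnonzero(~pinned)
        if free.size:
            try:
                sub = AI[np.ix_(free, free)]
                step = np.linalg.solve(sub + 1e-10 * np.eye(free.size),
                                       score[free])
                prop = theta.copy()
                prop[free] = theta[free] + step
                prop = np.maximum(prop, VAR_FLOOR)
                res = _reml_loglik(y, X, A_list, R, prop)
                tries = 0
                while res is not None and res[0] < ll - 1e-10 and tries < 5:
                    prop = 0.5 * (prop + theta)       # step halving
                    res = _reml_loglik(y, X, A_list, R, prop)
                    tries += 1
                if res is not None and res[0] >= ll - 1e-10:
                    cand = (prop, res)
            except np.linalg.LinAlgError:
                pass
        if cand is None:
            res = _reml_loglik(y, X, A_list, R, em)
            if res is None:
                logger.warning("EM update failed; stopping")
                break
            # numerical safeguard: halve toward current if decrease
            prop = em
            tries = 0
            while res[0] < ll - 1e-8 and tries < 20:
                prop = 0.5 * (prop + theta)
                res = _reml_loglik(y, X, A_list, R, prop)
                tries += 1
                if res is None:
                    break
            if res is None:
                break
            cand = (prop, res)
        new_theta, (new_ll, P, Py, _, _) = cand
        d_ll = new_ll - ll
        d_theta = np.max(np.abs(new_theta - theta) / np.maximum(theta, 1e-3))
        theta, ll = new_theta, new_ll
        if abs(d_ll) < tol_ll and d_theta < tol_theta:
            converged = True
            break
    if not converged:
        # boundary-adjacent components can stall both the AI step and EM;
        # polish with a direct search on log-variances
        def neg(x):
            res = _reml_loglik(y, X, A_list, R, np.exp(x))
            return 1e12 if res is None else -res[0]

        start = optimize.minimize(neg, np.log(np.maximum(theta, VAR_FLOOR)),
                                  method="Nelder-Mead",
                                  options={"maxfev": 400, "fatol": 1e-8,
                                           "xatol": 1e-6})
        polished = np.maximum(np.exp(start.x), VAR_FLOOR)
        res = _reml_loglik(y, X, A_list, R, polished)
        if res is not None and res[0] >= ll:
            theta = polished
            ll, P, Py, _, _ = res
            converged = True
        else:
            logger.warning("REML not converged after %d iterations", it)
    se = np.full(k, np.nan)
    if AI is not None:
        try:
            se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
        except np.linalg.LinAlgError:
            pass
    return theta, se, ll, converged, it, P, Py


def _blups(terms, theta, P, Py, y, X):
    """BLUPs, PEVs and reliabilities at the converged variance components."""
    out = {}
    for i, t in enumerate(terms):
        s2 = theta[i]
        G = t.G if t.G is not None else np.eye(t.Z.shape[1])
        GZt = G @ t.Z.T
        u = s2 * GZt @ Py
        # PEV = var(u - uhat) = s2 G - s2^2 G Z' P Z G
        M = s2 * G - s2 ** 2 * GZt @ P @ GZt.T
        pev = np.clip(np.diag(M), 0.0, None)
        denom = s2 * np.diag(G)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(denom > 0, 1.0 - pev / denom, 0.0)
        rel = np.clip(rel, 0.0, 1.0)
        n_obs = t.Z.sum(axis=0)
        out[t.name] = pd.DataFrame({
            "level": t.levels, "blup": u, "pev": pev,
            "reliability": rel, "n_obs": n_obs,
        })
    return out


def reml_fit(pheno: pd.DataFrame, spec: TrialModelSpec,
             rel: RelationshipMatrix | None = None,
             H: pd.DataFrame | None = None,
             rho: tuple | None = None,
             max_iter: int = 200) -> TrialFit:
    """Fit one trial site's mixed model by REML.

    For ``residual='ar1xar1'`` the two AR1 parameters are profiled out with a
    derivative-free outer search (Nelder–Mead on atanh-transformed
    correlations) around the inner variance-component REML, unless ``rho``
    is supplied.
    """
    y, X, names, terms, df = build_site_design(pheno, spec, H=H, rel=rel)
    n = len(y)

    def fit_at(R, theta0=None, inner_iter=max_iter):
        return fit_mixed_model(y, X, terms, R=R, theta0=theta0,
                               max_iter=inner_iter)

    rho_hat = None
    if spec.residual == "iid":
        theta, se, ll, conv, it, P, Py = fit_at(None)
        n_par = len(terms) + 1
    else:
        if df["row"].nunique() == 1 or df["col"].nunique() == 1:
            logger.warning("1-D layout: falling back to single-direction AR1")
        warm = {"theta": None}

        def neg_ll(z):
            rr, rc = np.tanh(z)
            R = _residual_corr(df, rr, rc)
            try:
                th, _, l, _, _, _, _ = fit_at(R, theta0=warm["theta"],
                                              inner_iter=60)
            except np.linalg.LinAlgError:
                return 1e10
            warm["theta"] = th
            return -l

        if rho is None:
            z0 = np.arctanh([0.3, 0.3])
            res = optimize.minimize(neg_ll, z0, method="Nelder-Mead",
                                    options={"xatol": 1e-3, "fatol": 1e-4,
                                             "maxfev": 80})
            rho_hat = tuple(np.tanh(res.x))
        else:
            rho_hat = tuple(rho)
        R = _residual_corr(df, *rho_hat)
        theta, se, ll, conv, it, P, Py = fit_at(R, theta0=warm.get("theta"))
        n_par = len(terms) + 1 + 2

    Vinv_beta = None
    # fixed effects: GLS at converged components
    #   beta = (X' V^-1 X)^-1 X' V^-1 y ; recover via P: V^-1 y = P y + V^-1 X beta
    # simplest: rebuild V
    R_used = np.eye(n) if spec.residual == "iid" else _residual_corr(df, *rho_hat)
    V = theta[-1] * R_used
    for th, t in zip(theta[:-1], terms):
        A = t.Z @ (t.Z.T if t.G is None else t.G @ t.Z.T)
        V = V + th * A
    Vinv = np.linalg.inv(V)
    C = X.T @ Vinv @ X
    beta = np.linalg.solve(C, X.T @ Vinv @ y)
    blups = _blups(terms, theta, P, Py, y, X)
    varcomp = {t.name: float(theta[i]) for i, t in enumerate(terms)}
    varcomp["residual"] = float(theta[-1])
    varcomp_se = {t.name: float(se[i]) for i, t in enumerate(terms)}
    varcomp_se["residual"] = float(se[-1])
    aic = -2.0 * ll + 2.0 * n_par
    return TrialFit(varcomp=varcomp, varcomp_se=varcomp_se, loglik=ll,
                    converged=conv, n_iter=it,
                    beta=pd.Series(beta, index=names), blups=blups,
                    residual=spec.residual, rho=rho_hat, aic=aic, spec=spec)


def compare_spatial(pheno: pd.DataFrame, spec: TrialModelSpec,
                    rel: RelationshipMatrix | None = None,
                    H: pd.DataFrame | None = None) -> dict:
    """Fit iid and AR1⊗AR1 residual variants; pick the lower AIC.

    Returns {"iid": fit, "ar1xar1": fit, "selected": name, "fit": winner}.
    """
    fits = {}
    for res_type in ("iid", "ar1xar1"):
        s = TrialModelSpec(genetic=spec.genetic, design_terms=spec.design_terms,
                           residual=res_type, relationship=spec.relationship)
        fits[res_type] = reml_fit(pheno, s, rel=rel, H=H)
    selected = min(fits, key=lambda k: fits[k].aic)
    return {"iid": fits["iid"], "ar1xar1": fits["ar1xar1"],
            "selected": selected, "fit": fits[selected]}


# ---------------------------------------------------------------------------
# Multi-site convenience
# ---------------------------------------------------------------------------

def fit_all_sites(pheno: pd.DataFrame, spec: TrialModelSpec,
                  H: pd.DataFrame | None = None,
                  rel: RelationshipMatrix | None = None) -> dict:
    """reml_fit per site; returns {site: TrialFit}."""
    out = {}
    for site, df in pheno.groupby("site", sort=True):
        out[site] = reml_fit(df, spec, rel=rel, H=H)
        logger.info("site %s: varcomp %s, ll=%.2f", site,
                    {k: round(v, 4) for k, v in out[site].varcomp.items()},
                    out[site].loglik)
    return out


def parent_blup_table(fits: dict, term: str = "additive",
                      min_obs: int = 1) -> pd.DataFrame:
    """Stack per-site parent BLUPs into a levels × sites table (NaN where a
    parent has fewer than ``min_obs`` plots at a site)."""
    cols = {}
    for site, fit in fits.items():
        t = fit.blups[term].set_index("level")
        vals = t["blup"].where(t["n_obs"] >= min_obs)
        cols[site] = vals
    return pd.DataFrame(cols)
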
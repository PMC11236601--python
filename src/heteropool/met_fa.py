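"""Factor-analytic model of additive effects across trial sites.

Stage-1 per-site additive BLUPs (rows = genotypes/parents, columns = sites)
feed an EM factor analysis of the between-site genetic covariance
G = ΛΛᵀ + Ψ, tolerating missing cells (a genotype untested at a site).
From the fitted G we derive the additive genetic correlation matrix, percent
variance explained by the leading factors, and a hierarchical clustering of
sites into environment clusters on distance 1 − correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "FAModel",
    "EnvClustering",
    "fit_fa",
    "genetic_correlation",
    "variance_explained",
    "cluster_sites",
]


@dataclass
class FAModel:
    """Fitted factor-analytic covariance ΛΛᵀ + Ψ over sites."""

    loadings: np.ndarray        # sites × k, lower-triangular identification
    psi: np.ndarray             # site-specific variances (diagonal of Ψ)
    sites: np.ndarray
    loglik: float
    loglik_path: np.ndarray
    converged: bool
    n_genotypes: int

    def __post_init__(self) -> None:
        if (self.psi < -1e-10).any():
            raise ValueError("specific variances must be >= 0")
        self.psi = np.clip(self.psi, 0.0, None)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def G(self) -> np.ndarray:
        """Implied between-site additive covariance."""
        return self.loadings @ self.loadings.T + np.diag(self.psi)


@dataclass
class EnvClustering:
    linkage: np.ndarray
    labels: np.ndarray          # cluster id per site, 1..n_clusters
    sites: np.ndarray
    n_clusters: int
    distance: str = "1-correlation"
    method: str = "average"
    degenerate: bool = False

    def groups(self) -> dict:
        out: dict[int, list] = {}
        for s, l in zip(self.sites, self.labels):
            out.setdefault(int(l), []).append(s)
        return out


# ---------------------------------------------------------------------------
# EM factor analysis with missing data
# ---------------------------------------------------------------------------

def _rotate_lower_triangular(lam: np.ndarray) -> np.ndarray:
    """Rotate Λ to the lower-triangular identification with non-negative
    leading diagonal (Λ ← Λ·T, T orthogonal)."""
    k = lam.shape[1]
    if k == 1:
        return lam if lam[0, 0] >= 0 else -lam
    q, r = np.linalg.qr(lam.T)            # lamᵀ = q r, r upper (k × S)
    lam_rot = r.T                          # S × k, upper triangle zero
    signs = np.sign(np.diag(lam_rot[:k, :k]))
    signs[signs == 0] = 1.0
    return lam_rot * signs[None, :]


def fit_fa(effects: pd.DataFrame, k: int, weights: pd.Series | None = None,
           tol: float = 1e-8, max_iter: int = 20000,
           psi_floor: float = 1e-10, seed: int = 0) -> FAModel:
    """Weighted EM factor analysis of a genotype × site effects table.

    Rows are genotypes, columns are sites; NaN marks a genotype absent at a
    site. Columns are centered, then y_g ~ N(0, ΛΛᵀ + Ψ) is maximized by EM
    over the observed entries (missing entries are integrated out, so sparse
    tables are handled exactly). Optional per-genotype weights multiply each
    genotype's contribution to the sufficient statistics.

    Sites sharing fewer than 2 genotypes with every other site are excluded
    with a warning. The returned loadings are rotated to the standard
    lower-triangular identification.
    """
    Y = effects.to_numpy(float)
    sites = np.asarray(effects.columns, dtype=object)
    S = Y.shape[1]
    if k >= S:
        raise ValueError(f"k={k} must be smaller than the number of sites {S}")
    obs = ~np.isnan(Y)
    # drop sites with insufficient overlap
    overlap = (obs.astype(int).T @ obs.astype(int))
    np.fill_diagonal(overlap, 0)
    ok = overlap.max(axis=1) >= 2
    if not ok.all():
        dropped = sites[~ok]
        warnings.warn(f"sites excluded for insufficient genotype overlap: "
                      f"{list(dropped)}")
        Y, sites, obs = Y[:, ok], sites[ok], obs[:, ok]
        S = Y.shape[1]
        if k >= S:
            raise ValueError("k too large after dropping low-overlap sites")
    keep_rows = obs.any(axis=1)
    Y, obs = Y[keep_rows], obs[keep_rows]
    N = Y.shape[0]
    w = (np.ones(N) if weights is None
         else np.asarray(weights.reindex(effects.index[keep_rows]).fillna(1.0)))
    wsum = w.sum()
    mu = np.array([np.average(Y[obs[:, j], j], weights=w[obs[:, j]])
                   for j in range(S)])
    Yc = Y - mu[None, :]

    rng = np.random.default_rng(seed)
    col_var = np.array([np.var(Yc[obs[:, j], j]) if obs[:, j].sum() > 1 else 1.0
                        for j in range(S)])
    col_var = np.maximum(col_var, 1e-6)
    lam = rng.normal(0, 1, size=(S, k)) * np.sqrt(col_var / (k + 1))[:, None]
    psi = col_var / 2.0

    # group genotypes by observation pattern to amortize the E-step
    patterns: dict[bytes, list[int]] = {}
    for g in range(N):
        patterns.setdefault(obs[g].tobytes(), []).append(g)

    path = []
    ll_old = -np.inf
    converged = False
    for it in range(max_iter):
        S_ff = np.zeros((k, k))
        S_yf = np.zeros((S, k))
        S_yy = np.zeros(S)
        ll = 0.0
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            if not o.any():
                continue
            idx = np.asarray(rows)
            lam_o = lam[o]
            G_oo = lam_o @ lam_o.T + np.diag(psi[o])
            try:
                Gi = np.linalg.inv(G_oo)
            except np.linalg.LinAlgError:
                Gi = np.linalg.pinv(G_oo)
            Yo = Yc[np.ix_(idx, np.flatnonzero(o))]
            wg = w[idx]
            # observed-data loglik for this pattern
            sign, logdet = np.linalg.slogdet(G_oo)
            quad = np.einsum("gi,ij,gj->g", Yo, Gi, Yo)
            ll += float(np.sum(wg * (-0.5 * (o.sum() * np.log(2 * np.pi)
                                             + logdet + quad))))
            B = Gi @ lam_o                       # (o, k)
            mu_f = Yo @ B                        # (n_g, k)
            Sigma_f = np.eye(k) - lam_o.T @ B    # (k, k)
            W = wg.sum()
            Eff = W * Sigma_f + (mu_f * wg[:, None]).T @ mu_f
            S_ff += Eff
            # observed sites
            oi = np.flatnonzero(o)
            S_yf[oi] += (Yo * wg[:, None]).T @ mu_f
            S_yy[oi] += np.sum(wg[:, None] * Yo ** 2, axis=0)
            # missing sites: expectations under current params
            mi = np.flatnonzero(~o)
            if mi.size:
                lam_m = lam[mi]
                S_yf[mi] += lam_m @ Eff
                ym = mu_f @ lam_m.T              # E[y_m]
                var_m = (np.einsum("ij,jk,ik->i", lam_m, Sigma_f, lam_m)
                         + psi[mi])
                S_yy[mi] += W * var_m + np.sum(wg[:, None] * ym ** 2, axis=0)
                # note E[y_m^2] = Var(y_m|y_o) + E[y_m|y_o]^2 per genotype;
                # Var term is pattern-constant so scales by summed weight
        lam_new = np.linalg.solve(S_ff.T, S_yf.T).T
        psi_new = np.maximum((S_yy - np.sum(lam_new * S_yf, axis=1)) / wsum,
                             psi_floor)
        lam, psi = lam_new, psi_new
        path.append(ll)
        if it > 0 and abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    if not converged:
        logger.warning("fit_fa: EM not converged after %d iterations", max_iter)
    lam = _rotate_lower_triangular(lam)
    return FAModel(loadings=lam, psi=psi, sites=sites, loglik=ll_old,
                   loglik_path=np.array(path), converged=converged,
                   n_genotypes=N)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def genetic_correlation(model: FAModel,
                        site_reliability: pd.Series | None = None) -> pd.DataFrame:
    """Additive genetic correlation C = D^{-1/2} G D^{-1/2}, D = diag(G).

    When the FA was fitted to stage-1 BLUPs, their shrinkage attenuates the
    between-site correlation by sqrt(rel_i · rel_j) (each site's BLUP is
    rel·g plus independent estimation noise). Passing the per-site mean
    reliabilities applies the inverse correction, clipped to [−1, 1].

    Sites with zero total variance get NaN correlations (with a warning)."""
    G = model.G
    d = np.diag(G).copy()
    zero = d <= 0
    if zero.any():
        warnings.warn(f"zero additive variance at sites "
                      f"{list(model.sites[zero])}; correlations undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        s = 1.0 / np.sqrt(np.where(zero, np.nan, d))
    C = G * s[:, None] * s[None, :]
    np.fill_diagonal(C, np.where(zero, np.nan, 1.0))
    C = np.clip(C, -1.0, 1.0)
    if site_reliability is not None:
        rel = site_reliability.reindex(model.sites).to_numpy(float)
        if np.isnan(rel).any() or (rel <= 0).any() or (rel > 1).any():
            raise ValueError("site reliabilities must cover all sites and "
                             "lie in (0, 1]")
        atten = np.sqrt(rel[:, None] * rel[None, :])
        C = np.clip(C / atten, -1.0, 1.0)
        np.fill_diagonal(C, np.where(zero, np.nan, 1.0))
    return pd.DataFrame(C, index=model.sites, columns=model.sites)


def variance_explained(model: FAModel, m: int) -> dict:
    """Percent additive variance explained per site by the first m factors,
    plus the unweighted mean and the variance-weighted mean over sites."""
    if m > model.k or m < 0:
        raise ValueError("m must lie in [0, k]")
    lam2 = model.loadings ** 2
    total = lam2.sum(axis=1) + model.psi
    lead = lam2[:, :m].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(total > 0, 100.0 * lead / total, 0.0)
    overall = float(per_site.mean())
    weighted = float(100.0 * lead.sum() / total.sum()) if total.sum() > 0 else 0.0
    return {"per_site": pd.Series(per_site, index=model.sites),
            "overall_mean": overall, "overall_weighted": weighted}


def cluster_sites(corr: pd.DataFrame, n_clusters: int | None = None,
                  method: str = "average") -> EnvClustering:
    """Agglomerative clustering of sites on distance 1 − correlation.

    If ``n_clusters`` is None the count is chosen at the largest relative gap
    between successive merge heights; a flat dendrogram (all merge heights
    equal) degenerates to a single cluster with a warning.
    """
    sites = np.asarray(corr.columns, dtype=object)
    S = len(sites)
    if n_clusters is not None and n_clusters > S:
        raise ValueError("n_clusters exceeds the number of sites")
    C = np.clip(corr.to_numpy(float), -1.0, 1.0)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    degenerate = False
    if n_clusters is None:
        heights = Z[:, 2]
        if np.allclose(heights, heights[0]):
            warnings.warn("flat merge heights: no cluster structure; "
                          "falling back to a single cluster")
            n_clusters = 1
            degenerate = True
        else:
            # largest relative gap between successive merge heights; the gap
            # after merge i supports S - i - 1 clusters
            base = np.maximum(heights[:-1], 1e-12)
            gaps = np.diff(heights) / base
            cut = int(np.argmax(gaps))
            n_clusters = S - cut - 1
    raw = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    # relabel clusters 1..n in order of first site appearance (stable under
    # site permutation up to label names)
    relabel: dict[int, int] = {}
    labels = np.empty_like(raw)
    for i, r in enumerate(raw):
        labels[i] = relabel.setdefault(r, len(relabel) + 1)
    return EnvClustering(linkage=Z, labels=labels, sites=sites,
                         n_clusters=int(labels.max()), method=method,
                         degenerate=degenerate)


def dendrogram_newick(clust: EnvClustering) -> str:
    """Dendrogram as a newick string (branch lengths = merge heights)."""
    tree = hierarchy.to_tree(clust.linkage)
    names = list(map(str, clust.sites))

    def rec(node, parent_h):
        length = max(parent_h - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
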
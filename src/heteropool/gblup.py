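"""Genomic relationship matrix, GBLUP and marker-effect backsolving.

The genomic relationship matrix follows the classical marker-based
construction K = ZZᵀ / (2 Σ p(1−p)) with Z the column-centered dosage
matrix. GBLUP solves the mixed-model equations with parent effects
distributed N(0, K σ²_a); per-marker additive effects are recovered by the
backsolve α = Zᵀ K⁻¹ ĝ / (2 Σ p(1−p)), which reproduces ĝ exactly whenever
K has full rank from these markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GRM",
    "MarkerEffects",
    "compute_grm",
    "gblup_solve",
    "backsolve_markers",
    "effect_profile",
    "effect_concordance",
]


@dataclass
class GRM:
    """Genomic relationship matrix over parents."""

    values: np.ndarray
    ids: np.ndarray
    allele_freq: np.ndarray
    scaling: float                   # 2 Σ p(1-p)
    Z: np.ndarray                    # centered (mean-imputed) dosage used
    marker_ids: np.ndarray
    ridge_applied: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        self.values = 0.5 * (v + v.T)
        self.ids = np.asarray(self.ids, dtype=object)


@dataclass
class MarkerEffects:
    """Per-marker additive effects (yield units per allele dose)."""

    table: pd.DataFrame              # marker, chrom, cm, effect[, top]
    site: str | None = None

    def __post_init__(self) -> None:
        need = {"marker", "effect"}
        if not need.issubset(self.table.columns):
            raise ValueError("marker effect table needs 'marker' and 'effect'")

    @property
    def effects(self) -> np.ndarray:
        return self.table["effect"].to_numpy(float)


def compute_grm(g: GenotypeMatrix, freq: np.ndarray | None = None) -> GRM:
    """Marker-based relationship matrix.

    Z = dosage − 2p with missing dosages mean-imputed (at 2p) per marker
    before centering; K = ZZᵀ / (2 Σ p(1−p)). Allele frequencies are
    observed by default; a supplied vector overrides them.
    """
    x = g.dosage_float()
    p = g.allele_freq() if freq is None else np.asarray(freq, float)
    if np.isnan(p).any():
        raise ValueError("allele frequency not estimable for some markers")
    n_imp = int(np.isnan(x).sum())
    if n_imp:
        logger.info("compute_grm: mean-imputed %d missing dosages", n_imp)
    x = np.where(np.isnan(x), 2.0 * p[None, :], x)
    Z = x - 2.0 * p[None, :]
    scaling = float(2.0 * np.sum(p * (1.0 - p)))
    if scaling <= 0:
        raise ValueError("all markers monomorphic: GRM scaling constant is zero")
    K = (Z @ Z.T) / scaling
    return GRM(values=K, ids=g.individual_ids.copy(), allele_freq=p,
               scaling=scaling, Z=Z, marker_ids=g.marker_ids.copy())


def gblup_solve(effects: pd.DataFrame, K: GRM,
                design: pd.DataFrame | None = None,
                variances: tuple | None = None,
                ridge: float = 1e-8) -> dict:
    """GBLUP of parent additive effects from phenotypes or adjusted means.

    ``effects`` has columns ``entry`` and ``value``; an entry is either a
    parent id (direct records) or a hybrid id present in ``design`` (the
    hybrid → parent incidence), in which case its expectation is the sum of
    its two parents' effects. Model: value = μ + z'u + e with
    u ~ N(0, K σ²_a), e ~ N(0, I σ²_e). Variances are REML-estimated when
    not supplied. Hybrid additive values are returned as parent-GEBV sums.
    """
    ids = list(K.ids)
    pidx = {p: i for i, p in enumerate(ids)}
    n = len(effects)
    Z = np.zeros((n, len(ids)))
    for r, entry in enumerate(effects["entry"]):
        if entry in pidx:
            Z[r, pidx[entry]] = 1.0
        elif design is not None and entry in design.index:
            row = design.loc[entry]
            for p, v in row[row > 0].items():
                Z[r, pidx[p]] += float(v)
        else:
            raise ValueError(f"entry {entry!r} is neither a parent in the GRM "
                             "nor a hybrid in the design")
    y = effects["value"].to_numpy(float)
    X = np.ones((n, 1))
    Kv = K.values
    if variances is None:
        from .trial_models import RandomTerm, fit_mixed_model
        term = RandomTerm(name="additive", Z=Z, levels=np.asarray(ids, object),
                          G=Kv)
        theta, _, ll, conv, _, P, Py = fit_mixed_model(y, X, [term])
        s2a, s2e = float(theta[0]), float(theta[1])
    else:
        s2a, s2e = map(float, variances)
        ll, conv = np.nan, True
    # V-form BLUP (never inverts K, which is singular by construction when
    # built from observed-frequency-centered markers):
    #   V = Z (s2a K) Z' + s2e I;  beta = GLS;  u = s2a K Z' V^-1 (y - X beta)
    KZt = Kv @ Z.T
    V = s2a * (Z @ KZt) + s2e * np.eye(n)
    applied = 0.0
    try:
        Vc = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        applied = ridge
        logger.warning("singular GBLUP system: adding ridge %.1e", ridge)
        Vc = np.linalg.cholesky(V + ridge * np.eye(n))
    from scipy.linalg import cho_solve
    ViX = cho_solve((Vc, True), X)
    beta = np.linalg.solve(X.T @ ViX, ViX.T @ y)
    r = y - X @ beta
    u = s2a * KZt @ cho_solve((Vc, True), r)
    mu = float(beta[0])
    gebv = pd.Series(u, index=ids, name="gebv")
    hybrid_values = None
    if design is not None:
        hv = design.to_numpy() @ gebv.reindex(design.columns).to_numpy()
        hybrid_values = pd.Series(hv, index=design.index, name="additive")
    return {"gebv": gebv, "hybrid_additive": hybrid_values, "mu": mu,
            "sigma2_a": s2a, "sigma2_e": s2e, "loglik": ll,
            "converged": conv, "ridge_applied": applied}


def backsolve_markers(gebv: pd.Series, grm: GRM) -> MarkerEffects:
    """Backsolve per-marker additive effects from parent GEBVs.

    α = Zᵀ K⁻¹ ĝ / (2 Σ p(1−p)). When K is singular (fewer informative
    markers than parents) the pseudo-inverse is used and the rank logged.
    """
    g = gebv.reindex(grm.ids).to_numpy(float)
    if np.isnan(g).any():
        raise ValueError("GEBV vector does not cover all GRM individuals")
    K = grm.values
    w, v = np.linalg.eigh(K)
    rank_tol = 1e-10 * max(w.max(), 1.0)
    rank = int((w > rank_tol).sum())
    if rank < K.shape[0]:
        logger.info("backsolve_markers: GRM rank %d < %d, using pseudo-inverse",
                    rank, K.shape[0])
        winv = np.where(w > rank_tol, 1.0 / np.where(w > rank_tol, w, 1.0), 0.0)
        Kg = v @ (winv * (v.T @ g))
    else:
        Kg = np.linalg.solve(K, g)
    alpha = grm.Z.T @ Kg / grm.scaling
    table = pd.DataFrame({"marker": grm.marker_ids, "effect": alpha})
    return MarkerEffects(table=table)


def effect_profile(effects: MarkerEffects, top_fraction: float = 0.10,
                   chrom: np.ndarray | None = None,
                   cm: np.ndarray | None = None) -> pd.DataFrame:
    """Flag the top fraction of markers by |effect| and order the table by
    genome position for Manhattan-style plotting. Ties at the |effect|
    threshold are broken by marker order."""
    t = effects.table.copy()
    if chrom is not None:
        t["chrom"] = np.asarray(chrom, dtype=object)
    if cm is not None:
        t["cm"] = np.asarray(cm, float)
    n_top = int(round(top_fraction * len(t)))
    order = np.argsort(-np.abs(t["effect"].to_numpy()), kind="stable")
    flag = np.zeros(len(t), dtype=bool)
    flag[order[:n_top]] = True
    t["top"] = flag
    if "chrom" in t and "cm" in t:
        t = t.sort_values(["chrom", "cm"], kind="stable").reset_index(drop=True)
    return t


def effect_concordance(a: MarkerEffects, b: MarkerEffects) -> dict:
    """Cross-site concordance of two marker-effect vectors: sign-agreement
    fraction and Pearson correlation on shared markers."""
    ta = a.table.set_index("marker")["effect"]
    tb = b.table.set_index("marker")["effect"]
    shared = ta.index.intersection(tb.index)
    x, y = ta.loc[shared].to_numpy(), tb.loc[shared].to_numpy()
    nz = (x != 0) & (y != 0)
    sign_agree = float(np.mean(np.sign(x[nz]) == np.sign(y[nz]))) if nz.any() else np.nan
    if x.std() > 0 and y.std() > 0:
        corr = float(np.corrcoef(x, y)[0, 1])
    else:
        corr = 1.0 if np.allclose(x, y) else np.nan
    return {"n_shared": int(len(shared)), "sign_agreement": sign_agree,
            "correlation": corr}
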
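"""Population-structure characterization of the parental panel.

Marker QC (heterozygosity / missingness / complete-LD pruning), Rogers'
genetic distance, classical principal coordinate analysis, and a
maximum-likelihood admixture model (binomial likelihood in ancestry
proportions Q and ancestral allele frequencies P, maximized by EM) with
masked-entry cross-validation to choose the number of ancestral populations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import GenotypeMatrix, _stream

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "AdmixtureFit",
    "PCoAResult",
    "filter_markers",
    "prune_complete_ld",
    "rogers_distance",
    "pcoa",
    "admixture_fit",
    "select_K_cv",
]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_markers(g: GenotypeMatrix, max_het: float = 0.5,
                   max_missing: float = 0.1) -> GenotypeMatrix:
    """Drop markers whose heterozygote fraction exceeds ``max_het`` or whose
    missing fraction exceeds ``max_missing`` (strictly greater triggers
    exclusion). Marker order is preserved."""
    if g.n_markers == 0 or g.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    if not (0 <= max_het <= 1 and 0 <= max_missing <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    keep = (g.het_fraction() <= max_het) & (g.missing_fraction() <= max_missing)
    logger.info("filter_markers: kept %d of %d markers", keep.sum(), g.n_markers)
    return g.take_markers(np.flatnonzero(keep))


def prune_complete_ld(g: GenotypeMatrix, tol: float = 1e-12) -> GenotypeMatrix:
    """Remove one marker of every pair in complete linkage (r² = 1).

    Monomorphic markers (zero dosage variance among non-missing calls) are
    dropped first, since r² is undefined for them. For each remaining pair
    with squared pairwise-complete Pearson correlation within ``tol`` of 1,
    the later marker in input order is dropped; applied transitively so no
    surviving pair has r² = 1.
    """
    if g.n_markers == 0:
        raise ValueError("empty genotype matrix")
    x = g.dosage_float()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(x, axis=0)
    poly = np.flatnonzero(var > 0)
    n_mono = g.n_markers - poly.size
    if n_mono:
        logger.info("prune_complete_ld: dropped %d monomorphic markers", n_mono)
    x = x[:, poly]
    m = x.shape[1]
    keep_mask = np.ones(m, dtype=bool)
    obs = ~np.isnan(x)
    xf = np.where(obs, x, 0.0)
    for j in range(m):
        if not keep_mask[j]:
            continue
        later = np.flatnonzero(keep_mask[j + 1:]) + j + 1
        if later.size == 0:
            continue
        # pairwise-complete correlation of column j with each later survivor
        oj = obs[:, j]
        both = oj[:, None] & obs[:, later]
        n = both.sum(axis=0).astype(float)
        valid = n > 1
        with np.errstate(invalid="ignore", divide="ignore"):
            sx = np.where(both, xf[:, [j]], 0.0).sum(axis=0)
            sy = np.where(both, xf[:, later], 0.0).sum(axis=0)
            sxx = np.where(both, xf[:, [j]] ** 2, 0.0).sum(axis=0)
            syy = np.where(both, xf[:, later] ** 2, 0.0).sum(axis=0)
            sxy = np.where(both, xf[:, [j]] * xf[:, later], 0.0).sum(axis=0)
            cov = sxy - sx * sy / n
            vx = sxx - sx ** 2 / n
            vy = syy - sy ** 2 / n
            r2 = cov ** 2 / (vx * vy)
        dup = valid & np.isfinite(r2) & (r2 >= 1.0 - tol)
        keep_mask[later[dup]] = False
    kept = poly[keep_mask]
    logger.info("prune_complete_ld: kept %d of %d markers", kept.size, g.n_markers)
    return g.take_markers(kept)


# ---------------------------------------------------------------------------
# Rogers' distance and PCoA
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Square symmetric Rogers' distance matrix over individuals."""

    values: np.ndarray
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("Rogers' distances must lie in [0, 1]")
        self.values = d
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)


def rogers_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Locus-mean Rogers' distance.

    Per biallelic locus each individual is the frequency vector
    ((2−d)/2, d/2); the per-locus distance sqrt(½ Σ (p−q)²) reduces to
    |d_i − d_j| / 2, and the total distance is the mean over loci observed in
    both individuals.
    """
    x = g.dosage_float()
    n = g.n_individuals
    obs = ~np.isnan(x)
    xf = np.where(obs, x, 0.0)
    # sum_k |d_i - d_j| over shared loci, via the identity
    # |a-b| on dosages in {0,1,2}: compute with indicator expansion per level.
    d = np.zeros((n, n))
    shared = obs.astype(float) @ obs.T.astype(float)
    for i in range(n):
        diff = np.abs(xf[i] - xf)            # (n, m)
        both = obs[i] & obs                   # (n, m)
        d[i] = np.where(both, diff, 0.0).sum(axis=1)
    if (shared == 0).any():
        ii, jj = np.nonzero(shared == 0)
        off = ii != jj
        if off.any():
            i0, j0 = ii[off][0], jj[off][0]
            raise ValueError(
                "no shared non-missing loci between "
                f"{g.individual_ids[i0]!r} and {g.individual_ids[j0]!r}")
    with np.errstate(invalid="ignore"):
        d = d / (2.0 * shared)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(values=d, individual_ids=g.individual_ids.copy())


@dataclass
class PCoAResult:
    coordinates: np.ndarray     # (n, n_axes) for positive-eigenvalue axes
    eigenvalues: np.ndarray     # all eigenvalues, descending (incl. negative)
    individual_ids: np.ndarray


def pcoa(d: DistanceMatrix, n_axes: int = 2) -> PCoAResult:
    """Classical multidimensional scaling of a distance matrix.

    Double-centers −½D², eigendecomposes, and returns axes sorted by
    eigenvalue. Negative eigenvalues are reported in ``eigenvalues`` but
    contribute no axes.
    """
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = 0.5 * (B + B.T)
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > 1e-10 * max(1.0, abs(w[0]))
    k = min(n_axes, int(pos.sum()))
    coords = v[:, :k] * np.sqrt(w[:k])
    return PCoAResult(coordinates=coords, eigenvalues=w,
                      individual_ids=d.individual_ids.copy())


# ---------------------------------------------------------------------------
# Admixture model
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureFit:
    """Maximum-likelihood admixture fit.

    Q (individuals × K) are ancestry proportions (rows on the simplex);
    P (K × markers) are ancestral allele frequencies.
    """

    Q: np.ndarray
    P: np.ndarray
    K: int
    loglik: float
    loglik_path: np.ndarray
    converged: bool
    cv_error: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")
        if self.P.min() < -1e-12 or self.P.max() > 1 + 1e-12:
            raise ValueError("P entries must lie in [0, 1]")


def _admix_loglik(d: np.ndarray, w: np.ndarray, Q: np.ndarray,
                  P: np.ndarray) -> float:
    f = np.clip(Q @ P, 1e-300, 1.0)
    g1 = np.clip(1.0 - Q @ P, 1e-300, 1.0)
    return float(np.sum(w * (d * np.log(f) + (2.0 - d) * np.log(g1))))


def admixture_fit(g: GenotypeMatrix, K: int, seed: int = 0,
                  tol: float = 1e-6, max_iter: int = 2000,
                  mask: np.ndarray | None = None) -> AdmixtureFit:
    """Fit the admixture likelihood by EM.

    The model treats the two alleles of individual i at marker j as Binomial
    draws with success probability f_ij = Σ_k q_ik p_kj. EM alternates
    expected allele-origin counts with closed-form updates of Q and P; the
    log-likelihood is non-decreasing every iteration. Missing genotype cells
    (and any cells in ``mask``) are excluded from the likelihood.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    d = g.dosage_float()
    w = (~np.isnan(d)).astype(float)
    if mask is not None:
        w = w * (~mask).astype(float)
    d = np.where(w > 0, np.nan_to_num(d), 0.0)
    n, m = d.shape
    if K == 1:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (w * d).sum(axis=0) / (2.0 * w.sum(axis=0))
        p = np.nan_to_num(p, nan=0.5)
        Q = np.ones((n, 1))
        P = p[None, :]
        ll = _admix_loglik(d, w, Q, P)
        return AdmixtureFit(Q=Q, P=P, K=1, loglik=ll,
                            loglik_path=np.array([ll]), converged=True)

    rng = _stream(seed, f"admixture:K={K}")
    Q = rng.dirichlet(np.ones(K), size=n)
    base = (w * d).sum(axis=0) / np.maximum(2.0 * w.sum(axis=0), 1e-12)
    P = np.clip(base[None, :] + rng.normal(0, 0.05, size=(K, m)), 0.01, 0.99)

    eps = 1e-12
    d2 = 2.0 - d

    def em_step(Q, P):
        """One ECM sweep (P-block then Q-block); each block is an ascent."""
        F = np.clip(Q @ P, eps, 1 - eps)
        WdF = w * d / F
        Wd2F = w * d2 / (1.0 - F)
        num = P * (Q.T @ WdF)                   # K × m
        den = num + (1.0 - P) * (Q.T @ Wd2F)
        P = np.clip(num / np.maximum(den, eps), eps, 1 - eps)
        F = np.clip(Q @ P, eps, 1 - eps)
        WdF = w * d / F
        Wd2F = w * d2 / (1.0 - F)
        counts = Q * (WdF @ P.T + Wd2F @ (1.0 - P).T)   # n × K
        Q = counts / np.maximum(counts.sum(axis=1, keepdims=True), eps)
        return Q, P

    def project(Q, P):
        Q = np.clip(Q, eps, None)
        Q = Q / Q.sum(axis=1, keepdims=True)
        return Q, np.clip(P, eps, 1 - eps)

    # Safeguarded SQUAREM acceleration: extrapolate along two EM steps and
    # keep the extrapolated point only if it does not lower the likelihood,
    # so the recorded path stays monotone while escaping EM's slow ridge.
    path = [_admix_loglik(d, w, Q, P)]
    converged = False
    n_em = 0
    while n_em < max_iter:
        Q1, P1 = em_step(Q, P)
        Q2, P2 = em_step(Q1, P1)
        n_em += 2
        rQ, rP = Q1 - Q, P1 - P
        vQ, vP = (Q2 - Q1) - rQ, (P2 - P1) - rP
        r_norm = np.sqrt((rQ ** 2).sum() + (rP ** 2).sum())
        v_norm = np.sqrt((vQ ** 2).sum() + (vP ** 2).sum())
        ll2 = _admix_loglik(d, w, Q2, P2)
        if v_norm > 0:
            alpha = max(-r_norm / v_norm, -64.0)
            Qs, Ps = project(Q - 2 * alpha * rQ + alpha ** 2 * vQ,
                             P - 2 * alpha * rP + alpha ** 2 * vP)
            Qs, Ps = em_step(Qs, Ps)            # stabilizing EM step
            n_em += 1
            lls = _admix_loglik(d, w, Qs, Ps)
            if lls >= ll2:
                Q, P, ll = Qs, Ps, lls
            else:
                Q, P, ll = Q2, P2, ll2
        else:
            Q, P, ll = Q2, P2, ll2
        path.append(ll)
        if ll - path[-2] < tol:
            converged = True
            break
    if not converged:
        logger.warning("admixture_fit K=%d: not converged after %d EM steps",
                       K, max_iter)
    ll_old = path[-1]
    return AdmixtureFit(Q=Q, P=P, K=K, loglik=ll_old,
                        loglik_path=np.array(path), converged=converged)


def select_K_cv(g: GenotypeMatrix, k_min: int = 2, k_max: int = 10,
                folds: int = 3, seed: int = 0,
                max_iter: int = 500) -> tuple[int, dict]:
    """Choose the number of ancestral populations by masked-entry CV.

    Non-missing genotype cells are partitioned into ``folds`` random folds;
    for each fold and candidate K the model is fitted with the fold's cells
    masked and scored by the squared error between masked dosages and their
    fitted expectation 2·(QP). Returns the K with minimum mean CV error and
    the full error curve {K: [fold errors]}.
    """
    if k_min > k_max:
        raise ValueError("k_min must be <= k_max")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = _stream(seed, "cv-folds")
    obs = ~np.isnan(g.dosage_float())
    cells = np.flatnonzero(obs.ravel())
    if cells.size < folds:
        raise ValueError("not enough observed cells for the requested folds")
    perm = rng.permutation(cells)
    fold_of = np.full(obs.size, -1, dtype=int)
    fold_of[perm] = np.arange(perm.size) % folds
    d = np.nan_to_num(g.dosage_float())
    curve: dict[int, list[float]] = {}
    for K in range(k_min, k_max + 1):
        errs = []
        for f in range(folds):
            mask = (fold_of == f).reshape(obs.shape)
            if not mask.any():
                raise ValueError(f"fold {f} has no masked entries")
            fit = admixture_fit(g, K=K, seed=seed + 1000 * (f + 1),
                                max_iter=max_iter, mask=mask)
            pred = 2.0 * fit.Q @ fit.P
            sel = mask & obs
            errs.append(float(np.mean((d[sel] - pred[sel]) ** 2)))
        curve[K] = errs
        logger.info("select_K_cv: K=%d mean CV error %.5f", K,
                    float(np.mean(errs)))
    best = min(curve, key=lambda k: float(np.mean(curve[k])))
    return best, curve


def assign_subgroups(fit: AdmixtureFit) -> np.ndarray:
    """Hard subgroup labels (1..K) from the largest ancestry proportion."""
    return fit.Q.argmax(axis=1) + 1
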
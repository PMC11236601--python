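"""Recovery and oracle experiments that validate the pipeline end-to-end.

Each function sets up a synthetic experiment with known ground truth (or an
algebraic identity), runs the relevant pipeline stages, and returns the
measured quantity. These are the package's own evidence that its estimators
work: variance-component recovery, FA + clustering recovery, admixture model
choice, GBLUP/ridge-regression equivalence, backsolve identity, Shukla
brute-force agreement, doubled-haploid recombination calibration, and the
inter- vs intra-population usefulness contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gblup, genomics, met_fa, stability, trial_models as tm, usefulness as uf
from .synthetic import (FounderPanel, GenotypeMatrix, _stream, desk_preset,
                        simulate_founders, simulate_map)

__all__ = [
    "gblup_rrblup_equivalence",
    "backsolve_identity",
    "varcomp_recovery",
    "fa_cluster_recovery",
    "admixture_k_selection",
    "shukla_vs_bruteforce",
    "shukla_bruteforce",
    "dh_recombination_calibration",
    "uc_contrast",
    "complementary_panel",
]


# ---------------------------------------------------------------------------
# Algebraic oracles
# ---------------------------------------------------------------------------

def _random_inbred_matrix(n: int, m: int, seed: int) -> GenotypeMatrix:
    rng = _stream(seed, "oracle-panel")
    dos = (2 * rng.integers(0, 2, size=(n, m))).astype(np.int8)
    return GenotypeMatrix(dosage=dos,
                          individual_ids=[f"P{i:03d}" for i in range(n)],
                          marker_ids=[f"M{j:04d}" for j in range(m)])


def gblup_rrblup_equivalence(seed: int, n: int = 40, m: int = 300,
                             s2a: float = 0.6, s2e: float = 1.0) -> float:
    """Max |GBLUP prediction − ridge-regression-on-markers prediction|.

    The two routes are algebraically identical with λ = σ²_e/σ²_m and
    σ²_m = σ²_a / (2Σp(1−p)); the ridge route is solved through the
    marker-level mixed-model equations, independent of the kinship-level
    V-form used by :func:`heteropool.gblup.gblup_solve`.
    """
    g = _random_inbred_matrix(n, m, seed)
    grm = gblup.compute_grm(g)
    rng = _stream(seed, "oracle-pheno")
    y = rng.normal(0.0, 1.0, n)
    eff = pd.DataFrame({"entry": g.individual_ids, "value": y})
    out = gblup.gblup_solve(eff, grm, variances=(s2a, s2e))
    # independent ridge oracle
    Z = grm.Z
    lam = s2e / (s2a / grm.scaling)
    X = np.ones((n, 1))
    C = np.block([[X.T @ X, X.T @ Z],
                  [Z.T @ X, Z.T @ Z + lam * np.eye(m)]])
    sol = np.linalg.solve(C, np.concatenate([X.T @ y, Z.T @ y]))
    pred_rr = Z @ sol[1:]
    return float(np.abs(pred_rr - out["gebv"].to_numpy()).max())


def backsolve_identity(seed: int, n: int = 40, m: int = 300) -> float:
    """Max |Z α̂ − ĝ| after backsolving marker effects from GEBVs."""
    g = _random_inbred_matrix(n, m, seed)
    grm = gblup.compute_grm(g)
    rng = _stream(seed, "oracle-pheno")
    y = rng.normal(0.0, 1.0, n)
    eff = pd.DataFrame({"entry": g.individual_ids, "value": y})
    out = gblup.gblup_solve(eff, grm, variances=(0.6, 1.0))
    fx = gblup.backsolve_markers(out["gebv"], grm)
    recon = grm.Z @ fx.effects
    return float(np.abs(recon - out["gebv"].to_numpy()).max())


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------

def varcomp_recovery(n_seeds: int = 20, seed0: int = 0,
                     sigma2_a: float = 0.5, sigma2_e: float = 1.0) -> dict:
    """Per-seed mean REML additive-variance estimate over the desk MET.

    Simulates the sparse desk preset (8 sites, 200 hybrids, 40 parents) and
    fits every site's additive+SCA model; the estimated hybrid additive
    variance is twice the parental GCA component. Returns the across-seed
    mean, its empirical SE and the |z|-score against the generating value.
    """
    spec = tm.TrialModelSpec(genetic="additive+sca", residual="iid")
    means = []
    for s in range(n_seeds):
        d = desk_preset(seed=seed0 + s, sigma2_a=sigma2_a, sigma2_e=sigma2_e)
        H = tm.build_hybrid_additive_design(
            d.plan, parents=list(d.panel.genotypes.individual_ids))
        fits = tm.fit_all_sites(d.pheno, spec, H=H)
        means.append(np.mean([2.0 * f.varcomp["additive"]
                              for f in fits.values()]))
    m = np.asarray(means)
    emp_se = float(m.std(ddof=1) / np.sqrt(len(m)))
    return {"mean": float(m.mean()), "emp_se": emp_se,
            "true": sigma2_a, "z": float((m.mean() - sigma2_a) / emp_se),
            "n_seeds": n_seeds}


def fa_cluster_recovery(n_seeds: int = 20, seed0: int = 0) -> dict:
    """Fraction of seeds in which FA + hierarchical clustering recovers the
    two simulated environment clusters exactly.

    Uses the dense variant of the desk MET (every hybrid at every site) so
    site-to-site overlap supports the between-site correlation; additive
    correlation is 0.8 within and −0.2 between the two site clusters.
    """
    spec = tm.TrialModelSpec(genetic="additive+sca", residual="iid")
    hits = 0
    auto_hits = 0
    for s in range(n_seeds):
        d = desk_preset(seed=seed0 + s, hybrids_per_site=200)
        H = tm.build_hybrid_additive_design(
            d.plan, parents=list(d.panel.genotypes.individual_ids))
        fits = tm.fit_all_sites(d.pheno, spec, H=H)
        table = tm.parent_blup_table(fits)
        model = met_fa.fit_fa(table, k=2)
        corr = met_fa.genetic_correlation(model)
        truth = np.array([1] * 4 + [2] * 4)
        cl = met_fa.cluster_sites(corr, n_clusters=2)
        hits += int(np.array_equal(cl.labels, truth)
                    or np.array_equal(cl.labels, 3 - truth))
        cla = met_fa.cluster_sites(corr)
        auto_hits += int(cla.n_clusters == 2
                         and (np.array_equal(cla.labels, truth)
                              or np.array_equal(cla.labels, 3 - truth)))
    return {"success_rate": hits / n_seeds,
            "auto_rule_success_rate": auto_hits / n_seeds,
            "n_seeds": n_seeds}


def admixture_k_selection(n_reps: int = 10, seed0: int = 0, K_true: int = 3,
                          fst: float = 0.15, n_per_group: int = 20,
                          n_markers: int = 500, k_min: int = 2,
                          k_max: int = 6) -> dict:
    """Fraction of seeded panels for which 3-fold masked-entry CV selects
    the generating number of ancestral populations."""
    selected = []
    for r in range(n_reps):
        panel = simulate_founders(K=K_true, n_per_group=n_per_group,
                                  n_markers=n_markers, fst=fst,
                                  seed=seed0 + r)
        K, _ = genomics.select_K_cv(panel.genotypes, k_min=k_min, k_max=k_max,
                                    folds=3, seed=seed0 + r)
        selected.append(K)
    hits = sum(k == K_true for k in selected)
    return {"success_rate": hits / n_reps, "selected": selected,
            "K_true": K_true, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# Shukla brute-force oracle
# ---------------------------------------------------------------------------

def shukla_bruteforce(X: np.ndarray) -> np.ndarray:
    """Naive nested-loop evaluation of Shukla's stability variance."""
    X = np.asarray(X, float)
    G, E = X.shape
    grand = X.mean()
    w = np.empty_like(X)
    for i in range(G):
        for j in range(E):
            w[i, j] = X[i, j] - X[i].mean() - X[:, j].mean() + grand
    total = sum(w[i, j] ** 2 for i in range(G) for j in range(E))
    out = np.empty(G)
    for i in range(G):
        ssi = sum(w[i, j] ** 2 for j in range(E))
        out[i] = (G * ssi / ((G - 2) * (E - 1))
                  - total / ((G - 1) * (G - 2) * (E - 1)))
    return out


def shukla_vs_bruteforce(seed: int = 0) -> float:
    """Max |module − brute force| on a 4×3 small-integer table."""
    rng = _stream(seed, "shukla-toy")
    X = rng.integers(-4, 5, size=(4, 3)).astype(float)
    table = pd.DataFrame(X, index=[f"G{i}" for i in range(4)],
                         columns=[f"E{j}" for j in range(3)])
    mod = stability.shukla_variance(table)["sigma2_shukla"].to_numpy()
    ref = shukla_bruteforce(X)
    return float(np.abs(mod - ref).max())


# ---------------------------------------------------------------------------
# DH calibration and UC contrast
# ---------------------------------------------------------------------------

def dh_recombination_calibration(seed: int = 0, n_gametes: int = 10000,
                                 d_cM: float = 10.0) -> dict:
    """Observed recombination fraction between two markers d cM apart over
    simulated DH gametes, plus the homozygosity check."""
    gmap = simulate_map(n_chrom=1, markers_per_chrom=2, chrom_length_cM=d_cM,
                        seed=0, marker_ids=["A", "B"])
    gmap.table.loc[:, "cm"] = [0.0, d_cM]
    p1 = np.array([0, 0])
    p2 = np.array([2, 2])
    pop = uf.simulate_dh(p1, p2, gmap, np.array(["A", "B"], dtype=object),
                         n=n_gametes, seed=seed)
    rec = float(np.mean(pop.dosage[:, 0] != pop.dosage[:, 1]))
    expected = 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))
    homozygous = bool(np.isin(pop.dosage, (0, 2)).all())
    return {"recombination_fraction": rec, "haldane_expected": float(expected),
            "all_homozygous": homozygous, "n_gametes": n_gametes}


def complementary_panel(seed: int, K: int = 3, n_per_group: int = 8,
                        n_markers: int = 210, n_favorable: int = 30,
                        effect: float = 0.05,
                        background_sd: float = 0.005) -> tuple:
    """Panel where the anchor subgroup (G1) and one partner subgroup (G2)
    are fixed for complementary favorable alleles at disjoint locus sets.

    Returns (panel, genetic map, marker effects): positive effects of equal
    size at both favorable sets, so intra-anchor crosses segregate at
    neither set while anchor×partner crosses segregate at both — same
    progeny mean, strictly larger progeny variance.
    """
    panel = simulate_founders(K=K, n_per_group=n_per_group,
                              n_markers=n_markers, fst=0.10, seed=seed)
    rng = _stream(seed, "complementarity")
    loci = rng.choice(n_markers, size=2 * n_favorable, replace=False)
    set_a, set_b = loci[:n_favorable], loci[n_favorable:]
    dos = panel.genotypes.dosage
    g1 = panel.true_membership == 1
    g2 = panel.true_membership == 2
    dos[np.ix_(g1, set_a)] = 2
    dos[np.ix_(g1, set_b)] = 0
    dos[np.ix_(g2, set_a)] = 0
    dos[np.ix_(g2, set_b)] = 2
    alpha = rng.normal(0.0, background_sd, size=n_markers)
    alpha[set_a] = effect
    alpha[set_b] = effect
    gmap = simulate_map(n_chrom=7, markers_per_chrom=n_markers // 7,
                        chrom_length_cM=150.0, seed=seed,
                        marker_ids=list(panel.genotypes.marker_ids))
    fx = gblup.MarkerEffects(table=pd.DataFrame(
        {"marker": panel.genotypes.marker_ids, "effect": alpha}), site="S1")
    return panel, gmap, fx


def uc_contrast(n_seeds: int = 20, seed0: int = 0, n_dh: int = 100,
                p: float = 0.10) -> dict:
    """Fraction of seeds where the inter-population median UC (anchor ×
    complementary partner subgroup) exceeds the intra-population median."""
    wins = 0
    margins = []
    for s in range(n_seeds):
        panel, gmap, fx = complementary_panel(seed=seed0 + s)
        uc = uf.compare_cross_sets(panel, anchor_group=1,
                                   effects_by_site={"S1": fx}, gmap=gmap,
                                   site_means={"S1": 6.0}, n=n_dh, p=p,
                                   seed=seed0 + s)
        med = uc.groupby("category")["uc"].median()
        margin = float(med["inter:G2"] - med["intra"])
        wins += int(margin > 0)
        margins.append(margin)
    return {"success_rate": wins / n_seeds,
            "median_margin": float(np.median(margins)), "n_seeds": n_seeds}
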
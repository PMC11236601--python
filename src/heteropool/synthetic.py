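"""Synthetic hybrid testcross trial data with known ground truth.

Generates everything the downstream analysis consumes: structured inbred
founder panels (Balding–Nichols divergence model), genetic maps, sparse
partially-replicated multi-environment testcross designs, and plot-level
yield tables whose generating parameters (additive/SCA/residual variances,
spatial correlation, between-site additive correlation) are recorded so that
every estimation stage can be checked by parameter recovery.

All randomness flows from a single integer seed through named
``numpy.random.Generator`` streams, one per component, so regenerating with
the same seed is bit-for-bit reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GeneticMap",
    "FounderPanel",
    "TruthParams",
    "CrossPlan",
    "simulate_founders",
    "simulate_map",
    "make_cross_plan",
    "simulate_met",
    "desk_preset",
    "write_dosage_csv",
    "read_dosage_csv",
    "write_vcf",
    "read_vcf",
    "write_map_csv",
    "read_map_csv",
    "write_pheno_csv",
    "read_pheno_csv",
]


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Individuals × biallelic markers, allele dosage in {0, 1, 2}.

    Missing calls are flagged in ``missing``; the dosage value underneath a
    missing flag is arbitrary (kept at 0). Marker metadata (chromosome, cM)
    is optional and aligned with ``marker_ids``.
    """

    dosage: np.ndarray              # (n_ind, n_mrk) int8
    individual_ids: np.ndarray      # (n_ind,) str
    marker_ids: np.ndarray          # (n_mrk,) str
    missing: np.ndarray | None = None   # (n_ind, n_mrk) bool
    chrom: np.ndarray | None = None     # (n_mrk,)
    cm: np.ndarray | None = None        # (n_mrk,) float

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        n, m = self.dosage.shape
        if self.individual_ids.shape[0] != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if self.marker_ids.shape[0] != m:
            raise ValueError("marker_ids length does not match dosage columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker ids must be unique")
        if self.missing is None:
            self.missing = np.zeros((n, m), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (n, m):
                raise ValueError("missing mask shape mismatch")
        observed = self.dosage[~self.missing]
        if observed.size and not np.isin(observed, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def dosage_float(self) -> np.ndarray:
        """Dosage as float with NaN at missing calls."""
        x = self.dosage.astype(float)
        x[self.missing] = np.nan
        return x

    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of the counted allele among non-missing calls."""
        x = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(x, axis=0) / 2.0

    def het_fraction(self) -> np.ndarray:
        obs = ~self.missing
        het = (self.dosage == 1) & obs
        n_obs = obs.sum(axis=0)
        out = np.zeros(self.n_markers)
        ok = n_obs > 0
        out[ok] = het.sum(axis=0)[ok] / n_obs[ok]
        return out

    def missing_fraction(self) -> np.ndarray:
        return self.missing.mean(axis=0)

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            individual_ids=self.individual_ids.copy(),
            marker_ids=self.marker_ids[idx],
            missing=self.missing[:, idx],
            chrom=None if self.chrom is None else np.asarray(self.chrom, dtype=object)[idx],
            cm=None if self.cm is None else np.asarray(self.cm, float)[idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosage=self.dosage[idx, :],
            individual_ids=self.individual_ids[idx],
            marker_ids=self.marker_ids.copy(),
            missing=self.missing[idx, :],
            chrom=self.chrom,
            cm=self.cm,
        )

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"unknown individual id {e.args[0]!r}") from None


class GeneticMap:
    """Marker → (chromosome, cM position), sorted within chromosome."""

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "chrom", "cm"}
        if not required.issubset(table.columns):
            raise ValueError(f"genetic map needs columns {sorted(required)}")
        t = table.loc[:, ["marker", "chrom", "cm"]].copy()
        if t["marker"].duplicated().any():
            raise ValueError("duplicate marker ids in genetic map")
        if (t["cm"] < 0).any():
            raise ValueError("negative cM positions")
        self.table = t.sort_values(["chrom", "cm"], kind="stable").reset_index(drop=True)

    @property
    def chromosomes(self) -> list:
        return list(pd.unique(self.table["chrom"]))

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def positions(self, chrom) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def __contains__(self, marker: str) -> bool:
        return marker in set(self.table["marker"])


@dataclass
class FounderPanel:
    """Inbred founder panel with known subgroup structure."""

    genotypes: GenotypeMatrix
    true_membership: np.ndarray     # (n_ind,) int labels in 1..K
    subgroup_count: int
    fst: float

    def __post_init__(self) -> None:
        self.true_membership = np.asarray(self.true_membership, dtype=int)
        obs = self.genotypes.dosage[~self.genotypes.missing]
        if obs.size and not np.isin(obs, (0, 2)).all():
            raise ValueError("founder panel must be fully inbred (dosage 0 or 2)")
        labels = set(self.true_membership)
        if not labels.issubset(set(range(1, self.subgroup_count + 1))):
            raise ValueError("membership labels must lie in 1..K")

    def members(self, group: int) -> np.ndarray:
        return self.genotypes.individual_ids[self.true_membership == group]


@dataclass
class TruthParams:
    """Ground-truth generating parameters for one synthetic MET.

    ``sigma2_a`` is the additive variance among hybrids per site (the sum of
    two independent parental GCA draws, each with variance sigma2_a/2).
    ``site_corr`` is the between-site correlation of additive effects.
    """

    n_sites: int
    sigma2_a: float = 0.5
    sigma2_s: float = 0.1           # SCA (non-additive, hybrid-specific)
    sigma2_e: float = 1.0           # iid plot residual
    sigma2_spatial: float = 0.0     # AR1xAR1-correlated component
    rho_row: float = 0.0
    rho_col: float = 0.0
    sigma2_row: float = 0.05
    sigma2_col: float = 0.05
    sigma2_block: float = 0.05
    site_corr: np.ndarray | None = None   # (n_sites, n_sites)
    site_means: np.ndarray | None = None
    gca_from_markers: bool = False
    n_marker_effects: int | None = None   # markers used when gca_from_markers

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_s", "sigma2_e", "sigma2_spatial",
                     "sigma2_row", "sigma2_col", "sigma2_block"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (-1 < self.rho_row < 1 and -1 < self.rho_col < 1):
            raise ValueError("AR1 correlations must lie in (-1, 1)")
        if self.site_corr is None:
            self.site_corr = np.eye(self.n_sites)
        self.site_corr = np.asarray(self.site_corr, float)
        if self.site_corr.shape != (self.n_sites, self.n_sites):
            raise ValueError("site_corr shape mismatch")
        if not np.allclose(self.site_corr, self.site_corr.T):
            raise ValueError("site_corr must be symmetric")
        if not np.allclose(np.diag(self.site_corr), 1.0):
            raise ValueError("site_corr must have unit diagonal")
        w = np.linalg.eigvalsh(self.site_corr)
        if w.min() < -1e-8:
            raise ValueError("site_corr is not positive semi-definite")
        if self.site_means is None:
            self.site_means = np.full(self.n_sites, 6.0)
        self.site_means = np.asarray(self.site_means, float)
        if self.site_means.shape[0] != self.n_sites:
            raise ValueError("site_means length mismatch")


@dataclass
class CrossPlan:
    """Hybrid cross plan plus per-site allocation and checks."""

    crosses: pd.DataFrame           # columns: hybrid, male, female
    site_hybrids: dict              # site name -> list of hybrid ids
    checks: list                    # check cultivar names, present at all sites

    def __post_init__(self) -> None:
        need = {"hybrid", "male", "female"}
        if not need.issubset(self.crosses.columns):
            raise ValueError(f"crosses needs columns {sorted(need)}")
        if self.crosses["hybrid"].duplicated().any():
            raise ValueError("duplicate hybrid ids in cross plan")
        known = set(self.crosses["hybrid"])
        for site, hyb in self.site_hybrids.items():
            unknown = set(hyb) - known
            if unknown:
                raise ValueError(f"site {site} allocates unknown hybrids {sorted(unknown)[:3]}")

    @property
    def sites(self) -> list:
        return list(self.site_hybrids)

    @property
    def parents(self) -> list:
        seen: dict = {}
        for p in pd.concat([self.crosses["male"], self.crosses["female"]]):
            seen.setdefault(p, None)
        return list(seen)

    def validate_against(self, panel: FounderPanel) -> None:
        have = set(panel.genotypes.individual_ids)
        missing = set(self.parents) - have
        if missing:
            raise ValueError(f"cross plan parents not in panel: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _stream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of one master seed (stable across processes)."""
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    ss = np.random.SeedSequence(seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def simulate_founders(K: int, n_per_group: int, n_markers: int, fst: float,
                      seed: int) -> FounderPanel:
    """Balding–Nichols founder panel of fully inbred lines.

    Ancestral allele frequency p ~ Uniform(0.05, 0.95) per marker; each of the
    K subgroups draws its own frequency from Beta(p(1-Fst)/Fst,
    (1-p)(1-Fst)/Fst); every inbred line then draws a single allele per marker
    and is recorded as dosage 0 or 2.
    """
    if K < 1 or n_per_group < 1 or n_markers < 1:
        raise ValueError("K, n_per_group and n_markers must be positive")
    if not (0.0 < fst < 1.0):
        raise ValueError("fst must lie strictly inside (0, 1)")
    rng = _stream(seed, "founders")
    p_anc = rng.uniform(0.05, 0.95, size=n_markers)
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    n = K * n_per_group
    dosage = np.empty((n, n_markers), dtype=np.int8)
    membership = np.repeat(np.arange(1, K + 1), n_per_group)
    for k in range(K):
        pk = rng.beta(a, b)
        rows = slice(k * n_per_group, (k + 1) * n_per_group)
        allele = rng.random((n_per_group, n_markers)) < pk
        dosage[rows] = 2 * allele.astype(np.int8)
    ids = np.array([f"P{i + 1:04d}" for i in range(n)], dtype=object)
    mids = np.array([f"M{j + 1:05d}" for j in range(n_markers)], dtype=object)
    g = GenotypeMatrix(dosage=dosage, individual_ids=ids, marker_ids=mids)
    return FounderPanel(genotypes=g, true_membership=membership,
                        subgroup_count=K, fst=fst)


def simulate_map(n_chrom: int, markers_per_chrom: int, chrom_length_cM: float,
                 seed: int = 0, marker_ids: Sequence[str] | None = None) -> GeneticMap:
    """Uniform-random marker placement, sorted within chromosome."""
    if n_chrom < 1 or markers_per_chrom < 1 or chrom_length_cM <= 0:
        raise ValueError("map arguments must be positive")
    rng = _stream(seed, "map")
    total = n_chrom * markers_per_chrom
    if marker_ids is None:
        marker_ids = [f"M{j + 1:05d}" for j in range(total)]
    elif len(marker_ids) != total:
        raise ValueError("marker_ids length must equal n_chrom*markers_per_chrom")
    rows = []
    it = iter(marker_ids)
    for c in range(1, n_chrom + 1):
        pos = np.sort(rng.uniform(0, chrom_length_cM, size=markers_per_chrom))
        for x in pos:
            rows.append((next(it), c, float(x)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cm"]))


def make_cross_plan(panel: FounderPanel, n_hybrids: int, sites: Sequence[str],
                    hybrids_per_site: int, checks: Sequence[str], seed: int,
                    female_fraction: float = 0.25) -> CrossPlan:
    """Random sparse testcross plan.

    A fraction of the panel acts as female (seed) parents, the rest as male
    (pollen) parents — mirroring a testcross system where a small female pool
    is crossed to a broad male panel. Each site receives a random subset of
    hybrids; all checks go to every site.
    """
    rng = _stream(seed, "plan")
    ids = panel.genotypes.individual_ids
    n = len(ids)
    n_female = max(1, int(round(female_fraction * n)))
    perm = rng.permutation(n)
    females = ids[perm[:n_female]]
    males = ids[perm[n_female:]]
    pairs = set()
    rows = []
    max_pairs = len(males) * len(females)
    if n_hybrids > max_pairs:
        raise ValueError(f"cannot form {n_hybrids} distinct crosses from "
                         f"{len(males)}x{len(females)} parents")
    while len(rows) < n_hybrids:
        m = males[rng.integers(len(males))]
        f = females[rng.integers(len(females))]
        if (m, f) in pairs:
            continue
        pairs.add((m, f))
        rows.append((f"H{len(rows) + 1:04d}", m, f))
    crosses = pd.DataFrame(rows, columns=["hybrid", "male", "female"])
    hybrids_per_site = min(hybrids_per_site, n_hybrids)
    site_hybrids = {}
    for s in sites:
        pick = rng.choice(crosses["hybrid"].to_numpy(), size=hybrids_per_site,
                          replace=False)
        site_hybrids[s] = list(pick)
    plan = CrossPlan(crosses=crosses, site_hybrids=site_hybrids,
                     checks=list(checks))
    plan.validate_against(panel)
    return plan


def _ar1_corr(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _psd_sqrt(R: np.ndarray) -> np.ndarray:
    """Symmetric square root with negative eigenvalues clipped to zero (so a
    singular correlation matrix, e.g. all-ones, is handled exactly)."""
    w, v = np.linalg.eigh(R)
    return v * np.sqrt(np.clip(w, 0.0, None))


def draw_site_marker_effects(panel: FounderPanel, truth: TruthParams,
                             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-site marker effect vectors whose implied GCAs have the truth's
    between-site correlation and per-site variance sigma2_a/2 (in the panel).

    Returns (alpha: markers × sites, gca: parents × sites).
    """
    m_all = panel.genotypes.n_markers
    m = truth.n_marker_effects or m_all
    m = min(m, m_all)
    L = _psd_sqrt(truth.site_corr)
    raw = rng.standard_normal((m, truth.n_sites)) @ L.T
    alpha = np.zeros((m_all, truth.n_sites))
    use = rng.choice(m_all, size=m, replace=False) if m < m_all else np.arange(m_all)
    alpha[use] = raw
    Z = panel.genotypes.dosage.astype(float)
    Z = Z - Z.mean(axis=0, keepdims=True)
    gca = Z @ alpha
    target_sd = np.sqrt(truth.sigma2_a / 2.0)
    sd = gca.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    scale = target_sd / sd
    alpha *= scale
    gca *= scale
    return alpha, gca


def draw_gca(panel: FounderPanel, truth: TruthParams,
             rng: np.random.Generator) -> np.ndarray:
    """Parent GCA matrix (parents × sites) ~ N(0, (sigma2_a/2)·site_corr)."""
    n = panel.genotypes.n_individuals
    L = _psd_sqrt(truth.site_corr)
    z = rng.standard_normal((n, truth.n_sites))
    return np.sqrt(truth.sigma2_a / 2.0) * (z @ L.T)


@dataclass
class METTruth:
    """Realized ground truth attached to a simulated MET."""
    gca: pd.DataFrame                  # parents × sites
    marker_effects: pd.DataFrame | None  # markers × sites (marker mode only)
    sca: pd.DataFrame                  # hybrids × sites
    check_effects: dict


def simulate_met(panel: FounderPanel, plan: CrossPlan, truth: TruthParams,
                 seed: int, p_rep: float = 0.3,
                 n_check_reps: int = 2) -> tuple[pd.DataFrame, METTruth]:
    """Simulate plot-level yields for every site of a sparse testcross MET.

    yield = site mean + row + column + block effects + (male GCA + female GCA)
    + SCA + AR1⊗AR1 spatial noise + iid residual. A fraction ``p_rep`` of each
    site's hybrids is duplicated within the site; every check appears
    ``n_check_reps`` times at every site.

    Returns the stacked PhenoTable and the realized ground truth.
    """
    plan.validate_against(panel)
    sites = plan.sites
    if len(sites) != truth.n_sites:
        raise ValueError("truth.n_sites does not match the plan's site count")
    rng = _stream(seed, "met")
    parents = list(panel.genotypes.individual_ids)
    pidx = {p: i for i, p in enumerate(parents)}

    if truth.gca_from_markers:
        alpha, gca = draw_site_marker_effects(panel, truth, rng)
        marker_fx = pd.DataFrame(alpha, index=panel.genotypes.marker_ids,
                                 columns=sites)
    else:
        gca = draw_gca(panel, truth, rng)
        marker_fx = None
    gca_df = pd.DataFrame(gca, index=parents, columns=sites)

    hybrids = plan.crosses["hybrid"].to_numpy()
    sca = rng.normal(0.0, np.sqrt(truth.sigma2_s),
                     size=(len(hybrids), truth.n_sites))
    sca_df = pd.DataFrame(sca, index=hybrids, columns=sites)
    check_fx = {c: rng.normal(0.0, np.sqrt(truth.sigma2_a))
                for c in plan.checks}

    cross_lookup = plan.crosses.set_index("hybrid")
    records = []
    for s_i, site in enumerate(sites):
        site_rng = _stream(seed, f"site:{site}")
        hyb = list(plan.site_hybrids[site])
        n_dup = int(round(p_rep * len(hyb)))
        dup = list(site_rng.choice(hyb, size=n_dup, replace=False)) if n_dup else []
        entries = ([(h, False) for h in hyb] + [(h, False) for h in dup]
                   + [(c, True) for c in plan.checks for _ in range(n_check_reps)])
        site_rng.shuffle(entries)
        n_plot = len(entries)
        n_row = int(np.ceil(np.sqrt(n_plot)))
        n_col = int(np.ceil(n_plot / n_row))
        row_fx = site_rng.normal(0, np.sqrt(truth.sigma2_row), n_row)
        col_fx = site_rng.normal(0, np.sqrt(truth.sigma2_col), n_col)
        n_block = 2
        block_fx = site_rng.normal(0, np.sqrt(truth.sigma2_block), n_block)
        if truth.sigma2_spatial > 0:
            Rr = _ar1_corr(n_row, truth.rho_row)
            Rc = _ar1_corr(n_col, truth.rho_col)
            Lr = np.linalg.cholesky(Rr + 1e-10 * np.eye(n_row))
            Lc = np.linalg.cholesky(Rc + 1e-10 * np.eye(n_col))
            spatial = np.sqrt(truth.sigma2_spatial) * (
                Lr @ site_rng.standard_normal((n_row, n_col)) @ Lc.T)
        else:
            spatial = np.zeros((n_row, n_col))
        resid = site_rng.normal(0, np.sqrt(truth.sigma2_e), n_plot)
        for k, (entry, is_check) in enumerate(entries):
            r, c = divmod(k, n_col)
            block = 1 if c < n_col / 2 else 2
            if is_check:
                genetic = check_fx[entry]
                male = female = ""
            else:
                male = cross_lookup.at[entry, "male"]
                female = cross_lookup.at[entry, "female"]
                genetic = (gca[pidx[male], s_i] + gca[pidx[female], s_i]
                           + sca_df.at[entry, site])
            y = (truth.site_means[s_i] + row_fx[r] + col_fx[c]
                 + block_fx[block - 1] + genetic + spatial[r, c] + resid[k])
            records.append((site, r + 1, c + 1, block, entry, male, female,
                            is_check, y))
    pheno = pd.DataFrame(records, columns=["site", "row", "col", "block",
                                           "entry", "male", "female",
                                           "is_check", "yield"])
    return pheno, METTruth(gca=gca_df, marker_effects=marker_fx, sca=sca_df,
                           check_effects=check_fx)


# ---------------------------------------------------------------------------
# Desk-scale preset
# ---------------------------------------------------------------------------

def two_cluster_corr(n_sites: int, within: float = 0.8,
                     between: float = -0.2) -> np.ndarray:
    """Two equal blocks of sites: correlation `within` inside a block,
    `between` across blocks."""
    half = n_sites // 2
    labels = np.array([0] * half + [1] * (n_sites - half))
    same = labels[:, None] == labels[None, :]
    R = np.where(same, within, between).astype(float)
    np.fill_diagonal(R, 1.0)
    w = np.linalg.eigvalsh(R)
    if w.min() < -1e-8:
        raise ValueError("two-cluster correlation matrix not PSD for these values")
    return R


@dataclass
class DeskData:
    """Bundle returned by :func:`desk_preset`."""
    panel: FounderPanel
    genetic_map: GeneticMap
    plan: CrossPlan
    truth: TruthParams
    pheno: pd.DataFrame
    met_truth: METTruth


def desk_preset(seed: int, n_sites: int = 8, n_hybrids: int = 200,
                n_parents: int = 40, n_markers: int = 350, n_chrom: int = 7,
                K: int = 4, fst: float = 0.15, sigma2_a: float = 0.5,
                sigma2_e: float = 1.0, hybrids_per_site: int = 80,
                gca_from_markers: bool = True) -> DeskData:
    """Desk-scale analogue of a global sparse testcross network.

    Eight sites in two environment clusters (additive correlation 0.8 within,
    −0.2 between), 200 hybrids from 40 structured inbred parents, 350 mapped
    SNPs on 7 chromosomes — small enough for laptop-speed REML yet rich
    enough for every pipeline stage to have signal.
    """
    if n_parents % K:
        raise ValueError("n_parents must be divisible by K")
    panel = simulate_founders(K=K, n_per_group=n_parents // K,
                              n_markers=n_markers, fst=fst, seed=seed)
    gmap = simulate_map(n_chrom=n_chrom, markers_per_chrom=n_markers // n_chrom,
                        chrom_length_cM=150.0, seed=seed,
                        marker_ids=list(panel.genotypes.marker_ids))
    pos = gmap.table.set_index("marker")
    panel.genotypes.chrom = pos.loc[panel.genotypes.marker_ids, "chrom"].to_numpy()
    panel.genotypes.cm = pos.loc[panel.genotypes.marker_ids, "cm"].to_numpy()
    sites = [f"S{i + 1:02d}" for i in range(n_sites)]
    checks = ["CHK1", "CHK2", "CHK3"]
    plan = make_cross_plan(panel, n_hybrids=n_hybrids, sites=sites,
                           hybrids_per_site=hybrids_per_site, checks=checks,
                           seed=seed)
    truth = TruthParams(
        n_sites=n_sites, sigma2_a=sigma2_a, sigma2_s=0.1, sigma2_e=sigma2_e,
        sigma2_spatial=0.2, rho_row=0.4, rho_col=0.4,
        site_corr=two_cluster_corr(n_sites),
        gca_from_markers=gca_from_markers,
    )
    pheno, met_truth = simulate_met(panel, plan, truth, seed=seed)
    return DeskData(panel=panel, genetic_map=gmap, plan=plan, truth=truth,
                    pheno=pheno, met_truth=met_truth)


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def write_dosage_csv(g: GenotypeMatrix, path) -> None:
    """Rows = individuals, columns = markers; missing as empty cell."""
    df = pd.DataFrame(g.dosage_float(), index=g.individual_ids,
                      columns=g.marker_ids)
    df.index.name = "individual"
    df.to_csv(path, float_format="%.0f")


def read_dosage_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    x = df.to_numpy(dtype=float)
    missing = np.isnan(x)
    dosage = np.where(missing, 0, x).astype(np.int8)
    return GenotypeMatrix(dosage=dosage,
                          individual_ids=df.index.to_numpy(dtype=object),
                          marker_ids=df.columns.to_numpy(dtype=object),
                          missing=missing)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal biallelic-SNP VCF with GT-only genotypes (./." for missing)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, g.individual_ids)) + "\n")
        chrom = g.chrom if g.chrom is not None else np.ones(g.n_markers, int)
        for j in range(g.n_markers):
            calls = ["./." if g.missing[i, j] else gt_map[int(g.dosage[i, j])]
                     for i in range(g.n_individuals)]
            fh.write(f"{chrom[j]}\t{j + 1}\t{g.marker_ids[j]}\tA\tB\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP records into a dosage matrix (via cyvcf2)."""
    from cyvcf2 import VCF
    v = VCF(str(path))
    ids = np.array(v.samples, dtype=object)
    dosages, missings, mids, chroms = [], [], [], []
    for rec in v:
        if len(rec.ALT) != 1:
            continue
        gts = np.array(rec.gt_types)  # 0 hom-ref, 1 het, 2 missing, 3 hom-alt
        miss = gts == 2
        d = np.select([gts == 0, gts == 1, gts == 3], [0, 1, 2], default=0)
        dosages.append(d.astype(np.int8))
        missings.append(miss)
        mids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
    return GenotypeMatrix(dosage=np.array(dosages).T,
                          individual_ids=ids,
                          marker_ids=np.array(mids, dtype=object),
                          missing=np.array(missings).T,
                          chrom=np.array(chroms, dtype=object))


def write_map_csv(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, index=False)


def read_map_csv(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path))


def write_pheno_csv(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def read_pheno_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False,
                     dtype={"male": str, "female": str, "entry": str})
    df["is_check"] = df["is_check"].astype(str).str.lower().isin(["true", "1"])
    for col in ("row", "col", "block"):
        df[col] = df[col].astype(int)
    df["yield"] = df["yield"].astype(float)
    return df
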
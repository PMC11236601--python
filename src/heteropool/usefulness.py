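"""Doubled-haploid progeny simulation and the usefulness criterion.

Simulates DH progeny of a biparental cross of fully inbred parents on a
genetic map under a no-interference (Poisson) crossover process, scores
progeny with site-specific marker effects plus the site mean, and computes
the usefulness criterion UC = μ + i·h·σ — the expected mean of the selected
upper fraction of progeny — for comparing inter- vs intra-subgroup crosses.

Under no interference, recombination between adjacent mapped markers follows
Haldane's map function r = (1 − e^{−2d/100})/2; a gamete's parental phase
along each chromosome is therefore a two-state Markov chain over the ordered
markers, which is simulated directly (distributionally identical to drawing
Poisson crossover counts with uniform positions and reading off marker
phases).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import FounderPanel, GeneticMap, _stream
from .gblup import MarkerEffects

logger = logging.getLogger(__name__)

__all__ = [
    "DHPopulation",
    "UCResult",
    "simulate_dh",
    "gebv_score",
    "selection_intensity",
    "usefulness_criterion",
    "compare_cross_sets",
]


@dataclass
class DHPopulation:
    """Doubled-haploid progeny of one cross (all entries 0 or 2)."""

    dosage: np.ndarray              # (n, n_mapped_markers) int8, {0, 2}
    marker_ids: np.ndarray
    parent1: str
    parent2: str
    seed: int

    def __post_init__(self) -> None:
        if not np.isin(self.dosage, (0, 2)).all():
            raise ValueError("DH progeny must be fully homozygous (dosage 0/2)")

    @property
    def n(self) -> int:
        return self.dosage.shape[0]


@dataclass
class UCResult:
    cross: tuple
    mu: float
    sigma: float
    p: float
    intensity: float
    h: float
    uc: float
    site: str | None = None
    category: str | None = None


def _haldane_r(d_cM: np.ndarray) -> np.ndarray:
    """Recombination fraction between loci d centimorgans apart (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, float) / 100.0))


def simulate_dh(parent1: np.ndarray, parent2: np.ndarray, gmap: GeneticMap,
                marker_ids: np.ndarray, n: int = 250, seed: int = 0,
                parent_ids: tuple = ("P1", "P2")) -> DHPopulation:
    """Simulate n DH lines from a cross of two fully inbred parents.

    ``parent1``/``parent2`` are dosage vectors over ``marker_ids``; markers
    absent from the map are excluded with a warning. Per chromosome one
    recombinant gamete is formed (no-interference crossovers on the cM scale)
    and doubled to homozygosity. Loci where the parents share an allele are
    fixed for it.
    """
    p1 = np.asarray(parent1, float)
    p2 = np.asarray(parent2, float)
    if np.isin(p1, (0, 2)).all() and np.isin(p2, (0, 2)).all():
        pass
    else:
        raise ValueError("parents must be fully homozygous at every locus")
    marker_ids = np.asarray(marker_ids, dtype=object)
    mapped = gmap.table.set_index("marker")
    on_map = np.array([m in mapped.index for m in marker_ids])
    if not on_map.all():
        warnings.warn(f"{(~on_map).sum()} markers without map positions "
                      "excluded from DH simulation")
    use = np.flatnonzero(on_map)
    ids_used = marker_ids[use]
    chrom = mapped.loc[ids_used, "chrom"].to_numpy()
    pos = mapped.loc[ids_used, "cm"].to_numpy(float)
    order = np.lexsort((pos, chrom.astype(str)))
    ids_used, chrom, pos = ids_used[order], chrom[order], pos[order]
    h1 = (p1[use][order] / 2).astype(np.int8)
    h2 = (p2[use][order] / 2).astype(np.int8)

    rng = _stream(seed, f"dh:{parent_ids[0]}x{parent_ids[1]}")
    m = len(ids_used)
    phase = np.empty((n, m), dtype=np.int8)
    start = 0
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        mc = sel.size
        r = _haldane_r(np.diff(pos[sel]))
        ph0 = rng.integers(0, 2, size=n, dtype=np.int8)
        if mc > 1:
            flips = (rng.random((n, mc - 1)) < r[None, :]).astype(np.int8)
            cum = np.concatenate([np.zeros((n, 1), np.int8),
                                  np.cumsum(flips, axis=1,
                                            dtype=np.int64).astype(np.int8)],
                                 axis=1)
            ph = (ph0[:, None] + cum) % 2
        else:
            ph = ph0[:, None]
        phase[:, sel] = ph
        start += mc
    allele = np.where(phase == 0, h1[None, :], h2[None, :])
    dosage = (2 * allele).astype(np.int8)
    return DHPopulation(dosage=dosage, marker_ids=ids_used,
                        parent1=parent_ids[0], parent2=parent_ids[1], seed=seed)


def gebv_score(pop: DHPopulation, effects: MarkerEffects,
               site_mean: float = 0.0) -> np.ndarray:
    """Progeny genomic values: dosage · α + site mean.

    The effect vector must cover every marker in the population; extra
    markers in the effect table are ignored.
    """
    fx = effects.table.set_index("marker")["effect"]
    missing = [m for m in pop.marker_ids if m not in fx.index]
    if missing:
        raise ValueError(f"marker effects missing for {len(missing)} markers, "
                         f"e.g. {missing[:3]}")
    alpha = fx.reindex(pop.marker_ids).to_numpy(float)
    return pop.dosage.astype(float) @ alpha + site_mean


def selection_intensity(p: float) -> float:
    """Standardized mean of the selected upper-p tail of a standard normal:
    i = φ(z_p)/p with z_p the upper-p quantile."""
    if not (0.0 < p < 1.0):
        raise ValueError("selected fraction p must lie in (0, 1)")
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def usefulness_criterion(values: np.ndarray, p: float = 0.10,
                         h: float = 1.0, cross: tuple = ("?", "?"),
                         site: str | None = None,
                         category: str | None = None) -> UCResult:
    """UC = μ + i(p)·h·σ with μ, σ the progeny mean and SD (n−1 denominator)."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("usefulness criterion needs at least 2 progeny")
    mu = float(v.mean())
    sigma = float(v.std(ddof=1))
    i = selection_intensity(p)
    return UCResult(cross=cross, mu=mu, sigma=sigma, p=p, intensity=i, h=h,
                    uc=mu + i * h * sigma, site=site, category=category)


def compare_cross_sets(panel: FounderPanel, anchor_group: int,
                       effects_by_site: dict, gmap: GeneticMap,
                       site_means: dict | None = None, n: int = 250,
                       p: float = 0.10, h: float = 1.0, seed: int = 0,
                       max_crosses_per_pair: int | None = None) -> pd.DataFrame:
    """UC of every anchor×other (inter) and anchor×anchor (intra) DH cross.

    For each cross, DH progeny are simulated once and scored with each site's
    marker-effect vector; one UC row per (cross, site). ``category`` is
    "intra" for anchor×anchor and "inter:Gk" for anchor×group-k crosses.
    """
    labels = panel.true_membership
    groups = sorted(set(labels))
    if anchor_group not in groups:
        raise ValueError(f"anchor group {anchor_group} not present in panel")
    ids = panel.genotypes.individual_ids
    anchor_ids = ids[labels == anchor_group]
    rng = _stream(seed, "cross-sets")
    pairs = []
    a_list = list(anchor_ids)
    for i, a in enumerate(a_list):
        for b in a_list[i + 1:]:
            pairs.append((a, b, "intra"))
    for g in groups:
        if g == anchor_group:
            continue
        for a in a_list:
            for b in ids[labels == g]:
                pairs.append((a, b, f"inter:G{g}"))
    if max_crosses_per_pair is not None:
        by_cat: dict[str, list] = {}
        for pr in pairs:
            by_cat.setdefault(pr[2], []).append(pr)
        pairs = []
        for cat, lst in sorted(by_cat.items()):
            if len(lst) > max_crosses_per_pair:
                idx = rng.choice(len(lst), size=max_crosses_per_pair,
                                 replace=False)
                lst = [lst[i] for i in sorted(idx)]
            pairs.extend(lst)
    lookup = {v: i for i, v in enumerate(ids)}
    rows = []
    for a, b, cat in pairs:
        pop = simulate_dh(panel.genotypes.dosage[lookup[a]],
                          panel.genotypes.dosage[lookup[b]], gmap,
                          panel.genotypes.marker_ids, n=n,
                          seed=int(rng.integers(2 ** 31)), parent_ids=(a, b))
        for site, fx in effects_by_site.items():
            sm = 0.0 if site_means is None else float(site_means.get(site, 0.0))
            vals = gebv_score(pop, fx, site_mean=sm)
            r = usefulness_criterion(vals, p=p, h=h, cross=(a, b), site=site,
                                     category=cat)
            rows.append((a, b, cat, site, r.mu, r.sigma, r.intensity, h, r.uc))
    return pd.DataFrame(rows, columns=["parent1", "parent2", "category",
                                       "site", "mu", "sigma", "intensity",
                                       "h", "uc"])


def uc_summary(uc_table: pd.DataFrame) -> pd.DataFrame:
    """Median/quartile UC per (site, category) for boxplot-style reporting."""
    return (uc_table.groupby(["site", "category"])["uc"]
            .describe(percentiles=[0.25, 0.5, 0.75])
            .reset_index())
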
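"""Shukla's stability variance and mean-vs-stability quadrant classification.

Operates on a genotype × environment table of additive effects (per-site
parent BLUPs/GEBVs). Shukla's estimator partitions the genotype-by-
environment interaction sum of squares into per-genotype variances; a
genotype with small σ²ᵢ contributes consistently across environments.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["shukla_variance", "quadrant_classify", "stability_table"]


def shukla_variance(effects: pd.DataFrame, complete: bool = True) -> pd.DataFrame:
    """Shukla's stability variance per genotype.

    With interaction residuals w_ij = x_ij − x̄_i· − x̄_·j + x̄·· over G
    genotypes and E environments:

        σ²_i = [G/((G−2)(E−1))]·Σ_j w_ij² − ΣΣ w² / ((G−1)(G−2)(E−1))

    The unbiased estimator can be negative; estimates are reported as-is with
    a truncated-at-zero companion column. With ``complete=False`` missing
    cells are mean-filled (genotype mean + environment mean − grand mean)
    with a warning; otherwise missing cells are an error.
    """
    X = effects.to_numpy(float)
    G, E = X.shape
    if G < 3:
        raise ValueError("Shukla's variance needs at least 3 genotypes")
    if E < 2:
        raise ValueError("Shukla's variance needs at least 2 environments")
    if np.isnan(X).any():
        if complete:
            raise ValueError("missing cells in effects table (pass complete=False)")
        warnings.warn("mean-filling missing cells for Shukla's variance")
        gm = np.nanmean(X)
        rm = np.nanmean(X, axis=1)
        cm = np.nanmean(X, axis=0)
        fill = rm[:, None] + cm[None, :] - gm
        X = np.where(np.isnan(X), fill, X)
    w = X - X.mean(axis=1, keepdims=True) - X.mean(axis=0, keepdims=True) + X.mean()
    row_ss = (w ** 2).sum(axis=1)
    total_ss = row_ss.sum()
    sigma2 = (G * row_ss / ((G - 2) * (E - 1))
              - total_ss / ((G - 1) * (G - 2) * (E - 1)))
    return pd.DataFrame({
        "sigma2_shukla": sigma2,
        "sigma2_shukla_trunc": np.clip(sigma2, 0.0, None),
        "sqrt_stability": np.sqrt(np.clip(sigma2, 0.0, None)),
        "mean_effect": effects.mean(axis=1, skipna=True).to_numpy(),
        "n_env": E,
    }, index=effects.index)


def quadrant_classify(table: pd.DataFrame, mean_threshold: float = 0.0,
                      stability_threshold: float | None = None) -> pd.DataFrame:
    """Label parents by (mean effect ≷ threshold) × (stability ≷ threshold).

    "stable-positive" = mean above the mean threshold AND sqrt stability
    variance below the stability threshold (low interaction variance). The
    stability threshold defaults to the panel median of sqrt σ²ᵢ. Axis
    orientation is recorded in the ``quadrant`` labels themselves.
    """
    if table.empty:
        raise ValueError("empty stability table")
    t = table.copy()
    if stability_threshold is None:
        stability_threshold = float(t["sqrt_stability"].median())
    hi_mean = t["mean_effect"] > mean_threshold
    stable = t["sqrt_stability"] < stability_threshold
    label = np.where(hi_mean & stable, "stable-positive",
             np.where(hi_mean & ~stable, "unstable-positive",
              np.where(~hi_mean & stable, "stable-negative",
                       "unstable-negative")))
    t["quadrant"] = label
    t.attrs["mean_threshold"] = float(mean_threshold)
    t.attrs["stability_threshold"] = float(stability_threshold)
    return t


def stability_table(effects: pd.DataFrame, subgroup: pd.Series | None = None,
                    complete: bool = True, mean_threshold: float = 0.0,
                    stability_threshold: float | None = None,
                    min_env: int = 2) -> pd.DataFrame:
    """End-to-end stability analysis: Shukla variances + quadrant labels.

    Genotypes observed in fewer than ``min_env`` environments are dropped.
    """
    obs = effects.notna().sum(axis=1)
    use = effects.loc[obs >= min_env]
    t = shukla_variance(use, complete=complete)
    t = quadrant_classify(t, mean_threshold=mean_threshold,
                          stability_threshold=stability_threshold)
    if subgroup is not None:
        t["subgroup"] = subgroup.reindex(t.index)
    return t
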
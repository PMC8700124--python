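"""Statistical feature/protein filters and the ">20% altered" census.

Per protein and compartment this module computes a one-way fixed-effects
ANOVA across the three age groups on ArcSinh-transformed abundances, the
post-hoc power of that ANOVA via the noncentral F distribution, and the
max/min group-mean fold change on the raw abundance scale.  Two filters
are derived from those statistics:

* the feature filter keeps proteins with power >= power_min AND
  fold change >= fc_min AND p <= alpha;
* the protein filter keeps proteins with unique_peptides >=
  min_unique_peptides AND p <= alpha.

Degenerate conventions: zero within-group variance with differing means
gives p = 0 (power 1); all values identical gives p = 1 (power alpha).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AGES, PipelineConfig
from .io import AbundanceMatrix, group_means

# Relative tolerance below which a sum of squares counts as exactly zero.
_SS_REL_TOL = 1e-12


def arcsinh_transform(x):
    """Inverse hyperbolic sine, ln(x + sqrt(x^2 + 1)); variance stabiliser.

    Accepts scalars or arrays of finite values >= 0.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("arcsinh_transform requires finite input")
    if np.any(arr < 0):
        raise ValueError("arcsinh_transform requires non-negative input")
    out = np.arcsinh(arr)
    return out if out.ndim else float(out)


def _group_arrays(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("ANOVA groups must be non-empty")
    return arrs


def _anova_ss(groups: Sequence[np.ndarray]) -> tuple[float, float, int, int]:
    """Between/within sums of squares and degrees of freedom."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = all_vals.size - len(groups)
    return float(ssb), float(ssw), df1, df2


def anova_p(groups: Sequence[Sequence[float]]) -> float:
    """One-way fixed-effects ANOVA F-test p-value across groups.

    Values are expected to be ArcSinh-transformed by the caller when used
    for the abundance filters.
    """
    arrs = _group_arrays(groups)
    ssb, ssw, df1, df2 = _anova_ss(arrs)
    if df2 < 1:
        raise ValueError("ANOVA requires at least 1 residual degree of freedom")
    scale = ssb + ssw
    if ssw <= _SS_REL_TOL * scale or scale == 0.0:
        # no within-group variation: p is 0 if means differ, 1 otherwise
        return 0.0 if ssb > _SS_REL_TOL * scale and scale > 0 else 1.0
    f_stat = (ssb / df1) / (ssw / df2)
    return float(stats.f.sf(f_stat, df1, df2))


def anova_power(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> float:
    """Post-hoc power of the one-way ANOVA at level ``alpha``.

    Uses the noncentral F distribution with noncentrality
    lambda = sum_i n_i (m_i - m)^2 / MSE (equivalently n_total times the
    between-group variance of the observed means over the pooled
    within-group variance).  Zero within-variance gives power 1 when the
    means differ and alpha when they do not.
    """
    arrs = _group_arrays(groups)
    ssb, ssw, df1, df2 = _anova_ss(arrs)
    if df2 < 1:
        raise ValueError("power requires at least 1 residual degree of freedom")
    scale = ssb + ssw
    if ssw <= _SS_REL_TOL * scale or scale == 0.0:
        return 1.0 if (ssb > _SS_REL_TOL * scale and scale > 0) else float(alpha)
    lam = ssb / (ssw / df2)
    f_crit = stats.f.isf(alpha, df1, df2)
    # scipy's noncentral F misbehaves at lambda = 0; the central F applies there
    power = stats.f.sf(f_crit, df1, df2) if lam == 0 else stats.ncf.sf(f_crit, df1, df2, lam)
    return float(np.clip(power, 0.0, 1.0))


def max_fold_change(means: Sequence[float]) -> float:
    """Max/min ratio over group means (>= 1).  Means must be positive."""
    arr = np.asarray(means, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("group means must be positive and finite")
    return float(arr.max() / arr.min())


def _vectorised_anova(values: np.ndarray, group_cols: list[np.ndarray], alpha: float):
    """ANOVA p and power for every row of ``values`` at once."""
    n_prot = values.shape[0]
    k = len(group_cols)
    ns = np.array([c.size for c in group_cols])
    n_total = int(ns.sum())
    df1, df2 = k - 1, n_total - k

    gmeans = np.column_stack([values[:, c].mean(axis=1) for c in group_cols])
    grand = values.mean(axis=1)
    ssb = (ns * (gmeans - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.zeros(n_prot)
    for j, c in enumerate(group_cols):
        ssw += ((values[:, c] - gmeans[:, j][:, None]) ** 2).sum(axis=1)

    scale = ssb + ssw
    degenerate = (ssw <= _SS_REL_TOL * scale) | (scale == 0.0)
    means_differ = ssb > _SS_REL_TOL * scale

    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ssb / df1) / (ssw / df2)
    p = np.where(
        degenerate,
        np.where(means_differ & (scale > 0), 0.0, 1.0),
        stats.f.sf(np.where(degenerate, 1.0, f_stat), df1, df2),
    )
    lam = np.where(degenerate, 0.0, ssb / np.where(ssw == 0, 1.0, ssw / df2))
    f_crit = stats.f.isf(alpha, df1, df2)
    # scipy's noncentral F misbehaves at lambda = 0; the central F applies there
    ncf_power = stats.ncf.sf(f_crit, df1, df2, np.where(lam > 0, lam, 1.0))
    central = stats.f.sf(f_crit, df1, df2)
    power = np.where(
        degenerate,
        np.where(means_differ & (scale > 0), 1.0, alpha),
        np.where(lam > 0, ncf_power, central),
    )
    return p, np.clip(power, 0.0, 1.0)


def feature_stats(
    matrix: AbundanceMatrix, config: PipelineConfig, compartment: str
) -> pd.DataFrame:
    """Per-protein filter statistics within one compartment.

    Returns a DataFrame indexed by protein id with columns ``anova_p``,
    ``power`` (both from the ArcSinh-transformed ANOVA across ages),
    ``max_fold_change`` (raw group-mean max/min ratio) and
    ``unique_peptides``.
    """
    sub = matrix.subset_compartment(compartment)
    ages_present = [a for a in AGES if (sub.samples["age"] == a).any()]
    group_cols = [
        np.flatnonzero((sub.samples["age"] == a).to_numpy()) for a in ages_present
    ]
    transformed = np.arcsinh(sub.values.to_numpy(dtype=float))
    p, power = _vectorised_anova(transformed, group_cols, config.alpha)

    gm = group_means(sub)[compartment].to_numpy(dtype=float)
    fc = gm.max(axis=1) / gm.min(axis=1)

    return pd.DataFrame(
        {
            "anova_p": p,
            "power": power,
            "max_fold_change": fc,
            "unique_peptides": sub.unique_peptides.astype(int),
        },
        index=sub.values.index,
    )


def filter_features(stats_table: pd.DataFrame, config: PipelineConfig) -> list[str]:
    """Feature filter: keep power >= power_min, fc >= fc_min, p <= alpha."""
    keep = (
        (stats_table["power"] >= config.power_min)
        & (stats_table["max_fold_change"] >= config.fc_min)
        & (stats_table["anova_p"] <= config.alpha)
    )
    return list(stats_table.index[keep])


def filter_proteins(stats_table: pd.DataFrame, config: PipelineConfig) -> list[str]:
    """Protein filter: keep unique_peptides >= minimum and p <= alpha."""
    keep = (stats_table["unique_peptides"] >= config.min_unique_peptides) & (
        stats_table["anova_p"] <= config.alpha
    )
    return list(stats_table.index[keep])


def common_proteins(
    matrix_a: AbundanceMatrix, matrix_b: AbundanceMatrix
) -> list[str]:
    """Intersection of protein ids, in the order of the first matrix."""
    in_b = set(matrix_b.protein_ids)
    return [p for p in matrix_a.protein_ids if p in in_b]


def count_altered(matrix: AbundanceMatrix, threshold: float = 0.2) -> dict[str, int]:
    """Per compartment: proteins whose max fold change across ages > 1+threshold."""
    gm = group_means(matrix)
    out: dict[str, int] = {}
    for comp in gm.columns.get_level_values("compartment").unique():
        block = gm[comp].to_numpy(dtype=float)
        ratio = block.max(axis=1) / block.min(axis=1)
        out[comp] = int((ratio > 1.0 + threshold).sum())
    return out
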
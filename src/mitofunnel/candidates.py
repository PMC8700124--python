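"""Trend classification and the subtractive candidate funnel.

The funnel mirrors the candidate-prioritisation logic of the temporal
analysis: statistically filtered common proteins are clustered per
compartment by MCL on the Pearson co-expression graph; clusters (or
proteins) are labelled with a temporal trend (steady up/down, late-stage
up/down); proteins altered in the same manner in both compartments are
subtracted; survivors with concordant young/mid but divergent old-age
cross-compartment ratio-to-young profiles are "archetypal"; and a final
old-age fold-change cut yields the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AGES, TREND_CLASSES, PipelineConfig
from .filtering import common_proteins, feature_stats, filter_features, filter_proteins
from .io import AbundanceMatrix, group_means
from .networks import ClusterSet, build_protein_graph, cluster_profiles, mcl_cluster


def classify_trend(profile, epsilon: float) -> str:
    """Label a (young, mid, old) mean profile.

    With r1 = mid/young and r2 = old/mid and a relative-change threshold
    epsilon: ``steady_up`` needs both steps >= 1+eps; ``steady_down`` both
    <= 1/(1+eps); ``late_up``/``late_down`` need r1 inside the flat band
    (1/(1+eps), 1+eps) and r2 beyond it; anything else is ``other``.
    """
    young, mid, old = (float(v) for v in profile)
    if min(young, mid, old) <= 0:
        raise ValueError("profile means must be positive")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    up = 1.0 + epsilon
    down = 1.0 / up
    r1 = mid / young
    r2 = old / mid
    if r1 >= up and r2 >= up:
        return "steady_up"
    if r1 <= down and r2 <= down:
        return "steady_down"
    if down < r1 < up and r2 >= up:
        return "late_up"
    if down < r1 < up and r2 <= down:
        return "late_down"
    return "other"


def label_clusters(clusters: ClusterSet, epsilon: float) -> ClusterSet:
    """Attach a trend label to every cluster from its mean profile."""
    if clusters.profiles is None:
        raise ValueError("cluster profiles must be computed first")
    labels = [
        classify_trend(clusters.profiles.loc[i, list(AGES)], epsilon)
        for i in range(clusters.n_clusters)
    ]
    return ClusterSet(clusters=clusters.clusters, profiles=clusters.profiles, labels=labels)


def trend_candidates(
    clusters: ClusterSet, classes: tuple[str, ...] = TREND_CLASSES
) -> dict[str, list[str]]:
    """Member proteins of clusters whose trend label is a class of interest.

    Returns a mapping class -> ordered protein list (union over matching
    clusters, cluster order preserved).
    """
    if clusters.labels is None:
        raise ValueError("clusters must be labelled first")
    out: dict[str, list[str]] = {c: [] for c in classes}
    for members, label in zip(clusters.clusters, clusters.labels):
        if label in out:
            out[label].extend(members)
    return out


def subtract_common(
    syn_sets: dict[str, list[str]],
    nonsyn_sets: dict[str, list[str]],
    pooled: bool = False,
) -> list[str]:
    """Remove proteins altered in the same manner in both compartments.

    Per trend class the symmetric difference of the two compartments'
    sets is kept; the union over classes is returned sorted by protein id
    (deterministic).  With ``pooled=True`` all classes are pooled before
    the subtraction.
    """
    if pooled:
        syn_sets = {"pooled": [p for c in syn_sets.values() for p in c]}
        nonsyn_sets = {"pooled": [p for c in nonsyn_sets.values() for p in c]}
    kept: list[str] = []
    seen: set[str] = set()
    for cls in syn_sets.keys() | nonsyn_sets.keys():
        s = set(syn_sets.get(cls, ()))
        ns = set(nonsyn_sets.get(cls, ()))
        sym = (s | ns) - (s & ns)
        for p in list(syn_sets.get(cls, ())) + list(nonsyn_sets.get(cls, ())):
            if p in sym and p not in seen:
                kept.append(p)
                seen.add(p)
    kept.sort()
    return kept


def ratio_to_young(matrix: AbundanceMatrix, compartment: str) -> pd.DataFrame:
    """Per-protein (1, mid/young, old/young) group-mean profile."""
    gm = group_means(matrix)
    if compartment not in gm.columns.get_level_values("compartment"):
        raise ValueError(f"no samples for compartment {compartment!r}")
    block = gm[compartment]
    young = block["young"].to_numpy(dtype=float)
    if np.any(young <= 0):
        raise ValueError("young group mean must be positive")
    out = block[list(AGES)].div(block["young"], axis=0)
    out.columns = list(AGES)
    return out


def archetypal_filter(
    candidate_ids,
    profiles_syn: pd.DataFrame,
    profiles_nonsyn: pd.DataFrame,
    config: PipelineConfig,
) -> list[str]:
    """Concordant-then-divergent profile selection.

    Keeps candidates whose ratio-to-young profiles satisfy
    |log2(p_S(mid)/p_NS(mid))| <= concord_tau (young/mid concordance;
    young is 1:1 by construction) and |log2(p_S(old)/p_NS(old))| >
    concord_tau (demarcation at old age).
    """
    kept = []
    for pid in candidate_ids:
        if pid not in profiles_syn.index or pid not in profiles_nonsyn.index:
            raise KeyError(f"missing profile for candidate {pid!r}")
        mid = abs(np.log2(profiles_syn.at[pid, "mid"] / profiles_nonsyn.at[pid, "mid"]))
        old = abs(np.log2(profiles_syn.at[pid, "old"] / profiles_nonsyn.at[pid, "old"]))
        if mid <= config.concord_tau and old > config.concord_tau:
            kept.append(pid)
    return kept


def fold_change_filter(
    candidate_ids,
    profiles_syn: pd.DataFrame,
    profiles_nonsyn: pd.DataFrame,
    divergence_fold: float,
) -> list[str]:
    """Keep candidates with >= divergence_fold cross-compartment change at old age."""
    cut = np.log2(divergence_fold)
    kept = []
    for pid in candidate_ids:
        old = abs(np.log2(profiles_syn.at[pid, "old"] / profiles_nonsyn.at[pid, "old"]))
        if old >= cut:
            kept.append(pid)
    return kept


@dataclass
class FunnelResult:
    """Output of :func:`run_funnel`.

    ``table`` holds one row per common protein with per-compartment trend
    labels, the mid/old cross-compartment log2 ratios and the nested pass
    flags ``in_subtracted_set`` -> ``archetypal`` -> ``pass_fold``;
    ``counts`` records the funnel stage sizes; the cluster sets and
    ratio-to-young profiles are kept for inspection and plotting.
    """

    table: pd.DataFrame
    counts: dict[str, int]
    clusters_syn: ClusterSet
    clusters_nonsyn: ClusterSet
    profiles_syn: pd.DataFrame
    profiles_nonsyn: pd.DataFrame

    @property
    def final_candidates(self) -> list[str]:
        return list(self.table.index[self.table["pass_fold"]])


def _protein_trends(
    matrix: AbundanceMatrix,
    retained: list[str],
    config: PipelineConfig,
    compartment: str,
) -> tuple[dict[str, str], ClusterSet]:
    """Trend label per protein for one compartment (via clusters by default)."""
    sub = matrix.subset_compartment(compartment).subset_proteins(retained)
    if config.per_protein_trends:
        prof = group_means(sub)[compartment]
        labels = {
            pid: classify_trend(prof.loc[pid, list(AGES)], config.trend_epsilon)
            for pid in sub.protein_ids
        }
        clusters = ClusterSet(clusters=[[p] for p in sub.protein_ids])
        return labels, clusters
    graph = build_protein_graph(sub, config)
    clusters = mcl_cluster(graph, config)
    clusters = cluster_profiles(clusters, sub)
    clusters = label_clusters(clusters, config.trend_epsilon)
    labels = {
        pid: clusters.labels[i]
        for i, members in enumerate(clusters.clusters)
        for pid in members
    }
    return labels, clusters


def run_funnel(
    matrix_syn: AbundanceMatrix,
    matrix_nonsyn: AbundanceMatrix,
    config: PipelineConfig | None = None,
) -> FunnelResult:
    """Run the full candidate funnel on two single-compartment matrices.

    Stages: common-protein intersection -> feature/protein statistical
    filters (a protein is retained if it passes in at least one
    compartment) -> per-compartment correlation graph + MCL + trend
    labelling -> per-class cross-compartment subtraction -> archetypal
    profile selection on ratio-to-young profiles -> old-age fold-change
    filter.  Fully deterministic given the inputs and config.
    """
    config = config or PipelineConfig()
    common = common_proteins(matrix_syn, matrix_nonsyn)
    syn = matrix_syn.subset_proteins(common)
    nonsyn = matrix_nonsyn.subset_proteins(common)

    stats_syn = feature_stats(syn, config, "synaptic")
    stats_nonsyn = feature_stats(nonsyn, config, "non_synaptic")

    def _passes(st: pd.DataFrame) -> pd.Series:
        # combined feature + protein filter within one compartment
        return (
            (st["power"] >= config.power_min)
            & (st["max_fold_change"] >= config.fc_min)
            & (st["anova_p"] <= config.alpha)
            & (st["unique_peptides"] >= config.min_unique_peptides)
        )

    ok = _passes(stats_syn).reindex(common) | _passes(stats_nonsyn).reindex(common)
    retained = [p for p in common if bool(ok[p])]

    trends_syn, clusters_syn = _protein_trends(matrix_syn, retained, config, "synaptic")
    trends_nonsyn, clusters_nonsyn = _protein_trends(
        matrix_nonsyn, retained, config, "non_synaptic"
    )
    syn_sets = {
        c: [p for p in retained if trends_syn.get(p) == c] for c in TREND_CLASSES
    }
    nonsyn_sets = {
        c: [p for p in retained if trends_nonsyn.get(p) == c] for c in TREND_CLASSES
    }
    n_trend = len(
        {p for s in syn_sets.values() for p in s}
        | {p for s in nonsyn_sets.values() for p in s}
    )
    subtracted = subtract_common(syn_sets, nonsyn_sets, pooled=config.pooled_subtraction)

    profiles_syn = ratio_to_young(syn, "synaptic")
    profiles_nonsyn = ratio_to_young(nonsyn, "non_synaptic")
    archetypal = archetypal_filter(subtracted, profiles_syn, profiles_nonsyn, config)
    final = fold_change_filter(
        archetypal, profiles_syn, profiles_nonsyn, config.divergence_fold
    )

    sub_set, arch_set, final_set = set(subtracted), set(archetypal), set(final)
    mid_ratio = np.log2(profiles_syn["mid"] / profiles_nonsyn["mid"])
    old_ratio = np.log2(profiles_syn["old"] / profiles_nonsyn["old"])
    table = pd.DataFrame(
        {
            "trend_syn": [trends_syn.get(p, "other") for p in common],
            "trend_nonsyn": [trends_nonsyn.get(p, "other") for p in common],
            "mid_log2_ratio": mid_ratio.reindex(common),
            "old_log2_ratio": old_ratio.reindex(common),
            "retained": [p in set(retained) for p in common],
            "in_subtracted_set": [p in sub_set for p in common],
            "archetypal": [p in arch_set for p in common],
            "pass_fold": [p in final_set for p in common],
        },
        index=pd.Index(common, name="protein_id"),
    )
    counts = {
        "input_synaptic": matrix_syn.n_proteins,
        "input_non_synaptic": matrix_nonsyn.n_proteins,
        "common": len(common),
        "retained": len(retained),
        "trend_labelled": n_trend,
        "subtracted": len(subtracted),
        "archetypal": len(archetypal),
        "final": len(final),
    }
    return FunnelResult(
        table=table,
        counts=counts,
        clusters_syn=clusters_syn,
        clusters_nonsyn=clusters_nonsyn,
        profiles_syn=profiles_syn,
        profiles_nonsyn=profiles_nonsyn,
    )
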
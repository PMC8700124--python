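"""QC and annotation statistics.

Three independent utilities: two-sample t-tests on marker proteins to
verify compartment enrichment (e.g. synaptophysin, SV2A, synaptotagmin-7
in synaptic vs non-synaptic fractions), over-representation of annotation
terms with fold enrichment + one-sided Fisher exact p + Benjamini-Hochberg
FDR, and a generic activation z-score for user-supplied signed
regulator->target networks (net direction-consistent targets over sqrt N).
No annotation databases are bundled; the annotation map is a two-column
TSV (term_id, protein_id).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceMatrix


def marker_ttest(
    matrix: AbundanceMatrix,
    marker_ids: Iterable[str],
    compartment_a: str = "synaptic",
    compartment_b: str = "non_synaptic",
    welch: bool = False,
) -> pd.DataFrame:
    """Unpaired two-tailed t-test per marker between two compartments.

    Pooled-variance Student's t by default; ``welch=True`` drops the
    equal-variance assumption.  Returns mean_a, mean_b, t and p per
    marker.
    """
    cols_a = matrix.samples.index[matrix.samples["compartment"] == compartment_a]
    cols_b = matrix.samples.index[matrix.samples["compartment"] == compartment_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 replicates per compartment")
    rows = []
    for pid in marker_ids:
        if pid not in matrix.values.index:
            raise KeyError(f"marker {pid!r} not in matrix")
        a = matrix.values.loc[pid, cols_a].to_numpy(dtype=float)
        b = matrix.values.loc[pid, cols_b].to_numpy(dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError(f"zero pooled variance for marker {pid!r}")
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {
                "protein_id": pid,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "t": float(t),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def fisher_exact_p(observed, selection_size, term_size, background_size):
    """One-sided (enrichment) Fisher exact p: hypergeometric upper tail.

    P(X >= observed) for X ~ Hypergeom(background, term, selection).
    Accepts scalars or broadcastable arrays.
    """
    return stats.hypergeom.sf(
        np.asarray(observed) - 1, background_size, term_size, selection_size
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def overrepresentation(
    selection: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Term over-representation of a selection against a background.

    Per term: observed overlap, expected = \\|selection\\| * \\|term\\| /
    \\|background\\|, fold_enrichment = (observed/\\|selection\\|) /
    (\\|term\\|/\\|background\\|), one-sided Fisher exact p and BH FDR
    across terms.  Term annotations are clipped to the background;
    ``selection`` must be a subset of ``background``.
    """
    bg = list(dict.fromkeys(background))
    bg_set = set(bg)
    sel = list(dict.fromkeys(selection))
    stray = [s for s in sel if s not in bg_set]
    if stray:
        raise ValueError(f"selection not a subset of background: {stray[:5]}")
    sel_set = set(sel)
    n_bg, n_sel = len(bg), len(sel)

    rows = []
    for term, members in annotation.items():
        term_set = set(members) & bg_set
        if not term_set:
            continue
        observed = len(term_set & sel_set)
        expected = n_sel * len(term_set) / n_bg
        fold = (observed / n_sel) / (len(term_set) / n_bg) if n_sel else math.nan
        p = float(fisher_exact_p(observed, n_sel, len(term_set), n_bg))
        rows.append(
            {
                "term_id": term,
                "observed": observed,
                "expected": expected,
                "fold_enrichment": fold,
                "p": p,
            }
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "observed", "expected", "fold_enrichment", "p"]
    ).set_index("term_id")
    result["fdr"] = bh_fdr(result["p"].to_numpy()) if len(result) else []
    return result


def activation_z(
    expectations: Mapping[str, int], observed: Mapping[str, int]
) -> dict:
    """Activation z-score of one regulator against observed direction calls.

    ``expectations`` maps target -> expected sign (+1 activation, -1
    inhibition); ``observed`` maps target -> observed direction (+1 up,
    -1 down); targets absent from ``observed`` are ignored.  z =
    (n_consistent - n_inconsistent) / sqrt(n_consistent + n_inconsistent);
    reported as None when no target is observed.
    """
    n_cons = n_incons = 0
    for target, expect in expectations.items():
        if expect not in (1, -1):
            raise ValueError(f"expected sign for {target!r} must be +1 or -1")
        obs = observed.get(target)
        if obs is None:
            continue
        if obs not in (1, -1):
            raise ValueError(f"observed direction for {target!r} must be +1 or -1")
        if obs == expect:
            n_cons += 1
        else:
            n_incons += 1
    total = n_cons + n_incons
    z = (n_cons - n_incons) / math.sqrt(total) if total else None
    return {"n_consistent": n_cons, "n_inconsistent": n_incons, "z": z}


def read_annotation(path) -> dict[str, list[str]]:
    """Read a two-column (term_id, protein_id) TSV annotation map."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"term_id", "protein_id"} <= set(table.columns):
        raise ValueError(f"{path}: needs columns term_id and protein_id")
    out: dict[str, list[str]] = {}
    for term, pid in zip(table["term_id"], table["protein_id"]):
        out.setdefault(term, []).append(pid)
    return out
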
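"""Synthetic timecourse generator with planted temporal structure.

Emulates a two-compartment (synaptic / non-synaptic mitochondria) x
three-age (young, mid, old) x n-replicate label-free proteomics design.
Each protein is assigned one planted class:

``flat``
    equal means across ages in both compartments;
``steady_up`` / ``steady_down``
    mean multiplied (divided) by ``effect_size`` at each successive age,
    in both compartments;
``late_up`` / ``late_down``
    young == mid, old = mid * effect_size (or / effect_size), in both
    compartments;
``divergent_old``
    flat in non-synaptic mitochondria; flat young->mid in synaptic with
    old = mid * divergent_fold (sign alternating per protein index).

Noise is multiplicative log-normal: abundance = mean * exp(N(0, noise_sd^2)).
Baselines are drawn log-uniformly from ``baseline_range``.  Identical seed
implies bit-identical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AGES, COMPARTMENTS, SIM_CLASSES, SimConfig
from .io import AbundanceMatrix

_COMP_SHORT = {"synaptic": "syn", "non_synaptic": "nsyn"}


def _class_counts(config: SimConfig) -> dict[str, int]:
    """Integer class sizes by largest-remainder apportionment."""
    n = int(config.n_proteins)
    raw = {c: config.class_fractions[c] * n for c in SIM_CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    remainders = sorted(raw, key=lambda c: (raw[c] - counts[c], c), reverse=True)
    for c in remainders[:short]:
        counts[c] += 1
    return counts


def planted_age_multipliers(
    label: str, compartment: str, effect_size: float, divergent_fold: float, sign: int = 1
) -> np.ndarray:
    """Mean multiplier per age (young, mid, old) for one planted class."""
    e = effect_size
    if label == "flat":
        m = (1.0, 1.0, 1.0)
    elif label == "steady_up":
        m = (1.0, e, e * e)
    elif label == "steady_down":
        m = (1.0, 1.0 / e, 1.0 / (e * e))
    elif label == "late_up":
        m = (1.0, 1.0, e)
    elif label == "late_down":
        m = (1.0, 1.0, 1.0 / e)
    elif label == "divergent_old":
        if compartment == "synaptic":
            f = divergent_fold if sign >= 0 else 1.0 / divergent_fold
            m = (1.0, 1.0, f)
        else:
            m = (1.0, 1.0, 1.0)
    else:
        raise ValueError(f"unknown planted class {label!r}")
    return np.asarray(m, dtype=float)


def sample_table(replicates_per_group: int) -> pd.DataFrame:
    """Sample metadata for the full 2 x 3 x R design, canonical order."""
    rows = []
    for comp in COMPARTMENTS:
        for age in AGES:
            for rep in range(1, replicates_per_group + 1):
                rows.append(
                    {
                        "sample_id": f"{_COMP_SHORT[comp]}_{age}_r{rep}",
                        "compartment": comp,
                        "age": age,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_dataset(config: SimConfig) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Generate an abundance matrix and its ground-truth table.

    Returns
    -------
    matrix : AbundanceMatrix
        ``n_proteins`` rows x (2 compartments x 3 ages x replicates)
        columns of strictly positive abundances.
    truth : pandas.DataFrame
        Indexed by protein id with columns ``class`` (planted label) and
        ``compartment`` (where the effect was planted: ``both`` for
        flat/steady/late classes, ``synaptic`` for divergent_old).
    """
    rng = np.random.default_rng(config.seed)
    n = int(config.n_proteins)
    reps = int(config.replicates_per_group)
    meta = sample_table(reps)
    n_samples = len(meta)

    counts = _class_counts(config)
    labels = np.concatenate(
        [np.full(counts[c], c, dtype=object) for c in SIM_CLASSES]
    )
    protein_ids = [f"P{i:05d}" for i in range(n)]

    low, high = config.baseline_range
    baselines = np.exp(rng.uniform(np.log(low), np.log(high), size=n))

    # Planted mean per (protein, sample): baseline * age multiplier.
    means = np.empty((n, n_samples))
    div_rank = 0  # position within the divergent block, drives sign alternation
    sample_comp = meta["compartment"].to_numpy()
    sample_age_idx = np.array([AGES.index(a) for a in meta["age"]])
    for i in range(n):
        label = labels[i]
        if label == "divergent_old":
            sign = 1 if div_rank % 2 == 0 else -1
            div_rank += 1
        else:
            sign = 1
        for comp in COMPARTMENTS:
            mult = planted_age_multipliers(
                label, comp, config.effect_size, config.divergent_fold, sign
            )
            cols = sample_comp == comp
            means[i, cols] = baselines[i] * mult[sample_age_idx[cols]]

    values = means
    if config.noise_sd > 0:
        values = values * np.exp(rng.normal(0.0, config.noise_sd, size=means.shape))
    if config.biological_sd > 0:
        values = values * np.exp(
            rng.normal(0.0, config.biological_sd, size=means.shape)
        )

    peptides = rng.integers(2, 21, size=n)
    n_single = int(round(config.frac_single_peptide * n))
    if n_single > 0:
        single_idx = rng.choice(n, size=n_single, replace=False)
        peptides[single_idx] = 1

    matrix = AbundanceMatrix(
        values=pd.DataFrame(values, index=protein_ids, columns=meta.index),
        samples=meta,
        unique_peptides=pd.Series(peptides, index=protein_ids, name="unique_peptides"),
    )
    truth = pd.DataFrame(
        {
            "class": labels,
            "compartment": [
                "synaptic" if lab == "divergent_old" else "both" for lab in labels
            ],
        },
        index=pd.Index(protein_ids, name="protein_id"),
    )
    return matrix, truth
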
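"""Minimal plotting: per-candidate ratio-to-young profile SVGs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .config import AGES
from .candidates import FunnelResult


def plot_candidate_profiles(
    result: FunnelResult, outdir, max_candidates: int = 50
) -> list[Path]:
    """One SVG per final candidate: synaptic vs non-synaptic ratio to young."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    x = range(len(AGES))
    for pid in result.final_candidates[:max_candidates]:
        fig, ax = plt.subplots(figsize=(3.2, 2.4))
        ax.plot(x, result.profiles_syn.loc[pid, list(AGES)], "o-", color="grey",
                label="synaptic")
        ax.plot(x, result.profiles_nonsyn.loc[pid, list(AGES)], "s-", color="black",
                label="non-synaptic")
        ax.set_xticks(list(x), AGES)
        ax.set_ylabel("ratio to young")
        ax.set_title(pid, fontsize=9)
        ax.legend(fontsize=7, frameon=False)
        fig.tight_layout()
        path = outdir / f"{pid}.svg"
        fig.savefig(path)
        plt.close(fig)
        paths.append(path)
    return paths
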
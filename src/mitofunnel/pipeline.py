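"""End-to-end orchestration: simulate/load -> filter -> graphs -> MCL ->
trends -> candidate funnel -> QC, with a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import COMPARTMENTS, PipelineConfig, SimConfig
from .candidates import FunnelResult, run_funnel
from .filtering import count_altered, feature_stats, filter_features, filter_proteins
from .io import AbundanceMatrix, read_abundance, write_dataset
from .networks import build_sample_graph, connected_components, write_graphml, write_membership
from .simulate import generate_dataset

log = logging.getLogger("mitofunnel")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written once per pipeline output directory."""

    config: dict
    seed: int | None
    input_digests: dict[str, str]
    stage_counts: dict[str, int]
    version: str = __version__

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "input_digests": self.input_digests,
                    "stage_counts": self.stage_counts,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def stats_table(matrix: AbundanceMatrix, config: PipelineConfig) -> pd.DataFrame:
    """Filter statistics for every compartment present, with pass flags."""
    frames = []
    for comp in COMPARTMENTS:
        if not (matrix.samples["compartment"] == comp).any():
            continue
        st = feature_stats(matrix, config, comp)
        st.insert(0, "compartment", comp)
        st["pass_feature"] = st.index.isin(filter_features(st, config))
        st["pass_protein"] = st.index.isin(filter_proteins(st, config))
        frames.append(st)
    out = pd.concat(frames)
    out.index.name = "protein_id"
    return out


def run_all(
    config: PipelineConfig,
    outdir: Path | str,
    input_path: Path | str | None = None,
    sim_config: SimConfig | None = None,
) -> RunManifest:
    """Execute every stage and write all artifacts plus a manifest.

    Either ``input_path`` (a dataset directory readable by
    :func:`read_abundance`) or ``sim_config`` (simulate first) must be
    given.  Identical config + seed gives byte-identical TSV outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()

    if (input_path is None) == (sim_config is None):
        raise ValueError("exactly one of input_path / sim_config is required")

    stage_counts: dict[str, int] = {}
    input_digests: dict[str, str] = {}
    seed = None
    if sim_config is not None:
        seed = sim_config.seed
        log.info("simulating %d proteins (seed %d)", sim_config.n_proteins, seed)
        matrix, truth = generate_dataset(sim_config)
        written = write_dataset(matrix, truth, outdir / "dataset")
        input_digests = {k: _sha256(p) for k, p in written.items()}
    else:
        input_path = Path(input_path)
        if not input_path.exists():
            raise FileNotFoundError(f"input path {input_path} does not exist")
        matrix = read_abundance(input_path)
        for f in sorted(Path(input_path).glob("*.tsv")):
            input_digests[f.name] = _sha256(f)
    stage_counts["proteins"] = matrix.n_proteins
    stage_counts["samples"] = matrix.n_samples

    log.info("computing filter statistics")
    st = stats_table(matrix, config)
    st.to_csv(outdir / "stats.tsv", sep="\t", float_format="%.10g")

    log.info("building sample-sample graphs")
    for comp in COMPARTMENTS:
        if not (matrix.samples["compartment"] == comp).any():
            continue
        g = build_sample_graph(matrix.subset_compartment(comp), config)
        write_graphml(g, outdir / f"sample_graph_{comp}.graphml")
        stage_counts[f"sample_components_{comp}"] = len(connected_components(g))

    log.info("running candidate funnel")
    funnel = run_funnel(
        matrix.subset_compartment("synaptic"),
        matrix.subset_compartment("non_synaptic"),
        config,
    )
    funnel.table.to_csv(outdir / "candidates.tsv", sep="\t", float_format="%.10g")
    write_membership(funnel.clusters_syn, outdir / "clusters_synaptic.tsv")
    write_membership(funnel.clusters_nonsyn, outdir / "clusters_non_synaptic.tsv")
    with open(outdir / "funnel.json", "w") as fh:
        json.dump(funnel.counts, fh, indent=2, sort_keys=True)
        fh.write("\n")
    stage_counts.update({f"funnel_{k}": v for k, v in funnel.counts.items()})
    stage_counts["clusters_synaptic"] = funnel.clusters_syn.n_clusters
    stage_counts["clusters_non_synaptic"] = funnel.clusters_nonsyn.n_clusters
    stage_counts.update(
        {f"altered_gt20pct_{k}": v for k, v in count_altered(matrix).items()}
    )

    manifest = RunManifest(
        config=config.to_dict()
        | ({"sim": sim_config.to_dict()} if sim_config else {}),
        seed=seed,
        input_digests=input_digests,
        stage_counts=stage_counts,
    )
    manifest.write(outdir / "manifest.json")
    log.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return manifest
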
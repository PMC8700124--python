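"""Shared data model and delimited-text I/O.

The universal currency of the pipeline is the :class:`AbundanceMatrix`:
a proteins x samples table of strictly positive normalised abundances plus
per-sample metadata (compartment, age, replicate) and per-protein unique
peptide counts.  Abundances are assumed already normalised upstream; no
additional between-sample normalisation is applied here.

File dialect: tab-separated, UTF-8, '.' decimal, mandatory header row,
'#'-prefixed comment lines ignored.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AGES, COMPARTMENTS

MATRIX_FILE = "abundance.tsv"
SAMPLES_FILE = "samples.tsv"
TRUTH_FILE = "truth.tsv"


class ParseError(ValueError):
    """Raised when an input file violates the data-model invariants."""


@dataclass
class AbundanceMatrix:
    """Proteins x samples matrix of normalised abundances with metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows indexed by protein id (input order preserved), columns by
        sample id; entries strictly positive and finite.
    samples : pandas.DataFrame
        Indexed by sample id, columns ``compartment`` (synaptic /
        non_synaptic), ``age`` (young / mid / old) and ``replicate``
        (positive integer).  Column order of ``values`` follows this table.
    unique_peptides : pandas.Series
        Per-protein unique peptide count (positive integers), indexed like
        ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unique_peptides: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.unique_peptides is None:
            self.unique_peptides = pd.Series(
                2, index=self.values.index, name="unique_peptides"
            )
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate protein ids: {dupes[:5]}")
        if self.samples.index.has_duplicates:
            dupes = self.samples.index[self.samples.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dupes[:5]}")
        if list(v.columns) != list(self.samples.index):
            raise ParseError("sample columns of values do not match sample metadata")
        arr = v.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(arr) | (arr <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                "abundances must be strictly positive and finite; offending cell "
                f"protein={v.index[i]!r} sample={v.columns[j]!r} value={arr[i, j]!r}"
            )
        unknown_comp = set(self.samples["compartment"]) - set(COMPARTMENTS)
        if unknown_comp:
            raise ParseError(f"unknown compartment token(s): {sorted(unknown_comp)}")
        unknown_age = set(self.samples["age"]) - set(AGES)
        if unknown_age:
            raise ParseError(f"unknown age token(s): {sorted(unknown_age)}")
        if (self.samples["replicate"].astype(int) <= 0).any():
            raise ParseError("replicate numbers must be positive integers")
        up = self.unique_peptides
        if not up.index.equals(v.index):
            raise ParseError("unique_peptides index does not match protein ids")
        if len(up) and (up.astype(int) <= 0).any():
            raise ParseError("unique_peptides must be positive integers")

    # -- convenience ----------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_compartment(self, compartment: str) -> "AbundanceMatrix":
        """Restrict to the samples of one compartment (protein order kept)."""
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        keep = self.samples.index[self.samples["compartment"] == compartment]
        return AbundanceMatrix(
            values=self.values[keep].copy(),
            samples=self.samples.loc[keep].copy(),
            unique_peptides=self.unique_peptides.copy(),
        )

    def subset_proteins(self, protein_ids) -> "AbundanceMatrix":
        """Restrict to the given proteins, preserving this matrix's order."""
        ids = [p for p in self.protein_ids if p in set(protein_ids)]
        return AbundanceMatrix(
            values=self.values.loc[ids].copy(),
            samples=self.samples.copy(),
            unique_peptides=self.unique_peptides.loc[ids].copy(),
        )


def group_means(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-protein mean abundance for each (compartment, age) cell.

    Returns a DataFrame indexed like the matrix with MultiIndex columns
    ``(compartment, age)`` in canonical order, covering every cell that has
    at least one sample.  Raises :class:`ParseError` if a compartment is
    present but one of its ages has no samples.
    """
    cols = []
    blocks = []
    present_comps = [c for c in COMPARTMENTS if (matrix.samples["compartment"] == c).any()]
    for comp in present_comps:
        for age in AGES:
            sel = matrix.samples.index[
                (matrix.samples["compartment"] == comp) & (matrix.samples["age"] == age)
            ]
            if len(sel) == 0:
                raise ParseError(f"no samples for group ({comp}, {age})")
            cols.append((comp, age))
            blocks.append(matrix.values[sel].to_numpy(dtype=float).mean(axis=1))
    out = pd.DataFrame(
        np.column_stack(blocks) if blocks else np.empty((matrix.n_proteins, 0)),
        index=matrix.values.index,
        columns=pd.MultiIndex.from_tuples(cols, names=["compartment", "age"]),
    )
    return out


# -- reading ------------------------------------------------------------

def _read_tsv(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def read_abundance(path: str | os.PathLike) -> AbundanceMatrix:
    """Read an abundance dataset from a directory (or matrix-file path).

    Expects ``abundance.tsv`` (columns: protein_id, unique_peptides, then
    one column per sample) and ``samples.tsv`` (columns: sample_id,
    compartment, age, replicate) side by side.  Sample order follows the
    metadata file.
    """
    path = Path(path)
    if path.is_dir():
        matrix_path = path / MATRIX_FILE
        samples_path = path / SAMPLES_FILE
    else:
        matrix_path = path
        samples_path = path.parent / SAMPLES_FILE

    raw = _read_tsv(matrix_path)
    meta = _read_tsv(samples_path)

    for col in ("sample_id", "compartment", "age", "replicate"):
        if col not in meta.columns:
            raise ParseError(f"{samples_path}: missing column {col!r}")
    try:
        meta["replicate"] = meta["replicate"].astype(int)
    except ValueError as exc:
        raise ParseError(f"{samples_path}: non-integer replicate: {exc}") from exc
    meta = meta.set_index("sample_id")

    if "protein_id" not in raw.columns:
        raise ParseError(f"{matrix_path}: missing column 'protein_id'")
    if "unique_peptides" not in raw.columns:
        raise ParseError(f"{matrix_path}: missing column 'unique_peptides'")
    missing = [s for s in meta.index if s not in raw.columns]
    if missing:
        raise ParseError(f"{matrix_path}: missing sample column(s) {missing[:5]}")

    raw = raw.set_index("protein_id")
    try:
        peptides = raw["unique_peptides"].astype(int)
    except ValueError as exc:
        raise ParseError(f"{matrix_path}: non-integer unique_peptides: {exc}") from exc
    try:
        values = raw[list(meta.index)].astype(float)
    except ValueError as exc:
        raise ParseError(f"{matrix_path}: non-numeric abundance: {exc}") from exc

    return AbundanceMatrix(values=values, samples=meta, unique_peptides=peptides)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    """Read a ground-truth table (protein_id, class, compartment)."""
    path = Path(path)
    if path.is_dir():
        path = path / TRUTH_FILE
    truth = _read_tsv(path)
    for col in ("protein_id", "class", "compartment"):
        if col not in truth.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return truth.set_index("protein_id")


# -- writing ------------------------------------------------------------

def write_dataset(
    matrix: AbundanceMatrix,
    truth: pd.DataFrame | None,
    path: str | os.PathLike,
) -> dict[str, Path]:
    """Write matrix + sample metadata (+ optional truth) as TSV files.

    Round-trips losslessly through :func:`read_abundance` (floats are
    written with ``repr`` precision).  Returns the paths written.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix_path = outdir / MATRIX_FILE
    table = matrix.values.copy()
    table.insert(0, "unique_peptides", matrix.unique_peptides.astype(int))
    table.index.name = "protein_id"
    table.to_csv(matrix_path, sep="\t", float_format="%.17g")

    samples_path = outdir / SAMPLES_FILE
    meta = matrix.samples.copy()
    meta.index.name = "sample_id"
    meta.to_csv(samples_path, sep="\t")

    written = {"matrix": matrix_path, "samples": samples_path}
    if truth is not None:
        truth_path = outdir / TRUTH_FILE
        t = truth.copy()
        t.index.name = "protein_id"
        t.to_csv(truth_path, sep="\t")
        written["truth"] = truth_path
    return written
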
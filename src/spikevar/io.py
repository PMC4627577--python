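"""Readers and writers for the tabular formats the pipeline consumes.

TSV count matrices carry the header row of cell ids and a first column of
gene ids; MatrixMarket matrices use ``.rows``/``.cols`` sidecar files with
one id per line. Allele counts travel as a long TSV. All writers round-trip
exactly through the corresponding reader.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datatypes import (
    ENDOGENOUS,
    SPIKEIN,
    AlleleCountTable,
    CellQCTable,
    CountMatrix,
    SpikeInReference,
)

#: molecules per (attomole/ul * ul): 1 attomol = 6.02214e5 molecules
MOLECULES_PER_ATTOMOLE = 6.02214e5

DEFAULT_SPIKEIN_PREFIX = "ERCC-"


def load_count_matrix(
    path: str | Path,
    spikein_pattern: str = DEFAULT_SPIKEIN_PREFIX,
    batch_map: dict[str, str] | pd.Series | None = None,
) -> CountMatrix:
    """Read a genes x cells matrix from TSV or MatrixMarket triplet form.

    Gene roles are assigned by id prefix (default ``"ERCC-"``); cells default
    to a single batch unless ``batch_map`` provides labels.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        counts = _read_mtx(path)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
        if counts.shape[0] == 0:
            raise ValueError(f"no genes parsed from {path}")
        counts.index = counts.index.astype(str).rename(None)
        counts.columns = counts.columns.astype(str)
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene ids")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate cell ids")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative values in count matrix")

    is_spike = counts.index.str.startswith(spikein_pattern)
    gene_role = pd.Series(
        np.where(is_spike, SPIKEIN, ENDOGENOUS), index=counts.index
    )
    if not is_spike.any():
        warnings.warn(
            f"no gene ids match spike-in pattern {spikein_pattern!r}; "
            "technical-model fitting will fail",
            stacklevel=2,
        )
    cell_batch = None
    if batch_map is not None:
        cell_batch = pd.Series(batch_map).reindex(counts.columns)
        if cell_batch.isna().any():
            missing = counts.columns[cell_batch.isna()]
            raise ValueError(f"batch_map missing cells: {list(missing)[:5]}")
    return CountMatrix(counts=counts, gene_role=gene_role, cell_batch=cell_batch)


def _read_mtx(path: Path) -> pd.DataFrame:
    mat = scipy.io.mmread(path)
    rows_path = path.with_suffix(".rows")
    cols_path = path.with_suffix(".cols")
    genes = rows_path.read_text().split()
    cells = cols_path.read_text().split()
    dense = np.asarray(
        mat.todense() if scipy.sparse.issparse(mat) else mat
    )
    if dense.shape != (len(genes), len(cells)):
        raise ValueError("MatrixMarket shape disagrees with sidecar files")
    if len(genes) == 0:
        raise ValueError(f"no genes parsed from {path}")
    return pd.DataFrame(dense, index=genes, columns=cells)


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write the counts as TSV (gene id first column, cell ids as header)."""
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")


def load_spikein_reference(
    path: str | Path,
    dilution: float = 1.0,
    volume_ul: float = 1.0,
) -> SpikeInReference:
    """Read a spike-in reference table.

    Accepts either a ``molecules_per_cell`` column (used verbatim) or a
    ``concentration_attomol_ul`` column, converted as
    ``n_s = conc * volume_ul / dilution * 6.02214e5`` (attomole to molecules
    via Avogadro). ``dilution`` of 100 means a 1:100 dilution of the mix.
    """
    if dilution <= 0:
        raise ValueError("dilution must be positive")
    if volume_ul <= 0:
        raise ValueError("volume_ul must be positive")
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    if "molecules_per_cell" in table.columns:
        n_s = table["molecules_per_cell"].astype(float)
    elif "concentration_attomol_ul" in table.columns:
        conc = table["concentration_attomol_ul"].astype(float)
        if (conc <= 0).any():
            raise ValueError("nonpositive spike-in concentration")
        n_s = conc * volume_ul / dilution * MOLECULES_PER_ATTOMOLE
    else:
        raise ValueError(
            "spike-in reference needs a 'molecules_per_cell' or "
            "'concentration_attomol_ul' column"
        )
    return SpikeInReference(n_s=n_s)


def write_spikein_reference(ref: SpikeInReference, path: str | Path) -> None:
    pd.DataFrame({"molecules_per_cell": ref.n_s}).to_csv(
        path, sep="\t", index_label="spike_id"
    )


def load_allele_counts(path: str | Path) -> AlleleCountTable:
    """Read a long-format allele count TSV.

    Required columns: snp_id, gene_id, cell_id, maternal, paternal.
    """
    records = pd.read_csv(path, sep="\t")
    for col in AlleleCountTable.REQUIRED:
        if col not in records.columns:
            raise ValueError(f"allele table missing column '{col}'")
    return AlleleCountTable(records=records[list(AlleleCountTable.REQUIRED)])


def write_allele_counts(table: AlleleCountTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def load_cell_qc(path: str | Path) -> CellQCTable:
    """Read the per-cell QC table (TSV, first column cell id)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    if "visual_fail" in table.columns:
        table["visual_fail"] = table["visual_fail"].astype(bool)
    return CellQCTable(table=table)


def write_cell_qc(qc: CellQCTable, path: str | Path) -> None:
    qc.table.to_csv(path, sep="\t", index_label="cell_id")
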
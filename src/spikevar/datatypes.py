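"""Core domain containers for spike-in-calibrated single-cell count data.

All tabular data are held in pandas objects; the classes here add the
invariants that downstream model fitting relies on (role tags for genes,
batch tags for cells, raw-vs-normalized tracking, allele-table consistency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ENDOGENOUS = "endogenous"
SPIKEIN = "spikein"


@dataclass
class CountMatrix:
    """A genes x cells count matrix with gene roles and cell batches.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are genes (including spike-in species), columns are cells.
        Raw matrices are integer-valued; normalization produces reals.
    gene_role : pandas.Series
        Maps gene id -> ``"endogenous"`` or ``"spikein"``.
    cell_batch : pandas.Series
        Maps cell id -> batch label. Defaults to a single batch.
    raw : bool
        True for unnormalized integer counts. Fitting operations that
        require a particular scale assert on this flag.
    """

    counts: pd.DataFrame
    gene_role: pd.Series | None = None
    cell_batch: pd.Series | None = None
    raw: bool = True

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate cell ids")
        values = self.counts.to_numpy()
        if values.size and np.nanmin(values) < 0:
            raise ValueError("negative counts")
        if self.gene_role is None:
            self.gene_role = pd.Series(ENDOGENOUS, index=self.counts.index)
        else:
            self.gene_role = self.gene_role.reindex(self.counts.index)
            if self.gene_role.isna().any():
                raise ValueError("gene_role missing for some genes")
            bad = set(self.gene_role.unique()) - {ENDOGENOUS, SPIKEIN}
            if bad:
                raise ValueError(f"unknown gene roles: {sorted(bad)}")
        if self.cell_batch is None:
            self.cell_batch = pd.Series("batch0", index=self.counts.columns)
        else:
            self.cell_batch = self.cell_batch.reindex(self.counts.columns)
            if self.cell_batch.isna().any():
                raise ValueError("cell_batch missing for some cells")

    # -- convenience views ------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def spikein_ids(self) -> pd.Index:
        return self.counts.index[(self.gene_role == SPIKEIN).to_numpy()]

    def endogenous_ids(self) -> pd.Index:
        return self.counts.index[(self.gene_role == ENDOGENOUS).to_numpy()]

    def spikeins(self) -> pd.DataFrame:
        """Counts restricted to spike-in rows."""
        return self.counts.loc[self.spikein_ids()]

    def endogenous(self) -> pd.DataFrame:
        """Counts restricted to endogenous gene rows."""
        return self.counts.loc[self.endogenous_ids()]

    def subset_cells(self, cell_ids) -> "CountMatrix":
        cell_ids = pd.Index(cell_ids)
        return CountMatrix(
            counts=self.counts.loc[:, cell_ids],
            gene_role=self.gene_role,
            cell_batch=self.cell_batch.loc[cell_ids],
            raw=self.raw,
        )

    def with_counts(self, counts: pd.DataFrame, raw: bool) -> "CountMatrix":
        return CountMatrix(
            counts=counts,
            gene_role=self.gene_role.reindex(counts.index),
            cell_batch=self.cell_batch.reindex(counts.columns),
            raw=raw,
        )


@dataclass
class SpikeInReference:
    """Expected number of input molecules per cell for each spike-in species.

    ``n_s`` is the quantity every cell's lysate received, so any cross-cell
    variation in the observed counts of these species is technical.
    """

    n_s: pd.Series

    def __post_init__(self) -> None:
        self.n_s = self.n_s.astype(float)
        if self.n_s.index.has_duplicates:
            raise ValueError("duplicate spike-in ids")
        if (self.n_s <= 0).any():
            raise ValueError("expected molecule counts must be positive")

    def aligned_to(self, spike_ids: pd.Index) -> pd.Series:
        """n_s reordered to the given spike ids; missing ids are an error."""
        missing = spike_ids.difference(self.n_s.index)
        if len(missing):
            raise ValueError(
                f"spike-ins absent from reference: {sorted(missing)[:5]}"
            )
        return self.n_s.loc[spike_ids]


@dataclass
class CellQCTable:
    """Per-cell read-mapping statistics used by the cell filters.

    Columns: total_reads, exon_reads, mito_reads (integer counts) and
    visual_fail (bool; empty/multiple-cell/debris capture sites).
    """

    table: pd.DataFrame

    REQUIRED = ("total_reads", "exon_reads", "mito_reads", "visual_fail")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"cell QC table missing column '{col}'")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate cell ids in QC table")
        t = self.table
        if (t["exon_reads"] > t["total_reads"]).any():
            raise ValueError("exon_reads exceeds total_reads")
        if (t["mito_reads"] > t["total_reads"]).any():
            raise ValueError("mito_reads exceeds total_reads")


@dataclass
class AlleleCountTable:
    """Long-format maternal/paternal counts per SNP per cell.

    Columns: snp_id, gene_id, cell_id, maternal, paternal. Each SNP maps to
    exactly one gene; (snp_id, cell_id) pairs are unique. Counts may be real
    after size-factor normalization.
    """

    records: pd.DataFrame

    REQUIRED = ("snp_id", "gene_id", "cell_id", "maternal", "paternal")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise ValueError(f"allele table missing column '{col}'")
        rec = self.records
        if (rec[["maternal", "paternal"]].to_numpy() < 0).any():
            raise ValueError("negative allele counts")
        if rec.duplicated(["snp_id", "cell_id"]).any():
            raise ValueError("duplicate (snp_id, cell_id) pairs")
        genes_per_snp = rec.groupby("snp_id")["gene_id"].nunique()
        if (genes_per_snp > 1).any():
            bad = genes_per_snp[genes_per_snp > 1].index[0]
            raise ValueError(f"snp {bad!r} maps to more than one gene")

    @property
    def cell_ids(self) -> pd.Index:
        return pd.Index(pd.unique(self.records["cell_id"]))

    @property
    def snp_ids(self) -> pd.Index:
        return pd.Index(pd.unique(self.records["snp_id"]))

    def snp_gene_map(self) -> pd.Series:
        return self.records.groupby("snp_id")["gene_id"].first()

    def pivot(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Wide (snp x cell) maternal and paternal matrices, zeros filled.

        The cell universe is the union of cell ids present in the table, so
        files should carry explicit zero rows for silent cells if those cells
        are to count towards mean-expression estimates.
        """
        mat = self.records.pivot(
            index="snp_id", columns="cell_id", values="maternal"
        ).fillna(0.0)
        pat = self.records.pivot(
            index="snp_id", columns="cell_id", values="paternal"
        ).fillna(0.0)
        return mat, pat


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP site with the annotations the SNP filters use.

    Coordinates are 1-based inclusive (VCF convention). ``n_flank_snps``
    counts other SNP sites within +/- read_length of ``pos``;
    ``has_flank_indel`` flags any indel in the same window.
    """

    snp_id: str
    chrom: str
    pos: int
    filter_status: str = "PASS"
    n_flank_snps: int | None = None
    has_flank_indel: bool | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")
        if self.n_flank_snps is not None and self.n_flank_snps < 0:
            raise ValueError("n_flank_snps must be >= 0")


@dataclass(frozen=True)
class VcfSite:
    """A minimal parsed VCF site: enough to classify SNP vs indel."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    filter_status: str = "PASS"

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_indel(self) -> bool:
        return not self.is_snp


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside synthetic experiments.

    genes : per-gene true mean molecules and biological variance.
    alleles : per-gene true maternal/paternal means and allelic var_bio.
    cells : per-cell true capture and sequencing efficiencies.
    """

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    alleles: pd.DataFrame = field(default_factory=pd.DataFrame)
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)
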
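"""Cell-level and SNP-level quality filters.

Cell filters discard low-quality libraries before any model fitting: too few
spike-in or endogenous transcripts (library failure at the molecule level),
too few exon-mapped reads (sequencing failure), excess mitochondrial reads
(ruptured cells) or a failed visual inspection of the capture site. SNP
filters remove sites prone to allelic mapping bias: non-PASS calls, dense
SNP neighbourhoods, nearby indels, and chromosome X in a male sample.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CellQCTable, CountMatrix, SnpRecord, VcfSite

X_CHROM_NAMES = {"X", "chrX", "x", "chrx"}


@dataclass(frozen=True)
class CellFilterParams:
    """Thresholds for :func:`filter_cells`; defaults follow standard QC
    practice for full-length single-cell libraries with ERCC spike-ins."""

    min_spikein_transcripts: float = 500
    min_endogenous_transcripts: float = 10_000
    min_exon_reads: float = 500_000
    min_exon_fraction: float = 0.5
    max_mito_fraction: float = 0.10
    # flank window for SNP QC, +/- read length in bp
    read_length: int = 100
    max_flank_snps: int = 4


@dataclass
class FilterResult:
    """Outcome of a filter: kept ids plus a reason per discarded id."""

    kept: list = field(default_factory=list)
    discarded: dict = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"id": i, "kept": True, "reason": ""} for i in self.kept]
        rows += [
            {"id": i, "kept": False, "reason": r}
            for i, r in self.discarded.items()
        ]
        return pd.DataFrame(rows, columns=["id", "kept", "reason"])


def filter_cells(
    matrix: CountMatrix,
    qc: CellQCTable | None = None,
    params: CellFilterParams | None = None,
) -> FilterResult:
    """Apply the cell-level QC criteria.

    A cell is discarded if it violates ANY criterion; the recorded reason is
    the first violated one in the order: min_spikein, min_endogenous,
    min_exon, max_mito, visual_fail. Criteria are:

    - fewer than ``min_spikein_transcripts`` spike-in counts (strict <);
    - fewer than ``min_endogenous_transcripts`` endogenous counts;
    - fewer than ``min_exon_reads`` exon-mapped reads AND exon fraction below
      ``min_exon_fraction`` (either alone is enough to keep);
    - mitochondrial read fraction strictly greater than ``max_mito_fraction``;
    - visual failure of the capture site.

    The read-based criteria require a QC table; omitting it restricts the
    filter to the transcript-count criteria.
    """
    params = params or CellFilterParams()
    spike_sums = matrix.spikeins().sum(axis=0)
    endo_sums = matrix.endogenous().sum(axis=0)

    if qc is not None:
        missing = matrix.cell_ids.difference(qc.table.index)
        if len(missing):
            raise ValueError(
                f"cells absent from QC table: {list(missing)[:5]}"
            )

    result = FilterResult()
    for cell in matrix.cell_ids:
        reason = None
        if spike_sums[cell] < params.min_spikein_transcripts:
            reason = "min_spikein"
        elif endo_sums[cell] < params.min_endogenous_transcripts:
            reason = "min_endogenous"
        elif qc is not None:
            row = qc.table.loc[cell]
            total = row["total_reads"]
            exon_frac = row["exon_reads"] / total if total > 0 else 0.0
            mito_frac = row["mito_reads"] / total if total > 0 else 0.0
            if (
                row["exon_reads"] < params.min_exon_reads
                and exon_frac < params.min_exon_fraction
            ):
                reason = "min_exon"
            elif mito_frac > params.max_mito_fraction:
                reason = "max_mito"
            elif bool(row["visual_fail"]):
                reason = "visual_fail"
        if reason is None:
            result.kept.append(cell)
        else:
            result.discarded[cell] = reason
    return result


def filter_snps(
    records: list[SnpRecord],
    params: CellFilterParams | None = None,
) -> FilterResult:
    """Remove SNPs prone to reference-allele mapping bias.

    A SNP is removed if its VCF FILTER is not ``PASS``, if four or more other
    SNP sites fall within +/- read length, if any indel falls in that window,
    or if it lies on chromosome X. Records missing flank annotations are
    removed with reason ``"malformed"``.
    """
    params = params or CellFilterParams()
    result = FilterResult()
    for rec in records:
        if rec.n_flank_snps is None or rec.has_flank_indel is None:
            result.discarded[rec.snp_id] = "malformed"
        elif rec.filter_status != "PASS":
            result.discarded[rec.snp_id] = "non_pass"
        elif rec.n_flank_snps >= params.max_flank_snps:
            result.discarded[rec.snp_id] = "flank_snps"
        elif rec.has_flank_indel:
            result.discarded[rec.snp_id] = "flank_indel"
        elif rec.chrom in X_CHROM_NAMES:
            result.discarded[rec.snp_id] = "chrX"
        else:
            result.kept.append(rec.snp_id)
    return result


def annotate_snp_flanks(
    sites: list[VcfSite],
    read_length: int,
    snp_ids: dict[tuple[str, int], str] | None = None,
) -> list[SnpRecord]:
    """Annotate each SNP site with flank-SNP counts and flank-indel flags.

    The window is ``[pos - read_length, pos + read_length]``, inclusive at
    both ends; the SNP itself is excluded from its own flank-SNP count and
    sites sharing a position (multi-allelic splits) are counted once.
    """
    by_chrom_snp: dict[str, list[int]] = {}
    by_chrom_indel: dict[str, list[int]] = {}
    for site in sites:
        target = by_chrom_snp if site.is_snp else by_chrom_indel
        target.setdefault(site.chrom, []).append(site.pos)
    for d in (by_chrom_snp, by_chrom_indel):
        for chrom in d:
            d[chrom] = sorted(set(d[chrom]))

    records = []
    for site in sites:
        if not site.is_snp:
            continue
        snps = by_chrom_snp.get(site.chrom, [])
        lo = bisect_left(snps, site.pos - read_length)
        hi = bisect_right(snps, site.pos + read_length)
        n_flank = (hi - lo) - 1  # window contains the site itself once
        indels = by_chrom_indel.get(site.chrom, [])
        ilo = bisect_left(indels, site.pos - read_length)
        ihi = bisect_right(indels, site.pos + read_length)
        snp_id = None
        if snp_ids is not None:
            snp_id = snp_ids.get((site.chrom, site.pos))
        if snp_id is None:
            snp_id = f"{site.chrom}:{site.pos}"
        records.append(
            SnpRecord(
                snp_id=snp_id,
                chrom=site.chrom,
                pos=site.pos,
                filter_status=site.filter_status,
                n_flank_snps=n_flank,
                has_flank_indel=ihi > ilo,
            )
        )
    return records


def read_vcf_sites(path: str | Path) -> list[VcfSite]:
    """Parse a VCF into minimal sites (CHROM, POS, REF, ALT, FILTER only)."""
    from cyvcf2 import VCF

    sites = []
    for variant in VCF(str(path)):
        filt = variant.FILTER if variant.FILTER is not None else "PASS"
        sites.append(
            VcfSite(
                chrom=str(variant.CHROM),
                pos=int(variant.POS),
                ref=str(variant.REF),
                alts=tuple(str(a) for a in variant.ALT),
                filter_status=filt,
            )
        )
    return sites


def write_filter_summary(result: FilterResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False)
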
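"""Size-factor and batch-efficiency normalization.

Two median-of-ratios (DESeq-style) size factors are computed per cell: a
technical factor from spike-ins (sequencing-depth variation only) and a
biological factor from endogenous genes (depth plus total mRNA content).
Separately, when cells were processed in batches, the per-batch mean combined
efficiency E[eta] estimated from spike-ins is divided out so that the
expected observed spike-in count equals the known input quantity in every
batch, removing batch effects from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, SpikeInReference


@dataclass
class SizeFactors:
    """Per-cell scaling constants; ``technical`` from spike-ins,
    ``biological`` from endogenous genes."""

    technical: pd.Series
    biological: pd.Series

    def __post_init__(self) -> None:
        for name in ("technical", "biological"):
            f = getattr(self, name)
            if (f <= 0).any():
                raise ValueError(f"{name} size factors must be positive")


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """DESeq median-of-ratios factors for a genes x cells count block.

    The per-gene reference is the geometric mean across cells; genes with a
    zero in any cell are excluded (their geometric mean degenerates). Each
    cell's factor is the median ratio of its counts to the reference.
    """
    values = counts.to_numpy(dtype=float)
    usable = (values > 0).all(axis=1)
    if not usable.any():
        raise ValueError("size factors undefined: no gene nonzero in all cells")
    logs = np.log(values[usable])
    log_ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_ref, axis=0))
    return pd.Series(factors, index=counts.columns)


def compute_size_factors(matrix: CountMatrix, subset: str) -> pd.Series:
    """Median-of-ratios factors from the ``"spikein"`` or ``"endogenous"``
    rows of a raw count matrix."""
    if subset == "spikein":
        block = matrix.spikeins()
    elif subset == "endogenous":
        block = matrix.endogenous()
    else:
        raise ValueError("subset must be 'spikein' or 'endogenous'")
    if block.shape[0] == 0:
        raise ValueError(f"no {subset} genes in matrix")
    return median_of_ratios(block)


def compute_both_size_factors(matrix: CountMatrix) -> SizeFactors:
    return SizeFactors(
        technical=compute_size_factors(matrix, "spikein"),
        biological=compute_size_factors(matrix, "endogenous"),
    )


def normalize_counts(matrix: CountMatrix, factors: SizeFactors) -> CountMatrix:
    """Divide spike-in rows by the technical factor and endogenous rows by
    the biological factor of each cell."""
    for f in (factors.technical, factors.biological):
        missing = matrix.cell_ids.difference(f.index)
        if len(missing):
            raise ValueError(f"missing size factor for cells: {list(missing)[:5]}")
    out = matrix.counts.astype(float).copy()
    spike_ids = matrix.spikein_ids()
    endo_ids = matrix.endogenous_ids()
    out.loc[spike_ids] = out.loc[spike_ids].div(
        factors.technical.loc[matrix.cell_ids], axis=1
    )
    out.loc[endo_ids] = out.loc[endo_ids].div(
        factors.biological.loc[matrix.cell_ids], axis=1
    )
    return matrix.with_counts(out, raw=False)


def estimate_batch_efficiency(
    matrix: CountMatrix,
    reference: SpikeInReference,
    method: str = "ols",
) -> pd.Series:
    """Per-batch mean combined efficiency E[eta] from spike-ins.

    Pools all (spike, cell) pairs of a batch and fits the zero-intercept
    regression of observed on expected counts: ``sum(x*n) / sum(n^2)``
    (``method="ols"``, the default) or the ratio of sums ``sum(x) / sum(n)``
    (``method="ratio"``); the two differ only in how spikes are weighted.
    """
    spikes = matrix.spikeins()
    if spikes.shape[0] == 0:
        raise ValueError("no spike-in rows present")
    n_s = reference.aligned_to(spikes.index).to_numpy()
    estimates = {}
    for batch, cells in matrix.cell_batch.groupby(matrix.cell_batch).groups.items():
        x = spikes.loc[:, cells].to_numpy(dtype=float)
        if x.sum() == 0:
            raise ValueError(f"batch {batch!r} has all-zero spike-in counts")
        n_tiled = np.broadcast_to(n_s[:, None], x.shape)
        if method == "ols":
            eta = float((x * n_tiled).sum() / (n_tiled**2).sum())
        elif method == "ratio":
            eta = float(x.sum() / n_tiled.sum())
        else:
            raise ValueError("method must be 'ols' or 'ratio'")
        estimates[batch] = eta
    return pd.Series(estimates, name="E[eta]")


def normalize_by_batch_efficiency(
    matrix: CountMatrix, batch_eta: pd.Series
) -> CountMatrix:
    """Divide every count in a batch by that batch's E[eta].

    Afterwards the expected observed spike-in count equals the known input
    molecule number n_s in every batch, so batch differences in capture and
    sequencing efficiency no longer confound downstream comparisons.
    """
    missing = set(matrix.cell_batch.unique()) - set(batch_eta.index)
    if missing:
        raise ValueError(f"no efficiency estimate for batches: {sorted(missing)}")
    per_cell = matrix.cell_batch.map(batch_eta)
    out = matrix.counts.astype(float).div(per_cell, axis=1)
    return matrix.with_counts(out, raw=False)
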
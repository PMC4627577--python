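"""Pseudo-cell simulation and synthetic-experiment generation.

Two simulation modes mirror the two null hypotheses of the analysis:

- ``"T"`` (technical only): every cell carries the same true molecule count
  (mean-preserving stochastic rounding for fractional means), and all
  cross-cell variation in the observed counts comes from capture and
  sequencing. This is the null for the stochastic-ASE test.
- ``"T+B"`` (technical + biological): true molecule counts vary across cells
  following a Gamma-Poisson (negative binomial) law with the requested mean
  and variance. Only the first two moments are treated as meaningful; the
  Gamma-Poisson is a two-moment-sufficient convention, not a biological claim.

``generate_synthetic_experiment`` emits a complete, ground-truthed input set
(count matrix with spike-ins, allele table, QC table) that exercises every
stage of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    ENDOGENOUS,
    SPIKEIN,
    AlleleCountTable,
    CellQCTable,
    CountMatrix,
    SpikeInReference,
    SyntheticTruth,
)
from .technical import TechnicalNoiseModel, _beta_from_moments, _gamma_from_moments

MODE_T = "T"
MODE_TB = "T+B"


@dataclass
class SimulationSpec:
    """Settings for pseudo-cell simulation.

    mu may be a scalar (one entity) or an array (one entity per value); for
    allele pairs use :func:`simulate_allele_pseudo_cells`.
    """

    mode: str = MODE_T
    n_cells: int = 54
    mu: float | np.ndarray = 10.0
    var_bio: float | np.ndarray = 0.0
    efficiency_source: str = "empirical_resample"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in (MODE_T, MODE_TB):
            raise ValueError("mode must be 'T' or 'T+B'")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if np.any(np.asarray(self.mu) < 0):
            raise ValueError("mu must be nonnegative")
        if np.any(np.asarray(self.var_bio) < 0):
            raise ValueError("var_bio must be nonnegative")


def stochastic_round(mu, rng: np.random.Generator) -> np.ndarray:
    """Mean-preserving integer rounding: floor(mu) + Bernoulli(frac(mu))."""
    mu = np.asarray(mu, dtype=float)
    floor = np.floor(mu)
    return (floor + (rng.random(mu.shape) < (mu - floor))).astype(np.int64)


def simulate_true_counts(
    mode: str,
    mu,
    n_cells: int,
    rng: np.random.Generator,
    var_bio=0.0,
) -> np.ndarray:
    """Draw true molecule counts m per cell.

    Mode ``"T"``: constant-by-design counts via stochastic rounding (minimal
    variance at the requested mean; Poisson input variation would itself be
    biological under the technical/biological dichotomy, so the technical
    null must exclude it). Mode ``"T+B"``: negative binomial with mean ``mu``
    and variance ``max(var_bio, mu)``; a Gamma-Poisson cannot be
    underdispersed, so ``var_bio < mu`` falls back to Poisson.
    """
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), (n_cells,)).copy()
    if mode == MODE_T:
        return stochastic_round(mu_arr, rng)
    if mode != MODE_TB:
        raise ValueError("mode must be 'T' or 'T+B'")
    var = np.broadcast_to(np.asarray(var_bio, dtype=float), (n_cells,))
    out = np.empty(n_cells, dtype=np.int64)
    over = var > mu_arr
    pois = ~over & (mu_arr > 0)
    if pois.any():
        out[pois] = rng.poisson(mu_arr[pois])
    if over.any():
        m, v = mu_arr[over], var[over]
        shape = m**2 / (v - m)
        lam = rng.gamma(shape, (v - m) / m)
        out[over] = rng.poisson(lam)
    out[mu_arr == 0] = 0
    return out


def simulate_observation(
    m, theta, gamma, rng: np.random.Generator
) -> np.ndarray:
    """Observe true counts through the technical model:
    z ~ Binomial(m, theta), x ~ Poisson(z * gamma)."""
    m = np.asarray(m)
    theta = np.asarray(theta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if np.any(theta <= 0) or np.any(theta > 1):
        raise ValueError("theta must lie in (0, 1]")
    if np.any(gamma < 0):
        raise ValueError("gamma must be nonnegative")
    z = rng.binomial(m, np.broadcast_to(theta, m.shape))
    return rng.poisson(z * np.broadcast_to(gamma, m.shape))


def draw_efficiencies(
    model: TechnicalNoiseModel,
    n_cells: int,
    rng: np.random.Generator,
    source: str = "empirical_resample",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pseudo-cell (theta, gamma) pairs.

    ``empirical_resample`` samples fitted per-cell pairs with replacement,
    preserving their joint structure (and hence the per-cell combined
    efficiencies exactly); ``parametric`` draws independent moment-matched
    Beta and Gamma variates.
    """
    if source == "empirical_resample":
        est = model.cell_estimates_
        if est.shape[0] < 3:
            raise ValueError("empirical resampling needs >= 3 fitted cells")
        idx = rng.integers(0, est.shape[0], size=n_cells)
        theta = est["theta_hat"].to_numpy()[idx]
        gamma = est["gamma_hat"].to_numpy()[idx]
        return theta, gamma
    if source == "parametric":
        if model.var_theta_ > 0:
            theta = _beta_from_moments(model.mu_theta_, model.var_theta_).rvs(
                n_cells, random_state=rng
            )
        else:
            theta = np.full(n_cells, model.mu_theta_)
        if model.var_gamma_ > 0:
            gamma = _gamma_from_moments(model.mu_gamma_, model.var_gamma_).rvs(
                n_cells, random_state=rng
            )
        else:
            gamma = np.full(n_cells, model.mu_gamma_)
        return np.clip(theta, 1e-12, 1.0), gamma
    raise ValueError("source must be 'empirical_resample' or 'parametric'")


def simulate_pseudo_cells(
    model: TechnicalNoiseModel, spec: SimulationSpec
) -> CountMatrix:
    """Simulate a genes x pseudo-cells matrix from a fitted model.

    Entities are independent given the shared per-cell efficiencies.
    """
    rng = np.random.default_rng(spec.seed)
    mu = np.atleast_1d(np.asarray(spec.mu, dtype=float))
    var_bio = np.broadcast_to(np.asarray(spec.var_bio, dtype=float), mu.shape)
    theta, gamma = draw_efficiencies(
        model, spec.n_cells, rng, spec.efficiency_source
    )
    counts = np.empty((len(mu), spec.n_cells), dtype=np.int64)
    for g in range(len(mu)):
        m = simulate_true_counts(spec.mode, mu[g], spec.n_cells, rng, var_bio[g])
        counts[g] = simulate_observation(m, theta, gamma, rng)
    genes = [f"sim_gene_{g}" for g in range(len(mu))]
    cells = [f"pseudo_{c}" for c in range(spec.n_cells)]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=cells),
        gene_role=pd.Series(ENDOGENOUS, index=genes),
        raw=model.fitted_on_raw_,
    )


def simulate_allele_ratio_null(
    model: TechnicalNoiseModel,
    mu_mat: float,
    mu_pat: float,
    n_cells: int,
    n_sim: int,
    rng: np.random.Generator,
    mode: str = MODE_T,
    var_bio_mat: float = 0.0,
    var_bio_pat: float = 0.0,
    efficiency_source: str = "empirical_resample",
    max_redraw_factor: int = 10,
    eta_divisor: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized null distribution of the mean allelic ratio.

    Simulates ``n_sim`` replicates of ``n_cells`` pseudo cells with the two
    alleles expressed independently at (mu_mat, mu_pat); each replicate's
    statistic is the mean over informative cells (maternal+paternal > 0) of
    max(allele)/total. Replicates with no informative cell are redrawn
    (bounded by ``max_redraw_factor * n_sim`` total draws).

    Returns ``(r_bar, mu_mat_rep, mu_pat_rep, n_redrawn)`` where the middle
    two are each replicate's own plug-in allelic mean estimates (mean counts
    divided by ``eta_divisor``, default the mean fitted per-cell efficiency)
    - the nuisance features used for p-value calibration.
    """
    if eta_divisor is None:
        if efficiency_source == "empirical_resample":
            eta_divisor = float(model.cell_estimates_["eta_hat"].mean())
        else:
            eta_divisor = model.mu_eta_

    def draw(k: int):
        theta, gamma = draw_efficiencies(
            model, k * n_cells, rng, efficiency_source
        )
        theta = theta.reshape(k, n_cells)
        gamma = gamma.reshape(k, n_cells)
        sims = []
        for mu, vb in ((mu_mat, var_bio_mat), (mu_pat, var_bio_pat)):
            if mode == MODE_T:
                m = stochastic_round(np.full((k, n_cells), mu), rng)
            else:
                m = simulate_true_counts(
                    MODE_TB, mu, k * n_cells, rng, vb
                ).reshape(k, n_cells)
            z = rng.binomial(m, theta)
            sims.append(rng.poisson(z * gamma))
        x_mat, x_pat = sims
        total = x_mat + x_pat
        informative = total > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.maximum(x_mat, x_pat) / total
        ratio = np.where(informative, ratio, np.nan)
        n_inf = informative.sum(axis=1)
        r_bar = np.where(
            n_inf > 0, np.nansum(ratio, axis=1) / np.maximum(n_inf, 1), np.nan
        )
        return (
            r_bar,
            x_mat.mean(axis=1) / eta_divisor,
            x_pat.mean(axis=1) / eta_divisor,
        )

    r_bar, mu_m_rep, mu_p_rep = draw(n_sim)
    redrawn = 0
    budget = max_redraw_factor * n_sim
    drawn = n_sim
    while np.isnan(r_bar).any() and drawn < budget:
        bad = np.where(np.isnan(r_bar))[0]
        k = len(bad)
        drawn += k
        redrawn += k
        new_r, new_m, new_p = draw(k)
        r_bar[bad] = new_r
        mu_m_rep[bad] = new_m
        mu_p_rep[bad] = new_p
    if np.isnan(r_bar).any():
        # expression so low that even the redraw budget produced empty
        # replicates; report the defined ones only
        ok = ~np.isnan(r_bar)
        r_bar, mu_m_rep, mu_p_rep = r_bar[ok], mu_m_rep[ok], mu_p_rep[ok]
    return r_bar, mu_m_rep, mu_p_rep, redrawn


# ---------------------------------------------------------------------------
# full synthetic experiments
# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Design of a ground-truthed synthetic experiment.

    Defaults emulate a plate of cells spiked with a 92-species dilution
    series spanning the dynamic range, efficiency laws matching reported
    single-cell capture rates (theta ~ 10%, moderately variable) and read
    yields below one count per captured molecule, plus gene and allele grids
    covering null, imprinted-like and stochastic-ASE regimes.
    """

    n_cells: int = 200
    n_spikes: int = 92
    spike_min: float = 0.5
    spike_max: float = 1000.0
    mu_theta: float = 0.1
    var_theta: float = 0.001
    mu_gamma: float = 0.8
    var_gamma: float = 0.04
    n_batches: int = 1
    batch_eta_scale: tuple[float, ...] = ()
    # endogenous gene grid: (mu, cv_bio) pairs, replicated
    gene_mus: tuple[float, ...] = (1.0, 5.0, 20.0, 100.0, 500.0)
    gene_cv_bios: tuple[float, ...] = (0.0, 0.5, 1.0)
    genes_per_condition: int = 10
    # bulk of the transcriptome: moderately variable expressed genes that
    # carry realistic per-cell totals (so default QC thresholds are meaningful)
    n_background_genes: int = 300
    background_mu: float = 600.0
    background_cv: float = 0.5
    # allele grid
    n_null_alleles: int = 20
    n_imprinted: int = 5
    n_stochastic: int = 5
    allele_mu: float = 30.0
    qc_mean_total_reads: float = 2_000_000.0
    seed_qc_failures: bool = False


@dataclass
class SyntheticExperiment:
    matrix: CountMatrix
    reference: SpikeInReference
    allele_table: AlleleCountTable
    qc_table: CellQCTable
    truth: SyntheticTruth = field(default_factory=SyntheticTruth)


def generate_synthetic_experiment(
    config: SyntheticConfig | None = None, seed: int = 0
) -> SyntheticExperiment:
    """Generate a complete synthetic experiment with known ground truth.

    Deterministic given ``seed``. The emitted tables parse through the
    package loaders and exercise QC, normalization, model fitting, variance
    decomposition and the ASE test.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    cells = [f"cell_{c:03d}" for c in range(cfg.n_cells)]
    batches = pd.Series(
        [f"batch{c % max(cfg.n_batches, 1)}" for c in range(cfg.n_cells)],
        index=cells,
    )

    theta = (
        _beta_from_moments(cfg.mu_theta, cfg.var_theta).rvs(
            cfg.n_cells, random_state=rng
        )
        if cfg.var_theta > 0
        else np.full(cfg.n_cells, cfg.mu_theta)
    )
    gamma = (
        _gamma_from_moments(cfg.mu_gamma, cfg.var_gamma).rvs(
            cfg.n_cells, random_state=rng
        )
        if cfg.var_gamma > 0
        else np.full(cfg.n_cells, cfg.mu_gamma)
    )
    # optional batch effects scale the sequencing efficiency per batch
    if cfg.batch_eta_scale:
        scale = np.array(
            [
                cfg.batch_eta_scale[c % cfg.n_batches]
                for c in range(cfg.n_cells)
            ]
        )
        gamma = gamma * scale

    n_s = np.geomspace(cfg.spike_min, cfg.spike_max, cfg.n_spikes)
    spike_ids = [f"ERCC-{i:05d}" for i in range(cfg.n_spikes)]
    m_spike = stochastic_round(
        np.broadcast_to(n_s[:, None], (cfg.n_spikes, cfg.n_cells)), rng
    )
    z = rng.binomial(m_spike, theta[None, :])
    spike_counts = rng.poisson(z * gamma[None, :])

    gene_rows, gene_truth = [], []
    gidx = 0
    for mu in cfg.gene_mus:
        for cv in cfg.gene_cv_bios:
            for _ in range(cfg.genes_per_condition):
                var_bio = (cv * mu) ** 2
                mode = MODE_T if var_bio == 0 else MODE_TB
                m = simulate_true_counts(mode, mu, cfg.n_cells, rng, var_bio)
                zg = rng.binomial(m, theta)
                gene_rows.append(rng.poisson(zg * gamma))
                gene_truth.append(
                    {
                        "gene_id": f"gene_{gidx:04d}",
                        "mu": mu,
                        "cv_bio": cv,
                        "var_bio": var_bio,
                    }
                )
                gidx += 1
    for _ in range(cfg.n_background_genes):
        mu = cfg.background_mu
        var_bio = (cfg.background_cv * mu) ** 2
        m = simulate_true_counts(
            MODE_T if var_bio == 0 else MODE_TB, mu, cfg.n_cells, rng, var_bio
        )
        zg = rng.binomial(m, theta)
        gene_rows.append(rng.poisson(zg * gamma))
        gene_truth.append(
            {
                "gene_id": f"bg_{gidx:04d}",
                "mu": mu,
                "cv_bio": cfg.background_cv,
                "var_bio": var_bio,
            }
        )
        gidx += 1
    gene_ids = [t["gene_id"] for t in gene_truth]
    gene_block = (
        np.asarray(gene_rows)
        if gene_rows
        else np.empty((0, cfg.n_cells), dtype=np.int64)
    )
    counts = pd.DataFrame(
        np.vstack([gene_block, spike_counts]),
        index=gene_ids + spike_ids,
        columns=cells,
    )
    gene_role = pd.Series(
        [ENDOGENOUS] * len(gene_ids) + [SPIKEIN] * len(spike_ids),
        index=counts.index,
    )
    matrix = CountMatrix(counts=counts, gene_role=gene_role, cell_batch=batches)
    reference = SpikeInReference(n_s=pd.Series(n_s, index=spike_ids))

    # allele table: null (equal alleles, T), imprinted-like (unequal means),
    # stochastic (bimodal: each cell expresses one allele)
    allele_records = []
    allele_truth = []

    def observe(m_arr):
        zz = rng.binomial(m_arr, theta)
        return rng.poisson(zz * gamma)

    aidx = 0
    for _ in range(cfg.n_null_alleles):
        mu = cfg.allele_mu
        x_m = observe(stochastic_round(np.full(cfg.n_cells, mu / 2), rng))
        x_p = observe(stochastic_round(np.full(cfg.n_cells, mu / 2), rng))
        allele_truth.append(
            {"class": "null", "mu_mat": mu / 2, "mu_pat": mu / 2}
        )
        allele_records.append((aidx, x_m, x_p))
        aidx += 1
    for _ in range(cfg.n_imprinted):
        mu_m, mu_p = 0.9 * cfg.allele_mu, 0.1 * cfg.allele_mu
        x_m = observe(stochastic_round(np.full(cfg.n_cells, mu_m), rng))
        x_p = observe(stochastic_round(np.full(cfg.n_cells, mu_p), rng))
        allele_truth.append(
            {"class": "imprinted", "mu_mat": mu_m, "mu_pat": mu_p}
        )
        allele_records.append((aidx, x_m, x_p))
        aidx += 1
    for _ in range(cfg.n_stochastic):
        pick_m = rng.random(cfg.n_cells) < 0.5
        m_m = np.where(pick_m, int(cfg.allele_mu), 0)
        m_p = np.where(pick_m, 0, int(cfg.allele_mu))
        x_m = observe(m_m)
        x_p = observe(m_p)
        allele_truth.append(
            {
                "class": "stochastic",
                "mu_mat": cfg.allele_mu / 2,
                "mu_pat": cfg.allele_mu / 2,
            }
        )
        allele_records.append((aidx, x_m, x_p))
        aidx += 1

    rows = []
    for aidx, x_m, x_p in allele_records:
        for c, cell in enumerate(cells):
            rows.append(
                {
                    "snp_id": f"snp_{aidx:04d}",
                    "gene_id": f"ase_gene_{aidx:04d}",
                    "cell_id": cell,
                    "maternal": int(x_m[c]),
                    "paternal": int(x_p[c]),
                }
            )
    allele_columns = ["snp_id", "gene_id", "cell_id", "maternal", "paternal"]
    allele_table = AlleleCountTable(
        records=pd.DataFrame(rows, columns=allele_columns)
    )
    for i, t in enumerate(allele_truth):
        t["snp_id"] = f"snp_{i:04d}"
        t["gene_id"] = f"ase_gene_{i:04d}"

    # per-cell QC table: exon/mito reads in realistic proportions, with a
    # couple of deliberate failures when requested
    total = rng.normal(cfg.qc_mean_total_reads, cfg.qc_mean_total_reads / 10, cfg.n_cells)
    total = np.maximum(total, 1e5).astype(np.int64)
    exon_frac = rng.uniform(0.6, 0.8, cfg.n_cells)
    mito_frac = rng.uniform(0.01, 0.06, cfg.n_cells)
    visual_fail = np.zeros(cfg.n_cells, dtype=bool)
    if cfg.seed_qc_failures and cfg.n_cells >= 3:
        exon_frac[0] = 0.1
        total[0] = 400_000
        mito_frac[1] = 0.2
        visual_fail[2] = True
    qc_table = CellQCTable(
        table=pd.DataFrame(
            {
                "total_reads": total,
                "exon_reads": (total * exon_frac).astype(np.int64),
                "mito_reads": (total * mito_frac).astype(np.int64),
                "visual_fail": visual_fail,
            },
            index=pd.Index(cells, name="cell_id"),
        )
    )

    truth = SyntheticTruth(
        genes=pd.DataFrame(
            gene_truth, columns=["gene_id", "mu", "cv_bio", "var_bio"]
        ).set_index("gene_id"),
        alleles=pd.DataFrame(
            allele_truth,
            columns=["snp_id", "gene_id", "class", "mu_mat", "mu_pat"],
        ).set_index("snp_id"),
        cells=pd.DataFrame(
            {"theta": theta, "gamma": gamma, "batch": batches.to_numpy()},
            index=pd.Index(cells, name="cell_id"),
        ),
    )
    return SyntheticExperiment(
        matrix=matrix,
        reference=reference,
        allele_table=allele_table,
        qc_table=qc_table,
        truth=truth,
    )
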
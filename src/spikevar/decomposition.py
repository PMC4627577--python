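"""Per-gene decomposition of observed variance into technical and biological
components.

For a gene with normalized counts x across cells, the mean true abundance is
``mu_hat = mean(x)/mu_eta`` and

    var_obs = mu_hat*A + mu_hat^2*B + var_bio * r2_theta * r2_gamma

so the biological variance (cross-cell variance of true molecule counts) is
obtained by subtracting the technical terms and dividing by
``r2_theta*r2_gamma``. The subtraction is a moment estimate: for lowly
expressed genes it is noisy and frequently negative, in which case it is
clamped to zero and flagged rather than erroring - that noisiness is the
reason apparent variability at low expression should not be over-interpreted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import CountMatrix, SpikeInReference
from .technical import TechnicalNoiseModel


def estimate_mean_expression(counts, model: TechnicalNoiseModel):
    """Mean true molecules per cell: mean(x) / mu_eta.

    ``counts`` is a vector (one gene) or genes x cells array/DataFrame.
    """
    if model.mu_eta_ <= 0:
        raise ValueError("mu_eta must be positive")
    arr = np.asarray(counts, dtype=float)
    return arr.mean(axis=-1) / model.mu_eta_


class VarianceDecomposer(BaseEstimator):
    """Estimator splitting per-gene variance into technical and biological
    parts, with optional bootstrap uncertainty for the biological CV.

    Parameters
    ----------
    model : TechnicalNoiseModel
        A fitted technical-noise model on the same count scale as the data.
    n_boot : int, default 0
        Cell bootstrap resamples for the SE of cv_bio (0 disables).
    random_state : int or None
        Bootstrap seed.

    Attributes (after ``fit``)
    --------------------------
    results_ : pandas.DataFrame
        Per gene: mu_hat, var_obs, var_tech, var_bio, cv2_bio, frac_bio,
        clamped (and bootstrap_se when requested).
    """

    def __init__(
        self,
        model: TechnicalNoiseModel,
        n_boot: int = 0,
        random_state: int | None = None,
    ):
        self.model = model
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(
        self,
        matrix: CountMatrix,
        reference: SpikeInReference | None = None,
    ) -> "VarianceDecomposer":
        """Decompose every endogenous gene of ``matrix``.

        ``reference`` is only needed when bootstrapping (per-cell-dependent
        quantities are refitted on each cell resample).
        """
        if matrix.n_cells < 3:
            raise ValueError("variance decomposition needs >= 3 cells")
        if matrix.raw != self.model.fitted_on_raw_:
            raise ValueError(
                "count matrix and model are on different scales "
                "(raw vs normalized)"
            )
        endo = matrix.endogenous()
        self.results_ = _decompose_frame(endo, self.model)
        if self.n_boot >= 2:
            if reference is None:
                raise ValueError("bootstrap requires the spike-in reference")
            self.results_["bootstrap_se"] = bootstrap_biological_cv(
                matrix,
                self.model,
                reference,
                n_boot=self.n_boot,
                seed=self.random_state,
            )
        return self

    def transform(self, matrix: CountMatrix) -> pd.DataFrame:
        """Decompose without storing state; returns the per-gene table."""
        return _decompose_frame(matrix.endogenous(), self.model)

    def fit_transform(self, matrix: CountMatrix, reference=None) -> pd.DataFrame:
        return self.fit(matrix, reference).results_


def _decompose_frame(
    endo: pd.DataFrame, model: TechnicalNoiseModel
) -> pd.DataFrame:
    x = endo.to_numpy(dtype=float)
    mu_hat = x.mean(axis=1) / model.mu_eta_
    var_obs = x.var(axis=1, ddof=1)
    var_tech = mu_hat * model.A_ + mu_hat**2 * model.B_
    scale = model.r2_theta_ * model.r2_gamma_
    var_bio_raw = (var_obs - var_tech) / scale
    clamped = var_bio_raw < 0
    var_bio = np.maximum(var_bio_raw, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2_bio = np.where(mu_hat > 0, var_bio / mu_hat**2, 0.0)
        frac_bio = np.where(var_obs > 0, var_bio * scale / var_obs, 0.0)
    frac_bio = np.clip(frac_bio, 0.0, 1.0)
    return pd.DataFrame(
        {
            "mu_hat": mu_hat,
            "var_obs": var_obs,
            "var_tech": var_tech,
            "var_bio": var_bio,
            "cv2_bio": cv2_bio,
            "frac_bio": frac_bio,
            "clamped": clamped,
        },
        index=endo.index,
    )


def decompose_variance(
    matrix: CountMatrix, model: TechnicalNoiseModel
) -> pd.DataFrame:
    """Thin functional wrapper over :class:`VarianceDecomposer`."""
    return VarianceDecomposer(model).fit(matrix).results_


def bootstrap_biological_cv(
    matrix: CountMatrix,
    model: TechnicalNoiseModel,
    reference: SpikeInReference,
    n_boot: int = 100,
    seed: int | None = None,
) -> pd.Series:
    """Cell-bootstrap standard error of the biological CV per gene.

    Cells are resampled with replacement; the per-cell-dependent quantities
    (the combined efficiency, hence the scale of the technical coefficients)
    are re-estimated on each resample from the resampled spike-ins, then the
    gene decomposition is recomputed. The shape of the efficiency laws is
    held at the full-data fit - the bootstrap tracks sampling variability of
    the decomposition, not of the matching optimization. Deterministic given
    ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    n_cells = matrix.n_cells
    endo = matrix.endogenous()
    spikes = matrix.spikeins().to_numpy(dtype=float)
    n_s = reference.aligned_to(matrix.spikein_ids()).to_numpy()
    endo_arr = endo.to_numpy(dtype=float)
    scale = model.r2_theta_ * model.r2_gamma_
    cv_samples = np.empty((n_boot, endo.shape[0]))
    for b in range(n_boot):
        idx = rng.integers(0, n_cells, size=n_cells)
        mu_eta_b = spikes[:, idx].sum() / (n_s.sum() * n_cells)
        ratio = mu_eta_b / model.mu_eta_
        a_b, b_b = model.A_ * ratio, model.B_ * ratio**2
        xb = endo_arr[:, idx]
        mu_hat = xb.mean(axis=1) / mu_eta_b
        var_obs = xb.var(axis=1, ddof=1)
        var_bio = np.maximum(
            (var_obs - mu_hat * a_b - mu_hat**2 * b_b) / (scale * ratio**2),
            0.0,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            cv_samples[b] = np.where(
                mu_hat > 0, np.sqrt(var_bio) / mu_hat, 0.0
            )
    return pd.Series(cv_samples.std(axis=0, ddof=1), index=endo.index)


def summarize_frac_bio_by_expression(
    results: pd.DataFrame,
    quantiles: tuple[float, float] = (0.2, 0.8),
) -> pd.DataFrame:
    """Mean biological variance fraction in expression-percentile bins.

    Default bins contrast lowly expressed genes (below the 20th percentile
    of mu_hat) with highly expressed ones (above the 80th).
    """
    if results.empty:
        raise ValueError("empty decomposition results")
    lo_q, hi_q = quantiles
    mu = results["mu_hat"]
    if len(results) == 1:
        return pd.DataFrame(
            {
                "bin": ["all"],
                "n_genes": [1],
                "mean_frac_bio": [float(results["frac_bio"].iloc[0])],
            }
        )
    lo, hi = mu.quantile(lo_q), mu.quantile(hi_q)
    bins = {
        f"below_p{int(lo_q * 100)}": results[mu < lo],
        "middle": results[(mu >= lo) & (mu <= hi)],
        f"above_p{int(hi_q * 100)}": results[mu > hi],
    }
    rows = [
        {
            "bin": name,
            "n_genes": len(sub),
            "mean_frac_bio": float(sub["frac_bio"].mean()) if len(sub) else np.nan,
        }
        for name, sub in bins.items()
    ]
    return pd.DataFrame(rows)
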
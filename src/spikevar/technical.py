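"""Generative technical-noise model fitted from spike-ins.

The model: for cell ``c``, capture efficiency ``theta_c`` (i.i.d., moments
``mu_theta, var_theta``) and sequencing efficiency ``gamma_c`` (i.i.d.,
moments ``mu_gamma, var_gamma``) are independent of each other. An entity
with true molecule count ``m`` in cell ``c`` is observed as

    z | m     ~ Binomial(m, theta_c)      (stochastic transcript dropout)
    x | z     ~ Poisson(z * gamma_c)      (amplification + shot noise)

By the law of total variance, for an entity whose true abundance has mean
``E[m]`` and variance ``Var(m)`` across cells,

    E[x]   = E[m] * mu_eta,            mu_eta = mu_theta * mu_gamma
    Var(x) = E[m] * A + E[m]^2 * B + Var(m) * r2_theta * r2_gamma

with ``r2_theta = E[theta^2]``, ``r2_gamma = E[gamma^2]`` and

    A = mu_theta * mu_gamma + (mu_theta - r2_theta) * r2_gamma
    B = r2_theta * r2_gamma - mu_theta^2 * mu_gamma^2.

Spike-ins have known, constant input ``m = n_s`` in every cell, so their
cross-cell variance is purely technical, ``n_s * A + n_s^2 * B``; this
identifies the four moment parameters. Subtracting the technical terms from
a gene's observed variance then yields its biological variance with no
distributional assumption on the true molecule counts.

Estimation
----------
Per cell, the combined efficiency ``eta_c = theta_c * gamma_c`` is measured
precisely as the ratio of observed to expected spike totals. Splitting it
into capture and sequencing parts uses two further per-cell signals: the
within-cell overdispersion slope ``w_c = eta_c * (1 + gamma_c - eta_c)``
(zero-intercept regression of squared residuals on ``n_s``) and the per-cell
dropout rate ``d_c = theta_c * (1 - exp(-gamma_c))`` (maximum likelihood on
the cell's zero-count pattern). Both per-cell split estimates are noisy at
realistic spike designs, so the population moments are NOT the sample
moments of the per-cell values: instead the four parameters are fitted by
matching bias-corrected pooled statistics (zero-fraction curve across
spikes, mean/variance of per-cell efficiency, mean overdispersion slope,
mean/variance of the per-cell dropout rate and its covariance with
efficiency) to their exact expectations under moment-parametrized Beta
(capture) and Gamma (sequencing) efficiency laws, computed by Gauss-Legendre
quadrature in probability space. The parametric laws serve only as smoothing
devices; the estimands are the first two moments.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .datatypes import CountMatrix, SpikeInReference

MOMENT_FIELDS = (
    "mu_theta",
    "var_theta",
    "mu_gamma",
    "var_gamma",
    "mu_eta",
    "r2_theta",
    "r2_gamma",
    "A",
    "B",
)

_LEGENDRE_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _legendre01(k: int) -> tuple[np.ndarray, np.ndarray]:
    if k not in _LEGENDRE_CACHE:
        u, w = np.polynomial.legendre.leggauss(k)
        _LEGENDRE_CACHE[k] = ((u + 1) / 2, w / 2)
    return _LEGENDRE_CACHE[k]


def _quad_nodes(dist, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-space Gauss-Legendre nodes; robust for any shape params."""
    u, w = _legendre01(k)
    return dist.ppf(u), w


def _beta_from_moments(mean: float, var: float):
    var = min(var, mean * (1 - mean) * 0.999)
    conc = mean * (1 - mean) / var - 1
    return stats.beta(mean * conc, (1 - mean) * conc)


def _gamma_from_moments(mean: float, var: float):
    return stats.gamma(mean**2 / var, scale=var / mean)


def _p0_mixture(q, n_s):
    """P(x=0) given per-molecule zero probability q and fractional input n_s.

    Molecule counts are integers; fractional expected inputs are realized by
    mean-preserving stochastic rounding, so the zero probability is the
    floor/ceil mixture rather than a continuous power.
    """
    n_floor = np.floor(n_s)
    frac = n_s - n_floor
    return (1 - frac) * q**n_floor + frac * q ** (n_floor + 1)


def _dropout_mle(n_s: np.ndarray, zeros: np.ndarray):
    """Per-cell MLE of the dropout rate d = 1 - q from the zero pattern.

    ``zeros`` is spikes x cells boolean. Returns (d_hat, fisher_var).
    """
    n_cells = zeros.shape[1]
    n_floor = np.floor(n_s)
    frac = n_s - n_floor
    d_hat = np.empty(n_cells)
    d_var = np.empty(n_cells)
    for c in range(n_cells):
        zc = zeros[:, c]

        def nll(log_q):
            q = np.exp(log_q)
            p0 = np.clip(_p0_mixture(q, n_s), 1e-12, 1 - 1e-12)
            return -(np.log(p0[zc]).sum() + np.log1p(-p0[~zc]).sum())

        res = optimize.minimize_scalar(
            nll, bounds=(np.log(1e-5), -1e-10), method="bounded"
        )
        q = np.exp(res.x)
        p0 = np.clip(_p0_mixture(q, n_s), 1e-12, 1 - 1e-12)
        dp0 = (1 - frac) * n_floor * q ** (n_floor - 1) + frac * (
            n_floor + 1
        ) * q**n_floor
        info = (dp0**2 / (p0 * (1 - p0))).sum()
        d_hat[c] = 1 - q
        d_var[c] = 1 / max(info, 1e-12)
    return d_hat, d_var


def _gamma_from_dropout_ratio(ratio: float) -> float:
    """Solve (1 - exp(-g))/g = ratio for g; ratio in (0, 1)."""
    f = lambda g: (1 - np.exp(-g)) / g - ratio  # noqa: E731
    lo, hi = 1e-4, 100.0
    if f(lo) < 0:  # ratio above attainable range -> g below lo
        return lo
    if f(hi) > 0:  # ratio below attainable range -> g above hi
        return hi
    return float(optimize.brentq(f, lo, hi))


def estimate_cell_efficiencies(
    spike_counts: pd.DataFrame,
    n_s: pd.Series,
    gamma_floor: float = 0.01,
) -> pd.DataFrame:
    """Per-cell efficiency estimates from observed vs expected spike counts.

    Columns of the result:

    - ``eta_hat``: combined efficiency, ratio of sums ``sum_s x_sc / sum_s n_s``.
    - ``w_hat``: within-cell overdispersion slope, the zero-intercept
      regression of squared residuals ``(x - n*eta_hat)^2`` on ``n``, with
      the finite-sample denominator correction for the fitted mean.
    - ``d_hat``, ``d_var``: dropout-rate MLE from the cell's zero pattern
      and its Fisher variance.
    - ``gamma_hat``, ``theta_hat``: the capture/sequencing split. Under the
      model ``w/eta = 1 + gamma - eta`` and ``d/eta = (1-exp(-gamma))/gamma``
      exactly; gamma is taken from the dropout route when the cell has
      informative zeros (bounded, positive), otherwise from the
      overdispersion identity, floored at ``gamma_floor``.
    - ``degenerate``: True when neither route is informative (no zeros and
      near-zero residuals) and the floor was imposed.
    """
    n_s = n_s.reindex(spike_counts.index)
    if n_s.isna().any():
        raise ValueError("spike ids missing from reference")
    n = n_s.to_numpy(dtype=float)
    x = spike_counts.to_numpy(dtype=float)
    if spike_counts.shape[0] < 10 or (
        n.max() / max(n.min(), np.finfo(float).tiny) < 100
    ):
        warnings.warn(
            "fewer than 10 spike-in species or under 2 decades of input "
            "molecule counts; efficiency estimates may be unstable",
            stacklevel=2,
        )
    col_sums = x.sum(axis=0)
    if (col_sums == 0).any():
        bad = spike_counts.columns[col_sums == 0]
        raise ValueError(
            "cells with zero spike-in counts (should be QC-filtered): "
            f"{list(bad)[:5]}"
        )
    sum_n = n.sum()
    eta_hat = col_sums / sum_n
    resid_sq = (x - np.outer(n, eta_hat)) ** 2
    # E[(x_s - n_s*eta_hat)^2] = Var(x_s) * (1 - n_s/sum_n); correct exactly
    denom = (n**2 * (1 - n / sum_n)).sum()
    w_hat = (n[:, None] * resid_sq).sum(axis=0) / denom

    zeros = x == 0
    d_hat, d_var = _dropout_mle(n, zeros)

    n_cells = x.shape[1]
    gamma_hat = np.empty(n_cells)
    theta_hat = np.empty(n_cells)
    degenerate = np.zeros(n_cells, dtype=bool)
    for c in range(n_cells):
        has_zeros = zeros[:, c].any()
        ratio = d_hat[c] / eta_hat[c]
        if has_zeros and 0 < ratio < 1:
            g = _gamma_from_dropout_ratio(ratio)
        else:
            g = w_hat[c] / eta_hat[c] - 1 + eta_hat[c]
            if g < gamma_floor:
                degenerate[c] = True
        g = max(g, gamma_floor)
        t = eta_hat[c] / g
        if t > 1:  # capture efficiency is a probability
            t = 1.0
            g = eta_hat[c]
        gamma_hat[c] = g
        theta_hat[c] = t

    return pd.DataFrame(
        {
            "eta_hat": eta_hat,
            "w_hat": w_hat,
            "d_hat": d_hat,
            "d_var": d_var,
            "gamma_hat": gamma_hat,
            "theta_hat": theta_hat,
            "degenerate": degenerate,
        },
        index=spike_counts.columns,
    )


def technical_coefficients(
    mu_theta: float, var_theta: float, mu_gamma: float, var_gamma: float
) -> dict[str, float]:
    """Derived coefficients (mu_eta, r2_theta, r2_gamma, A, B) from the four
    moment parameters."""
    r2_theta = mu_theta**2 + var_theta
    r2_gamma = mu_gamma**2 + var_gamma
    mu_eta = mu_theta * mu_gamma
    A = mu_theta * mu_gamma + (mu_theta - r2_theta) * r2_gamma
    B = r2_theta * r2_gamma - mu_eta**2
    return {
        "mu_eta": mu_eta,
        "r2_theta": r2_theta,
        "r2_gamma": r2_gamma,
        "A": A,
        "B": B,
    }


class _StatisticPredictor:
    """Exact expectations of the pooled fit statistics under Beta/Gamma
    efficiency laws, including their within-cell sampling contributions."""

    def __init__(self, n_s: np.ndarray, n_quad: int = 24):
        self.n = n_s
        self.k = n_quad
        self.sum_n = n_s.sum()
        self.n_floor = np.floor(n_s)
        self.frac = n_s - self.n_floor
        self.denom_w = (n_s**2 * (1 - n_s / self.sum_n)).sum()

    def __call__(self, params) -> dict[str, float | np.ndarray]:
        mu_t, var_t, mu_g, var_g = params
        if var_t < 1e-12:
            th, wt = np.array([mu_t]), np.array([1.0])
        else:
            th, wt = _quad_nodes(_beta_from_moments(mu_t, var_t), self.k)
        if var_g < 1e-12:
            ga, wg = np.array([mu_g]), np.array([1.0])
        else:
            ga, wg = _quad_nodes(_gamma_from_moments(mu_g, var_g), self.k)
        weight = np.outer(wt, wg).ravel()
        theta = np.repeat(th, len(ga))
        gamma = np.tile(ga, len(th))
        eta = theta * gamma
        q = 1 - theta * (1 - np.exp(-gamma))
        n, n_floor, frac = self.n, self.n_floor, self.frac
        log_q = np.log(np.maximum(q, 1e-300))
        p0 = (1 - frac)[:, None] * np.exp(n_floor[:, None] * log_q[None, :]) + frac[
            :, None
        ] * np.exp((n_floor + 1)[:, None] * log_q[None, :])
        # Var(x_s | theta, gamma): n*eta*(1+gamma-eta) + rounding term
        c1 = eta * (1 + gamma - eta)
        var_x = n[:, None] * c1[None, :] + (frac * (1 - frac))[:, None] * (
            eta**2
        )[None, :]
        dropout = theta * (1 - np.exp(-gamma))

        out: dict[str, float | np.ndarray] = {}
        mu_eta = float((weight * eta).sum())
        out["mu_eta"] = mu_eta
        out["var_eta"] = float(
            (weight * eta**2).sum()
            - mu_eta**2
            + (weight * var_x.sum(axis=0)).sum() / self.sum_n**2
        )
        w_nodes = (
            n[:, None] * var_x * (1 - n / self.sum_n)[:, None]
        ).sum(axis=0) / self.denom_w
        out["mean_w"] = float((weight * w_nodes).sum())
        mu_d = float((weight * dropout).sum())
        out["mu_d"] = mu_d
        out["var_d"] = float((weight * dropout**2).sum() - mu_d**2)
        out["cov_eta_d"] = float((weight * eta * dropout).sum() - mu_eta * mu_d)
        out["p0"] = (weight[None, :] * p0).sum(axis=1)
        return out


def _calibrate_dropout_mle(
    n_s: np.ndarray,
    d_hat: np.ndarray,
    d_var: np.ndarray,
    rng: np.random.Generator,
    n_cells: int = 60,
    n_rep: int = 24,
):
    """Parametric bootstrap of the per-cell dropout MLE.

    Returns (variance ratio relative to the Fisher approximation, mean bias),
    averaged over a subsample of cells at their estimated dropout rates.
    """
    idx = rng.choice(len(d_hat), size=min(n_cells, len(d_hat)), replace=False)
    ratios, biases = [], []
    for c in idx:
        d0 = d_hat[c]
        p0 = np.clip(_p0_mixture(1 - d0, n_s), 1e-12, 1 - 1e-12)
        draws = rng.random((n_rep, len(n_s))) < p0[None, :]
        d_rep, _ = _dropout_mle(n_s, draws.T)
        ratios.append(((d_rep - d0) ** 2).mean() / max(d_var[c], 1e-12))
        biases.append(d_rep.mean() - d0)
    return float(np.mean(ratios)), float(np.mean(biases))


def _sampling_cov_eta_dropout(
    n_s: np.ndarray, eta_hat: np.ndarray, d_hat: np.ndarray
) -> np.ndarray:
    """Within-cell sampling covariance of (eta_hat, d_hat).

    Zeros anti-correlate with count sums: Cov(x_s, 1{x_s=0}) = -E[x_s]*p0_s.
    Propagated through the dropout MLE's influence function.
    """
    n_floor = np.floor(n_s)
    frac = n_s - n_floor
    out = np.empty(len(d_hat))
    for c in range(len(d_hat)):
        q = 1 - d_hat[c]
        p0 = np.clip(_p0_mixture(q, n_s), 1e-12, 1 - 1e-12)
        dp0 = (1 - frac) * n_floor * q ** (n_floor - 1) + frac * (
            n_floor + 1
        ) * q**n_floor
        info = (dp0**2 / (p0 * (1 - p0))).sum()
        influence = (dp0 / (p0 * (1 - p0))) / max(info, 1e-12)
        out[c] = (influence * (-p0 * n_s * eta_hat[c])).sum() / n_s.sum()
    return out


class TechnicalNoiseModel(BaseEstimator):
    """Estimator for the four-parameter technical-noise model.

    Fit on the spike-in rows of a count matrix together with the expected
    input molecule numbers; afterwards predicts the purely technical variance
    of any entity from its mean true abundance.

    Parameters
    ----------
    gamma_floor : float, default 0.01
        Lower bound for the per-cell sequencing-efficiency estimate when
        neither the dropout nor the overdispersion route is informative.
    fit_method : {"matching", "sample_moments"}, default "matching"
        ``"matching"`` fits the four population moments by minimum-distance
        matching of pooled statistics to their exact Beta/Gamma expectations
        (recommended); ``"sample_moments"`` takes sample mean/variance of the
        per-cell estimates (fast, but the variance parameters absorb per-cell
        estimation noise).
    n_quad : int, default 24
        Gauss-Legendre nodes per efficiency dimension for the matching fit.
    random_state : int, default 0
        Seed for the parametric-bootstrap calibration inside the matching
        fit; the fit is deterministic given data and this seed.

    Attributes (after ``fit``)
    --------------------------
    mu_theta_, var_theta_, mu_gamma_, var_gamma_ : float
        The four population moment parameters.
    mu_eta_, r2_theta_, r2_gamma_, A_, B_ : float
        Derived coefficients of the variance decomposition.
    cell_estimates_ : pandas.DataFrame
        Per-cell ``eta_hat``, ``w_hat``, ``d_hat``, ``gamma_hat``,
        ``theta_hat``, ``degenerate``.
    direct_fit_ : dict
        Cross-validation record: (A, B) from a direct zero-intercept
        quadratic regression of per-spike sample variances on (n_s, n_s^2).
    fit_diagnostics_ : dict
        Objective value, fallback flag and calibration constants.
    """

    def __init__(
        self,
        gamma_floor: float = 0.01,
        fit_method: str = "matching",
        n_quad: int = 24,
        random_state: int = 0,
    ):
        self.gamma_floor = gamma_floor
        self.fit_method = fit_method
        self.n_quad = n_quad
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(
        self, matrix: CountMatrix, reference: SpikeInReference
    ) -> "TechnicalNoiseModel":
        """Fit the model from the spike-in rows of ``matrix``.

        The matrix may be raw or batch-normalized; the fitted coefficients
        apply to counts on whichever scale was supplied.
        """
        spikes = matrix.spikeins()
        if spikes.shape[0] == 0:
            raise ValueError("no spike-in rows in matrix")
        if spikes.shape[1] < 3:
            raise ValueError("technical model needs at least 3 cells")
        n_s = reference.aligned_to(spikes.index)
        est = estimate_cell_efficiencies(
            spikes, n_s, gamma_floor=self.gamma_floor
        )
        self.cell_estimates_ = est
        self.n_cells_ = est.shape[0]
        self.fitted_on_raw_ = matrix.raw

        n = n_s.to_numpy(dtype=float)
        x = spikes.to_numpy(dtype=float)
        if self.fit_method == "matching":
            fitted = self._fit_matching(n, x, est)
        elif self.fit_method == "sample_moments":
            fitted = self._fit_sample_moments(est)
        else:
            raise ValueError("fit_method must be 'matching' or 'sample_moments'")
        (
            self.mu_theta_,
            self.var_theta_,
            self.mu_gamma_,
            self.var_gamma_,
        ) = fitted
        self._set_derived()

        # independent check: per-spike cross-cell sample variances regressed
        # on (n_s, n_s^2) with zero intercept
        if x.shape[1] >= 2:
            v_s = x.var(axis=1, ddof=1)
            design = np.column_stack([n, n**2])
            coef, *_ = np.linalg.lstsq(design, v_s, rcond=None)
            self.direct_fit_ = {"A": float(coef[0]), "B": float(coef[1])}
        else:
            self.direct_fit_ = {}
        return self

    def _fit_sample_moments(self, est: pd.DataFrame):
        theta = est["theta_hat"].to_numpy()
        gamma = est["gamma_hat"].to_numpy()
        return (
            float(theta.mean()),
            max(float(theta.var(ddof=1)), 0.0),
            float(gamma.mean()),
            max(float(gamma.var(ddof=1)), 0.0),
        )

    def _fit_matching(self, n: np.ndarray, x: np.ndarray, est: pd.DataFrame):
        n_cells = x.shape[1]
        rng = np.random.default_rng(self.random_state)
        eta_hat = est["eta_hat"].to_numpy()
        w_hat = est["w_hat"].to_numpy()
        d_hat = est["d_hat"].to_numpy()
        d_var = est["d_var"].to_numpy()
        zeros = x == 0
        p0_obs = zeros.mean(axis=1)

        naive = self._fit_sample_moments(est)
        if n_cells < 10 or not zeros.any() or eta_hat.var(ddof=1) == 0:
            # not enough cross-cell structure for the matching fit
            self.fit_diagnostics_ = {"fallback": "sample_moments"}
            return naive

        rho, bias = _calibrate_dropout_mle(n, d_hat, d_var, rng)
        samp_cov = _sampling_cov_eta_dropout(n, eta_hat, d_hat)

        obs = {
            "mu_eta": eta_hat.mean(),
            "var_eta": eta_hat.var(ddof=1),
            "mean_w": w_hat.mean(),
            "mu_d": d_hat.mean() - bias,
            "var_d": d_hat.var(ddof=1) - rho * d_var.mean(),
            "cov_eta_d": np.cov(eta_hat, d_hat)[0, 1] - samp_cov.mean(),
        }
        var_eta_s = eta_hat.var(ddof=1)
        var_d_s = d_hat.var(ddof=1)
        wts = {
            "mu_eta": var_eta_s / n_cells,
            "var_eta": 2 * var_eta_s**2 / (n_cells - 1),
            "mean_w": w_hat.var(ddof=1) / n_cells,
            "mu_d": var_d_s / n_cells,
            "var_d": 2 * var_d_s**2 / (n_cells - 1),
            "cov_eta_d": (var_eta_s * var_d_s + obs["cov_eta_d"] ** 2) / n_cells,
        }
        wts = {k: max(v, 1e-16) for k, v in wts.items()}
        w_p0 = np.maximum(p0_obs * (1 - p0_obs), 1e-4) / n_cells
        # zeros of different spikes share the cell's (theta, gamma): treat
        # the 92-point curve as worth ~8 independent observations
        p0_scale = 8.0 / len(n)

        predictor = _StatisticPredictor(n, self.n_quad)
        keys = list(obs)
        obs_vec = np.array([obs[k] for k in keys])
        wts_vec = np.array([wts[k] for k in keys])

        def objective(log_params):
            params = np.exp(log_params)
            if not np.all(np.isfinite(params)) or params[0] > 0.99:
                return 1e12
            try:
                pred = predictor(params)
            except (ValueError, FloatingPointError):
                return 1e12
            pred_vec = np.array([pred[k] for k in keys])
            if not (
                np.all(np.isfinite(pred_vec)) and np.all(np.isfinite(pred["p0"]))
            ):
                return 1e12
            r = float((((pred_vec - obs_vec) ** 2) / wts_vec).sum())
            r += float(
                (((pred["p0"] - p0_obs) ** 2) / w_p0).sum() * p0_scale
            )
            return r

        mu_t0 = float(np.clip(naive[0], 1e-3, 0.9))
        x0 = np.log(
            [mu_t0, max(naive[1] / 4, 1e-5), max(naive[2], 0.05), 0.05]
        )
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options=dict(maxiter=3000, xatol=1e-6, fatol=1e-10),
        )
        params = np.exp(res.x)
        if not res.success and res.fun >= 1e12:
            self.fit_diagnostics_ = {"fallback": "sample_moments"}
            return naive
        self.fit_diagnostics_ = {
            "fallback": None,
            "objective": float(res.fun),
            "n_iterations": int(res.nit),
            "dropout_var_ratio": rho,
            "dropout_bias": bias,
        }
        return tuple(float(p) for p in params)

    def _set_derived(self) -> None:
        derived = technical_coefficients(
            self.mu_theta_, self.var_theta_, self.mu_gamma_, self.var_gamma_
        )
        self.mu_eta_ = derived["mu_eta"]
        self.r2_theta_ = derived["r2_theta"]
        self.r2_gamma_ = derived["r2_gamma"]
        self.A_ = derived["A"]
        self.B_ = derived["B"]

    # ------------------------------------------------------------------
    def technical_variance(self, mu_m) -> np.ndarray | float:
        """Technical variance ``V_tech(mu) = mu*A + mu^2*B`` on the
        observed-count scale, for an entity with constant true abundance
        ``mu_m`` molecules per cell."""
        self._check_fitted()
        mu = np.asarray(mu_m, dtype=float)
        if np.any(mu < 0):
            raise ValueError("mean molecule count must be nonnegative")
        out = mu * self.A_ + mu**2 * self.B_
        return float(out) if np.isscalar(mu_m) else out

    def predict(self, mu_m) -> np.ndarray | float:
        """Alias for :meth:`technical_variance`."""
        return self.technical_variance(mu_m)

    def predicted_spikein_cv2(
        self, matrix: CountMatrix, reference: SpikeInReference
    ) -> pd.DataFrame:
        """Mean-variance validation table for the spike-ins.

        Per spike: predicted mean ``n_s * mu_eta`` and predicted
        ``CV^2 = V_tech(n_s)/(n_s*mu_eta)^2`` against the observed cross-cell
        sample moments, on the scale the model was fitted on.
        """
        self._check_fitted()
        spikes = matrix.spikeins()
        n_s = reference.aligned_to(spikes.index)
        pred_mean = n_s * self.mu_eta_
        pred_var = self.technical_variance(n_s.to_numpy())
        obs_mean = spikes.mean(axis=1)
        obs_var = spikes.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pred_cv2 = pred_var / pred_mean.to_numpy() ** 2
            obs_cv2 = obs_var / obs_mean**2
        return pd.DataFrame(
            {
                "n_s": n_s,
                "pred_mean": pred_mean,
                "pred_cv2": pred_cv2,
                "obs_mean": obs_mean,
                "obs_cv2": obs_cv2,
            }
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "A_"):
            raise RuntimeError("model is not fitted")

    # -- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "params": self.get_params(),
            "moments": {f: getattr(self, f + "_") for f in MOMENT_FIELDS},
            "direct_fit": self.direct_fit_,
            "fit_diagnostics": getattr(self, "fit_diagnostics_", {}),
            "n_cells": self.n_cells_,
            "fitted_on_raw": self.fitted_on_raw_,
            "cell_estimates": {
                col: self.cell_estimates_[col].tolist()
                for col in self.cell_estimates_.columns
            },
            "cell_ids": list(map(str, self.cell_estimates_.index)),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TechnicalNoiseModel":
        model = cls(**payload.get("params", {}))
        for f in MOMENT_FIELDS:
            setattr(model, f + "_", float(payload["moments"][f]))
        model.direct_fit_ = payload.get("direct_fit", {})
        model.fit_diagnostics_ = payload.get("fit_diagnostics", {})
        model.n_cells_ = int(payload.get("n_cells", 0))
        model.fitted_on_raw_ = bool(payload.get("fitted_on_raw", True))
        cells = payload.get("cell_ids", [])
        model.cell_estimates_ = pd.DataFrame(
            payload.get("cell_estimates", {}), index=pd.Index(cells)
        )
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TechnicalNoiseModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_technical_model(
    matrix: CountMatrix,
    reference: SpikeInReference,
    **kwargs,
) -> TechnicalNoiseModel:
    """Thin functional wrapper over :class:`TechnicalNoiseModel`."""
    return TechnicalNoiseModel(**kwargs).fit(matrix, reference)


def technical_variance(model: TechnicalNoiseModel, mu_m) -> np.ndarray | float:
    return model.technical_variance(mu_m)
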
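"""Errors-in-variables (total-least-squares) Gaussian-process normative model.

The normative relation between gestational age ``t_b`` (weeks) and mean
placental T2* (ms) is learned from a low-risk cohort. Both coordinates are
measured with error: gestational age is only a proxy for biological placental
age (term delivery spans 37-42 weeks, giving an age uncertainty
``sigma_eps = (42 - 37) / (2 * 1.96) ~ 1.3`` weeks), and the mean T2* carries
measurement/segmentation noise ``sigma_delta`` (default 8.7 ms). An ordinary
regression of one coordinate on the other attributes all noise to the
response and produces age-biased residuals; the total-least-squares (TLS)
construction removes that bias.

TLS-GP construction, with the n training pairs as columns of a 2 x n matrix X:

1. demean X with the training means and scale each row by its expected error
   SD, ``Xs = S (X - E[X])`` with ``S = diag(1/sigma_eps, 1/sigma_delta)``, so
   both coordinates have unit expected error;
2. rotate onto the principal axes of the scaled data, ``X' = U^T Xs`` with U
   the left singular vectors of Xs — the first row of X' runs along the
   maturation trend, the second row is the orthogonal deviation;
3. fit a Gaussian process predicting the second row from the first
   (constant mean; kernel = dot product + squared exponential with bounded
   length-scale + white noise; hyperparameters by maximizing the log marginal
   likelihood).

Z-scores of unseen points are computed in the projected space as the GP
posterior-predictive standardized residual of the second coordinate; curves
and credible bands are mapped back to (age, T2*) space through the inverse
projection ``x = E[X] + S^-1 U x'``. The probability of abnormally
accelerated aging marginalizes the Z-score over the input-noise distribution
``N(0, diag(sigma_eps^2, sigma_delta^2))`` by Monte-Carlo sampling and
reports ``P(Z < -3)``.

:class:`OLSGPBaseline` is the conventional alternative (GP regression of age
on mean T2*, all error on age) used to demonstrate the bias the TLS
construction avoids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    ConstantKernel,
    DotProduct,
    WhiteKernel,
)

__all__ = [
    "NoiseModel",
    "TLSGPNormativeModel",
    "OLSGPBaseline",
    "estimate_sigma_eps",
    "estimate_sigma_delta_bins",
    "split_cohort",
    "InfeasibleBinningError",
]

DEFAULT_SIGMA_EPS = 1.3  # weeks
DEFAULT_SIGMA_DELTA = 8.7  # ms
Z_ABNORMAL = -3.0


class InfeasibleBinningError(ValueError):
    """Not enough data to form the requested age bins."""


@dataclass(frozen=True)
class NoiseModel:
    """Expected measurement-error SDs of the two coordinates."""

    sigma_eps: float = DEFAULT_SIGMA_EPS  # weeks, error of gestational age
    sigma_delta: float = DEFAULT_SIGMA_DELTA  # ms, error of mean T2*

    def validate(self) -> None:
        if not (self.sigma_eps > 0 and self.sigma_delta > 0):
            raise ValueError("noise SDs must be positive")


def estimate_sigma_eps(term_lo: float = 37.0, term_hi: float = 42.0) -> float:
    """Age-uncertainty SD from the normal full-term delivery window.

    Treats the term window as a 95% interval of biological age at delivery:
    ``(term_hi - term_lo) / (2 * 1.96)``; the default window 37-42 weeks gives
    about 1.3 weeks.
    """
    if not term_hi > term_lo:
        raise ValueError("term_hi must exceed term_lo")
    return (term_hi - term_lo) / (2.0 * 1.96)


def estimate_sigma_delta_bins(
    ga_weeks,
    t2s_mean,
    sigma_eps: float = DEFAULT_SIGMA_EPS,
    min_per_bin: int = 4,
    n_bins: int = 4,
) -> float:
    """Estimate the mean-T2* error SD by pooling narrow age bins.

    Scans candidate bin centres from low to high gestational age and greedily
    accepts disjoint windows of half-width ``sigma_eps`` containing at least
    ``min_per_bin`` measurements; the estimate is the arithmetic mean of the
    per-bin sample SDs of mean T2*. Within a +/- 1 sigma_eps window the
    normative trend is nearly flat, so the within-bin spread is dominated by
    measurement noise.
    """
    ga = np.asarray(ga_weeks, dtype=float)
    t2 = np.asarray(t2s_mean, dtype=float)
    if ga.shape != t2.shape or ga.ndim != 1:
        raise ValueError("ga_weeks and t2s_mean must be equal-length 1D vectors")
    centres = np.arange(ga.min(), ga.max() + 1e-9, sigma_eps / 10.0)
    sds: list[float] = []
    last_centre = -np.inf
    for c in centres:
        if c - last_centre < 2.0 * sigma_eps:
            continue
        members = np.abs(ga - c) <= sigma_eps
        if members.sum() >= min_per_bin:
            sds.append(float(np.std(t2[members], ddof=1)))
            last_centre = c
            if len(sds) == n_bins:
                break
    if len(sds) < n_bins:
        raise InfeasibleBinningError(
            f"only {len(sds)} of {n_bins} bins with >= {min_per_bin} points within "
            f"+/-{sigma_eps:.2f} weeks are achievable (per-bin SDs so far: {sds})"
        )
    return float(np.mean(sds))


def split_cohort(cohort: pd.DataFrame, ratio=(7, 3), seed: int = 0):
    """Split a cohort table into normative-train and test sets.

    Only low-risk subjects are eligible for training (the normative model must
    see normal maturation only); they are shuffled and divided in
    ``ratio[0] : ratio[1]``. All high-risk subjects go to the test set.
    Deterministic per seed; returns ``(train, test)`` DataFrames whose union
    is the input.
    """
    if ratio[0] <= 0 or ratio[1] <= 0:
        raise ValueError("split ratio parts must be positive")
    if len(cohort) < 10:
        raise ValueError("need at least 10 subjects to split")
    low = cohort[cohort["group"] == "low_risk"]
    high = cohort[cohort["group"] != "low_risk"]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(low))
    n_train = int(round(len(low) * ratio[0] / (ratio[0] + ratio[1])))
    train = low.iloc[perm[:n_train]].copy()
    test = pd.concat([low.iloc[perm[n_train:]], high]).copy()
    train["split"] = "train"
    test["split"] = "test"
    return train, test


def _as_pairs(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("expected (n, 2) array with columns [age_weeks, mean_t2s]")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in input")
    return X


def _make_kernel(input_sd: float, length_scale_max_factor: float):
    # The length-scale is bounded above by ~1 SD of the input coordinate (the
    # squared-exponential term models *local* deviation from the linear
    # trend) and below by 0.2 SD: shorter scales fall under the typical
    # training-point spacing, where the RBF merely duplicates the white-noise
    # kernel and injects spurious wiggles into the normative curve.
    ls_hi = max(length_scale_max_factor * input_sd, 1e-8)
    ls_lo = min(0.2 * input_sd, ls_hi / 2.0)
    return (
        DotProduct(sigma_0=1.0, sigma_0_bounds=(1e-3, 1e3))
        + ConstantKernel(1.0, (1e-3, 1e3))
        * RBF(length_scale=np.sqrt(ls_lo * ls_hi), length_scale_bounds=(ls_lo, ls_hi))
        + WhiteKernel(noise_level=0.1, noise_level_bounds=(1e-6, 1e1))
    )


class TLSGPNormativeModel(BaseEstimator):
    """Normative (GA, mean T2*) model with errors in both variables.

    Parameters
    ----------
    sigma_eps, sigma_delta : expected error SDs of age (weeks) and mean T2*
        (ms) used for the TLS scaling and for the Monte-Carlo noise
        integration.
    length_scale_max_factor : upper bound of the squared-exponential
        length-scale as a multiple of the SD of the GP input coordinate.
    n_restarts : restarts of the marginal-likelihood optimizer.
    random_state : seeds the GP optimizer restarts.

    Fitted attributes: ``mean_`` (training means), ``scale_`` (error SDs as a
    length-2 vector; ``S = diag(1/scale_)``), ``rotation_`` (the 2x2 U),
    ``gp_`` (the fitted GP), ``train_proj_`` (projected training data).
    """

    def __init__(
        self,
        sigma_eps: float = DEFAULT_SIGMA_EPS,
        sigma_delta: float = DEFAULT_SIGMA_DELTA,
        length_scale_max_factor: float = 1.0,
        n_restarts: int = 5,
        random_state: int = 0,
    ):
        self.sigma_eps = sigma_eps
        self.sigma_delta = sigma_delta
        self.length_scale_max_factor = length_scale_max_factor
        self.n_restarts = n_restarts
        self.random_state = random_state

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(self.sigma_eps, self.sigma_delta)

    # -- projection algebra --------------------------------------------------

    def fit(self, X, y=None):
        """Fit on low-risk (age, mean T2*) pairs; X is (n, 2)."""
        self.noise.validate()
        X = _as_pairs(X)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training pairs")
        if np.ptp(X[:, 0]) == 0 or np.ptp(X[:, 1]) == 0:
            raise ValueError("degenerate training data: zero variance in a coordinate")
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.array([self.sigma_eps, self.sigma_delta], dtype=float)
        Xs = (X - self.mean_) / self.scale_  # rows are scaled, demeaned samples
        # right singular vectors of the n x 2 sample matrix = left singular
        # vectors of its 2 x n transpose (the data-as-columns convention)
        _, _, Vt = np.linalg.svd(Xs, full_matrices=False)
        U = Vt.T
        # deterministic sign convention: maturation axis has positive age
        # component, the orthogonal axis positive T2* component
        if U[0, 0] < 0:
            U[:, 0] = -U[:, 0]
        if U[1, 1] < 0:
            U[:, 1] = -U[:, 1]
        self.rotation_ = U
        self.train_proj_ = Xs @ U

        t = self.train_proj_[:, 0]
        kernel = _make_kernel(float(t.std()), self.length_scale_max_factor)
        self.gp_ = GaussianProcessRegressor(
            kernel=kernel,
            n_restarts_optimizer=self.n_restarts,
            normalize_y=True,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign bound-hit notices
            self.gp_.fit(t[:, None], self.train_proj_[:, 1])
        return self

    def transform(self, X) -> np.ndarray:
        """Project (age, T2*) pairs into the scaled, rotated TLS space."""
        self._check_fitted()
        X = _as_pairs(X)
        return ((X - self.mean_) / self.scale_) @ self.rotation_

    def inverse_transform(self, Xp) -> np.ndarray:
        """Map projected coordinates back to (age, T2*) space."""
        self._check_fitted()
        Xp = np.asarray(Xp, dtype=float)
        return (Xp @ self.rotation_.T) * self.scale_ + self.mean_

    # -- scoring -------------------------------------------------------------

    def z_score(self, X) -> np.ndarray:
        """Posterior-predictive Z-score of each (age, mean T2*) pair.

        The observed second projected coordinate is compared with the GP
        posterior predictive distribution at the first projected coordinate;
        the denominator is the full predictive SD (latent + fitted white
        noise), so normative data score approximately standard normal.
        """
        proj = self.transform(X)
        m, s = self.gp_.predict(proj[:, :1], return_std=True)
        return (proj[:, 1] - m) / s

    def predict_curve(self, query_ages, z_levels=(1.96, 3.0)) -> pd.DataFrame:
        """Normative curve and credible bands in (age, T2*) space.

        Evaluates the GP along the maturation axis, forms bands at
        ``mean +/- z * predictive SD`` in projected space (z = 1.96 and 3
        delimit the central 95% and 99.7% of a normal predictive
        distribution), back-projects every curve and interpolates each at the
        query ages. Queries outside the training age range trigger a warning.
        """
        self._check_fitted()
        ages = np.atleast_1d(np.asarray(query_ages, dtype=float))
        t_tr = self.train_proj_[:, 0]
        span = t_tr.max() - t_tr.min()
        grid = np.linspace(t_tr.min() - 0.25 * span, t_tr.max() + 0.25 * span, 512)
        m, s = self.gp_.predict(grid[:, None], return_std=True)

        train_ages = self.inverse_transform(self.train_proj_)[:, 0]
        if ages.min() < train_ages.min() - 1 or ages.max() > train_ages.max() + 1:
            warnings.warn(
                "query ages extend beyond the training age range; "
                "extrapolated normative values are unreliable",
                stacklevel=2,
            )

        out = {"age": ages}
        curves = {"mean": m}
        for z in z_levels:
            curves[f"lower_{z:g}"] = m - z * s
            curves[f"upper_{z:g}"] = m + z * s
        for name, y2 in curves.items():
            back = self.inverse_transform(np.column_stack([grid, y2]))
            order = np.argsort(back[:, 0])
            out[name] = np.interp(ages, back[order, 0], back[order, 1])
        return pd.DataFrame(out)

    def prob_accelerated_aging(
        self,
        X,
        n_samples: int = 10000,
        z_threshold: float = Z_ABNORMAL,
        random_state: int | None = None,
        noise: NoiseModel | None = None,
    ) -> np.ndarray:
        """Probability that each subject's placenta is abnormally aged.

        Marginalizes the Z-score over the measurement-noise distribution
        ``N(0, diag(sigma_eps^2, sigma_delta^2))`` with ``n_samples`` i.i.d.
        Monte-Carlo draws and returns the fraction with
        ``Z < z_threshold`` (default -3). Deterministic per ``random_state``.
        Pass a zero-noise ``NoiseModel``-like object to recover the indicator
        of the observed Z-score.
        """
        self._check_fitted()
        X = _as_pairs(X)
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        nz = noise if noise is not None else self.noise
        rng = np.random.default_rng(random_state)
        sds = np.array([nz.sigma_eps, nz.sigma_delta], dtype=float)
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            pert = row[None, :] + rng.standard_normal((n_samples, 2)) * sds
            z = self.z_score(pert)
            out[i] = float(np.mean(z < z_threshold))
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "gp_"):
            raise RuntimeError("model is not fitted")


class OLSGPBaseline(BaseEstimator):
    """Conventional GP regression of age on mean T2* (all error on age).

    Same kernel family as the TLS model; the Z-score is the standardized age
    residual ``(observed age - predicted age) / predictive SD``, so a placenta
    that looks older than it is (low T2* for age) scores negative. The
    accelerated-aging probability uses the same Monte-Carlo noise integration
    as the TLS model for a like-for-like comparison.
    """

    def __init__(
        self,
        sigma_eps: float = DEFAULT_SIGMA_EPS,
        sigma_delta: float = DEFAULT_SIGMA_DELTA,
        length_scale_max_factor: float = 1.0,
        n_restarts: int = 5,
        random_state: int = 0,
    ):
        self.sigma_eps = sigma_eps
        self.sigma_delta = sigma_delta
        self.length_scale_max_factor = length_scale_max_factor
        self.n_restarts = n_restarts
        self.random_state = random_state

    @property
    def noise(self) -> NoiseModel:
        return NoiseModel(self.sigma_eps, self.sigma_delta)

    def fit(self, X, y=None):
        X = _as_pairs(X)
        if X.shape[0] < 3:
            raise ValueError("need at least 3 training pairs")
        if np.ptp(X[:, 1]) == 0:
            raise ValueError("degenerate training data: zero variance in mean T2*")
        t2s = X[:, 1]
        kernel = _make_kernel(float(t2s.std()), self.length_scale_max_factor)
        self.gp_ = GaussianProcessRegressor(
            kernel=kernel,
            n_restarts_optimizer=self.n_restarts,
            normalize_y=True,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.gp_.fit(t2s[:, None], X[:, 0])
        return self

    def predict(self, t2s_mean) -> np.ndarray:
        """Predicted age (weeks) for given mean T2* values."""
        t2s = np.atleast_1d(np.asarray(t2s_mean, dtype=float))
        return self.gp_.predict(t2s[:, None])

    def z_score(self, X) -> np.ndarray:
        X = _as_pairs(X)
        m, s = self.gp_.predict(X[:, 1:2], return_std=True)
        return (X[:, 0] - m) / s

    def prob_accelerated_aging(
        self,
        X,
        n_samples: int = 10000,
        z_threshold: float = Z_ABNORMAL,
        random_state: int | None = None,
        noise: NoiseModel | None = None,
    ) -> np.ndarray:
        X = _as_pairs(X)
        nz = noise if noise is not None else self.noise
        rng = np.random.default_rng(random_state)
        sds = np.array([nz.sigma_eps, nz.sigma_delta], dtype=float)
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            pert = row[None, :] + rng.standard_normal((n_samples, 2)) * sds
            z = self.z_score(pert)
            out[i] = float(np.mean(z < z_threshold))
        return out
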
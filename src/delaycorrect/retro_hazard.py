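r"""Nonparametric estimation of the delay cdf from right-truncated data.

Let :math:`T` be the delay to diagnosis (whole days) and :math:`\tau_i` the
truncation horizon of unit *i*. Only units with :math:`t_i \le \tau_i` are
registered. The reverse-time (retro) hazard

.. math:: \rho(u) = f(u) / F(u)

is the same in the marginal and the right-truncated distribution of
:math:`T`, which makes it estimable from truncated data alone. With event
counts :math:`D^*_u = \#\{i : t_i = u\}` and backward risk sets
:math:`R^*_u = \#\{i : t_i \le u \le \tau_i\}`, the maximum-likelihood
estimate is :math:`\hat\rho(u) = D^*_u / R^*_u`, and the identifiable part of
the cdf is the product-limit estimator in reverse time

.. math:: \hat F_T(t \mid \tau^*) = \prod_{u=t+1}^{\tau^*} (1 - \hat\rho(u)),

where :math:`\tau^* = \max_i \tau_i`. Only :math:`F(t)/F(\tau^*)` is
identifiable; the unobservable upper-tail mass :math:`\theta = 1 - F(\tau^*)`
is carried as a parameter and applied by the Horvitz-Thompson module.

A Greenwood-type variance for :math:`\hat F_t` and the delta-method variance
of the inverse-probability weight :math:`1/\hat F_t` are provided, together
with bootstrap quantile intervals, the truncated log-likelihood, and
stratified fits.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._exceptions import (
    ConfigurationError,
    DataError,
    InfiniteWeightError,
    UndefinedVarianceError,
)
from .registry_io import TruncatedDelaySample

__all__ = [
    "RetroHazardEstimator",
    "fit_retro_hazard",
    "greenwood_variance",
    "weight_variance",
    "truncated_loglik",
    "delay_quantiles",
    "fit_stratified",
]


def _as_arrays(X, sample_weight=None):
    """Coerce input to integer (t, tau, n) arrays."""
    if isinstance(X, TruncatedDelaySample):
        return X.t, X.tau, X.n
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ConfigurationError(
            "X must be a TruncatedDelaySample or an (n, 2) array of [delay, horizon]"
        )
    t = X[:, 0].astype(np.int64)
    tau = X[:, 1].astype(np.int64)
    if sample_weight is None:
        n = np.ones_like(t)
    else:
        n = np.asarray(sample_weight, dtype=np.int64)
    return t, tau, n


def _count_arrays(t, tau, n, tau_star):
    """Event counts D*_u and backward risk counts R*_u on u = 0..tau_star.

    R*_u = #{i : t_i <= u <= tau_i} = #{t_i <= u} - #{tau_i < u}, computed via
    cumulative sums of the two bincounts.
    """
    D = np.bincount(t, weights=n, minlength=tau_star + 1)
    started = np.cumsum(D)  # #{t_i <= u}
    ended = np.cumsum(np.bincount(tau, weights=n, minlength=tau_star + 1))  # #{tau_i <= u}
    R = started.copy()
    R[1:] -= ended[:-1]  # subtract #{tau_i < u}
    return D, R


def _product_limit(D, R):
    """Hazard, cdf and Greenwood cumulants from counts on u = 0..tau_star."""
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(R > 0, D / np.where(R > 0, R, 1), 0.0)
    rho[0] = 0.0  # grid starts at u = 1; delay 0 is the cdf origin
    one_minus = 1.0 - rho[1:]
    # F[t] = prod_{u=t+1..tau*}(1 - rho_u); reversed cumulative product.
    if len(one_minus):
        tail = np.cumprod(one_minus[::-1])[::-1]
        F = np.concatenate([tail, [1.0]])
    else:
        F = np.ones(1)
    # Greenwood summand D/(R(R-D)); undefined (NaN) where R == D > 0.
    terms = np.zeros_like(rho)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = R * (R - D)
        vals = np.where(denom > 0, D / np.where(denom > 0, denom, 1), np.nan)
    terms[1:] = np.where(D[1:] > 0, vals[1:], 0.0)
    # gcum[t] = sum_{u=t+1..tau*} terms[u]
    gcum = np.concatenate([np.cumsum(terms[1:][::-1])[::-1], [0.0]])
    return rho, F, gcum


class RetroHazardEstimator(BaseEstimator):
    """Reverse-time-hazard product-limit estimator of a right-truncated cdf.

    Parameters
    ----------
    bin_width : int, default 1
        Grid granularity in days. Delays and horizons are floored to bins of
        this width before estimation; the default daily grid matches
        day-denominated registry data.
    theta : float, default 0.0
        Unidentifiable upper-tail mass ``1 - F(tau*)``. Stored here, applied
        only when weighting (``(1-theta) * F(t|tau*)``); 0 is appropriate for
        cohorts observed long enough.

    Attributes
    ----------
    grid_ : ndarray
        Estimation grid ``u = 1..tau_star_`` (bin units; days by default).
    event_counts_, risk_counts_ : ndarray
        ``D*_u`` and ``R*_u`` on the grid.
    hazard_ : ndarray
        ``rho_u = D*_u / R*_u`` (0 where the risk set is empty).
    cdf_ : ndarray
        ``F(t | tau*)`` for ``t = 0..tau_star_``.
    cdf_variance_ : ndarray
        Greenwood variance of ``cdf_``; NaN where undefined.
    tau_star_ : int
        Largest horizon on the bin grid.
    n_units_ : int
        Units counting multiplicities.
    identifiable_floor_ : int
        Smallest ``t`` with positive estimated cdf.
    """

    def __init__(self, bin_width: int = 1, theta: float = 0.0):
        self.bin_width = bin_width
        self.theta = theta

    def fit(self, X, y=None, sample_weight=None) -> "RetroHazardEstimator":
        """Fit from a :class:`TruncatedDelaySample` or an ``(n, 2)`` array."""
        if not (isinstance(self.bin_width, (int, np.integer)) and self.bin_width >= 1):
            raise ConfigurationError("bin_width must be a positive integer")
        if not 0.0 <= self.theta < 1.0:
            raise ConfigurationError("theta must lie in [0, 1)")
        t, tau, n = _as_arrays(X, sample_weight)
        if len(t) == 0:
            raise DataError("cannot fit a retro hazard on an empty sample")
        t = t // self.bin_width
        tau = tau // self.bin_width
        if np.any(t > tau):  # can only happen through inconsistent binning input
            raise DataError("binning produced a delay beyond its horizon")
        self.sample_t_, self.sample_tau_, self.sample_n_ = t, tau, n
        tau_star = int(tau.max())
        D, R = _count_arrays(t, tau, n, tau_star)
        self._finalize(D, R)
        return self

    def _finalize(self, D, R) -> None:
        tau_star = len(D) - 1
        rho, F, gcum = _product_limit(D, R)
        self.tau_star_ = tau_star
        self.grid_ = np.arange(1, tau_star + 1)
        self.event_counts_ = D[1:]
        self.risk_counts_ = R[1:]
        self.hazard_ = rho[1:]
        self.cdf_ = F
        self._gcum = gcum
        with np.errstate(invalid="ignore"):
            self.cdf_variance_ = F**2 * gcum
        self.n_units_ = int(D.sum())
        positive = np.flatnonzero(F > 0)
        self.identifiable_floor_ = int(positive[0]) if len(positive) else tau_star

    @classmethod
    def from_counts(
        cls, event_counts, risk_counts, bin_width: int = 1, theta: float = 0.0
    ) -> "RetroHazardEstimator":
        """Rebuild an estimate from stored ``D*_u``, ``R*_u`` on ``u = 1..tau*``.

        Used to reload serialized fits; bootstrap resampling is unavailable on
        such an object because unit-level data are not retained.
        """
        est = cls(bin_width=bin_width, theta=theta)
        D = np.concatenate([[0], np.asarray(event_counts, dtype=float)])
        R = np.concatenate([[0], np.asarray(risk_counts, dtype=float)])
        est._finalize(D, R)
        return est

    # -- lookups -----------------------------------------------------------

    def _to_bins(self, times) -> np.ndarray:
        return np.asarray(times, dtype=np.int64) // self.bin_width

    def cdf_at(self, times) -> np.ndarray:
        """Evaluate ``F(t | tau*)`` at day values; 0 below 0, 1 beyond tau*."""
        scalar = np.isscalar(times)
        b = np.atleast_1d(self._to_bins(times))
        out = np.empty(b.shape, dtype=float)
        below = b < 0
        above = b > self.tau_star_
        inside = ~(below | above)
        out[below] = 0.0
        out[above] = 1.0
        out[inside] = self.cdf_[b[inside]]
        return float(out[0]) if scalar else out

    def _gcum_at(self, times) -> np.ndarray:
        """Greenwood cumulant at day values; 0 beyond tau* (no mass there)."""
        b = np.clip(np.atleast_1d(self._to_bins(times)), 0, self.tau_star_)
        return self._gcum[b]

    def to_frame(self) -> pd.DataFrame:
        """Grid-level summary (columns u, D, R, rho, F, var_F)."""
        return pd.DataFrame(
            {
                "u": self.grid_ * self.bin_width,
                "D": self.event_counts_,
                "R": self.risk_counts_,
                "rho": self.hazard_,
                "F": self.cdf_[1:],
                "var_F": self.cdf_variance_[1:],
            }
        )


def fit_retro_hazard(
    sample: TruncatedDelaySample, bin_width: int = 1, theta: float = 0.0
) -> RetroHazardEstimator:
    """Fit the reverse-time-hazard cdf estimator on a truncated sample."""
    return RetroHazardEstimator(bin_width=bin_width, theta=theta).fit(sample)


def _check_time(est: RetroHazardEstimator, t: int) -> int:
    tb = int(t) // est.bin_width
    if not 0 <= tb <= est.tau_star_:
        raise ConfigurationError(f"t={t} outside the estimated grid [0, {est.tau_star_}]")
    return tb


def _offending_units(est: RetroHazardEstimator, tb: int) -> np.ndarray:
    D, R = est.event_counts_, est.risk_counts_
    bad = (D > 0) & (R == D) & (est.grid_ > tb)
    return est.grid_[bad]


def greenwood_variance(est: RetroHazardEstimator, t: int) -> float:
    r"""Greenwood variance of :math:`\hat F_t`:
    :math:`(\hat F_t)^2 \sum_{u>t} D^*_u / (R^*_u (R^*_u - D^*_u))`.

    Grid points without events contribute nothing; a point with
    ``R*_u == D*_u > 0`` strictly above ``t`` makes the variance undefined.
    """
    tb = _check_time(est, t)
    g = est._gcum[tb]
    if np.isnan(g):
        bad = _offending_units(est, tb)
        raise UndefinedVarianceError(
            f"variance undefined: risk set exhausted (R*_u == D*_u > 0) at u={bad.tolist()}"
        )
    return float(est.cdf_[tb] ** 2 * g)


def weight_variance(est: RetroHazardEstimator, t: int) -> float:
    r"""Delta-method variance of the HT weight :math:`1/\hat F_t`:
    :math:`\sum_{u>t} D^*_u/(R^*_u(R^*_u - D^*_u)) \,/\, (\hat F_t)^2`.

    Equals ``greenwood_variance / F_t**4`` wherever both are defined.
    """
    tb = _check_time(est, t)
    if est.cdf_[tb] <= 0.0:
        raise InfiniteWeightError(
            f"F({t}) = 0: the weight 1/F is infinite and its variance undefined"
        )
    g = est._gcum[tb]
    if np.isnan(g):
        bad = _offending_units(est, tb)
        raise UndefinedVarianceError(
            f"variance undefined: risk set exhausted (R*_u == D*_u > 0) at u={bad.tolist()}"
        )
    return float(g / est.cdf_[tb] ** 2)


def truncated_loglik(est: RetroHazardEstimator, rho) -> float:
    r"""Truncated log-likelihood at an arbitrary hazard sequence.

    :math:`\ell(\rho) = \sum_u [D^*_u \log \rho(u) + (R^*_u - D^*_u)
    \log(1-\rho(u))]` with the convention :math:`0 \log 0 = 0`. Returns
    ``-inf`` when a zero (or one) hazard faces a nonzero opposing count.
    """
    rho = np.asarray(rho, dtype=float)
    if rho.shape != est.grid_.shape:
        raise ConfigurationError(
            f"rho must be given on the grid u=1..{est.tau_star_} ({est.grid_.size} values)"
        )
    if np.any((rho < 0) | (rho > 1)):
        raise ConfigurationError("rho values must lie in [0, 1]")
    D = est.event_counts_
    S = est.risk_counts_ - D
    if np.any((D > 0) & (rho == 0.0)) or np.any((S > 0) & (rho == 1.0)):
        return float("-inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        term_d = np.where(D > 0, D * np.log(np.where(rho > 0, rho, 1.0)), 0.0)
        term_s = np.where(S > 0, S * np.log(np.where(rho < 1, 1.0 - rho, 1.0)), 0.0)
    return float(np.sum(term_d + term_s))


def _quantile_from_cdf(F: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Smallest t with F(t) >= p, per probability."""
    return np.searchsorted(F, probs, side="left")


def delay_quantiles(
    est: RetroHazardEstimator,
    probs: Sequence[float] = (0.25, 0.5, 0.75),
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Quantiles of the identifiable delay cdf with bootstrap intervals.

    The point estimate at probability *p* is the smallest ``t`` with
    ``F(t | tau*) >= p``. Intervals come from a nonparametric bootstrap of
    units (resampling ``(t_i, tau_i)`` pairs, refitting, re-extracting), with
    the percentile method. Probabilities below the cdf value at the
    identifiable floor are flagged non-identifiable: the truncated sample
    carries no information on quantiles below the smallest observed delay.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any((probs <= 0) | (probs >= 1)):
        raise ConfigurationError("probs must lie strictly inside (0, 1)")
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    if not hasattr(est, "sample_t_"):
        raise ConfigurationError("bootstrap quantiles need a fit with unit-level data")
    points = _quantile_from_cdf(est.cdf_, probs) * est.bin_width
    floor_value = est.cdf_[est.identifiable_floor_]
    identifiable = probs >= floor_value - 1e-12

    t_units = np.repeat(est.sample_t_, est.sample_n_)
    tau_units = np.repeat(est.sample_tau_, est.sample_n_)
    m = len(t_units)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, probs.size))
    for b in range(n_boot):
        idx = rng.integers(0, m, size=m)
        tb, taub = t_units[idx], tau_units[idx]
        ts = int(taub.max())
        D, R = _count_arrays(tb, taub, np.ones_like(tb), ts)
        _, F, _ = _product_limit(D, R)
        boot[b] = _quantile_from_cdf(F, probs)
    boot *= est.bin_width
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return pd.DataFrame(
        {
            "prob": probs,
            "point": points,
            "ci_low": lo,
            "ci_high": hi,
            "identifiable": identifiable,
        }
    )


def fit_stratified(
    sample: TruncatedDelaySample,
    labels=None,
    min_stratum_size: int = 20,
    bin_width: int = 1,
) -> Mapping[str, RetroHazardEstimator]:
    """Independent retro-hazard fits per stratum.

    ``labels`` defaults to the sample's own ``stratum`` field; every unit must
    be labelled. Strata smaller (in units) than ``min_stratum_size`` trigger a
    warning but are still fitted.
    """
    if labels is None:
        labels = sample.stratum
    if labels is None:
        raise ConfigurationError("no stratum labels on the sample and none supplied")
    labels = np.asarray(labels, dtype=object)
    if labels.shape != sample.t.shape:
        raise ConfigurationError("labels must match the sample in length")
    if any(lab is None or (isinstance(lab, float) and np.isnan(lab)) for lab in labels):
        raise ConfigurationError("every unit must carry a stratum label")
    fits: dict[str, RetroHazardEstimator] = {}
    for lab in pd.unique(labels):
        sub = sample.subset(labels == lab)
        if len(sub) == 0:  # defensive; pd.unique only yields present labels
            warnings.warn(f"stratum {lab!r} is empty and was omitted", stacklevel=2)
            continue
        if sub.n_total < min_stratum_size:
            warnings.warn(
                f"stratum {lab!r} has only {sub.n_total} units; estimate will be unstable",
                stacklevel=2,
            )
        fits[lab] = fit_retro_hazard(sub, bin_width=bin_width)
    return fits
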
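r"""Horvitz-Thompson correction of registry incidence for reporting delay.

A case with onset at :math:`x_i` is registered only if diagnosed by the
archive closure :math:`t_{end}`, which happens with probability
:math:`1-p_{0i} = \Pr(t_i \le t_{end} - x_i) = F(\tau_i)`. Weighting each
registered case by the inverse of this probability yields the
Horvitz-Thompson estimate of the true incident count,

.. math:: \hat N = \Big\lfloor \sum_i n_i / (1-\hat p_{0i}) \Big\rfloor,
          \qquad 1-\hat p_{0i} = (1-\theta)\,\hat F(a_i \mid \tau^*),

with :math:`\hat F` projected from an older, longer-observed onset cohort.
Two weighting-time conventions are supported: ``weight_mode='horizon'``
evaluates the cdf at the unit's truncation horizon :math:`a_i=\tau_i`
(the registration-probability derivation above), while ``'delay'`` evaluates
it at the observed delay :math:`a_i=t_i`. Both are first class; the package
logs when they disagree materially.

The corrected incidence rate is :math:`\hat I = \sum_i \hat W_i / S` on a
person-years denominator *S*, with a marginal-variance decomposition

.. math:: \widehat{var}(\hat I) = \frac{1}{S^2}\sum_i var(\hat W_i)
          \;+\; \bar W^2 \frac{D}{S^2},

where the first term propagates the uncertainty of the fitted cdf
(delta-method variance of each weight) and the second is the crude-count
(Poisson-type) term scaled by the squared mean weight
:math:`\bar W = \sum_i \hat W_i / D`. With all weights 1 it reduces to the
standard crude-rate variance :math:`D/S^2`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._exceptions import ConfigurationError, DataError, InfiniteWeightError
from .registry_io import TruncatedDelaySample
from .retro_hazard import RetroHazardEstimator, _as_arrays, fit_retro_hazard, weight_variance

__all__ = [
    "HTCorrection",
    "IncidenceEstimate",
    "BacktestResult",
    "HTIncidenceEstimator",
    "registration_probability",
    "ht_count",
    "incidence_rate",
    "incidence_variance",
    "backtest_robustness",
]

logger = logging.getLogger(__name__)

#: Reference cdf: a fitted estimator, or a known cdf as a vectorized callable.
ReferenceCdf = Union[RetroHazardEstimator, Callable[[np.ndarray], np.ndarray]]

#: Relative discrepancy between the two weighting modes worth logging.
_MODE_DISCREPANCY_TOL = 0.05


@dataclass
class HTCorrection:
    """Per-unit HT weights and the corrected count."""

    weights: np.ndarray
    registration_probs: np.ndarray
    eval_times: np.ndarray
    multiplicities: np.ndarray
    n_hat: int
    n_observed: int
    theta: float
    weight_mode: str

    @property
    def weight_sum(self) -> float:
        """Unfloored HT total ``sum n_i W_i`` (``n_hat`` is its integer part)."""
        return float(np.sum(self.multiplicities * self.weights))


@dataclass
class IncidenceEstimate:
    """Incidence rate per ``scale`` person-years, with optional CI."""

    rate: float
    person_years: float
    scale: float
    corrected_count: float
    crude_rate: float | None = None
    variance: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float | None = None

    def rounded(self, ndigits: int = 2) -> float:
        """Rate at reporting precision (stored values stay full precision)."""
        return round(self.rate, ndigits)


@dataclass
class BacktestResult:
    """Early-window HT estimate vs the count eventually observed."""

    estimated: int
    observed: int
    n_early: int
    early_t_end: pd.Timestamp
    late_t_end: pd.Timestamp


def _cdf_values(reference: ReferenceCdf, times: np.ndarray) -> np.ndarray:
    if isinstance(reference, RetroHazardEstimator):
        beyond = np.asarray(times) > reference.tau_star_ * reference.bin_width
        if beyond.any():
            logger.info(
                "%d target unit(s) beyond the reference tau*=%d; cdf capped at 1",
                int(beyond.sum()),
                reference.tau_star_ * reference.bin_width,
            )
        return np.atleast_1d(reference.cdf_at(times))
    vals = np.asarray(reference(np.asarray(times)), dtype=float)
    return np.clip(np.atleast_1d(vals), 0.0, 1.0)


def registration_probability(
    reference_fit: ReferenceCdf,
    target_sample: TruncatedDelaySample,
    theta: float = 0.0,
    weight_mode: str = "horizon",
) -> np.ndarray:
    """Per-unit probability of being registered by the archive closure.

    Returns ``(1 - theta) * F(a_i | tau*)`` where ``a_i`` is the truncation
    horizon (``weight_mode='horizon'``) or the observed delay (``'delay'``).
    Times beyond the reference support get cdf 1. A zero probability raises
    :class:`InfiniteWeightError` naming the unit.
    """
    if not 0.0 <= theta < 1.0:
        raise ConfigurationError("theta must lie in [0, 1)")
    if weight_mode not in ("horizon", "delay"):
        raise ConfigurationError("weight_mode must be 'horizon' or 'delay'")
    a = target_sample.tau if weight_mode == "horizon" else target_sample.t
    base = _cdf_values(reference_fit, a)
    if np.any(base <= 0.0):
        bad = int(np.argmax(base <= 0.0))
        raise InfiniteWeightError(
            f"registration probability 0 for unit {bad} "
            f"(weighting time {int(a[bad])} d below the reference identifiable range); "
            "exclude the unit or widen the reference fit"
        )
    return (1.0 - theta) * base


def ht_count(
    probs: np.ndarray,
    multiplicities=None,
    *,
    eval_times=None,
    theta: float = 0.0,
    weight_mode: str = "horizon",
) -> HTCorrection:
    """Horvitz-Thompson corrected count from registration probabilities.

    ``N_hat`` is the integer part of ``sum n_i / prob_i``.
    """
    probs = np.asarray(probs, dtype=float)
    if np.any(probs <= 0.0):
        bad = int(np.argmax(probs <= 0.0))
        raise InfiniteWeightError(f"registration probability 0 for unit {bad}")
    if np.any(probs > 1.0):
        raise ConfigurationError("registration probabilities must lie in (0, 1]")
    n = (
        np.ones(probs.shape, dtype=np.int64)
        if multiplicities is None
        else np.asarray(multiplicities, dtype=np.int64)
    )
    weights = 1.0 / probs
    total = float(np.sum(n * weights))
    return HTCorrection(
        weights=weights,
        registration_probs=probs,
        eval_times=np.asarray(eval_times) if eval_times is not None else np.full(probs.shape, -1),
        multiplicities=n,
        n_hat=int(math.floor(total)),
        n_observed=int(n.sum()),
        theta=theta,
        weight_mode=weight_mode,
    )


def incidence_rate(
    corrected: HTCorrection | float,
    person_years: float,
    scale: float = 1e5,
    n_observed: int | None = None,
) -> IncidenceEstimate:
    """Point incidence rate per ``scale`` person-years.

    ``corrected`` may be an :class:`HTCorrection` (the unfloored weight sum is
    used, matching the estimator's definition) or a plain count.
    """
    if person_years <= 0:
        raise ConfigurationError("person_years must be positive")
    if isinstance(corrected, HTCorrection):
        count = corrected.weight_sum
        n_obs = corrected.n_observed
    else:
        count = float(corrected)
        n_obs = n_observed
    crude = None if n_obs is None else n_obs / person_years * scale
    return IncidenceEstimate(
        rate=count / person_years * scale,
        person_years=person_years,
        scale=scale,
        corrected_count=count,
        crude_rate=crude,
    )


def incidence_variance(
    corrected: HTCorrection,
    reference_fit: ReferenceCdf,
    person_years: float,
    ci_level: float = 0.95,
    scale: float = 1e5,
) -> IncidenceEstimate:
    """Corrected rate with marginal-rule variance and normal-approximation CI.

    The weight-uncertainty term sums the delta-method variance of ``1/F`` at
    each target unit's weighting time; it is zero when the reference cdf is
    supplied as a known function rather than a fitted estimate.
    """
    if not 0.0 < ci_level < 1.0:
        raise ConfigurationError("ci_level must lie in (0, 1)")
    est = incidence_rate(corrected, person_years, scale=scale)
    S = person_years
    D = corrected.n_observed
    if isinstance(reference_fit, RetroHazardEstimator):
        var_w = np.array(
            [weight_variance(reference_fit, int(a)) for a in corrected.eval_times]
        )
        # theta rescales each weight by 1/(1-theta), hence its variance by the square
        var_w = var_w / (1.0 - corrected.theta) ** 2
        term_weights = float(np.sum(corrected.multiplicities * var_w)) / S**2
    else:
        term_weights = 0.0
    w_bar = corrected.weight_sum / D
    var = term_weights + w_bar**2 * D / S**2
    z = stats.norm.ppf(0.5 * (1.0 + ci_level))
    half = z * scale * math.sqrt(var)
    est.variance = var
    est.ci_low = est.rate - half
    est.ci_high = est.rate + half
    est.ci_level = ci_level
    return est


class HTIncidenceEstimator(BaseEstimator):
    """Delay-corrected incidence estimator in scikit-learn style.

    Parameters
    ----------
    reference : RetroHazardEstimator or callable, optional
        Delay cdf used to weight the target cohort. A fitted
        :class:`RetroHazardEstimator` (typically from an older onset cohort)
        contributes its estimation uncertainty to the variance; a callable is
        treated as a known cdf. If ``None``, the reference is fitted on the
        target sample itself.
    theta : float, default 0.0
        Unidentifiable upper-tail mass of the reference cdf.
    weight_mode : {'horizon', 'delay'}, default 'horizon'
        Weighting time convention (see module docstring).
    person_years : float, optional
        Person-time denominator; rate attributes are set only when given.
    scale : float, default 1e5
        Rate scale (cases per ``scale`` person-years).
    ci_level : float, default 0.95
        Confidence level for the rate interval.
    exclude_nonidentifiable : bool, default False
        A target unit whose weighting time falls below the reference cdf's
        identifiable floor has estimated registration probability 0 and an
        infinite weight. By default this raises; opting in drops such units
        from the weighting (they are counted in ``n_excluded_``), which
        understates the corrected count by at least the excluded units.

    Attributes
    ----------
    correction_ : HTCorrection
    registration_probs_, weights_ : ndarray
    n_hat_, n_observed_ : int
    incidence_ : IncidenceEstimate (only with ``person_years``)
    rate_, crude_rate_, variance_, ci_low_, ci_high_ : float
    """

    def __init__(
        self,
        reference: ReferenceCdf | None = None,
        theta: float = 0.0,
        weight_mode: str = "horizon",
        person_years: float | None = None,
        scale: float = 1e5,
        ci_level: float = 0.95,
        exclude_nonidentifiable: bool = False,
    ):
        self.reference = reference
        self.theta = theta
        self.weight_mode = weight_mode
        self.person_years = person_years
        self.scale = scale
        self.ci_level = ci_level
        self.exclude_nonidentifiable = exclude_nonidentifiable

    def fit(self, X, y=None, sample_weight=None) -> "HTIncidenceEstimator":
        """Weight a target sample (:class:`TruncatedDelaySample` or (n,2) array)."""
        t, tau, n = _as_arrays(X, sample_weight)
        sample = X if isinstance(X, TruncatedDelaySample) else TruncatedDelaySample(t, tau, n)
        reference = self.reference
        if reference is None:
            reference = fit_retro_hazard(sample)
        self.n_excluded_ = 0
        if self.exclude_nonidentifiable:
            a_all = sample.tau if self.weight_mode == "horizon" else sample.t
            identifiable = _cdf_values(reference, a_all) > 0.0
            if not identifiable.all():
                self.n_excluded_ = int(sample.n[~identifiable].sum())
                logger.warning(
                    "%d unit(s) below the reference identifiable floor excluded "
                    "from HT weighting; the corrected count is understated",
                    self.n_excluded_,
                )
                sample = sample.subset(identifiable)
        probs = registration_probability(reference, sample, self.theta, self.weight_mode)
        a = sample.tau if self.weight_mode == "horizon" else sample.t
        self.correction_ = ht_count(
            probs,
            sample.n,
            eval_times=a,
            theta=self.theta,
            weight_mode=self.weight_mode,
        )
        self.reference_ = reference
        self.registration_probs_ = self.correction_.registration_probs
        self.weights_ = self.correction_.weights
        self.n_hat_ = self.correction_.n_hat
        self.n_observed_ = self.correction_.n_observed
        self._log_mode_discrepancy(reference, sample)
        if self.person_years is not None:
            self.incidence_ = incidence_variance(
                self.correction_,
                reference,
                self.person_years,
                ci_level=self.ci_level,
                scale=self.scale,
            )
            self.rate_ = self.incidence_.rate
            self.crude_rate_ = self.incidence_.crude_rate
            self.variance_ = self.incidence_.variance
            self.ci_low_ = self.incidence_.ci_low
            self.ci_high_ = self.incidence_.ci_high
        return self

    def _log_mode_discrepancy(self, reference, sample) -> None:
        other = "delay" if self.weight_mode == "horizon" else "horizon"
        try:
            probs_other = registration_probability(reference, sample, self.theta, other)
        except InfiniteWeightError:
            logger.info("alternative weight_mode=%r has an infinite weight", other)
            return
        n_other = float(np.sum(sample.n / probs_other))
        n_this = self.correction_.weight_sum
        if n_this > 0 and abs(n_this - n_other) / max(n_this, n_other) > _MODE_DISCREPANCY_TOL:
            logger.info(
                "weighting modes disagree by >%.0f%%: %s -> %.1f, %s -> %.1f",
                100 * _MODE_DISCREPANCY_TOL,
                self.weight_mode,
                n_this,
                other,
                n_other,
            )


def backtest_robustness(
    sample: TruncatedDelaySample,
    cohort_window: tuple | None,
    early_t_end,
    late_t_end,
    reference_fit: ReferenceCdf | None = None,
    theta: float = 0.0,
    weight_mode: str = "horizon",
) -> BacktestResult:
    """Robustness back-test: early-window HT estimate vs eventual count.

    Restricts to the onset cohort (``cohort_window``, onset dates inclusive),
    HT-corrects the cases diagnosed by ``early_t_end`` (recomputing horizons
    against that earlier closure) and compares with the raw count of the
    cohort's cases diagnosed by ``late_t_end``. When ``reference_fit`` is
    ``None`` the cdf is fitted on the early-window sample itself.
    """
    early_t_end = pd.Timestamp(early_t_end)
    late_t_end = pd.Timestamp(late_t_end)
    if early_t_end >= late_t_end:
        raise ConfigurationError("early_t_end must precede late_t_end")
    if sample.t_end is not None and pd.Timestamp(sample.t_end) != late_t_end:
        raise ConfigurationError(
            f"sample was truncated at {pd.Timestamp(sample.t_end).date()}, "
            f"not at late_t_end={late_t_end.date()}"
        )
    shift = (late_t_end - early_t_end).days
    # Onset dates are recoverable from the horizons: onset = late_t_end - tau.
    onset = late_t_end - pd.to_timedelta(sample.tau, unit="D")
    cohort_mask = np.ones(len(sample), dtype=bool)
    if cohort_window is not None:
        lo, hi = pd.Timestamp(cohort_window[0]), pd.Timestamp(cohort_window[1])
        cohort_mask = (onset >= lo) & (onset <= hi)
        cohort_mask = np.asarray(cohort_mask)
    observed = int(sample.n[cohort_mask].sum())

    tau_early = sample.tau - shift
    early_mask = cohort_mask & (tau_early >= 0) & (sample.t <= tau_early)
    if not early_mask.any():
        raise DataError(f"no cohort cases diagnosed by early_t_end={early_t_end.date()}")
    early_sample = TruncatedDelaySample(
        t=sample.t[early_mask],
        tau=tau_early[early_mask],
        n=sample.n[early_mask],
        t_end=early_t_end,
    )
    reference = reference_fit if reference_fit is not None else fit_retro_hazard(early_sample)
    probs = registration_probability(reference, early_sample, theta, weight_mode)
    correction = ht_count(probs, early_sample.n, theta=theta, weight_mode=weight_mode)
    return BacktestResult(
        estimated=correction.n_hat,
        observed=observed,
        n_early=early_sample.n_total,
        early_t_end=early_t_end,
        late_t_end=late_t_end,
    )
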
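"""Silencing kinetics: normalization, empirical rates, and β fitting.

The silenced fraction measured with recruitment (S_dox+) is corrected
for the background silenced fraction of the matched no-recruitment
control (S_dox−) and renormalized by the fraction still available for
silencing::

    S_norm = (S_dox+ − S_dox−) / (1 − S_dox−)

Under the stochastic switching model, each cell's promoter switches
irreversibly from active to silent at a constant per-day rate β (which
may depend on CpG density c), so the active fraction A(t) = 1 − S_norm
decays exponentially: dA/dt = −βA.  β is estimated by ordinary least
squares of ln A(t) on t (with intercept); its standard error is the
slope SE of the regression, and two fitted rates are compared with a
Wald z-test built from those estimates and standard errors.

An empirical, model-free per-day rate over each pair of neighbouring
timepoints is also provided: ΔS / (Δt · remaining fraction), with
pairs above a configurable fraction (default 80%) omitted because the
normalizing remaining fraction becomes too small.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateComparisonError,
    InsufficientPointsError,
    UndefinedNormalizationError,
)

__all__ = [
    "SilencingTimecourse",
    "SwitchingFit",
    "StochasticSwitchingModel",
    "normalize_fraction",
    "empirical_rates",
    "fit_switching_rate",
    "compare_rates",
    "bootstrap_normalization",
]

logger = logging.getLogger(__name__)


def normalize_fraction(s_plus: float, s_minus: float) -> float:
    """Background-corrected silenced fraction (S+ − S−)/(1 − S−), clamped to [0, 1].

    Negative values (control noisier than sample) are logged before
    clamping.
    """
    if not (0.0 <= s_minus <= 1.0) or not (0.0 <= s_plus <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    if s_minus == 1.0:
        raise UndefinedNormalizationError(
            "background silenced fraction is 1; normalization undefined"
        )
    value = (s_plus - s_minus) / (1.0 - s_minus)
    if value < 0.0:
        logger.info(
            "normalized fraction %.4g < 0 (s_plus=%.4g below background %.4g); clamped",
            value,
            s_plus,
            s_minus,
        )
        return 0.0
    return min(value, 1.0)


@dataclasses.dataclass
class SilencingTimecourse:
    """Normalized silenced fractions over time for one promoter.

    ``points`` columns: t (days, strictly increasing), s_plus, s_minus,
    s_norm, active (= 1 − s_norm).
    """

    promoter_name: str
    points: pd.DataFrame

    def __post_init__(self):
        need = {"t", "s_plus", "s_minus", "s_norm", "active"}
        if not need.issubset(self.points.columns):
            raise ValueError(f"points must have columns {sorted(need)}")
        t = self.points["t"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def from_raw(
        cls,
        promoter_name: str,
        t: Sequence[float],
        s_plus: Sequence[float],
        s_minus: Sequence[float],
    ) -> "SilencingTimecourse":
        s_norm = [normalize_fraction(p, m) for p, m in zip(s_plus, s_minus)]
        df = pd.DataFrame(
            {
                "t": np.asarray(t, dtype=float),
                "s_plus": np.asarray(s_plus, dtype=float),
                "s_minus": np.asarray(s_minus, dtype=float),
                "s_norm": s_norm,
            }
        ).sort_values("t", ignore_index=True)
        df["active"] = 1.0 - df["s_norm"]
        return cls(promoter_name, df)

    @classmethod
    def from_normalized(
        cls, promoter_name: str, t: Sequence[float], s_norm: Sequence[float]
    ) -> "SilencingTimecourse":
        """Build directly from already-normalized fractions."""
        s = np.asarray(s_norm, dtype=float)
        df = pd.DataFrame(
            {"t": np.asarray(t, dtype=float), "s_plus": s, "s_minus": 0.0, "s_norm": s}
        ).sort_values("t", ignore_index=True)
        df["active"] = 1.0 - df["s_norm"]
        return cls(promoter_name, df)


def empirical_rates(
    tc: SilencingTimecourse, omit_above: float = 0.8
) -> pd.DataFrame:
    """Model-free per-day silencing rate between neighbouring timepoints.

    For each consecutive pair (t_i, S_i), (t_{i+1}, S_{i+1}) with both
    S ≤ ``omit_above``::

        rate = (S_{i+1} − S_i) / ((t_{i+1} − t_i) · (1 − S_i))

    using the earlier point's remaining fraction, matching the hazard
    reading rate = −ΔA/(Δt·A).  Pairs with either fraction above
    ``omit_above`` are omitted (the remaining fraction is too small to
    normalize by) and logged.  Returns a DataFrame (t_mid, rate); warns
    if every pair was omitted.
    """
    df = tc.points
    if len(df) < 2:
        raise InsufficientPointsError("need at least 2 timepoints")
    t = df["t"].to_numpy(dtype=float)
    s = df["s_norm"].to_numpy(dtype=float)
    rows, omitted = [], []
    for i in range(len(t) - 1):
        if s[i] > omit_above or s[i + 1] > omit_above:
            omitted.append((t[i], t[i + 1]))
            continue
        rate = (s[i + 1] - s[i]) / ((t[i + 1] - t[i]) * (1.0 - s[i]))
        rows.append({"t_mid": 0.5 * (t[i] + t[i + 1]), "rate": rate})
    if omitted:
        logger.info(
            "%s: omitted %d pair(s) above %.0f%% fraction: %s",
            tc.promoter_name,
            len(omitted),
            100 * omit_above,
            omitted,
        )
    if not rows:
        warnings.warn(
            f"{tc.promoter_name}: all timepoint pairs above "
            f"{100 * omit_above:.0f}% fraction; no empirical rates",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["t_mid", "rate"])


@dataclasses.dataclass(frozen=True)
class SwitchingFit:
    """Fitted stochastic switching rate for one promoter."""

    promoter_name: str
    beta: float
    beta_se: float
    intercept: float
    r_squared: float
    n_points_used: int
    excluded_times: tuple[float, ...] = ()

    def __post_init__(self):
        if self.beta_se < 0:
            raise ValueError("beta_se must be >= 0")
        if self.n_points_used < 2:
            raise ValueError("n_points_used must be >= 2")


class StochasticSwitchingModel(BaseEstimator):
    """Exponential-decay fit of the active fraction: A(t) = exp(a − βt).

    OLS of ln A on t with intercept; ``beta_`` is minus the slope and
    ``beta_se_`` the slope standard error, reported as the larger of the
    classical residual-based estimate and the HC3 heteroscedasticity-
    robust estimate.  With a handful of timepoints and counting noise
    that grows as the active fraction shrinks, the classical SE can be
    anti-conservative (late, noisy points carry high leverage) while
    HC3 alone is unstable at small n; taking the larger of the two keeps
    the ±3·SE interval honest across the practical rate range.

    Points with A at or below ``a_floor`` (zero cells left active;
    default drops only A ≤ 0) are excluded with a warning, as are any
    times listed in ``exclude_times`` (e.g. t = 0 when the protocol has
    no release phase before the first measurement).

    Attributes: ``beta_``, ``beta_se_``, ``intercept_`` (fitted ln A at
    t = 0), ``r_squared_``, ``n_points_used_``, ``excluded_times_``.
    """

    def __init__(
        self, exclude_times: Sequence[float] = (), a_floor: float | None = None
    ):
        self.exclude_times = exclude_times
        self.a_floor = a_floor

    def fit(self, t, A=None) -> "StochasticSwitchingModel":
        t = np.asarray(t, dtype=float).ravel()
        A = np.asarray(A, dtype=float).ravel()
        if t.shape != A.shape:
            raise ValueError("t and A must have the same length")
        excluded = []
        keep = np.ones(t.size, dtype=bool)
        for te in self.exclude_times:
            hit = np.isclose(t, te)
            if hit.any():
                keep &= ~hit
                excluded.append(float(te))
        floor = self.a_floor if self.a_floor is not None else 0.0
        low = A <= floor
        if np.any(low & keep):
            warnings.warn(
                f"dropping {int((low & keep).sum())} point(s) with active fraction "
                f"<= {floor:g}",
                stacklevel=2,
            )
        keep &= ~low
        if keep.sum() < 2:
            raise InsufficientPointsError(
                f"only {int(keep.sum())} usable point(s) after exclusions"
            )
        tk, yk = t[keep], np.log(A[keep])
        X = np.column_stack([np.ones_like(tk), tk])
        xtx_inv = np.linalg.inv(X.T @ X)
        coef = xtx_inv @ X.T @ yk
        resid = yk - X @ coef
        dof = tk.size - 2
        if dof > 0:
            se_ols = math.sqrt(float(resid @ resid) / dof * xtx_inv[1, 1])
            leverage = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
            omega = resid**2 / np.maximum(1.0 - leverage, 1e-12) ** 2
            cov_hc3 = xtx_inv @ (X.T @ (X * omega[:, None])) @ xtx_inv
            se_hc3 = math.sqrt(max(cov_hc3[1, 1], 0.0))
            se = max(se_ols, se_hc3)
        else:
            se = 0.0
        ss_tot = float(np.sum((yk - yk.mean()) ** 2))
        ss_res = float(resid @ resid)
        self.beta_ = -float(coef[1])
        self.beta_se_ = se
        self.intercept_ = float(coef[0])
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        self.n_points_used_ = int(keep.sum())
        self.excluded_times_ = tuple(excluded)
        return self

    def predict(self, t) -> np.ndarray:
        """Predicted active fraction exp(intercept − β·t)."""
        t = np.asarray(t, dtype=float)
        return np.exp(self.intercept_ - self.beta_ * t)


def fit_switching_rate(
    tc: SilencingTimecourse,
    exclude_times: Sequence[float] = (),
    a_floor: float | None = None,
) -> SwitchingFit:
    """Fit β for one promoter's timecourse by OLS of ln A(t) on t."""
    model = StochasticSwitchingModel(exclude_times=exclude_times, a_floor=a_floor).fit(
        tc.points["t"], tc.points["active"]
    )
    return SwitchingFit(
        promoter_name=tc.promoter_name,
        beta=model.beta_,
        beta_se=model.beta_se_,
        intercept=model.intercept_,
        r_squared=model.r_squared_,
        n_points_used=model.n_points_used_,
        excluded_times=model.excluded_times_,
    )


def compare_rates(fit_a: SwitchingFit, fit_b: SwitchingFit) -> float:
    """Two-sided Wald p-value for β_a ≠ β_b from the fits' estimates and SEs."""
    se = np.hypot(fit_a.beta_se, fit_b.beta_se)
    if se == 0:
        raise DegenerateComparisonError("both fits have zero standard error")
    z = (fit_a.beta - fit_b.beta) / se
    return float(2.0 * stats.norm.sf(abs(z)))


def bootstrap_normalization(
    samples_plus: Sequence[float], samples_minus: Sequence[float]
) -> tuple[np.ndarray, float, float]:
    """All pairwise background-corrected fractions, their mean and sample SD.

    Each with-recruitment replicate is normalized to each no-recruitment
    control replicate (3 × 3 replicates give 9 points); the SD (ddof=1,
    0.0 for a single point) is the error bar.
    """
    if len(samples_plus) == 0 or len(samples_minus) == 0:
        raise ValueError("both replicate lists must be non-empty")
    points = np.array(
        [normalize_fraction(p, m) for p in samples_plus for m in samples_minus]
    )
    sd = float(points.std(ddof=1)) if points.size > 1 else 0.0
    return points, float(points.mean()), sd
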
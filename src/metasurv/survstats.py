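"""Core survival estimators: Cox, the D-index, Kaplan-Meier, log-rank.

The central quantity is the D-index of Royston & Sauerbrei: a rank-based
estimate of the log hazard ratio comparing two equal-sized prognostic
groups.  A risk score is ranked, mapped to normal order statistics (Blom's
approximation), scaled by kappa = sqrt(8/pi), and regressed through a
univariate Cox model; the fitted coefficient is D.  Because only the ranks
of the score enter, D is invariant to any strictly increasing rescaling of
the score — the property that makes it comparable across microarray
platforms with different dynamic ranges.

Cox fitting uses the package's own vectorized Efron-tie Newton solver
(:mod:`metasurv._cox`); Kaplan-Meier curves and the two-group log-rank test
are delegated to lifelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from ._cox import BatchCoxResult, DegenerateInputError, cox_fit_batch

#: scaling constant relating the rankit coefficient to the log hazard ratio
#: between two equal-sized prognostic groups
KAPPA = math.sqrt(8.0 / math.pi)


@dataclass
class DIndexResult:
    """D-index of a risk score: log hazard ratio between equal-sized groups."""

    log_hr: float
    se: float
    p_value: float
    n: int
    n_events: int

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)

    def ci95(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se
        return (self.log_hr - half, self.log_hr + half)


def _check_endpoints(time: np.ndarray, event: np.ndarray) -> None:
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(time <= 0):
        raise ValueError("survival times must be strictly positive")


def fit_cox(covariate: np.ndarray, time: np.ndarray, event: np.ndarray,
            ) -> tuple[float, float, float]:
    """Univariate Cox fit -> (coef, se, two-sided Wald p).

    Efron handling of tied event times; raises
    :class:`~metasurv._cox.DegenerateInputError` for a constant covariate or
    fewer than two events.
    """
    covariate = np.asarray(covariate, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_endpoints(time, event)
    if covariate.shape != time.shape:
        raise ValueError("covariate and endpoints must have equal length")
    if event.sum() < 2:
        raise DegenerateInputError("fewer than 2 events")
    if np.ptp(covariate) == 0:
        raise DegenerateInputError("constant covariate")
    res = cox_fit_batch(covariate[:, None], time, event)
    if not res.converged[0]:
        raise DegenerateInputError("Cox fit did not converge")
    return float(res.coef[0]), float(res.se[0]), float(res.p_value[0])


def rankits(scores: np.ndarray) -> np.ndarray:
    """Blom normal order statistics of a score vector, ties averaged.

    Phi^{-1}((r - 3/8) / (n + 1/4)) with r the average rank.
    """
    scores = np.asarray(scores, dtype=float)
    r = stats.rankdata(scores, axis=0)
    n = scores.shape[0]
    return stats.norm.ppf((r - 0.375) / (n + 0.25))


def d_index(risk_scores: np.ndarray, time: np.ndarray, event: np.ndarray,
            ) -> DIndexResult:
    """D-index of a risk score against a survival endpoint.

    The score is reduced to scaled rankits (Blom / kappa) and fed through a
    univariate Cox fit; the coefficient is D, interpretable as the log
    hazard ratio between the upper and lower prognostic halves.
    """
    risk_scores = np.asarray(risk_scores, dtype=float)
    z = rankits(risk_scores) / KAPPA
    coef, se, p = fit_cox(z, time, event)
    return DIndexResult(log_hr=coef, se=se, p_value=p,
                        n=len(risk_scores), n_events=int(np.sum(event)))


def d_index_batch(scores: np.ndarray, time: np.ndarray, event: np.ndarray,
                  ) -> BatchCoxResult:
    """D-index for every column of a (samples x genes) score matrix.

    Vectorized path for genome-wide scans; columns that are constant or
    otherwise degenerate come back with ``converged=False``.
    """
    scores = np.asarray(scores, dtype=float)
    z = rankits(scores) / KAPPA
    return cox_fit_batch(z, np.asarray(time, float), np.asarray(event, int))


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray       # event/censor times, ascending, prepended 0
    survival: np.ndarray    # S(t) at those times

    def __call__(self, t: float | np.ndarray) -> np.ndarray | float:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.survival) - 1)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def km_curve(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """Kaplan-Meier estimate of the survival function."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_endpoints(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return KMCurve(times=sf.index.to_numpy(dtype=float),
                   survival=sf.iloc[:, 0].to_numpy(dtype=float))


def logrank_test(group_labels: np.ndarray, time: np.ndarray, event: np.ndarray,
                 ) -> tuple[float, float]:
    """Two-group log-rank test -> (chi-square, p), one degree of freedom."""
    group_labels = np.asarray(group_labels)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_endpoints(time, event)
    groups = np.unique(group_labels)
    if groups.size != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups.size}")
    if event.sum() < 1:
        raise ValueError("log-rank needs at least one event")
    mask = group_labels == groups[0]
    res = _ll_logrank(time[mask], time[~mask], event[mask], event[~mask])
    return float(res.test_statistic), float(res.p_value)


def median_split(scores: np.ndarray) -> np.ndarray:
    """High/low labels at the within-cohort median; high iff score > median.

    With an odd sample count the median element lands in the low group;
    an all-constant score vector yields a single (low) group with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    labels = scores > np.median(scores)
    if not labels.any():
        warnings.warn("median split is degenerate: all scores equal",
                      stacklevel=2)
    return labels.astype(int)
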
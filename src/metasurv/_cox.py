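"""Vectorized single-covariate Cox partial-likelihood engine.

Genome-wide prognostic scans fit one univariate Cox model per gene in every
dataset, which can mean hundreds of thousands of fits per analysis.  This
module implements a Newton solver for the single-covariate case that is
vectorized across covariate columns: one pass over the risk sets updates the
coefficient of every gene simultaneously.  Tied event times use the Efron
correction.

The solver is deliberately restricted to one covariate per model; the
surrounding package never fits multivariable models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MAX_ITER = 50
COEF_TOL = 1e-9


@dataclass
class BatchCoxResult:
    """Per-column results of a batch of univariate Cox fits."""

    coef: np.ndarray        # (G,) partial-likelihood maximizer
    se: np.ndarray          # (G,) from observed information
    p_value: np.ndarray     # (G,) two-sided Wald
    converged: np.ndarray   # (G,) bool; False also flags degenerate columns
    n: int
    n_events: int


class DegenerateInputError(ValueError):
    """Raised when a Cox fit cannot be attempted (constant covariate, <2 events)."""


def _risk_set_layout(time: np.ndarray, event: np.ndarray):
    """Sort observations and locate tied event groups.

    Returns the sort order plus, per distinct event time, the index of the
    first observation still at risk and the row indices of the events.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    groups = []
    event_idx = np.flatnonzero(e == 1)
    if event_idx.size:
        # observations with equal time share one risk set
        first_at_time = np.searchsorted(t, t, side="left")
        for tval in np.unique(t[event_idx]):
            members = event_idx[t[event_idx] == tval]
            groups.append((first_at_time[members[0]], members))
    return order, groups


class _GroupLayout:
    """Tied-event bookkeeping: singleton event times vectorized, ties listed."""

    def __init__(self, raw_groups):
        singles_first = []
        singles_member = []
        self.tied = []  # (first_at_risk_idx, member_idx, efron_fractions)
        for first, members in raw_groups:
            if members.size == 1:
                singles_first.append(first)
                singles_member.append(members[0])
            else:
                self.tied.append((first, members,
                                  np.arange(members.size) / members.size))
        self.singles_first = np.asarray(singles_first, dtype=int)
        self.singles_member = np.asarray(singles_member, dtype=int)


def _loglik_grad_info(beta: np.ndarray, x: np.ndarray, groups: _GroupLayout,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Efron log partial likelihood, gradient and information.

    ``x`` is (n, G) already sorted by time ascending; ``beta`` is (G,).
    All three outputs are per column.  Untied event times are handled in
    one vectorized pass; only tied groups are visited individually.
    """
    eta = x * beta  # (n, G)
    # guard against overflow for extreme trial steps
    w = np.exp(np.clip(eta, -500.0, 500.0))
    wx = w * x
    wxx = wx * x
    # reverse cumulative sums: S*[i] = sum over observations with index >= i
    s0_cum = np.cumsum(w[::-1], axis=0)[::-1]
    s1_cum = np.cumsum(wx[::-1], axis=0)[::-1]
    s2_cum = np.cumsum(wxx[::-1], axis=0)[::-1]

    G = x.shape[1]
    loglik = np.zeros(G)
    grad = np.zeros(G)
    info = np.zeros(G)
    if groups.singles_first.size:
        S0 = s0_cum[groups.singles_first]
        r1 = s1_cum[groups.singles_first] / S0
        loglik += (eta[groups.singles_member] - np.log(S0)).sum(axis=0)
        grad += (x[groups.singles_member] - r1).sum(axis=0)
        info += (s2_cum[groups.singles_first] / S0 - r1 * r1).sum(axis=0)
    for first, members, frac in groups.tied:
        S0 = s0_cum[first]
        S1 = s1_cum[first]
        S2 = s2_cum[first]
        loglik += eta[members].sum(axis=0)
        grad += x[members].sum(axis=0)
        t0 = w[members].sum(axis=0)
        t1 = wx[members].sum(axis=0)
        t2 = wxx[members].sum(axis=0)
        for f in frac:
            denom = S0 - f * t0
            r1 = (S1 - f * t1) / denom
            loglik -= np.log(denom)
            grad -= r1
            info += (S2 - f * t2) / denom - r1 * r1
    return loglik, grad, info


def cox_fit_batch(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> BatchCoxResult:
    """Fit univariate Cox models for every column of ``x`` at once.

    Parameters
    ----------
    x : (n, G) float array, no missing values.
    time, event : (n,) survival endpoint; event coded 0/1.

    Newton-Raphson with step-halving; convergence when the coefficient moves
    by less than ``COEF_TOL``. Columns that are constant (or if there are
    fewer than 2 events) are reported with ``converged=False`` and NaN
    estimates rather than raising, so that genome-wide callers can skip them.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, G = x.shape
    n_events = int(event.sum())

    order, raw_groups = _risk_set_layout(time, event)
    xs = x[order]
    groups = _GroupLayout(raw_groups)

    usable = xs.std(axis=0) > 0
    if n_events < 2:
        usable = np.zeros(G, dtype=bool)

    beta = np.zeros(G)
    converged = np.zeros(G, dtype=bool)
    if usable.any():
        active = usable.copy()
        ll, _, _ = _loglik_grad_info(beta, xs, groups)
        for _ in range(MAX_ITER):
            _, grad, info = _loglik_grad_info(beta, xs, groups)
            step = np.zeros(G)
            ok = active & (info > 0)
            step[ok] = grad[ok] / info[ok]
            # step-halving: insist the partial likelihood does not decrease
            for _half in range(30):
                ll_new, _, _ = _loglik_grad_info(beta + step, xs, groups)
                bad = active & (ll_new < ll - 1e-12)
                if not bad.any():
                    break
                step[bad] *= 0.5
            beta = beta + step
            ll = ll_new
            done = active & (np.abs(step) < COEF_TOL)
            converged |= done
            active &= ~done
            if not active.any():
                break

    _, _, info = _loglik_grad_info(beta, xs, groups)
    se = np.full(G, np.nan)
    good = converged & (info > 0)
    se[good] = 1.0 / np.sqrt(info[good])
    coef = np.where(good, beta, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return BatchCoxResult(coef=coef, se=se, p_value=p, converged=good,
                          n=n, n_events=n_events)


def efron_loglik(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Efron log partial likelihood at a single coefficient value.

    Exposed for score tests and for brute-force verification of the solver.
    """
    x = np.asarray(x, dtype=float)[:, None]
    order, raw_groups = _risk_set_layout(np.asarray(time, float), np.asarray(event, int))
    ll, _, _ = _loglik_grad_info(np.array([beta]), x[order], _GroupLayout(raw_groups))
    return float(ll[0])


def score_test_stat(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox score test statistic U(0)^2 / I(0) for a single covariate."""
    x = np.asarray(x, dtype=float)[:, None]
    order, raw_groups = _risk_set_layout(np.asarray(time, float), np.asarray(event, int))
    _, grad, info = _loglik_grad_info(np.zeros(1), x[order], _GroupLayout(raw_groups))
    return float(grad[0] ** 2 / info[0])
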
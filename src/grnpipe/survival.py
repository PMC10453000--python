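"""Survival analysis: Kaplan-Meier curves, log-rank tests, single-covariate
Cox regression, and the quartile-bounded best-cutoff scan with FDR gating.

The scan enumerates every distinct observed expression value strictly
between the lower and upper quartiles, tests the high-vs-low split at each
cutoff with the log-rank statistic (identical to the Cox score test in the
absence of ties), adjusts p-values with Benjamini-Hochberg, and selects the
smallest-p cutoff among those with q below the FDR gate; the hazard ratio
at the selected cutoff comes from a full Cox fit (Breslow ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger(__name__)


class MonotoneLikelihoodError(RuntimeError):
    """Raised when the Cox partial likelihood has no finite maximizer
    (e.g. all events fall in one group)."""


def _validate(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("time and event must have the same length")
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return t, e


def km_curve(time, event) -> pd.DataFrame:
    """Product-limit survival estimate with right censoring.

    Returns a step function as a frame (time, at_risk, events, survival);
    survival starts at 1 and is non-increasing.
    """
    t, e = _validate(time, event)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    times = np.unique(t)
    n = len(t)
    rows = []
    surv = 1.0
    for u in times:
        at_risk = int(np.sum(t >= u))
        d = int(np.sum(e[t == u]))
        if d > 0:
            surv *= 1.0 - d / at_risk
        rows.append((float(u), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test (ties pooled, hypergeometric variance).

    Returns (chi-square statistic, p-value from a 1-df chi-square).
    """
    t, e = _validate(time, event)
    g = np.asarray(group).astype(bool)
    if g.all() or not g.any():
        raise ValueError("both groups must be non-empty")
    if e.sum() == 0:
        raise ValueError("at least one event is required")
    event_times = np.unique(t[e == 1])
    O1 = E1 = V = 0.0
    for u in event_times:
        at = t >= u
        n_tot = at.sum()
        n1 = (at & g).sum()
        d = int(e[(t == u)].sum())
        d1 = int(e[(t == u) & g].sum())
        O1 += d1
        E1 += d * n1 / n_tot
        if n_tot > 1:
            V += d * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d) / (n_tot - 1)
    if V <= 0:
        return 0.0, 1.0
    stat = (O1 - E1) ** 2 / V
    return float(stat), float(chi2.sf(stat, df=1))


def _cox_derivs(beta: float, t, e, x) -> tuple[float, float, float]:
    """Breslow log partial likelihood and derivatives for one binary/real
    covariate, at the given beta."""
    order = np.argsort(-t, kind="stable")  # descending time
    ts, es, xs = t[order], e[order], x[order]
    r = np.exp(beta * xs)
    # cumulative risk-set sums walking from the largest time down
    s0 = np.cumsum(r)
    s1 = np.cumsum(r * xs)
    s2 = np.cumsum(r * xs * xs)
    ll = 0.0
    U = 0.0
    I = 0.0
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        # risk set at this time = everything up to j-1 in descending order
        block = slice(i, j)
        d_idx = np.nonzero(es[block])[0]
        d = len(d_idx)
        if d > 0:
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            xsum = xs[block][d_idx].sum()
            ll += beta * xsum - d * np.log(S0)
            U += xsum - d * S1 / S0
            I += d * (S2 / S0 - (S1 / S0) ** 2)
        i = j
    return ll, U, I


def cox_hr(
    time, event, group, max_iter: int = 50, tol: float = 1e-10
) -> tuple[float, float, float]:
    """Single-covariate Cox regression for a binary split.

    Newton-maximizes the Breslow partial likelihood; returns
    (hazard ratio, beta, score-test chi-square at beta=0). The score test
    equals the log-rank chi-square when there are no tied event times.
    Raises ``MonotoneLikelihoodError`` when one group carries all events
    and RuntimeError on non-convergence.
    """
    t, e = _validate(time, event)
    x = np.asarray(group).astype(float)
    if np.unique(x).size < 2:
        raise ValueError("both groups must be non-empty")
    if e.sum() == 0:
        raise ValueError("at least one event is required")
    if e[x == 1].sum() == 0 or e[x == 0].sum() == 0:
        raise MonotoneLikelihoodError(
            "all events in one group: hazard ratio diverges"
        )
    _, U0, I0 = _cox_derivs(0.0, t, e, x)
    score_chi2 = U0 * U0 / I0 if I0 > 0 else 0.0
    beta = 0.0
    for it in range(max_iter):
        _, U, I = _cox_derivs(beta, t, e, x)
        if I <= 0:
            raise RuntimeError(f"singular information at iteration {it}")
        step = U / I
        beta += step
        if abs(step) < tol:
            return float(np.exp(beta)), float(beta), float(score_chi2)
    raise RuntimeError(
        f"Cox Newton iteration did not converge after {max_iter} steps "
        f"(last beta={beta:.4g}, step={step:.2e})"
    )


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class BestCutoff:
    """Outcome of the cutoff scan: either a selected cutoff with its
    statistics, or an explicit no-selection marker."""

    selected: bool
    cutoff: float | None = None
    p: float | None = None
    q: float | None = None
    hazard_ratio: float | None = None

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "cutoff": self.cutoff,
            "p": self.p,
            "q": self.q,
            "hazard_ratio": self.hazard_ratio,
        }


def scan_cutoffs(
    dataset: pd.DataFrame, fdr: float = 0.10
) -> tuple[pd.DataFrame, BestCutoff]:
    """Scan all expression cutoffs strictly between the quartiles.

    ``dataset`` columns: time, event, expression. Candidates are the
    distinct observed expression values strictly inside (Q1, Q3); each
    split (high = expression > cutoff) is tested with the log-rank
    statistic, q-values are Benjamini-Hochberg across the scan, and only
    cutoffs with q < ``fdr`` are accepted. Among accepted cutoffs the one
    with the smallest p (ties: smallest cutoff) is selected and its hazard
    ratio estimated by a full Cox fit; otherwise the no-selection marker is
    returned.
    """
    t, e = _validate(dataset["time"], dataset["event"])
    expr = np.asarray(dataset["expression"], dtype=float)
    if np.unique(expr).size < 2:
        raise ValueError("all expression values are identical")
    q1, q3 = np.quantile(expr, [0.25, 0.75])
    candidates = np.unique(expr[(expr > q1) & (expr < q3)])
    if candidates.size == 0:
        raise ValueError("no candidate cutoff strictly between the quartiles")

    rows = []
    for c in candidates:
        high = expr > c
        stat, p = logrank_test(t, e, high)
        rows.append((float(c), stat, p, int(high.sum()), int((~high).sum())))
    scan = pd.DataFrame(rows, columns=["cutoff", "chi2", "p", "n_high", "n_low"])
    scan["q"] = bh_adjust(scan["p"].to_numpy())

    accepted = scan[scan["q"] < fdr]
    if accepted.empty:
        return scan, BestCutoff(selected=False)
    best = accepted.sort_values(["p", "cutoff"], kind="stable").iloc[0]
    hr, _, _ = cox_hr(t, e, expr > best["cutoff"])
    return scan, BestCutoff(
        selected=True,
        cutoff=float(best["cutoff"]),
        p=float(best["p"]),
        q=float(best["q"]),
        hazard_ratio=float(hr),
    )
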
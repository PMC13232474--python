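"""Association and survival statistics linking subtype labels to outcomes.

Subtype calls are associated with external classifications by chi-square
tests on cross-tabulations, and with progression outcomes by Kaplan-Meier
estimation and the log-rank test.  The survival machinery is implemented
from the definitions (product-limit estimator; observed-minus-expected
event counts with hypergeometric variance) so its calibration can be
verified by simulation; tied event and censoring times follow the
standard convention that events are processed before censorings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def cross_tab(labels_a: pd.Series, labels_b: pd.Series
              ) -> tuple[pd.DataFrame, int]:
    """Joint counts of two label vectors over shared unit ids.

    Units missing either label are dropped; returns ``(table, n_dropped)``.
    """
    labels_a, labels_b = pd.Series(labels_a), pd.Series(labels_b)
    shared = labels_a.dropna().index.intersection(labels_b.dropna().index)
    if len(shared) == 0:
        raise ValueError("no shared unit ids between label vectors")
    dropped = len(labels_a.index.union(labels_b.index)) - len(shared)
    table = pd.crosstab(labels_a.loc[shared], labels_b.loc[shared])
    return table, dropped


def chi_square_test(table: pd.DataFrame,
                    fisher: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    ``X^2 = sum (O - E)^2 / E`` with ``df = (r-1)(c-1)``.  Raises when an
    expected count is zero (collapse sparse categories first).  For 2x2
    tables ``fisher=True`` switches to Fisher's exact test (df reported 1).
    """
    obs = np.asarray(table, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("empty contingency table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected count; collapse sparse categories")
    if fisher:
        if obs.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        _, p = stats.fisher_exact(obs)
        return float("nan"), 1, float(p)
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


@dataclass
class KMCurve:
    times: np.ndarray        # event times, ascending
    survival: np.ndarray     # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """Right-continuous survival probability at time t."""
        i = np.searchsorted(self.times, t, side="right")
        return float(self.survival[i - 1]) if i > 0 else 1.0


def km_estimate(table: pd.DataFrame, group: str | None = None
                ) -> dict[str, KMCurve]:
    """Kaplan-Meier product-limit estimate per group.

    ``table`` needs columns (time, event) and optionally ``group``.
    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)`` over distinct event times;
    censored subjects leave the risk set after their time.
    """
    if (table.time < 0).any():
        raise ValueError("negative survival time")
    if len(table) == 0:
        raise ValueError("empty survival table")
    groups = table.groupby(group) if group else [("all", table)]
    out: dict[str, KMCurve] = {}
    for name, g in groups:
        t = g.time.to_numpy(dtype=float)
        e = g.event.to_numpy(dtype=int)
        ev_times = np.unique(t[e == 1])
        surv, s = [], 1.0
        n_risk, n_ev = [], []
        for ti in ev_times:
            n_i = int((t >= ti).sum())       # events precede censorings at ties
            d_i = int(((t == ti) & (e == 1)).sum())
            s *= 1.0 - d_i / n_i
            surv.append(s)
            n_risk.append(n_i)
            n_ev.append(d_i)
        out[str(name)] = KMCurve(times=ev_times, survival=np.array(surv),
                                 n_at_risk=np.array(n_risk),
                                 n_events=np.array(n_ev))
    return out


def logrank_test(table: pd.DataFrame, group: str = "group"
                 ) -> tuple[float, float]:
    """k-group log-rank test; chi-square statistic with df = k - 1.

    At each distinct event time the observed events per group are compared
    with their expectation under a common hazard, accumulating the
    hypergeometric covariance; the statistic is the quadratic form over
    the first k-1 groups.
    """
    groups = table[group].astype(str)
    names = sorted(groups.unique())
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for name in names:
        if (groups == name).sum() == 0:
            raise ValueError(f"group {name!r} has no subjects")
    t = table.time.to_numpy(dtype=float)
    e = table.event.to_numpy(dtype=int)
    gidx = groups.map({n: i for i, n in enumerate(names)}).to_numpy()

    ev_times = np.unique(t[e == 1])
    u = np.zeros(k)
    v = np.zeros((k, k))
    for ti in ev_times:
        at_risk = t >= ti
        n_i = int(at_risk.sum())
        n_ij = np.bincount(gidx[at_risk], minlength=k).astype(float)
        died = (t == ti) & (e == 1)
        d_i = int(died.sum())
        d_ij = np.bincount(gidx[died], minlength=k).astype(float)
        exp_ij = d_i * n_ij / n_i
        u += d_ij - exp_ij
        if n_i > 1:
            frac = n_ij / n_i
            v += (d_i * (n_i - d_i) / (n_i - 1)) * (np.diag(frac) - np.outer(frac, frac))
    uu, vv = u[:-1], v[:-1, :-1]
    if not np.any(np.abs(vv) > 0):
        raise ValueError("log-rank variance is zero (no usable events)")
    stat = float(uu @ np.linalg.pinv(vv) @ uu)
    p = float(stats.chi2.sf(stat, k - 1))
    return stat, p
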
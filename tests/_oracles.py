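"""Independent brute-force oracles used by the tests.

These are deliberately simple, loop-based implementations kept separate
from the package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np


def logrank_chi2_oracle(times, events, labels) -> float:
    """K-group log-rank chi-square via explicit per-event-time risk tables."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    k = len(groups)
    u = np.zeros(k - 1)
    v = np.zeros((k - 1, k - 1))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        ng = np.array([(at_risk & (labels == g)).sum() for g in groups], float)
        dg = np.array(
            [((times == t) & (events == 1) & (labels == g)).sum() for g in groups],
            float,
        )
        u += dg[:-1] - ng[:-1] * d / n
        if n > 1:
            c = d * (n - d) / (n - 1)
            for a in range(k - 1):
                for b in range(k - 1):
                    delta = 1.0 if a == b else 0.0
                    v[a, b] += c * (ng[a] / n) * (delta - ng[b] / n)
    return float(u @ np.linalg.pinv(v) @ u)


def standardized_logrank_oracle(times, events, in_group) -> float:
    """Standardized two-group log-rank statistic |Z| by direct summation."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    in_group = np.asarray(in_group, bool)
    u = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        n1 = (at_risk & in_group).sum()
        d1 = ((times == t) & (events == 1) & in_group).sum()
        u += d1 - n1 * d / n
        if n > 1:
            var += d * (n - d) / (n - 1) * (n1 / n) * (1 - n1 / n)
    return abs(u) / np.sqrt(var) if var > 0 else 0.0


def maxstat_scan_oracle(marker, times, events, min_group_frac):
    """Exhaustive binary cut scan; returns (best |Z|, best cut)."""
    marker = np.asarray(marker, float)
    n = len(marker)
    gmin = int(np.ceil(min_group_frac * n))
    s = np.sort(np.unique(marker))
    best = (-1.0, None)
    for i in range(len(s) - 1):
        cut = (s[i] + s[i + 1]) / 2
        low = marker <= cut
        if low.sum() < gmin or (~low).sum() < gmin:
            continue
        z = standardized_logrank_oracle(times, events, low)
        if z > best[0] + 1e-12:
            best = (z, cut)
    return best


def xtile_scan_oracle(marker, times, events, min_group_frac):
    """Exhaustive two-cut scan; returns (best chi2, (c1, c2))."""
    marker = np.asarray(marker, float)
    n = len(marker)
    gmin = int(np.ceil(min_group_frac * n))
    s = np.sort(np.unique(marker))
    best = (-1.0, None)
    for i in range(len(s) - 1):
        c1 = (s[i] + s[i + 1]) / 2
        for j in range(i + 1, len(s) - 1):
            c2 = (s[j] + s[j + 1]) / 2
            lab = np.where(marker <= c1, 0, np.where(marker <= c2, 1, 2))
            counts = np.bincount(lab, minlength=3)
            if counts.min() < gmin:
                continue
            chi2 = logrank_chi2_oracle(times, events, lab)
            if chi2 > best[0] + 1e-9:
                best = (chi2, (c1, c2))
    return best


def random_survival_cohort(rng, n):
    """Marker-linked exponential survival data for oracle comparisons."""
    marker = rng.random(n)
    lam = 0.03 * np.exp(0.8 * (marker - 0.5))
    t_event = rng.exponential(1 / lam)
    t_cens = rng.exponential(60, n)
    times = np.round(np.minimum(t_event, t_cens), 1) + 0.1
    events = (t_event <= t_cens).astype(int)
    return marker, times, events
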
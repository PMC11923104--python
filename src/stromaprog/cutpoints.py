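"""Optimal survival cutpoints for continuous markers.

Two searches are provided, both rank-based and both scanning candidate
thresholds at midpoints between consecutive distinct marker values:

* :func:`maxstat_binary` — the maximally selected rank statistic: the cut
  maximizing the absolute standardized log-rank statistic between the two
  resulting groups, with a Lausen–Schumacher improved-Bonferroni p-value
  that accounts for the multiple looks (optionally a seeded permutation p).
  Used for the lymphocyte fraction (LIP-low vs LIP-high).
* :func:`xtile_two_cut` — an X-tile-style exhaustive search over ordered
  threshold pairs (c1 < c2), maximizing the three-group log-rank chi-square.
  Used for the stroma fraction (SIP-low / SIP-intermediate / SIP-high).
  The maximized chi-square is reported descriptively, without a selection
  correction, and is therefore optimistically biased.

Both searches enforce a minimum group size (fraction of n) and break ties
toward the smallest threshold (lexicographically smallest pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CutpointResult:
    """Selected cut(s), maximized statistic, p-value and group labels."""

    cut_values: tuple
    max_statistic: float
    p_value: float | None
    group_labels: np.ndarray

    def summary(self) -> str:
        cuts = ", ".join(f"{c:.4g}" for c in self.cut_values)
        lines = [
            f"cut value(s): {cuts}",
            f"max statistic: {self.max_statistic:.4f}",
        ]
        if self.p_value is not None:
            lines.append(f"p-value: {self.p_value:.4g}")
        labels, counts = np.unique(self.group_labels, return_counts=True)
        lines.append(
            "groups: " + ", ".join(f"{l}={c}" for l, c in zip(labels, counts))
        )
        return "\n".join(lines)


def logrank(
    times: Sequence[float], events: Sequence[int], labels: Sequence
) -> tuple[float, float]:
    """Log-rank chi-square and p-value for two or more groups."""
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two non-empty groups")
    if events.sum() == 0:
        raise ValueError("log-rank statistic undefined without events")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def _risk_matrices(times: np.ndarray, events: np.ndarray, order: np.ndarray):
    """Prefix at-risk / event matrices over marker rank.

    Returns ``(event_times, n_prefix, d_prefix)`` where for distinct event
    time j and rank r, ``n_prefix[j, r]`` counts at-risk patients among the
    r smallest-marker patients and ``d_prefix[j, r]`` their events at j.
    """
    t_sorted = times[order]
    e_sorted = events[order]
    ev_times = np.unique(times[events == 1])
    at_risk = t_sorted[None, :] >= ev_times[:, None]
    is_event = (t_sorted[None, :] == ev_times[:, None]) & (e_sorted[None, :] == 1)
    n_prefix = np.zeros((len(ev_times), len(times) + 1))
    d_prefix = np.zeros_like(n_prefix)
    np.cumsum(at_risk, axis=1, out=n_prefix[:, 1:])
    np.cumsum(is_event, axis=1, out=d_prefix[:, 1:])
    return ev_times, n_prefix, d_prefix


def _candidate_ranks(marker_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boundary ranks between distinct values and their midpoint cuts."""
    diff = np.nonzero(np.diff(marker_sorted) > 0)[0]
    ranks = diff + 1
    cuts = (marker_sorted[diff] + marker_sorted[diff + 1]) / 2.0
    return ranks, cuts


def lausen_schumacher_p(b: float, minprop: float, maxprop: float) -> float:
    """Improved-Bonferroni approximation of P(sup |Z| > b) over the scan band."""
    if b <= 0:
        return 1.0
    db = stats.norm.pdf(b)
    span = np.log((maxprop * (1 - minprop)) / (minprop * (1 - maxprop)))
    p = db * (b - 1.0 / b) * span + 4.0 * db / b
    return float(min(max(p, 0.0), 1.0))


def maxstat_binary(
    marker: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    min_group_frac: float = 0.10,
    permutations: int = 0,
    seed: int = 0,
) -> CutpointResult:
    """Maximally selected standardized log-rank cutpoint for a marker.

    Scans midpoints between consecutive distinct marker values whose smaller
    side holds at least ``min_group_frac`` of the cohort, and returns the cut
    maximizing |Z|, where Z is the standardized log-rank statistic for the
    marker-low vs marker-high split.  The p-value uses the
    Lausen–Schumacher approximation; if ``permutations > 0`` a seeded
    permutation p-value is computed instead.
    """
    marker = np.asarray(marker, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(marker)
    if n < 10:
        raise ValueError("need at least 10 patients")
    if len(np.unique(marker)) < 2:
        raise ValueError("need at least 2 distinct marker values")
    if events.sum() == 0:
        raise ValueError("no events")

    def scan(mk):
        order = np.argsort(mk, kind="stable")
        ranks, cuts = _candidate_ranks(mk[order])
        gmin = int(np.ceil(min_group_frac * n))
        keep = (ranks >= gmin) & (n - ranks >= gmin)
        ranks, cuts = ranks[keep], cuts[keep]
        if len(ranks) == 0:
            raise ValueError("no admissible candidate cut")
        _, n_pre, d_pre = _risk_matrices(times, events, order)
        n_tot = n_pre[:, -1]
        d_tot = d_pre[:, -1]
        w = d_tot / n_tot
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
        n1 = n_pre[:, ranks]
        d1 = d_pre[:, ranks]
        u = (d1 - n1 * w[:, None]).sum(axis=0)
        frac = n1 / n_tot[:, None]
        v = (c[:, None] * frac * (1 - frac)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(v > 0, np.abs(u) / np.sqrt(v), 0.0)
        best = int(np.argmax(z))  # first (smallest cut) among ties
        return z[best], cuts[best], ranks[best] / n, ranks.min() / n, ranks.max() / n

    z_obs, cut, _, minprop, maxprop = scan(marker)
    if permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            z_p = scan(rng.permutation(marker))[0]
            if z_p >= z_obs:
                count += 1
        p = (1 + count) / (permutations + 1)
    else:
        p = lausen_schumacher_p(z_obs, minprop, maxprop)
    labels = np.where(marker <= cut, "low", "high")
    return CutpointResult((float(cut),), float(z_obs), p, labels)


def xtile_two_cut(
    marker: Sequence[float],
    times: Sequence[float],
    events: Sequence[int],
    min_group_frac: float = 0.10,
) -> CutpointResult:
    """Exhaustive two-threshold search maximizing the 3-group log-rank chi2.

    All ordered candidate pairs (c1 < c2) whose three groups each hold at
    least ``min_group_frac`` of the cohort are scored by the (unadjusted)
    three-group log-rank chi-square; the maximizing pair labels patients
    low / intermediate / high.  The reported p-value is the naive
    chi-square(2 df) tail and is biased by the selection.
    """
    marker = np.asarray(marker, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(marker)
    if n < 15:
        raise ValueError("need at least 15 patients")
    if len(np.unique(marker)) < 3:
        raise ValueError("need at least 3 distinct marker values")
    if events.sum() == 0:
        raise ValueError("no events")

    order = np.argsort(marker, kind="stable")
    ranks, cuts = _candidate_ranks(marker[order])
    gmin = int(np.ceil(min_group_frac * n))
    _, n_pre, d_pre = _risk_matrices(times, events, order)
    n_tot = n_pre[:, -1]
    d_tot = d_pre[:, -1]
    w = d_tot / n_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)

    u_full = (d_pre - n_pre * w[:, None]).sum(axis=0)  # (n+1,)
    a_full = (c[:, None] * n_pre / n_tot[:, None]).sum(axis=0)
    n_tilde = (np.sqrt(c)[:, None] / n_tot[:, None]) * n_pre
    q_full = n_tilde.T @ n_tilde  # (n+1, n+1)

    # admissible candidate ranks for each threshold
    ok1 = (ranks >= gmin) & (n - ranks >= 2 * gmin)
    ok2 = (ranks >= 2 * gmin) & (n - ranks >= gmin)
    r1 = ranks[ok1]
    r2 = ranks[ok2]
    c1s = cuts[ok1]
    c2s = cuts[ok2]
    if len(r1) == 0 or len(r2) == 0:
        raise ValueError("no admissible candidate pair")
    pair_ok = (r2[None, :] - r1[:, None]) >= gmin
    if not pair_ok.any():
        raise ValueError("no admissible candidate pair")

    u1 = u_full[r1][:, None]
    u2 = u_full[r2][None, :] - u_full[r1][:, None]
    q11 = q_full[r1, r1][:, None]
    q22 = q_full[r2, r2][None, :]
    q12 = q_full[np.ix_(r1, r2)]
    v11 = (a_full[r1] - q_full[r1, r1])[:, None]
    v22 = (a_full[r2][None, :] - a_full[r1][:, None]) - (q22 - 2 * q12 + q11)
    v12 = -(q12 - q11)
    det = v11 * v22 - v12**2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (u1**2 * v22 - 2 * u1 * u2 * v12 + u2**2 * v11) / det
    chi2 = np.where(pair_ok & (det > 1e-12), chi2, -np.inf)
    flat = int(np.argmax(chi2))  # row-major: lexicographically smallest pair
    i, j = divmod(flat, chi2.shape[1])
    if not np.isfinite(chi2[i, j]):
        raise ValueError("log-rank statistic degenerate for all candidate pairs")
    c1, c2 = float(c1s[i]), float(c2s[j])
    stat = float(chi2[i, j])
    labels = np.where(marker <= c1, "low", np.where(marker <= c2, "intermediate", "high"))
    p = float(stats.chi2.sf(stat, df=2))
    return CutpointResult((c1, c2), stat, p, labels)


def merge_sip_lh(labels: Sequence) -> np.ndarray:
    """Merge SIP-low and SIP-high into SIP-LH; keep intermediate."""
    labels = np.asarray(labels)
    known = {"low", "intermediate", "high"}
    unknown = set(np.unique(labels)) - known
    if unknown:
        raise ValueError(f"unknown SIP labels: {sorted(unknown)}")
    return np.where(labels == "intermediate", "intermediate", "LH")


def combined_groups(sip_binary: Sequence, lip_binary: Sequence) -> np.ndarray:
    """Combined risk group per patient from SIP and LIP categories.

    Group 1: SIP-intermediate and LIP-high (optimal stroma, high
    lymphocyte infiltration); Group 3: SIP-LH and LIP-low (both
    unfavourable); Group 2: all other combinations.
    """
    sip = np.asarray(sip_binary)
    lip = np.asarray(lip_binary)
    if sip.shape != lip.shape:
        raise ValueError("label arrays must align")
    if not set(np.unique(sip)) <= {"intermediate", "LH"}:
        raise ValueError("sip labels must be 'intermediate' or 'LH'")
    if not set(np.unique(lip)) <= {"high", "low"}:
        raise ValueError("lip labels must be 'high' or 'low'")
    out = np.full(sip.shape, 2, dtype=int)
    out[(sip == "intermediate") & (lip == "high")] = 1
    out[(sip == "LH") & (lip == "low")] = 3
    return out
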
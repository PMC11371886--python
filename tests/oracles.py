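"""Naive brute-force reference implementations used only by the tests.

Each function restates the defining formula of a statistic as directly as
possible (explicit loops, no shared code with the package) so the package
implementations can be checked against an independent computation.
"""

from __future__ import annotations

import math

import numpy as np


def sdnn_naive(x) -> float:
    x = list(map(float, x))
    n = len(x)
    m = sum(x) / n
    return math.sqrt(sum((v - m) ** 2 for v in x) / (n - 1))


def rmssd_naive(x) -> float:
    x = list(map(float, x))
    diffs = [b - a for a, b in zip(x, x[1:])]
    return math.sqrt(sum(d * d for d in diffs) / len(diffs))


def pnn50_naive(x) -> float:
    x = list(map(float, x))
    diffs = [abs(b - a) for a, b in zip(x, x[1:])]
    return 100.0 * sum(1 for d in diffs if d > 50.0) / len(diffs)


def sdann_naive(intervals, times, segment_len=300.0, min_fill=0.5):
    t0 = times[0]
    segments = {}
    for v, t in zip(intervals, times):
        k = int((t - t0) // segment_len)
        segments.setdefault(k, []).append(float(v))
    means = [
        sum(vals) / len(vals)
        for k, vals in sorted(segments.items())
        if sum(vals) / 1000.0 >= min_fill * segment_len
    ]
    if len(means) < 2:
        return None
    return sdnn_naive(means)


def prsa_naive(x, direction, L=2, max_rel=0.05):
    """Anchor-averaged profile and Haar capacity by explicit loops."""
    x = list(map(float, x))
    n = len(x)
    anchors = []
    for i in range(1, n):
        if direction == "deceleration":
            ok = x[i] > x[i - 1]
        else:
            ok = x[i] < x[i - 1]
        if ok and abs(x[i] - x[i - 1]) <= max_rel * x[i - 1]:
            if i - L >= 0 and i + L - 1 <= n - 1:
                anchors.append(i)
    if not anchors:
        return None
    profile = []
    for k in range(-L, L):
        profile.append(sum(x[i + k] for i in anchors) / len(anchors))
    # profile index of offset k is k + L
    cap = (profile[L] + profile[L + 1] - profile[L - 1] - profile[L - 2]) / 4.0
    return cap


def sample_entropy_naive(x, m=2, r=None):
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * np.std(x, ddof=1)
    n_t = len(x) - m
    B = A = 0
    for i in range(n_t):
        for j in range(i + 1, n_t):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                B += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                A += 1
    if B == 0 or A == 0:
        return None
    return -math.log(A / B)


def correlation_sums_naive(points, radii, theiler):
    points = np.asarray(points, dtype=float)
    n = len(points)
    radii = np.asarray(radii, dtype=float)
    counts = np.zeros(len(radii))
    total = 0
    for i in range(n):
        for j in range(n):
            if j - i > theiler:
                d = np.max(np.abs(points[i] - points[j]))
                total += 1
                counts += d < radii
    return counts / total


def breslow_loglik_naive(beta, X, time, event):
    """Breslow partial log-likelihood with explicit risk-set sums."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            denom = sum(math.exp(float(X[j] @ beta)) for j in risk)
            ll += float(X[i] @ beta) - math.log(denom)
    return ll


def cox_beta_grid_oracle(X, time, event, lo=-5.0, hi=5.0, step=1e-4):
    """Single-covariate Cox estimate by grid search on the Breslow likelihood."""
    grid = np.arange(lo, hi + step, step)
    lls = [breslow_loglik_naive([b], X, time, event) for b in grid]
    return float(grid[int(np.argmax(lls))])


def logrank_naive(time, event, group):
    """Textbook two-sample log-rank statistic (standardized)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=bool)
    num = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        Y = at_risk.sum()
        Y1 = (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        num += d1 - Y1 * d / Y
        if Y > 1:
            var += (Y1 / Y) * (1 - Y1 / Y) * d * (Y - d) / (Y - 1)
    if var <= 0:
        return 0.0
    return num / math.sqrt(var)


def km_survival_naive(time, event):
    """Product-limit estimate at each distinct event time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    s = 1.0
    out = []
    for t in sorted(set(time[event == 1])):
        n_at = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1.0 - d / n_at
        out.append((t, s))
    return out


def modwt_naive(x, g, h, levels):
    """MODWT pyramid with explicit loops (circular boundary)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    L = len(g)
    v = x.copy()
    details = []
    for j in range(1, levels + 1):
        step = 2 ** (j - 1)
        w_j = np.zeros(n)
        v_j = np.zeros(n)
        for t in range(n):
            for l in range(L):
                src = v[(t - step * l) % n]
                w_j[t] += h[l] * src
                v_j[t] += g[l] * src
        details.append(w_j)
        v = v_j
    return np.asarray(details)
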
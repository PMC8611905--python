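"""Independent brute-force reference implementations used only by the tests.

Every function here is written as a direct transcription of the defining
formula — explicit Python loops, no shared code with the package — so the
package implementations can be checked against them.
"""

from __future__ import annotations

import math

import numpy as np


def naive_reconstruction(x, x_hat) -> float:
    n = len(x)
    total = 0.0
    for i in range(n):
        for j in range(len(x[i])):
            total += (x[i][j] - x_hat[i][j]) ** 2
    return total / n


def naive_bce(x, x_hat, eps: float = 1e-7) -> float:
    total, count = 0.0, 0
    for i in range(len(x)):
        for j in range(len(x[i])):
            p = min(max(x_hat[i][j], eps), 1.0 - eps)
            total += -(x[i][j] * math.log(p) + (1.0 - x[i][j]) * math.log(1.0 - p))
            count += 1
    return total / count


def naive_clustering(b, centroids) -> float:
    n = len(b)
    total = 0.0
    for i in range(n):
        d2 = sorted(sum((b[i][d] - c[d]) ** 2 for d in range(len(c))) for c in centroids)
        total += d2[0] - d2[1]
    return total / n


def naive_survival(scores, time, event) -> float:
    n = len(scores)
    total = 0.0
    for i in range(n):
        if event[i] == 1:
            risk = [j for j in range(n) if time[j] >= time[i]]
            total += scores[i] - math.log(sum(math.exp(scores[j]) for j in risk))
    return -total


def naive_silhouette(b, labels) -> float:
    b = np.asarray(b, dtype=float)
    labels = list(labels)
    n = len(labels)
    dist = [[math.dist(b[i], b[j]) for j in range(n)] for i in range(n)]
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a_i = sum(dist[i][j] for j in same) / len(same)
        b_i = math.inf
        for other in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            b_i = min(b_i, sum(dist[i][j] for j in members) / len(members))
        scores.append((b_i - a_i) / max(a_i, b_i))
    return float(np.mean(scores))


def naive_cox_loglik(beta, x, time, event) -> float:
    """Breslow partial log-likelihood, direct transcription."""
    n = len(x)
    total = 0.0
    for i in range(n):
        if event[i] == 1:
            risk = [j for j in range(n) if time[j] >= time[i]]
            total += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return total


def naive_farthest_pair(b) -> tuple[int, int]:
    best, pair = -1.0, (0, 1)
    n = len(b)
    for i in range(n):
        for j in range(i + 1, n):
            d = sum((b[i][k] - b[j][k]) ** 2 for k in range(len(b[i])))
            if d > best:
                best, pair = d, (i, j)
    return pair


def naive_km_table(time, event):
    """Product-limit estimate as (event_time, survival) pairs."""
    order = np.argsort(time, kind="stable")
    s = 1.0
    out = []
    for t in sorted(set(np.asarray(time)[np.asarray(event) == 1])):
        at_risk = sum(1 for i in order if time[i] >= t)
        deaths = sum(1 for i in order if time[i] == t and event[i] == 1)
        s *= 1.0 - deaths / at_risk
        out.append((t, s))
    return out
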
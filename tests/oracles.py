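"""Independent oracles used by the test suite.

These are deliberately naive, straight-line implementations kept separate
from the package: a literal transcription of the online clustering loop
without any of the engine's structure, and a dense-linear-algebra GP
posterior.  They must never import from the modules they check beyond the
plain data types.
"""

import numpy as np


def reference_odc(samples, R, M):
    """Literal transcription of the online clustering loop.

    Returns (clusters, outliers) where each cluster is a dict with keys
    ``c`` (center) and ``ticks`` (member ticks in insertion order), and
    outliers is a list of ticks.
    """
    clusters = []
    outliers = []  # list of (tick, x)
    first = True
    for s in samples:
        x = np.asarray(s.x, dtype=float)
        if first:
            clusters.append({"c": x.copy(), "ticks": [s.t], "xs": [x]})
            first = False
            continue
        dists = [np.linalg.norm(x - cl["c"]) for cl in clusters]
        joined = [i for i, d in enumerate(dists) if d <= R]
        if joined:
            for i in joined:
                clusters[i]["ticks"].append(s.t)
                clusters[i]["xs"].append(x)
                if dists[i] <= 2.0 * R / 3.0:
                    n = len(clusters[i]["ticks"])
                    clusters[i]["c"] = (clusters[i]["c"] * (n - 1) + x) / n
        else:
            outliers.append((s.t, x))
            group = [pair for pair in outliers if np.linalg.norm(pair[1] - x) <= R]
            if len(group) >= M:
                xs = [pair[1] for pair in group]
                clusters.append({
                    "c": np.mean(xs, axis=0),
                    "ticks": [t for t, _ in group],
                    "xs": xs,
                })
                kept = {id(pair) for pair in group}
                outliers = [pair for pair in outliers if id(pair) not in kept]
    return clusters, [t for t, _ in outliers]


def matern52(a, b, length_scale, signal_var):
    r = np.linalg.norm(np.asarray(a) - np.asarray(b)) / length_scale
    s = np.sqrt(5.0) * r
    return signal_var * (1.0 + s + s * s / 3.0) * np.exp(-s)


def gp_posterior(Xtr, ytr, xq, length_scale, signal_var, noise_var,
                 jitter=1e-10):
    """Dense-solve GP posterior (Matérn 5/2 + white noise, centered targets).

    Mean: k*^T (K + (noise+jitter) I)^-1 (y - ybar) + ybar
    Var:  (signal + noise) - k*^T (K + (noise+jitter) I)^-1 k*
    """
    Xtr = np.atleast_2d(np.asarray(Xtr, dtype=float))
    ytr = np.asarray(ytr, dtype=float)
    xq = np.atleast_1d(np.asarray(xq, dtype=float))
    n = Xtr.shape[0]
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = matern52(Xtr[i], Xtr[j], length_scale, signal_var)
    K += (noise_var + jitter) * np.eye(n)
    ks = np.array([matern52(xq, Xtr[i], length_scale, signal_var) for i in range(n)])
    ybar = ytr.mean()
    alpha = np.linalg.solve(K, ytr - ybar)
    mean = ks @ alpha + ybar
    var = (signal_var + noise_var) - ks @ np.linalg.solve(K, ks)
    return float(mean), float(var)
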
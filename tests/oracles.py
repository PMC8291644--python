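"""Independent brute-force oracles used by the test suite.

Deliberately written with plain loops / dense linear algebra, sharing no
code paths with the package implementation they check.
"""

import math

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def dense_weights(coords, scheme, band_km=100.0, k=8, row_standardized=True,
                  min_distance_km=1.0):
    """Full n-by-n weight matrix built entry-by-entry."""
    n = len(coords)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = haversine_km(coords[i][0], coords[i][1], coords[j][0], coords[j][1])
    w = np.zeros((n, n))
    if scheme == "inverse_distance":
        for i in range(n):
            for j in range(n):
                if i != j and d[i, j] <= band_km:
                    w[i, j] = 1.0 / max(d[i, j], min_distance_km)
    elif scheme == "distance_band":
        for i in range(n):
            for j in range(n):
                if i != j and d[i, j] <= band_km:
                    w[i, j] = 1.0
    elif scheme == "k_nearest":
        for i in range(n):
            order = sorted((d[i, j], j) for j in range(n) if j != i)
            for _, j in order[:k]:
                w[i, j] = 1.0
    else:
        raise ValueError(scheme)
    if row_standardized:
        for i in range(n):
            s = w[i].sum()
            if s > 0:
                w[i] /= s
    return w


def dense_moran(values, w):
    """Statistic, S0/S1/S2 and randomization moments from a dense matrix."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    z = values - values.mean()
    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    I = (n / s0) * (z @ w @ z) / (z @ z)
    e = -1.0 / (n - 1)
    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    num1 = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
    num2 = b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
    var = (num1 - num2) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e**2
    return {"I": I, "S0": s0, "S1": s1, "S2": s2, "E": e, "Var": var}


def newton_logistic(X, y, tol=1e-12, max_iter=100):
    """Unpenalized logistic MLE by plain Newton-Raphson."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        H = X.T @ (X * (mu * (1 - mu))[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def logistic_deviance(X, y, beta):
    mu = np.clip(1.0 / (1.0 + np.exp(-(X @ beta))), 1e-12, 1 - 1e-12)
    return -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
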
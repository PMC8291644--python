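"""Global Moran's I with spatial weights computed on the fly.

The n-by-n weights matrix is never materialized: observations are
processed in row blocks, each block's weights recomputed from the
coordinates, so peak auxiliary memory is O(block_size * n).  The
statistic, the randomization-assumption moments (via S0, S1, S2) and the
permutation null are all accumulated blockwise and are independent of
the block size.

Supported schemes: row-standardized (or raw) inverse great-circle
distance within a distance band, binary distance band, and k-nearest
neighbours with ties broken toward the lower index.  Coincident points
are handled by flooring distances at ``min_distance_km`` (DHS-style
clusters share coordinates, which would otherwise give infinite inverse-
distance weights).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.stats import norm

from .geo import chord_sq_matrix, chord_to_km, km_to_chord, unit_vectors

logger = logging.getLogger(__name__)

SCHEMES = ("inverse_distance", "k_nearest", "distance_band")


@dataclass
class WeightSpec:
    """Definition of the implied spatial weights matrix."""

    coords: np.ndarray  # (n, 2) lat, lon
    scheme: str = "inverse_distance"
    band_km: float = 100.0
    k: int = 8
    row_standardized: bool = True
    min_distance_km: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        if self.scheme in ("inverse_distance", "distance_band") and self.band_km <= 0:
            raise ValueError("band_km must be positive")
        if self.scheme == "k_nearest" and not 1 <= self.k < self.coords.shape[0]:
            raise ValueError("k must be in [1, n-1]")
        if self.scheme == "inverse_distance":
            logger.info(
                "inverse-distance weights: distances floored at %.3g km for coincident points",
                self.min_distance_km,
            )

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "band_km": self.band_km if self.scheme != "k_nearest" else None,
            "k": self.k if self.scheme == "k_nearest" else None,
            "row_standardized": self.row_standardized,
            "min_distance_km": self.min_distance_km,
        }


@dataclass
class MoranResult:
    I: float
    expectation: float
    variance: float
    z: float
    p_value: float
    method: str
    n: int
    n_permutations: int | None = None
    weight_spec: dict | None = None


def _knn_neighbours(U: np.ndarray, k: int, block_size: int) -> np.ndarray:
    """(n, k) neighbour indices by chord distance, ties to the lower index."""
    n = U.shape[0]
    nbr = np.empty((n, k), dtype=np.int64)
    for lo in range(0, n, block_size):
        hi = min(lo + block_size, n)
        d2 = chord_sq_matrix(U[lo:hi], U)
        rows = np.arange(lo, hi)
        d2[np.arange(hi - lo), rows] = np.inf
        # stable sort on equal distances keeps ascending index order
        nbr[lo:hi] = np.argsort(d2, axis=1, kind="stable")[:, :k]
    return nbr


class _WeightStream:
    """Yields raw weight blocks a[i, :] for i in consecutive row blocks."""

    def __init__(self, spec: WeightSpec, block_size: int):
        self.spec = spec
        self.block_size = max(int(block_size), 1)
        self.U = unit_vectors(spec.coords[:, 0], spec.coords[:, 1])
        self.n = spec.n
        # precomputed pieces of the haversine formula (used for exact
        # distances on within-band pairs; the chord Gram product alone
        # loses precision at short range)
        self._phi = np.radians(spec.coords[:, 0])
        self._lam = np.radians(spec.coords[:, 1])
        self._cosphi = np.cos(self._phi)
        self._nbr = None
        if spec.scheme == "k_nearest":
            self._nbr = _knn_neighbours(self.U, spec.k, self.block_size)

    def _haversine_pairs(self, gi: np.ndarray, gj: np.ndarray) -> np.ndarray:
        s1 = np.sin((self._phi[gj] - self._phi[gi]) / 2.0) ** 2
        s2 = self._cosphi[gi] * self._cosphi[gj] * np.sin((self._lam[gj] - self._lam[gi]) / 2.0) ** 2
        from .geo import EARTH_RADIUS_KM

        return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(s1 + s2)))

    def blocks(self) -> Iterator[tuple[int, int, np.ndarray]]:
        for lo in range(0, self.n, self.block_size):
            hi = min(lo + self.block_size, self.n)
            yield lo, hi, self.raw_block(lo, hi)

    def raw_block(self, lo: int, hi: int) -> np.ndarray:
        spec = self.spec
        b = hi - lo
        if spec.scheme == "k_nearest":
            a = np.zeros((b, self.n))
            a[np.repeat(np.arange(b), spec.k), self._nbr[lo:hi].ravel()] = 1.0
            return a
        d2 = chord_sq_matrix(self.U[lo:hi], self.U)
        cut2 = float(km_to_chord(spec.band_km)) ** 2
        # generous candidate mask from the chord product, then exact
        # haversine distances on the candidates only
        cand = d2 <= cut2 * (1.0 + 1e-6) + 1e-12
        cand[np.arange(b), np.arange(lo, hi)] = False
        ii, jj = np.nonzero(cand)
        km = self._haversine_pairs(lo + ii, jj)
        inside = km <= spec.band_km
        a = np.zeros((b, self.n))
        if spec.scheme == "distance_band":
            a[ii[inside], jj[inside]] = 1.0
        else:
            a[ii[inside], jj[inside]] = 1.0 / np.maximum(km[inside], spec.min_distance_km)
        return a

    def raw_block_transposed(self, lo: int, hi: int, raw: np.ndarray | None = None) -> np.ndarray:
        """(b, n) block of a[j, i] for i in [lo, hi), all j (a columns)."""
        if self.spec.scheme != "k_nearest":
            # symmetric raw weights: reuse the row block when provided
            return raw if raw is not None else self.raw_block(lo, hi)
        b = hi - lo
        pos = np.full(self.n, -1, dtype=np.int64)
        pos[np.arange(lo, hi)] = np.arange(b)
        sel = pos[self._nbr]  # (n, k): local column or -1
        jj, kk = np.nonzero(sel >= 0)
        at = np.zeros((b, self.n))
        at[sel[jj, kk], jj] = 1.0
        return at


def _accumulate(values: np.ndarray, spec: WeightSpec, block_size: int) -> dict:
    """One full streamed pass: cross-product, S0, S1, S2, row/col sums."""
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if spec.n != n:
        raise ValueError("values and coords length mismatch")
    z = values - values.mean()
    z2 = float(z @ z)
    if z2 == 0:
        raise ValueError("constant values: Moran's I is undefined")

    stream = _WeightStream(spec, block_size)

    row_raw = np.empty(n)
    for lo, hi, a in stream.blocks():
        row_raw[lo:hi] = a.sum(axis=1)
    safe_row = np.where(row_raw > 0, row_raw, 1.0)

    S0 = 0.0
    S1 = 0.0
    cross = 0.0
    row_w = np.empty(n)
    col_w = np.zeros(n)
    for lo, hi, a in stream.blocks():
        if spec.row_standardized:
            w = a / safe_row[lo:hi, None]
            wt = stream.raw_block_transposed(lo, hi, raw=a) / safe_row[None, :]
        else:
            w = a
            wt = stream.raw_block_transposed(lo, hi, raw=a)
        S0 += w.sum()
        S1 += 0.5 * ((w + wt) ** 2).sum()
        cross += float(z[lo:hi] @ (w @ z))
        row_w[lo:hi] = w.sum(axis=1)
        col_w += w.sum(axis=0)
    S2 = float(((row_w + col_w) ** 2).sum())
    if S0 == 0:
        raise ValueError("all weights are zero; widen the band or increase k")
    I = (n / S0) * cross / z2
    b2 = n * float((z**4).sum()) / z2**2
    return {"I": I, "S0": S0, "S1": S1, "S2": S2, "n": n, "z": z, "z2": z2, "b2": b2,
            "stream": stream, "safe_row": safe_row}


def moran_statistic(values, spec: WeightSpec, block_size: int = 256) -> float:
    """I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2, streamed in blocks."""
    return _accumulate(values, spec, block_size)["I"]


def _moments_from(acc: dict) -> tuple[float, float]:
    n, S0, S1, S2, b2 = acc["n"], acc["S0"], acc["S1"], acc["S2"], acc["b2"]
    E = -1.0 / (n - 1)
    num1 = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2)
    num2 = b2 * ((n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2)
    var = (num1 - num2) / ((n - 1) * (n - 2) * (n - 3) * S0**2) - E**2
    return E, float(var)


def moran_moments(values, spec: WeightSpec, block_size: int = 256) -> tuple[float, float]:
    """Randomization-assumption E[I] = -1/(n-1) and Var[I] from S0, S1, S2
    and the sample kurtosis, all accumulated blockwise."""
    acc = _accumulate(values, spec, block_size)
    return _moments_from(acc)


def moran_test(
    values,
    spec: WeightSpec,
    method: str = "analytic",
    n_permutations: int = 999,
    seed=None,
    block_size: int = 256,
) -> MoranResult:
    """Two-sided test of no spatial autocorrelation.

    ``analytic`` uses the normal approximation under the randomization
    assumption; ``permutation`` shuffles the values (seeded) and streams
    all permuted cross-products in the same blockwise pass as the
    observed statistic.
    """
    acc = _accumulate(values, spec, block_size)
    E, var = _moments_from(acc)
    I = acc["I"]
    z_stat = (I - E) / np.sqrt(var)
    if method == "analytic":
        p = float(2.0 * norm.sf(abs(z_stat)))
        return MoranResult(I=I, expectation=E, variance=var, z=float(z_stat), p_value=p,
                           method="analytic", n=acc["n"], weight_spec=spec.summary())
    if method != "permutation":
        raise ValueError("method must be 'analytic' or 'permutation'")
    B = int(n_permutations)
    if B < 99:
        raise ValueError("permutation test needs n_permutations >= 99")
    rng = np.random.default_rng(seed)
    n, z = acc["n"], acc["z"]
    Z = np.empty((n, B))
    for b in range(B):
        Z[:, b] = z[rng.permutation(n)]
    cross = np.zeros(B)
    stream, safe_row = acc["stream"], acc["safe_row"]
    for lo, hi, a in stream.blocks():
        w = a / safe_row[lo:hi, None] if spec.row_standardized else a
        cross += np.einsum("bk,bk->k", w @ Z, Z[lo:hi])  # sum_i z_perm_i (Wz_perm)_i
    I_perm = (n / acc["S0"]) * cross / acc["z2"]
    extreme = int(np.count_nonzero(np.abs(I_perm - E) >= abs(I - E) - 1e-15))
    p = (1.0 + extreme) / (B + 1.0)
    return MoranResult(I=I, expectation=E, variance=var, z=float(z_stat), p_value=float(p),
                       method="permutation", n=n, n_permutations=B, weight_spec=spec.summary())
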
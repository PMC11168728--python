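"""Bit-packed evaluation kernels for the Heaviside-kernel (sample-entropy) estimator.

The estimator counts, for every reference sample, how many other samples fall
within a Chebyshev ball of radius ``r`` in the embedding space.  Because the
Chebyshev (maximum-norm) indicator of a joint space factorises into a logical
AND of per-coordinate indicators, the neighbour structure of any embedding
vector set can be represented as the bitwise AND of per-(series, lag) boolean
neighbour matrices.  These kernels store each series' neighbour matrix as
bit-packed uint64 rows (doubled along the column axis so that circularly
shifted lag/surrogate windows are contiguous bit ranges) and evaluate
conditional entropies by AND + popcount, which is what makes greedy
nonuniform-embedding selection with hundreds of surrogates affordable.

Constraint: all windows are taken from a single trial of length ``n`` with a
common analysis range of ``m = n - max_lag`` samples, so a lagged (or
time-shift surrogate) copy of series ``s`` is fully described by a start
offset ``base`` into the doubled bit rows.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_ONE = np.uint64(1)
_FULL = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _pop(v):
    v = v - ((v >> _ONE) & _M1)
    v = (v & _M2) + ((v >> np.uint64(2)) & _M2)
    v = (v + (v >> np.uint64(4))) & _M4
    return (v * _H01) >> np.uint64(56)


@njit(cache=True)
def _build_rows2(x, r, w2p):
    """Neighbour matrix of a 1-d series, rows bit-packed over doubled columns.

    Bit j of row i (j in [0, 2n)) is 1 iff |x[i] - x[j mod n]| <= r.
    """
    n = x.shape[0]
    out = np.zeros((n, w2p), dtype=np.uint64)
    for i in range(n):
        xi = x[i]
        for j in range(2 * n):
            jj = j if j < n else j - n
            d = xi - x[jj]
            if d < 0.0:
                d = -d
            if d <= r:
                out[i, j >> 6] |= _ONE << np.uint64(j & 63)
    return out


@njit(cache=True, inline="always")
def _window_word(row, base, w, wm, lastmask):
    bp = base + (w << 6)
    q = bp >> 6
    sh = np.uint64(bp & 63)
    v = row[q] >> sh
    if sh != np.uint64(0):
        v |= row[q + 1] << (np.uint64(64) - sh)
    if w == wm - 1:
        v &= lastmask
    return v


@njit(cache=True)
def _extract_packed(rows2, base, m, n, wm, lastmask):
    """Packed m x m window matrix for a lag/shift offset ``base``."""
    out = np.empty((m, wm), dtype=np.uint64)
    for a in range(m):
        row = rows2[(base + a) % n]
        for w in range(wm):
            out[a, w] = _window_word(row, base, w, wm, lastmask)
    return out


@njit(cache=True)
def _entropy_packed(jp, m):
    """Sample entropy of a packed neighbour matrix: -(1/m) sum_a ln(c_a / m)."""
    h = 0.0
    wm = jp.shape[1]
    for a in range(m):
        c = np.uint64(0)
        for w in range(wm):
            c += _pop(jp[a, w])
        h -= np.log(c / m)
    return h / m


@njit(cache=True)
def _scan(rows2_all, series_idx, bases, m, n, wm, lastmask, jp, jyp):
    """Joint entropies H(V u c) and H(Y, V u c) for a batch of windows.

    Each window c is (series_idx[k], bases[k]); jp/jyp are the packed
    neighbour matrices of the current conditioning set V and of {Y} u V.
    """
    nc = series_idx.shape[0]
    h1 = np.empty(nc)
    h2 = np.empty(nc)
    for k in range(nc):
        rows2 = rows2_all[series_idx[k]]
        base = bases[k]
        s1 = 0.0
        s2 = 0.0
        for a in range(m):
            row = rows2[(base + a) % n]
            c1 = np.uint64(0)
            c2 = np.uint64(0)
            for w in range(wm):
                v = _window_word(row, base, w, wm, lastmask)
                c1 += _pop(v & jp[a, w])
                c2 += _pop(v & jyp[a, w])
            s1 -= np.log(c1 / m)
            s2 -= np.log(c2 / m)
        h1[k] = s1 / m
        h2[k] = s2 / m
    return h1, h2


def pack_all_ones(m: int) -> np.ndarray:
    wm = (m + 63) // 64
    jp = np.full((m, wm), _FULL, dtype=np.uint64)
    rem = m & 63
    if rem:
        jp[:, -1] = (np.uint64(1) << np.uint64(rem)) - np.uint64(1)
    return jp


class TrialEngine:
    """Packed neighbour matrices for one standardized multichannel trial.

    Parameters
    ----------
    data : (n_channels, n_samples) float array, each channel standardized.
    r : Chebyshev kernel radius (on the standardized scale).
    max_lag : maximum embedding lag; analysis samples are t = max_lag .. n-1.
    """

    def __init__(self, data: np.ndarray, r: float, max_lag: int):
        data = np.ascontiguousarray(data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError("data must be 2-d (channels x samples)")
        self.n_ch, self.n = data.shape
        if max_lag >= self.n:
            raise ValueError(f"max_lag={max_lag} must be < n_samples={self.n}")
        self.max_lag = int(max_lag)
        self.m = self.n - self.max_lag
        if self.m < 10:
            raise ValueError("fewer than 10 analysis samples after lag trimming")
        self.r = float(r)
        self.wm = (self.m + 63) // 64
        rem = self.m & 63
        self.lastmask = (
            (np.uint64(1) << np.uint64(rem)) - np.uint64(1) if rem else _FULL
        )
        w2p = (2 * self.n + 63) // 64 + 1
        self.rows2 = np.empty((self.n_ch, self.n, w2p), dtype=np.uint64)
        for s in range(self.n_ch):
            self.rows2[s] = _build_rows2(data[s], self.r, w2p)

    # -- offsets ---------------------------------------------------------
    def base_for(self, lag: int, shift: int = 0) -> int:
        """Start offset of the window holding x_s[t - lag] for the (optionally
        circularly time-shifted) series, t = max_lag .. n-1."""
        return (self.max_lag - lag - shift) % self.n

    # -- packed windows --------------------------------------------------
    def window(self, series: int, lag: int, shift: int = 0) -> np.ndarray:
        return _extract_packed(
            self.rows2[series], self.base_for(lag, shift), self.m, self.n,
            self.wm, self.lastmask,
        )

    def ones(self) -> np.ndarray:
        return pack_all_ones(self.m)

    # -- entropies -------------------------------------------------------
    def entropy(self, jp: np.ndarray) -> float:
        return _entropy_packed(jp, self.m)

    def scan(self, series_idx, lags, jp, jyp, shifts=None):
        """H(V u c), H(Y, V u c) for candidates (series_idx[k], lags[k]),
        optionally each with its own circular time shift."""
        series_idx = np.asarray(series_idx, dtype=np.int64)
        lags = np.asarray(lags, dtype=np.int64)
        if shifts is None:
            shifts = np.zeros_like(lags)
        else:
            shifts = np.asarray(shifts, dtype=np.int64)
        bases = (self.max_lag - lags - shifts) % self.n
        return _scan(
            self.rows2, series_idx, bases.astype(np.int64), self.m, self.n,
            self.wm, self.lastmask, jp, jyp,
        )

    def joint_packed(self, terms) -> np.ndarray:
        """AND of the packed windows of a list of (series, lag) terms."""
        jp = self.ones()
        for s, lag in terms:
            jp &= self.window(s, lag)
        return jp
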
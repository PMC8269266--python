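"""Maximal information coefficient (MIC).

Classic MINE approximation: for every grid resolution (nx, ny) with
nx * ny <= n^alpha, the y-axis is equipartitioned into ny rows and the
x-axis partition is optimized by dynamic programming over clump boundaries
(clump factor c limits the number of superclumps to c * nx). The
characteristic value is I(X;Y) / log2(min(nx, ny)); MIC is its maximum over
resolutions and both axis orientations, always in [0, 1].

Entropies are in bits. The DP maximizes the column-additive quantity
sum_pq m_pq log2(m_pq / m_p) = -n H(Q|P), which plus H(Q) gives I.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, spearmanr

from .errors import InvalidArgumentError

__all__ = ["mic", "mic_matrix"]


def _equipartition_rows(y: np.ndarray, ny: int) -> np.ndarray:
    """Assign each point a row index, keeping tied y values together."""
    n = len(y)
    order = np.argsort(y, kind="stable")
    rows = np.empty(n, dtype=np.int64)
    target = n / ny
    assigned = 0
    row = 0
    i = 0
    ys = y[order]
    while i < n:
        j = i
        while j < n and ys[j] == ys[i]:
            j += 1
        size = j - i
        if assigned > 0 and row < ny - 1:
            if abs(assigned + size - (row + 1) * target) >= abs(
                assigned - (row + 1) * target
            ):
                row += 1
        rows[order[i:j]] = row
        assigned += size
        i = j
    return rows


def _clump_cumulatives(
    x: np.ndarray, rows: np.ndarray, n_rows: int, max_clumps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Prefix row-counts at clump boundaries along the x-sorted axis.

    Clumps are maximal runs of equal x values; if there are more than
    ``max_clumps`` they are merged into superclumps of near-equal size
    (respecting clump boundaries).
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    rs = rows[order]
    # clump end indices (exclusive)
    ends = list(np.flatnonzero(np.diff(xs) != 0) + 1) + [n]
    if len(ends) > max_clumps:
        merged = []
        target = n / max_clumps
        next_cut = target
        for e in ends:
            if e >= next_cut - 1e-9 or e == n:
                merged.append(e)
                next_cut = e + target
        if merged[-1] != n:
            merged.append(n)
        ends = merged
    k = len(ends)
    cum = np.zeros((n_rows, k + 1), dtype=np.int64)
    start = 0
    for t, e in enumerate(ends, start=1):
        seg = rs[start:e]
        cum[:, t] = cum[:, t - 1] + np.bincount(seg, minlength=n_rows)
        start = e
    return cum, np.array([0] + ends, dtype=np.int64)


def _xlog2x(m: np.ndarray) -> np.ndarray:
    out = np.zeros_like(m, dtype=float)
    pos = m > 0
    out[pos] = m[pos] * np.log2(m[pos])
    return out


def _optimize_axis(
    x: np.ndarray, rows: np.ndarray, n_rows: int, kmax: int, c: int
) -> np.ndarray:
    """Best I(X;Y) (bits) for each number of x bins l = 2..kmax.

    Returns an array indexed by l (entries 0,1 unused).
    """
    n = len(x)
    cum, csum = _clump_cumulatives(x, rows, n_rows, max_clumps=max(c * kmax, kmax))
    k = cum.shape[1] - 1  # number of clumps
    # W[s, t] = sum_q m_q log2 m_q - m log2 m for the column spanning clumps s+1..t
    MQ = cum[:, None, :] - cum[:, :, None]  # (rows, s, t)
    S1 = _xlog2x(MQ).sum(axis=0)
    M = (csum[None, :] - csum[:, None]).astype(float)
    W = S1 - _xlog2x(M)

    neg_inf = -np.inf
    J = np.full((k + 1,), neg_inf)
    for t in range(1, k + 1):
        J[t] = W[0, t]
    best = np.full(kmax + 1, neg_inf)
    if k >= 1:
        best[1] = J[k]
    out = np.zeros(kmax + 1)
    row_tot = cum[:, k].astype(float)
    hq = -(_xlog2x(row_tot).sum() / n) + np.log2(n)
    for l in range(2, kmax + 1):
        Jn = np.full((k + 1,), neg_inf)
        # Jn[t] = max over s in [l-1, t-1] of J[s] + W[s, t]
        with np.errstate(invalid="ignore"):
            cand = J[:, None] + W  # (s, t)
        for t in range(l, k + 1):
            Jn[t] = cand[l - 1 : t, t].max()
        J = Jn
        if k >= l:
            out[l] = hq + J[k] / n
    return out


def mic(x, y, alpha: float = 0.6, c: int = 15) -> float:
    """Maximal information coefficient of two equal-length vectors.

    ``alpha`` bounds the grid search (nx * ny <= n^alpha); ``c`` is the
    superclump factor of the column-optimization DP. Symmetric in its
    arguments; in [0, 1]; invariant to strictly monotone transforms.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise InvalidArgumentError("x and y must have equal length")
    if n < 8:
        raise InvalidArgumentError("need at least 8 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidArgumentError("constant vector has undefined MIC")
    b = max(n**alpha, 4.0)
    max_rows = int(np.floor(b / 2.0))
    score = 0.0
    for u, v in ((x, y), (y, x)):
        for ny in range(2, max_rows + 1):
            kmax = int(np.floor(b / ny))
            if kmax < 2:
                break
            rows = _equipartition_rows(v, ny)
            n_rows = int(rows.max()) + 1
            if n_rows < 2:
                continue
            ivals = _optimize_axis(u, rows, n_rows, kmax, c)
            for l in range(2, kmax + 1):
                denom = np.log2(min(l, ny))
                if denom > 0 and ivals[l] > 0:
                    score = max(score, ivals[l] / denom)
    return float(min(score, 1.0))


def mic_matrix(
    counts: pd.DataFrame,
    alpha: float = 0.6,
    c: int = 15,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """MIC for all OTU pairs with a shared permutation null and BH correction.

    Rows of ``counts`` are OTUs; MIC is computed on per-sample relative
    abundances. The null distribution is shared across pairs: each draw
    permutes the sample order of one member of a (cycled) pair. Returns a
    long table (otu_a, otu_b, mic, rho, p, q).
    """
    if n_perm < 100:
        raise InvalidArgumentError("n_perm must be >= 100")
    rel = (counts / counts.sum(axis=0)).to_numpy(dtype=float)
    ids = list(counts.index)
    pairs = list(itertools.combinations(range(len(ids)), 2))
    if not pairs:
        raise InvalidArgumentError("need at least 2 OTUs")
    rng = np.random.default_rng(seed)

    null = np.empty(n_perm)
    for r in range(n_perm):
        i, j = pairs[r % len(pairs)]
        null[r] = mic(rel[i], rng.permutation(rel[j]), alpha=alpha, c=c)
    null.sort()

    rows = []
    for i, j in pairs:
        m = mic(rel[i], rel[j], alpha=alpha, c=c)
        rho = float(spearmanr(rel[i], rel[j]).statistic)
        n_ge = n_perm - np.searchsorted(null, m - 1e-12, side="left")
        p = (1.0 + n_ge) / (1.0 + n_perm)
        rows.append((ids[i], ids[j], m, rho, p))
    out = pd.DataFrame(rows, columns=["otu_a", "otu_b", "mic", "rho", "p"])
    out["q"] = false_discovery_control(out["p"].to_numpy(), method="bh")
    return out
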
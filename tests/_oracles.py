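"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths: the GRM oracle is a
naive double loop over animal pairs, the REML oracle is a profile
likelihood on the eigen-rotated single-GRM model maximized by bounded
scalar search, and the QTL oracle merges intervals by repeated pairwise
passes.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


def naive_grm(m: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Entrywise double-loop VanRaden method 1 on a coded matrix."""
    n, k = m.shape
    het = p * (1 - p)
    poly = het > 0
    denom = 2.0 * het[poly].sum()
    g = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for l in range(k):
                if not poly[l]:
                    continue
                zi = m[i, l] - 2 * (p[l] - 0.5)
                zj = m[j, l] - 2 * (p[l] - 0.5)
                acc += zi * zj
            g[i, j] = acc / denom
    return g


def single_grm_reml_oracle(
    y: np.ndarray, g: np.ndarray, weights: np.ndarray | None = None
) -> tuple[float, float]:
    """Profile REML on the eigen-rotated model, maximized over the
    variance ratio by bounded search; returns (sigma_g2, sigma_e2)."""
    y = np.asarray(y, float)
    n = y.size
    s = np.sqrt(weights) if weights is not None else np.ones(n)
    yt = s * y
    x = s.copy()
    ks = s[:, None] * np.asarray(g, float) * s[None, :]
    lam, u = np.linalg.eigh(ks)
    lam = np.clip(lam, 0.0, None)
    yr = u.T @ yt
    xr = u.T @ x

    def profile_nll(log_gamma: float) -> float:
        gam = np.exp(log_gamma)
        d = gam * lam + 1.0
        sx = np.sum(xr**2 / d)
        bh = np.sum(xr * yr / d) / sx
        q = np.sum((yr - bh * xr) ** 2 / d)
        return 0.5 * ((n - 1) * np.log(q / (n - 1)) + np.sum(np.log(d)) + np.log(sx) + (n - 1))

    res = minimize_scalar(profile_nll, bounds=(-14, 14), method="bounded",
                          options={"xatol": 1e-12})
    gam = float(np.exp(res.x))
    d = gam * lam + 1.0
    sx = np.sum(xr**2 / d)
    bh = np.sum(xr * yr / d) / sx
    q = np.sum((yr - bh * xr) ** 2 / d)
    sig_e = float(q / (n - 1))
    return gam * sig_e, sig_e


def naive_qtl_merge(
    positions: list[tuple[int, int, int]], flank: int
) -> list[tuple[int, int, int]]:
    """Repeated pairwise merging of (chrom, start, end) variants whose
    inter-variant distance is <= flank; returns merged member spans."""
    clusters = [[v] for v in positions]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if _cluster_close(clusters[i], clusters[j], flank):
                    clusters[i] = clusters[i] + clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    out = []
    for cl in clusters:
        chrom = cl[0][0]
        out.append((chrom, min(v[1] for v in cl), max(v[2] for v in cl)))
    return sorted(out)


def _cluster_close(a, b, flank):
    for ca, sa, ea in a:
        for cb, sb, eb in b:
            if ca == cb and max(sa, sb) - min(ea, eb) <= flank:
                return True
    return False


def naive_overlaps(
    windows: list[tuple[int, int, int]], genes: list[tuple[int, int, int, str]]
) -> list[set]:
    """All-pairs 1-based inclusive interval overlap."""
    out = []
    for wc, ws, we in windows:
        hits = {name for gc, gs, ge, name in genes if gc == wc and gs <= we and ge >= ws}
        out.append(hits)
    return out
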
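"""Daubechies multilevel wavelet decomposition and per-level log-energy features.

The decomposition is the classic orthonormal DWT with *periodized* (circular)
convolution.  Periodization keeps the transform unitary at every level whose
input length is even, so the level energies satisfy Parseval's identity
exactly: the sum over levels of (coefficient count x mean-square) equals the
window's total energy.  That identity is what makes the per-level energy a
well-defined partition of signal power across dyadic frequency bands.

Daubechies scaling filters are constructed by spectral factorization of the
Bernstein polynomial (extremal-phase choice: roots inside the unit circle),
so any order is available without tabulated coefficients.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "daubechies_filters",
    "dwt_periodized",
    "wavedec_periodized",
    "max_feasible_level",
    "wavelet_level_features",
    "level_energies",
]


@lru_cache(maxsize=32)
def daubechies_filters(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Return the (dec_lo, dec_hi) analysis filter pair for db<order>.

    ``order`` is the number of vanishing moments; the filters have length
    2*order.  Built by spectral factorization: |m0|^2 is fixed by the
    Daubechies Bernstein polynomial, and the minimum-phase square root
    (all roots inside the unit circle) is taken.  For order 1 this is the
    Haar pair.
    """
    if order < 1:
        raise ValueError("Daubechies order must be >= 1")
    N = order
    if N == 1:
        h = np.array([1.0, 1.0]) / np.sqrt(2.0)
    else:
        # P(y) = sum_k C(N-1+k, k) y^k ; y = sin^2(w/2)
        from math import comb

        P = np.array([comb(N - 1 + k, k) for k in range(N)], dtype=float)
        yroots = np.roots(P[::-1])  # np.roots wants highest degree first
        # each root y maps to a quadratic in z: z^2 - (2 - 4y) z + 1 = 0
        zkeep = []
        for y in yroots:
            zs = np.roots([1.0, 4.0 * y - 2.0, 1.0])
            zkeep.append(zs[np.argmin(np.abs(zs))])  # minimum-phase root
        # h(z) ~ (1+z)^N * prod (z - z_i); normalize to sum h = sqrt(2)
        h = np.array([1.0 + 0j])
        for _ in range(N):
            h = np.convolve(h, [1.0, 1.0])
        for z in zkeep:
            h = np.convolve(h, [1.0, -z])
        h = np.real(h)
        h *= np.sqrt(2.0) / h.sum()
    # quadrature mirror: g[n] = (-1)^n h[L-1-n]
    L = h.size
    g = h[::-1] * ((-1.0) ** np.arange(L))
    return h, g


def dwt_periodized(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """One circular DWT step along the last axis (length must be even).

    a[k] = sum_m lo[m] * x[(2k + 1 - m) mod n], and likewise for the detail
    band with the high-pass filter; each output has length n/2.  Unitary for
    any even n (the wrapped filter bank stays orthonormal).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n < 2 or n % 2:
        raise ValueError(f"periodized DWT needs an even window length >= 2, got {n}")
    lo, hi = daubechies_filters(order)
    L = lo.size
    k = np.arange(n // 2)[:, None]
    idx = (2 * k + 1 - np.arange(L)[None, :]) % n  # (n/2, L) gather table
    windows = x[..., idx]
    return windows @ lo, windows @ hi


def max_feasible_level(n: int) -> int:
    """Deepest level reachable by halving ``n`` while the length stays even
    (the 2-adic valuation of n).  Beyond this the circular transform is no
    longer defined, whatever the filter order."""
    lvl = 0
    while n >= 2 and n % 2 == 0:
        n //= 2
        lvl += 1
    return lvl


def wavedec_periodized(x: np.ndarray, level: int, order: int) -> list[np.ndarray]:
    """Multilevel circular decomposition along the last axis.

    Returns ``[d1, d2, ..., dJ, aJ]`` with J = min(level, feasible); detail
    bands ordered fine-to-coarse, final approximation last.  Vectorized over
    leading axes.
    """
    x = np.asarray(x, dtype=float)
    J = min(level, max_feasible_level(x.shape[-1]))
    details = []
    a = x
    for _ in range(J):
        a, d = dwt_periodized(a, order)
        details.append(d)
    return details + [a]


def level_energies(window: np.ndarray, level: int, order: int) -> np.ndarray:
    """Mean-square coefficient energy per band: levels 1..J details then the
    approximation; infeasible levels (J < level) padded with 0.  Shape
    (..., level+1).  Vectorized over leading axes."""
    window = np.asarray(window, dtype=float)
    coeffs = wavedec_periodized(window, level, order)
    J = len(coeffs) - 1
    out = np.zeros(window.shape[:-1] + (level + 1,))
    for j, c in enumerate(coeffs[:-1]):
        out[..., j] = np.mean(c * c, axis=-1)
    out[..., level] = np.mean(coeffs[-1] ** 2, axis=-1)
    return out


def wavelet_level_features(
    window: np.ndarray, level: int, order: int = 4, eps: float = 1e-12
) -> np.ndarray:
    """Per-level log-energy feature vector of length ``level + 1``.

    Entry j (0-based, j < level) is log10(eps + mean-square detail
    coefficient at level j+1); the last entry is the same statistic on the
    final approximation band.  A constant window therefore yields
    log10(eps) in every detail entry (the Daubechies vanishing moment
    annihilates constants) while the approximation entry carries the DC
    energy.  Levels beyond dyadic feasibility of the window are reported as
    log10(eps): zero information, but the output length is always level+1.
    """
    window = np.asarray(window, dtype=float)
    if window.shape[-1] < 2:
        raise ValueError("window must contain at least 2 samples")
    if level < 0:
        raise ValueError("wavelet level must be >= 0")
    if eps <= 0:
        raise ValueError("energy_epsilon must be positive")
    return np.log10(eps + level_energies(window, level, order))
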
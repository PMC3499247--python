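"""Shared low-level helpers: sequence ops, sliding window sums, IUPAC codes."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC degeneracy codes mapped to the set of bases they admit.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def window_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Centered sliding-window sum.

    ``out[i] = sum(x[i - w//2 : i - w//2 + w])`` with the window clipped at the
    array bounds, so edge positions sum over a truncated window.
    """
    if w <= 0:
        raise ValueError(f"window must be > 0, got {w}")
    n = x.shape[0]
    c = np.concatenate(([0.0], np.cumsum(x, dtype=np.float64)))
    idx = np.arange(n)
    lo = np.clip(idx - w // 2, 0, n)
    hi = np.clip(idx - w // 2 + w, 0, n)
    return c[hi] - c[lo]


def moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with truncated edge windows (same length as x)."""
    if w <= 1:
        return np.asarray(x, dtype=float)
    n = x.shape[0]
    sums = window_sum(np.asarray(x, dtype=float), w)
    idx = np.arange(n)
    lo = np.clip(idx - w // 2, 0, n)
    hi = np.clip(idx - w // 2 + w, 0, n)
    return sums / np.maximum(hi - lo, 1)


def iupac_matches(code: str, base: str) -> bool:
    """True if ``base`` is admitted by the IUPAC ``code``."""
    return base in IUPAC.get(code, "")
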
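"""Data-dependent knockoff thresholds and selected sets.

The threshold at target level q scans the positive magnitudes t in
{|W_j| : W_j != 0} in increasing order and picks the smallest t whose
estimated false-discovery ratio

    (#{j : W_j <= -t} + offset) / max(#{j : W_j >= t}, 1)

is <= q, with offset 0 (standard knockoff, approximate FDR control) or 1
(knockoff+, exact finite-sample control).  If no candidate qualifies the
threshold is +inf and nothing is selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = ["SelectionResult", "knockoff_threshold", "select"]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of thresholding one W vector at level q."""

    q: float
    threshold: float
    selected: NDArray  # sorted 0-based indices
    plus: bool

    @property
    def n_selected(self) -> int:
        return int(self.selected.size)

    def selected_set(self) -> frozenset[int]:
        return frozenset(int(j) for j in self.selected)


def _check_w_q(W, q):
    W = np.asarray(W, dtype=float).ravel()
    if not np.all(np.isfinite(W)):
        raise ValueError("W must be finite")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    return W


def knockoff_threshold(W: ArrayLike, q: float, plus: bool = False) -> float:
    """Smallest candidate t with (plus-adjusted) negative/positive ratio <= q.

    Candidates are the strictly positive magnitudes |W_j|; zero-valued W carry
    no evidence and are never selectable.  Returns +inf when no candidate
    qualifies (an empty selection, not an error).
    """
    W = _check_w_q(W, q)
    offset = 1 if plus else 0
    candidates = np.unique(np.abs(W[W != 0]))
    for t in candidates:  # ascending: first hit is the minimum
        neg = int(np.sum(W <= -t))
        pos = int(np.sum(W >= t))
        if (neg + offset) / max(pos, 1) <= q:
            return float(t)
    return np.inf


def select(W: ArrayLike, q: float, plus: bool = False) -> SelectionResult:
    """Threshold W at level q and return the selected index set."""
    W = _check_w_q(W, q)
    t = knockoff_threshold(W, q, plus=plus)
    selected = np.flatnonzero(W >= t) if np.isfinite(t) else np.array([], dtype=int)
    return SelectionResult(q=float(q), threshold=t, selected=selected, plus=bool(plus))
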
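"""Aggregation of repeated knockoff runs (the AKO scheme).

The knockoff (or knockoff+) filter is run k times at per-run target levels
q_1 >= ... >= q_k, each with a fresh knockoff draw, and the selected sets are
combined by union.  When the levels sum to the total target q, FDR control of
the union follows from subadditivity of the per-run knockoff+ guarantees:

    FDR(union) <= sum_i FDR(run i) <= sum_i q_i = q.

The recommended halving schedule q_i = q / 2^{i-1} slightly oversums
(sum = q (2 - 2^{1-k})) but works well in practice; the "strict" schedule
rescales it so the levels sum to q exactly, giving the certified bound.
With k = 1 the scheme reduces to the plain knockoff filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .knockoffs import (
    KnockoffModel,
    build_knockoff_model,
    compute_s_vector,
    estimate_covariance,
    sample_knockoffs,
)
from .selection import SelectionResult, select
from .statistics import KnockoffStatistics, compute_statistics

__all__ = [
    "LevelSchedule",
    "AggregationResult",
    "make_schedule",
    "aggregate_knockoffs",
]

DEFAULT_K = 5
DEFAULT_Q = 0.1


@dataclass(frozen=True)
class LevelSchedule:
    """Per-run target levels q_1..q_k for a total budget q."""

    q: float
    k: int
    levels: NDArray
    mode: str

    def __iter__(self):
        return iter(self.levels)


@dataclass(frozen=True)
class AggregationResult:
    """Union selection with the per-run results that produced it."""

    union_selected: NDArray  # sorted 0-based indices
    per_run: list[SelectionResult]
    schedule: LevelSchedule
    plus: bool
    statistics: list[KnockoffStatistics]

    def union_set(self) -> frozenset[int]:
        return frozenset(int(j) for j in self.union_selected)


def make_schedule(q: float, k: int = DEFAULT_K, mode: str = "geometric") -> LevelSchedule:
    """Build the halving level schedule.

    ``"geometric"`` gives q_i = q / 2^{i-1} (the practical recommendation);
    ``"strict"`` rescales the same sequence to sum to q exactly, which is the
    schedule under which the union FDR bound is certified.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must lie in (0, 1], got {q}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    geometric = q / 2.0 ** np.arange(k)
    if mode == "geometric":
        levels = geometric
    elif mode == "strict":
        levels = geometric / (2.0 - 2.0 ** (1 - k))
    else:
        raise ValueError(f"unknown schedule mode {mode!r}; use 'geometric' or 'strict'")
    return LevelSchedule(q=float(q), k=int(k), levels=levels, mode=mode)


def derive_run_seeds(seed: int, k: int) -> list[np.random.SeedSequence]:
    """Deterministic child seed streams, one per knockoff run."""
    return list(np.random.SeedSequence(seed).spawn(k))


def _resolve_model(X: NDArray, sigma, s_method: str) -> KnockoffModel:
    if isinstance(sigma, str):
        if sigma != "estimate":
            raise ValueError(f"sigma must be a matrix or 'estimate', got {sigma!r}")
        sigma = estimate_covariance(X, method="shrinkage")
    a = compute_s_vector(sigma, method=s_method)
    return build_knockoff_model(sigma, a)


def aggregate_knockoffs(
    X: ArrayLike,
    y: ArrayLike,
    sigma: ArrayLike | str = "estimate",
    q: float = DEFAULT_Q,
    k: int = DEFAULT_K,
    loss: str = "linear",
    plus: bool = True,
    mode: str = "geometric",
    seed: int = 0,
    shared_knockoffs: bool = False,
    s_method: str = "equi",
    n_grid: int = 100,
) -> AggregationResult:
    """Run the knockoff filter k times and take the union of selections.

    Parameters
    ----------
    X, y
        Design matrix (n x p) and outcomes (continuous for ``loss="linear"``,
        binary 0/1 for ``loss="logistic"``).
    sigma
        Known row covariance, or ``"estimate"`` for Ledoit-Wolf shrinkage
        estimation from X.
    q, k, mode
        Total FDR budget, number of runs, and level schedule mode.
    plus
        Use the knockoff+ threshold (exact finite-sample FDR control).
    seed
        Master seed; run i draws its knockoffs from a deterministically
        derived child stream, so results are fully reproducible.
    shared_knockoffs
        Reuse the first run's knockoff matrix in every run (ablation option);
        the default draws a fresh knockoff matrix per run.
    """
    X = np.asarray(X, dtype=float)
    schedule = make_schedule(q, k, mode)
    model = _resolve_model(X, sigma, s_method)
    seeds = derive_run_seeds(seed, k)
    per_run: list[SelectionResult] = []
    stats_list: list[KnockoffStatistics] = []
    X_tilde_shared = None
    for i, q_i in enumerate(schedule.levels):
        if shared_knockoffs and X_tilde_shared is not None:
            X_tilde = X_tilde_shared
        else:
            X_tilde = sample_knockoffs(X, model, seeds[i])
            if shared_knockoffs:
                X_tilde_shared = X_tilde
        stats = compute_statistics(X, X_tilde, y, loss=loss, n_grid=n_grid)
        per_run.append(select(stats.W, q_i, plus=plus))
        stats_list.append(stats)
    union = sorted(set().union(*(r.selected_set() for r in per_run)))
    return AggregationResult(
        union_selected=np.asarray(union, dtype=int),
        per_run=per_run,
        schedule=schedule,
        plus=bool(plus),
        statistics=stats_list,
    )
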
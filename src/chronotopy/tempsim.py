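"""Dynamic-time-warping similarity of composition-vs-time (or rank) curves.

Cell-type proportion curves sampled at fine time resolution lack replicate
series, so ordinary per-timepoint tests do not apply.  Instead, the distance
between two curves is measured by dynamic time warping (DTW) — a dynamic
program that elastically but monotonically aligns the two index axes — and
its significance by a permutation null in which the value orderings of the
curves are shuffled and the distance recomputed.

The permutation p-value is the proportion of permuted distances strictly
greater than the observed distance.  The test is two-sided in interpretation:
p close to 0 means the curves are farther apart than chance, while p close to
1 means they are *closer* than chance (e.g. identical curves give p = 1).

The DTW variant used here is the plain textbook form: local cost
``|a_i - b_j|``, unit-weight steps {diagonal, down, right}, no window, and an
unnormalized accumulated cost.  The variant is recorded in each result's
``step_pattern`` tag.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "CompositionSeries",
    "DTWResult",
    "PermutationTestResult",
    "composition_timeseries",
    "dtw_distance",
    "dtw_permutation_test",
    "pairwise_dtw",
]

STEP_PATTERN = "abs-diff local cost; unit-weight symmetric steps; unnormalized"


@dataclass(frozen=True)
class CompositionSeries:
    """One labeled curve: values over an ordered grid (timepoints or ranks)."""

    label: str
    x: np.ndarray
    v: np.ndarray
    compositional: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        if self.x.ndim != 1 or self.x.shape != self.v.shape:
            raise ValueError("x and v must be 1-D arrays of equal length")
        if len(self.x) < 2:
            raise ValueError("a series needs at least two points")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("x grid must be strictly increasing")
        if self.compositional and (self.v.min() < -1e-12 or self.v.max() > 1 + 1e-12):
            raise ValueError("compositional values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class DTWResult:
    distance: float
    path: tuple[tuple[int, int], ...]
    step_pattern: str = STEP_PATTERN


@dataclass(frozen=True)
class PermutationTestResult:
    observed: float
    n_perm: int
    n_greater: int
    p: float
    seed: int | None
    exhaustive: bool
    shuffle_mode: str
    null_distances: np.ndarray | None = field(default=None, repr=False)


def _values(series) -> np.ndarray:
    if isinstance(series, CompositionSeries):
        return series.v
    return np.asarray(series, dtype=float)


def composition_timeseries(labels: pd.DataFrame) -> list[CompositionSeries]:
    """Per-timepoint cell-type fractions from per-cell (timepoint, type) labels.

    Builds the contingency table of types by timepoint, normalizes each
    timepoint to fractions (so fractions sum to 1 per timepoint), and returns
    one series per type over the shared timepoint grid.
    """
    if not {"timepoint", "type"} <= set(labels.columns):
        raise ValueError("expected columns 'timepoint' and 'type'")
    if labels.empty:
        raise ConfigurationError("no cells supplied")
    table = pd.crosstab(labels["timepoint"], labels["type"], normalize="index")
    table = table.sort_index()
    grid = table.index.to_numpy(dtype=float)
    return [
        CompositionSeries(
            label=str(col), x=grid, v=table[col].to_numpy(), compositional=True
        )
        for col in table.columns
    ]


def dtw_distance(a, b) -> DTWResult:
    """Textbook DTW distance with a backtracked optimal alignment path.

    Ties during backtracking prefer the diagonal step, then the vertical one;
    the distance itself is tie-independent.
    """
    av, bv = _values(a), _values(b)
    if len(av) < 2 or len(bv) < 2:
        raise ValueError("DTW requires series of length >= 2")
    n, m = len(av), len(bv)
    cost = np.abs(av[:, None] - bv[None, :])
    acc = np.empty((n, m))
    acc[0, 0] = cost[0, 0]
    acc[0, 1:] = cost[0, 1:].cumsum() + cost[0, 0]
    acc[:, 0] = cost[:, 0].cumsum()
    for i in range(1, n):
        for j in range(1, m):
            acc[i, j] = cost[i, j] + min(acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1])
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            options = (
                (acc[i - 1, j - 1], i - 1, j - 1),
                (acc[i - 1, j], i - 1, j),
                (acc[i, j - 1], i, j - 1),
            )
            _, i, j = min(options, key=lambda t: t[0])
        path.append((i, j))
    return DTWResult(distance=float(acc[-1, -1]), path=tuple(reversed(path)))


def _dtw_batch(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """DTW distances for B many pairs at once: A is (k, n), B is (k, m)."""
    k, n = A.shape
    m = B.shape[1]
    prev = np.empty((k, m))
    cur = np.empty((k, m))
    prev[:, 0] = np.abs(A[:, 0] - B[:, 0])
    for j in range(1, m):
        prev[:, j] = prev[:, j - 1] + np.abs(A[:, 0] - B[:, j])
    for i in range(1, n):
        cur[:, 0] = prev[:, 0] + np.abs(A[:, i] - B[:, 0])
        for j in range(1, m):
            best = np.minimum(np.minimum(prev[:, j - 1], prev[:, j]), cur[:, j - 1])
            cur[:, j] = best + np.abs(A[:, i] - B[:, j])
        prev, cur = cur, prev
    return prev[:, -1].copy()


def _exhaustive_orderings(n: int) -> Iterable[tuple[int, ...]]:
    return itertools.permutations(range(n))


def dtw_permutation_test(
    a,
    b,
    n_perm: int = 100_000,
    seed: int | None = None,
    shuffle: str = "both",
    batch_size: int = 4096,
) -> PermutationTestResult:
    """Permutation test on the DTW distance between two curves.

    Each permutation independently shuffles the value ordering of both curves
    (``shuffle="both"``, the default) or of the second curve only
    (``shuffle="b_only"``); the x-grids are irrelevant to the distance.  The
    p-value is the proportion of permuted distances strictly greater than the
    observed distance (ties count as not greater).  When the total number of
    distinct orderings does not exceed ``n_perm``, all of them — including the
    identity — are enumerated exactly and the result is flagged exhaustive.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if shuffle not in ("both", "b_only"):
        raise ConfigurationError("shuffle must be 'both' or 'b_only'")
    av, bv = _values(a), _values(b)
    if len(av) < 3 or len(bv) < 3:
        raise ValueError("permutation testing requires series of length >= 3")
    observed = dtw_distance(av, bv).distance
    n, m = len(av), len(bv)

    total = math.factorial(m) * (math.factorial(n) if shuffle == "both" else 1)
    if total <= n_perm:
        if shuffle == "both":
            pairs = itertools.product(_exhaustive_orderings(n), _exhaustive_orderings(m))
            A = np.empty((total, n))
            B = np.empty((total, m))
            for k, (pa, pb) in enumerate(pairs):
                A[k] = av[list(pa)]
                B[k] = bv[list(pb)]
        else:
            A = np.tile(av, (total, 1))
            B = np.array([bv[list(p)] for p in _exhaustive_orderings(m)])
        null = _dtw_batch(A, B)
        n_greater = int((null > observed).sum())
        return PermutationTestResult(
            observed=observed,
            n_perm=total,
            n_greater=n_greater,
            p=n_greater / total,
            seed=seed,
            exhaustive=True,
            shuffle_mode=shuffle,
            null_distances=null,
        )

    rng = np.random.default_rng(seed)
    nulls = []
    remaining = n_perm
    while remaining > 0:
        k = min(batch_size, remaining)
        if shuffle == "both":
            A = rng.permuted(np.tile(av, (k, 1)), axis=1)
        else:
            A = np.tile(av, (k, 1))
        B = rng.permuted(np.tile(bv, (k, 1)), axis=1)
        nulls.append(_dtw_batch(A, B))
        remaining -= k
    null = np.concatenate(nulls)
    n_greater = int((null > observed).sum())
    return PermutationTestResult(
        observed=observed,
        n_perm=n_perm,
        n_greater=n_greater,
        p=n_greater / n_perm,
        seed=seed,
        exhaustive=False,
        shuffle_mode=shuffle,
        null_distances=null,
    )


def pairwise_dtw(
    series: Sequence[CompositionSeries],
    n_perm: int = 100_000,
    seed: int | None = None,
    shuffle: str = "both",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance and permutation-p matrices over every pair of curves.

    Off-diagonal entries equal the single-pair test run at a matched sub-seed:
    pair (i, j) with i < j (row-major order) uses the k-th spawned child of
    ``seed``.  The diagonal is 0 distance and p = 1 by the zero-self-distance
    convention (no permutations are spent on it).
    """
    if len(series) < 2:
        raise ValueError("need at least two series")
    labels = [s.label for s in series]
    k = len(series)
    n_pairs = k * (k - 1) // 2
    children = np.random.SeedSequence(seed).spawn(n_pairs)
    dist = np.zeros((k, k))
    pmat = np.ones((k, k))
    pair_idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            sub_seed = int(children[pair_idx].generate_state(1)[0] % (2**31))
            pair_idx += 1
            res = dtw_permutation_test(
                series[i], series[j], n_perm=n_perm, seed=sub_seed, shuffle=shuffle
            )
            dist[i, j] = dist[j, i] = res.observed
            pmat[i, j] = pmat[j, i] = res.p
    return (
        pd.DataFrame(dist, index=labels, columns=labels),
        pd.DataFrame(pmat, index=labels, columns=labels),
    )
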
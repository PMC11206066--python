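"""Fixed-margin matrix randomisation kernels.

Two null-model samplers over non-negative matrices:

* count quasiswap — preserves row sums, column sums, grand total and fill
  (number of nonzero cells).  Each draw starts from an independent
  fixed-margin random table (label-pairing construction, equivalent to
  Patefield's algorithm) whose fill is then repaired by 2x2 quasiswap
  moves until it matches the original.
* binary trial-swap — a Markov chain over 0/1 matrices with fixed row and
  column sums, mixing by checkerboard swaps.  The proposal is symmetric so
  the stationary distribution is uniform over all fixed-margin tables.

Inner loops are plain Python over list-of-lists state; this is fast enough
for the matrix sizes used here (hundreds of rows, ~100 columns).
"""

from __future__ import annotations

import warnings
from collections.abc import Iterator

import numpy as np

__all__ = ["random_fixed_margin_table", "quasiswap_count_matrices", "quasiswap_binary_matrices"]


def random_fixed_margin_table(
    row_sums: np.ndarray, col_sums: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw a random contingency table with the given margins.

    Pairs the multiset of row labels with a shuffled multiset of column
    labels; the resulting table follows the multivariate hypergeometric
    (Fisher) distribution conditional on both margins.
    """
    row_sums = np.asarray(row_sums, dtype=np.int64)
    col_sums = np.asarray(col_sums, dtype=np.int64)
    if row_sums.sum() != col_sums.sum():
        raise ValueError("row and column sums must have equal totals")
    rows = np.repeat(np.arange(len(row_sums)), row_sums)
    cols = np.repeat(np.arange(len(col_sums)), col_sums)
    rng.shuffle(cols)
    out = np.zeros((len(row_sums), len(col_sums)), dtype=np.int64)
    np.add.at(out, (rows, cols), 1)
    return out


class _NonzeroSet:
    """Flat-index set of nonzero cells with O(1) add/remove/random-pick."""

    def __init__(self, matrix: np.ndarray):
        self.items: list[int] = [int(x) for x in np.flatnonzero(matrix)]
        self.pos: dict[int, int] = {v: i for i, v in enumerate(self.items)}

    def __len__(self) -> int:
        return len(self.items)

    def add(self, idx: int) -> None:
        self.pos[idx] = len(self.items)
        self.items.append(idx)

    def remove(self, idx: int) -> None:
        i = self.pos.pop(idx)
        last = self.items.pop()
        if last != idx:
            self.items[i] = last
            self.pos[last] = i


def _repair_fill(
    a: np.ndarray, target_fill: int, rng: np.random.Generator, max_steps: int
) -> bool:
    """Apply 2x2 quasiswap moves in place until fill equals *target_fill*.

    Returns True on success. Moves preserve both margins; fill-reducing
    moves merge mass into already-occupied cells, fill-increasing moves
    split mass into empty cells.
    """
    n_rows, n_cols = a.shape
    mat = a.tolist()
    nz = _NonzeroSet(a)
    fill = len(nz)
    randbuf = rng.random(8192)
    ri = 0
    for _ in range(max_steps):
        if fill == target_fill:
            break
        if ri + 2 > len(randbuf):
            randbuf = rng.random(8192)
            ri = 0
        p = nz.items[int(randbuf[ri] * fill)]
        q = nz.items[int(randbuf[ri + 1] * fill)]
        ri += 2
        i, j = divmod(p, n_cols)
        k, l = divmod(q, n_cols)
        if i == k or j == l:
            continue
        aij = mat[i][j]
        akl = mat[k][l]
        ail = mat[i][l]
        akj = mat[k][j]
        if fill > target_fill:
            # merge: move min(aij, akl) onto the (already filled) anti-diagonal
            if ail == 0 or akj == 0:
                continue
            d = aij if aij < akl else akl
            mat[i][j] = aij - d
            mat[k][l] = akl - d
            mat[i][l] = ail + d
            mat[k][j] = akj + d
            if aij == d:
                nz.remove(p)
                fill -= 1
            if akl == d:
                nz.remove(q)
                fill -= 1
        else:
            # split: move one unit into at least one empty cell, no emptying
            if aij < 2 or akl < 2:
                continue
            gain = (ail == 0) + (akj == 0)
            if gain == 0:
                continue
            mat[i][j] = aij - 1
            mat[k][l] = akl - 1
            mat[i][l] = ail + 1
            mat[k][j] = akj + 1
            if ail == 0:
                nz.add(i * n_cols + l)
            if akj == 0:
                nz.add(k * n_cols + j)
            fill += gain
    else:
        return False
    a[:] = np.asarray(mat, dtype=np.int64)
    return fill == target_fill


def quasiswap_count_matrices(
    counts: np.ndarray,
    n: int,
    seed: int | np.random.Generator,
    max_steps: int | None = None,
    max_restarts: int = 10,
) -> Iterator[np.ndarray]:
    """Yield *n* independent count-quasiswap null matrices.

    Every draw preserves row sums, column sums, grand total and fill of
    *counts*.  ``max_steps`` bounds the repair trials per draw; the default
    (30,000, scaled up for large matrices) is almost always enough — the
    draw is restarted from a fresh random table if not.  Matrices with no
    swappable 2x2 configuration (e.g. a single row) are returned unchanged
    with a warning.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 2 or (counts < 0).any():
        raise ValueError("counts must be a non-negative 2-D integer matrix")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    target_fill = int(np.count_nonzero(counts))
    if max_steps is None:
        max_steps = max(30_000, 60 * counts.size)
    degenerate = min(counts.shape) < 2 or np.count_nonzero(row_sums) < 2 or np.count_nonzero(col_sums) < 2
    if degenerate:
        warnings.warn("matrix has no swappable 2x2 configuration; returning originals")
        for _ in range(n):
            yield counts.copy()
        return
    for _ in range(n):
        for _attempt in range(max_restarts):
            a = random_fixed_margin_table(row_sums, col_sums, rng)
            if _repair_fill(a, target_fill, rng, max_steps):
                break
        else:
            raise RuntimeError(
                f"could not restore fill {target_fill} within {max_steps} steps "
                f"after {max_restarts} restarts"
            )
        yield a


def quasiswap_binary_matrices(
    incidence: np.ndarray,
    n: int,
    seed: int | np.random.Generator,
    burnin: int | None = None,
    thin: int | None = None,
) -> Iterator[np.ndarray]:
    """Yield *n* binary fixed-margin null matrices from a trial-swap chain.

    Row and column sums are preserved on every draw.  Defaults: burn-in of
    10x fill attempted swaps, thinning of fill attempted swaps between
    saved draws.  Rows (or columns) with no freedom — all ones or all
    zeros — simply never participate in a checkerboard swap.
    """
    a = np.asarray(incidence)
    if not np.isin(a, (0, 1)).all():
        raise ValueError("incidence matrix must be binary")
    a = a.astype(np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_rows, n_cols = a.shape
    fill = int(a.sum())
    if n_rows < 2 or n_cols < 2 or fill == 0 or fill == a.size:
        warnings.warn("matrix has no swappable checkerboard; returning originals")
        for _ in range(n):
            yield a.copy()
        return
    if burnin is None:
        burnin = 10 * fill
    if thin is None:
        thin = fill
    mat = a.tolist()

    buf_size = 16384
    buf = np.empty(0, dtype=np.int64)
    bi = buf_size  # force initial refill

    def run_steps(k: int) -> None:
        nonlocal bi, buf
        done = 0
        while done < k:
            if bi + 4 > len(buf):
                half = rng.integers(0, n_rows, size=buf_size)
                half2 = rng.integers(0, n_cols, size=buf_size)
                buf = np.empty(2 * buf_size, dtype=np.int64)
                buf[0::2] = half
                buf[1::2] = half2
                bi = 0
            r1 = buf[bi]
            c1 = buf[bi + 1]
            r2 = buf[bi + 2]
            c2 = buf[bi + 3]
            bi += 4
            done += 1
            if r1 == r2 or c1 == c2:
                continue
            row1 = mat[r1]
            row2 = mat[r2]
            x11 = row1[c1]
            x22 = row2[c2]
            x12 = row1[c2]
            x21 = row2[c1]
            if x11 == 1 and x22 == 1 and x12 == 0 and x21 == 0:
                row1[c1] = 0
                row2[c2] = 0
                row1[c2] = 1
                row2[c1] = 1
            elif x11 == 0 and x22 == 0 and x12 == 1 and x21 == 1:
                row1[c1] = 1
                row2[c2] = 1
                row1[c2] = 0
                row2[c1] = 0

    run_steps(burnin)
    for _ in range(n):
        run_steps(thin)
        yield np.asarray(mat, dtype=np.int64)
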
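"""Exact integer linear algebra helpers.

Ranks of the differentials are needed in exact rational arithmetic (they are
the authoritative kernel dimensions against which floating-point spectra are
reconciled).  The differential matrices are sparse with entries in {-1,0,1},
so almost every pivot is a unit: `sparse_integer_rank` repeatedly eliminates
unit pivots with pure integer row operations (no fractions, no rounding),
choosing pivots by a Markowitz-style minimum fill heuristic, and falls back
to fraction-free Bareiss elimination on the (typically tiny) remaining core
where no unit entry survives.
"""

from __future__ import annotations

__all__ = ["integer_rank", "sparse_integer_rank"]


def integer_rank(rows: list[list[int]]) -> int:
    """Rank over the rationals of a dense integer matrix (Bareiss elimination).

    Pure Python integers: no overflow, no floating point.
    """
    m = [list(r) for r in rows]
    if not m or not m[0]:
        return 0
    n_rows, n_cols = len(m), len(m[0])
    rank = 0
    prev = 1
    row = 0
    for col in range(n_cols):
        pivot_row = next((r for r in range(row, n_rows) if m[r][col] != 0), None)
        if pivot_row is None:
            continue
        if pivot_row != row:
            m[row], m[pivot_row] = m[pivot_row], m[row]
        pivot = m[row][col]
        for r in range(row + 1, n_rows):
            factor = m[r][col]
            if factor == 0 and prev == 1:
                continue
            for c in range(col, n_cols):
                m[r][c] = (pivot * m[r][c] - factor * m[row][c]) // prev
        prev = pivot
        row += 1
        rank += 1
        if row == n_rows:
            break
    return rank


def sparse_integer_rank(entries) -> int:
    """Exact rank of a sparse integer matrix.

    ``entries`` is an iterable of (row, col, value) with integer values.
    Unit pivots are eliminated with integer row operations; any residual
    core without unit entries goes through dense Bareiss.
    """
    rows: dict[int, dict[int, int]] = {}
    for i, j, v in entries:
        v = int(v)
        if v:
            rows.setdefault(int(i), {})[int(j)] = v
    # drop cancelled entries if duplicates were accumulated upstream
    cols: dict[int, set[int]] = {}
    for i, r in rows.items():
        for j in r:
            cols.setdefault(j, set()).add(i)
    rank = 0
    while rows:
        # pick a unit pivot with minimal Markowitz cost
        best = None
        best_cost = None
        for i, r in rows.items():
            li = len(r)
            for j, v in r.items():
                if v == 1 or v == -1:
                    cost = (li - 1) * (len(cols[j]) - 1)
                    if best_cost is None or cost < best_cost:
                        best, best_cost = (i, j), cost
                        if cost == 0:
                            break
            if best_cost == 0:
                break
        if best is None:
            # no unit entry left: finish the core with Bareiss
            live_rows = sorted(rows)
            live_cols = sorted({j for r in rows.values() for j in r})
            col_pos = {j: c for c, j in enumerate(live_cols)}
            dense = [[0] * len(live_cols) for _ in live_rows]
            for a, i in enumerate(live_rows):
                for j, v in rows[i].items():
                    dense[a][col_pos[j]] = v
            return rank + integer_rank(dense)
        pi, pj = best
        pivot_row = rows.pop(pi)
        pv = pivot_row[pj]
        for j in pivot_row:
            cols[j].discard(pi)
        for i in list(cols.get(pj, ())):
            r = rows[i]
            f = r[pj] * pv  # pv in {1,-1} so f = r[pj]/pv
            for j, v in pivot_row.items():
                nv = r.get(j, 0) - f * v
                if nv:
                    r[j] = nv
                    cols.setdefault(j, set()).add(i)
                else:
                    if j in r:
                        del r[j]
                        cols[j].discard(i)
            if not r:
                del rows[i]
        rank += 1
    return rank
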
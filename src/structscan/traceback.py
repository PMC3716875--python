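"""Left-end recovery and full alignment traceback by bounded recomputation.

The scanner never stores whole DP matrices, so tracing an occurrence with
right end j re-runs the banded engine over a window whose width is bounded
through the recorded score: the occurrence cannot be more than delta
positions longer or shorter than the query, where delta is derived from the
best possible per-column contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .model import NEG_INF, Alignment, ConsensusStructure
from .scan import ScanEngine, ScanTables

__all__ = ["length_bound", "recompute_region", "traceback", "TracebackRegion"]


class TracebackError(RuntimeError):
    """Internal consistency failure (recomputed score != recorded score)."""


def length_bound(s_j: int, tables: ScanTables) -> int:
    """Max length difference between query and occurrence compatible with s_j.

    Uses the instantiated maxima of the single-base contribution and of the
    full base-pair-match contribution (tau plus both psi terms); gamma itself
    joins the per-column cap so deleted columns are covered even when all
    similarities are negative.  Ceiling; gap opening ignored (conservative).
    """
    t = tables
    m = t.m
    sigma_max = int(t.sigma_mat[:, 1:].max()) if m >= 1 else 0
    cap = float(max(sigma_max, t.gamma))
    if t.qpairs and t.tpairs:
        psi_t_max = max(p for _, _, p in t.tpairs)
        psi_q = np.array([p for _, _, p in t.qpairs], dtype=np.int64)
        pair_best = int((t.tau_tab[:4, :4, :] + psi_q[None, None, :]).max())
        cap = max(cap, (pair_best + psi_t_max) / 2.0)
    delta = math.ceil((s_j - m * cap) / t.gamma)
    return max(0, delta)


@dataclass
class TracebackRegion:
    engine: ScanEngine
    j: int
    s_j: int
    row_lo: int
    delta: int


def recompute_region(j: int, s_j: int, tables: ScanTables) -> TracebackRegion:
    """Re-run the DP over rows [j-m-delta, j] and check score consistency."""
    delta = length_bound(s_j, tables)
    row_lo = max(1, j - tables.m - delta)
    engine = ScanEngine(
        tables, row_lo=row_lo, row_hi=j, region_init=True, keep_all=True
    )
    last = None
    for jj, s in engine.run():
        last = s
    if last != s_j:
        raise TracebackError(
            f"recomputed S*({j},{tables.m}) = {last} != recorded {s_j}"
        )
    return TracebackRegion(engine, j, s_j, row_lo, delta)


def traceback(region: TracebackRegion) -> Tuple[Alignment, ConsensusStructure, int]:
    """Recover (alignment, consensus structure, left end) scoring exactly s_j."""
    tr = _Tracer(region)
    tr.trace_star(region.j, region.engine.m)
    a = Alignment(set(tr.edges))
    s = ConsensusStructure(set(tr.pairs))
    a.validate()
    s.validate(a)
    left = min((i for i, _ in tr.edges), default=region.j)
    return a, s, left


class _Tracer:
    """Equality-driven walk through the retained region matrices.

    Case order everywhere: gap states before the match case, match before
    structure; structure candidates by smallest target left end, then
    smallest query left end.  This mirrors a fixed evaluation order and makes
    tracebacks deterministic under ties.
    """

    def __init__(self, region: TracebackRegion):
        self.e = region.engine
        self.t = region.engine.t
        self.g = self.t.gamma
        self.op = self.t.gap_open
        self.edges: List[Tuple[int, int]] = []
        self.pairs: List[Tuple[Tuple[int, int], Tuple[int, int]]] = []

    # -- S* level -----------------------------------------------------------

    def _star(self, j: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.e.rows[j]

    def trace_star(self, j: int, l: int) -> None:
        e, g, op = self.e, self.g, self.op
        M, X, Y = self._star(j)
        # pick the first state attaining the cell value in fixed order
        state = "M"
        if l > 0:
            best = max(M[l], X[l], Y[l])
            for st, v in (("X", X[l]), ("Y", Y[l]), ("M", M[l])):
                if v == best:
                    state = st
                    break

        while True:
            M, X, Y = self._star(j)
            if l == 0:
                return  # free left end: alignment starts here
            if state == "X":
                val = X[l]
                pM, pX, pY = self._star(j - 1)
                if pX[l] + g == val:
                    state = "X"
                elif pM[l] + g + op == val:
                    state = "M"
                elif pY[l] + g + op == val:
                    state = "Y"
                else:
                    raise TracebackError(f"no predecessor for X*({j},{l})")
                j -= 1
            elif state == "Y":
                val = Y[l]
                if Y[l - 1] + g == val:
                    state = "Y"
                elif M[l - 1] + g + op == val:
                    state = "M"
                elif X[l - 1] + g + op == val:
                    state = "X"
                else:
                    raise TracebackError(f"no predecessor for Y*({j},{l})")
                l -= 1
            else:
                val = M[l]
                pM, pX, pY = self._star(j - 1)
                sg = self.t.sigma_mat[self.e.nt_idx[j - 1], l]
                matched = False
                for st, v in (("M", pM[l - 1]), ("X", pX[l - 1]), ("Y", pY[l - 1])):
                    if v > NEG_INF and v + sg == val:
                        self.edges.append((j, l))
                        j, l, state = j - 1, l - 1, st
                        matched = True
                        break
                if matched:
                    continue
                found = self._star_structure_case(j, l, val)
                if found is None:
                    raise TracebackError(f"no case explains S*_M({j},{l})={val}")
                j, l, state = found

    def _star_structure_case(self, j, l, val) -> Optional[Tuple[int, int, str]]:
        e = self.e
        tps = sorted(
            (i for i, _ in e.tp_by_right.get(j, ()) if i >= e.row_lo)
        )
        for i in tps:
            darr = e.D.get(i, {}).get(j)
            if darr is None:
                continue
            bM, bX, bY = self._star(i - 1)
            qis = [qi for qi in np.flatnonzero(e.q_l == l)]
            qis.sort(key=lambda qi: e.q_k[qi])
            for qi in qis:
                d = int(darr[qi])
                if d <= NEG_INF:
                    continue
                k = int(e.q_k[qi])
                for st, v in (("M", bM[k - 1]), ("X", bX[k - 1]), ("Y", bY[k - 1])):
                    if v > NEG_INF and v + d == val:
                        self.edges.append((i, k))
                        self.edges.append((j, l))
                        self.pairs.append(((i, j), (k, l)))
                        self._trace_D(i, j, k, qi, int(e.q_l[qi]))
                        return i - 1, k - 1, st
        return None

    # -- D / slice level ----------------------------------------------------

    def _trace_D(self, i: int, j: int, k: int, qi: int, l: int) -> None:
        e = self.e
        sl = e.slices.get((j - 1, l - 1))
        if sl is None:
            raise TracebackError(f"slice ({j-1},{l-1}) not retained")
        Ms, Xs, Ys, BF, i_lo = sl
        d = int(e.D[i][j][qi])
        inner = d - (
            next(p for (ti, tj, p) in self.t.tpairs if ti == i and tj == j)
            + int(e.psi_q[qi])
            + int(self.t.tau_tab[e.nt_idx[i - 1], e.nt_idx[j - 1], qi])
        )
        r = i + 1 - i_lo
        b = k + 1
        for st, v in (("M", Ms[r, b]), ("X", Xs[r, b]), ("Y", Ys[r, b])):
            if int(v) == inner:
                self._trace_slice(j - 1, l - 1, i + 1, k + 1, st)
                return
        raise TracebackError(f"D({i},{j},{k},{l}) inner value not found in slice")

    def _trace_slice(self, J: int, Lq: int, a: int, b: int, state: str) -> None:
        e, g, op = self.e, self.g, self.op
        Ms, Xs, Ys, BF, i_lo = e.slices[(J, Lq)]
        while True:
            if a == J + 1 or b == Lq + 1:
                return  # remaining positions of one side are deleted
            r = a - i_lo
            if state == "X":
                val = Xs[r, b]
                nM, nX, nY = Ms[r + 1, b], Xs[r + 1, b], Ys[r + 1, b]
                if nX + g == val:
                    state = "X"
                elif nM + g + op == val:
                    state = "M"
                elif nY + g + op == val:
                    state = "Y"
                else:
                    raise TracebackError(f"slice X({a},{b}) has no predecessor")
                a += 1
            elif state == "Y":
                val = Ys[r, b]
                nM, nX, nY = Ms[r, b + 1], Xs[r, b + 1], Ys[r, b + 1]
                if nY + g == val:
                    state = "Y"
                elif nM + g + op == val:
                    state = "M"
                elif nX + g + op == val:
                    state = "X"
                else:
                    raise TracebackError(f"slice Y({a},{b}) has no predecessor")
                b += 1
            else:
                val = Ms[r, b]
                sg = self.t.sigma_mat[e.nt_idx[a - 1], b]
                nxt = ((("M", Ms[r + 1, b + 1]), ("X", Xs[r + 1, b + 1]),
                        ("Y", Ys[r + 1, b + 1])))
                matched = False
                for st, v in nxt:
                    if v > NEG_INF and v + sg == val:
                        self.edges.append((a, b))
                        a, b, state = a + 1, b + 1, st
                        matched = True
                        break
                if matched:
                    continue
                if not self._slice_structure_case(J, Lq, a, b, int(val)):
                    raise TracebackError(
                        f"no case explains slice M({a},{b}) in ({J},{Lq})"
                    )
                return

    def _slice_structure_case(self, J, Lq, a, b, val) -> bool:
        e, op = self.e, self.op
        Ms, Xs, Ys, BF, i_lo = e.slices[(J, Lq)]
        cands = sorted(j2 for j2, _ in e.tp_by_left.get(a, ()) if j2 <= J)
        for j2 in cands:
            darr = e.D.get(a, {}).get(j2)
            if darr is None:
                continue
            qis = [qi for qi in np.flatnonzero((e.q_k == b) & (e.q_l <= Lq))]
            qis.sort(key=lambda qi: e.q_l[qi])
            for qi in qis:
                d = int(darr[qi])
                if d <= NEG_INF:
                    continue
                l2 = int(e.q_l[qi])
                rj = j2 + 1 - i_lo
                follow = (
                    ("M", Ms[rj, l2 + 1]),
                    ("X", Xs[rj, l2 + 1] + op),
                    ("Y", Ys[rj, l2 + 1] + op),
                )
                for st, v in follow:
                    if v > NEG_INF and d + v == val:
                        self.edges.append((a, b))
                        self.edges.append((j2, l2))
                        self.pairs.append(((a, j2), (b, l2)))
                        self._trace_D(a, j2, b, qi, l2)
                        self._trace_slice(J, Lq, j2 + 1, l2 + 1, st)
                        return True
        return False
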
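"""Banded semi-global sequence-structure alignment DP.

One left-to-right pass over the target; for every target position j the
engine materializes the S slices with right ends (j-1, l-1) needed to derive
the sparse D entries with right end j, then fills the S* band row j.  Live
memory is bounded by the band span L and the query length m, independent of
the target length.

Gap costs are affine via the usual three-state (match / target-gap /
query-gap) split; the linear model of the plain recursion is recovered at
gap opening 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .model import (
    NEG_INF,
    NT_INDEX,
    BppMatrix,
    QueryInput,
    QueryProfile,
    ScoreParams,
    TargetSequence,
    build_profile,
    psi,
    query_bpp_from_structure,
    sigma,
    tau,
)

__all__ = ["ScanEngine", "ScanResult", "ScanTables", "build_tables", "scan"]


def _max3(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.maximum(np.maximum(a, b), c)


@dataclass
class ScanTables:
    """Precomputed integer scoring tables driving the engine."""

    residues: str
    tpairs: List[Tuple[int, int, int]]           # (i, j, psi_T)
    qpairs: List[Tuple[int, int, int]]           # (k, l, psi_Q)
    sigma_mat: np.ndarray                        # (5, m+1) int64
    tau_tab: np.ndarray                          # (5, 5, nq) int64
    gamma: int
    gap_open: int
    L: int
    m: int


def build_tables(
    target: TargetSequence,
    target_bpp: BppMatrix,
    query: QueryInput,
    params: ScoreParams,
    profile: Optional[QueryProfile] = None,
    query_bpp: Optional[BppMatrix] = None,
) -> Tuple[ScanTables, QueryProfile, BppMatrix]:
    """Derive scoring tables from the model-level objects."""
    m = query.m
    if query_bpp is None:
        if query.consensus_structure is not None:
            query_bpp = query_bpp_from_structure(query.consensus_structure, m)
        else:
            query_bpp = BppMatrix(m)
    if profile is None:
        profile = build_profile(query, params.pseudocount_mass, query_bpp)

    qpairs = []
    for (k, l) in query_bpp.pairs():
        pq = psi(query_bpp, (k, l), params)
        if pq > NEG_INF:
            qpairs.append((k, l, pq))

    res = target.residues
    tpairs = []
    for (i, j) in target_bpp.pairs():
        if j - i > params.max_span:
            continue
        if res[i - 1] == "N" or res[j - 1] == "N":
            continue  # ambiguity codes never pair
        pt = psi(target_bpp, (i, j), params)
        if pt > NEG_INF:
            tpairs.append((i, j, pt))

    sigma_mat = np.zeros((5, m + 1), dtype=np.int64)
    tau_tab = np.zeros((5, 5, len(qpairs)), dtype=np.int64)
    if params.use_sequence_scores:
        for t, ti in NT_INDEX.items():
            for k in range(1, m + 1):
                sigma_mat[ti, k] = sigma(t, k, profile)
        for a, ai in NT_INDEX.items():
            if a == "N":
                continue
            for b, bi in NT_INDEX.items():
                if b == "N":
                    continue
                for qi, (k, l, _) in enumerate(qpairs):
                    tau_tab[ai, bi, qi] = tau(a, b, k, l, profile, params.tau_factor)

    tables = ScanTables(
        residues=res,
        tpairs=tpairs,
        qpairs=qpairs,
        sigma_mat=sigma_mat,
        tau_tab=tau_tab,
        gamma=params.gamma,
        gap_open=params.gap_opening,
        L=params.max_span,
        m=m,
    )
    return tables, profile, query_bpp


@dataclass
class ScanResult:
    score_trace: List[int]
    occurrences: list = field(default_factory=list)
    histogram: Dict[int, int] = field(default_factory=dict)
    cells_evaluated: int = 0
    peak_live_entries: int = 0


class ScanEngine:
    """Evaluates the interleaved recursion over a row range of the target.

    ``region_init=True`` with ``row_lo=i0`` reproduces the bounded traceback
    recomputation: row i0-1 is initialized to -inf except at query prefix 0,
    and all intermediate state is retained for tracing.
    """

    BAND_PAD = 2  # band holds rows j-L-1 .. j

    def __init__(
        self,
        tables: ScanTables,
        row_lo: int = 1,
        row_hi: Optional[int] = None,
        region_init: bool = False,
        keep_all: bool = False,
    ):
        t = tables
        self.t = t
        self.n = len(t.residues)
        self.m = t.m
        self.L = t.L
        self.gamma = t.gamma
        self.open = t.gap_open
        self.row_lo = row_lo
        self.row_hi = self.n if row_hi is None else row_hi
        self.region_init = region_init
        self.keep_all = keep_all

        self.nq = len(t.qpairs)
        self.q_k = np.array([k for k, _, _ in t.qpairs], dtype=np.int64)
        self.q_l = np.array([l for _, l, _ in t.qpairs], dtype=np.int64)
        self.psi_q = np.array([p for _, _, p in t.qpairs], dtype=np.int64)
        self.qp_by_l: Dict[int, np.ndarray] = {}
        for qi, (_, l, _) in enumerate(t.qpairs):
            self.qp_by_l.setdefault(l, []).append(qi)
        self.qp_by_l = {l: np.array(v, dtype=np.int64) for l, v in self.qp_by_l.items()}

        self.tp_by_right: Dict[int, List[Tuple[int, int]]] = {}
        self.tp_by_left: Dict[int, List[Tuple[int, int]]] = {}
        for (i, j, pt) in t.tpairs:
            self.tp_by_right.setdefault(j, []).append((i, pt))
            self.tp_by_left.setdefault(i, []).append((j, pt))

        self.nt_idx = np.array([NT_INDEX[c] for c in t.residues], dtype=np.int64)

        # D store: left end -> right end -> int64 array over query pairs
        self.D: Dict[int, Dict[int, np.ndarray]] = {}
        nrow = self.L + self.BAND_PAD
        self.bandM = np.full((nrow, self.m + 1), NEG_INF, dtype=np.int64)
        self.bandX = np.full((nrow, self.m + 1), NEG_INF, dtype=np.int64)
        self.bandY = np.full((nrow, self.m + 1), NEG_INF, dtype=np.int64)
        self.rows: Dict[int, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.slices: Dict[Tuple[int, int], tuple] = {}

        self.cells_evaluated = 0
        self.peak_live_entries = 0

        self._init_first_row()

    # -- initialization -----------------------------------------------------

    def _band(self, j: int) -> int:
        return j % (self.L + self.BAND_PAD)

    def _init_first_row(self) -> None:
        j0 = self.row_lo - 1
        M = np.full(self.m + 1, NEG_INF, dtype=np.int64)
        X = np.full(self.m + 1, NEG_INF, dtype=np.int64)
        Y = np.full(self.m + 1, NEG_INF, dtype=np.int64)
        M[0] = 0
        # a region clipped to the target start keeps the true row-0 init
        if (not self.region_init or self.row_lo == 1) and self.m >= 1:
            ls = np.arange(1, self.m + 1, dtype=np.int64)
            Y[1:] = self.open + self.gamma * ls
        self._store_row(j0, M, X, Y)

    def _store_row(self, j: int, M: np.ndarray, X: np.ndarray, Y: np.ndarray) -> None:
        b = self._band(j)
        self.bandM[b], self.bandX[b], self.bandY[b] = M, X, Y
        if self.keep_all:
            self.rows[j] = (M, X, Y)

    def _row(self, j: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        b = self._band(j)
        return self.bandM[b], self.bandX[b], self.bandY[b]

    # -- S slices -----------------------------------------------------------

    def compute_slice(self, J: int, Lq: int, i_lo_min: Optional[int] = None):
        """All S entries with right ends (J, Lq), rows max(row_lo, J-L+2)..J+1.

        ``i_lo_min`` prunes rows below the smallest left end actually needed
        by the pairs ending at J+1; the recursion only ever reads rows above
        the current one, so the retained rows are exact.

        Returns (M, X, Y, BF, i_lo) where arrays are indexed [i' - i_lo, k']
        and BF[r, k] = max(M, X+open, Y+open), the value available to a
        following block that may have to open fresh gap runs.
        """
        g, op = self.gamma, self.open
        i_lo = max(self.row_lo, J + 2 - self.L)
        if i_lo_min is not None:
            i_lo = max(i_lo, i_lo_min)
        nrows = J + 1 - i_lo + 1
        ncol = Lq + 2
        Ms = np.full((nrows, ncol), NEG_INF, dtype=np.int64)
        Xs = np.full((nrows, ncol), NEG_INF, dtype=np.int64)
        Ys = np.full((nrows, ncol), NEG_INF, dtype=np.int64)
        BF = np.full((nrows, ncol), NEG_INF, dtype=np.int64)

        cols = np.arange(ncol, dtype=np.int64)
        # border row i' = J+1: empty target range
        r = nrows - 1
        Ms[r, Lq + 1] = 0
        if Lq >= 1:
            ks = cols[1 : Lq + 1]
            Ys[r, 1 : Lq + 1] = op + g * (Lq - ks + 1)
        BF[r] = _max3(Ms[r], Xs[r] + op, Ys[r] + op)

        qsel_lt = None
        for r in range(nrows - 2, -1, -1):
            ip = i_lo + r
            pM, pX, pY = Ms[r + 1], Xs[r + 1], Ys[r + 1]
            tnt = self.nt_idx[ip - 1]
            Mrow = Ms[r]
            if Lq >= 1:
                best_prev = _max3(pM, pX, pY)
                Mrow[1 : Lq + 1] = (
                    self.t.sigma_mat[tnt, 1 : Lq + 1] + best_prev[2 : Lq + 2]
                )
            # structure case: pair starting at (ip, k') closing at (j2, l2<=Lq)
            for (j2, _pt) in self.tp_by_left.get(ip, ()):  # noqa: B007
                if j2 > J:
                    continue
                darr = self.D.get(ip, {}).get(j2)
                if darr is None:
                    continue
                if qsel_lt is None:
                    qsel_lt = np.flatnonzero(self.q_l <= Lq)
                if qsel_lt.size == 0:
                    continue
                rj = j2 + 1 - i_lo
                vals = darr[qsel_lt] + BF[rj, self.q_l[qsel_lt] + 1]
                np.maximum.at(Mrow, self.q_k[qsel_lt], vals)
            np.maximum(Mrow, NEG_INF, out=Mrow)
            Mrow[0] = NEG_INF
            Mrow[Lq + 1] = NEG_INF

            Xs[r, 1:] = np.maximum(
                pX[1:] + g, np.maximum(pM[1:], pY[1:]) + g + op
            )
            np.maximum(Xs[r], NEG_INF, out=Xs[r])

            # Y: delete query k'..t-1 then continue at (ip, t) in M or X
            c = np.maximum(Mrow, Xs[r]) + op
            z = c + g * cols
            sfx = np.maximum.accumulate(z[::-1])[::-1]
            if Lq >= 1:
                ks = cols[1 : Lq + 1]
                Ys[r, 1 : Lq + 1] = sfx[2 : Lq + 2] - g * ks
            np.maximum(Ys[r], NEG_INF, out=Ys[r])
            BF[r] = _max3(Mrow, Xs[r] + op, Ys[r] + op)

        self.cells_evaluated += nrows * ncol
        return Ms, Xs, Ys, BF, i_lo

    # -- main pass ----------------------------------------------------------

    def run(self) -> Iterator[Tuple[int, int]]:
        g, op = self.gamma, self.open
        m = self.m
        cols = np.arange(m + 1, dtype=np.int64)
        band_cells = self.bandM.size * 3

        for j in range(self.row_lo, self.row_hi + 1):
            tps = self.tp_by_right.get(j, ())
            tps = [(i, pt) for (i, pt) in tps if i >= self.row_lo]
            # derive D entries with right end j
            if tps and self.nq:
                i_lo_min = min(i for (i, _pt) in tps) + 1
                for l, qsel in self.qp_by_l.items():
                    sl = self.compute_slice(j - 1, l - 1, i_lo_min)
                    Ms, Xs, Ys, _BF, i_lo = sl
                    if self.keep_all:
                        self.slices[(j - 1, l - 1)] = sl
                    tnt_j = self.nt_idx[j - 1]
                    for (i, pt) in tps:
                        r = i + 1 - i_lo
                        kcol = self.q_k[qsel] + 1
                        inner = _max3(Ms[r, kcol], Xs[r, kcol], Ys[r, kcol])
                        dv = inner + pt + self.psi_q[qsel] + self.t.tau_tab[
                            self.nt_idx[i - 1], tnt_j, qsel
                        ]
                        np.maximum(dv, NEG_INF, out=dv)
                        darr = self.D.setdefault(i, {}).get(j)
                        if darr is None:
                            darr = np.full(self.nq, NEG_INF, dtype=np.int64)
                            self.D[i][j] = darr
                        darr[qsel] = dv
                        self.cells_evaluated += qsel.size
                    live = (
                        band_cells
                        + Ms.size * 3
                        + sum(len(dd) for dd in self.D.values()) * self.nq
                    )
                    if live > self.peak_live_entries:
                        self.peak_live_entries = live

            # S* row j
            pM, pX, pY = self._row(j - 1)
            M = np.full(m + 1, NEG_INF, dtype=np.int64)
            X = np.full(m + 1, NEG_INF, dtype=np.int64)
            Y = np.full(m + 1, NEG_INF, dtype=np.int64)
            M[0] = 0
            if m >= 1:
                tnt = self.nt_idx[j - 1]
                best_prev = _max3(pM, pX, pY)
                M[1:] = self.t.sigma_mat[tnt, 1:] + best_prev[:m]
            for (i, _pt) in tps:
                darr = self.D.get(i, {}).get(j)
                if darr is None:
                    continue
                bM, bX, bY = self._row(i - 1)
                pb = _max3(bM, bX, bY)
                cand = pb[self.q_k - 1] + darr
                np.maximum.at(M, self.q_l, cand)
            np.maximum(M, NEG_INF, out=M)
            M[0] = 0

            X[1:] = np.maximum(pX[1:] + g, np.maximum(pM[1:], pY[1:]) + g + op)
            np.maximum(X, NEG_INF, out=X)
            X[0] = NEG_INF

            c = np.maximum(M, X) + op
            d = c - g * cols
            pfx = np.maximum.accumulate(d)
            if m >= 1:
                Y[1:] = g * cols[1:] + pfx[:m]
            np.maximum(Y, NEG_INF, out=Y)
            Y[0] = NEG_INF

            self._store_row(j, M, X, Y)
            self.cells_evaluated += m + 1

            live = band_cells + sum(len(dd) for dd in self.D.values()) * self.nq
            if live > self.peak_live_entries:
                self.peak_live_entries = live

            s_j = int(max(M[m], X[m], Y[m]))
            yield j, max(s_j, NEG_INF)

            if not self.keep_all:
                stale = j - self.L
                if stale in self.D:
                    del self.D[stale]

    def score_trace(self) -> List[int]:
        return [s for _, s in self.run()]


def scan(
    target: TargetSequence,
    target_bpp: BppMatrix,
    query: QueryInput,
    params: ScoreParams,
) -> Tuple[ScanResult, ScanTables, QueryProfile, BppMatrix]:
    """One pass over the target; returns the streamed score trace s_j."""
    tables, profile, query_bpp = build_tables(target, target_bpp, query, params)
    engine = ScanEngine(tables)
    trace = [s for _, s in engine.run()]
    result = ScanResult(
        score_trace=trace,
        cells_evaluated=engine.cells_evaluated,
        peak_live_entries=engine.peak_live_entries,
    )
    return result, tables, profile, query_bpp
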
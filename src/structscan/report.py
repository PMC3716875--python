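"""Streaming occurrence reporting.

Consumes the score trace s_j emitted by the scanner, keeps only local maxima,
prunes nearby dominated maxima with a bounded online list, optionally retains
the K best occurrences, and calibrates empirical significance from an affine
fit to the right tail of the log10 survival counts.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

from .model import NEG_INF

log = logging.getLogger(__name__)

MIN_SCORES_FOR_FIT = 30


@dataclass
class Occurrence:
    """A reported hit; left end and alignment are filled by traceback."""

    j: int                      # right end, 1-based inclusive
    score: int                  # centi-units
    target_id: str = ""
    evalue: Optional[float] = None
    left_end: Optional[int] = None
    aligned_target: Optional[str] = None
    aligned_query: Optional[str] = None
    aligned_structure: Optional[str] = None


def local_maxima(scores: Iterable[Tuple[int, int]]) -> Iterator[Tuple[int, int]]:
    """Yield (j, s_j) where s_j >= max(s_{j-1}, s_{j+1}); ends use -inf."""
    prev_j = prev_s = None
    prev_prev_s = NEG_INF - 1
    for j, s in scores:
        if prev_j is not None:
            if prev_s >= prev_prev_s and prev_s >= s:
                yield prev_j, prev_s
            prev_prev_s = prev_s
        prev_j, prev_s = j, s
    if prev_j is not None and prev_s >= prev_prev_s:
        yield prev_j, prev_s


def dominates(j: int, j2: int, s_j: int, s_j2: int, m: int) -> bool:
    """True iff occurrence j suppresses occurrence j2 (within distance m)."""
    if j == j2:
        raise ValueError("dominates() needs two distinct positions")
    if abs(j - j2) > m:
        return False
    return s_j > s_j2 or (s_j == s_j2 and j < j2)


class OnlinePruner:
    """Bounded-memory resolution of the domination relation, in stream order.

    Maintains a list of pending local maxima with (1) increasing positions,
    (2) successive distances <= m, (3) strictly increasing scores.  Entries
    are resolved and emitted as soon as they are independent of everything
    still to come.
    """

    def __init__(self, m: int):
        self.m = m
        self.pending: List[Tuple[int, int]] = []
        self.max_list_len = 0

    def _check_invariants(self) -> None:
        p = self.pending
        for (j1, s1), (j2, s2) in zip(p, p[1:]):
            assert j1 < j2 and j2 - j1 <= self.m and s1 < s2

    def _resolve(self) -> List[Tuple[int, int]]:
        out = []
        p = self.pending
        while p:
            j, s = p.pop()
            out.append((j, s))
            while p and j - p[-1][0] <= self.m:
                p.pop()  # dominated: closer than m and lower score
        out.sort()
        return out

    def feed(self, j: int, s: int) -> List[Tuple[int, int]]:
        emitted: List[Tuple[int, int]] = []
        if self.pending and j - self.m > self.pending[-1][0]:
            emitted = self._resolve()
        if not (self.pending and dominates(
                self.pending[-1][0], j, self.pending[-1][1], s, self.m)):
            self.pending.append((j, s))
            if len(self.pending) > self.max_list_len:
                self.max_list_len = len(self.pending)
        return emitted

    def finish(self) -> List[Tuple[int, int]]:
        return self._resolve()


def online_prune(
    maxima: Iterable[Tuple[int, int]], m: int
) -> Iterator[Tuple[int, int]]:
    pruner = OnlinePruner(m)
    for j, s in maxima:
        yield from pruner.feed(j, s)
    yield from pruner.finish()


def offline_nondominated(
    maxima: List[Tuple[int, int]], m: int
) -> List[Tuple[int, int]]:
    """Reference resolution: repeatedly report the best remaining maximum
    (ties toward smaller position) and drop everything it dominates."""
    kept: List[Tuple[int, int]] = []
    for j, s in sorted(maxima, key=lambda t: (-t[1], t[0])):
        if all(abs(j - jk) > m for jk, _ in kept):
            kept.append((j, s))
    kept.sort()
    return kept


class TopK:
    """Priority queue of the K best occurrences (min score on top).

    Eviction ties are broken toward larger position, so equal-scoring earlier
    hits survive.  K=None keeps everything.
    """

    def __init__(self, k: Optional[int] = None):
        if k is not None and k < 1:
            raise ValueError("K must be >= 1")
        self.k = k
        self._heap: List[Tuple[int, int, int]] = []  # (score, -j, j)

    def push(self, j: int, s: int) -> None:
        heapq.heappush(self._heap, (s, -j, j))
        if self.k is not None and len(self._heap) > self.k:
            heapq.heappop(self._heap)

    def items(self) -> List[Tuple[int, int]]:
        return sorted(((j, s) for s, _, j in self._heap))


@dataclass
class TailFit:
    slope: float
    intercept: float
    tail_fraction: float
    effective_trials: int


def fit_tail(
    histogram: Dict[int, int], tail_fraction: float = 0.05
) -> Optional[TailFit]:
    """Affine least-squares fit of log10(survival count) vs score.

    Uses the distinct scores carrying the top ``tail_fraction`` of the
    locally-maximal score mass.  Returns None (significance disabled) when
    fewer than 30 scores were observed.
    """
    n = sum(histogram.values())
    if n < MIN_SCORES_FOR_FIT:
        log.warning(
            "only %d locally-maximal scores; significance disabled (need %d)",
            n, MIN_SCORES_FOR_FIT,
        )
        return None
    scores = sorted(histogram)
    surv: Dict[int, int] = {}
    acc = 0
    for s in reversed(scores):
        acc += histogram[s]
        surv[s] = acc
    target = max(2.0, math.ceil(tail_fraction * n))
    pts = [s for s in scores if surv[s] <= target]
    if len(pts) < 2:  # extend downward until the fit is determined
        pts = scores[-2:]
    xs = np.array(pts, dtype=float)
    ys = np.log10([surv[s] for s in pts])
    slope, intercept = np.polyfit(xs, ys, 1)
    if slope >= 0:
        log.warning("tail fit slope %.3g is not negative; calibration dubious", slope)
    return TailFit(float(slope), float(intercept), tail_fraction, n)


def evalue(fit: TailFit, score: float) -> float:
    e = 10.0 ** (fit.intercept + fit.slope * score)
    return float(min(e, fit.effective_trials))


class Reporter:
    """Ties the streaming stages together for one target record."""

    def __init__(self, m: int, k: Optional[int] = None,
                 tail_fraction: float = 0.05, target_id: str = ""):
        self.m = m
        self.target_id = target_id
        self.tail_fraction = tail_fraction
        self.pruner = OnlinePruner(m)
        self.topk = TopK(k)
        self.histogram: Dict[int, int] = {}
        self._prev: Optional[Tuple[int, int]] = None
        self._prev_prev_s: int = NEG_INF - 1

    def feed(self, j: int, s: int) -> None:
        if self._prev is not None:
            pj, ps = self._prev
            if ps >= self._prev_prev_s and ps >= s:
                self._on_maximum(pj, ps)
            self._prev_prev_s = ps
        self._prev = (j, s)

    def _on_maximum(self, j: int, s: int) -> None:
        self.histogram[s] = self.histogram.get(s, 0) + 1
        for rj, rs in self.pruner.feed(j, s):
            self.topk.push(rj, rs)

    def finish(self) -> List[Occurrence]:
        if self._prev is not None:
            pj, ps = self._prev
            if ps >= self._prev_prev_s:
                self._on_maximum(pj, ps)
        for rj, rs in self.pruner.finish():
            self.topk.push(rj, rs)
        fit = fit_tail(self.histogram, self.tail_fraction)
        occs = []
        for j, s in self.topk.items():
            occ = Occurrence(j=j, score=s, target_id=self.target_id)
            if fit is not None:
                occ.evalue = evalue(fit, s)
            occs.append(occ)
        self.fit = fit
        return occs


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_hits_tsv(path, occurrences: List[Occurrence], header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# target_id\tleft_end\tright_end\tscore\te_value\t"
                 "aln_target\taln_query\taln_structure\n")
        for o in occurrences:
            fh.write(
                "\t".join([
                    o.target_id,
                    str(o.left_end) if o.left_end is not None else ".",
                    str(o.j),
                    f"{o.score / 100.0:.2f}",
                    f"{o.evalue:.3g}" if o.evalue is not None else ".",
                    o.aligned_target or ".",
                    o.aligned_query or ".",
                    o.aligned_structure or ".",
                ]) + "\n"
            )


def write_bed6(path, occurrences: List[Occurrence]) -> None:
    """BED6 export; 0-based half-open conversion happens only here."""
    with open(path, "w") as fh:
        for o in occurrences:
            start = (o.left_end - 1) if o.left_end is not None else o.j - 1
            fh.write(
                f"{o.target_id}\t{start}\t{o.j}\thit\t"
                f"{o.score / 100.0:.2f}\t+\n"
            )
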
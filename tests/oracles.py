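"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's DP engines: scores are evaluated by
exhaustive enumeration of all consistent (alignment, consensus structure)
pairs from the additive score definition, and folding ensembles by explicit
enumeration of all legal structures.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

NEG = float("-inf")


# ---------------------------------------------------------------------------
# alignment/structure enumeration oracle
# ---------------------------------------------------------------------------


@dataclass
class Instance:
    """A tiny scan problem with raw scoring tables."""

    n: int
    m: int
    tpairs: Dict[Tuple[int, int], int]          # (i,j) -> psi_T
    qpairs: Dict[Tuple[int, int], int]          # (k,l) -> psi_Q
    sigma: Dict[Tuple[int, int], int]           # (i,k) -> score
    tau: Dict[Tuple[int, int, int, int], int]   # (i,j,k,l) -> score
    gamma: int
    gap_open: int = 0
    L: Optional[int] = None


def _alignments(n: int, m: int):
    """All monotone matchings between {1..n} and {1..m}."""
    out = [[]]
    def rec(prefix, i0, k0):
        out_local.append(list(prefix))
        for i in range(i0, n + 1):
            for k in range(k0, m + 1):
                prefix.append((i, k))
                rec(prefix, i + 1, k + 1)
                prefix.pop()
    out_local: List[List[Tuple[int, int]]] = []
    rec([], 1, 1)
    return out_local


def _noncrossing(pairs: Sequence[Tuple[int, int]]) -> bool:
    for (i, j), (i2, j2) in itertools.combinations(sorted(pairs), 2):
        if i2 >= j:
            continue
        if not (i < i2 and j2 < j):
            return False
        if i == i2 or j == j2:
            return False
    ends = [x for p in pairs for x in p]
    return len(ends) == len(set(ends))


def _structures_for(inst: Instance, edges: List[Tuple[int, int]]):
    """All consensus structures consistent with an alignment."""
    emap = dict(edges)
    cands = []
    for (i, k) in edges:
        for (j, l) in edges:
            if i < j and k < l and (i, j) in inst.tpairs and (k, l) in inst.qpairs:
                if inst.L is None or j - i <= inst.L:
                    cands.append(((i, j), (k, l)))
    structures = [[]]
    for r in range(1, len(cands) + 1):
        for combo in itertools.combinations(cands, r):
            tp = [c[0] for c in combo]
            qp = [c[1] for c in combo]
            if _noncrossing(tp) and _noncrossing(qp):
                structures.append(list(combo))
    return structures


def _gap_runs(positions: Sequence[int]) -> int:
    runs, prev = 0, None
    for x in sorted(positions):
        if prev is None or x != prev + 1:
            runs += 1
        prev = x
    return runs


def score_pair(
    inst: Instance,
    edges: List[Tuple[int, int]],
    structure: List[Tuple[Tuple[int, int], Tuple[int, int]]],
    right_end: Optional[int] = None,
) -> float:
    """Additive score; free target end deletions (both ends, or left only
    when ``right_end`` anchors the occurrence)."""
    s = 0.0
    struct_edges: Set[Tuple[int, int]] = set()
    for (i, j), (k, l) in structure:
        s += inst.tpairs[(i, j)] + inst.qpairs[(k, l)]
        s += inst.tau.get((i, j, k, l), 0)
        struct_edges.update([(i, k), (j, l)])
    for (i, k) in edges:
        if (i, k) not in struct_edges:
            s += inst.sigma.get((i, k), 0)

    if not edges:
        return s + inst.gamma * inst.m + (inst.gap_open if inst.m else 0)
    at = {i for i, _ in edges}
    aq = {k for _, k in edges}
    lo = min(at)
    hi = max(at) if right_end is None else right_end
    if right_end is not None and right_end < max(at):
        raise ValueError("right_end before last edge")
    del_t = [i for i in range(lo, hi + 1) if i not in at]
    del_q = [k for k in range(1, inst.m + 1) if k not in aq]
    s += inst.gamma * (len(del_t) + len(del_q))
    s += inst.gap_open * (_gap_runs(del_t) + _gap_runs(del_q))
    return s


def oracle_prefix_scores(inst: Instance) -> List[float]:
    """Best right-anchored score for every right end j=1..n.

    This is exactly the quantity the scanner streams: free left end
    deletions, target charged through position j.
    """
    best = [NEG] * (inst.n + 1)
    empty = inst.gamma * inst.m + (inst.gap_open if inst.m else 0)
    for aln in _alignments(inst.n, inst.m):
        if not aln:
            for j in range(1, inst.n + 1):
                best[j] = max(best[j], empty)
            continue
        hi = max(i for i, _ in aln)
        for structure in _structures_for(inst, aln):
            base = score_pair(inst, aln, structure, right_end=hi)
            # extending the anchor rightwards adds one deletion run
            for j in range(hi, inst.n + 1):
                if j == hi:
                    sc = base
                else:
                    sc = base + inst.gamma * (j - hi) + inst.gap_open
                if sc > best[j]:
                    best[j] = sc
    return best[1:]


def oracle_semiglobal(inst: Instance) -> float:
    """Best score with free target end deletions at both ends."""
    best = inst.gamma * inst.m + (inst.gap_open if inst.m else 0)
    for aln in _alignments(inst.n, inst.m):
        if not aln:
            continue
        for structure in _structures_for(inst, aln):
            sc = score_pair(inst, aln, structure)
            if sc > best:
                best = sc
    return best


def oracle_global(inst: Instance) -> float:
    """Global gap count: every unaligned position of both sequences scored."""
    best = NEG
    for aln in _alignments(inst.n, inst.m):
        at = {i for i, _ in aln}
        aq = {k for _, k in aln}
        del_t = [i for i in range(1, inst.n + 1) if i not in at]
        del_q = [k for k in range(1, inst.m + 1) if k not in aq]
        for structure in _structures_for(inst, aln):
            s = 0.0
            struct_edges = set()
            for (i, j), (k, l) in structure:
                s += inst.tpairs[(i, j)] + inst.qpairs[(k, l)]
                s += inst.tau.get((i, j, k, l), 0)
                struct_edges.update([(i, k), (j, l)])
            for e in aln:
                if e not in struct_edges:
                    s += inst.sigma.get(e, 0)
            s += inst.gamma * (len(del_t) + len(del_q))
            s += inst.gap_open * (_gap_runs(del_t) + _gap_runs(del_q))
            if s > best:
                best = s
    return best


# ---------------------------------------------------------------------------
# secondary structure enumeration oracle
# ---------------------------------------------------------------------------


def enumerate_structures(
    seq: str,
    pair_energy: Dict[str, float],
    min_loop: int = 3,
    span: Optional[int] = None,
    no_lonely_pairs: bool = True,
) -> List[List[Tuple[int, int]]]:
    """All legal structures (lists of 1-based pairs), including the empty one."""
    n = len(seq)
    cand = [
        (i, j)
        for i in range(1, n + 1)
        for j in range(i + min_loop + 1, n + 1)
        if (span is None or j - i <= span) and (seq[i - 1] + seq[j - 1]) in pair_energy
    ]

    results: List[List[Tuple[int, int]]] = []

    def rec(chosen: List[Tuple[int, int]], rest: List[Tuple[int, int]]):
        results.append(list(chosen))
        for idx, p in enumerate(rest):
            chosen.append(p)
            if _noncrossing(chosen):
                rec(chosen, rest[idx + 1 :])
            chosen.pop()

    rec([], cand)
    if no_lonely_pairs:
        def ok(st):
            ps = set(st)
            return all(
                (i + 1, j - 1) in ps or (i - 1, j + 1) in ps for (i, j) in st
            )
        results = [st for st in results if ok(st)]
    # deduplicate (rec can reach the same set along one path only, but be safe)
    seen = set()
    uniq = []
    for st in results:
        key = tuple(sorted(st))
        if key not in seen:
            seen.add(key)
            uniq.append(sorted(st))
    return uniq


def count_helices(st: Sequence[Tuple[int, int]]) -> int:
    ps = set(st)
    return sum(1 for (i, j) in st if (i - 1, j + 1) not in ps)


def boltzmann(
    seq: str,
    pair_energy: Dict[str, float],
    rt: float = 1.0,
    min_loop: int = 3,
    span: Optional[int] = None,
    no_lonely_pairs: bool = True,
    helix_init: float = 0.0,
):
    """Exhaustive partition function, pair probabilities, and MFE structure."""
    structures = enumerate_structures(seq, pair_energy, min_loop, span,
                                      no_lonely_pairs)
    z = 0.0
    probs: Dict[Tuple[int, int], float] = {}
    best_e, best_st = math.inf, []
    weights = []
    for st in structures:
        e = sum(pair_energy[seq[i - 1] + seq[j - 1]] for (i, j) in st)
        e += helix_init * count_helices(st)
        w = math.exp(-e / rt)
        weights.append(w)
        z += w
        if e < best_e:
            best_e, best_st = e, st
    for st, w in zip(structures, weights):
        for p in st:
            probs[p] = probs.get(p, 0.0) + w / z
    return z, probs, best_e, best_st, structures
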
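"""Domain types and scoring functions shared by the DP engine and benchmark.

All scores are integers in hundredths ("centi-units") of natural-log odds;
contributions are rounded half-away-from-zero at the point where they are
defined so the additive total is exactly reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

log = logging.getLogger(__name__)

#: Reserved minus-infinity sentinel (centi-units).  Saturating: legal scores
#: never come within 2^20 of it, and sums drift by at most a few 1e7.
NEG_INF = -(1 << 40)

ALPHABET = "ACGU"
NT_INDEX = {c: i for i, c in enumerate(ALPHABET)}
NT_INDEX["N"] = 4

#: The six canonical base pairs, fixed order (index into pair-frequency tables).
CANONICAL_PAIRS = ("AU", "UA", "CG", "GC", "GU", "UG")
PAIR_INDEX = {p: i for i, p in enumerate(CANONICAL_PAIRS)}
#: Index 6 pools all non-canonical nucleotide combinations.
NONCANONICAL_SLOT = 6

GAP_CHARS = set("-.~_N")

PAIR_BACKGROUND = 1.0 / 6.0
SINGLE_BACKGROUND = 0.25


class ParseError(ValueError):
    """Malformed input (sequence, structure, or bpp file)."""


class ContractError(ValueError):
    """A documented precondition was violated by the caller."""


def centi(x: float) -> int:
    """Round ``100*x`` half away from zero to an integer score."""
    v = abs(x) * 100.0
    r = math.floor(v + 0.5)
    return r if x >= 0 else -r


# ---------------------------------------------------------------------------
# sequences and queries
# ---------------------------------------------------------------------------


def _normalize_rna(s: str) -> str:
    return s.upper().replace("T", "U")


@dataclass
class TargetSequence:
    """A target RNA; residues over {A,C,G,U,N}, 1-based positions."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = _normalize_rna(self.residues)
        if len(self.residues) < 1:
            raise ParseError(f"target {self.identifier!r}: empty sequence")
        bad = set(self.residues) - set("ACGUN")
        if bad:
            raise ParseError(
                f"target {self.identifier!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i: int) -> str:
        """1-based residue access."""
        return self.residues[i - 1]


@dataclass
class QueryInput:
    """Query as an alignment (a single sequence is a 1-row alignment).

    Rows may contain gap characters; ``consensus_structure`` is an optional
    dot-bracket string of the alignment length.
    """

    rows: List[str]
    consensus_structure: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ParseError("query: no rows")
        self.rows = [_normalize_rna(r) for r in self.rows]
        m = len(self.rows[0])
        if m == 0:
            raise ParseError("query: empty rows")
        for r in self.rows:
            if len(r) != m:
                raise ParseError("query: rows differ in length")
        if self.consensus_structure is not None and len(self.consensus_structure) != m:
            raise ParseError("query: structure length != alignment length")

    @property
    def m(self) -> int:
        return len(self.rows[0])


# ---------------------------------------------------------------------------
# base pair probability matrices
# ---------------------------------------------------------------------------


class BppMatrix:
    """Sparse substochastic matrix of base-pair probabilities.

    Entries map ordered pairs ``(i, j)`` with ``i < j`` (1-based) to a
    probability in (0, 1].  ``max_span`` limits ``j - i`` (targets only).
    """

    SLACK = 1e-6

    def __init__(
        self,
        length: int,
        entries: Optional[Dict[Tuple[int, int], float]] = None,
        max_span: Optional[int] = None,
        p_min: float = 0.0,
    ):
        if length < 1:
            raise ValueError("BppMatrix length must be >= 1")
        self.length = length
        self.max_span = max_span
        self.p_min = p_min
        self.entries: Dict[Tuple[int, int], float] = {}
        if entries:
            for (i, j), p in entries.items():
                self.set(i, j, p)

    def set(self, i: int, j: int, p: float) -> None:
        if not (1 <= i < j <= self.length):
            raise ValueError(f"bad pair indices ({i},{j}) for length {self.length}")
        if not (0.0 < p <= 1.0):
            raise ValueError(f"pair ({i},{j}): probability {p} outside (0,1]")
        if self.max_span is not None and j - i > self.max_span:
            raise ValueError(f"pair ({i},{j}) exceeds max span {self.max_span}")
        self.entries[(i, j)] = p

    def get(self, i: int, j: int) -> float:
        return self.entries.get((i, j), 0.0)

    def __contains__(self, pair: Tuple[int, int]) -> bool:
        return pair in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def pairs(self) -> List[Tuple[int, int]]:
        return sorted(self.entries)

    def filtered(self, p_min: float) -> "BppMatrix":
        """Copy retaining entries with probability >= ``p_min``."""
        out = BppMatrix(self.length, max_span=self.max_span, p_min=p_min)
        for (i, j), p in self.entries.items():
            if p >= p_min:
                out.entries[(i, j)] = p
        return out

    def validate_substochastic(self) -> None:
        sums = [0.0] * (self.length + 1)
        for (i, j), p in self.entries.items():
            sums[i] += p
            sums[j] += p
        bad = [i for i, s in enumerate(sums) if s > 1.0 + self.SLACK]
        if bad:
            raise ValueError(f"not substochastic at positions {bad[:5]}")


def query_bpp_from_structure(structure: str, m: Optional[int] = None) -> BppMatrix:
    """Base pair probability matrix with the structure's pairs set to 1."""
    pairs = parse_dotbracket(structure)
    length = m if m is not None else len(structure)
    if length != len(structure):
        raise ParseError("structure length mismatch")
    bpp = BppMatrix(length)
    for i, j in pairs:
        bpp.set(i, j, 1.0)
    return bpp


_OPENERS = {"(": ")", "<": ">", "[": "]", "{": "}"}
_CLOSERS = {v: k for k, v in _OPENERS.items()}
_UNPAIRED = set(".:,-_~")


def parse_dotbracket(structure: str) -> List[Tuple[int, int]]:
    """Parse a dot-bracket string into a sorted list of 1-based pairs.

    Raises :class:`ParseError` naming the offending position for unbalanced
    strings; crossing pairs between bracket families are rejected.
    """
    stacks: Dict[str, List[int]] = {o: [] for o in _OPENERS}
    pairs: List[Tuple[int, int]] = []
    for pos, c in enumerate(structure, start=1):
        if c in _OPENERS:
            stacks[c].append(pos)
        elif c in _CLOSERS:
            stk = stacks[_CLOSERS[c]]
            if not stk:
                raise ParseError(f"unbalanced structure: unmatched {c!r} at position {pos}")
            pairs.append((stk.pop(), pos))
        elif c in _UNPAIRED:
            continue
        else:
            raise ParseError(f"illegal structure character {c!r} at position {pos}")
    for o, stk in stacks.items():
        if stk:
            raise ParseError(
                f"unbalanced structure: unmatched {o!r} at position {stk[0]} (unclosed)"
            )
    pairs.sort()
    _check_noncrossing(pairs, "structure")
    return pairs


def _check_noncrossing(pairs: Sequence[Tuple[int, int]], what: str) -> None:
    ps = sorted(pairs)
    for a in range(len(ps)):
        i, j = ps[a]
        for b in range(a + 1, len(ps)):
            i2, j2 = ps[b]
            if i2 >= j:
                break
            if not (j2 < j):  # i < i2 < j <= j2 crosses (shared ends included)
                raise ParseError(f"{what}: pairs ({i},{j}) and ({i2},{j2}) cross")
            if i == i2 or j == j2 or i2 == j:
                raise ParseError(f"{what}: pairs share an endpoint")


def pairs_to_dotbracket(pairs: Iterable[Tuple[int, int]], length: int) -> str:
    s = ["."] * length
    for i, j in pairs:
        s[i - 1] = "("
        s[j - 1] = ")"
    return "".join(s)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class ScoreParams:
    """Scanner scoring parameters (centi-unit integer scores).

    Defaults mirror the published parameterization: struct-weight 200
    (i.e. 2.0), tau weight 400 (4.0), indel -100, indel-opening -500.
    """

    gamma: int = -100
    gap_opening: int = -500
    struct_weight: int = 200
    tau_weight: int = 400
    p_min: float = 0.01
    max_span: int = 100
    use_sequence_scores: bool = True
    pseudocount_mass: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma >= 0:
            raise ValueError("gamma must be negative")
        if self.gap_opening > 0:
            raise ValueError("gap_opening must be <= 0")
        if not (0.0 < self.p_min < 1.0):
            raise ValueError("p_min must be in (0,1)")
        if self.max_span < 1:
            raise ValueError("max_span must be >= 1")

    @property
    def tau_factor(self) -> float:
        return self.tau_weight / 100.0


# ---------------------------------------------------------------------------
# query profile and the similarity functions sigma / tau / psi
# ---------------------------------------------------------------------------

_MONO_FLOOR = 0.01
_NONCANONICAL_FLOOR = 1e-3


class QueryProfile:
    """Per-column nucleotide and pair frequencies with pseudocounts.

    ``single[k]`` is a length-4 frequency vector over ACGU for column k
    (1-based); ``pair[(k, l)]`` is a length-7 vector over the six canonical
    pairs plus a pooled non-canonical slot.
    """

    def __init__(
        self,
        single: np.ndarray,
        pair: Dict[Tuple[int, int], np.ndarray],
        pseudocount_mass: float,
        background_mono: np.ndarray,
    ):
        self.single = single
        self.pair = pair
        self.pseudocount_mass = pseudocount_mass
        self.background_mono = background_mono
        self.m = single.shape[0] - 1

    def single_freq(self, k: int, t: str) -> float:
        return float(self.single[k, NT_INDEX[t]])

    def pair_freq(self, k: int, l: int, t: str, t2: str) -> float:
        tab = self.pair[(k, l)]
        idx = PAIR_INDEX.get(t + t2, NONCANONICAL_SLOT)
        return float(tab[idx])


def build_profile(
    query: QueryInput,
    pseudocount_mass: float = 1.0,
    query_bpp: Optional[BppMatrix] = None,
) -> QueryProfile:
    """Build the per-column (and per-pair-of-columns) frequency profile.

    Gap symbols (and N) are excluded from counts; pseudocounts are added in
    proportion to the query-wide mononucleotide frequencies (floored at 0.01
    and renormalized).  Pair tables are built only for columns ``(k, l)`` in
    the query bpp matrix.
    """
    if pseudocount_mass < 0:
        raise ValueError("pseudocount_mass must be >= 0")
    m = query.m
    rows = query.rows

    counts = np.zeros((m + 1, 4))
    total = np.zeros(4)
    for r in rows:
        for k, c in enumerate(r, start=1):
            if c in GAP_CHARS:
                continue
            if c not in NT_INDEX:
                raise ParseError(f"query: illegal residue {c!r} in column {k}")
            counts[k, NT_INDEX[c]] += 1
            total[NT_INDEX[c]] += 1

    if total.sum() > 0:
        bg = total / total.sum()
    else:
        bg = np.full(4, 0.25)
    bg = np.maximum(bg, _MONO_FLOOR)
    bg = bg / bg.sum()

    single = np.zeros((m + 1, 4))
    warned = False
    for k in range(1, m + 1):
        nongap = counts[k].sum()
        if nongap == 0 and pseudocount_mass == 0:
            if not warned:
                log.warning("query column %d has no residues; using background", k)
                warned = True
            single[k] = np.full(4, SINGLE_BACKGROUND)
        elif nongap == 0:
            if not warned:
                log.warning(
                    "query column %d has no residues; pseudocounts only", k
                )
                warned = True
            single[k] = (pseudocount_mass * bg) / pseudocount_mass
        else:
            single[k] = (counts[k] + pseudocount_mass * bg) / (
                nongap + pseudocount_mass
            )

    pair: Dict[Tuple[int, int], np.ndarray] = {}
    if query_bpp is not None:
        bg2 = np.array(
            [bg[NT_INDEX[p[0]]] * bg[NT_INDEX[p[1]]] for p in CANONICAL_PAIRS]
        )
        for (k, l) in query_bpp.pairs():
            c = np.zeros(6)
            nc = 0.0
            n_obs = 0.0
            for r in rows:
                a, b = r[k - 1], r[l - 1]
                if a in GAP_CHARS or b in GAP_CHARS:
                    continue
                n_obs += 1
                idx = PAIR_INDEX.get(a + b)
                if idx is None:
                    nc += 1
                else:
                    c[idx] += 1
            c = c + pseudocount_mass * bg2
            if c.sum() == 0:
                c = bg2 if bg2.sum() > 0 else np.full(6, 1.0)
            # pooled non-canonical mass, floored so tau stays finite
            nc_mass = max(nc, _NONCANONICAL_FLOOR * (n_obs + pseudocount_mass + 1.0))
            tab = np.concatenate([c, [nc_mass]])
            pair[(k, l)] = tab / tab.sum()

    return QueryProfile(single, pair, pseudocount_mass, bg)


def sigma(t: str, k: int, profile: QueryProfile) -> int:
    """Eq.-(8)-style single-stranded log-odds score, centi-units.

    N carries no evidence and scores 0.
    """
    if t == "N":
        return 0
    f = profile.single_freq(k, t)
    if f <= 0.0:
        return NEG_INF
    return centi(math.log(f / SINGLE_BACKGROUND))


def tau(
    t: str,
    t2: str,
    k: int,
    l: int,
    profile: QueryProfile,
    tau_factor: float = 1.0,
) -> int:
    """Paired log-odds score; the weight is applied to the rounded centi value."""
    if t == "N" or t2 == "N":
        return 0
    f = profile.pair_freq(k, l, t, t2)
    if f <= 0.0:
        return NEG_INF
    base = centi(math.log(f / PAIR_BACKGROUND))
    return int(round(tau_factor * base))


def psi(bpp: BppMatrix, pair: Tuple[int, int], params: ScoreParams) -> int:
    """Structure contribution of a base pair: bounded log odds vs p_min.

    Returns the minus-infinity sentinel below the cutoff; otherwise
    ``struct_weight * log(P/p_min)/log(1/p_min)`` in (0, struct_weight].
    """
    p = bpp.get(*pair)
    if p < params.p_min:
        return NEG_INF
    return int(round(params.struct_weight * math.log(p / params.p_min)
                     / math.log(1.0 / params.p_min)))


# ---------------------------------------------------------------------------
# alignments, consensus structures, total score
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """Set of edges (i, k): target position i aligned to query column k."""

    edges: Set[Tuple[int, int]] = field(default_factory=set)

    def validate(self) -> None:
        es = sorted(self.edges)
        for (i, k), (i2, k2) in zip(es, es[1:]):
            if not (i < i2 and k < k2):
                raise ContractError(f"alignment edges ({i},{k}),({i2},{k2}) conflict")

    def sorted_edges(self) -> List[Tuple[int, int]]:
        return sorted(self.edges)


@dataclass
class ConsensusStructure:
    """Set of matched base pairs ((i,j),(k,l)) of target and query."""

    pairs: Set[Tuple[Tuple[int, int], Tuple[int, int]]] = field(default_factory=set)

    def validate(self, alignment: Optional[Alignment] = None) -> None:
        tp = [p[0] for p in self.pairs]
        qp = [p[1] for p in self.pairs]
        try:
            _check_noncrossing(tp, "target structure")
            _check_noncrossing(qp, "query structure")
        except ParseError as e:
            raise ContractError(str(e)) from e
        if alignment is not None:
            for (i, j), (k, l) in self.pairs:
                if (i, k) not in alignment.edges or (j, l) not in alignment.edges:
                    raise ContractError(
                        f"structure pair (({i},{j}),({k},{l})) not supported by edges"
                    )


def _gap_runs(deleted: Sequence[int]) -> int:
    """Number of maximal runs of consecutive integers."""
    runs = 0
    prev = None
    for x in sorted(deleted):
        if prev is None or x != prev + 1:
            runs += 1
        prev = x
    return runs


def total_score(
    alignment: Alignment,
    structure: ConsensusStructure,
    target: TargetSequence,
    profile: QueryProfile,
    target_bpp: BppMatrix,
    query_bpp: BppMatrix,
    params: ScoreParams,
    mode: str = "semiglobal",
    right_end: Optional[int] = None,
) -> int:
    """Additive score of a consistent (alignment, consensus structure) pair.

    ``mode`` is "global" (Eq.-(2) global gap count) or "semiglobal" (free
    target end deletions).  With ``right_end`` set in semiglobal mode the
    target is charged up to that position (the subscore with free left end
    deletions only, as streamed by the scanner).
    """
    alignment.validate()
    structure.validate(alignment)

    n, m = len(target), profile.m
    score = 0
    struct_edge: Set[Tuple[int, int]] = set()
    for (i, j), (k, l) in structure.pairs:
        pt = psi(target_bpp, (i, j), params)
        pq = psi(query_bpp, (k, l), params)
        if pt <= NEG_INF or pq <= NEG_INF:
            raise ContractError(
                f"structure pair (({i},{j}),({k},{l})) below p_min"
            )
        score += pt + pq
        if params.use_sequence_scores:
            score += tau(target[i], target[j], k, l, profile, params.tau_factor)
        struct_edge.update([(i, k), (j, l)])

    if params.use_sequence_scores:
        for i, k in alignment.edges - struct_edge:
            score += sigma(target[i], k, profile)

    edges = alignment.sorted_edges()
    aligned_t = {i for i, _ in edges}
    aligned_q = {k for _, k in edges}
    if mode == "global":
        lo, hi = 1, n
    elif mode == "semiglobal":
        if not edges:
            n_gap = m
            runs = 1 if m > 0 else 0
            return score + params.gamma * n_gap + params.gap_opening * runs
        lo = min(aligned_t)
        hi = right_end if right_end is not None else max(aligned_t)
        if right_end is not None and right_end < max(aligned_t):
            raise ContractError("right_end before last aligned target position")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "global" and not edges:
        n_gap = n + m
        runs = (1 if n > 0 else 0) + (1 if m > 0 else 0)
        return score + params.gamma * n_gap + params.gap_opening * runs

    del_t = [i for i in range(lo, hi + 1) if i not in aligned_t]
    del_q = [k for k in range(1, m + 1) if k not in aligned_q]
    n_gap = len(del_t) + len(del_q)
    runs = _gap_runs(del_t) + _gap_runs(del_q)
    return score + params.gamma * n_gap + params.gap_opening * runs
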
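"""Target base-pair probabilities: file input or a built-in windowed folder.

The built-in model is a deliberately simple pair-additive Boltzmann ensemble
over non-crossing canonical structures (hairpin loops >= min_loop, optional
exclusion of lonely pairs via a helix grammar).  Inside values are computed
once for all intervals up to the window size; each window then gets an exact
outside pass and pair probabilities are averaged over the windows containing
the pair.  Computations use extended precision so no rescaling is needed at
the window sizes involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import AlignIO, SeqIO

from . import _kernels
from .model import (
    BppMatrix,
    ParseError,
    QueryInput,
    TargetSequence,
    parse_dotbracket,
    pairs_to_dotbracket,
)

_NT_CODE = {c: i for i, c in enumerate("ACGUN")}


def _codes(seq: str) -> np.ndarray:
    return np.array([_NT_CODE[c] for c in seq], dtype=np.int64)


def _weight_matrix(model: "EnergyModel") -> np.ndarray:
    w = np.zeros((5, 5))
    for pq, e in model.pair_energy.items():
        w[_NT_CODE[pq[0]], _NT_CODE[pq[1]]] = math.exp(-e / model.rt)
    return w

LD = np.longdouble

DEFAULT_PAIR_ENERGY = {
    "GC": -3.0, "CG": -3.0,
    "AU": -2.0, "UA": -2.0,
    "GU": -1.0, "UG": -1.0,
}


@dataclass
class EnergyModel:
    """Pair-additive Boltzmann stand-in for a thermodynamic folder.

    ``helix_init`` is a nonnegative cost charged once per helix (maximal
    stack), the coarse analogue of a loop-initiation penalty; it requires
    the helix grammar, i.e. ``no_lonely_pairs``.
    """

    pair_energy: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_ENERGY))
    min_loop: int = 3
    rt: float = 1.0
    no_lonely_pairs: bool = True
    helix_init: float = 0.0

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        if any(e >= 0 for e in self.pair_energy.values()):
            raise ValueError("pair energies must be negative")
        if self.rt <= 0:
            raise ValueError("rt must be positive")
        if self.helix_init < 0:
            raise ValueError("helix_init must be >= 0")
        if self.helix_init and not self.no_lonely_pairs:
            raise ValueError("helix_init requires no_lonely_pairs")

    def energy(self, a: str, b: str) -> Optional[float]:
        return self.pair_energy.get(a + b)

    def weight(self, a: str, b: str) -> float:
        e = self.energy(a, b)
        return 0.0 if e is None else math.exp(-e / self.rt)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_fasta(path) -> List[TargetSequence]:
    records = [
        TargetSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


def write_fasta(path, records: Sequence[TargetSequence]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.identifier}\n")
            for o in range(0, len(r.residues), 70):
                fh.write(r.residues[o : o + 70] + "\n")


def read_bpp(path, p_min: float = 0.0, length: Optional[int] = None) -> BppMatrix:
    """Sparse triplet text: lines "i<TAB>j<TAB>p", 1-based, '#' comments."""
    entries: Dict[Tuple[int, int], float] = {}
    max_j = 0
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{ln}: expected 'i j p', got {line!r}")
            try:
                i, j, p = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as e:
                raise ParseError(f"{path}:{ln}: {e}") from e
            if not i < j:
                raise ParseError(f"{path}:{ln}: need i < j")
            if not 0.0 < p <= 1.0:
                raise ParseError(f"{path}:{ln}: probability {p} outside (0,1]")
            if (i, j) in entries:
                raise ParseError(f"{path}:{ln}: duplicate pair ({i},{j})")
            entries[(i, j)] = p
            max_j = max(max_j, j)
    n = length if length is not None else max(max_j, 1)
    span = max((j - i for (i, j) in entries), default=None)
    bpp = BppMatrix(n, max_span=span, p_min=p_min)
    for (i, j), p in entries.items():
        if p >= p_min:
            bpp.entries[(i, j)] = p
    return bpp


def write_bpp(path, bpp: BppMatrix, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for (i, j) in bpp.pairs():
            fh.write(f"{i}\t{j}\t{bpp.get(i, j):.6g}\n")


def read_query(path, structure: Optional[str] = None, fmt: Optional[str] = None
               ) -> QueryInput:
    """Query loader: Stockholm (SS_cons), Clustal (+ separate structure),
    or a plain file of one sequence line followed by one dot-bracket line."""
    p = str(path)
    if fmt is None:
        if p.endswith((".sto", ".stk", ".stockholm")):
            fmt = "stockholm"
        elif p.endswith((".aln", ".clustal")):
            fmt = "clustal"
        else:
            fmt = "dotbracket"
    if fmt in ("stockholm", "clustal"):
        aln = AlignIO.read(p, fmt)
        rows = [str(rec.seq) for rec in aln]
        ss = structure
        if ss is None and fmt == "stockholm":
            ss = aln.column_annotations.get("secondary_structure")
        return QueryInput(rows=rows, consensus_structure=ss)
    lines = []
    with open(p) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith(("#", ">")):
                lines.append(line)
    if not lines:
        raise ParseError(f"{path}: empty query file")
    seq = lines[0]
    ss = structure if structure is not None else (lines[1] if len(lines) > 1 else None)
    return QueryInput(rows=[seq], consensus_structure=ss)


# ---------------------------------------------------------------------------
# inside recursion (shared across windows)
# ---------------------------------------------------------------------------


class InsideTables:
    """Diagonal-major inside values.

    ``Z[d][a]``: partition function over the interval [a, a+d] (0-based).
    ``H[d]``: interval closed by a pair that starts a helix (the pair and its
    inward neighbour both present when lonely pairs are excluded).
    ``G[d]``: interval closed by a pair relying on an outward stack.
    """

    def __init__(self, seq: str, model: EnergyModel, span: int, dmax: int,
                 dtype=LD):
        self.seq = seq
        self.model = model
        self.span = span
        self.dmax = dmax
        self.dtype = dtype
        self.hfac = dtype(math.exp(-model.helix_init / model.rt))
        n = len(seq)
        self.n = n
        ml = model.min_loop
        no_lp = model.no_lonely_pairs

        wrow = np.zeros((5, 5))
        idx = {c: i for i, c in enumerate("ACGUN")}
        for pq, e in model.pair_energy.items():
            wrow[idx[pq[0]], idx[pq[1]]] = math.exp(-e / model.rt)
        codes = np.array([idx[c] for c in seq], dtype=np.int64)

        self.w: Dict[int, np.ndarray] = {}
        self.Z: List[np.ndarray] = [np.ones(n, dtype=dtype)]
        self.H: Dict[int, np.ndarray] = {}
        self.G: Dict[int, np.ndarray] = {}

        for d in range(1, dmax + 1):
            nd = n - d
            if nd <= 0:
                break
            if ml + 1 <= d <= span:
                w = wrow[codes[:nd], codes[d:]].astype(dtype)
                self.w[d] = w
                if no_lp:
                    inner = d - 2
                    Yin = self.Z[inner][1 : 1 + nd] - self._h(inner, 1, nd)
                    g = w * (Yin + self._g(inner, 1, nd))
                    self.G[d] = g
                    h = (w * self.hfac) * self._g(inner, 1, nd)
                    if h.any():
                        self.H[d] = h
                else:
                    h = w * self.Z[d - 2][1 : 1 + nd]
                    if h.any():
                        self.H[d] = h
            z = self.Z[d - 1][:nd].copy()
            for e in range(ml + 1, min(d, span) + 1):
                he = self.H.get(e)
                if he is None:
                    continue
                if e == d:
                    z += he
                else:
                    z += self.Z[d - e - 1][:nd] * he[d - e : d - e + nd]
            self.Z.append(z)

    def _h(self, d: int, off: int, count: int) -> np.ndarray:
        h = self.H.get(d)
        if h is None:
            return np.zeros(count, dtype=self.dtype)
        return h[off : off + count]

    def _g(self, d: int, off: int, count: int) -> np.ndarray:
        g = self.G.get(d)
        if g is None:
            return np.zeros(count, dtype=self.dtype)
        return g[off : off + count]

    def zval(self, a: int, b: int):
        if b < a:
            return self.dtype(1.0)
        return self.Z[b - a][a]


def _window_pair_probs(ins: InsideTables, s: int, W: int) -> np.ndarray:
    """Exact pair probabilities for the window [s, s+W-1] (local indices)."""
    ml = ins.model.min_loop
    span = ins.span
    no_lp = ins.model.no_lonely_pairs

    def diag(src: Dict[int, np.ndarray] | List[np.ndarray], d: int) -> np.ndarray:
        arr = src[d] if not isinstance(src, dict) else src.get(d)
        if arr is None:
            return np.zeros(W - d, dtype=LD)
        return arr[s : s + W - d]

    Zl = np.zeros((W, W), dtype=LD)
    Hl = np.zeros((W, W), dtype=LD)
    Gl = np.zeros((W, W), dtype=LD)
    wl = np.zeros((W, W), dtype=LD)
    for d in range(0, W):
        u = np.arange(W - d)
        Zl[u, u + d] = diag(ins.Z, d)
        if ml + 1 <= d <= span:
            Hl[u, u + d] = diag(ins.H, d)
            if no_lp:
                Gl[u, u + d] = diag(ins.G, d)
            wl[u, u + d] = diag(ins.w, d)

    OZ = np.zeros((W, W), dtype=LD)
    OH = np.zeros((W, W), dtype=LD)
    OG = np.zeros((W, W), dtype=LD)
    OY = np.zeros((W, W), dtype=LD)
    OZ[0, W - 1] = 1.0

    for d in range(W - 1, -1, -1):
        u = np.arange(W - d)
        v = u + d
        if no_lp:
            oy = OY[u, v]
            OZ[u, v] += oy
            OH[u, v] -= oy
        oz = OZ[u, v]
        if d >= 1:
            OZ[u, v - 1] += oz
        for e in range(ml + 1, min(d, span) + 1):
            k = v - e
            h = Hl[k, v]
            if e == d:
                OH[k, v] += oz
            else:
                OZ[u, k - 1] += oz * h
                OH[k, v] += oz * Zl[u, k - 1]
        if ml + 1 <= d <= span:
            w = wl[u, v]
            oh = OH[u, v]
            if no_lp:
                OG[u + 1, v - 1] += oh * (w * ins.hfac)
                og = OG[u, v]
                OY[u + 1, v - 1] += og * w
                OG[u + 1, v - 1] += og * w
            else:
                OZ[u + 1, v - 1] += oh * w

    ztot = Zl[0, W - 1]
    if no_lp:
        P = (OH * Hl + OG * Gl) / ztot
    else:
        P = OH * Hl / ztot
    return P


def local_partition_fold(
    target: TargetSequence | str,
    window: int,
    span: int,
    model: Optional[EnergyModel] = None,
    floor: float = 0.0,
    step: int = 1,
) -> BppMatrix:
    """Windowed pair probabilities, averaged over windows containing a pair.

    ``step`` subsamples window start positions (1 reproduces the
    scan-every-position behaviour); it is capped so every admissible pair is
    covered by at least one window.
    """
    model = model or EnergyModel()
    seq = target.residues if isinstance(target, TargetSequence) else str(target)
    n = len(seq)
    if window < span:
        raise ValueError("window must be >= span")
    W = min(window, n)
    span = min(span, W - 1) if W > 1 else 0
    if n < model.min_loop + 2 or span < model.min_loop + 1:
        return BppMatrix(max(n, 1), max_span=span or None)
    step = max(1, min(step, max(1, W - span)))

    starts = list(range(0, n - W + 1, step))
    if starts[-1] != n - W:
        starts.append(n - W)

    # pairs contributing < collect_min to the window mean are treated as 0;
    # exact (1e-12) when a single window covers everything
    collect_min = 1e-12 if len(starts) == 1 else max(1e-9, floor * 0.02)

    windows = _iter_window_probs(seq, model, W, span, starts)

    psum: Dict[Tuple[int, int], float] = {}
    for s, P in windows:
        iu, ju = np.nonzero(P > collect_min)
        for u, v in zip(iu.tolist(), ju.tolist()):
            key = (s + u + 1, s + v + 1)  # back to 1-based
            psum[key] = psum.get(key, 0.0) + float(P[u, v])

    first, last = starts[0], n - W
    extra = starts[-1] if starts[-1] % step else None

    def n_windows(i0: int, j0: int) -> int:
        lo = max(first, j0 - W + 1)
        hi = min(i0, last)
        if hi < lo:
            return 0
        cnt = hi // step - (lo + step - 1) // step + 1
        if extra is not None and lo <= extra <= hi and extra % step:
            cnt += 1
        return cnt

    bpp = BppMatrix(n, max_span=span, p_min=floor)
    for (i, j), tot in psum.items():
        cnt = n_windows(i - 1, j - 1)
        p = min(1.0, tot / cnt)
        if p >= floor:
            bpp.entries[(i, j)] = p
    return bpp


def _iter_window_probs(seq, model, W, span, starts):
    """Yield (start, P) per window; jitted float64 with extended-precision
    fallback on overflow or when numba is missing."""
    ml = model.min_loop
    no_lp = model.no_lonely_pairs
    ins_ld = None
    use_fast = _kernels.HAS_NUMBA
    Zf = Hf = Gf = None
    if use_fast:
        codes = _codes(seq)
        wmat = _weight_matrix(model)
        hfac = math.exp(-model.helix_init / model.rt)
        Zf, Hf, Gf = _kernels.inside_diag(
            codes, wmat, hfac, ml, span, W - 1, no_lp)
        if not np.isfinite(Zf[-1]).all():
            use_fast = False

    for s in starts:
        P = None
        if use_fast:
            P = _kernels.outside_window(
                Zf, Hf, Gf, codes, wmat, hfac, s, W, ml, span, no_lp)
            if not np.isfinite(P).all():
                P = None
        if P is None:
            if ins_ld is None:
                ins_ld = InsideTables(seq, model, span=span, dmax=W - 1)
            P = _window_pair_probs(ins_ld, s, W).astype(float)
        yield s, P


# ---------------------------------------------------------------------------
# single-structure probability and constrained minimum-energy folding
# ---------------------------------------------------------------------------


def _structure_in_ensemble(seq: str, pairs, model: EnergyModel) -> bool:
    ps = set(pairs)
    for (i, j) in pairs:
        if model.energy(seq[i - 1], seq[j - 1]) is None:
            return False
        if j - i - 1 < model.min_loop:
            return False
        if model.no_lonely_pairs:
            if (i + 1, j - 1) not in ps and (i - 1, j + 1) not in ps:
                return False
    return True


def structure_probability(
    target: TargetSequence | str, structure: str, model: Optional[EnergyModel] = None
) -> float:
    """Boltzmann probability of one structure in the full-length ensemble."""
    model = model or EnergyModel()
    seq = target.residues if isinstance(target, TargetSequence) else str(target)
    pairs = parse_dotbracket(structure)
    if len(structure) != len(seq):
        raise ValueError("structure length != sequence length")
    if not _structure_in_ensemble(seq, pairs, model):
        return 0.0
    energy = sum(model.energy(seq[i - 1], seq[j - 1]) for (i, j) in pairs)
    if model.helix_init:
        ps = set(pairs)
        n_helices = sum(1 for (i, j) in pairs if (i - 1, j + 1) not in ps)
        energy += model.helix_init * n_helices
    n = len(seq)
    span = max(n - 1, 1)
    if _kernels.HAS_NUMBA:
        Z, _, _ = _kernels.inside_diag(
            _codes(seq), _weight_matrix(model),
            math.exp(-model.helix_init / model.rt),
            model.min_loop, span, n - 1, model.no_lonely_pairs)
        z = Z[n - 1, 0]
        w = math.exp(-energy / model.rt) if -energy / model.rt < 700 else np.inf
        if np.isfinite(z) and np.isfinite(w):
            return float(w / z)
    # extended-precision fallback
    ins = InsideTables(seq, model, span=span, dmax=n - 1, dtype=LD)
    z = ins.zval(0, n - 1)
    w = np.exp(LD(-energy / model.rt))
    if not (np.isfinite(z) and np.isfinite(w)):
        raise OverflowError("partition function overflowed extended precision")
    return float(w / z)


INF = float("inf")


def constrained_fold(
    target: TargetSequence | str,
    constraint: Optional[str] = None,
    model: Optional[EnergyModel] = None,
) -> str:
    """Minimum-energy structure honouring an optional constraint string.

    Constraint characters: '(' ')' enforce that exact pair; '.' forbids
    pairing; '?' (or no constraint) leaves a position free.  Deterministic:
    ties resolve toward leaving the rightmost base unpaired, then the
    innermost helix continuation.
    """
    model = model or EnergyModel()
    seq = target.residues if isinstance(target, TargetSequence) else str(target)
    n = len(seq)
    ml = model.min_loop
    no_lp = model.no_lonely_pairs

    partner = [None] * (n + 1)
    forced_unpaired = [False] * (n + 1)
    if constraint is not None:
        if len(constraint) != n:
            raise ParseError("constraint length != sequence length")
        for (i, j) in parse_dotbracket(constraint.replace("?", "~")):
            partner[i], partner[j] = j, i
        for pos, c in enumerate(constraint, start=1):
            if c == ".":
                forced_unpaired[pos] = True
        bad = [
            (i, partner[i])
            for i in range(1, n + 1)
            if partner[i] and i < partner[i]
            and model.energy(seq[i - 1], seq[partner[i] - 1]) is None
        ]
        if bad:
            raise ParseError(f"constraint enforces non-canonical pairs at {bad}")

    def e_pair(i: int, j: int) -> float:
        if j - i - 1 < ml:
            return INF
        if forced_unpaired[i] or forced_unpaired[j]:
            return INF
        if partner[i] not in (None, j) or partner[j] not in (None, i):
            return INF
        e = model.energy(seq[i - 1], seq[j - 1])
        return INF if e is None else e

    def may_skip(pos: int) -> bool:
        return partner[pos] is None

    # bottom-up min-plus tables over 1-based inclusive intervals
    E: Dict[Tuple[int, int], float] = {}
    Hm: Dict[Tuple[int, int], float] = {}
    Gm: Dict[Tuple[int, int], float] = {}
    Ym: Dict[Tuple[int, int], float] = {}

    def get(tab, a, b, empty=0.0):
        if b < a:
            return empty
        return tab.get((a, b), INF)

    for d in range(0, n):
        for a in range(1, n - d + 1):
            b = a + d
            ep = e_pair(a, b)
            if ep < INF:
                gm = ep + min(get(Ym, a + 1, b - 1), get(Gm, a + 1, b - 1, INF))
                if gm < INF:
                    Gm[(a, b)] = gm
                hm = (ep + model.helix_init + get(Gm, a + 1, b - 1, INF)) \
                    if no_lp else (ep + get(E, a + 1, b - 1))
                if hm < INF:
                    Hm[(a, b)] = hm
            best_e = get(E, a, b - 1) if may_skip(b) else INF
            best_y = best_e
            for k in range(a, b - ml):
                h = get(Hm, k, b, INF)
                if h >= INF:
                    continue
                cand = get(E, a, k - 1) + h
                best_e = min(best_e, cand)
                if k > a:
                    best_y = min(best_y, cand)
            if best_e < INF:
                E[(a, b)] = best_e
            if best_y < INF:
                Ym[(a, b)] = best_y

    if get(E, 1, n) >= INF:
        raise ParseError("constraint is infeasible under the energy model")

    pairs: List[Tuple[int, int]] = []

    def trace_E(a: int, b: int, tab: str) -> None:
        while b >= a:
            val = get(Ym, a, b) if tab == "Y" else get(E, a, b)
            if may_skip(b) and get(E, a, b - 1) == val:
                b -= 1
                tab = "E"
                continue
            lo = a + 1 if tab == "Y" else a
            done = False
            for k in range(lo, b - ml):
                h = get(Hm, k, b, INF)
                if h < INF and get(E, a, k - 1) + h == val:
                    trace_closed(k, b, "H")
                    b = k - 1
                    tab = "E"
                    done = True
                    break
            if not done:
                raise RuntimeError("constrained fold trace failed")

    def trace_closed(i: int, j: int, tab: str) -> None:
        while True:
            pairs.append((i, j))
            ep = e_pair(i, j)
            if tab == "H" and no_lp:
                # helix start: inner pair guaranteed
                i, j, tab = i + 1, j - 1, "G"
                continue
            if tab == "H":
                trace_E(i + 1, j - 1, "E")
                return
            # tab == "G": continue helix or stop with a pair-free boundary
            if get(Gm, i, j, INF) == ep + get(Gm, i + 1, j - 1, INF):
                i, j, tab = i + 1, j - 1, "G"
                continue
            trace_E(i + 1, j - 1, "Y")
            return

    trace_E(1, n, "E")
    return pairs_to_dotbracket(sorted(pairs), n)
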
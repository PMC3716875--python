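"""Synthetic benchmark: designed decoys, pseudogenome assembly, evaluation.

Two decoy classes share a structure template and mononucleotide statistics
but differ in thermodynamics: the stabilized class is driven by an adaptive
walk until the template structure reaches a target ensemble probability; the
non-stabilized class merely admits the template's canonical pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fold import EnergyModel, structure_probability
from .model import parse_dotbracket, pairs_to_dotbracket

log = logging.getLogger(__name__)

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
CANONICAL_COMBOS = ("GC", "CG", "AU", "UA", "GU", "UG")


@dataclass
class StructureTemplate:
    structure: str
    source: str = "cloverleaf"

    @property
    def length(self) -> int:
        return len(self.structure)


@dataclass
class Decoy:
    identifier: str
    sequence: str
    structure: str
    class_label: str  # "stabilized" | "nonstabilized"
    structure_probability: Optional[float] = None


@dataclass
class Pseudogenome:
    sequence: str
    annotations: List[Tuple[int, int, str, str]]  # start, end, decoy id, class


def delta_energy_for_probability(p: float, rt: float = 1.0) -> float:
    """Energy gap equivalent to ensemble probability p: -RT ln(p)."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0,1)")
    return -rt * math.log(p)


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


@dataclass
class CloverleafDims:
    """Helix/loop dimensions of a cloverleaf; a 'family' shape."""

    acc: int
    stems: Tuple[int, int, int]
    loops: Tuple[int, int, int]
    spacers: Tuple[int, int, int, int]
    tail: int

    def render(self) -> str:
        s = "(" * self.acc
        for stem, loop, sp in zip(self.stems, self.loops, self.spacers[:3]):
            s += "." * sp + "(" * stem + "." * loop + ")" * stem
        s += "." * self.spacers[3] + ")" * self.acc + "." * self.tail
        return s


def sample_cloverleaf_dims(rng: np.random.Generator) -> CloverleafDims:
    return CloverleafDims(
        acc=int(rng.integers(6, 9)),
        stems=tuple(int(rng.integers(3, 7)) for _ in range(3)),
        loops=tuple(int(rng.integers(4, 10)) for _ in range(3)),
        spacers=tuple(int(rng.integers(1, 4)) for _ in range(4)),
        tail=int(rng.integers(2, 6)),
    )


def sample_family_dims(
    rng: np.random.Generator, length_range: Tuple[int, int] = (74, 88)
) -> CloverleafDims:
    """A family base shape with jitter headroom inside the template range."""
    lo, hi = length_range
    for _ in range(10_000):
        dims = sample_cloverleaf_dims(rng)
        if lo <= len(dims.render()) <= hi:
            return dims
    raise RuntimeError("failed to sample a family shape")


def make_cloverleaf_template(
    rng: np.random.Generator,
    length_range: Tuple[int, int] = (70, 92),
    family: Optional[CloverleafDims] = None,
) -> StructureTemplate:
    """Random 4-helix cloverleaf: acceptor stem 6-8 bp and three hairpin
    arms (stems 3-6 bp, loops 4-9 nt), rejection-sampled into the tRNA-like
    length range.

    With ``family`` set, only small jitters (+-1 on loops/tail, occasional
    +-1 on one stem) are applied to the given shape, emulating the mild
    structural variation within one RNA family.
    """
    lo, hi = length_range
    for _ in range(1000):
        if family is None:
            dims = sample_cloverleaf_dims(rng)
        else:
            loops = [
                int(np.clip(l + rng.integers(-1, 2), 4, 9)) for l in family.loops
            ]
            stems = list(family.stems)
            if rng.random() < 0.3:
                arm = int(rng.integers(3))
                stems[arm] = int(np.clip(stems[arm] + rng.integers(-1, 2), 3, 6))
            tail = int(np.clip(family.tail + rng.integers(-1, 2), 2, 5))
            dims = CloverleafDims(family.acc, tuple(stems), tuple(loops),
                                  family.spacers, tail)
        s = dims.render()
        if lo <= len(s) <= hi:
            return StructureTemplate(structure=s)
    raise RuntimeError("failed to sample a template in the length range")


def project_structure(aligned_row: str, consensus: str) -> Tuple[str, str]:
    """Drop gap columns of a row; pairs losing one side become unpaired."""
    if len(aligned_row) != len(consensus):
        raise ValueError("row and consensus differ in length")
    keep = [c not in "-.~_" for c in aligned_row]
    pairs = parse_dotbracket(consensus)
    new_pos = {}
    p = 0
    for col, k in enumerate(keep, start=1):
        if k:
            p += 1
            new_pos[col] = p
    out_pairs = [
        (new_pos[i], new_pos[j]) for (i, j) in pairs if keep[i - 1] and keep[j - 1]
    ]
    seq = "".join(c for c, k in zip(aligned_row, keep) if k).upper().replace("T", "U")
    return seq, pairs_to_dotbracket(out_pairs, p)


# ---------------------------------------------------------------------------
# decoy construction
# ---------------------------------------------------------------------------


def _random_compatible_sequence(
    structure: str, rng: np.random.Generator, gc_bias: float = 0.5
) -> List[str]:
    pairs = parse_dotbracket(structure)
    paired = {i for p in pairs for i in p}
    seq = [""] * (len(structure) + 1)
    combo_p = np.array([gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 3,
                        (1 - gc_bias) / 3, (1 - gc_bias) / 6, (1 - gc_bias) / 6])
    for (i, j) in pairs:
        combo = CANONICAL_COMBOS[rng.choice(6, p=combo_p)]
        seq[i], seq[j] = combo[0], combo[1]
    for i in range(1, len(structure) + 1):
        if i not in paired:
            seq[i] = "ACGU"[rng.integers(4)]
    return seq


def make_stabilized_decoy(
    template: StructureTemplate,
    model: EnergyModel,
    p_target: float = 0.75,
    rng: Optional[np.random.Generator] = None,
    max_iter: int = 3000,
    retry_max: int = 4,
    identifier: str = "decoy",
) -> Decoy:
    """Adaptive-walk inverse folding until the template structure reaches
    ensemble probability ``p_target``.

    Proposals are single-position mutations at unpaired sites and
    pair-preserving double mutations at paired sites; only improvements are
    accepted.  The stop criterion is equivalent to an energy gap of
    -RT ln(p_target) between the structure and the ensemble free energy.
    """
    rng = rng if rng is not None else np.random.default_rng()
    structure = template.structure
    pairs = parse_dotbracket(structure)
    paired = {i for p in pairs for i in p}
    unpaired = [i for i in range(1, len(structure) + 1) if i not in paired]
    sites = pairs + [(i, None) for i in unpaired]

    for attempt in range(retry_max):
        seq = _random_compatible_sequence(structure, rng, gc_bias=0.6)
        p = structure_probability("".join(seq[1:]), structure, model)
        it = 0
        while p < p_target and it < max_iter:
            it += 1
            i, j = sites[rng.integers(len(sites))]
            if j is None:
                old = seq[i]
                seq[i] = "ACGU"[rng.integers(4)]
                if seq[i] == old:
                    continue
                p_new = structure_probability("".join(seq[1:]), structure, model)
                if p_new > p:
                    p = p_new
                else:
                    seq[i] = old
            else:
                old_i, old_j = seq[i], seq[j]
                combo = CANONICAL_COMBOS[rng.integers(6)]
                if (combo[0], combo[1]) == (old_i, old_j):
                    continue
                seq[i], seq[j] = combo[0], combo[1]
                p_new = structure_probability("".join(seq[1:]), structure, model)
                if p_new > p:
                    p = p_new
                else:
                    seq[i], seq[j] = old_i, old_j
        if p >= p_target:
            return Decoy(identifier, "".join(seq[1:]), structure, "stabilized", p)
        log.info("inverse folding attempt %d reached only p=%.3f", attempt + 1, p)
    raise RuntimeError(
        f"inverse folding failed to reach p>={p_target} in {retry_max} attempts"
    )


def mononucleotide_frequencies(decoys: Sequence[Decoy]) -> Dict[str, float]:
    counts = {c: 0 for c in "ACGU"}
    for d in decoys:
        for c in d.sequence:
            counts[c] += 1
    total = sum(counts.values())
    return {c: counts[c] / total for c in "ACGU"}


def make_nonstabilized_decoy(
    template: StructureTemplate,
    mono_freq: Dict[str, float],
    rng: np.random.Generator,
    identifier: str = "decoy",
) -> Decoy:
    """Unpaired bases and left pair ends drawn from ``mono_freq``; right pair
    ends are the Watson-Crick complement of the left end (GU disallowed)."""
    structure = template.structure
    pairs = parse_dotbracket(structure)
    nts = list("ACGU")
    probs = np.array([mono_freq[c] for c in nts])
    probs = probs / probs.sum()
    seq = [""] * (len(structure) + 1)
    left_of = {i: j for (i, j) in pairs}
    right = {j for (_, j) in pairs}
    for i in range(1, len(structure) + 1):
        if i in right:
            continue
        seq[i] = nts[rng.choice(4, p=probs)]
        if i in left_of:
            seq[left_of[i]] = WC_COMPLEMENT[seq[i]]
    return Decoy(identifier, "".join(seq[1:]), structure, "nonstabilized")


def build_pseudogenome(
    decoys: Sequence[Decoy],
    spacing: int,
    mono_freq: Dict[str, float],
    rng: np.random.Generator,
) -> Pseudogenome:
    """One decoy every ``spacing`` bases, padded with random nucleotides."""
    for d in decoys:
        if len(d.sequence) > spacing:
            raise ValueError(f"decoy {d.identifier} longer than spacing {spacing}")
    order = list(decoys)
    perm = rng.permutation(len(order))
    order = [order[i] for i in perm]
    nts = list("ACGU")
    probs = np.array([mono_freq[c] for c in nts])
    probs = probs / probs.sum()
    chunks: List[str] = []
    annotations = []
    pos = 0
    for k, d in enumerate(order):
        start = k * spacing + 1
        chunks.append(d.sequence)
        annotations.append((start, start + len(d.sequence) - 1, d.identifier,
                            d.class_label))
        pad = spacing - len(d.sequence)
        if pad:
            chunks.append("".join(nts[i] for i in rng.choice(4, size=pad, p=probs)))
        pos += spacing
    return Pseudogenome("".join(chunks), annotations)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationResult:
    per_decoy: List[Tuple[str, str, Optional[float]]]  # id, class, best score
    thresholds: List[Tuple[float, int, int]]  # threshold, n_stab, n_nonstab
    auc: float


def rank_auc(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Mann-Whitney AUC with midranks for ties."""
    vals = [(v, 1) for v in pos] + [(v, 0) for v in neg]
    vals.sort(key=lambda t: t[0])
    ranks = {}
    i = 0
    rank_sum_pos = 0.0
    while i < len(vals):
        k = i
        while k < len(vals) and vals[k][0] == vals[i][0]:
            k += 1
        midrank = (i + 1 + k) / 2.0
        for idx in range(i, k):
            if vals[idx][1]:
                rank_sum_pos += midrank
        i = k
    n_pos, n_neg = len(pos), len(neg)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes for AUC")
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def evaluate_hits(
    occurrences,
    annotations: Sequence[Tuple[int, int, str, str]],
    min_overlap: float = 0.10,
) -> EvaluationResult:
    """Assign occurrences overlapping >= 10% of a decoy; keep the best score
    per decoy; tabulate recovered decoys per threshold and the class AUC."""
    best: Dict[str, Optional[float]] = {a[2]: None for a in annotations}
    classes = {a[2]: a[3] for a in annotations}
    for occ in occurrences:
        if occ.left_end is None:
            raise ValueError(f"occurrence at {occ.j} lacks a left end (no traceback)")
        for (ds, de, did, _cls) in annotations:
            ov = min(occ.j, de) - max(occ.left_end, ds) + 1
            if ov <= 0:
                continue
            if ov / (de - ds + 1) >= min_overlap:
                sc = occ.score / 100.0
                if best[did] is None or sc > best[did]:
                    best[did] = sc
    per_decoy = [(did, classes[did], best[did]) for did in best]

    miss = float("-inf")
    pos = [s if s is not None else miss for d, c, s in per_decoy if c == "stabilized"]
    neg = [s if s is not None else miss for d, c, s in per_decoy
           if c == "nonstabilized"]
    auc = rank_auc(pos, neg)

    scores = sorted({s for s in best.values() if s is not None}, reverse=True)
    thresholds = []
    for t in scores:
        n_s = sum(1 for d, c, s in per_decoy
                  if c == "stabilized" and s is not None and s >= t)
        n_n = sum(1 for d, c, s in per_decoy
                  if c == "nonstabilized" and s is not None and s >= t)
        thresholds.append((t, n_s, n_n))
    return EvaluationResult(per_decoy, thresholds, auc)


def write_decoy_table(path, decoys: Sequence[Decoy]) -> None:
    with open(path, "w") as fh:
        fh.write("id\tclass\tlength\tstructure_probability\n")
        for d in decoys:
            p = f"{d.structure_probability:.4f}" if d.structure_probability else "."
            fh.write(f"{d.identifier}\t{d.class_label}\t{len(d.sequence)}\t{p}\n")


def write_annotation_bed(path, genome: Pseudogenome, name: str = "pseudogenome"
                         ) -> None:
    with open(path, "w") as fh:
        for (s, e, did, cls) in genome.annotations:
            fh.write(f"{name}\t{s - 1}\t{e}\t{did}|{cls}\t0\t+\n")
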
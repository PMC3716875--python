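"""Scoring-function and domain-type tests."""

from __future__ import annotations

import math

import numpy as np
import pytest

from structscan.model import (
    NEG_INF,
    Alignment,
    BppMatrix,
    ConsensusStructure,
    ContractError,
    ParseError,
    QueryInput,
    ScoreParams,
    TargetSequence,
    build_profile,
    centi,
    parse_dotbracket,
    psi,
    query_bpp_from_structure,
    sigma,
    tau,
    total_score,
)


class TestTypes:
    def test_target_maps_t_to_u(self):
        t = TargetSequence("x", "acgt")
        assert t.residues == "ACGU"
        assert t[4] == "U"

    def test_target_rejects_bad_alphabet(self):
        with pytest.raises(ParseError):
            TargetSequence("x", "ACGB")

    def test_query_rows_must_match(self):
        with pytest.raises(ParseError):
            QueryInput(rows=["ACGU", "ACG"])

    def test_bpp_bounds(self):
        b = BppMatrix(10)
        b.set(1, 9, 0.8)
        with pytest.raises(ValueError):
            b.set(1, 9, 1.2)
        with pytest.raises(ValueError):
            b.set(9, 1, 0.5)

    def test_bpp_substochastic_check(self):
        b = BppMatrix(4)
        b.set(1, 4, 0.7)
        b.set(2, 4, 0.7)
        with pytest.raises(ValueError):
            b.validate_substochastic()

    def test_bpp_span_limit(self):
        b = BppMatrix(100, max_span=10)
        with pytest.raises(ValueError):
            b.set(1, 50, 0.5)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ScoreParams(gamma=100)
        with pytest.raises(ValueError):
            ScoreParams(p_min=1.5)


class TestDotBracket:
    def test_simple_hairpin(self):
        bpp = query_bpp_from_structure("((...))")
        assert bpp.pairs() == [(1, 7), (2, 6)]
        assert bpp.get(1, 7) == 1.0

    def test_all_dots_empty(self):
        assert query_bpp_from_structure(".......").pairs() == []

    def test_unbalanced_reports_position(self):
        with pytest.raises(ParseError, match="position 1"):
            parse_dotbracket("((.)")

    def test_unmatched_closer(self):
        with pytest.raises(ParseError, match="position 3"):
            parse_dotbracket("()) ".strip())

    def test_bracket_families(self):
        pairs = parse_dotbracket("(<...>)")
        assert pairs == [(1, 7), (2, 6)]


class TestSigma:
    def test_uniform_column_scores_zero(self):
        q = QueryInput(rows=["A", "C", "G", "U"])
        prof = build_profile(q, pseudocount_mass=0.0)
        for t in "ACGU":
            assert sigma(t, 1, prof) == 0

    def test_pure_column_log4(self):
        q = QueryInput(rows=["A"])
        prof = build_profile(q, pseudocount_mass=0.0)
        assert sigma("A", 1, prof) == 139  # round(100*ln 4)

    def test_n_scores_zero(self):
        q = QueryInput(rows=["A"])
        prof = build_profile(q, pseudocount_mass=0.0)
        assert sigma("N", 1, prof) == 0

    def test_pseudocounted_single_row(self):
        # query "A": mono background floors C,G,U at 0.01 and renormalizes
        q = QueryInput(rows=["A"])
        prof = build_profile(q, pseudocount_mass=1.0)
        bg = np.array([1.0, 0.01, 0.01, 0.01])
        bg = bg / bg.sum()
        f_g = (0 + 1.0 * bg[2]) / (1 + 1.0)
        assert sigma("G", 1, prof) == centi(math.log(f_g / 0.25))

    def test_gap_only_column_backs_off(self):
        q = QueryInput(rows=["-A"], consensus_structure=None)
        prof = build_profile(q, pseudocount_mass=0.0)
        assert sigma("C", 1, prof) == 0  # background fallback: log(0.25/0.25)


class TestTau:
    def _gc_profile(self, pc=0.0):
        q = QueryInput(rows=["GAAAC"], consensus_structure="(...)")
        bpp = query_bpp_from_structure("(...)")
        return build_profile(q, pseudocount_mass=pc, query_bpp=bpp)

    def test_uniform_pairs_score_zero(self):
        rows = ["GAAAC", "CAAAG", "AAAAU", "UAAAA", "GAAAU", "UAAAG"]
        q = QueryInput(rows=rows)
        bpp = query_bpp_from_structure("(...)")
        prof = build_profile(q, pseudocount_mass=0.0, query_bpp=bpp)
        # six canonical pairs observed once each; nc floor slightly below 1/6
        for p in ("GC", "CG", "AU"):
            assert abs(tau(p[0], p[1], 1, 5, prof)) <= 1

    def test_pure_gc_log6(self):
        prof = self._gc_profile()
        v = tau("G", "C", 1, 5, prof, tau_factor=1.0)
        # frequency is 1 minus the pooled non-canonical floor
        expect = centi(math.log((1.0 / (1.0 + 1e-3 * 2.0)) / (1 / 6)))
        assert v == expect
        assert 178 <= v <= 179

    def test_tau_weight_scales_rounded_value(self):
        prof = self._gc_profile()
        v1 = tau("G", "C", 1, 5, prof, tau_factor=1.0)
        v4 = tau("G", "C", 1, 5, prof, tau_factor=4.0)
        assert v4 == 4 * v1

    def test_noncanonical_pair_floor(self):
        prof = self._gc_profile()
        v = tau("A", "A", 1, 5, prof, tau_factor=1.0)
        assert v < -400  # pooled floor is far below background


class TestPsi:
    def test_max_probability_gives_struct_weight(self):
        params = ScoreParams(struct_weight=200, p_min=0.01)
        b = BppMatrix(10)
        b.set(2, 8, 1.0)
        assert psi(b, (2, 8), params) == 200

    def test_below_cutoff_sentinel(self):
        params = ScoreParams(p_min=0.01)
        b = BppMatrix(10)
        b.set(2, 8, 0.005)
        assert psi(b, (2, 8), params) == NEG_INF

    def test_intermediate_value(self):
        params = ScoreParams(struct_weight=200, p_min=0.01)
        b = BppMatrix(10)
        b.set(2, 8, 0.8)
        assert psi(b, (2, 8), params) == round(
            200 * math.log(0.8 / 0.01) / math.log(100))
        assert psi(b, (2, 8), params) == 190

    def test_strictly_increasing(self):
        params = ScoreParams(struct_weight=200, p_min=0.01)
        vals = []
        for p in [0.01, 0.05, 0.2, 0.5, 0.9, 1.0]:
            b = BppMatrix(10)
            b.set(2, 8, p)
            vals.append(psi(b, (2, 8), params))
        assert vals == sorted(vals)
        assert vals[-1] == 200
        assert vals[0] >= 0


class TestBuildProfile:
    def test_single_row_no_pseudocount(self):
        prof = build_profile(QueryInput(rows=["AC"]), pseudocount_mass=0.0)
        assert prof.single_freq(1, "A") == 1.0
        assert prof.single_freq(2, "C") == 1.0

    def test_two_row_column(self):
        prof = build_profile(QueryInput(rows=["A", "G"]), pseudocount_mass=0.0)
        assert prof.single_freq(1, "A") == 0.5
        assert prof.single_freq(1, "G") == 0.5

    def test_pseudocount_with_gap(self):
        # rows {A,-} in col 1; query-wide mono freq from all residues
        q = QueryInput(rows=["AA", "-C"])
        prof = build_profile(q, pseudocount_mass=1.0)
        bg = np.array([2 / 3, 1 / 3, 0.01, 0.01])
        bg = bg / bg.sum()
        want = (1 + 1.0 * bg[0]) / (1 + 1.0)
        assert prof.single_freq(1, "A") == pytest.approx(want)

    def test_columns_sum_to_one(self):
        q = QueryInput(rows=["ACGU", "AG-U", "A--U"])
        prof = build_profile(q, pseudocount_mass=1.0)
        for k in range(1, 5):
            assert sum(prof.single_freq(k, t) for t in "ACGU") == pytest.approx(1.0)


class TestTotalScore:
    def _setup(self, target="GGGAAACCC", struct="(((...)))"):
        t = TargetSequence("t", target)
        q = QueryInput(rows=[target], consensus_structure=struct)
        qbpp = query_bpp_from_structure(struct)
        tbpp = BppMatrix(len(target))
        for (i, j) in qbpp.pairs():
            tbpp.set(i, j, 0.9)
        params = ScoreParams(max_span=len(target), gap_opening=0,
                             use_sequence_scores=False)
        prof = build_profile(q, 1.0, qbpp)
        return t, q, prof, tbpp, qbpp, params

    def test_full_diagonal_structure(self):
        t, q, prof, tbpp, qbpp, params = self._setup()
        edges = {(i, i) for i in range(1, 10)}
        pairs = {((i, j), (i, j)) for (i, j) in qbpp.pairs()}
        a, s = Alignment(edges), ConsensusStructure(pairs)
        got = total_score(a, s, t, prof, tbpp, qbpp, params, mode="semiglobal")
        want = sum(psi(tbpp, p, params) + psi(qbpp, p, params)
                   for p in qbpp.pairs())
        assert got == want

    def test_empty_alignment_global(self):
        t = TargetSequence("t", "ACG")
        q = QueryInput(rows=["AC"])
        prof = build_profile(q, 1.0)
        params = ScoreParams(gamma=-100, gap_opening=0, max_span=3)
        got = total_score(Alignment(set()), ConsensusStructure(set()), t, prof,
                          BppMatrix(3), BppMatrix(2), params, mode="global")
        assert got == -500

    def test_inconsistent_structure_rejected(self):
        t, q, prof, tbpp, qbpp, params = self._setup()
        a = Alignment({(1, 1)})
        s = ConsensusStructure({((1, 9), (1, 9))})
        with pytest.raises(ContractError):
            total_score(a, s, t, prof, tbpp, qbpp, params)

    def test_order_invariance_is_additive(self):
        t, q, prof, tbpp, qbpp, params = self._setup()
        edges = {(i, i) for i in range(1, 10)}
        pairs = list({((i, j), (i, j)) for (i, j) in qbpp.pairs()})
        a = Alignment(edges)
        v1 = total_score(a, ConsensusStructure(set(pairs)), t, prof, tbpp,
                         qbpp, params)
        v2 = total_score(a, ConsensusStructure(set(reversed(pairs))), t, prof,
                         tbpp, qbpp, params)
        assert v1 == v2

    def test_reduces_to_sequence_alignment_without_structure(self):
        # S = empty, linear gaps: standard semi-global alignment score,
        # cross-checked against an independent small NW implementation
        rng = np.random.default_rng(5)
        for _ in range(50):
            n, m = int(rng.integers(2, 9)), int(rng.integers(1, 6))
            ts = "".join("ACGU"[i] for i in rng.integers(0, 4, size=n))
            qs = "".join("ACGU"[i] for i in rng.integers(0, 4, size=m))
            t = TargetSequence("t", ts)
            q = QueryInput(rows=[qs])
            params = ScoreParams(gamma=-100, gap_opening=0, max_span=n)
            prof = build_profile(q, pseudocount_mass=0.0)
            best = _nw_semiglobal(ts, qs, prof, params)
            # exhaustive max of total_score over all alignments
            got = max(
                total_score(Alignment(set(e)), ConsensusStructure(set()), t,
                            prof, BppMatrix(n), BppMatrix(m), params)
                for e in _all_matchings(n, m)
            )
            assert got == best


def _all_matchings(n, m):
    out = []
    def rec(prefix, i0, k0):
        out.append(list(prefix))
        for i in range(i0, n + 1):
            for k in range(k0, m + 1):
                prefix.append((i, k))
                rec(prefix, i + 1, k + 1)
                prefix.pop()
    rec([], 1, 1)
    return out


def _nw_semiglobal(ts, qs, prof, params):
    """Textbook semi-global DP (free target end gaps), independent layout."""
    import numpy as np
    n, m = len(ts), len(qs)
    g = params.gamma
    S = np.full((n + 1, m + 1), -(10 ** 9), dtype=np.int64)
    S[:, 0] = 0
    for l in range(1, m + 1):
        S[0, l] = g * l
    for i in range(1, n + 1):
        for l in range(1, m + 1):
            S[i, l] = max(
                S[i - 1, l] + g,
                S[i, l - 1] + g,
                S[i - 1, l - 1] + sigma(ts[i - 1], l, prof),
            )
    return int(S[:, m].max())
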